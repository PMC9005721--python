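"""Final model fitting, suitability-map projection and map summaries.

After feature selection the forest is refitted on all assembled rows and
projected cellwise over an environmental stack, giving a habitat-suitability
map (occurrence probability in [0, 1] with the stack's NODATA mask).  Maps
are summarised by the reporting bands used throughout the analysis —
fraction of territory below 0.25 (likely unsuitable) and above 0.5 (likely
suitable) — plus the mean/max suitability and a spatial-block variability
diagnostic (mean over 100-km blocks of the within-block sd of predictions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import BlockTiling
from .grid_io import EnvStack, Grid
from .spatial_cv import RFParams, make_rf

__all__ = [
    "FittedModel",
    "SuitabilityMap",
    "AreaSummary",
    "fit_final_model",
    "project",
    "summarize",
    "compare_scenarios",
]


@dataclass
class FittedModel:
    """A trained occurrence classifier plus its variable ordering."""

    model: object
    variables: list[str]
    seed: int

    def predict_table(self, features: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in features.columns]
        if missing:
            raise ValueError(f"feature table missing variables: {missing}")
        X = features[self.variables].to_numpy(dtype=float)
        classes = list(self.model.classes_)
        return self.model.predict_proba(X)[:, classes.index(1)]


@dataclass
class SuitabilityMap:
    """Raster of predicted occurrence probabilities with provenance tags."""

    grid: Grid
    model_id: str
    stack_id: str
    scenario: str


@dataclass
class AreaSummary:
    """Band fractions and variability diagnostics of a suitability map."""

    fraction_below_low: float
    fraction_mid: float
    fraction_above_high: float
    mean_suitability: float
    max_suitability: float
    block_variability: float
    low: float
    high: float

    def as_dict(self) -> dict:
        return {
            "fraction_below_low": self.fraction_below_low,
            "fraction_mid": self.fraction_mid,
            "fraction_above_high": self.fraction_above_high,
            "mean_suitability": self.mean_suitability,
            "max_suitability": self.max_suitability,
            "block_variability": self.block_variability,
        }


def fit_final_model(
    features: pd.DataFrame,
    labels,
    selected_vars: list[str],
    rf_params: RFParams | None = None,
    seed: int = 0,
) -> FittedModel:
    """Train the final forest on all rows, restricted to selected variables."""
    missing = [v for v in selected_vars if v not in features.columns]
    if missing:
        raise ValueError(f"selected variables not in feature table: {missing}")
    model = make_rf(rf_params, seed=seed)
    model.fit(features[list(selected_vars)].to_numpy(dtype=float), np.asarray(labels, dtype=int))
    return FittedModel(model=model, variables=list(selected_vars), seed=seed)


def project(model: FittedModel, stack: EnvStack, scenario_tag: str = "present") -> SuitabilityMap:
    """Predict suitability for every unmasked cell of the stack.

    The stack must contain every selected variable (for future stacks the
    soil layers are expected to be carried over unchanged from the present).
    NODATA cells are preserved in the output mask.
    """
    missing = [v for v in model.variables if v not in stack]
    if missing:
        raise ValueError(f"stack is missing selected variable(s): {missing}")
    h = stack.header
    mask = stack.union_mask
    ok = ~mask
    X = np.column_stack([stack[v].values[ok] for v in model.variables])
    classes = list(model.model.classes_)
    probs = model.model.predict_proba(X)[:, classes.index(1)]
    values = np.zeros((h.nrows, h.ncols))
    values[ok] = probs
    return SuitabilityMap(
        grid=Grid(h, values, mask.copy()),
        model_id=f"rf-seed{model.seed}",
        stack_id=str(id(stack)),
        scenario=scenario_tag,
    )


def summarize(
    smap: SuitabilityMap,
    low: float = 0.25,
    high: float = 0.5,
    block_km: float = 100.0,
) -> AreaSummary:
    """Band fractions, mean/max suitability and block variability.

    Fractions are over unmasked cells; the three bands (p < low,
    low <= p <= high, p > high) partition them exactly.  Block variability
    is the mean over occupied blocks of the within-block population sd of
    cell predictions, blocks taken over cell centres.
    """
    grid = smap.grid
    ok = ~grid.mask
    n = int(ok.sum())
    if n == 0:
        raise ValueError("fully masked map: summary undefined")
    p = grid.values[ok]
    frac_low = float((p < low).sum() / n)
    frac_high = float((p > high).sum() / n)
    frac_mid = float(((p >= low) & (p <= high)).sum() / n)

    rows, cols = np.where(ok)
    lon, lat = grid.header.cell_center(rows, cols)
    centres = np.column_stack([lon, lat])
    tiling = BlockTiling.for_points(centres, block_km)
    ij = tiling.block_index(centres)
    _, block = np.unique(ij, axis=0, return_inverse=True)
    sds = [float(p[block == b].std()) for b in range(block.max() + 1)]
    return AreaSummary(
        fraction_below_low=frac_low,
        fraction_mid=frac_mid,
        fraction_above_high=frac_high,
        mean_suitability=float(p.mean()),
        max_suitability=float(p.max()),
        block_variability=float(np.mean(sds)),
        low=low,
        high=high,
    )


def compare_scenarios(
    maps: list[SuitabilityMap],
    low: float = 0.25,
    high: float = 0.5,
    block_km: float = 100.0,
) -> tuple[pd.DataFrame, dict[str, Grid]]:
    """Summarise a set of aligned scenario maps and difference them.

    The first map is the reference (present climate); difference maps are
    scenario minus reference on unmasked cells.
    """
    if not maps:
        raise ValueError("no maps")
    ref = maps[0]
    rows = []
    diffs: dict[str, Grid] = {}
    for m in maps:
        if not m.grid.header.aligned_with(ref.grid.header):
            raise ValueError(f"map {m.scenario!r} is not aligned with the reference")
        s = summarize(m, low=low, high=high, block_km=block_km)
        rows.append({"scenario": m.scenario, **s.as_dict()})
        if m is not ref:
            d = m.grid.values - ref.grid.values
            mask = m.grid.mask | ref.grid.mask
            d = np.where(mask, 0.0, d)
            diffs[m.scenario] = Grid(ref.grid.header, d, mask)
    return pd.DataFrame(rows), diffs
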