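"""Pseudo-absence generation and training-set assembly.

Presence-only data carries no negatives, so binary classification needs
artificial "absence" points.  Two strategies are combined: a *disk* strategy
that places background points no closer than an exclusion radius (default
25 km) to any presence, and a *filtered random* strategy that places points
only in the far north (default: latitude above 64 deg), where the species is
assumed physiologically excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid_io import EnvStack, Grid, extract_values
from .geo import pairwise_haversine_km

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoAbsenceConfig",
    "OccurrenceSet",
    "InfeasibleSamplingError",
    "generate_disk",
    "generate_random_filtered",
    "assemble_training_set",
]

_PROPOSAL_CAP_FACTOR = 1000


class InfeasibleSamplingError(RuntimeError):
    """Raised when a pseudo-absence constraint admits no (or too few) points."""


@dataclass
class PseudoAbsenceConfig:
    """Configuration of the combined disk + filtered-random strategy.

    ``n_total`` defaults to the presence count (1:1 class balance) when set
    to None in :func:`assemble_training_set`.
    """

    n_total: int | None = None
    disk_fraction: float = 0.5
    min_dist_km: float = 25.0
    random_lat_threshold: float = 64.0
    seed: int = 0
    #: optional sampling-effort grid; when set, disk pseudo-absences are
    #: drawn with the same spatial bias as the presence records
    effort: "Grid | None" = None

    def __post_init__(self) -> None:
        if self.n_total is not None and self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0.0 <= self.disk_fraction <= 1.0:
            raise ValueError("disk_fraction must be in [0, 1]")
        if self.min_dist_km <= 0:
            raise ValueError("min_dist_km must be > 0")


@dataclass
class OccurrenceSet:
    """Labelled point set: presences (label 1) and pseudo-absences (0)."""

    points: np.ndarray
    labels: np.ndarray
    source: list[str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary")
        if not (len(self.points) == len(self.labels) == len(self.source)):
            raise ValueError("points, labels and source must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lon": self.points[:, 0], "lat": self.points[:, 1], "label": self.labels, "source": self.source}
        )


def _unmasked_cells(domain: Grid) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.where(~domain.mask)
    if rows.size == 0:
        raise InfeasibleSamplingError("domain mask has no valid cells")
    return rows, cols


def _jitter_in_cells(header, rows, cols, rng) -> np.ndarray:
    n = rows.size
    lon = header.xllcorner + (cols + rng.uniform(0.0, 1.0, n)) * header.cellsize
    lat = header.ytop - (rows + rng.uniform(0.0, 1.0, n)) * header.cellsize
    return np.column_stack([lon, lat])


def generate_disk(
    presences,
    domain: Grid,
    n: int,
    min_dist_km: float = 25.0,
    seed: int = 0,
    effort: Grid | None = None,
) -> np.ndarray:
    """Disk-strategy pseudo-absences: uniform over the domain, but at least
    ``min_dist_km`` (haversine) from every presence.

    When an ``effort`` grid is given, proposal cells are drawn with
    probability proportional to it instead of uniformly, giving the
    pseudo-absences the same sampling bias as effort-driven presence records
    (the bias then cancels in the presence/background contrast).

    Rejection-samples jittered cell points until ``n`` are accepted; raises
    :class:`InfeasibleSamplingError` after ``1000 * n`` proposals.
    """
    presences = np.asarray(presences, dtype=float).reshape(-1, 2)
    if presences.shape[0] == 0:
        raise ValueError("at least one presence required")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.zeros((0, 2))
    rows, cols = _unmasked_cells(domain)
    weights = None
    if effort is not None:
        if not effort.header.aligned_with(domain.header):
            raise ValueError("effort grid is not aligned with the domain")
        w = effort.values[rows, cols]
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("effort weights must be non-negative with positive sum")
        weights = w / w.sum()
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    n_acc = 0
    proposals = 0
    cap = _PROPOSAL_CAP_FACTOR * n
    batch = max(4 * n, 256)
    while n_acc < n:
        if proposals >= cap:
            raise InfeasibleSamplingError(
                f"disk strategy: no admissible points at min_dist_km={min_dist_km} "
                f"after {proposals} proposals"
            )
        m = min(batch, cap - proposals)
        idx = rng.choice(rows.size, size=m, p=weights) if weights is not None else rng.integers(rows.size, size=m)
        cand = _jitter_in_cells(domain.header, rows[idx], cols[idx], rng)
        proposals += m
        d = pairwise_haversine_km(np.vstack([cand, presences]))[:m, m:]
        ok = d.min(axis=1) >= min_dist_km
        good = cand[ok]
        if good.shape[0]:
            accepted.append(good)
            n_acc += good.shape[0]
    return np.vstack(accepted)[:n]


def generate_random_filtered(
    domain: Grid,
    n: int,
    lat_threshold: float = 64.0,
    seed: int = 0,
) -> np.ndarray:
    """Filtered-random pseudo-absences: uniform over unmasked cells lying
    entirely north of ``lat_threshold``, jittered within the cell."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rows, cols = _unmasked_cells(domain)
    h = domain.header
    # southern edge of cell r is ytop - (r+1)*cellsize
    south_edge = h.ytop - (rows + 1) * h.cellsize
    ok = south_edge >= lat_threshold
    if not ok.any():
        raise InfeasibleSamplingError(
            f"no unmasked cells north of latitude {lat_threshold}"
        )
    if n == 0:
        return np.zeros((0, 2))
    rows, cols = rows[ok], cols[ok]
    rng = np.random.default_rng(seed)
    idx = rng.integers(rows.size, size=n)
    return _jitter_in_cells(h, rows[idx], cols[idx], rng)


def assemble_training_set(
    presences,
    config: PseudoAbsenceConfig,
    stack: EnvStack,
) -> tuple[OccurrenceSet, pd.DataFrame]:
    """Build the labelled modelling table: presences + pseudo-absences.

    ``round(disk_fraction * n_total)`` disk points and the remainder
    filtered-random points are generated, every point is pushed through
    covariate extraction, and rows falling outside the extent or on NODATA
    are dropped (count logged).

    Returns the assembled :class:`OccurrenceSet` and its feature table
    (columns ordered as ``stack.names``).
    """
    presences = np.asarray(presences, dtype=float).reshape(-1, 2)
    n_pres = presences.shape[0]
    if n_pres == 0:
        raise ValueError("no presences")
    n_total = config.n_total if config.n_total is not None else n_pres
    n_disk = int(round(config.disk_fraction * n_total))
    n_rand = n_total - n_disk

    domain = Grid(stack.header, np.zeros((stack.header.nrows, stack.header.ncols)), stack.union_mask)
    disk_pts = generate_disk(
        presences, domain, n_disk, config.min_dist_km, seed=config.seed, effort=config.effort
    )
    rand_pts = (
        generate_random_filtered(domain, n_rand, config.random_lat_threshold, seed=config.seed + 1)
        if n_rand > 0
        else np.zeros((0, 2))
    )

    points = np.vstack([presences, disk_pts, rand_pts])
    labels = np.concatenate([np.ones(n_pres, int), np.zeros(n_disk + n_rand, int)])
    source = ["presence"] * n_pres + ["pa_disk"] * n_disk + ["pa_random"] * n_rand

    features, valid = extract_values(stack, points)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("assemble_training_set: dropped %d point(s) with invalid covariates", n_dropped)
    occ = OccurrenceSet(
        points=points[valid],
        labels=labels[valid],
        source=[s for s, v in zip(source, valid) if v],
    )
    table = pd.DataFrame(features[valid], columns=stack.names)
    return occ, table
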