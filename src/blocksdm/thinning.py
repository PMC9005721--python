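"""Spatial thinning of occurrence records.

Citizen-science occurrence data over-represents accessible places, so record
density tracks recording effort rather than habitat quality.  Thinning
enforces a minimum nearest-neighbour distance between retained records: the
proximity graph (edges between points closer than the distance) is pruned by
repeatedly removing a random point of maximal degree until no edges remain.
Because the greedy rule is randomised, the procedure is repeated (default
100 iterations) and the iteration retaining the most points wins — an
approximation to the maximum independent set of the proximity graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import pairwise_haversine_km

__all__ = ["ThinningResult", "thin", "compare_thinnings", "DEFAULT_THINNING_DISTANCES_KM"]

#: Pipeline presets for the thinning-distance comparison.
DEFAULT_THINNING_DISTANCES_KM = (4.0, 7.0, 10.0)


@dataclass
class ThinningResult:
    """Outcome of repeated randomised thinning.

    ``retained`` indexes the input point array; no two retained points are
    closer than ``distance_km`` (haversine), and ``len(retained)`` equals the
    best (maximal) per-iteration retention count.
    """

    distance_km: float
    iterations: int
    retained: np.ndarray
    per_iteration_counts: list[int]
    seed: int

    @property
    def n_retained(self) -> int:
        return int(self.retained.size)


def thin(points, distance_km: float, iterations: int = 100, seed: int = 0) -> ThinningResult:
    """Thin a point set to a minimum inter-point distance.

    Parameters
    ----------
    points : (n, 2) lon/lat array-like.
    distance_km : minimum allowed haversine distance between retained points.
    iterations : number of randomised repetitions; the best iteration
        (maximal retention, first achieved on ties) provides the result.
    seed : RNG seed; results are deterministic given the seed.
    """
    if distance_km <= 0:
        raise ValueError("distance_km must be > 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n == 0:
        return ThinningResult(distance_km, iterations, np.zeros(0, dtype=int), [], seed)

    dist = pairwise_haversine_km(pts)
    adj = dist < distance_km
    np.fill_diagonal(adj, False)
    neighbours = [np.flatnonzero(adj[i]) for i in range(n)]
    degrees = adj.sum(axis=1).astype(np.int64)

    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    counts: list[int] = []
    for _ in range(iterations):
        alive = np.ones(n, dtype=bool)
        deg = degrees.copy()
        active = np.where(alive, deg, -1)
        while True:
            m = active.max()
            if m <= 0:
                break
            cand = np.flatnonzero(active == m)
            victim = int(cand[rng.integers(cand.size)])
            alive[victim] = False
            active[victim] = -1
            nb = neighbours[victim]
            live_nb = nb[alive[nb]]
            active[live_nb] -= 1
        kept = int(alive.sum())
        counts.append(kept)
        if best is None or kept > best.size:
            best = np.flatnonzero(alive)
    assert best is not None
    return ThinningResult(distance_km, iterations, best, counts, seed)


def compare_thinnings(datasets: dict, stack, config=None, truth=None):
    """Run the downstream pipeline once per thinned dataset and compare.

    Parameters
    ----------
    datasets : mapping label -> (n, 2) presence array.  Conventionally keyed
        by thinning distance in km, with e.g. ``"full"`` for the unthinned
        baseline.
    stack : EnvStack of environmental covariates.
    config : PipelineConfig (defaults used when None).
    truth : optional Grid of true suitability; when given, the report gains a
        ``rmse_truth`` column (synthetic benchmarking).

    Returns
    -------
    (report, outputs) : a pandas DataFrame with one row per dataset
        (n_points, cv AUC mean/sd, area fractions, block variability, and a
        ``suggested`` flag on the row maximising block variability) and a
        dict label -> per-dataset pipeline outputs (model, map, summary).
    """
    import pandas as pd

    from .pipeline import PipelineConfig, run_dataset

    if not datasets:
        raise ValueError("no datasets to compare")
    config = config or PipelineConfig()
    rows = []
    outputs = {}
    for label, pts in datasets.items():
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if pts.shape[0] == 0:
            raise ValueError(f"dataset {label!r} is empty")
        try:
            res = run_dataset(pts, stack, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for thinning dataset {label!r}") from exc
        outputs[label] = res
        summ = res["summary"]
        row = {
            "dataset": label,
            "n_points": pts.shape[0],
            "cv_auc_mean": res["cv_report"].auc_mean,
            "cv_auc_sd": res["cv_report"].auc_sd,
            "fraction_below_low": summ.fraction_below_low,
            "fraction_above_high": summ.fraction_above_high,
            "mean_suitability": summ.mean_suitability,
            "block_variability": summ.block_variability,
        }
        if truth is not None:
            m = res["map"].grid
            ok = ~(m.mask | truth.mask)
            row["rmse_truth"] = float(np.sqrt(np.mean((m.values[ok] - truth.values[ok]) ** 2)))
        rows.append(row)
    report = pd.DataFrame(rows)
    suggested = report["block_variability"].idxmax()
    report["suggested"] = False
    report.loc[suggested, "suggested"] = True
    return report, outputs
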