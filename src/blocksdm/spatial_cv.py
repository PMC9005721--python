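"""Spatial-block cross-validation and ROC-AUC.

Occurrence data is spatially autocorrelated: random train/test splits leak
near-duplicate neighbours across the split and report optimistic scores.
Block CV assigns contiguous square geographic blocks (default edge 100 km),
not individual points, to folds (default k = 13), and repeats the random
block-to-fold assignment (default 20 times).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .geo import BlockTiling

logger = logging.getLogger(__name__)

__all__ = [
    "RFParams",
    "make_rf",
    "BlockFoldAssignment",
    "CVReport",
    "UndefinedAUCError",
    "make_folds",
    "make_random_folds",
    "roc_auc",
    "cross_validate",
]


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters (binary occurrence classifier).

    Defaults: 500 trees, sqrt(p) candidate features per split, unlimited
    depth, plain bootstrap.
    """

    n_estimators: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    min_samples_leaf: int = 1
    class_weight: str | None = None
    n_jobs: int = 1


def make_rf(params: RFParams | None = None, seed: int = 0) -> RandomForestClassifier:
    p = params or RFParams()
    return RandomForestClassifier(
        n_estimators=p.n_estimators,
        max_features=p.max_features,
        max_depth=p.max_depth,
        min_samples_leaf=p.min_samples_leaf,
        class_weight=p.class_weight,
        n_jobs=p.n_jobs,
        random_state=int(seed) % (2**31),
    )


class UndefinedAUCError(ValueError):
    """ROC-AUC is undefined when only one class is present."""


def roc_auc(scores, labels) -> float:
    """Tie-aware ROC-AUC: (concordant + 0.5 * tied pairs) / (n_pos * n_neg).

    Computed via the Mann-Whitney rank-sum identity with average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class BlockFoldAssignment:
    """Point -> block and block -> fold maps for one CV repeat."""

    point_block: np.ndarray  # (n,) integer block id per point
    block_fold: dict[int, int]  # block id -> fold in 1..k
    k: int
    block_km: float
    repeat_id: int
    tiling: BlockTiling | None = None

    @property
    def point_fold(self) -> np.ndarray:
        return np.array([self.block_fold[b] for b in self.point_block])

    def test_mask(self, fold: int) -> np.ndarray:
        return self.point_fold == fold


def make_folds(
    points,
    block_km: float = 100.0,
    k: int = 13,
    repeats: int = 20,
    seed: int = 0,
) -> list[BlockFoldAssignment]:
    """Assign 100-km-style square blocks to k folds, `repeats` times.

    Every point in a block shares the block's fold.  If a random assignment
    leaves a fold empty it is repaired by moving one block from the largest
    fold, keeping all k folds populated on small point sets.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if k < 2:
        raise ValueError("k must be >= 2")
    tiling = BlockTiling.for_points(pts, block_km)
    ij = tiling.block_index(pts)
    # encode (i, j) pairs as single ids
    _, point_block = np.unique(ij, axis=0, return_inverse=True)
    n_blocks = int(point_block.max()) + 1
    if n_blocks < k:
        raise ValueError(
            f"only {n_blocks} spatial blocks for k={k} folds; use a smaller block_km"
        )
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(repeats):
        fold_of_block = rng.integers(1, k + 1, size=n_blocks)
        # repair empty folds by stealing a block from the largest fold
        for f in range(1, k + 1):
            while (fold_of_block == f).sum() == 0:
                counts = np.bincount(fold_of_block, minlength=k + 1)
                donor = int(np.argmax(counts[1:])) + 1
                movable = np.flatnonzero(fold_of_block == donor)
                fold_of_block[movable[rng.integers(movable.size)]] = f
        out.append(
            BlockFoldAssignment(
                point_block=point_block,
                block_fold={b: int(fold_of_block[b]) for b in range(n_blocks)},
                k=k,
                block_km=block_km,
                repeat_id=rep,
                tiling=tiling,
            )
        )
    return out


def make_random_folds(points, k: int = 13, repeats: int = 20, seed: int = 0) -> list[BlockFoldAssignment]:
    """Conventional (non-spatial) random k-fold splits in the same container:
    every point is its own block.  Used to quantify the optimism that block
    CV removes."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer points than folds")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(repeats):
        folds = np.ones(n, dtype=int)
        perm = rng.permutation(n)
        for f in range(k):
            folds[perm[f::k]] = f + 1
        out.append(
            BlockFoldAssignment(
                point_block=np.arange(n),
                block_fold={i: int(folds[i]) for i in range(n)},
                k=k,
                block_km=0.0,
                repeat_id=rep,
            )
        )
    return out


@dataclass
class CVReport:
    """Per-fold AUC bookkeeping plus the aggregate mean/sd.

    Folds where either the training or the test side has a single class are
    recorded as skipped, never imputed.
    """

    table: pd.DataFrame
    auc_mean: float = field(init=False)
    auc_sd: float = field(init=False)

    def __post_init__(self) -> None:
        defined = self.table.loc[~self.table["skipped"], "auc"]
        self.auc_mean = float(defined.mean()) if len(defined) else float("nan")
        self.auc_sd = float(defined.std(ddof=1)) if len(defined) > 1 else 0.0


def cross_validate(
    features,
    labels,
    assignments: Sequence[BlockFoldAssignment],
    rf_params: RFParams | None = None,
    seed: int = 0,
) -> CVReport:
    """Repeated block-CV evaluation of a random forest.

    For each repeat and fold: fit on the training blocks, score the test
    blocks with class-probability votes, and compute tie-aware ROC-AUC.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rows = []
    for a in assignments:
        point_fold = a.point_fold
        for f in range(1, a.k + 1):
            test = point_fold == f
            train = ~test
            n_tp = int(y[test].sum())
            n_ta = int((y[test] == 0).sum())
            rec = {
                "repeat": a.repeat_id,
                "fold": f,
                "n_test_presence": n_tp,
                "n_test_absence": n_ta,
                "auc": np.nan,
                "skipped": True,
            }
            if test.sum() == 0 or train.sum() == 0 or len(np.unique(y[train])) < 2 or n_tp == 0 or n_ta == 0:
                logger.debug("skipping degenerate fold %d of repeat %d", f, a.repeat_id)
            else:
                model = make_rf(rf_params, seed=seed + 1000 * a.repeat_id + f)
                model.fit(X[train], y[train])
                scores = model.predict_proba(X[test])[:, list(model.classes_).index(1)]
                rec["auc"] = roc_auc(scores, y[test])
                rec["skipped"] = False
            rows.append(rec)
    return CVReport(table=pd.DataFrame(rows))
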