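"""Two-stage covariate selection: correlation grouping, then importance.

Bioclimatic layers are heavily redundant (e.g. annual mean temperature vs
mean temperature of the coldest quarter), and random forests dilute
importance across correlated copies.  Selection therefore proceeds in two
stages: (1) group variables into connected components of the |Pearson r| >=
threshold graph (default threshold 0.8); (2) rank all variables by Mean
Decrease Gini (MDG) and Mean Decrease Accuracy (MDA) and resolve each
correlated group down to a single representative — when the two rankings
disagree about a group's best member, one candidate model per contender is
fitted (excluding the rest of the group) and the cross-validated AUC decides.
Every keep/drop decision is recorded in an audit log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .spatial_cv import RFParams, cross_validate, make_folds, make_random_folds, make_rf

logger = logging.getLogger(__name__)

__all__ = ["CorrelationGroups", "correlation_groups", "importance", "select_features"]


@dataclass
class CorrelationGroups:
    """Pearson matrix plus connected components at |r| >= threshold."""

    matrix: pd.DataFrame
    groups: list[list[str]]
    threshold: float
    excluded: list[str]  # zero-variance columns, flagged and left out

    def group_of(self, name: str) -> list[str]:
        for g in self.groups:
            if name in g:
                return g
        raise KeyError(name)


def correlation_groups(features: pd.DataFrame, threshold: float = 0.8) -> CorrelationGroups:
    """Group covariates by the |Pearson r| >= threshold graph.

    Zero-variance columns have undefined correlations: they are excluded
    from grouping with a warning and listed in ``excluded``.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 rows")
    if not np.isfinite(features.to_numpy()).all():
        raise ValueError("non-finite values in feature table")
    variances = features.var(axis=0, ddof=0)
    excluded = list(features.columns[variances == 0.0])
    if excluded:
        warnings.warn(f"zero-variance columns excluded from selection: {excluded}")
    cols = [c for c in features.columns if c not in excluded]
    X = features[cols].to_numpy()
    r = np.corrcoef(X, rowvar=False) if len(cols) > 1 else np.ones((len(cols), len(cols)))
    matrix = pd.DataFrame(r, index=cols, columns=cols)
    adj = (np.abs(r) >= threshold).astype(int)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[c for c, l in zip(cols, labels) if l == comp] for comp in range(n_comp)]
    return CorrelationGroups(matrix=matrix, groups=groups, threshold=threshold, excluded=excluded)


def importance(
    features: pd.DataFrame,
    labels,
    rf_params: RFParams | None = None,
    n_permutations: int = 10,
    seed: int = 0,
    holdout_fraction: float = 0.25,
) -> pd.DataFrame:
    """MDG and MDA importance of every covariate.

    A forest is fitted on a stratified internal training split; MDG is the
    forest's mean decrease in Gini impurity, MDA the mean drop in held-out
    accuracy over ``n_permutations`` column permutations.  Rank 1 = most
    important; ranks are returned for both scores.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = features.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=seed % (2**31)
    )
    model = make_rf(rf_params, seed=seed)
    model.fit(X_tr, y_tr)
    mdg = model.feature_importances_
    perm = permutation_importance(
        model, X_te, y_te, scoring="accuracy", n_repeats=n_permutations, random_state=seed % (2**31)
    )
    mda = perm.importances_mean
    table = pd.DataFrame({"mdg": mdg, "mda": mda}, index=list(features.columns))
    table["rank_mdg"] = table["mdg"].rank(ascending=False, method="first").astype(int)
    table["rank_mda"] = table["mda"].rank(ascending=False, method="first").astype(int)
    return table


def select_features(
    features: pd.DataFrame,
    labels,
    threshold: float = 0.8,
    rf_params: RFParams | None = None,
    seed: int = 0,
    points=None,
    cv_k: int = 5,
    cv_repeats: int = 2,
    cv_block_km: float = 100.0,
    n_permutations: int = 10,
) -> tuple[list[str], dict]:
    """Select a non-redundant, important covariate subset.

    Procedure: (1) correlation groups at ``threshold``; (2) MDG/MDA
    importances over all (non-degenerate) variables; (3) singleton groups are
    kept when ranked in the top half by MDG *or* MDA; (4) each multi-member
    group is resolved to one representative — the member best by both
    rankings if unambiguous, otherwise the contender (best-by-MDG vs
    best-by-MDA) whose candidate model, fitted with the group's other members
    excluded, achieves the higher cross-validated AUC.  Spatial-block CV is
    used when point coordinates are supplied, conventional random folds
    otherwise.

    Returns the ordered selected list and an audit log (JSON-serialisable
    dict) of every decision.
    """
    y = np.asarray(labels, dtype=int)
    cg = correlation_groups(features, threshold)
    usable = [c for c in features.columns if c not in cg.excluded]
    imp = importance(features[usable], y, rf_params=rf_params, n_permutations=n_permutations, seed=seed)
    n = len(usable)
    half = int(np.ceil(n / 2))
    audit: dict = {
        "threshold": threshold,
        "excluded_zero_variance": cg.excluded,
        "groups": cg.groups,
        "importance": imp.reset_index(names="variable").to_dict(orient="records"),
        "decisions": [],
    }

    selected: list[str] = []
    for group in cg.groups:
        if len(group) == 1:
            v = group[0]
            top = bool(imp.loc[v, "rank_mdg"] <= half or imp.loc[v, "rank_mda"] <= half)
            audit["decisions"].append(
                {
                    "group": group,
                    "kept": v if top else None,
                    "rule": "singleton_top_half" if top else "singleton_dropped",
                    "rank_mdg": int(imp.loc[v, "rank_mdg"]),
                    "rank_mda": int(imp.loc[v, "rank_mda"]),
                }
            )
            if top:
                selected.append(v)
            continue
        best_mdg = imp.loc[group, "mdg"].idxmax()
        best_mda = imp.loc[group, "mda"].idxmax()
        if best_mdg == best_mda:
            audit["decisions"].append(
                {"group": group, "kept": best_mdg, "rule": "group_consensus"}
            )
            selected.append(best_mdg)
            continue
        # rankings disagree: fit one candidate model per contender and let
        # cross-validated AUC decide
        aucs = {}
        for cand in (best_mdg, best_mda):
            cand_cols = [c for c in usable if c not in group or c == cand]
            if points is not None:
                folds = make_folds(points, block_km=cv_block_km, k=cv_k, repeats=cv_repeats, seed=seed + 17)
            else:
                folds = make_random_folds(features.to_numpy(), k=cv_k, repeats=cv_repeats, seed=seed + 17)
            rep = cross_validate(features[cand_cols], y, folds, rf_params=rf_params, seed=seed + 29)
            aucs[cand] = rep.auc_mean
        winner = max(aucs, key=lambda c: aucs[c])
        audit["decisions"].append(
            {
                "group": group,
                "kept": winner,
                "rule": "group_cv_tiebreak",
                "contenders": {c: float(a) for c, a in aucs.items()},
            }
        )
        selected.append(winner)

    ordered = [c for c in features.columns if c in selected]
    audit["selected"] = ordered
    return ordered, audit
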