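import numpy as np
import pandas as pd
import pytest

from blocksdm.feature_selection import correlation_groups, importance, select_features
from blocksdm.spatial_cv import RFParams

FAST_RF = RFParams(n_estimators=100)


def noise_frame(rng, n, cols):
    return pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)


class TestCorrelationGroups:
    def test_duplicated_column_is_grouped(self):
        rng = np.random.default_rng(1)
        df = noise_frame(rng, 200, ["a", "b"])
        df["a2"] = df["a"]
        cg = correlation_groups(df, 0.8)
        assert sorted(cg.group_of("a")) == ["a", "a2"]

    def test_independent_noise_gives_singletons(self):
        rng = np.random.default_rng(2)
        df = noise_frame(rng, 500, list("abcde"))
        cg = correlation_groups(df, 0.8)
        assert all(len(g) == 1 for g in cg.groups)

    def test_engineered_pair_is_grouped(self, world, training):
        _, feat = training
        cg = correlation_groups(feat, 0.8)
        assert "BIO11" in cg.group_of("BIO1")

    def test_matrix_matches_two_pass_pearson_oracle(self):
        rng = np.random.default_rng(3)
        df = noise_frame(rng, 60, list("abcd"))
        cg = correlation_groups(df, 0.8)
        X = df.to_numpy()
        for i, ci in enumerate(df.columns):
            for j, cj in enumerate(df.columns):
                x, y = X[:, i], X[:, j]
                xm, ym = x - x.mean(), y - y.mean()
                r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
                assert cg.matrix.loc[ci, cj] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_column_is_flagged_and_excluded(self):
        rng = np.random.default_rng(4)
        df = noise_frame(rng, 100, ["a", "b"])
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            cg = correlation_groups(df, 0.8)
        assert cg.excluded == ["flat"]
        assert "flat" not in cg.matrix.columns


class TestImportance:
    def test_planted_signal_ranks_first_by_both_scores(self):
        rng = np.random.default_rng(5)
        df = noise_frame(rng, 500, [f"v{i}" for i in range(6)])
        y = (df["v3"] > 0).astype(int)
        table = importance(df, y, rf_params=FAST_RF, seed=6)
        assert table.loc["v3", "rank_mdg"] == 1
        assert table.loc["v3", "rank_mda"] == 1

    def test_pure_noise_variable_has_null_mda(self):
        rng = np.random.default_rng(6)
        mdas = []
        for seed in range(20):
            df = noise_frame(rng, 200, ["signal", "noise"])
            y = (df["signal"] > 0).astype(int)
            t = importance(df, y, rf_params=FAST_RF, seed=seed)
            mdas.append(t.loc["noise", "mda"])
        mdas = np.asarray(mdas)
        assert abs(mdas.mean()) <= 2 * mdas.std()

    def test_duplicate_splits_importance_between_copies(self):
        rng = np.random.default_rng(7)
        df = noise_frame(rng, 500, ["s", "n1", "n2"])
        y = (df["s"] > 0).astype(int)
        solo = importance(df, y, rf_params=FAST_RF, seed=8)
        dup = df.copy()
        dup["s_copy"] = dup["s"]
        both = importance(dup, y, rf_params=FAST_RF, seed=8)
        assert both.loc["s", "mdg"] < solo.loc["s", "mdg"]
        assert both.loc["s", "mdg"] + both.loc["s_copy", "mdg"] >= both.loc["s", "mdg"]

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(8)
        df = noise_frame(rng, 50, ["a"])
        with pytest.raises(ValueError, match="class"):
            importance(df, np.ones(50, dtype=int), rf_params=FAST_RF)

    def test_ranks_are_permutations(self):
        rng = np.random.default_rng(9)
        df = noise_frame(rng, 300, [f"v{i}" for i in range(5)])
        y = (df["v0"] + df["v1"] > 0).astype(int)
        t = importance(df, y, rf_params=FAST_RF, seed=10)
        assert sorted(t["rank_mdg"]) == [1, 2, 3, 4, 5]
        assert sorted(t["rank_mda"]) == [1, 2, 3, 4, 5]


class TestSelectFeatures:
    def test_informative_singletons_kept_noise_dropped(self):
        rng = np.random.default_rng(10)
        df = noise_frame(rng, 400, ["a", "b", "n1", "n2"])
        y = ((df["a"] + df["b"]) > 0).astype(int)
        selected, audit = select_features(df, y, rf_params=FAST_RF, seed=11)
        assert "a" in selected and "b" in selected

    def test_at_most_one_member_per_group_selected(self, training):
        occ, feat = training
        selected, audit = select_features(
            feat, occ.labels, rf_params=FAST_RF, seed=12, points=occ.points
        )
        assert not ("BIO1" in selected and "BIO11" in selected)
        for decision in audit["decisions"]:
            group = set(decision["group"])
            assert len(group & set(selected)) <= 1

    def test_selection_is_deterministic(self, training):
        occ, feat = training
        a, _ = select_features(feat, occ.labels, rf_params=FAST_RF, seed=13, points=occ.points)
        c, _ = select_features(feat, occ.labels, rf_params=FAST_RF, seed=13, points=occ.points)
        assert a == c

    def test_audit_log_covers_every_group(self, training):
        occ, feat = training
        selected, audit = select_features(
            feat, occ.labels, rf_params=FAST_RF, seed=14, points=occ.points
        )
        audited = sorted(v for d in audit["decisions"] for v in d["group"])
        assert audited == sorted(feat.columns)
        assert audit["selected"] == selected

    def test_manual_override_accepts_published_style_list(self, world):
        # a fixed 8-variable list (as a completed analysis would pin down)
        # must be accepted verbatim by the pipeline config
        from blocksdm.pipeline import PipelineConfig, run_dataset

        manual = ["SOC", "CEC", "BIO1", "BIO8", "BIO10", "BIO13", "BIO15", "BIO19"]
        rng = np.random.default_rng(15)
        presences = np.column_stack([rng.uniform(32, 58, 60), rng.uniform(42, 62, 60)])
        cfg = PipelineConfig(
            selected_vars=manual, rf_params=FAST_RF, cv_repeats=2, cv_folds=5, seed=16
        )
        res = run_dataset(presences, world.stack, cfg)
        assert res["selected"] == manual
        assert res["model"].variables == manual
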