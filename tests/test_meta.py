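import math

import numpy as np
import pandas as pd
import pytest

from rhizometa import meta as ma
from rhizometa import synth

# Fixed 12-study dataset cross-checked against R metafor 4.8 (method="DL",
# regtest model="lm", trimfill estimator="L0" on the fixed-effect model).
ORACLE_Y = np.array([0.2762, -0.06, 0.3876, 0.4351, -0.2878, -0.1255,
                     0.232, 0.1209, 0.1958, -0.0133, 0.4198, 0.3944])
ORACLE_V = np.array([0.03397, 0.04202, 0.02495, 0.01523, 0.02996, 0.00787,
                     0.04224, 0.03342, 0.03911, 0.02095, 0.04868, 0.04519])
ORACLE_TAU2 = 0.04178971
ORACLE_MEAN = 0.1524737
ORACLE_EGGER_P = 0.2000306
ORACLE_TRIMFILL_K0 = 5


def _records(y, v):
    return [ma.EffectRecord(f"s{i:02d}", "var", 1, 1, 0, 0, 5, 5,
                            lnrr=float(a), v=float(b))
            for i, (a, b) in enumerate(zip(y, v))]


class TestEffectFromGroups:
    def test_identity_ratio(self):
        rec = ma.effect_from_groups([3, 3, 3], [3, 3, 3], "s", "v")
        assert rec.lnrr == 0.0
        assert rec.v == 0.0

    def test_worked_example(self):
        # group means 12 vs 10, SDs 2 vs 1, n = 5 each
        rhizo = np.array([12.0] * 5)
        rhizo = rhizo + (np.array([-1, -0.5, 0, 0.5, 1]) * 2 / np.std(
            [-1, -0.5, 0, 0.5, 1], ddof=1))
        bulk = np.array([10.0] * 5) + (np.array([-1, -0.5, 0, 0.5, 1]) * 1 / np.std(
            [-1, -0.5, 0, 0.5, 1], ddof=1))
        rec = ma.effect_from_groups(rhizo, bulk, "s", "v")
        assert rec.x_t == pytest.approx(12.0)
        assert rec.s_t == pytest.approx(2.0)
        assert rec.lnrr == pytest.approx(0.18232, abs=1e-5)
        assert rec.v == pytest.approx(0.0075556, abs=1e-5)

    def test_non_positive_mean_skipped(self):
        assert ma.effect_from_groups([-1, 1], [1, 1], "s", "v") is None

    def test_single_sample_group_flagged(self):
        rec = ma.effect_from_groups([2.0], [1.0, 1.0], "s", "v")
        assert rec.degenerate
        assert rec.s_t == 0.0


class TestRandomEffectsPool:
    def test_matches_metafor_oracle(self):
        recs = _records(ORACLE_Y, ORACLE_V)
        s = ma.random_effects_pool(recs, n_boot=199, seed=0)
        assert s.tau2 == pytest.approx(ORACLE_TAU2, abs=1e-6)
        assert s.mean_lnrr == pytest.approx(ORACLE_MEAN, abs=1e-6)

    def test_homogeneous_studies(self):
        recs = _records([0.3] * 5, [0.01] * 5)
        s = ma.random_effects_pool(recs, n_boot=99, seed=1)
        assert s.mean_lnrr == pytest.approx(0.3)
        assert s.tau2 == pytest.approx(0.0)

    def test_percent_change_of_ln2(self):
        assert ma.percent_change(math.log(2)) == pytest.approx(100.0)

    def test_percent_change_round_trips(self):
        recs = _records(ORACLE_Y, ORACLE_V)
        s = ma.random_effects_pool(recs, n_boot=99, seed=0)
        assert math.log(1 + s.pct_change / 100) == pytest.approx(
            s.mean_lnrr, abs=1e-12)

    def test_bootstrap_is_deterministic_under_seed(self):
        recs = _records(ORACLE_Y, ORACLE_V)
        a = ma.random_effects_pool(recs, n_boot=299, seed=7)
        b = ma.random_effects_pool(recs, n_boot=299, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_swapping_groups_negates_pooled_mean(self):
        rng = np.random.default_rng(2)
        groups = synth.simulate_group_values(0.2, 0.01, 10, 5, cv=0.1, seed=3)
        fwd = [ma.effect_from_groups(t, c, s, "v") for s, t, c in groups]
        rev = [ma.effect_from_groups(c, t, s, "v") for s, t, c in groups]
        sf = ma.random_effects_pool(fwd, n_boot=99, seed=4)
        sr = ma.random_effects_pool(rev, n_boot=99, seed=4)
        assert sf.mean_lnrr == pytest.approx(-sr.mean_lnrr, abs=1e-12)

    def test_pooled_mean_invariant_to_ordering_and_common_scale(self):
        groups = synth.simulate_group_values(0.1, 0.02, 8, 4, cv=0.15, seed=5)
        recs = [ma.effect_from_groups(t, c, s, "v") for s, t, c in groups]
        scaled = [ma.effect_from_groups(3.7 * t, 3.7 * c, s, "v")
                  for s, t, c in groups]
        base = ma.random_effects_pool(recs, n_boot=49, seed=0).mean_lnrr
        assert ma.random_effects_pool(recs[::-1], n_boot=49, seed=0
                                      ).mean_lnrr == pytest.approx(base, abs=1e-9)
        assert ma.random_effects_pool(scaled, n_boot=49, seed=0
                                      ).mean_lnrr == pytest.approx(base, abs=1e-9)

    def test_degenerate_case_flagged(self):
        recs = _records([0.2] * 4, [0.0] * 4)
        s = ma.random_effects_pool(recs, n_boot=49, seed=0)
        assert s.degenerate_ci
        assert s.ci_low == s.ci_high == pytest.approx(0.2)

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ma.random_effects_pool(_records([0.1], [0.01]))


class TestSubgroupAnalysis:
    def test_small_subgroup_excluded(self, caplog):
        groups = synth.simulate_group_values(0.1, 0.01, 25, 5, cv=0.1, seed=6)
        recs = [ma.effect_from_groups(t, c, s, "v") for s, t, c in groups]
        labels = {r.study_id: ("big" if i < 16 else "small")
                  for i, r in enumerate(recs)}  # small has 9 studies
        with caplog.at_level("INFO", logger="rhizometa"):
            summaries, part = ma.subgroup_analysis(recs, labels, min_k=10,
                                                   n_boot=49, seed=0)
        assert [s.group for s in summaries] == ["big"]
        assert part is None
        assert "excluded" in caplog.text

    def test_partition_identity(self):
        groups = synth.simulate_group_values(0.1, 0.02, 30, 5, cv=0.15, seed=8)
        recs = [ma.effect_from_groups(t, c, s, "v") for s, t, c in groups]
        labels = {r.study_id: ("A" if i % 2 else "B") for i, r in enumerate(recs)}
        _, part = ma.subgroup_analysis(recs, labels, min_k=10, n_boot=49, seed=0)
        assert part.q_total == pytest.approx(part.q_within + part.q_between,
                                             abs=1e-9)
        assert part.q_between >= -1e-12
        assert part.df_between == 1


class TestEgger:
    def test_symmetric_funnel_zero_intercept(self):
        # effects mirrored around 0 at matched precisions
        v = np.array([0.01, 0.02, 0.04, 0.01, 0.02, 0.04])
        y = np.array([0.1, 0.2, 0.3, -0.1, -0.2, -0.3])
        res = ma.egger_test(_records(y, v))
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_metafor_oracle(self):
        res = ma.egger_test(_records(ORACLE_Y, ORACLE_V))
        assert res["p_value"] == pytest.approx(ORACLE_EGGER_P, abs=1e-6)

    def test_zero_variance_records_excluded(self, caplog):
        y = np.concatenate([ORACLE_Y, [0.5]])
        v = np.concatenate([ORACLE_V, [0.0]])
        with caplog.at_level("WARNING", logger="rhizometa"):
            res = ma.egger_test(_records(y, v))
        assert res["k"] == len(ORACLE_Y)

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ma.egger_test(_records([0.1, 0.2], [0.01, 0.01]))


class TestTrimAndFill:
    def test_symmetric_set_imputes_nothing(self):
        v = np.array([0.01, 0.02, 0.04, 0.01, 0.02, 0.04])
        y = np.array([0.1, 0.2, 0.3, -0.1, -0.2, -0.3])
        res = ma.trim_and_fill(_records(y, v), side="left")
        assert res.k0 == 0
        assert res.adjusted_mean == pytest.approx(res.unadjusted_mean)

    def test_matches_metafor_oracle(self):
        res = ma.trim_and_fill(_records(ORACLE_Y, ORACLE_V), side="left")
        assert res.k0 == ORACLE_TRIMFILL_K0
        assert res.converged

    def test_imputed_records_mirror_through_center(self):
        res = ma.trim_and_fill(_records(ORACLE_Y, ORACLE_V), side="left")
        funnel = res.funnel
        imputed = funnel[funnel["imputed"]]["lnrr"].to_numpy()
        observed = funnel[~funnel["imputed"]]["lnrr"].to_numpy()
        assert len(imputed) == res.k0
        # every imputed effect is the mirror image of an observed one
        trimmed_top = np.sort(observed)[-res.k0:]
        center = (np.sort(imputed)[::-1] + trimmed_top) / 2
        assert np.allclose(center, center[0])

    def test_estimator_flag_validated(self):
        with pytest.raises(ValueError, match="estimator"):
            ma.trim_and_fill(_records(ORACLE_Y, ORACLE_V), estimator="X0")


class TestPredictorImportance:
    def test_strong_predictor_recovered(self):
        hits_signal, noise_ok = 0, 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(9000 + rep)
            n = 60
            x = pd.DataFrame(rng.normal(size=(n, 4)),
                             columns=["signal", "n1", "n2", "n3"])
            v = rng.uniform(0.005, 0.02, n)
            y = 0.5 * x["signal"].to_numpy() + rng.normal(0, np.sqrt(v))
            imp = ma.predictor_importance(y, v, x)
            hits_signal += imp.loc["signal", "importance"] > 0.8
            noise_ok += imp.loc[["n1", "n2", "n3"], "importance"].max() < 0.8
        assert hits_signal >= 18
        assert noise_ok >= 18

    def test_importances_within_unit_interval(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.normal(size=30)
        v = np.full(30, 0.01)
        imp = ma.predictor_importance(y, v, x)
        assert ((imp["importance"] >= 0) & (imp["importance"] <= 1)).all()

    def test_duplicating_rows_preserves_ranking(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = 0.4 * x["a"].to_numpy() + rng.normal(0, 0.1, 40)
        v = np.full(40, 0.01)
        order1 = list(ma.predictor_importance(y, v, x).index)
        x2 = pd.concat([x, x], ignore_index=True)
        order2 = list(ma.predictor_importance(np.tile(y, 2), np.tile(v, 2), x2).index)
        assert order1 == order2

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        x["b"] = x["a"]
        with pytest.raises(ValueError, match="'a' and 'b'"):
            ma.predictor_importance(rng.normal(size=30), np.full(30, 0.01), x)

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(30, 7)))
        x.columns = [f"p{i}" for i in range(7)]
        with pytest.raises(ValueError, match="at most 6"):
            ma.predictor_importance(rng.normal(size=30), np.full(30, 0.01), x)
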