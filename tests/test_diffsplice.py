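import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crypticsplice import (
    ConfigurationError,
    DiffSpliceConfig,
    IntegrityError,
    SimulationConfig,
    apply_thresholds,
    build_psi_matrix,
    detect_events,
    differential_test,
    filter_and_impute,
    simulate_cohort,
    standardize,
    transform_psi,
)


def _matrix(rows, samples=None):
    df = pd.DataFrame(rows)
    df.index = [f"e{i}" for i in range(len(df))]
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


def pooled_t_oracle(x, y):
    """Textbook pooled two-sample t: independent of the implementation path."""
    nx, ny = len(x), len(y)
    sx2 = sum((v - sum(x) / nx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - sum(y) / ny) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    t = (sum(x) / nx - sum(y) / ny) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * stats.t.sf(abs(t), nx + ny - 2)
    return t, p


class TestTransform:
    def test_ln_of_one_is_zero(self):
        out = transform_psi(_matrix([[0.0]]), x=1.0)
        assert out.iloc[0, 0] == 0.0

    def test_closed_form(self):
        out = transform_psi(_matrix([[0.3]]), x=0.01)
        assert out.iloc[0, 0] == pytest.approx(math.log(0.31), abs=1e-12)

    def test_missing_propagates(self):
        out = transform_psi(_matrix([[0.5, np.nan]]), x=0.01)
        assert np.isnan(out.iloc[0, 1]) and not np.isnan(out.iloc[0, 0])

    def test_invalid_pseudocount(self):
        with pytest.raises(ConfigurationError):
            transform_psi(_matrix([[0.5]]), x=0.0)

    def test_out_of_range_psi_rejected(self):
        with pytest.raises(IntegrityError):
            transform_psi(_matrix([[1.5]]), x=0.01)


class TestFilterImpute:
    def test_constant_event_removed(self):
        out = filter_and_impute(_matrix([[0.2, 0.2, 0.2, 0.2], [0.1, 0.2, 0.3, 0.4]]))
        assert list(out.index) == ["e1"]

    def test_all_missing_event_removed(self):
        out = filter_and_impute(_matrix([[np.nan] * 3, [0.1, 0.2, 0.3]]))
        assert list(out.index) == ["e1"]

    def test_mean_imputation_uses_event_mean(self):
        out = filter_and_impute(_matrix([[0.1, np.nan, 0.3]]))
        assert out.iloc[0, 1] == pytest.approx(0.2)
        assert not out.isna().any().any()


class TestStandardize:
    def test_closed_form_population_sd(self):
        out = standardize(_matrix([[1.0, 2.0, 3.0]]))
        expected = [-math.sqrt(3 / 2), 0.0, math.sqrt(3 / 2)]
        assert np.allclose(out.iloc[0], expected, atol=1e-12)
        assert np.allclose(out.iloc[0], [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.random((20, 7)))
        out = standardize(m)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_residual_zero_variance_rejected(self):
        with pytest.raises(IntegrityError):
            standardize(_matrix([[0.5, 0.5, 0.5]]))

    def test_t_statistic_invariant_under_standardization(self):
        """Location-scale invariance of t, checked numerically."""
        rng = np.random.default_rng(1)
        m = _matrix(rng.random((30, 7)))
        std = standardize(m)
        for i in range(len(m)):
            t_raw = stats.ttest_ind(m.iloc[i, 3:], m.iloc[i, :3]).statistic
            t_std = stats.ttest_ind(std.iloc[i, 3:], std.iloc[i, :3]).statistic
            assert t_raw == pytest.approx(t_std, abs=1e-9)


class TestDifferentialTest:
    GROUPS = {"w1": "WT", "w2": "WT", "w3": "WT", "m1": "MUT", "m2": "MUT", "m3": "MUT"}

    def test_matches_textbook_oracle_through_the_full_chain(self):
        """The reported t/p equal the pooled-t oracle applied to the
        standardized transformed values, and ΔPSI stays on the raw scale."""
        psi = _matrix(
            [[0.10, 0.20, 0.30, 0.40, 0.50, 0.60]],
            samples=list(self.GROUPS),
        )
        res = differential_test(psi, self.GROUPS, DiffSpliceConfig())
        z = standardize(filter_and_impute(transform_psi(psi, 0.01)))
        t_exp, p_exp = pooled_t_oracle(list(z.iloc[0, 3:]), list(z.iloc[0, :3]))
        assert res.loc["e0", "t"] == pytest.approx(t_exp, abs=1e-9)
        assert res.loc["e0", "p"] == pytest.approx(p_exp, abs=1e-9)
        assert res.loc["e0", "delta_psi"] == pytest.approx(0.5 - 0.2, abs=1e-12)
        assert res.loc["e0", ["n_wt", "n_mut"]].tolist() == [3, 3]

    def test_textbook_example_values(self):
        """Values 1..3 vs 4..6: |t| = 3.674, p ≈ 0.0213 (df = 4)."""
        t, p = pooled_t_oracle([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.6742346, abs=1e-6)
        assert p == pytest.approx(0.021312, abs=1e-5)

    def test_constant_null_event_removed_upstream(self):
        psi = _matrix([[0.0] * 6], samples=list(self.GROUPS))
        res = differential_test(psi, self.GROUPS)
        assert len(res) == 0

    def test_group_with_one_observation_gets_missing_p(self):
        psi = _matrix(
            [[0.1, np.nan, np.nan, 0.4, 0.5, 0.6]], samples=list(self.GROUPS)
        )
        res = differential_test(psi, self.GROUPS)
        assert np.isnan(res.loc["e0", "p"])
        assert not res.loc["e0", "significant"]

    def test_fewer_than_two_samples_per_group_rejected(self):
        psi = _matrix([[0.1, 0.2, 0.3]], samples=["w1", "w2", "m1"])
        with pytest.raises(ConfigurationError):
            differential_test(psi, {"w1": "WT", "w2": "WT", "m1": "MUT"})

    def test_welch_differs_from_pooled_under_unequal_spread(self):
        psi = _matrix(
            [[0.10, 0.11, 0.12, 0.2, 0.5, 0.8]], samples=list(self.GROUPS)
        )
        pooled = differential_test(psi, self.GROUPS, DiffSpliceConfig(test="pooled"))
        welch = differential_test(psi, self.GROUPS, DiffSpliceConfig(test="welch"))
        assert pooled.loc["e0", "p"] != welch.loc["e0", "p"]

    def test_null_rejection_rate_near_nominal(self):
        """1000 null events, 4 vs 4: empirical size within 3 binomial SEs of
        the nominal level, for alpha in {0.01, 0.05}."""
        cfg = SimulationConfig(
            n_genes=1000, n_wt=4, n_mut=4, fraction_responsive=0.0,
            coverage_mean=50, background_event_mix={"A5SS": 0.0, "exon_skip": 0.0},
        )
        cohort = simulate_cohort(cfg, 17)
        events = detect_events(cohort.junctions, cohort.sim.genes)
        m = build_psi_matrix(events, cohort.junctions, cohort.sample_sheet.sample_ids)
        res = differential_test(m.psi, cohort.sample_sheet.groups)
        p = res["p"].dropna()
        assert len(p) > 900
        for alpha in (0.01, 0.05):
            se = math.sqrt(alpha * (1 - alpha) / len(p))
            assert abs((p < alpha).mean() - alpha) <= 3 * se


class TestThresholds:
    def _results(self, delta, p):
        return pd.DataFrame(
            {"delta_psi": [delta], "p": [p], "p_adj": [p], "n_wt": 3, "n_mut": 4},
            index=["e0"],
        )

    def test_default_rule(self):
        assert apply_thresholds(self._results(0.15, 0.005), DiffSpliceConfig())[
            "significant"
        ].iloc[0]
        assert not apply_thresholds(self._results(0.15, 0.02), DiffSpliceConfig())[
            "significant"
        ].iloc[0]

    def test_pan_cancer_preset_requires_both_bounds(self):
        cfg = DiffSpliceConfig.pan_cancer()
        assert (cfg.delta_psi_min, cfg.p_max) == (0.05, 1e-10)
        assert not apply_thresholds(self._results(0.05, 1e-12), cfg)["significant"].iloc[0]
        assert apply_thresholds(self._results(0.06, 1e-12), cfg)["significant"].iloc[0]

    def test_bh_adjustment_used_when_configured(self):
        res = pd.DataFrame(
            {
                "delta_psi": [0.3, 0.3],
                "p": [0.004, 0.009],
                "p_adj": [0.008, 0.02],
                "n_wt": 3,
                "n_mut": 4,
            },
            index=["e0", "e1"],
        )
        out = apply_thresholds(res, DiffSpliceConfig(adjust="BH"))
        assert out["significant"].tolist() == [True, False]
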