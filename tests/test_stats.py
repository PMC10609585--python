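import math

import numpy as np
import pytest
from scipy import stats as sps

from prokrates.stats import (
    AssumptionWarning,
    FactorialDataset,
    build_effects_table,
    levene,
    omega_g_squared,
    shapiro_wilk,
    two_way_anova,
)


def projection_oracle(y):
    """Brute-force linear-model oracle for the balanced 2x2 ANOVA.

    y has shape (2, 2, n).  Sums of squares are obtained as residual
    sum-of-squares differences between the full effect-coded linear model
    and the model with one column dropped.
    """
    n = y.shape[2]
    rows, a_code, b_code = [], [], []
    for i in range(2):
        for j in range(2):
            for k in range(n):
                rows.append(y[i, j, k])
                a_code.append(2 * i - 1)
                b_code.append(2 * j - 1)
    yy = np.array(rows)
    a = np.array(a_code, dtype=float)
    b = np.array(b_code, dtype=float)
    full = np.column_stack([np.ones_like(a), a, b, a * b])

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, yy, rcond=None)
        r = yy - x @ beta
        return float(r @ r)

    rss_full = rss(full)
    out = {}
    for name, col in (("A", 1), ("B", 2), ("AxB", 3)):
        reduced = np.delete(full, col, axis=1)
        ss = rss(reduced) - rss_full
        df_err = yy.size - 4
        f = (ss / 1.0) / (rss_full / df_err)
        out[name] = (ss, f, float(sps.f.sf(f, 1, df_err)))
    out["error"] = rss_full
    out["total"] = rss(np.ones((yy.size, 1)))
    return out


def random_dataset(rng, n=3, scale=1.0):
    cells = [[list(rng.normal(rng.normal(0, 2), scale, n)) for _ in range(2)] for _ in range(2)]
    return FactorialDataset("y", cells)


class TestTwoWayAnova:
    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            data = random_dataset(rng)
            rep = two_way_anova(data, warn_assumptions=False)
            oracle = projection_oracle(data.as_array())
            for eff, key in zip(rep.effects, ("A", "B", "AxB")):
                ss, f, p = oracle[key]
                assert eff.ss == pytest.approx(ss, abs=1e-10)
                assert eff.f == pytest.approx(f, rel=1e-10)
                assert eff.p == pytest.approx(p, abs=1e-10)
            assert rep.ss_error == pytest.approx(oracle["error"], abs=1e-10)
            assert rep.ss_total == pytest.approx(oracle["total"], abs=1e-10)

    def test_matches_statsmodels(self):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(3)
        data = random_dataset(rng)
        rep = two_way_anova(data, warn_assumptions=False)
        y = data.as_array()
        rows = [
            {"y": y[i, j, k], "a": i, "b": j}
            for i in range(2)
            for j in range(2)
            for k in range(y.shape[2])
        ]
        tab = anova_lm(smf.ols("y ~ C(a) * C(b)", pd.DataFrame(rows)).fit(), typ=2)
        assert rep.effect("A").ss == pytest.approx(tab.loc["C(a)", "sum_sq"], rel=1e-9)
        assert rep.effect("B").ss == pytest.approx(tab.loc["C(b)", "sum_sq"], rel=1e-9)
        assert rep.effect("AxB").p == pytest.approx(tab.loc["C(a):C(b)", "PR(>F)"], abs=1e-9)

    def test_constant_data_gives_null_result(self):
        data = FactorialDataset("y", [[[5.0] * 3, [5.0] * 3], [[5.0] * 3, [5.0] * 3]])
        rep = two_way_anova(data, warn_assumptions=False)
        for eff in rep.effects:
            assert eff.f == 0.0
            assert eff.p == 1.0

    def test_zero_error_interaction_handled_as_p_zero(self):
        data = FactorialDataset("y", [[[0.0] * 3, [0.0] * 3], [[0.0] * 3, [1.0] * 3]])
        rep = two_way_anova(data, warn_assumptions=False)
        assert rep.ss_error == 0.0
        assert rep.effect("AxB").p == 0.0
        assert math.isinf(rep.effect("AxB").f)

    def test_ss_additivity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            rep = two_way_anova(random_dataset(rng), warn_assumptions=False)
            parts = sum(e.ss for e in rep.effects) + rep.ss_error
            assert parts == pytest.approx(rep.ss_total, abs=1e-9)

    def test_unbalanced_or_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            FactorialDataset("y", [[[1.0, 2.0], [1.0, 2.0, 3.0]], [[1.0, 2.0], [1.0, 2.0]]])
        with pytest.raises(ValueError):
            FactorialDataset("y", [[[1.0], [1.0]], [[1.0], [1.0]]])

    def test_assumption_violation_warns_but_reports(self):
        cells = [[[0.0, 0.001, -0.001], [0.0, 0.002, -0.002]],
                 [[10.0, 30.0, -20.0], [5.0, 25.0, -15.0]]]
        with pytest.warns(AssumptionWarning):
            rep = two_way_anova(FactorialDataset("y", cells))
        assert len(rep.effects) == 3


class TestLevene:
    def test_identical_spread_groups(self):
        groups = [[1.0, 2.0, 3.0], [11.0, 12.0, 13.0], [21.0, 22.0, 23.0]]
        f, p = levene(groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_oracle_identity_with_anova_on_absolute_deviations(self):
        rng = np.random.default_rng(19)
        groups = [list(rng.normal(0, s, 3)) for s in (1.0, 1.0, 1.0, 10.0)]
        f, p = levene(groups)
        abs_dev = [np.abs(np.array(g) - np.mean(g)) for g in groups]
        f_ref, p_ref = sps.f_oneway(*abs_dev)
        assert f == pytest.approx(float(f_ref), abs=1e-10)
        assert p == pytest.approx(float(p_ref), abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(23)
        groups = [list(rng.normal(0, s, 4)) for s in (1.0, 3.0)]
        f1, _ = levene(groups)
        f2, _ = levene([[x * 7.5 for x in g] for g in groups])
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_requires_two_groups_with_replication(self):
        with pytest.raises(ValueError):
            levene([[1.0, 2.0]])
        with pytest.raises(ValueError):
            levene([[1.0], [2.0, 3.0]])


class TestShapiroWilk:
    def test_calibrated_on_normal_samples(self):
        rng = np.random.default_rng(29)
        ps = [shapiro_wilk(rng.normal(size=100))[1] for _ in range(50)]
        assert np.median(ps) > 0.1

    def test_detects_bimodality_at_n12(self):
        x = [0.0] * 6 + [10.0] * 6
        x = [v + 1e-3 * i for i, v in enumerate(x)]  # break exact ties
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_constant_vector_inapplicable(self):
        w, p = shapiro_wilk([3.0] * 10)
        assert math.isnan(w) and math.isnan(p)

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestOmegaSquared:
    def test_null_effect_negative_estimate(self):
        # SS_eff = 0 with MS_error > 0 gives a small negative value
        val = omega_g_squared(0.0, 1, 2.0, 100.0)
        assert val < 0.0

    def test_dominant_effect_approaches_one(self):
        assert omega_g_squared(1e8, 1, 1e-3, 1e8) == pytest.approx(1.0, abs=1e-6)

    def test_undefined_when_error_is_zero(self):
        assert math.isnan(omega_g_squared(1.0, 1, 0.0, 1.0))

    def test_never_exceeds_eta_squared(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            data = random_dataset(rng)
            rep = two_way_anova(data, warn_assumptions=False)
            for eff in rep.effects:
                eta_sq = eff.ss / rep.ss_total
                assert eff.omega_g_sq <= eta_sq + 1e-12

    def test_simulation_mean_matches_large_sample_value(self):
        """With a main effect of 4 sigma between levels, the large-sample
        generalized omega-squared is (delta^2/4)/(delta^2/4 + sigma^2) = 0.8;
        the small-sample estimator should be unbiased to Monte-Carlo error."""
        rng = np.random.default_rng(7)
        sigma, delta = 1.0, 4.0
        oms = []
        for _ in range(1000):
            cells = [
                [list(rng.normal(0, sigma, 3)), list(rng.normal(0, sigma, 3))],
                [list(rng.normal(delta, sigma, 3)), list(rng.normal(delta, sigma, 3))],
            ]
            rep = two_way_anova(FactorialDataset("y", cells), warn_assumptions=False)
            oms.append(rep.effect("A").omega_g_sq)
        oms = np.array(oms)
        mcse = oms.std(ddof=1) / math.sqrt(len(oms))
        assert abs(oms.mean() - 0.8) < 3 * mcse


class TestEffectsTable:
    def test_empty_reports_give_empty_table(self):
        assert build_effects_table([]).empty

    def test_significant_cells_always_paired_with_shown_omega(self):
        rng = np.random.default_rng(37)
        reports = [two_way_anova(random_dataset(rng), warn_assumptions=False) for _ in range(10)]
        table = build_effects_table(reports)
        for eff in ("A", "B", "AxB"):
            for _, row in table.iterrows():
                if row[f"{eff}_p"] < 0.05:
                    assert not math.isnan(row[f"{eff}_omega_g_sq"])
                    assert row[f"{eff}_omega_g_sq"] >= 0.0
                else:
                    assert math.isnan(row[f"{eff}_omega_g_sq"])
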