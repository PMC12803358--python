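"""EIC integration against closed forms; ANOVA/Tukey behaviour and cross-checks."""

import numpy as np
import pytest

from clicktrace import synthetic
from clicktrace.chem import CHOLINE, lpc_species
from clicktrace.quant import (
    EIC,
    compare_groups,
    integrate_eic,
    quant_report,
)


def gaussian_eic(amplitude=1000.0, sigma=0.05, center=1.0, dt=0.005, baseline=0.0):
    return synthetic.generate_eic(
        amplitude=amplitude, center=center, sigma=sigma, baseline=baseline,
        noise_sd=0.0, t_start=0.0, t_end=2.0, dt=dt,
    )


class TestIntegrate:
    def test_gaussian_closed_form_within_1pct(self):
        eic = gaussian_eic()
        area = integrate_eic(eic, (1.0 - 0.2, 1.0 + 0.2), "none")
        expected = 1000.0 * 0.05 * np.sqrt(2 * np.pi)  # ≈ 125.33
        assert area.auc == pytest.approx(expected, rel=0.01)

    def test_all_zero_trace(self):
        eic = EIC(100.0, 10.0, np.linspace(0, 1, 50), np.zeros(50))
        assert integrate_eic(eic, (0.1, 0.9), "none").auc == 0.0

    def test_piecewise_linear_equals_hand_trapezoid(self):
        # triangle: 0 at t=0, 10 at t=1, 0 at t=2 -> area 10
        eic = EIC(100.0, 10.0, np.array([0.0, 1.0, 2.0]), np.array([0.0, 10.0, 0.0]))
        assert integrate_eic(eic, (0.0, 2.0), "none").auc == pytest.approx(10.0)
        # sub-window [0.5, 1.5]: trapezoid of heights 5,10,5 -> 7.5
        assert integrate_eic(eic, (0.5, 1.5), "none").auc == pytest.approx(7.5)

    def test_linear_endpoints_baseline_removes_offset(self):
        eic = gaussian_eic(baseline=50.0)
        area = integrate_eic(eic, (0.8, 1.2), "linear_endpoints")
        expected = 1000.0 * 0.05 * np.sqrt(2 * np.pi)
        assert area.auc == pytest.approx(expected, rel=0.02)

    def test_window_errors(self):
        eic = gaussian_eic()
        with pytest.raises(ValueError):
            integrate_eic(eic, (1.0, 1.0), "none")
        with pytest.raises(ValueError):
            integrate_eic(eic, (-1.0, 0.5), "none")
        with pytest.raises(ValueError):
            integrate_eic(eic, (0.5, 1.0), "quadratic")

    def test_trapezoid_converges_order_h2(self):
        # integrate over ±1σ so the endpoint curvature terms dominate and the
        # O(h²) truncation error is visible (over the full support a Gaussian's
        # trapezoid error is below float precision)
        from scipy.special import erf

        expected = 1000.0 * 0.05 * np.sqrt(2 * np.pi) * erf(1 / np.sqrt(2))
        errors = []
        for dt in (0.02, 0.01, 0.005):
            area = integrate_eic(gaussian_eic(dt=dt), (0.95, 1.05), "none")
            errors.append(abs(area.auc - expected))
        # halving dt should shrink the error ~4x (allow slack for endpoint effects)
        assert errors[1] < errors[0] / 2.5
        assert errors[2] < errors[1] / 2.5


class TestCompareGroups:
    def test_identical_observations_degenerate(self):
        cmp = compare_groups("x", {"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert cmp.f_statistic == 0.0
        assert cmp.p_value == 1.0
        assert cmp.significant_pairs == []

    def test_identical_samples_f_zero(self):
        cmp = compare_groups("x", {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert cmp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-12)

    def test_zero_within_variance_unequal_means(self):
        cmp = compare_groups("x", {"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert cmp.p_value == 0.0
        assert cmp.significant_pairs == [("a", "b")]

    def test_group_too_small_errors(self):
        with pytest.raises(ValueError):
            compare_groups("x", {"a": [1.0], "b": [1.0, 2.0]})

    def test_tukey_adjusted_p_at_least_raw_p(self, rng):
        from scipy import stats

        for _ in range(50):
            groups = {g: rng.normal(0, 1, 5).tolist() for g in "abcd"}
            cmp = compare_groups("x", groups)
            raw = dict()
            for a, b, p in cmp.pairwise_raw:
                raw[(a, b)] = p
            for a, b, p_adj in cmp.pairwise:
                assert p_adj >= raw[(a, b)] - 1e-10
        # two groups only: the raw pooled test is the classical equal-variance
        # two-sample t-test; cross-check against scipy
        groups = {"a": rng.normal(0, 1, 6).tolist(), "b": rng.normal(1, 1, 6).tolist()}
        cmp = compare_groups("x", groups)
        _, p_t = stats.ttest_ind(groups["a"], groups["b"], equal_var=True)
        assert cmp.pairwise_raw[0][2] == pytest.approx(float(p_t), abs=1e-10)

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values, labels = [], []
        groups = {}
        for g in ("w", "x", "y", "z"):
            v = rng.normal({"w": 0, "x": 0.5, "y": 1.0, "z": 0}[g], 1.0, 6)
            groups[g] = v.tolist()
            values.extend(v)
            labels.extend([g] * 6)
        cmp = compare_groups("analyte", groups)
        sm = pairwise_tukeyhsd(np.array(values), np.array(labels), alpha=0.05)
        sm_p = {tuple(sorted((r[0], r[1]))): float(r[3]) for r in sm.summary().data[1:]}
        for a, b, p in cmp.pairwise:
            assert p == pytest.approx(sm_p[tuple(sorted((a, b)))], abs=1e-3)

    def test_unequal_group_sizes_supported(self, rng):
        groups = {"a": rng.normal(0, 1, 4).tolist(),
                  "b": rng.normal(2, 1, 7).tolist(),
                  "c": rng.normal(0, 1, 5).tolist()}
        cmp = compare_groups("x", groups)
        assert all(0.0 <= p <= 1.0 for _, _, p in cmp.pairwise)
        assert ("a", "b") in cmp.significant_pairs or ("b", "a") in cmp.significant_pairs


class TestQuantReport:
    def _table(self, effects, seed=0, targets=None):
        targets = targets or [CHOLINE]
        cfg = synthetic.GroupDesignConfig(
            seed=seed, targets=targets, group_effects=effects
        )
        return synthetic.generate_group_table(cfg), targets

    def test_planted_shift_flagged_against_all_others(self):
        effects = {("choline-LR", "choline"): 4.0}
        table, targets = self._table(effects, seed=5)
        _, results = quant_report(table, targets)
        res = results[0]
        assert res.detected
        assert res.elevated_group() == "choline-LR"

    def test_absent_target_reported_not_detected(self):
        table, _ = self._table({}, seed=1)
        stray = lpc_species(20, 4)  # not planted in this table
        qtable, results = quant_report(table, [stray], mz_tol_ppm=5.0)
        assert not results[0].detected
        assert (~qtable["detected"]).all()

    def test_lpc_panel_flagged_in_elevated_group(self):
        lpcs = [lpc_species(*p) for p in ((16, 1), (18, 2), (20, 4), (18, 1))]
        effects = {("choline-LR", s.name): 6.0 for s in lpcs}
        cfg = synthetic.GroupDesignConfig(seed=9, targets=lpcs, group_effects=effects)
        table = synthetic.generate_group_table(cfg)
        _, results = quant_report(table, lpcs)
        flagged = [r.elevated_group() for r in results]
        assert flagged == ["choline-LR"] * 4
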