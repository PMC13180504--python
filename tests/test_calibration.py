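"""Control function, truncated-normal conditional moments, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from rmstdesign import (
    CriticalValues,
    calibrate,
    conditional_moments,
    control_f,
    empirical_oc,
    q_from_m,
    simple_rmst_calibrate,
    simulate_stage_stats,
    stage_moments,
)
from rmstdesign.calibration import StageStats


class TestControlFunction:
    def test_closed_form_values(self):
        assert control_f(100, 100, 1.0) == pytest.approx(np.exp(-1))
        assert control_f(50, 100, 2.0) == pytest.approx(np.exp(-1))

    def test_small_gamma_limit_approaches_one(self):
        assert 0.999 < control_f(100, 100, 1e-3) < 1.0

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            control_f(50, 100, 0.0)

    @given(
        st.floats(0.05, 5.0),
        st.floats(0.05, 5.0),
        st.integers(2, 98),
        st.integers(2, 98),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_gamma_and_interim_size(self, g1, g2, n1, n2):
        """f is strictly decreasing in both arguments; interim threshold is
        always the more lenient one (f(N~) > f(N) whenever N~ < N)."""
        f = control_f
        if g1 != g2:
            lo, hi = sorted((g1, g2))
            assert f(n1, 100, hi) < f(n1, 100, lo)
        if n1 != n2:
            lo, hi = sorted((n1, n2))
            assert f(hi, 100, g1) < f(lo, 100, g1)
        assert 0.0 < f(n1, 100, g1) < 1.0
        assert f(n1, 100, g1) > f(100, 100, g1)


class TestStageMoments:
    def _stats(self, d1, re1, d2=None, re2=None):
        d1 = np.asarray(d1, float)
        re1 = np.asarray(re1, float)
        d2 = d1 if d2 is None else np.asarray(d2, float)
        re2 = re1 if re2 is None else np.asarray(re2, float)
        return StageStats(d1=d1, re1=re1, d2=d2, re2=re2, hypothesis="H1")

    def test_degenerate_replicates_give_zero_covariance(self):
        stats = self._stats([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        mom = stage_moments(stats)
        assert np.allclose(mom.cov[0], 0.0)

    def test_two_point_hand_covariance(self):
        mom = stage_moments(self._stats([0.0, 2.0], [0.0, 2.0]))
        assert mom.mean_d[0] == pytest.approx(1.0)
        assert mom.mean_e[0] == pytest.approx(1.0)
        _, _, _, _, rho = mom.stage(1)
        assert rho == pytest.approx(1.0)
        # Monte-Carlo (1/B) covariance convention
        assert mom.cov[0][0, 0] == pytest.approx(1.0)

    def test_recovers_generating_bivariate_normal(self, rng):
        b = 100_000
        cov = np.array([[0.4, 0.12], [0.12, 0.2]])
        x = rng.multivariate_normal([0.3, 0.8], cov, size=b)
        mom = stage_moments(self._stats(x[:, 0], x[:, 1]))
        se_mean = np.sqrt(np.diag(cov) / b)
        assert abs(mom.mean_d[0] - 0.3) < 3 * se_mean[0]
        assert abs(mom.mean_e[0] - 0.8) < 3 * se_mean[1]
        assert np.allclose(mom.cov[0], cov, atol=0.01)

    def test_h0_stats_rejected(self):
        stats = self._stats([0.0, 1.0], [0.0, 1.0])
        stats.hypothesis = "H0"
        with pytest.raises(ValueError):
            stage_moments(stats)


class TestConditionalMoments:
    def test_independence_reduces_to_marginal(self):
        mean, var = conditional_moments(1.0, 0.5, 0.0, 1.0, 0.0, m=2.0)
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(0.25)

    def test_no_truncation_limit(self):
        mean, var = conditional_moments(1.0, 0.5, 0.0, 1.0, 0.7, m=-40.0)
        assert mean == pytest.approx(1.0, abs=1e-6)
        assert var == pytest.approx(0.25, rel=1e-4)

    def test_standard_case_closed_form(self):
        mean, var = conditional_moments(0.0, 1.0, 0.0, 1.0, 0.5, m=0.0)
        assert mean == pytest.approx(norm.pdf(0) / norm.sf(0) * 0.5, rel=1e-9)
        assert var == pytest.approx(0.8408, abs=2e-4)

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            conditional_moments(0.0, 1.0, 0.0, 1.0, 0.5, m=100.0)

    def test_matches_rejection_sampling_oracle(self, rng):
        """Spot-check against brute-force conditioning (full sweep lives in
        the acceptance suite)."""
        for _ in range(10):
            mu_e, mu_d = rng.normal(0, 1, 2)
            s_e, s_d = rng.uniform(0.3, 2.0, 2)
            rho = rng.uniform(-0.9, 0.9)
            m = mu_d + rng.uniform(-1.0, 1.2) * s_d
            cov = np.array(
                [[s_d**2, rho * s_d * s_e], [rho * s_d * s_e, s_e**2]]
            )
            draws = rng.multivariate_normal([mu_d, mu_e], cov, size=200_000)
            kept = draws[draws[:, 0] > m, 1]
            mean, var = conditional_moments(mu_e, s_e, mu_d, s_d, rho, m)
            se_mean = kept.std(ddof=1) / np.sqrt(kept.size)
            assert abs(mean - kept.mean()) < 4 * se_mean
            assert var == pytest.approx(kept.var(ddof=1), rel=0.05)


class TestQFromM:
    def _moments(self):
        stats = StageStats(
            d1=np.array([0.0, 2.0, 1.0, -1.0]),
            re1=np.array([0.0, 2.0, 0.5, 1.5]),
            d2=np.array([0.0, 2.0, 1.0, -1.0]),
            re2=np.array([0.0, 2.0, 0.5, 1.5]),
            hypothesis="H1",
        )
        return stage_moments(stats)

    def test_median_is_conditional_mean(self):
        mom = self._moments()
        mean, _ = conditional_moments(*mom.stage(1), m=0.5)
        assert q_from_m(mom, 1, 0.5, 0.5) == pytest.approx(mean)

    def test_target_near_one_pushes_q_down(self):
        mom = self._moments()
        assert q_from_m(mom, 1, 0.5, 0.999) < q_from_m(mom, 1, 0.5, 0.5) - 1.0

    def test_composes_conditional_moment_oracle(self):
        # q must equal mean + z_{1-p} * sd of the conditional law
        d = np.array([-1.5, -0.5, 0.5, 1.5] * 2, float)
        stats = StageStats(d1=d, re1=d, d2=d, re2=d, hypothesis="H1")
        mom = stage_moments(stats)
        p = np.exp(-1)
        mean, var = conditional_moments(*mom.stage(1), m=0.0)
        expected = mean + norm.ppf(1 - p) * np.sqrt(var)
        assert q_from_m(mom, 1, 0.0, p) == pytest.approx(expected)


def _toy_stats(rng, b=4000, shift=0.0):
    d1 = rng.normal(shift * 0.5, 0.3, b)
    re1 = 0.6 * d1 + rng.normal(0.8 + shift, 0.2, b)
    d2 = 0.7 * d1 + rng.normal(shift, 0.25, b)
    re2 = 0.5 * d2 + rng.normal(1.0 + shift, 0.15, b)
    return StageStats(d1=d1, re1=re1, d2=d2, re2=re2, hypothesis="H1")


class TestEmpiricalOc:
    def _pair(self, rng):
        h0 = _toy_stats(rng, shift=0.0)
        h0.hypothesis = "H0"
        h1 = _toy_stats(rng, shift=0.4)
        return h0, h1

    def test_always_reject_rule(self, rng):
        h0, h1 = self._pair(rng)
        cv = CriticalValues(-np.inf, -np.inf, -np.inf, -np.inf)
        oc = empirical_oc(h0, h1, cv, 60, 100)
        assert oc.alpha == 1.0 and oc.power == 1.0
        assert oc.pet0 == 0.0 and oc.en0 == 100.0

    def test_always_stop_rule(self, rng):
        h0, h1 = self._pair(rng)
        cv = CriticalValues(np.inf, -np.inf, -np.inf, -np.inf)
        oc = empirical_oc(h0, h1, cv, 60, 100)
        assert oc.alpha == 0.0 and oc.power == 0.0
        assert oc.pet0 == 1.0 and oc.en0 == 60.0

    def test_mismatched_replicates_rejected(self, rng):
        h0, h1 = self._pair(rng)
        h1.d1 = h1.d1[:-1]
        h1.re1 = h1.re1[:-1]
        h1.d2 = h1.d2[:-1]
        h1.re2 = h1.re2[:-1]
        cv = CriticalValues(0, 0, 0, 0)
        with pytest.raises(ValueError):
            empirical_oc(h0, h1, cv, 60, 100)

    def test_monotone_in_each_critical_value(self, rng):
        """alpha and power can only fall as any threshold rises."""
        h0, h1 = self._pair(rng)
        base = CriticalValues(m1=0.0, q1=0.8, m2=0.0, q2=1.0)
        oc0 = empirical_oc(h0, h1, base, 60, 100)
        import dataclasses

        for field in ("m1", "q1", "m2", "q2"):
            stricter = dataclasses.replace(base, **{field: getattr(base, field) + 0.1})
            oc1 = empirical_oc(h0, h1, stricter, 60, 100)
            assert oc1.alpha <= oc0.alpha
            assert oc1.power <= oc0.power


class TestCalibrate:
    def _pair(self, rng):
        h0 = _toy_stats(rng, shift=0.0)
        h0.hypothesis = "H0"
        h1 = _toy_stats(rng, shift=0.4)
        return h0, h1

    def test_alpha_one_selects_global_power_maximizer(self, rng):
        h0, h1 = self._pair(rng)
        res = calibrate(
            h0, h1, 60, 100, alpha0=1.0, selection_rule="max_power", return_table=True
        )
        assert res.found
        assert res.n_feasible == len(res.feasible_table)
        assert res.oc.power == pytest.approx(res.feasible_table["powerE"].max())

    def test_selected_design_respects_alpha_constraint(self, rng):
        h0, h1 = self._pair(rng)
        for rule in ("max_power", "closest_power"):
            res = calibrate(h0, h1, 60, 100, alpha0=0.05, selection_rule=rule)
            assert res.found and res.oc.alpha <= 0.05

    def test_no_feasible_design_signal(self, rng):
        h0, h1 = self._pair(rng)
        # an unsatisfiable constraint must yield a signal, not an exception
        res = calibrate(h0, h1, 60, 100, alpha0=-1.0)
        assert not res.found and res.critical_values is None

    def test_sculpted_region_subset_of_simple_at_fixed_m(self, rng):
        """At identical (m1, m2), adding q-thresholds can only shrink the
        rejection set, hence alpha_sculpt <= alpha_simple replicate-wise."""
        h0, h1 = self._pair(rng)
        m1, m2 = 0.05, 0.1
        simple_rej_h0 = (h0.d1 > m1) & (h0.d2 > m2)
        for q1, q2 in ((0.7, 0.9), (0.9, 1.1), (1.1, 1.4)):
            sculpt_rej_h0 = simple_rej_h0 & (h0.re1 > q1) & (h0.re2 > q2)
            assert not np.any(sculpt_rej_h0 & ~simple_rej_h0)
            assert sculpt_rej_h0.mean() <= simple_rej_h0.mean()

    def test_forcing_q_to_zero_reproduces_simple_rule(self, rng):
        h0, h1 = self._pair(rng)
        # shift RMST stats well above zero so q=0 is inert, as for real RMSTs
        for s in (h0, h1):
            s.re1 = s.re1 + 5.0
            s.re2 = s.re2 + 5.0
        simple = simple_rmst_calibrate(h0, h1, 60, 100, 0.05, selection_rule="max_power")
        forced = calibrate(
            h0, h1, 60, 100, 0.05,
            selection_rule="max_power", gamma_grid=[1e-9],
        )
        # gamma -> 0 drives q -> -inf, so the sculpted search degenerates
        assert forced.oc.alpha == pytest.approx(simple.oc.alpha)
        assert forced.oc.power == pytest.approx(simple.oc.power)


def test_simple_calibration_on_simulated_trials(ph_scenario):
    """End-to-end: calibrated simple rule controls alpha on its replicates."""
    h0 = simulate_stage_stats(ph_scenario, 30, 60, 2000, seed=5, hypothesis="H0")
    h1 = simulate_stage_stats(ph_scenario, 30, 60, 2000, seed=5, hypothesis="H1")
    res = simple_rmst_calibrate(h0, h1, 30, 60, alpha0=0.05, selection_rule="max_power")
    assert res.found
    assert res.oc.alpha <= 0.05
    assert res.critical_values.q1 == 0.0 and res.critical_values.q2 == 0.0
    assert 30 <= res.oc.en0 <= 60
    assert res.oc.en_mean == pytest.approx((res.oc.en0 + res.oc.en1) / 2)
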