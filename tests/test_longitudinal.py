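import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ehrqa.config import LongitudinalParams
from ehrqa.longitudinal import (
    compute_ewma,
    decay_weight,
    deviation_variance_factor,
    heuristic_tau,
    qr_scores,
)
from .conftest import make_series


class TestHeuristicTau:
    @pytest.mark.parametrize(
        "omega,xi,expected,places",
        [
            (0.9, 12.0, 9.49, 2),       # 90% dependency one year away
            (0.9, 0.5, 0.4, 1),         # 90% dependency half a month away
            (math.exp(-1), 12.0, 1.0, 12),  # ln(e^-1) = -1 exactly
        ],
    )
    def test_published_values(self, omega, xi, expected, places):
        assert round(heuristic_tau(omega, xi), places) == expected

    def test_strictly_increasing_in_both_arguments(self):
        taus_omega = [heuristic_tau(w, 6.0) for w in (0.1, 0.5, 0.9, 0.99)]
        taus_xi = [heuristic_tau(0.9, x) for x in (0.5, 1, 6, 12)]
        assert taus_omega == sorted(taus_omega) and len(set(taus_omega)) == 4
        assert taus_xi == sorted(taus_xi) and len(set(taus_xi)) == 4

    @pytest.mark.parametrize("omega", [0.0, 1.0, -0.2, 1.5])
    def test_domain_error(self, omega):
        with pytest.raises(ValueError):
            heuristic_tau(omega, 12.0)


class TestDecayWeight:
    def test_self_weight_is_one(self):
        assert decay_weight(3.0, 99.0, tau=0.5, is_self=True) == 1.0

    @pytest.mark.parametrize("gap,expected", [(2.0, 0.81), (5.0, 0.59)])
    def test_published_dependencies_at_height_tau(self, gap, expected):
        tau = heuristic_tau(0.9, 12.0)
        assert round(decay_weight(0.0, gap, tau), 2) == expected

    def test_symmetric_in_times(self):
        assert decay_weight(1.0, 4.0, 2.0) == decay_weight(4.0, 1.0, 2.0)

    def test_same_timestamp_neighbor_weight_equals_self_weight(self):
        assert decay_weight(5.0, 5.0, 0.5) == 1.0


class TestEwma:
    def test_constant_series_reproduces_constant(self):
        s = make_series([200.0] * 5)
        for i in range(5):
            assert compute_ewma(s, i, tau=1.0) == pytest.approx(200.0, abs=1e-9)

    def test_huge_tau_gives_arithmetic_mean(self):
        s = make_series([1.0, 2.0, 6.0], times=[0.0, 3.0, 10.0])
        assert compute_ewma(s, 0, tau=1e12) == pytest.approx(3.0, rel=1e-9)

    def test_two_point_hand_oracle(self):
        # target the later point: weights (e^-1, 1)
        s = make_series([200.0, 180.0], times=[0.0, 1.0])
        w = math.exp(-1.0)
        expected = (w * 200.0 + 180.0) / (w + 1.0)
        assert compute_ewma(s, 1, tau=1.0) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=-100, max_value=100), min_size=1, max_size=12),
        st.floats(min_value=0.05, max_value=20),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_result_within_value_range(self, values, tau):
        s = make_series(values, times=np.sort(np.linspace(0, 5, len(values))))
        for i in range(len(values)):
            e = compute_ewma(s, i, tau)
            assert min(values) - 1e-9 <= e <= max(values) + 1e-9


class TestVarianceFactor:
    def test_two_equal_weights(self):
        w = np.array([1.0, 1.0])
        # Var(|y1-y2|/2) = Var(y)/2 under independence
        assert deviation_variance_factor(w, 0, "derived") == pytest.approx(0.5)
        # published formula with the + cross term
        assert deviation_variance_factor(w, 0, "paper") == pytest.approx(2.5)

    @pytest.mark.parametrize("n", [2, 3, 10, 50])
    def test_equal_weights_closed_form(self, n):
        w = np.ones(n)
        assert deviation_variance_factor(w, 0, "derived") == pytest.approx(1 - 1 / n)

    def test_derived_factor_positive_and_below_paper(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(2, 12)
            w = rng.uniform(0.01, 1.0, size=n)
            i = int(rng.integers(0, n))
            w[i] = 1.0
            d = deviation_variance_factor(w, i, "derived")
            p = deviation_variance_factor(w, i, "paper")
            assert 0 < d < p

    def test_monte_carlo_matches_derived_not_paper(self):
        """Empirical Var(ewma - y_i) matches the derived factor within
        3 MC standard errors and excludes the published (+) factor."""
        rng = np.random.default_rng(42)
        var_y = 4.0
        reps = 100_000
        for _ in range(20):
            n = int(rng.integers(2, 9))
            w = rng.uniform(0.05, 1.0, size=n)
            i = int(rng.integers(0, n))
            w[i] = 1.0
            y = rng.normal(0.0, math.sqrt(var_y), size=(reps, n))
            dev = y @ w / w.sum() - y[:, i]
            v_emp = dev.var(ddof=1)
            mc_se = v_emp * math.sqrt(2.0 / (reps - 1))
            v_derived = deviation_variance_factor(w, i, "derived") * var_y
            v_paper = deviation_variance_factor(w, i, "paper") * var_y
            assert abs(v_emp - v_derived) < 3 * mc_se
            assert abs(v_emp - v_paper) > 3 * mc_se


class TestQrScores:
    PARAMS = LongitudinalParams(tau=0.5, var_y=210.0)

    def test_constant_series_q_is_one(self):
        s = make_series([200.0] * 4, times=[0.0, 0.1, 0.2, 0.3])
        for r in qr_scores(s, self.PARAMS):
            assert r.d == pytest.approx(0.0, abs=1e-9)
            assert r.q_r == pytest.approx(1.0, abs=1e-9)
            assert not r.flag_r

    def test_z_at_standard_normal_quantile(self):
        """A record engineered to have z_r = 1.959964 scores q_r = 0.05."""
        z_target = 1.959964
        # two same-time points: ewma = mean, d = 1/2, derived factor = 1/2
        var_y = 0.25 / (0.5 * z_target**2)
        s = make_series([0.0, 1.0], times=[0.0, 0.0])
        r = qr_scores(s, LongitudinalParams(tau=1.0, var_y=var_y))[0]
        assert r.z_r == pytest.approx(z_target, rel=1e-12)
        assert r.q_r == pytest.approx(0.05, abs=1e-6)

    def test_three_point_hand_oracle(self):
        """Step-by-step scalar recomputation (weights -> ewma -> factor ->
        Z -> p) for the last point of [200, 200, 180]."""
        times = [50.0, 50.1, 50.2]
        values = [200.0, 200.0, 180.0]
        tau, var_y = 0.5, 210.0
        w = [math.exp(-abs(t - times[2]) / tau) for t in times[:2]] + [1.0]
        W = sum(w)
        ewma = sum(wj * yj for wj, yj in zip(w, values)) / W
        d = abs(values[2] - ewma)
        factor = sum(wj**2 for wj in w) / W**2 - 2 * w[2] / W + 1
        z = d / math.sqrt(factor * var_y)
        q_expected = 2 * (1 - stats.norm.cdf(z))

        s = make_series(values, times=times)
        r = qr_scores(s, LongitudinalParams(tau=tau, var_y=var_y))[2]
        assert r.ewma == pytest.approx(ewma, abs=1e-12)
        assert r.q_r == pytest.approx(q_expected, abs=1e-12)

    def test_single_measurement_returns_undefined_unflagged(self):
        s = make_series([180.0], times=[50.0])
        (r,) = qr_scores(s, self.PARAMS)
        assert r.status == "too_few" and math.isnan(r.q_r) and not r.flag_r

    def test_unit_invariance(self):
        """Scaling values by c and var_y by c^2 leaves z and q unchanged."""
        s = make_series([200.0, 240.0, 180.0, 210.0], times=[0.0, 0.4, 0.9, 1.5])
        base = qr_scores(s, LongitudinalParams(tau=0.5, var_y=210.0))
        c = 0.453592  # pounds -> kilograms
        s2 = make_series(s.values * c, times=s.times)
        scaled = qr_scores(s2, LongitudinalParams(tau=0.5, var_y=210.0 * c**2))
        for a, b in zip(base, scaled):
            assert b.z_r == pytest.approx(a.z_r, rel=1e-12)
            assert b.q_r == pytest.approx(a.q_r, rel=1e-12)

    def test_time_shift_invariance(self):
        s = make_series([200.0, 240.0, 180.0], times=[0.0, 0.4, 0.9])
        shifted = make_series([200.0, 240.0, 180.0], times=[70.0, 70.4, 70.9])
        for a, b in zip(qr_scores(s, self.PARAMS), qr_scores(shifted, self.PARAMS)):
            assert b.q_r == pytest.approx(a.q_r, rel=1e-12)

    def test_q_monotone_nonincreasing_in_deviation(self):
        """Growing the final value's deviation (all else fixed) never
        raises its p-value."""
        qs = []
        for dv in (0.0, 5.0, 10.0, 20.0, 40.0):
            s = make_series([200.0, 200.0, 200.0 + dv], times=[0.0, 0.1, 0.2])
            qs.append(qr_scores(s, self.PARAMS)[2].q_r)
        assert all(a >= b for a, b in zip(qs, qs[1:]))

    def test_null_calibration_iid_normal(self):
        """With iid Normal data and the true var_y, flag rate at cutoff
        alpha is alpha within binomial error (q_r exactly uniform)."""
        rng = np.random.default_rng(11)
        n_subj, n_per = 400, 8
        flags = []
        params = LongitudinalParams(tau=1.0, var_y=9.0, cutoff=0.05)
        for k in range(n_subj):
            times = np.sort(rng.uniform(0, 4, size=n_per))
            s = make_series(rng.normal(100.0, 3.0, size=n_per), times=times)
            flags.extend(r.flag_r for r in qr_scores(s, params))
        rate = np.mean(flags)
        se = math.sqrt(0.05 * 0.95 / len(flags))
        assert abs(rate - 0.05) < 3 * se
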