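"""Normalization, t_half / t_lag statistics and the secondary-nucleation
model with its parameter-recovery properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from s100b_abeta.kinetics import (
    KineticTrace,
    NormalizedTrace,
    SecondaryNucleationParams,
    delta_half_time,
    fit_model,
    half_time,
    lag_time,
    model_half_time,
    model_mass_fraction,
    normalize,
    summarize,
)
from s100b_abeta.synthetic import ThTRecipe, generate_tht_trace


def sigmoid_trace(midpoint=18000.0, slope=5e-4, a=1.0, b=0.0, n=101, dt=400.0):
    t = np.arange(n) * dt
    return KineticTrace(times=t, signal=a / (1 + np.exp(-slope * (t - midpoint))) + b)


class TestNormalize:
    def test_clean_unit_sigmoid_nearly_unchanged(self):
        tr = sigmoid_trace()
        out = normalize(tr)
        np.testing.assert_allclose(out.mass_fraction, tr.signal, atol=2e-3)

    def test_affine_invariance(self):
        tr = sigmoid_trace()
        scaled = KineticTrace(times=tr.times, signal=250.0 * tr.signal + 40.0)
        np.testing.assert_allclose(
            normalize(tr).mass_fraction, normalize(scaled).mass_fraction, atol=1e-12
        )

    def test_flat_trace_rejected(self):
        tr = KineticTrace(times=np.arange(20.0), signal=np.full(20, 5.0))
        with pytest.raises(ValueError, match="transition"):
            normalize(tr)

    def test_noisy_baseline_recentred(self):
        recipe = ThTRecipe(logistic=(20000.0, 5e-4), baseline_noise_sd=8.0, seed=5)
        out = normalize(generate_tht_trace(recipe))
        n = len(out.times)
        baseline = out.mass_fraction[: max(3, n // 10)]
        # mean of the baseline window is 0 by construction
        assert abs(baseline.mean()) < 1e-12


class TestHalfTime:
    def test_symmetric_logistic_midpoint(self):
        assert half_time(normalize(sigmoid_trace())) == pytest.approx(18000.0, abs=40.0)

    def test_linear_interpolation_between_samples(self):
        tr = NormalizedTrace(
            times=np.array([0.0, 400.0, 800.0, 1200.0]),
            mass_fraction=np.array([0.0, 0.4, 0.6, 1.0]),
        )
        assert half_time(tr) == pytest.approx(600.0)

    def test_hand_tabulated_step_series(self):
        mass = np.array([0.0, 0.01, 0.02, 0.05, 0.08, 0.12, 0.2, 0.35, 0.55, 0.8, 0.95, 1.0])
        t = np.arange(12) * 400.0
        tr = NormalizedTrace(times=t, mass_fraction=mass)
        # crossing between samples 7 (0.35) and 8 (0.55): 2800 + 400*(0.15/0.2)
        assert half_time(tr) == pytest.approx(3100.0)

    def test_never_crossing_rejected(self):
        tr = NormalizedTrace(times=np.arange(12.0), mass_fraction=np.full(12, 0.2))
        with pytest.raises(ValueError):
            half_time(tr)


class TestLagTime:
    def test_worked_six_point_series(self):
        tr = NormalizedTrace(
            times=np.arange(6) * 400.0,
            mass_fraction=np.array([0.00, 0.02, 0.05, 0.08, 0.30, 0.60]),
        )
        assert lag_time(tr) == 1200.0

    def test_measured_time_not_interpolated(self):
        tr = NormalizedTrace(
            times=np.arange(6) * 400.0,
            mass_fraction=np.array([0.0, 0.02, 0.09, 0.3, 0.6, 1.0]),
        )
        assert lag_time(tr) == 800.0  # the sample itself, no interpolation

    def test_post_plateau_dip_ignored(self):
        mass = np.array([0.0, 0.05, 0.3, 0.6, 0.9, 1.0, 0.05, 1.0, 1.0, 1.0])
        tr = NormalizedTrace(times=np.arange(10) * 400.0, mass_fraction=mass)
        assert lag_time(tr) == 400.0

    def test_lag_before_half_for_monotone_traces(self):
        out = normalize(sigmoid_trace())
        s = summarize(out)
        assert s.t_lag < s.t_half


class TestDeltaHalfTime:
    def test_identical_traces_zero(self):
        s = summarize(normalize(sigmoid_trace()))
        assert delta_half_time(s, s) == 0.0

    def test_pure_time_shift(self):
        s0 = summarize(normalize(sigmoid_trace(midpoint=16000.0)))
        s1 = summarize(normalize(sigmoid_trace(midpoint=19600.0)))
        assert delta_half_time(s1, s0) == pytest.approx(3600.0, abs=40.0)

    def test_reduced_secondary_nucleation_slows_aggregation(self):
        fast = model_half_time(kappa=7e-4, lam=7e-6)
        slow = model_half_time(kappa=7e-4 / np.sqrt(2.0), lam=7e-6)  # k2 halved
        assert slow > fast


class TestModelCurve:
    def test_boundary_conditions(self):
        p = SecondaryNucleationParams.from_effective_rates(5e-4, 5e-6)
        t = np.linspace(0.0, 1e6, 2000)
        m = model_mass_fraction(p, t)
        assert m[0] == 0.0
        assert m[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(m) >= -1e-12)

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_doubling_k2_accelerates(self, seed):
        rng = np.random.default_rng(seed)
        kappa = 10 ** rng.uniform(-4.0, -3.0)
        lam = kappa / 10 ** rng.uniform(0.7, 2.5)
        t1 = model_half_time(kappa, lam)
        t2 = model_half_time(kappa * np.sqrt(2.0), lam)  # k2 doubled
        assert t2 < t1

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=15, deadline=None)
    def test_monomer_concentration_speeds_both_timescales(self, seed):
        rng = np.random.default_rng(seed)
        base = dict(k_n=10 ** rng.uniform(-5, -3), k_plus=10 ** rng.uniform(4, 6),
                    k2=10 ** rng.uniform(3, 5))
        lo = SecondaryNucleationParams(m0=3e-6, **base)
        hi = SecondaryNucleationParams(m0=6e-6, **base)
        t_lo = model_half_time(lo.kappa, lo.lam)
        t_hi = model_half_time(hi.kappa, hi.lam)
        assert t_hi < t_lo

    def test_parameter_domain_enforced(self):
        with pytest.raises(ValueError):
            SecondaryNucleationParams(m0=-1e-6, k_n=1.0, k_plus=1.0, k2=1.0)


class TestFit:
    def test_noise_free_recovery(self):
        p = SecondaryNucleationParams.from_effective_rates(4e-4, 4e-6)
        t = np.arange(101) * 400.0
        tr = NormalizedTrace(times=t, mass_fraction=model_mass_fraction(p, t))
        fit = fit_model([tr])
        assert fit.kappa == pytest.approx(4e-4, rel=0.02)
        assert fit.lam == pytest.approx(4e-6, rel=0.02)

    def test_flat_trace_raises(self):
        tr = NormalizedTrace(times=np.arange(20) * 400.0, mass_fraction=np.zeros(20))
        with pytest.raises(ValueError):
            fit_model([tr])

    def test_recovery_under_one_percent_noise(self):
        p = SecondaryNucleationParams.from_effective_rates(4e-4, 4e-6)
        t = np.arange(101) * 400.0
        truth = model_mass_fraction(p, t)
        true_t50 = model_half_time(4e-4, 4e-6)
        rng = np.random.default_rng(11)
        errs, t50_errs = [], []
        for _ in range(10):
            tr = NormalizedTrace(times=t, mass_fraction=truth + rng.normal(0, 0.01, len(t)))
            fit = fit_model([tr])
            errs.append(abs(fit.kappa / 4e-4 - 1.0))
            t50_errs.append(abs(model_half_time(fit.kappa, fit.lam) - true_t50))
        assert np.median(errs) < 0.05
        assert max(t50_errs) < 400.0


class TestAffineInvarianceOfStatistics:
    @given(
        st.floats(min_value=0.1, max_value=1e4),
        st.floats(min_value=-1e3, max_value=1e3),
    )
    @settings(max_examples=30, deadline=None)
    def test_summary_invariant_under_affine_signal_transform(self, a, b):
        tr = sigmoid_trace()
        transformed = KineticTrace(times=tr.times, signal=a * tr.signal + b)
        s0 = summarize(normalize(tr))
        s1 = summarize(normalize(transformed))
        assert s1.t_half == pytest.approx(s0.t_half, rel=1e-9)
        assert s1.t_lag == s0.t_lag
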