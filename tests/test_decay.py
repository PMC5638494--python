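"""Lifetime and anisotropy-decay analysis tests.

Frozen expected values were computed with independent oracles: closed
forms evaluated at 40-digit precision (sympy) for the single-exponential
phase/modulation relations, and numerical Fourier quadrature of the
time-domain decay for the multi-exponential sweep.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from actospec import synthetic as syn
from actospec.decay import (
    AnisotropyDecayModel,
    DecayModel,
    PolarizedIntensities,
    average_lifetime,
    compute_anisotropy_trace,
    fit_anisotropy_decay,
    fit_intensity_decay,
    g_factor,
    phase_modulation,
    steady_state_anisotropy,
)


class TestDecayModel:
    def test_amplitudes_normalised_and_sorted(self):
        m = DecayModel((2.0, 6.0), (5.0, 1.0))
        assert m.lifetimes_ns == (1.0, 5.0)
        assert m.amplitudes == pytest.approx((0.75, 0.25))
        assert sum(m.amplitudes) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            DecayModel((1.0, -0.1), (1.0, 5.0))
        with pytest.raises(ValueError):
            DecayModel((1.0,), (0.0,))

    def test_intensity_by_direct_summation_oracle(self):
        # I(2 ns) for a=(0.5, 0.5), tau=(1, 5): 0.5 e^-2 + 0.5 e^-0.4
        m = DecayModel((0.5, 0.5), (1.0, 5.0))
        assert m.intensity(np.array([2.0]))[0] == pytest.approx(
            0.4028276646361260, rel=1e-12
        )


class TestPhaseModulation:
    def test_single_exponential_closed_form_at_omega_tau_one(self):
        # omega tau = 1 -> phase 45 deg, modulation 1/sqrt(2)
        tau = 3.0
        f_mhz = 1e3 / (2.0 * np.pi * tau)
        ph, m = phase_modulation(DecayModel((1.0,), (tau,)), np.array([f_mhz]))
        assert ph[0] == pytest.approx(45.0, rel=1e-12)
        assert m[0] == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-12)

    def test_single_exponential_against_high_precision_oracle(self):
        # tau = 2.92 ns at 80 MHz, closed forms evaluated at 40 digits
        ph, m = phase_modulation(DecayModel((1.0,), (2.92,)), np.array([80.0]))
        assert ph[0] == pytest.approx(55.73284896709922, rel=1e-12)
        assert m[0] == pytest.approx(0.5630523355000478, rel=1e-12)

    def test_two_component_against_frozen_transform_oracle(self):
        # a=(0.7, 0.3), tau=(1, 5) ns at 50 MHz; frozen 30-digit values
        # from the intensity-fraction transforms
        ph, m = phase_modulation(
            DecayModel((0.7, 0.3), (1.0, 5.0)), np.array([50.0])
        )
        assert ph[0] == pytest.approx(39.43218467673215, rel=1e-12)
        assert m[0] == pytest.approx(0.6295322315957694, rel=1e-12)

    def test_two_component_against_quadrature_oracle(self):
        # Fourier sine/cosine integrals of the time-domain decay
        model = DecayModel((0.7, 0.3), (1.0, 5.0))
        f_mhz = 50.0
        omega = 2.0 * np.pi * f_mhz * 1e-3  # per ns

        def intensity(t):
            return 0.7 * np.exp(-t / 1.0) + 0.3 * np.exp(-t / 5.0)

        n_w = quad(lambda t: intensity(t) * np.sin(omega * t), 0, 200, limit=400)[0]
        d_w = quad(lambda t: intensity(t) * np.cos(omega * t), 0, 200, limit=400)[0]
        total = quad(intensity, 0, 200)[0]
        ph, m = phase_modulation(model, np.array([f_mhz]))
        assert ph[0] == pytest.approx(np.degrees(np.arctan2(n_w, d_w)), rel=1e-8)
        assert m[0] == pytest.approx(np.hypot(n_w, d_w) / total, rel=1e-8)

    def test_empty_frequency_list_rejected(self):
        with pytest.raises(ValueError):
            phase_modulation(DecayModel((1.0,), (3.0,)), np.array([]))

    @given(
        tau1=st.floats(0.2, 10.0),
        tau2=st.floats(0.2, 10.0),
        a1=st.floats(0.1, 0.9),
    )
    @settings(max_examples=50, deadline=None)
    def test_modulation_strictly_decreasing_in_frequency(self, tau1, tau2, a1):
        # Note: the phase of a heterogeneous decay is NOT globally monotone
        # (it can dip between the two lifetime regimes, e.g. tau=(0.26, 5) ns
        # at equal amplitude), so strict monotonicity is asserted for the
        # modulation only; phase stays within its physical quadrant.
        model = DecayModel((a1, 1.0 - a1), tuple(sorted((tau1, tau2 + 0.01))))
        f = np.geomspace(1.0, 500.0, 60)
        ph, m = phase_modulation(model, f)
        assert np.all(np.diff(m) < 0)
        assert np.all((ph > 0) & (ph < 90))

    @given(tau=st.floats(0.2, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_single_component_phase_strictly_increasing(self, tau):
        f = np.geomspace(1.0, 500.0, 60)
        ph, _ = phase_modulation(DecayModel((1.0,), (tau,)), f)
        assert np.all(np.diff(ph) > 0)


class TestAverageLifetime:
    def test_single_component_identity_under_both_weightings(self):
        m = DecayModel((1.0,), (3.0,))
        assert average_lifetime(m, "amplitude") == pytest.approx(3.0)
        assert average_lifetime(m, "intensity") == pytest.approx(3.0)

    def test_amplitude_weighted_arithmetic(self):
        m = DecayModel((0.7, 0.3), (1.0, 5.0))
        assert average_lifetime(m, "amplitude") == pytest.approx(2.2, rel=1e-12)

    def test_intensity_weighted_formula(self):
        # (0.7*1 + 0.3*25) / (0.7*1 + 0.3*5) = 8.2 / 2.2
        m = DecayModel((0.7, 0.3), (1.0, 5.0))
        assert average_lifetime(m, "intensity") == pytest.approx(
            3.727272727272727, rel=1e-12
        )


class TestGFactorAndSteadyState:
    def test_g_factor_definition(self):
        assert g_factor(PolarizedIntensities(1, 1, 1.2, 1.0)) == pytest.approx(1.2)
        assert g_factor(PolarizedIntensities(1, 1, 2.0, 2.0)) == pytest.approx(1.0)

    def test_g_factor_requires_positive_ihh(self):
        with pytest.raises(ValueError):
            g_factor(PolarizedIntensities(1, 1, 1, 0))

    def test_isotropic_emission_gives_zero(self):
        assert steady_state_anisotropy(
            PolarizedIntensities(2.0, 2.0), g=1.0
        ) == pytest.approx(0.0)

    def test_unit_g_reduces_to_uncorrected_formula(self):
        pol = PolarizedIntensities(1.3, 0.9)
        expected = (1.3 - 0.9) / (1.3 + 2 * 0.9)
        assert steady_state_anisotropy(pol, g=1.0) == pytest.approx(expected)

    def test_constructed_intensities_recover_target_anisotropy(self):
        r, g = 0.083, 1.1
        pol = PolarizedIntensities(
            i_vv=(1 + 2 * r) / 3.0, i_vh=(1 - r) / (3.0 * g)
        )
        assert steady_state_anisotropy(pol, g) == pytest.approx(r, abs=1e-15)


class TestAnisotropyTrace:
    def test_isotropic_traces_give_zero_anisotropy(self):
        t = np.linspace(0, 20, 200)
        traces = syn.PolarizedDecayTraces(
            time_ns=t, i_vv=np.exp(-t / 3), i_vh=np.exp(-t / 3), g_factor=1.0
        )
        trace = compute_anisotropy_trace(traces)
        assert np.allclose(trace.r, 0.0, atol=1e-14)

    def test_generated_trace_matches_model_at_origin_and_phi(self):
        decay = DecayModel((1.0,), (2.92,))
        aniso = AnisotropyDecayModel((0.2,), (35.9,))
        traces = syn.gen_polarized_decay(
            decay, aniso, 1.0, np.linspace(0.0, 40.0, 4096)
        )
        t, r, _w = compute_anisotropy_trace(traces)
        assert r[0] == pytest.approx(0.2, rel=1e-9)
        # r(phi) = r0 / e, checked at the grid point nearest t = 35.9 ns
        idx = np.argmin(np.abs(t - 35.9))
        assert r[idx] == pytest.approx(0.2 * np.exp(-t[idx] / 35.9), rel=1e-9)

    def test_g_rescaling_identity(self):
        # r computed with G=1.1 equals r from i_vh pre-scaled by 1.1 at G=1
        rng = np.random.default_rng(7)
        t = np.linspace(0, 10, 100)
        i_vv = np.exp(-t / 3) * (1 + 0.1 * rng.random(t.size))
        i_vh = np.exp(-t / 3) * (0.8 + 0.1 * rng.random(t.size))
        a = syn.PolarizedDecayTraces(t, i_vv, i_vh, g_factor=1.1)
        b = syn.PolarizedDecayTraces(t, i_vv, 1.1 * i_vh, g_factor=1.0)
        ra = compute_anisotropy_trace(a).r
        rb = compute_anisotropy_trace(b).r
        np.testing.assert_allclose(ra, rb, rtol=1e-12)

    def test_all_zero_traces_rejected(self):
        t = np.linspace(0, 10, 50)
        traces = syn.PolarizedDecayTraces(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError):
            compute_anisotropy_trace(traces)

    def test_window_truncated_at_one_percent_of_peak(self):
        decay = DecayModel((1.0,), (3.0,))
        traces = syn.gen_polarized_decay(decay, None, 1.0, np.linspace(0, 50, 512))
        t = compute_anisotropy_trace(traces).time_ns
        # exp(-t/3) >= 0.01 until t = 3 ln(100) ~ 13.8 ns
        assert t[-1] <= 3.0 * np.log(100.0) + 0.2
        assert t[-1] >= 3.0 * np.log(100.0) - 0.5


class TestIntensityDecayFit:
    def test_noiseless_single_component_sweep_recovery(self):
        sweep = syn.gen_frequency_sweep(
            DecayModel((1.0,), (3.0,)), np.geomspace(5, 200, 12)
        )
        rep = fit_intensity_decay(sweep, 1)
        assert rep.converged
        assert rep.parameters.lifetimes_ns[0] == pytest.approx(3.0, rel=1e-6)
        assert rep.chi_sq_reduced == pytest.approx(0.0, abs=1e-12)

    def test_reported_lifetime_sweep_recovery(self):
        sweep = syn.gen_frequency_sweep(
            DecayModel((1.0,), (2.92,)), np.geomspace(5, 200, 10)
        )
        rep = fit_intensity_decay(sweep, 1)
        assert average_lifetime(rep.parameters) == pytest.approx(2.92, rel=1e-6)

    def test_time_domain_two_component_recovery(self):
        model = DecayModel((0.6, 0.4), (1.0, 5.0))
        traces = syn.gen_polarized_decay(model, None, 1.0, np.linspace(0, 50, 1024))
        rep = fit_intensity_decay(traces, 2)
        assert rep.converged
        assert rep.parameters.lifetimes_ns == pytest.approx((1.0, 5.0), rel=1e-6)
        assert rep.parameters.amplitudes == pytest.approx((0.6, 0.4), rel=1e-6)

    def test_amplitude_normalisation_preserved(self):
        sweep = syn.gen_frequency_sweep(
            DecayModel((0.7, 0.3), (1.0, 5.0)), np.geomspace(2, 300, 25)
        )
        rep = fit_intensity_decay(sweep, 2)
        assert sum(rep.parameters.amplitudes) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_two_component_median_recovery_vs_lattice_oracle(self):
        # median long-lifetime estimate over seeds within 2% of truth, and
        # consistent with an exhaustive coarse lattice search on one replicate
        truth = DecayModel((0.7, 0.3), (1.0, 5.0))
        freqs = np.geomspace(2, 300, 30)
        tau2_hats = []
        for seed in range(40):
            sweep = syn.gen_frequency_sweep(
                truth, freqs, syn.NoiseSpec(sigma=0.002, seed=seed)
            )
            rep = fit_intensity_decay(sweep, 2)
            tau2_hats.append(rep.parameters.lifetimes_ns[-1])
        assert np.median(tau2_hats) == pytest.approx(5.0, rel=0.02)

        # lattice oracle on the first replicate
        sweep = syn.gen_frequency_sweep(
            truth, freqs, syn.NoiseSpec(sigma=0.002, seed=0)
        )
        best = (np.inf, None)
        for a1 in np.linspace(0.5, 0.9, 9):
            for t1 in np.linspace(0.6, 1.6, 11):
                for t2 in np.linspace(3.5, 6.5, 13):
                    ph, m = phase_modulation(DecayModel((a1, 1 - a1), (t1, t2)), freqs)
                    cost = np.sum(np.radians(ph - sweep.phase_deg) ** 2) + np.sum(
                        (m - sweep.modulation) ** 2
                    )
                    if cost < best[0]:
                        best = (cost, t2)
        rep = fit_intensity_decay(sweep, 2)
        # fitted tau2 within one lattice cell of the exhaustive-search optimum
        assert abs(rep.parameters.lifetimes_ns[-1] - best[1]) < 0.25

    def test_invalid_component_count_rejected(self):
        sweep = syn.gen_frequency_sweep(DecayModel((1.0,), (3.0,)), [10, 20, 50])
        with pytest.raises(ValueError):
            fit_intensity_decay(sweep, 4)


class TestAnisotropyDecayFit:
    def test_noiseless_single_component_exact(self):
        t = np.linspace(0, 60, 600)
        r = 0.3 * np.exp(-t / 10.0)
        rep = fit_anisotropy_decay(t, r, 1)
        assert rep.parameters.fractional_anisotropies[0] == pytest.approx(0.3, rel=1e-8)
        assert rep.parameters.correlation_times_ns[0] == pytest.approx(10.0, rel=1e-8)

    def test_two_component_slow_time_recovery(self):
        decay = DecayModel((1.0,), (2.92,))
        aniso = AnisotropyDecayModel((0.1, 0.15), (0.5, 35.9))
        traces = syn.gen_polarized_decay(
            decay, aniso, 1.0, np.linspace(0, 150, 2048)
        )
        t, r, w = compute_anisotropy_trace(traces)
        rep = fit_anisotropy_decay(t, r, 2, weights=w)
        assert rep.parameters.correlation_times_ns[-1] == pytest.approx(35.9, rel=1e-6)

    def test_cterm_like_recovery_under_noise(self):
        # 6.9 ns correlation time, noisy replicates: median within 5%
        decay = DecayModel((1.0,), (3.26,))
        aniso = AnisotropyDecayModel((0.05, 0.2), (0.4, 6.9))
        grid = np.linspace(0, 40, 1024)
        hats = []
        for seed in range(40):
            traces = syn.gen_polarized_decay(
                decay, aniso, 1.0, grid, syn.NoiseSpec(sigma=0.005, seed=seed)
            )
            t, r, w = compute_anisotropy_trace(traces)
            rep = fit_anisotropy_decay(t, r, 2, weights=w)
            hats.append(rep.parameters.correlation_times_ns[-1])
        assert np.median(hats) == pytest.approx(6.9, rel=0.05)

    def test_subnanosecond_component_flagged(self):
        t = np.linspace(0, 50, 256)  # ~0.2 ns spacing
        r = 0.15 * np.exp(-t / 0.3) + 0.1 * np.exp(-t / 20.0)
        rep = fit_anisotropy_decay(t, r, 2)
        assert any("resolution-limited" in f for f in rep.flags)


class TestSteadyStateConsistency:
    def test_steady_state_equals_intensity_weighted_time_average(self):
        # r_ss from time-integrated polarized decays vs quadrature of I(t) r(t)
        decay = DecayModel((0.6, 0.4), (1.5, 4.0))
        aniso = AnisotropyDecayModel((0.08, 0.12), (1.0, 20.0))
        grid = np.linspace(0, 120.0, 8192)
        traces = syn.gen_polarized_decay(decay, aniso, 1.0, grid)
        i_vv = np.trapezoid(traces.i_vv, grid)
        i_vh = np.trapezoid(traces.i_vh, grid)
        r_ss = steady_state_anisotropy(PolarizedIntensities(i_vv, i_vh), g=1.0)

        num = quad(
            lambda t: decay.intensity(np.array([t]))[0]
            * aniso.anisotropy(np.array([t]))[0],
            0,
            300,
            limit=400,
        )[0]
        den = quad(lambda t: decay.intensity(np.array([t]))[0], 0, 300, limit=400)[0]
        assert r_ss == pytest.approx(num / den, abs=1e-4)
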