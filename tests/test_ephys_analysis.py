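"""Photocurrent characterization: peaks, exponential fits, spectra, ramps."""

import numpy as np
import pytest

from conftest import one_pulse_trace
from optopair.ephys_analysis import (
    DegenerateInputError,
    IVRamp,
    NoCrossingError,
    action_spectrum,
    desensitization_ratio,
    fit_off_tau,
    fit_on_tau,
    normalize_photocurrent,
    peak_photocurrent,
    percent_reduction,
    reversal_potential,
    wavelength_ratio,
)
from optopair.opsin_models import Trace, equal_flux_irradiance


def decay_trace(tau_ms=10.0, amp=-100.0, dt=1e-4, t_off=0.05, total=0.4,
                noise_sd=0.0, rng=None):
    t = np.arange(int(total / dt)) * dt
    y = np.zeros_like(t)
    mask = t >= t_off
    y[mask] = amp * np.exp(-(t[mask] - t_off) * 1e3 / tau_ms)
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, y.size)
    return Trace(t0=0.0, dt=dt, values=y)


class TestPeak:
    def test_flat_trace_zero_peak(self):
        tr = Trace(0.0, 1e-4, np.zeros(1000))
        assert peak_photocurrent(tr, (0.05, 0.08)) == 0.0

    def test_square_deflection_signed(self):
        v = np.zeros(2000)
        v[600:1200] = -200.0
        tr = Trace(0.0, 1e-4, v)
        assert peak_photocurrent(tr, (0.06, 0.12)) == -200.0

    def test_empty_window_rejected(self):
        tr = Trace(0.0, 1e-4, np.zeros(100))
        with pytest.raises(ValueError):
            peak_photocurrent(tr, (0.5, 0.6))

    def test_peak_magnitude_nondecreasing_in_irradiance(self, ivfchr):
        peaks = []
        for irr in (1.0, 4.0, 10.0):
            tr, proto = one_pulse_trace(ivfchr, 585.0, irr, duration=0.2)
            peaks.append(abs(peak_photocurrent(tr, (0.1, 0.3))))
        assert peaks[0] <= peaks[1] <= peaks[2]


class TestOffTauFit:
    def test_exact_recovery_noiseless(self):
        fit = fit_off_tau(decay_trace(tau_ms=10.0), light_off=0.05)
        assert fit.converged
        assert fit.tau == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(-100.0, rel=1e-4)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        tr = decay_trace(tau_ms=12.0, amp=-100.0, noise_sd=5.0, rng=rng)
        fit = fit_off_tau(tr, light_off=0.05, fit_len=0.1)
        # brute-force SSE grid over tau with the amplitude profiled out
        i0 = tr.index_of(0.05)
        t_ms = (tr.times[i0:] - 0.05) * 1e3
        y = tr.values[i0:]
        n = int(round(0.1 / tr.dt))
        t_ms, y = t_ms[:n], y[:n]
        taus = np.linspace(1.0, 50.0, 4000)
        best_tau, best_sse = None, np.inf
        for tau in taus:
            basis = np.exp(-t_ms / tau)
            a = (basis @ y) / (basis @ basis)
            sse = np.sum((y - a * basis) ** 2)
            if sse < best_sse:
                best_sse, best_tau = sse, tau
        assert fit.tau == pytest.approx(best_tau, rel=0.01)

    def test_simulated_slow_anion_channel_recovered(self, opsin_table):
        p = opsin_table["GtACR2"]
        tr, proto = one_pulse_trace(p, 470.0, 10.0, duration=1.0, dt=1e-4)
        fit = fit_off_tau(tr, proto.epochs[0].t_off)
        assert fit.converged
        assert fit.tau == pytest.approx(161.0, rel=0.02)

    @pytest.mark.parametrize("tau", [2.0, 9.5, 47.0, 161.0, 300.0])
    def test_fit_closure_across_tau_range(self, zipacr, tau):
        p = zipacr.with_(tau_off=tau, k_desens=0.0)
        tr, proto = one_pulse_trace(p, 470.0, 10.0, duration=0.3, dt=1e-4)
        fit = fit_off_tau(tr, proto.epochs[0].t_off)
        assert fit.tau == pytest.approx(tau, rel=0.02)

    def test_all_zero_segment_rejected(self):
        tr = Trace(0.0, 1e-4, np.zeros(1000))
        with pytest.raises(DegenerateInputError):
            fit_off_tau(tr, light_off=0.05)


class TestOnTauFit:
    def test_two_state_on_tau_closed_form(self, zipacr):
        # k_a = 0.1/ms with tau_off = 10 ms gives tau_on = 1/(0.1+0.1) = 5 ms
        from optopair.opsin_models import photon_flux

        p = zipacr.with_(
            tau_off=10.0, k_desens=0.0,
            sigma_eff=0.1 / photon_flux(10.0, 515.0),
        )
        tr, proto = one_pulse_trace(p, 515.0, 10.0, duration=0.1, dt=1e-5)
        fit = fit_on_tau(tr, proto.epochs[0].t_on, proto.epochs[0].t_off)
        assert fit.converged
        assert fit.tau == pytest.approx(5.0, rel=0.01)

    def test_on_tau_decreases_with_irradiance(self, opsin_table):
        p = opsin_table["Zip151T"].with_(k_desens=0.0)
        taus = []
        for irr in (0.5, 2.0, 10.0):
            tr, proto = one_pulse_trace(p, 470.0, irr, duration=0.15, dt=2e-5)
            fit = fit_on_tau(tr, proto.epochs[0].t_on, proto.epochs[0].t_off)
            taus.append(fit.tau)
        assert taus[0] > taus[1] > taus[2]

    def test_zero_length_segment_rejected(self):
        tr = Trace(0.0, 1e-4, np.ones(100))
        with pytest.raises(DegenerateInputError):
            fit_on_tau(tr, 0.005, 0.0051)


class TestNormalizationAndRatios:
    def test_normalization_arithmetic(self):
        assert normalize_photocurrent(-100.0, 10.0, 2.0) == -5.0
        assert normalize_photocurrent(-86.0, 20.0, 50.0) == pytest.approx(-0.086)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            normalize_photocurrent(-100.0, 0.0, 1.0)

    def test_equal_peaks_ratio_one(self):
        assert wavelength_ratio(-120.0, 120.0) == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wavelength_ratio(1.0, 0.0)

    def test_percent_reduction(self):
        assert percent_reduction(0.086, 0.145) == pytest.approx(40.69, abs=0.01)

    @pytest.mark.parametrize(
        "name,ref_nm,target,rel",
        [("HcKCR1", 530.0, 0.73, 0.03), ("HcKCR2", 470.0, 0.09, 0.30)],
    )
    def test_potassium_channel_590_response_ratio(self, opsin_table, name,
                                                  ref_nm, target, rel):
        p = opsin_table[name]
        peaks = {}
        for lam in (590.0, ref_nm):
            tr, proto = one_pulse_trace(p, lam, 10.0, duration=1.0, holding=-10.0)
            peaks[lam] = peak_photocurrent(tr, (proto.epochs[0].t_on, proto.epochs[0].t_off))
        assert wavelength_ratio(peaks[590.0], peaks[ref_nm]) == pytest.approx(target, rel=rel)


class TestActionSpectrum:
    def test_single_cell_normalized_to_unit_max(self):
        spec = action_spectrum({"c1": {470.0: -80.0, 515.0: -100.0, 590.0: -30.0}})
        assert max(m for m, _ in spec.values()) == pytest.approx(1.0)

    def test_gain_invariance_across_cells(self):
        base = {470.0: -80.0, 515.0: -100.0, 590.0: -30.0}
        doubled = {k: 2 * v for k, v in base.items()}
        spec = action_spectrum({"c1": base, "c2": doubled})
        for lam, (mean, sem) in spec.items():
            assert sem == pytest.approx(0.0, abs=1e-12)
            assert mean == pytest.approx(abs(base[lam]) / 100.0)

    def test_equal_flux_spectrum_peaks_near_515(self, zipacr):
        # sample 400-650 nm in 25-nm increments at the photon flux of
        # 15.4 mW/mm^2 at 650 nm
        responses = {}
        for lam in np.arange(400.0, 651.0, 25.0):
            irr = equal_flux_irradiance(15.4, 650.0, lam)
            tr, proto = one_pulse_trace(zipacr, lam, irr, duration=0.3, dt=5e-5)
            responses[lam] = peak_photocurrent(tr, (0.1, proto.epochs[0].t_off))
        spec = action_spectrum({"c1": responses})
        argmax = max(spec, key=lambda lam: spec[lam][0])
        assert abs(argmax - 515.0) <= 25.0

    def test_all_zero_cell_rejected(self):
        with pytest.raises(DegenerateInputError):
            action_spectrum({"c1": {470.0: 0.0, 590.0: 0.0}})


def make_ramp(e_rev, g=2.0, leak_g=1.5, e_leak=-70.0, offset=0.0, n=2000):
    v = np.linspace(-90.0, 30.0, n)
    dt = 1e-4
    i_chan = g * (v - e_rev)
    i_leak = leak_g * (v - e_leak) + offset
    on = IVRamp(Trace(0, dt, v, "mV", "voltage"), Trace(0, dt, i_chan + i_leak))
    off = IVRamp(Trace(0, dt, v, "mV", "voltage"), Trace(0, dt, i_leak))
    return on, off


class TestReversalPotential:
    def test_zero_reversal(self):
        on, off = make_ramp(0.0)
        assert reversal_potential(on, leak=off) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("e", [-65.2, -58.0, -50.7, -39.0, 0.0])
    def test_recovery_within_half_millivolt(self, e):
        on, off = make_ramp(e)
        assert reversal_potential(on, leak=off) == pytest.approx(e, abs=0.5)

    def test_offset_current_distractor_restored_by_leak_subtraction(self):
        on, off = make_ramp(-39.0, offset=40.0)
        shifted = reversal_potential(on)  # no subtraction: biased estimate
        assert abs(shifted - (-39.0)) > 2.0
        restored = reversal_potential(on, leak=off)
        assert restored == pytest.approx(-39.0, abs=0.5)

    def test_no_crossing_rejected(self):
        v = np.linspace(-90, -70, 100)
        ramp = IVRamp(Trace(0, 1e-4, v, "mV", "voltage"),
                      Trace(0, 1e-4, np.full(100, -50.0)))
        with pytest.raises(NoCrossingError):
            reversal_potential(ramp)


class TestDesensitization:
    def test_square_pulse_ratio_one(self):
        v = np.zeros(3000)
        v[1000:2000] = -150.0
        tr = Trace(0.0, 1e-4, v)
        assert desensitization_ratio(tr, 0.1, 0.2) == pytest.approx(1.0)

    def test_constructed_plateau_ratio(self):
        dt = 1e-4
        t = np.arange(3000) * dt
        v = np.zeros(3000)
        seg = (t >= 0.1) & (t < 0.2)
        v[seg] = -60.0 + -40.0 * np.exp(-(t[seg] - 0.1) / 0.01)
        tr = Trace(0.0, dt, v)
        assert desensitization_ratio(tr, 0.1, 0.2) == pytest.approx(0.6, rel=1e-3)

    def test_zero_peak_rejected(self):
        tr = Trace(0.0, 1e-4, np.zeros(3000))
        with pytest.raises(DegenerateInputError):
            desensitization_ratio(tr, 0.1, 0.2)

    def test_chrimson_desensitizes_more_at_higher_irradiance(self, ivfchr):
        ratios = []
        for irr in (4.0, 20.0):
            tr, proto = one_pulse_trace(ivfchr, 585.0, irr, duration=1.0)
            ratios.append(desensitization_ratio(tr, 0.1, 1.1))
        assert ratios[0] < 1.0 and ratios[1] < ratios[0]
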