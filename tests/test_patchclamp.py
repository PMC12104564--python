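"""Patch-clamp feature extraction against analytic sweep ground truth."""

import math

import numpy as np
import pytest

from nociscreen.doseresponse import boltzmann_inhibition
from nociscreen.patchclamp import (
    GapfreeClass,
    IapClass,
    IVCurve,
    PatchSweep,
    Protocol,
    StepEpoch,
    classify_current_step,
    classify_gapfree,
    extract_iv,
    resting_vm,
    spike_parameters,
    ttx_normalised_inhibition,
)
from nociscreen.synthgen import (
    simulate_ap_sweep,
    simulate_current_step_family,
    simulate_voltage_step_family,
)


class TestRestingVm:
    def test_constant_trace(self):
        t = np.arange(350000) / 10000.0
        sweep = PatchSweep(time=t, value=np.full_like(t, -60.0))
        assert resting_vm(sweep) == pytest.approx(-60.0)

    def test_spikes_excluded_from_mean(self):
        sweep, truth = simulate_ap_sweep("spontaneous", seed=4, duration=35.0,
                                         noise_sd_mv=0.1)
        assert resting_vm(sweep) == pytest.approx(truth.rest_mv, abs=0.5)

    def test_quiet_sweep_matches_truth_closely(self):
        sweep, truth = simulate_ap_sweep("quiet", seed=4, duration=35.0)
        assert resting_vm(sweep) == pytest.approx(truth.rest_mv, abs=0.1)

    def test_short_sweep_warns(self):
        t = np.arange(10000) / 10000.0
        sweep = PatchSweep(time=t, value=np.full_like(t, -55.0))
        with pytest.warns(UserWarning, match="shorter than 30 s"):
            assert resting_vm(sweep) == pytest.approx(-55.0)


class TestGapfreeClassification:
    @pytest.mark.parametrize("kind,expected", [
        ("quiet", GapfreeClass.QUIET),
        ("attempting", GapfreeClass.ATTEMPTING_SAP),
        ("spontaneous", GapfreeClass.SPONTANEOUS),
    ])
    def test_simulated_kinds_recovered(self, kind, expected):
        for seed in range(5):
            sweep, _ = simulate_ap_sweep(kind, seed=seed, duration=20.0)
            assert classify_gapfree(sweep) is expected

    def test_classification_stable_under_1mv_noise(self):
        for kind in ("quiet", "attempting", "spontaneous"):
            sweep, _ = simulate_ap_sweep(kind, seed=9, duration=20.0)
            noisy = PatchSweep(
                time=sweep.time,
                value=sweep.value + np.random.default_rng(1).normal(0, 1.0, sweep.value.size),
            )
            assert classify_gapfree(noisy) is classify_gapfree(sweep)


class TestCurrentStepClassification:
    @pytest.mark.parametrize("kind", [k.value for k in IapClass])
    def test_simulated_kinds_recovered(self, kind):
        for seed in range(3):
            family, _ = simulate_current_step_family(kind, seed=seed)
            assert classify_current_step(family) is IapClass(kind)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            classify_current_step([])


class TestSpikeParameters:
    def test_gaussian_spike_closed_form(self):
        # Gaussian spike of sigma = 0.5 ms: full width at half maximum
        # is 2*sigma*sqrt(2 ln 2) ~ 1.177 ms
        sweep, truth = simulate_ap_sweep("spontaneous", seed=6, duration=20.0,
                                         noise_sd_mv=0.05, sigma_ms=0.5)
        p = spike_parameters(sweep, 0)
        assert p.half_height_width == pytest.approx(truth.fwhm_ms, rel=0.05)

    def test_truth_recovery_across_sweep_bank(self):
        for seed in range(4):
            sweep, truth = simulate_ap_sweep("spontaneous", seed=seed,
                                             duration=20.0, noise_sd_mv=0.1)
            p = spike_parameters(sweep, 0)
            i = int(np.argmin(np.abs(truth.spike_times - p.peak_time)))
            assert p.overshoot == pytest.approx(truth.peak_mv[i], abs=1.0)
            assert p.half_height_width == pytest.approx(
                truth.half_height_width_ms, rel=0.05)
            assert p.depolarising_rate == pytest.approx(truth.max_dvdt[i], rel=0.05)
            assert -p.repolarising_rate == pytest.approx(truth.max_dvdt[i], rel=0.05)

    def test_overshoot_is_peak_voltage(self):
        sweep, truth = simulate_ap_sweep("spontaneous", seed=8, duration=20.0,
                                         noise_sd_mv=0.0)
        p = spike_parameters(sweep, 0)
        i = int(np.argmin(np.abs(truth.spike_times - p.peak_time)))
        assert p.overshoot == pytest.approx(truth.peak_mv[i], abs=0.1)
        assert p.spike_height == pytest.approx(p.overshoot - p.threshold)
        assert p.after_hyperpolarisation < 0

    def test_threshold_sits_early_on_the_rise(self):
        # for a Gaussian rise the third-derivative peak is at
        # -sqrt(3+sqrt(6))*sigma, i.e. ~6.6% of the amplitude
        sweep, truth = simulate_ap_sweep("spontaneous", seed=6, duration=20.0,
                                         noise_sd_mv=0.0)
        p = spike_parameters(sweep, 0)
        i = int(np.argmin(np.abs(truth.spike_times - p.peak_time)))
        amp = truth.peak_mv[i] - truth.rest_mv
        u = math.sqrt(3.0 + math.sqrt(6.0))
        expected = truth.rest_mv + amp * math.exp(-0.5 * u * u)
        assert p.threshold == pytest.approx(expected, abs=0.1 * amp)

    def test_missing_spike_index_rejected(self):
        sweep, _ = simulate_ap_sweep("quiet", seed=1, duration=10.0)
        with pytest.raises(IndexError):
            spike_parameters(sweep, 0)


def _flat_family(levels, value_fn, fs=20000.0):
    sweeps = []
    pre, step, post = 0.05, 0.2, 0.05
    n = int((pre + step + post) * fs)
    t = np.arange(n) / fs
    for lv in levels:
        v = np.zeros(n)
        in_step = (t >= pre) & (t < pre + step)
        v[in_step] = value_fn(lv)
        sweeps.append(PatchSweep(
            time=t, value=v, protocol=Protocol.VOLTAGE_STEP,
            step_schedule=(StepEpoch(-70.0, 0.0, pre), StepEpoch(lv, pre, step),
                           StepEpoch(-70.0, pre + step, post)),
        ))
    return sweeps


class TestIVExtraction:
    def test_constant_outward_plateau_is_kv_steady(self):
        fam = _flat_family([0.0, 20.0], lambda lv: 200.0)
        iv = extract_iv(fam)
        assert iv.at(0.0, "kv_steady") == pytest.approx(200.0)

    def test_known_inward_peak_recovered(self):
        fam = _flat_family([-35.0, 0.0], lambda lv: -500.0 if lv == -35.0 else 0.0)
        iv = extract_iv(fam)
        assert iv.at(-35.0) == pytest.approx(-500.0)
        assert iv.at(0.0) == pytest.approx(0.0)

    def test_ttx_family_has_no_inward_current(self):
        exp = simulate_voltage_step_family(4.0, 3.2, [4.0])
        iv = extract_iv(exp.ttx)
        assert np.all(iv.nav_activation >= -1e-9)

    def test_missing_schedule_rejected(self):
        t = np.arange(1000) / 20000.0
        sweep = PatchSweep(time=t, value=np.zeros_like(t),
                           protocol=Protocol.VOLTAGE_STEP)
        with pytest.raises(ValueError):
            extract_iv([sweep])


class TestTtxNormalisation:
    def _curves(self):
        pots = np.array([-40.0, -35.0, -30.0])
        mk = lambda peak: IVCurve(pots, np.array([0.0, peak, 0.0]),
                                  np.zeros(3), np.zeros(3))
        return mk(-1000.0), mk(0.0)

    def test_endpoints_and_midpoint(self):
        ctl, ttx = self._curves()
        assert ttx_normalised_inhibition(ctl, ctl, ttx) == pytest.approx(0.0)
        assert ttx_normalised_inhibition(ctl, ttx, ttx) == pytest.approx(1.0)
        halfway = IVCurve(ctl.test_potentials, np.array([0.0, -500.0, 0.0]),
                          np.zeros(3), np.zeros(3))
        assert ttx_normalised_inhibition(ctl, halfway, ttx) == pytest.approx(0.5)

    def test_equal_control_and_ttx_rejected(self):
        ctl, ttx = self._curves()
        with pytest.raises(ValueError):
            ttx_normalised_inhibition(ttx, ttx, ttx)

    def test_monotone_in_true_inhibition_fraction(self):
        concs = [1.0, 2.0, 4.0, 8.0, 16.0]
        exp = simulate_voltage_step_family(4.0, 3.2, concs)
        ctl, ttx = extract_iv(exp.control), extract_iv(exp.ttx)
        measured = [
            ttx_normalised_inhibition(ctl, extract_iv(exp.by_concentration[c]), ttx)
            for c in concs
        ]
        truth = [boltzmann_inhibition(c, 4.0, 3.2) for c in concs]
        assert np.all(np.diff(measured) > 0)
        np.testing.assert_allclose(measured, truth, atol=0.02)
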