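"""Statistical and determinism contracts of the synthetic generator."""

import numpy as np
import pytest
from scipy import stats

from nociscreen import Phase, boltzmann_inhibition
from nociscreen.patchclamp import extract_iv, ttx_normalised_inhibition
from nociscreen.synthgen import (
    CompoundTruth,
    PlateSpec,
    simulate_ap_sweep,
    simulate_current_step_family,
    simulate_ldh,
    simulate_plate,
    simulate_rate_table,
    simulate_voltage_step_family,
)
from nociscreen.toxicity import is_cytotoxic, ldh_activity
from nociscreen.pipeline import readings_from_table, toxicity_flags


class TestPlateSimulation:
    def test_same_seed_bitwise_identical(self, small_spec):
        a = simulate_plate(small_spec)
        b = simulate_plate(small_spec)
        for key in a.channels():
            for phase in Phase:
                assert np.array_equal(a.traces[key][phase].samples,
                                      b.traces[key][phase].samples)
                assert np.array_equal(a.true_spike_times[key][phase],
                                      b.true_spike_times[key][phase])

    def test_adding_wells_preserves_existing_channels(self):
        small = PlateSpec(n_wells=2, n_electrodes_per_well=4, duration=10.0, seed=3)
        big = PlateSpec(n_wells=4, n_electrodes_per_well=4, duration=10.0, seed=3)
        a = simulate_plate(small, render=False)
        b = simulate_plate(big, render=False)
        for key in a.channels():
            for phase in Phase:
                assert np.array_equal(a.true_spike_times[key][phase],
                                      b.true_spike_times[key][phase])

    def test_baseline_rate_calibrated_within_3_se(self):
        spec = PlateSpec(n_wells=4, n_electrodes_per_well=12, duration=300.0,
                         active_fraction=1.0, seed=5)
        plate = simulate_plate(spec, render=False)
        z = []
        for key in plate.channels():
            rate = plate.true_rates[key][Phase.BASELINE]
            n = plate.true_spike_times[key][Phase.BASELINE].size
            expected = rate * spec.duration
            z.append(abs(n - expected) / np.sqrt(expected))
        z = np.asarray(z)
        # per-channel counts are Poisson around the drawn rate: nearly
        # all within 3 SE, none grossly off
        assert np.mean(z <= 3.0) >= 0.95
        assert z.max() <= 4.5

    def test_washout_rate_between_post_and_baseline(self, small_spec, suppressor_truth):
        exposures = {"W01": ("CMP", 10.0)}
        plate = simulate_plate(small_spec, exposures, {"CMP": suppressor_truth},
                               render=False)
        for elec in small_spec.electrode_ids():
            r = plate.true_rates[("W01", elec)]
            assert r[Phase.POST] <= r[Phase.WASHOUT] <= r[Phase.BASELINE]

    def test_rendered_spike_count_matches_truth(self, small_plate):
        # every template insertion leaves a negative trough well below
        # the Gaussian noise floor at the recorded time
        spec = small_plate.spec
        for key in small_plate.channels():
            trace = small_plate.traces[key][Phase.BASELINE]
            truth = small_plate.true_spike_times[key][Phase.BASELINE]
            for t in truth:
                i = int(round(t * spec.sampling_rate))
                seg = trace.samples[i:i + 8]
                assert seg.min() < -0.8 * spec.spike_amplitude

    def test_at_ic50_post_counts_are_halved(self, suppressor_truth):
        spec = PlateSpec(n_wells=4, n_electrodes_per_well=12, duration=300.0,
                         active_fraction=1.0, seed=21)
        exposures = {w: ("CMP", suppressor_truth.ic50_true) for w in spec.well_ids()}
        plate = simulate_plate(spec, exposures, {"CMP": suppressor_truth},
                               render=False)
        n_post = sum(plate.true_spike_times[k][Phase.POST].size
                     for k in plate.channels())
        expected = sum(plate.true_rates[k][Phase.BASELINE]
                       for k in plate.channels()) * spec.duration / 2.0
        assert abs(n_post - expected) < 4.0 * np.sqrt(expected)

    def test_null_compound_leaves_rates_unchanged(self):
        # concentration 0 everywhere: paired Wilcoxon across channels is
        # non-significant at alpha=.01 in nearly all seeds
        truth = CompoundTruth("X", 2.0, 3.0)
        nonsig = 0
        for seed in range(20):
            spec = PlateSpec(n_wells=2, n_electrodes_per_well=12, duration=300.0,
                             active_fraction=1.0, seed=seed)
            exposures = {w: ("X", 0.0) for w in spec.well_ids()}
            plate = simulate_plate(spec, exposures, {"X": truth}, render=False)
            before = [plate.true_spike_times[k][Phase.BASELINE].size
                      for k in plate.channels()]
            after = [plate.true_spike_times[k][Phase.POST].size
                     for k in plate.channels()]
            d = np.array(after) - np.array(before)
            p = stats.wilcoxon(d[d != 0]).pvalue if np.any(d != 0) else 1.0
            nonsig += p >= 0.01
        assert nonsig >= 19

    def test_invalid_exposures_rejected(self, small_spec, suppressor_truth):
        with pytest.raises(KeyError):
            simulate_plate(small_spec, {"W01": ("nope", 1.0)},
                           {"CMP": suppressor_truth})
        with pytest.raises(ValueError):
            simulate_plate(small_spec, {"W01": ("CMP", -1.0)},
                           {"CMP": suppressor_truth})

    def test_rate_table_consistent_with_plate(self, small_spec):
        table = simulate_rate_table(small_spec)
        plate = simulate_plate(small_spec, render=False)
        for _, row in table.iterrows():
            key = (row["well"], row["electrode"])
            n = plate.true_spike_times[key][Phase(row["phase"])].size
            assert row["rate_hz"] == pytest.approx(n / small_spec.duration)


class TestLdhSimulation:
    def test_toxicity_flags_recover_truth_across_seeds(self):
        truths = {
            "TOX": CompoundTruth("TOX", 2.0, 3.0, toxic=True),
            "SAFE": CompoundTruth("SAFE", 2.0, 3.0, toxic=False),
        }
        ok_tox = ok_safe = 0
        for seed in range(200):
            flags = toxicity_flags(readings_from_table(simulate_ldh(truths, seed=seed)))
            ok_tox += flags["TOX"]
            ok_safe += not flags["SAFE"]
        assert ok_tox >= 195
        assert ok_safe >= 195

    def test_zero_noise_sample_at_vehicle_level_scores_zero(self):
        table = simulate_ldh({"C": CompoundTruth("C", 2.0, 3.0)}, seed=0,
                             noise_sd=0.0, nontoxic_effect=0.0)
        readings = readings_from_table(table)
        veh = next(r for r in readings if r.role == "vehicle")
        pos = next(r for r in readings if r.role == "positive_control")
        smp = next(r for r in readings if r.role == "sample")
        assert ldh_activity(smp, veh, pos) == pytest.approx(0.0)
        assert not is_cytotoxic(0.0)


class TestVoltageStepSimulation:
    def test_negligible_block_matches_control(self):
        # ic50 >> h: the inhibition fraction at c=0 is ~0, so the inward
        # peak equals the control amplitude
        exp = simulate_voltage_step_family(50.0, 5.0, [0.0])
        ctl = extract_iv(exp.control)
        c0 = extract_iv(exp.by_concentration[0.0])
        assert c0.at(-35.0) == pytest.approx(ctl.at(-35.0), rel=1e-4)

    def test_ttx_removes_inward_component(self):
        exp = simulate_voltage_step_family(4.0, 3.2, [4.0])
        ttx = extract_iv(exp.ttx)
        assert np.all(ttx.nav_activation >= -1e-9)

    def test_half_block_at_ic50(self):
        exp = simulate_voltage_step_family(50.0, 5.0, [50.0])
        frac = ttx_normalised_inhibition(
            extract_iv(exp.control), extract_iv(exp.by_concentration[50.0]),
            extract_iv(exp.ttx))
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_envelope_peaks_at_minus_35(self):
        exp = simulate_voltage_step_family(50.0, 5.0, [0.0])
        ctl = extract_iv(exp.control)
        peak_v = ctl.test_potentials[np.argmin(ctl.nav_activation)]
        assert peak_v == -35.0

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_voltage_step_family(4.0, 3.2, [])


class TestCurrentClampSimulation:
    def test_quiet_sweep_stays_below_minus_40(self):
        sweep, truth = simulate_ap_sweep("quiet", seed=1, duration=20.0)
        assert sweep.value.max() < -40.0
        assert truth.spike_times.size == 0

    def test_attempting_peaks_between_minus_40_and_0(self):
        _, truth = simulate_ap_sweep("attempting", seed=2, duration=20.0)
        assert truth.spike_times.size > 0
        assert np.all(truth.peak_mv > -40.0)
        assert np.all(truth.peak_mv < 0.0)

    def test_spontaneous_has_overshooting_spikes(self):
        _, truth = simulate_ap_sweep("spontaneous", seed=2, duration=20.0)
        assert np.any(truth.peak_mv >= 0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_ap_sweep("bursting")
        with pytest.raises(ValueError):
            simulate_current_step_family("bursting")

    def test_boltzmann_midpoint_closed_form(self):
        assert boltzmann_inhibition(4.0, 4.0, 3.2) == pytest.approx(0.5)
        assert boltzmann_inhibition(4.0 + 3.2, 4.0, 3.2) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)))
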