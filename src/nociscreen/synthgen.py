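"""Synthetic multiwell-MEA plates, assay readouts and patch sweeps.

The generator emulates the statistical structure of the screening
campaign so every downstream stage can be exercised without recordings:

* **MEA plates** — 24 wells × 12 electrodes, 300 s phases at 20 kHz by
  default.  Each channel fires as a homogeneous Poisson process (with
  an absolute refractory period equal to the detector dead time, so
  ground truth is recoverable) whose rate is drawn log-normally across
  channels; a configurable fraction of channels is silent.  Compound
  exposure multiplies the rate by the Hill activity model, washout
  restores a configurable fraction of the suppressed rate, and spikes
  are rendered as a fixed negative-leading biphasic 1 ms template in
  zero-mean Gaussian noise.
* **LDH tables** — background and signal absorbances with vehicle and
  lysis positive controls, at 1/6/24 h.
* **Voltage-step families** — a stylised Naᵥ-like inward transient
  (difference of exponentials, amplitude envelope peaking at the
  −35 mV step) scaled by the Boltzmann inhibition fraction, plus a
  compound-insensitive sustained Kᵥ-like outward current; TTX removes
  the inward component entirely.
* **Current-clamp sweeps** — gap-free and current-step protocols with
  Gaussian-shaped spikes whose analytic peak, width and maximal slopes
  are recorded as ground truth.

Determinism: identical (spec, exposures, seed) gives bit-identical
output.  Each channel derives its generator from a stable
``SeedSequence`` spawn key, so adding wells does not perturb existing
channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import boltzmann_inhibition, hill_activity
from .patchclamp import GapfreeClass, IapClass, PatchSweep, Protocol, StepEpoch
from .spikes import ChannelTrace, Phase

__all__ = [
    "PlateSpec",
    "CompoundTruth",
    "SimulatedPlate",
    "simulate_plate",
    "simulate_rate_table",
    "simulate_ldh",
    "VoltageStepExperiment",
    "simulate_voltage_step_family",
    "ApSweepTruth",
    "simulate_ap_sweep",
    "simulate_current_step_family",
]

PHASES = (Phase.BASELINE, Phase.POST, Phase.WASHOUT)


@dataclass(frozen=True)
class PlateSpec:
    """Geometry, timing and firing statistics of a simulated plate."""

    n_wells: int = 24
    n_electrodes_per_well: int = 12
    sampling_rate: float = 20000.0  # Hz
    duration: float = 300.0  # s per phase
    noise_sd: float = 3.0  # µV
    spike_amplitude: float = 30.0  # µV, template peak magnitude
    baseline_rate_hz: float = 1.5  # median of the log-normal rate draw
    rate_log_sigma: float = 0.6  # log-normal shape across channels
    active_fraction: float = 0.75  # channels with nonzero rate
    refractory_s: float = 3e-3  # matches detector dead_pre + dead_post
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells <= 0 or self.n_electrodes_per_well <= 0:
            raise ValueError("plate geometry must be positive")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be > 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")

    @property
    def total_channels(self) -> int:
        return self.n_wells * self.n_electrodes_per_well

    def well_ids(self) -> list[str]:
        return [f"W{i + 1:02d}" for i in range(self.n_wells)]

    def electrode_ids(self) -> list[str]:
        return [f"E{i + 1:02d}" for i in range(self.n_electrodes_per_well)]


@dataclass(frozen=True)
class CompoundTruth:
    """Ground-truth pharmacology of one simulated compound."""

    compound_id: str
    ic50_true: float  # µM
    hill_n_true: float
    toxic: bool = False
    reversible: bool = True
    recovery_fraction: float = 0.8  # fraction of suppressed rate regained

    def __post_init__(self) -> None:
        if self.ic50_true <= 0:
            raise ValueError("ic50_true must be > 0")
        if self.hill_n_true <= 0:
            raise ValueError("hill_n_true must be > 0")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must lie in [0, 1]")


@dataclass
class SimulatedPlate:
    """Rendered traces, exact spike times and per-well ground truth."""

    spec: PlateSpec
    exposures: dict[str, tuple[str, float]]  # well -> (compound_id, µM)
    truth: dict[str, CompoundTruth | None]  # well -> truth (None = vehicle)
    traces: dict[tuple[str, str], dict[Phase, ChannelTrace]]
    true_spike_times: dict[tuple[str, str], dict[Phase, np.ndarray]]
    true_rates: dict[tuple[str, str], dict[Phase, float]]

    def channels(self) -> list[tuple[str, str]]:
        return list(self.true_spike_times.keys())


def _channel_rng(seed: int, well: int, electrode: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(well, electrode, stream))
    )


def _poisson_refractory_times(
    rng: np.random.Generator, rate: float, duration: float, refractory: float
) -> np.ndarray:
    """Renewal spike times: exponential ISIs plus an absolute refractory.

    The exponential mean is shortened so the overall mean ISI stays
    1/rate (rates approaching 1/refractory are rejected).
    """
    if rate <= 0:
        return np.empty(0)
    if rate * refractory >= 0.9:
        raise ValueError(f"rate {rate:g} Hz too high for refractory {refractory:g} s")
    exp_mean = 1.0 / rate - refractory
    n_guess = int(rate * duration + 6.0 * math.sqrt(rate * duration) + 20)
    times: list[float] = []
    t = 0.0
    while True:
        isis = refractory + rng.exponential(exp_mean, size=n_guess)
        for isi in isis:
            t += isi
            if t >= duration:
                return np.asarray(times)
            times.append(t)


def _spike_template(sampling_rate: float, amplitude: float) -> np.ndarray:
    """Fixed negative-leading biphasic template, 1 ms total.

    The sharp 0.3 ms negative lobe followed by a broader shallow
    positive lobe mimics an extracellular sodium-spike waveform and
    keeps most energy inside the 1–10 kHz detection band.
    """
    n = max(int(round(1e-3 * sampling_rate)), 4)
    n1 = max(int(round(0.3e-3 * sampling_rate)), 2)
    n2 = n - n1
    u1 = np.sin(np.pi * (np.arange(n1) + 0.5) / n1)
    u2 = np.sin(np.pi * (np.arange(n2) + 0.5) / n2)
    w = np.concatenate([-u1, 0.4 * u2])
    return amplitude * w / np.abs(w).max()


def _phase_rates(
    base_rate: float, truth: CompoundTruth | None, concentration: float
) -> dict[Phase, float]:
    if truth is None or concentration == 0.0:
        return {p: base_rate for p in PHASES}
    activity = hill_activity(concentration, truth.ic50_true, truth.hill_n_true) / 100.0
    post = base_rate * activity
    washout = post + truth.recovery_fraction * (base_rate - post)
    return {Phase.BASELINE: base_rate, Phase.POST: post, Phase.WASHOUT: washout}


def _resolve_exposures(
    spec: PlateSpec,
    exposures: Mapping[str, tuple[str, float]] | None,
    truths: Mapping[str, CompoundTruth] | None,
) -> tuple[dict[str, tuple[str, float]], dict[str, CompoundTruth | None]]:
    exposures = dict(exposures or {})
    truths = dict(truths or {})
    wells = set(spec.well_ids())
    well_truth: dict[str, CompoundTruth | None] = {w: None for w in spec.well_ids()}
    for well, (cid, conc) in exposures.items():
        if well not in wells:
            raise KeyError(f"exposure names unknown well {well!r}")
        if conc < 0:
            raise ValueError(f"concentration must be >= 0 (well {well})")
        if cid not in truths:
            raise KeyError(f"unknown compound {cid!r} in exposures")
        well_truth[well] = truths[cid]
    return exposures, well_truth


def simulate_plate(
    spec: PlateSpec,
    exposures: Mapping[str, tuple[str, float]] | None = None,
    truths: Mapping[str, CompoundTruth] | None = None,
    render: bool = True,
) -> SimulatedPlate:
    """Simulate one plate over the baseline/post/washout phases.

    Per channel, baseline spiking is a homogeneous Poisson process at a
    rate drawn once from the plate's log-normal distribution; the
    post-phase rate is baseline × Hill activity at the well's
    concentration, and the washout rate restores ``recovery_fraction``
    of the suppressed rate.  With ``render=True`` (default) voltage
    traces are produced by adding the spike template to Gaussian noise
    (float32 µV); with ``render=False`` only spike times and rates are
    generated, which is much cheaper for rate-level studies.

    Wells missing from ``exposures`` are vehicle wells.
    """
    exposures, well_truth = _resolve_exposures(spec, exposures, truths)
    template = _spike_template(spec.sampling_rate, spec.spike_amplitude)
    n_samples = int(round(spec.duration * spec.sampling_rate))
    mu = math.log(spec.baseline_rate_hz)

    traces: dict[tuple[str, str], dict[Phase, ChannelTrace]] = {}
    spike_times: dict[tuple[str, str], dict[Phase, np.ndarray]] = {}
    rates: dict[tuple[str, str], dict[Phase, float]] = {}

    for wi, well in enumerate(spec.well_ids()):
        truth = well_truth[well]
        conc = exposures.get(well, ("", 0.0))[1]
        for ei, elec in enumerate(spec.electrode_ids()):
            rng_rate = _channel_rng(spec.seed, wi, ei, 0)
            active = rng_rate.uniform() < spec.active_fraction
            base_rate = float(rng_rate.lognormal(mu, spec.rate_log_sigma)) if active else 0.0
            ch_rates = _phase_rates(base_rate, truth, conc)
            key = (well, elec)
            spike_times[key] = {}
            rates[key] = ch_rates
            if render:
                traces[key] = {}
            for pi, phase in enumerate(PHASES):
                rng_sp = _channel_rng(spec.seed, wi, ei, 1 + pi)
                st = _poisson_refractory_times(
                    rng_sp, ch_rates[phase], spec.duration, spec.refractory_s
                )
                spike_times[key][phase] = st
                if not render:
                    continue
                rng_noise = _channel_rng(spec.seed, wi, ei, 4 + pi)
                samples = rng_noise.normal(0.0, spec.noise_sd, n_samples).astype(np.float32)
                for t in st:
                    i0 = int(round(t * spec.sampling_rate))
                    i1 = min(i0 + template.size, n_samples)
                    samples[i0:i1] += template[: i1 - i0].astype(np.float32)
                traces[key][phase] = ChannelTrace(
                    samples=samples, sampling_rate=spec.sampling_rate,
                    well_id=well, electrode_id=elec, phase=phase,
                )

    return SimulatedPlate(
        spec=spec, exposures=exposures, truth=well_truth,
        traces=traces, true_spike_times=spike_times, true_rates=rates,
    )


def simulate_rate_table(
    spec: PlateSpec,
    exposures: Mapping[str, tuple[str, float]] | None = None,
    truths: Mapping[str, CompoundTruth] | None = None,
) -> pd.DataFrame:
    """Per-channel empirical firing rates without trace rendering.

    Spike counts come from the same per-channel processes as
    :func:`simulate_plate` (identical seeds give identical counts),
    skipping only the voltage rendering.  Columns: well, electrode,
    phase, rate_hz, compound_id, concentration.
    """
    plate = simulate_plate(spec, exposures, truths, render=False)
    rows = []
    for (well, elec), by_phase in plate.true_spike_times.items():
        cid, conc = plate.exposures.get(well, ("", 0.0))
        for phase, st in by_phase.items():
            rows.append(
                {
                    "well": well, "electrode": elec, "phase": phase.value,
                    "rate_hz": st.size / spec.duration,
                    "compound_id": cid, "concentration": conc,
                }
            )
    return pd.DataFrame(rows)


def simulate_ldh(
    truths: Mapping[str, CompoundTruth],
    seed: int = 0,
    timepoints_h: Sequence[float] = (1.0, 6.0, 24.0),
    vehicle_net: float = 0.08,
    positive_net: float = 1.0,
    background: float = 0.05,
    toxic_effect: float = 0.20,  # toxic release as a fraction of positive span
    nontoxic_effect: float = 0.01,
    noise_sd: float = 0.005,  # absorbance read noise
) -> pd.DataFrame:
    """Simulated LDH absorbance table with vehicle and positive controls.

    Toxic compounds release LDH at ``toxic_effect`` of the
    vehicle-to-positive span (well above the 5% cut), non-toxic ones at
    ``nontoxic_effect``; Gaussian read noise is added to every
    absorbance.  Columns: compound_id, role, timepoint_h, a490, a680.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))
    rows = []

    def emit(cid: str, role: str, tp: float, net: float) -> None:
        a680 = background + rng.normal(0.0, noise_sd)
        a490 = background + net + rng.normal(0.0, noise_sd)
        rows.append(
            {"compound_id": cid, "role": role, "timepoint_h": tp,
             "a490": max(a490, 0.0), "a680": max(a680, 0.0)}
        )

    span = positive_net - vehicle_net
    for tp in timepoints_h:
        emit("vehicle", "vehicle", tp, vehicle_net)
        emit("positive_control", "positive_control", tp, positive_net)
        for cid, truth in truths.items():
            frac = toxic_effect if truth.toxic else nontoxic_effect
            emit(cid, "sample", tp, vehicle_net + frac * span)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# voltage-clamp families
# ---------------------------------------------------------------------------

VSTEP_POTENTIALS = np.arange(-120.0, 85.0, 5.0)  # mV
_NAV_TAU_RISE = 0.5e-3  # s
_NAV_TAU_DECAY = 3.0e-3  # s
_NAV_PEAK_MV = -35.0  # envelope maximum
_NAV_ENVELOPE_WIDTH = 12.0  # mV


@dataclass
class VoltageStepExperiment:
    """Voltage-step sweep families for control, compound and TTX."""

    test_potentials: np.ndarray
    control: list[PatchSweep]
    by_concentration: dict[float, list[PatchSweep]]
    ttx: list[PatchSweep] | None


def _nav_envelope(v: np.ndarray | float) -> np.ndarray | float:
    return np.exp(-((np.asarray(v, dtype=float) - _NAV_PEAK_MV) ** 2)
                  / (2.0 * _NAV_ENVELOPE_WIDTH ** 2))


def _vstep_family(
    inhibition: float,
    nav_block: bool,
    rng: np.random.Generator | None,
    noise_sd_pa: float,
    sampling_rate: float,
    nav_peak_pa: float,
    kv_max_pa: float,
) -> list[PatchSweep]:
    pre, step, post = 0.05, 0.2, 0.05
    n = int(round((pre + step + post) * sampling_rate))
    t = np.arange(n) / sampling_rate
    in_step = (t >= pre) & (t < pre + step)
    ts = t[in_step] - pre

    # normalised biexponential transient
    shape = np.exp(-ts / _NAV_TAU_DECAY) - np.exp(-ts / _NAV_TAU_RISE)
    shape /= shape.max()

    sweeps = []
    for v_test in VSTEP_POTENTIALS:
        i = np.zeros(n)
        if not nav_block:
            amp = nav_peak_pa * float(_nav_envelope(v_test)) * (1.0 - inhibition)
            i[in_step] -= amp * shape
        # delayed-rectifier-like activation: essentially closed at the
        # -35 mV step where the Nav peak is measured
        g = 1.0 / (1.0 + math.exp(-(v_test + 10.0) / 8.0))
        i_k = kv_max_pa * g * max(v_test + 90.0, 0.0) / 170.0
        i[in_step] += i_k * (1.0 - np.exp(-ts / 5e-3))
        if rng is not None and noise_sd_pa > 0:
            i = i + rng.normal(0.0, noise_sd_pa, n)
        sweeps.append(
            PatchSweep(
                time=t, value=i, protocol=Protocol.VOLTAGE_STEP,
                step_schedule=(
                    StepEpoch(-70.0, 0.0, pre),
                    StepEpoch(float(v_test), pre, step),
                    StepEpoch(-70.0, pre + step, post),
                ),
            )
        )
    return sweeps


def simulate_voltage_step_family(
    ic50: float,
    slope_h: float,
    concentrations: Sequence[float],
    include_ttx: bool = True,
    seed: int = 0,
    noise_sd_pa: float = 0.0,
    sampling_rate: float = 20000.0,
    nav_peak_pa: float = 1500.0,
    kv_max_pa: float = 800.0,
) -> VoltageStepExperiment:
    """Voltage-step current families under graded compound block.

    The Naᵥ-like inward transient is scaled by
    ``1 − boltzmann_inhibition(c, ic50, slope_h)``; the Kᵥ-like
    sustained outward component is unaffected by both compound and TTX,
    while the TTX family has the inward component removed entirely.
    Noiseless by default.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("concentration list must be non-empty")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")

    def rng_for(stream: int) -> np.random.Generator | None:
        if noise_sd_pa <= 0:
            return None
        return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(23, stream)))

    common = dict(noise_sd_pa=noise_sd_pa, sampling_rate=sampling_rate,
                  nav_peak_pa=nav_peak_pa, kv_max_pa=kv_max_pa)
    control = _vstep_family(0.0, False, rng_for(0), **common)
    by_conc = {
        float(c): _vstep_family(
            float(boltzmann_inhibition(c, ic50, slope_h)), False, rng_for(1 + k), **common
        )
        for k, c in enumerate(concentrations)
    }
    ttx = _vstep_family(0.0, True, rng_for(999), **common) if include_ttx else None
    return VoltageStepExperiment(
        test_potentials=VSTEP_POTENTIALS.copy(), control=control,
        by_concentration=by_conc, ttx=ttx,
    )


# ---------------------------------------------------------------------------
# current-clamp sweeps
# ---------------------------------------------------------------------------

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class ApSweepTruth:
    """Analytic ground truth of a simulated current-clamp sweep."""

    kind: str
    rest_mv: float
    spike_times: np.ndarray  # s, Gaussian peak centres
    peak_mv: np.ndarray  # mV at each spike peak
    sigma_ms: float
    fwhm_ms: float  # 2σ√(2 ln 2), full width at half the base-to-peak height
    half_height_width_ms: float  # width at half of (peak − threshold); see note
    max_dvdt: np.ndarray  # mV/ms per spike: A·e^{-1/2}/σ


def _add_gaussian_spikes(
    v: np.ndarray, t: np.ndarray, centres: np.ndarray, peaks: np.ndarray,
    rest: float, sigma_s: float, ahp_mv: float = 6.0, ahp_sigma_s: float = 6e-3,
    ahp_delay_s: float = 20e-3,
) -> None:
    for tc, pk in zip(centres, peaks):
        amp = pk - rest
        win = (t > tc - 8 * sigma_s) & (t < tc + 8 * sigma_s)
        v[win] += amp * np.exp(-((t[win] - tc) ** 2) / (2 * sigma_s ** 2))
        awin = (t > tc + ahp_delay_s - 4 * ahp_sigma_s) & (t < tc + ahp_delay_s + 4 * ahp_sigma_s)
        v[awin] -= ahp_mv * np.exp(-((t[awin] - tc - ahp_delay_s) ** 2) / (2 * ahp_sigma_s ** 2))


_GAPFREE_KIND_ALIASES = {
    "quiet": GapfreeClass.QUIET,
    "attempting": GapfreeClass.ATTEMPTING_SAP,
    "attempting_sap": GapfreeClass.ATTEMPTING_SAP,
    "spontaneous": GapfreeClass.SPONTANEOUS,
}


def simulate_ap_sweep(
    kind: str | GapfreeClass,
    seed: int = 0,
    duration: float = 60.0,
    sampling_rate: float = 10000.0,
    rest_mv: float = -60.0,
    noise_sd_mv: float = 0.3,
    sigma_ms: float = 1.0,
    rate_hz: float = 0.25,
) -> tuple[PatchSweep, ApSweepTruth]:
    """Gap-free current-clamp sweep with known spike ground truth.

    ``quiet`` sweeps never leave the resting band; ``attempting``
    spikes peak strictly between −40 and 0 mV; ``spontaneous`` sweeps
    contain overshooting (≥ 0 mV) spikes.  Spike shapes are Gaussian
    (σ = ``sigma_ms``) with a small after-hyperpolarisation, so the
    analytic peak, width and maximal slope are exact.
    """
    if isinstance(kind, str) and kind in _GAPFREE_KIND_ALIASES:
        cls = _GAPFREE_KIND_ALIASES[kind]
    else:
        try:
            cls = GapfreeClass(kind)
        except ValueError as err:
            raise ValueError(f"unknown AP sweep kind {kind!r}") from err

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(31,)))
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    v = rest_mv + rng.normal(0.0, noise_sd_mv, n)

    if cls is GapfreeClass.QUIET:
        centres = np.empty(0)
        peaks = np.empty(0)
    else:
        n_spikes = max(3, int(rng.poisson(rate_hz * duration)))
        margin = 1.0
        centres = np.sort(
            margin + (duration - 2 * margin) * (np.arange(n_spikes) + rng.uniform(0.2, 0.8, n_spikes))
            / n_spikes
        )
        if cls is GapfreeClass.SPONTANEOUS:
            peaks = np.clip(rng.normal(30.0, 5.0, n_spikes), 5.0, 45.0)
        else:
            peaks = np.clip(rng.normal(-20.0, 5.0, n_spikes), -38.0, -3.0)
        _add_gaussian_spikes(v, t, centres, peaks, rest_mv, sigma_ms * 1e-3)

    sweep = PatchSweep(time=t, value=v, protocol=Protocol.GAPFREE)
    amp = peaks - rest_mv if peaks.size else np.empty(0)
    # width at half of (peak - threshold) for a Gaussian spike whose
    # threshold sits at the rising-limb third-derivative maximum
    # (u = sqrt(3 + sqrt 6) sigma before the peak)
    f_thr = math.exp(-(3.0 + math.sqrt(6.0)) / 2.0)
    half_level = f_thr + 0.5 * (1.0 - f_thr)
    truth = ApSweepTruth(
        kind=cls.value, rest_mv=rest_mv, spike_times=centres, peak_mv=peaks,
        sigma_ms=sigma_ms, fwhm_ms=_GAUSS_FWHM * sigma_ms,
        half_height_width_ms=2.0 * sigma_ms * math.sqrt(2.0 * math.log(1.0 / half_level)),
        max_dvdt=amp * math.exp(-0.5) / sigma_ms,
    )
    return sweep, truth


def simulate_current_step_family(
    kind: str | IapClass,
    seed: int = 0,
    currents_pa: Sequence[float] = tuple(range(-10, 190, 10)),
    sampling_rate: float = 10000.0,
    step_duration: float = 1.0,
    hold_mv: float = -85.0,
    noise_sd_mv: float = 0.3,
    sigma_ms: float = 1.0,
    rheobase_pa: float = 60.0,
    input_resistance_mv_per_pa: float = 0.1,
) -> tuple[list[tuple[float, PatchSweep]], dict[float, np.ndarray]]:
    """Current-step family of a cell with a prescribed response class.

    The passive response is an exponential charging curve (τ = 20 ms);
    above rheobase the cell emits spikes according to ``kind``:
    complete spikes peak near +25 mV, "attempting" events near −15 mV,
    and train kinds place ≥ 3 events in the strong steps.  Returns the
    (current, sweep) family ordered by injected current plus the true
    spike times per current level.
    """
    cls = IapClass(kind)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(37,)))
    pre, post = 0.1, 0.1
    n = int(round((pre + step_duration + post) * sampling_rate))
    t = np.arange(n) / sampling_rate
    tau = 0.02

    family: list[tuple[float, PatchSweep]] = []
    truth: dict[float, np.ndarray] = {}
    for i_pa in currents_pa:
        v = hold_mv + rng.normal(0.0, noise_sd_mv, n)
        dv = input_resistance_mv_per_pa * i_pa
        in_step = (t >= pre) & (t < pre + step_duration)
        ts = t[in_step] - pre
        v[in_step] += dv * (1.0 - np.exp(-ts / tau))
        after = t >= pre + step_duration
        v[after] += dv * (1.0 - math.exp(-step_duration / tau)) * np.exp(
            -(t[after] - pre - step_duration) / tau
        )

        centres = np.empty(0)
        if cls is not IapClass.QUIET and i_pa >= rheobase_pa:
            if cls in (IapClass.TRAIN, IapClass.ATTEMPTING_TRAIN) and i_pa >= rheobase_pa + 40:
                n_spk = 6
            elif cls in (IapClass.TRAIN, IapClass.ATTEMPTING_TRAIN):
                n_spk = 2
            else:
                n_spk = 1
            centres = pre + 0.1 + 0.12 * np.arange(n_spk)
            complete = cls in (IapClass.SINGLE_IAP, IapClass.TRAIN)
            base = 25.0 if complete else -15.0
            peaks = np.clip(base + rng.normal(0.0, 3.0, n_spk), -38.0 if not complete else 5.0,
                            -3.0 if not complete else 45.0)
            plateau = hold_mv + dv
            _add_gaussian_spikes(v, t, centres, peaks, plateau, sigma_ms * 1e-3)

        truth[float(i_pa)] = centres
        family.append(
            (
                float(i_pa),
                PatchSweep(
                    time=t, value=v, protocol=Protocol.CURRENT_STEP,
                    step_schedule=(
                        StepEpoch(0.0, 0.0, pre),
                        StepEpoch(float(i_pa), pre, step_duration),
                        StepEpoch(0.0, pre + step_duration, post),
                    ),
                ),
            )
        )
    return family, truth
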