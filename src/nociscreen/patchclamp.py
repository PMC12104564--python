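"""Single-cell patch-clamp feature extraction and classification.

Covers three protocols:

* **gap-free current clamp** (0 pA holding, 60 s): resting membrane
  potential and spontaneous-activity class — ``quiet`` (no events),
  ``attempting_sap`` (spikes that never reach 0 mV) or ``spontaneous``
  (at least one overshooting spike);
* **current steps** (1 s injections, −10 to 180 pA): induced-activity
  class — quiet / attempting single / complete single / attempting
  train / complete train, where a train is ≥ 3 complete spikes in one
  step;
* **voltage steps** (−70 mV holding, test potentials −120..+80 mV in
  5 mV increments): Naᵥ activation/inactivation peaks and the Kᵥ
  steady-state current, plus TTX-normalised compound inhibition
  (ΔI/ΔI_TTX) at the −35 mV step.

Spike events inside current-clamp sweeps are found with a dV/dt
criterion (default ≥ 10 mV/ms) so sub-threshold "attempting" events
are caught; derivatives for spike parameters are taken on a
Savitzky–Golay local-polynomial smooth, since the third derivative of
a raw noisy trace is unusable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

log = logging.getLogger(__name__)

__all__ = [
    "Protocol",
    "StepEpoch",
    "PatchSweep",
    "APParameters",
    "GapfreeClass",
    "IapClass",
    "IVCurve",
    "detect_events",
    "resting_vm",
    "classify_gapfree",
    "classify_current_step",
    "spike_parameters",
    "extract_iv",
    "ttx_normalised_inhibition",
]


class Protocol(str, Enum):
    GAPFREE = "gapfree"
    CURRENT_STEP = "current_step"
    VOLTAGE_STEP = "voltage_step"


class GapfreeClass(str, Enum):
    QUIET = "quiet"
    ATTEMPTING_SAP = "attempting_sap"
    SPONTANEOUS = "spontaneous"


class IapClass(str, Enum):
    QUIET = "quiet"
    ATTEMPTING_SINGLE = "attempting_single"
    SINGLE_IAP = "single_iap"
    ATTEMPTING_TRAIN = "attempting_train"
    TRAIN = "train"


@dataclass(frozen=True)
class StepEpoch:
    """One held level of a stepped protocol."""

    level: float  # mV (voltage clamp) or pA (current clamp)
    onset: float  # s
    duration: float  # s

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class PatchSweep:
    """Uniformly sampled membrane-voltage (mV) or current (pA) sweep."""

    time: np.ndarray  # s
    value: np.ndarray  # mV or pA
    protocol: Protocol = Protocol.GAPFREE
    step_schedule: tuple[StepEpoch, ...] = ()

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value must have equal length")
        self.protocol = Protocol(self.protocol)
        for ep in self.step_schedule:
            if ep.end > self.time[-1] + self.time[1] - self.time[0] + 1e-9:
                raise ValueError("step schedule extends beyond the sweep")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class APParameters:
    """Extracted action-potential shape features."""

    overshoot: float  # mV; peak voltage relative to 0 mV
    after_hyperpolarisation: float  # mV relative to threshold (negative)
    depolarising_rate: float  # mV/ms, max rising slope
    repolarising_rate: float  # mV/ms, max falling slope (negative)
    spike_height: float  # mV, peak − threshold
    half_height_width: float  # ms at 50% of spike height
    threshold: float  # mV, at the third-derivative peak on the rise
    resting_vm: float  # mV
    peak_time: float  # s
    incomplete: bool = False  # spike truncated at a sweep edge


def _smooth(x: np.ndarray, fs: float, window_ms: float = 1.0, polyorder: int = 3,
            deriv: int = 0) -> np.ndarray:
    win = max(int(round(window_ms * 1e-3 * fs)) | 1, polyorder + 2 + ((polyorder + 2) % 2 == 0))
    win = min(win if win % 2 else win + 1, len(x) - (1 - len(x) % 2))
    delta_ms = 1e3 / fs  # derivatives in mV/ms^deriv
    return savgol_filter(x, win, polyorder, deriv=deriv, delta=delta_ms)


def detect_events(
    sweep: PatchSweep,
    dvdt_threshold: float = 10.0,  # mV/ms
    min_separation_ms: float = 5.0,
    min_amplitude_mv: float = 10.0,
) -> list[tuple[int, int, float]]:
    """Locate spike-like events by their rising slope.

    Returns (onset_index, peak_index, peak_mv) per event.  Using dV/dt
    rather than a voltage threshold means sub-threshold "attempting"
    events are detected too; a candidate is confirmed only if its peak
    rises at least ``min_amplitude_mv`` above the local pre-onset
    baseline, which rejects slope excursions produced by recording
    noise.
    """
    v = sweep.value
    fs = sweep.sampling_rate
    d1 = _smooth(v, fs, deriv=1)
    above = d1 >= dvdt_threshold
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    min_sep = int(round(min_separation_ms * 1e-3 * fs))
    base_w = int(round(5e-3 * fs))
    events: list[tuple[int, int, float]] = []
    last_end = -1
    for i in onsets:
        if i <= last_end:
            continue
        # peak = maximum within a 50 ms window after the slope onset
        j_max = min(len(v), i + int(round(0.050 * fs)))
        seg = v[i:j_max]
        peak_rel = int(np.argmax(seg))
        peak_idx = i + peak_rel
        base = float(np.median(v[max(0, i - base_w):max(i, 1)]))
        if v[peak_idx] - base < min_amplitude_mv:
            continue
        events.append((int(i), peak_idx, float(v[peak_idx])))
        last_end = peak_idx + min_sep
    return events


def resting_vm(sweep: PatchSweep, window_s: float = 30.0,
               dvdt_threshold: float = 10.0, mask_ms: float = 50.0) -> float:
    """Resting membrane potential: mean voltage over a 30 s window.

    Samples around detected spikes (±``mask_ms``) are excluded so the
    estimate reflects the resting level.  Sweeps shorter than the
    window are used in full with a warning.
    """
    fs = sweep.sampling_rate
    n = int(round(window_s * fs))
    if n > len(sweep.value):
        warnings.warn("sweep shorter than 30 s; using full length", stacklevel=2)
        n = len(sweep.value)
    v = sweep.value[:n]
    keep = np.ones(n, dtype=bool)
    half = int(round(mask_ms * 1e-3 * fs))
    for onset, peak, _ in detect_events(sweep, dvdt_threshold):
        if onset >= n:
            break
        keep[max(0, onset - half): min(n, peak + half)] = False
    if not keep.any():
        keep[:] = True
    return float(v[keep].mean())


def classify_gapfree(sweep: PatchSweep, dvdt_threshold: float = 10.0) -> GapfreeClass:
    """Spontaneous-activity class of a gap-free current-clamp sweep."""
    events = detect_events(sweep, dvdt_threshold)
    if not events:
        return GapfreeClass.QUIET
    if any(peak_mv >= 0.0 for _, _, peak_mv in events):
        return GapfreeClass.SPONTANEOUS
    return GapfreeClass.ATTEMPTING_SAP


def classify_current_step(
    sweeps: Sequence[tuple[float, PatchSweep]],
    dvdt_threshold: float = 10.0,
    train_min_spikes: int = 3,
) -> IapClass:
    """Induced-activity class from a current-step family.

    ``sweeps`` is ordered by injected current (−10 → 180 pA).  A step
    with ≥ 3 complete spikes (peak ≥ 0 mV) makes the cell a ``train``;
    1–2 complete spikes at its best step makes it ``single_iap``;
    events that never reach 0 mV give the corresponding "attempting"
    class; no events at any step is ``quiet``.
    """
    if not sweeps:
        raise ValueError("empty current-step family")
    best_complete = 0
    best_events = 0
    for _, sweep in sweeps:
        events = detect_events(sweep, dvdt_threshold)
        n_complete = sum(1 for _, _, p in events if p >= 0.0)
        best_complete = max(best_complete, n_complete)
        best_events = max(best_events, len(events))
    if best_complete >= train_min_spikes:
        return IapClass.TRAIN
    if best_complete >= 1:
        return IapClass.SINGLE_IAP
    if best_events >= train_min_spikes:
        return IapClass.ATTEMPTING_TRAIN
    if best_events >= 1:
        return IapClass.ATTEMPTING_SINGLE
    return IapClass.QUIET


def spike_parameters(
    sweep: PatchSweep,
    spike_index: int = 0,
    dvdt_threshold: float = 10.0,
    search_ms: float = 10.0,
    ahp_ms: float = 50.0,
) -> APParameters:
    """Shape parameters of one detected spike.

    The threshold is the voltage at the peak of the third derivative
    during the depolarising phase; spike height is peak − threshold;
    the half-height width is measured at 50% of that height; the
    after-hyperpolarisation is the post-peak minimum referenced to
    threshold.  Rates are the extrema of the first derivative (mV/ms).
    """
    events = detect_events(sweep, dvdt_threshold)
    if spike_index >= len(events):
        raise IndexError(f"spike {spike_index} not found ({len(events)} events)")
    onset, peak_idx, peak_mv = events[spike_index]
    v = sweep.value
    fs = sweep.sampling_rate
    dt_ms = 1e3 / fs

    vs = _smooth(v, fs)
    d1 = _smooth(v, fs, deriv=1)
    d3 = _smooth(v, fs, polyorder=5, deriv=3)

    incomplete = False
    w = int(round(search_ms * 1e-3 * fs))
    lo = max(0, peak_idx - w)
    if peak_idx - w < 0:
        incomplete = True
    rise = slice(lo, peak_idx + 1)
    # threshold: third-derivative peak on the rising limb, restricted to
    # where the membrane is actually depolarising
    d1_rise = d1[rise]
    mask = d1_rise > 0.05 * max(d1_rise.max(), 1e-12)
    if not mask.any():
        mask[:] = True
    d3_rise = np.where(mask, d3[rise], -np.inf)
    thr_idx = lo + int(np.argmax(d3_rise))
    threshold = float(vs[thr_idx])

    spike_height = float(peak_mv - threshold)
    half_level = threshold + 0.5 * spike_height

    # half-height width by linear interpolation around the peak
    i = peak_idx
    while i > lo and v[i] > half_level:
        i -= 1
    if v[i] > half_level:
        incomplete = True
        t_left = sweep.time[i]
    else:
        f = (half_level - v[i]) / (v[i + 1] - v[i])
        t_left = sweep.time[i] + f * (sweep.time[i + 1] - sweep.time[i])
    j = peak_idx
    hi = min(len(v) - 1, peak_idx + int(round(ahp_ms * 1e-3 * fs)))
    while j < hi and v[j] > half_level:
        j += 1
    if v[j] > half_level:
        incomplete = True
        t_right = sweep.time[j]
    else:
        f = (v[j - 1] - half_level) / (v[j - 1] - v[j])
        t_right = sweep.time[j - 1] + f * (sweep.time[j] - sweep.time[j - 1])
    width_ms = (t_right - t_left) * 1e3

    ahp_window = v[peak_idx:hi + 1]
    ahp = float(ahp_window.min() - threshold)
    if hi >= len(v) - 1:
        incomplete = True

    dep_rate = float(d1[rise].max())
    rep_rate = float(d1[peak_idx:hi + 1].min())

    return APParameters(
        overshoot=float(peak_mv),
        after_hyperpolarisation=ahp,
        depolarising_rate=dep_rate,
        repolarising_rate=rep_rate,
        spike_height=spike_height,
        half_height_width=float(width_ms),
        threshold=threshold,
        resting_vm=float(np.median(vs[: max(onset, 1)])) if onset > 0 else float(vs[0]),
        peak_time=float(sweep.time[peak_idx]),
        incomplete=incomplete,
    )


@dataclass
class IVCurve:
    """Current–voltage summary of a voltage-step family."""

    test_potentials: np.ndarray  # mV, strictly increasing in 5 mV steps
    nav_activation: np.ndarray  # pA, negative peaks in the step window
    nav_inactivation: np.ndarray  # pA, trough after the test step
    kv_steady: np.ndarray  # pA, mean of the last ~50 ms of the step

    def __post_init__(self) -> None:
        self.test_potentials = np.asarray(self.test_potentials, dtype=float)
        for name in ("nav_activation", "nav_inactivation", "kv_steady"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.test_potentials.shape:
                raise ValueError(f"{name} length must match test_potentials")

    def at(self, potential: float, which: str = "nav_activation") -> float:
        idx = np.flatnonzero(np.isclose(self.test_potentials, potential))
        if idx.size == 0:
            raise KeyError(f"test potential {potential} mV not in curve")
        return float(getattr(self, which)[idx[0]])


def extract_iv(
    family: Sequence[PatchSweep],
    activation_window_ms: float = 25.0,
    kv_window_ms: float = 50.0,
) -> IVCurve:
    """Reduce a voltage-step family to Naᵥ/Kᵥ current–voltage curves.

    Each sweep must carry a 3-epoch step schedule (hold, test step,
    hold).  Sweeps are baseline-subtracted at the holding level; the
    Naᵥ activation current is the most negative value in the first
    ``activation_window_ms`` of the test step, the inactivation current
    is the trough in the window between the test step and the final
    held level, and the Kᵥ current is the mean over the last
    ``kv_window_ms`` of the test step.
    """
    pots, act, inact, kv = [], [], [], []
    for sweep in family:
        if len(sweep.step_schedule) < 3:
            raise ValueError("voltage-step sweep needs a (hold, test, hold) schedule")
        hold, test, recov = sweep.step_schedule[0], sweep.step_schedule[1], sweep.step_schedule[2]
        t = sweep.time
        i_base = sweep.value[(t >= hold.onset) & (t < hold.end)].mean()
        v = sweep.value - i_base

        act_win = (t >= test.onset) & (t < test.onset + activation_window_ms * 1e-3)
        act.append(float(v[act_win].min()))
        inact_win = (t >= test.end) & (t < min(test.end + activation_window_ms * 1e-3, recov.end))
        inact.append(float(v[inact_win].min()) if inact_win.any() else 0.0)
        kv_win = (t >= test.end - kv_window_ms * 1e-3) & (t < test.end)
        kv.append(float(v[kv_win].mean()))
        pots.append(test.level)

    order = np.argsort(pots)
    return IVCurve(
        test_potentials=np.asarray(pots)[order],
        nav_activation=np.asarray(act)[order],
        nav_inactivation=np.asarray(inact)[order],
        kv_steady=np.asarray(kv)[order],
    )


def ttx_normalised_inhibition(
    control: IVCurve,
    compound: IVCurve,
    ttx: IVCurve,
    at: float = -35.0,
) -> float:
    """Compound inhibition as a fraction of the TTX-sensitive current.

    ``(I_control − I_compound) / (I_control − I_TTX)`` using the Naᵥ
    activation peaks at the ``at`` test potential (−35 mV, where the
    inward current is maximal).  Values outside [0, 1.05] are reported
    but flagged with a warning.
    """
    i_ctl = control.at(at)
    i_cmp = compound.at(at)
    i_ttx = ttx.at(at)
    denom = i_ctl - i_ttx
    if denom == 0:
        raise ValueError("control and TTX currents are equal; cannot normalise")
    frac = (i_ctl - i_cmp) / denom
    if not (0.0 <= frac <= 1.05):
        warnings.warn(f"ΔI/ΔI_TTX = {frac:.3f} outside [0, 1.05]", stacklevel=2)
    return float(frac)
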