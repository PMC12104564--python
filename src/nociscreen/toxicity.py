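"""LDH cytotoxicity and washout-reversibility filters.

LDH release is read as background-subtracted absorbance
(A490 − A680), normalised between the vehicle control (0%) and the
kit's lysis positive control (100%).  A compound is flagged cytotoxic
when its normalised LDH activity exceeds 5% of the positive control at
any of the measured timepoints (1, 6, 24 h); toxicity aggregates the
timepoints by worst case.

Reversibility compares firing after a washout to the inhibited
post-compound level: recovery is the fraction of the inhibited gap
regained, and a compound counts as reversible when washout activity
exceeds post activity by more than a configurable noise margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .doseresponse import DoseResponseFit

log = logging.getLogger(__name__)

__all__ = [
    "LdhReading",
    "RecoveryRecord",
    "ldh_activity",
    "is_cytotoxic",
    "toxicity_flags",
    "classify_reversibility",
    "select_patch_candidates",
]

LDH_TOXIC_PCT = 5.0  # % of positive control above which a compound is toxic
IC50_CANDIDATE_MAX_UM = 8.0  # µM cut for patch-clamp follow-up
RECOVERY_CANDIDATE_MIN_PCT = 60.0  # % recovery cut for patch-clamp follow-up


@dataclass(frozen=True)
class LdhReading:
    """One absorbance pair from the LDH plate."""

    compound_id: str  # or role label for controls
    a490: float  # LDH activity wavelength
    a680: float  # background wavelength
    timepoint_h: float = 24.0  # 1, 6 or 24 h post-exposure
    role: str = "sample"  # sample | vehicle | positive_control

    def __post_init__(self) -> None:
        if self.a490 < 0 or self.a680 < 0:
            raise ValueError("absorbances must be >= 0")

    @property
    def net(self) -> float:
        """Background-subtracted LDH signal (A490 − A680)."""
        return self.a490 - self.a680


@dataclass
class RecoveryRecord:
    """Baseline/post/washout activity for one compound (% of baseline)."""

    compound_id: str
    activity_post: float  # % of baseline after compound
    activity_washout: float  # % of baseline after washout
    activity_baseline: float = 100.0
    activity_se: float = 0.0  # measurement SE on the activity percentages
    recovery_pct: float = float("nan")
    reversible: bool = False
    undefined: bool = False  # set when the compound caused no inhibition


def ldh_activity(reading: LdhReading, vehicle: LdhReading, positive: LdhReading) -> float:
    """Normalised LDH activity as % of the positive control.

    ``100 × (sample − vehicle) / (positive − vehicle)`` on
    background-subtracted values.
    """
    span = positive.net - vehicle.net
    if span <= 0:
        raise ValueError(
            "assay failure: positive control signal does not exceed vehicle"
        )
    return 100.0 * (reading.net - vehicle.net) / span


def is_cytotoxic(activity_pct: float | Sequence[float]) -> bool:
    """True iff LDH activity exceeds 5% of positive control at any timepoint."""
    arr = np.atleast_1d(np.asarray(activity_pct, dtype=float))
    return bool(np.any(arr > LDH_TOXIC_PCT))


def toxicity_flags(readings: Iterable[LdhReading]) -> dict[str, bool]:
    """Per-compound worst-case toxicity verdict from an LDH reading set.

    Vehicle and positive-control rows are matched to samples by
    timepoint; a compound is toxic if any timepoint exceeds the 5% cut.
    """
    readings = list(readings)
    by_tp_controls: dict[float, dict[str, LdhReading]] = {}
    for r in readings:
        if r.role in ("vehicle", "positive_control"):
            by_tp_controls.setdefault(r.timepoint_h, {})[r.role] = r
    flags: dict[str, list[float]] = {}
    for r in readings:
        if r.role != "sample":
            continue
        ctrl = by_tp_controls.get(r.timepoint_h)
        if not ctrl or "vehicle" not in ctrl or "positive_control" not in ctrl:
            raise ValueError(
                f"missing vehicle/positive control at timepoint {r.timepoint_h} h"
            )
        pct = ldh_activity(r, ctrl["vehicle"], ctrl["positive_control"])
        flags.setdefault(r.compound_id, []).append(pct)
    return {cid: is_cytotoxic(pcts) for cid, pcts in flags.items()}


def classify_reversibility(rec: RecoveryRecord, noise_se_factor: float = 2.0) -> RecoveryRecord:
    """Classify washout reversibility and compute percent recovery.

    Recovery is the regained fraction of the inhibited gap::

        100 × (washout − post) / (baseline − post),  clipped to [0, 100]

    The compound is reversible when washout activity exceeds post
    activity by more than ``noise_se_factor × activity_se`` (a strict
    increase when no SE is supplied).  A record with no inhibition
    (post ≥ baseline) has undefined recovery and is flagged.
    """
    if rec.activity_post >= rec.activity_baseline:
        rec.undefined = True
        rec.recovery_pct = float("nan")
        rec.reversible = False
        log.warning("%s: no inhibition; reversibility undefined", rec.compound_id)
        return rec
    gap = rec.activity_baseline - rec.activity_post
    raw = 100.0 * (rec.activity_washout - rec.activity_post) / gap
    rec.recovery_pct = float(np.clip(raw, 0.0, 100.0))
    margin = noise_se_factor * rec.activity_se
    rec.reversible = rec.activity_washout - rec.activity_post > margin
    return rec


def select_patch_candidates(
    fits: Mapping[str, DoseResponseFit],
    recs: Mapping[str, RecoveryRecord],
    toxic: Mapping[str, bool] | None = None,
    ic50_max: float = IC50_CANDIDATE_MAX_UM,
    recovery_min: float = RECOVERY_CANDIDATE_MIN_PCT,
) -> list[str]:
    """Compounds advancing to patch clamp.

    Requires a converged fit with IC50 ≤ 8 µM, reversible inhibition
    with recovery ≥ 60%, and no cytotoxicity flag.
    """
    toxic = toxic or {}
    out = []
    for cid, fit in fits.items():
        if not fit.converged:
            continue
        rec = recs.get(cid)
        if rec is None or rec.undefined:
            continue
        if (
            fit.ic50 <= ic50_max
            and rec.reversible
            and rec.recovery_pct >= recovery_min
            and not toxic.get(cid, False)
        ):
            out.append(cid)
    return out
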