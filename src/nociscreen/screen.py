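"""Per-compound screening statistics and composite hit calling.

Each compound is summarised by paired per-channel firing rates before
and after exposure (only channels active at baseline enter the pairing)
and by four indexes: normalised activity (ratio of mean rates, %), an
FDR-corrected paired Wilcoxon p value, a robust z′ score (median
difference over pooled raw MAD), and Cohen's d.  A compound is a hit
when it clears every threshold simultaneously; hits are tiered by the
size of the rate reduction (high > 90%, moderate 70–90%, low 50–70%).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .doseresponse import Tier

log = logging.getLogger(__name__)

__all__ = [
    "ScreenMetrics",
    "HitCall",
    "HitThresholds",
    "normalised_activity",
    "paired_wilcoxon",
    "fdr_adjust",
    "robust_z",
    "cohen_d",
    "compute_metrics",
    "call_hit",
    "screen_library",
]


@dataclass
class ScreenMetrics:
    """Before/after rate lists and derived statistics for one compound."""

    compound_id: str
    rates_before: np.ndarray  # Hz, paired with rates_after
    rates_after: np.ndarray
    normalised_activity: float  # %
    p_raw: float
    robust_z: float
    cohen_d: float
    n_active: int
    median_separation_mads: float
    p_fdr: float = float("nan")  # filled once the whole library is adjusted

    def __post_init__(self) -> None:
        if len(self.rates_before) != len(self.rates_after):
            raise ValueError("before/after rate lists must be paired (equal length)")


@dataclass
class HitCall:
    compound_id: str
    is_hit: bool
    tier: Tier
    failed_criteria: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.is_hit != (self.tier is not Tier.NONE):
            raise ValueError("is_hit and tier must agree")


@dataclass(frozen=True)
class HitThresholds:
    """Composite hit-calling thresholds for the single-concentration screen."""

    max_normalised_activity: float = 50.0  # %
    max_p_fdr: float = 0.01
    z_cut: float = 1.96  # applied to |robust z'|
    d_cut: float = 0.80  # applied to |Cohen d|
    min_active: int = 9  # active channels at baseline
    min_median_sep_mads: float = 2.0  # optional extra criterion

    def __post_init__(self) -> None:
        for name in ("max_normalised_activity", "max_p_fdr", "z_cut", "d_cut",
                     "min_active", "min_median_sep_mads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def normalised_activity(rates_before: Sequence[float], rates_after: Sequence[float]) -> float:
    """Post/baseline ratio of mean firing rates, as a percentage.

    Returns NaN (with a log message) when the baseline mean is zero,
    in which case the compound is excluded from hit calling.
    """
    before = np.asarray(rates_before, dtype=float)
    after = np.asarray(rates_after, dtype=float)
    mb = before.mean()
    if mb <= 0:
        log.warning("baseline mean rate is 0; normalised activity undefined")
        return float("nan")
    return float(100.0 * after.mean() / mb)


def paired_wilcoxon(rates_before: Sequence[float], rates_after: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p for paired rate lists.

    Zero differences are excluded (the signed-rank zero-exclusion
    convention); if every difference is zero the p value is 1.
    """
    before = np.asarray(rates_before, dtype=float)
    after = np.asarray(rates_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired lists must have equal length")
    diffs = after - before
    if np.all(diffs == 0):
        return 1.0
    n_nonzero = int(np.count_nonzero(diffs))
    if n_nonzero < 6:
        warnings.warn(
            f"only {n_nonzero} non-tied pairs; signed-rank p is unreliable",
            stacklevel=2,
        )
    res = stats.wilcoxon(after, before, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (across compounds)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def _raw_mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def robust_z(rates_before: Sequence[float], rates_after: Sequence[float]) -> float:
    """Robust z′: difference in medians over the pooled raw MAD.

    Pooling is root-mean-square of the two unscaled MADs, so the score
    is expressed in MAD units (no 1.4826 normality factor).  A zero
    pooled MAD yields signed infinity when the medians differ and 0
    when they coincide.
    """
    before = np.asarray(rates_before, dtype=float)
    after = np.asarray(rates_after, dtype=float)
    if before.size == 0 or after.size == 0:
        raise ValueError("rate lists must be non-empty")
    dmed = float(np.median(after) - np.median(before))
    pooled = math.sqrt((_raw_mad(before) ** 2 + _raw_mad(after) ** 2) / 2.0)
    if pooled == 0.0:
        if dmed == 0.0:
            return 0.0
        log.warning("pooled MAD is 0 with unequal medians; robust z' is infinite")
        return math.copysign(math.inf, dmed)
    return dmed / pooled


def cohen_d(rates_before: Sequence[float], rates_after: Sequence[float]) -> float:
    """Cohen's d: difference in means over the pooled sample SD.

    Pooled variance uses the classical (n1 + n2 - 2) denominator.
    """
    before = np.asarray(rates_before, dtype=float)
    after = np.asarray(rates_after, dtype=float)
    if before.size < 2 or after.size < 2:
        raise ValueError("each list needs at least 2 values")
    dmean = float(after.mean() - before.mean())
    n1, n2 = before.size, after.size
    pooled_var = ((n1 - 1) * before.var(ddof=1) + (n2 - 1) * after.var(ddof=1)) / (n1 + n2 - 2)
    pooled_sd = math.sqrt(pooled_var)
    if pooled_sd == 0.0:
        if dmean == 0.0:
            return 0.0
        log.warning("pooled SD is 0 with unequal means; Cohen d is infinite")
        return math.copysign(math.inf, dmean)
    return dmean / pooled_sd


def compute_metrics(
    compound_id: str,
    rates_before: Sequence[float],
    rates_after: Sequence[float],
    active_rate_min: float = 0.33,
) -> ScreenMetrics:
    """Build :class:`ScreenMetrics` from paired per-channel rates.

    Only channels active at baseline (rate strictly above
    ``active_rate_min``) enter the paired lists; ``n_active`` counts
    them.  The FDR-adjusted p is left NaN until the whole library is
    adjusted together (see :func:`screen_library`).
    """
    before = np.asarray(rates_before, dtype=float)
    after = np.asarray(rates_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired lists must have equal length")
    keep = before > active_rate_min
    before, after = before[keep], after[keep]
    n_active = int(keep.sum())
    if n_active == 0:
        return ScreenMetrics(
            compound_id=compound_id, rates_before=before, rates_after=after,
            normalised_activity=float("nan"), p_raw=float("nan"),
            robust_z=float("nan"), cohen_d=float("nan"),
            n_active=0, median_separation_mads=float("nan"),
        )
    z = robust_z(before, after)
    return ScreenMetrics(
        compound_id=compound_id,
        rates_before=before,
        rates_after=after,
        normalised_activity=normalised_activity(before, after),
        p_raw=paired_wilcoxon(before, after),
        robust_z=z,
        cohen_d=cohen_d(before, after) if n_active >= 2 else float("nan"),
        n_active=n_active,
        median_separation_mads=abs(z),
    )


def call_hit(m: ScreenMetrics, t: HitThresholds = HitThresholds(),
             require_median_separation: bool = False) -> HitCall:
    """Apply the composite hit criteria and assign an intensity tier.

    A hit requires normalised activity below 50%, FDR-corrected
    p < .01, |robust z′| > 1.96, |Cohen d| > 0.80 and at least 9 active
    channels; the optional median-separation criterion (≥ 2 MADs) is
    applied when ``require_median_separation`` is set.  Tiers partition
    the reduction r = 100 − normalised activity: high (r > 90),
    moderate (70 < r ≤ 90), low (50 < r ≤ 70).
    """
    failed: list[str] = []
    if not (m.normalised_activity < t.max_normalised_activity):
        failed.append("max_normalised_activity")
    if not (m.p_fdr < t.max_p_fdr):
        failed.append("max_p_fdr")
    if not (abs(m.robust_z) > t.z_cut):
        failed.append("z_cut")
    if not (abs(m.cohen_d) > t.d_cut):
        failed.append("d_cut")
    if not (m.n_active >= t.min_active):
        failed.append("min_active")
    if require_median_separation and not (m.median_separation_mads >= t.min_median_sep_mads):
        failed.append("min_median_sep_mads")

    is_hit = not failed
    if is_hit:
        reduction = 100.0 - m.normalised_activity
        if reduction > 90.0:
            tier = Tier.HIGH
        elif reduction > 70.0:
            tier = Tier.MODERATE
        else:  # hit implies reduction > 50
            tier = Tier.LOW
    else:
        tier = Tier.NONE
    return HitCall(compound_id=m.compound_id, is_hit=is_hit, tier=tier,
                   failed_criteria=failed)


def screen_library(
    rates: dict[str, tuple[Sequence[float], Sequence[float]]],
    thresholds: HitThresholds = HitThresholds(),
    active_rate_min: float = 0.33,
    require_median_separation: bool = False,
) -> tuple[pd.DataFrame, list[HitCall]]:
    """Screen a compound library from paired per-channel rate lists.

    ``rates`` maps compound id to (before, after) per-channel firing
    rates.  Raw Wilcoxon p values are BH-adjusted across the library
    (one p per compound) before hit calling.  Returns a results table
    and the per-compound hit calls.
    """
    metrics = [
        compute_metrics(cid, before, after, active_rate_min=active_rate_min)
        for cid, (before, after) in rates.items()
    ]
    usable = [m for m in metrics if np.isfinite(m.p_raw)]
    if usable:
        adjusted = fdr_adjust([m.p_raw for m in usable])
        for m, p in zip(usable, adjusted):
            m.p_fdr = float(p)

    calls = [call_hit(m, thresholds, require_median_separation) for m in metrics]
    table = pd.DataFrame(
        {
            "compound_id": [m.compound_id for m in metrics],
            "normalised_activity": [m.normalised_activity for m in metrics],
            "p_raw": [m.p_raw for m in metrics],
            "p_fdr": [m.p_fdr for m in metrics],
            "robust_z": [m.robust_z for m in metrics],
            "cohen_d": [m.cohen_d for m in metrics],
            "n_active": [m.n_active for m in metrics],
            "is_hit": [c.is_hit for c in calls],
            "tier": [c.tier.value for c in calls],
            "failed_criteria": [";".join(c.failed_criteria) for c in calls],
        }
    )
    return table, calls
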