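"""Concentration–response models and fitting.

Two sigmoid forms are used in the screen:

* an inhibitory Hill curve on normalised MEA activity (percentage of
  baseline firing), with fixed asymptotes at 100% and 0%::

      A(c) = 100 / (1 + (c / IC50)^n)

  so that activity is 50% (i.e. 50% inhibition) exactly at ``c = IC50``;

* a Boltzmann sigmoid in *linear* concentration for patch-clamp
  inhibition fractions (ΔI/ΔI_TTX)::

      B(c) = emax / (1 + exp((IC50 - c) / h))

  whose slope factor ``h`` carries concentration units (µM).  ``emax``
  is fixed at 1 by default and can be freed for compounds that do not
  fully block the TTX-sensitive current.

Fits minimise the sum of squared residuals with a multi-start
trust-region least-squares optimiser; goodness of fit is reported as
``R² = 1 - SSE/SST``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

__all__ = [
    "DoseResponsePoint",
    "DoseResponseFit",
    "Tier",
    "TierRange",
    "hill_activity",
    "boltzmann_inhibition",
    "fit_dose_response",
    "select_tier_range",
    "TIER_GRIDS",
]


class Tier(str, Enum):
    """Hit-intensity tier from the single-concentration screen."""

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"
    NONE = "none"


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (concentration, response) observation.

    ``response`` is percent activity in MEA mode or an inhibition
    fraction ΔI/ΔI_TTX in patch mode.
    """

    concentration: float  # µM, >= 0
    response: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass
class DoseResponseFit:
    """Result of a nonlinear concentration–response fit."""

    model: str  # "hill_log" | "boltzmann_linear"
    ic50: float  # µM
    slope: float  # Hill n (dimensionless) or Boltzmann h (µM)
    r_squared: float
    sse: float
    concentration_grid: np.ndarray
    converged: bool
    max_inhibition: float = 1.0  # Boltzmann emax (1 unless freed)
    no_dose_dependence: bool = False
    compound_id: str = ""

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        if self.model == "hill_log":
            return hill_activity(c, self.ic50, self.slope)
        return self.max_inhibition * _boltzmann_core(np.asarray(c, dtype=float), self.ic50, self.slope)


@dataclass(frozen=True)
class TierRange:
    tier: Tier
    concentrations: tuple[float, ...]  # descending, ends with 0 (vehicle)


#: Tiered concentration grids (µM) for follow-up concentration–response
#: runs; 0 µM is the DMSO vehicle control.
TIER_GRIDS: dict[Tier, tuple[float, ...]] = {
    Tier.HIGH: (10.0, 8.0, 6.0, 4.0, 2.0, 0.0),
    Tier.MODERATE: (12.5, 10.0, 7.5, 5.0, 2.5, 0.0),
    Tier.LOW: (16.6, 13.3, 10.0, 6.6, 3.3, 0.0),
}


def hill_activity(c, ic50: float, n: float):
    """Percent activity remaining at concentration ``c`` (µM).

    Returns 100 at c = 0 and 50 at c = IC50; strictly decreasing for
    n > 0.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    if n <= 0:
        raise ValueError("Hill coefficient n must be > 0")
    c = np.asarray(c, dtype=float)
    out = 100.0 / (1.0 + (c / ic50) ** n)
    return float(out) if out.ndim == 0 else out


def _boltzmann_core(c: np.ndarray, ic50: float, h: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip((ic50 - c) / h, -700.0, 700.0)))


def boltzmann_inhibition(c, ic50: float, h: float):
    """Inhibition fraction at concentration ``c`` (µM), linear-c Boltzmann.

    Equals 0.5 at c = IC50; ``h`` (µM) sets the steepness.
    """
    if h == 0:
        raise ValueError("slope factor h must be nonzero")
    out = _boltzmann_core(np.asarray(c, dtype=float), ic50, h)
    return float(out) if out.ndim == 0 else out


def _model_functions(model: str, free_max: bool):
    if model == "hill_log":
        def f(params, c):
            ic50, slope = params
            return 100.0 / (1.0 + (c / ic50) ** slope)
        return f, 2
    if model == "boltzmann_linear":
        if free_max:
            def f(params, c):
                ic50, slope, emax = params
                return emax * _boltzmann_core(c, ic50, slope)
            return f, 3

        def f(params, c):
            ic50, slope = params
            return _boltzmann_core(c, ic50, slope)
        return f, 2
    raise ValueError(f"unknown model {model!r}")


def fit_dose_response(
    points: Iterable[DoseResponsePoint],
    model: str = "hill_log",
    init: Sequence[float] | None = None,
    free_max: bool = False,
    n_starts: int = 7,
    compound_id: str = "",
) -> DoseResponseFit:
    """Least-squares fit of a concentration–response model.

    Uses >= 5 log-spaced IC50 starting values spanning the observed
    concentration range and keeps the solution with the lowest SSE
    (ties broken toward the smaller IC50).  A fit whose SSE improves on
    the constant-mean model by less than 1% is flagged as showing no
    concentration–effect relationship and reported unconverged.

    Parameters
    ----------
    points
        Observations; at least 4 distinct concentrations are required.
    model
        ``"hill_log"`` (percent activity) or ``"boltzmann_linear"``
        (inhibition fraction).
    init
        Optional explicit parameter start, tried in addition to the
        multi-start grid.
    free_max
        Boltzmann mode only: free the maximum-inhibition asymptote
        instead of fixing it at 1 (for compounds with partial block).
    """
    pts = list(points)
    c = np.array([p.concentration for p in pts], dtype=float)
    y = np.array([p.response for p in pts], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")

    func, n_params = _model_functions(model, free_max)

    c_pos = c[c > 0]
    c_lo, c_hi = float(c_pos.min()), float(c_pos.max())
    ic50_starts = np.geomspace(c_lo / 3.0, c_hi * 3.0, max(5, n_starts))
    if model == "hill_log":
        slope_start = 1.0
        lower = [1e-9, 1e-3]
        upper = [1e6, 50.0]
    else:
        slope_start = max((c_hi - c_lo) / 4.0, 1e-3)
        lower = [1e-9, 1e-6]
        upper = [1e6, 1e5]
    if n_params == 3:
        lower.append(1e-3)
        upper.append(1.5)

    starts = []
    for s in ic50_starts:
        p0 = [float(s), slope_start]
        if n_params == 3:
            p0.append(1.0)
        starts.append(p0)
    if init is not None:
        starts.append(list(init))

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lower, upper)
        try:
            sol = least_squares(
                lambda p: func(p, c) - y, p0, bounds=(lower, upper),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # singular start; other starts still tried
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0] - 1e-15 or (
            abs(sse - best[0]) <= 1e-15 and sol.x[0] < best[1].x[0]
        ):
            best = (sse, sol)
    if best is None:
        raise RuntimeError("all optimiser starts failed")

    sse, sol = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    no_dep = sst == 0 or (sst - sse) / sst < 0.01
    if no_dep:
        log.warning("%s: no concentration-effect relationship detected", compound_id or model)

    ic50, slope = float(sol.x[0]), float(sol.x[1])
    emax = float(sol.x[2]) if n_params == 3 else 1.0
    grid = np.geomspace(max(c_lo / 10.0, 1e-4), c_hi * 10.0, 100)
    return DoseResponseFit(
        model=model, ic50=ic50, slope=slope, r_squared=r2, sse=sse,
        concentration_grid=grid, converged=bool(sol.success) and not no_dep,
        max_inhibition=emax, no_dose_dependence=no_dep, compound_id=compound_id,
    )


def select_tier_range(tier: Tier | str) -> TierRange:
    """Concentration grid for a hit tier's follow-up run (0 = vehicle)."""
    tier = Tier(tier)
    if tier is Tier.NONE:
        raise ValueError("no concentration range is defined for non-hits")
    return TierRange(tier=tier, concentrations=TIER_GRIDS[tier])
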