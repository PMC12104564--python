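"""End-to-end screening pipeline: detect → screen → filter → fit → select.

Wires the stage modules together for a whole plate (or a rate table):
spike detection per channel and phase, per-compound screening
statistics with library-wide FDR adjustment, LDH toxicity and washout
reversibility filters, optional concentration–response fits, and
patch-clamp candidate selection.  The funnel is monotone by
construction: candidates ⊆ reversible ⊆ non-toxic ⊆ hits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _version
from .doseresponse import DoseResponseFit, DoseResponsePoint, fit_dose_response
from .plateio import _container_from
from .screen import HitCall, HitThresholds, screen_library
from .spikes import DetectorConfig, Phase, bandpass, classify_active, detect_spikes, mean_rate
from .synthgen import CompoundTruth, PlateSpec
from .toxicity import (
    LdhReading,
    RecoveryRecord,
    classify_reversibility,
    select_patch_candidates,
    toxicity_flags,
)

log = logging.getLogger(__name__)

__all__ = [
    "summarise_plate",
    "paired_rates_by_compound",
    "readings_from_table",
    "design_screen",
    "FunnelReport",
    "run_pipeline",
]


def summarise_plate(plate, cfg: DetectorConfig = DetectorConfig()) -> pd.DataFrame:
    """Detect spikes on every channel/phase and tabulate firing rates.

    Accepts a :class:`~nociscreen.plateio.PlateContainer` or simulation
    output.  Columns: well, electrode, phase, rate_hz, active.
    """
    container = _container_from(plate)
    rows = []
    for (well, elec), by_phase in container.traces.items():
        for phase, trace in by_phase.items():
            filtered = bandpass(trace, cfg)
            train = detect_spikes(filtered, cfg)
            rate = mean_rate(train)
            rows.append(
                {
                    "well": well, "electrode": elec, "phase": phase.value,
                    "rate_hz": rate, "active": classify_active(rate, cfg),
                }
            )
    return pd.DataFrame(rows)


def paired_rates_by_compound(
    rates: pd.DataFrame,
    exposures: Mapping[str, tuple[str, float]],
) -> dict[str, dict[str, np.ndarray]]:
    """Pivot a rate table into per-compound paired phase arrays.

    Channels are pooled across all wells exposed to the same compound.
    Returns ``{compound: {"baseline": ..., "post": ..., "washout": ...}}``
    with channel pairing preserved across phases.
    """
    well_to_cid = {w: cid for w, (cid, _) in exposures.items()}
    pivot = rates.pivot_table(
        index=["well", "electrode"], columns="phase", values="rate_hz"
    )
    out: dict[str, dict[str, np.ndarray]] = {}
    for (well, _), row in pivot.iterrows():
        cid = well_to_cid.get(well)
        if cid is None:
            continue
        d = out.setdefault(cid, {p.value: [] for p in Phase})
        for p in Phase:
            d[p.value].append(row.get(p.value, np.nan))
    return {
        cid: {k: np.asarray(v, dtype=float) for k, v in d.items()}
        for cid, d in out.items()
    }


def readings_from_table(table: pd.DataFrame) -> list[LdhReading]:
    """Convert an LDH absorbance table into typed readings."""
    return [
        LdhReading(
            compound_id=row["compound_id"], a490=row["a490"], a680=row["a680"],
            timepoint_h=row["timepoint_h"], role=row["role"],
        )
        for _, row in table.iterrows()
    ]


def design_screen(
    n_compounds: int = 20,
    n_hits: int = 4,
    wells_per_compound: int = 3,
    concentration: float = 10.0,
    hit_ic50: float = 2.0,
    hit_hill_n: float = 3.0,
    null_ic50: float = 5000.0,
    n_toxic: int = 0,
    n_irreversible: int = 0,
    seed: int = 0,
    **spec_overrides,
) -> tuple[PlateSpec, dict[str, tuple[str, float]], dict[str, CompoundTruth]]:
    """Lay out a single-concentration screen for a synthetic library.

    Each compound occupies ``wells_per_compound`` wells (the screen
    records three to five wells per condition) at the standard 10 µM.
    The first ``n_hits`` compounds are true suppressors
    (IC50 = 2 µM, n = 3 → >95% suppression at 10 µM); the rest are
    inert (IC50 far above the tested range).  Optionally the first
    ``n_toxic`` hits are marked cytotoxic and the next
    ``n_irreversible`` get zero washout recovery.
    """
    spec = PlateSpec(
        n_wells=n_compounds * wells_per_compound,
        seed=seed,
        **spec_overrides,
    )
    truths: dict[str, CompoundTruth] = {}
    exposures: dict[str, tuple[str, float]] = {}
    wells = spec.well_ids()
    for k in range(n_compounds):
        cid = f"C{k + 1:03d}"
        is_hit = k < n_hits
        truths[cid] = CompoundTruth(
            compound_id=cid,
            ic50_true=hit_ic50 if is_hit else null_ic50,
            hill_n_true=hit_hill_n if is_hit else 1.0,
            toxic=is_hit and k < n_toxic,
            reversible=not (is_hit and n_toxic <= k < n_toxic + n_irreversible),
            recovery_fraction=0.0
            if (is_hit and n_toxic <= k < n_toxic + n_irreversible)
            else 0.8,
        )
        for j in range(wells_per_compound):
            exposures[wells[k * wells_per_compound + j]] = (cid, concentration)
    return spec, exposures, truths


@dataclass
class FunnelReport:
    """Stage-by-stage outcome of one screening run."""

    screen_table: pd.DataFrame
    hit_calls: list[HitCall]
    hits: list[str]
    toxic: dict[str, bool]
    nontoxic_hits: list[str]
    recovery: dict[str, RecoveryRecord]
    reversible: list[str]
    fits: dict[str, DoseResponseFit]
    candidates: list[str]
    counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {
                "compounds": len(self.screen_table),
                "hits": len(self.hits),
                "nontoxic_hits": len(self.nontoxic_hits),
                "reversible": len(self.reversible),
                "candidates": len(self.candidates),
            }
        # funnel monotonicity is a structural invariant of the analysis
        assert set(self.candidates) <= set(self.reversible)
        assert set(self.reversible) <= set(self.nontoxic_hits)
        assert set(self.nontoxic_hits) <= set(self.hits)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": _version,
            "seed": self.seed,
            "counts": self.counts,
            "hits": self.hits,
            "nontoxic_hits": self.nontoxic_hits,
            "reversible": self.reversible,
            "candidates": self.candidates,
            "excluded": {
                row["compound_id"]: row["failed_criteria"]
                for _, row in self.screen_table.iterrows()
                if row["failed_criteria"]
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(
    rates: pd.DataFrame,
    exposures: Mapping[str, tuple[str, float]],
    ldh_table: pd.DataFrame | None = None,
    thresholds: HitThresholds = HitThresholds(),
    detector: DetectorConfig = DetectorConfig(),
    dose_points: pd.DataFrame | None = None,
    require_median_separation: bool = False,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> FunnelReport:
    """Run screen → toxicity → reversibility → fits → candidate selection.

    ``rates`` is a per-channel rate table (from :func:`summarise_plate`
    or :func:`nociscreen.synthgen.simulate_rate_table`).  ``dose_points``
    optionally provides concentration–response observations (columns
    compound_id, concentration, response) for hits that survive the
    filters; compounds without fit data skip the IC50 cut.
    """
    paired = paired_rates_by_compound(rates, exposures)
    rate_lists = {
        cid: (d["baseline"], d["post"]) for cid, d in paired.items()
    }
    table, calls = screen_library(
        rate_lists, thresholds, active_rate_min=detector.active_rate_min,
        require_median_separation=require_median_separation,
    )
    hits = [c.compound_id for c in calls if c.is_hit]

    toxic = toxicity_flags(readings_from_table(ldh_table)) if ldh_table is not None else {}
    nontoxic_hits = [cid for cid in hits if not toxic.get(cid, False)]

    recovery: dict[str, RecoveryRecord] = {}
    reversible: list[str] = []
    for cid in nontoxic_hits:
        d = paired[cid]
        before, post, wash = d["baseline"], d["post"], d["washout"]
        keep = before > detector.active_rate_min
        before, post, wash = before[keep], post[keep], wash[keep]
        mb = before.mean()
        if mb <= 0:
            continue
        n = keep.sum()
        se = 100.0 / mb * np.sqrt(
            post.var(ddof=1) / n + wash.var(ddof=1) / n
        ) if n > 1 else 0.0
        rec = RecoveryRecord(
            compound_id=cid,
            activity_post=100.0 * post.mean() / mb,
            activity_washout=100.0 * wash.mean() / mb,
            activity_se=float(se),
        )
        recovery[cid] = classify_reversibility(rec)
        if recovery[cid].reversible:
            reversible.append(cid)

    fits: dict[str, DoseResponseFit] = {}
    if dose_points is not None:
        for cid in reversible:
            sub = dose_points[dose_points["compound_id"] == cid]
            if sub["concentration"].nunique() >= 4:
                pts = [
                    DoseResponsePoint(row["concentration"], row["response"])
                    for _, row in sub.iterrows()
                ]
                fits[cid] = fit_dose_response(pts, model="hill_log", compound_id=cid)

    if fits:
        candidates = select_patch_candidates(
            fits, recovery, toxic,
        )
        candidates = [c for c in candidates if c in reversible]
    else:
        candidates = [
            cid for cid in reversible if recovery[cid].recovery_pct >= 60.0
        ]

    report = FunnelReport(
        screen_table=table, hit_calls=calls, hits=hits, toxic=toxic,
        nontoxic_hits=nontoxic_hits, recovery=recovery, reversible=reversible,
        fits=fits, candidates=candidates, seed=seed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "screen_results.csv", index=False)
        report.to_json(out_dir / "funnel.json")
        if recovery:
            pd.DataFrame(
                [
                    {
                        "compound_id": cid, "activity_post": r.activity_post,
                        "activity_washout": r.activity_washout,
                        "recovery_pct": r.recovery_pct, "reversible": r.reversible,
                    }
                    for cid, r in recovery.items()
                ]
            ).to_csv(out_dir / "recovery.csv", index=False)
    return report
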