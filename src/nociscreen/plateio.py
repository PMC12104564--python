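"""Plate container formats and the cohort class tally.

A plate is stored either as an HDF5 file with groups
``/wells/<well>/<electrode>/<phase>`` holding µV sample arrays (root
attributes carry the sampling rate and duration, plus the plate map as
a JSON attribute), or — for small fixtures — as a directory of
one-column CSVs with a ``meta.json`` sidecar.  Round trips are
lossless for samples and metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np

from .spikes import ChannelTrace, Phase

__all__ = [
    "PlateContainer",
    "PlateValidationError",
    "write_plate",
    "read_plate",
    "write_truth_sidecar",
    "ClassTally",
    "tally_classes",
]

PHASES = (Phase.BASELINE, Phase.POST, Phase.WASHOUT)


class PlateValidationError(ValueError):
    """A plate container is structurally incomplete."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__("plate container is missing: " + ", ".join(missing))


@dataclass
class PlateContainer:
    """In-memory plate: traces per (well, electrode, phase) + metadata."""

    traces: dict[tuple[str, str], dict[Phase, ChannelTrace]]
    sampling_rate: float
    duration: float
    exposures: dict[str, tuple[str, float]] = field(default_factory=dict)

    def channels(self) -> list[tuple[str, str]]:
        return sorted(self.traces.keys())

    def validate(self) -> None:
        missing = []
        for key, by_phase in self.traces.items():
            for phase in PHASES:
                if phase not in by_phase:
                    missing.append(f"{key[0]}/{key[1]}/{phase.value}")
        if missing:
            raise PlateValidationError(missing)


def _container_from(plate) -> PlateContainer:
    if isinstance(plate, PlateContainer):
        return plate
    # duck-typed SimulatedPlate
    return PlateContainer(
        traces=plate.traces,
        sampling_rate=plate.spec.sampling_rate,
        duration=plate.spec.duration,
        exposures=dict(plate.exposures),
    )


def write_plate(path: str | Path, plate) -> Path:
    """Write a plate (container or simulation output) to HDF5 or CSV dir.

    Paths ending in ``.h5``/``.hdf5`` select HDF5; anything else is
    treated as a directory of CSV fixtures.
    """
    container = _container_from(plate)
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_hdf5(path, container)
    else:
        _write_csv_dir(path, container)
    return path


def _write_hdf5(path: Path, c: PlateContainer) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = c.sampling_rate
        f.attrs["duration"] = c.duration
        f.attrs["exposures"] = json.dumps(
            {w: [cid, conc] for w, (cid, conc) in c.exposures.items()}
        )
        wells = f.create_group("wells")
        for (well, elec), by_phase in c.traces.items():
            g = wells.require_group(well).require_group(elec)
            for phase, trace in by_phase.items():
                g.create_dataset(phase.value, data=trace.samples)


def _write_csv_dir(path: Path, c: PlateContainer) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "sampling_rate": c.sampling_rate,
        "duration": c.duration,
        "exposures": {w: [cid, conc] for w, (cid, conc) in c.exposures.items()},
        "channels": [[w, e] for (w, e) in c.channels()],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    for (well, elec), by_phase in c.traces.items():
        for phase, trace in by_phase.items():
            out = path / f"{well}_{elec}_{phase.value}.csv"
            # %.9g round-trips float32 samples exactly through decimal
            np.savetxt(out, np.asarray(trace.samples), fmt="%.9g",
                       header="voltage_uv", comments="")


def read_plate(path: str | Path) -> PlateContainer:
    """Read a plate container (HDF5 file or CSV directory) and validate it."""
    path = Path(path)
    if path.is_dir():
        container = _read_csv_dir(path)
    else:
        container = _read_hdf5(path)
    container.validate()
    return container


def _read_hdf5(path: Path) -> PlateContainer:
    traces: dict[tuple[str, str], dict[Phase, ChannelTrace]] = {}
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate"])
        duration = float(f.attrs["duration"])
        exposures = {
            w: (v[0], float(v[1]))
            for w, v in json.loads(f.attrs.get("exposures", "{}")).items()
        }
        for well in f["wells"]:
            for elec in f["wells"][well]:
                by_phase: dict[Phase, ChannelTrace] = {}
                for phase_name in f["wells"][well][elec]:
                    phase = Phase(phase_name)
                    by_phase[phase] = ChannelTrace(
                        samples=f["wells"][well][elec][phase_name][()],
                        sampling_rate=fs, well_id=well, electrode_id=elec,
                        phase=phase,
                    )
                traces[(well, elec)] = by_phase
    return PlateContainer(traces=traces, sampling_rate=fs, duration=duration,
                          exposures=exposures)


def _read_csv_dir(path: Path) -> PlateContainer:
    meta = json.loads((path / "meta.json").read_text())
    fs = float(meta["sampling_rate"])
    traces: dict[tuple[str, str], dict[Phase, ChannelTrace]] = {}
    for well, elec in meta["channels"]:
        by_phase: dict[Phase, ChannelTrace] = {}
        for phase in PHASES:
            f = path / f"{well}_{elec}_{phase.value}.csv"
            if not f.exists():
                continue
            samples = np.loadtxt(f, skiprows=1)
            by_phase[phase] = ChannelTrace(
                samples=np.atleast_1d(samples), sampling_rate=fs,
                well_id=well, electrode_id=elec, phase=phase,
            )
        traces[(well, elec)] = by_phase
    exposures = {w: (v[0], float(v[1])) for w, v in meta.get("exposures", {}).items()}
    return PlateContainer(traces=traces, sampling_rate=fs,
                          duration=float(meta["duration"]), exposures=exposures)


def write_truth_sidecar(path: str | Path, truths: Mapping[str, object]) -> Path:
    """Write compound ground truth next to a simulated plate as JSON."""
    path = Path(path)
    payload = {}
    for cid, t in truths.items():
        payload[cid] = {
            "ic50_true": t.ic50_true, "hill_n_true": t.hill_n_true,
            "toxic": t.toxic, "reversible": t.reversible,
            "recovery_fraction": t.recovery_fraction,
        }
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# cohort tallies
# ---------------------------------------------------------------------------


@dataclass
class ClassTally:
    """Counts and whole-percent shares of activity-class labels."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, int]  # rounded half-up to whole percent


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def tally_classes(labels: Iterable[str]) -> ClassTally:
    """Tally activity-class labels into counts and whole percentages.

    Percentages are rounded half-up (11 of 43 → 26%).
    """
    labels = [getattr(lab, "value", lab) for lab in labels]
    if not labels:
        raise ValueError("cannot tally an empty label list")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(labels)
    pct = {lab: _round_half_up(100.0 * n / total) for lab, n in counts.items()}
    return ClassTally(counts=counts, total=total, percentages=pct)
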