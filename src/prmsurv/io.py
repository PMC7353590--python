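"""Readers and writers for the on-disk artifacts of the workflow.

Formats
-------
FASTA
    Protein databases, read via Biopython; ids must be unique, bodies are
    upper-cased.
Transition TSV
    One row per (precursor, fragment) pair; fixed column order
    ``analyte_id, analyte_kind, precursor_mz, precursor_charge,
    fragment_label, fragment_mz, activation, rt_start_min, rt_end_min``
    with m/z serialized at 4 decimal places.
Run TSV
    Long-format chromatogram store, columns
    ``transition_id, time_min, intensity``; the canonical interchange for
    PRM runs in this package.
Spectrum-list XML
    A minimal centroided-spectrum dialect
    (``<spectrumList><spectrum time_min="..."><peak mz="..."
    intensity="..."/></spectrum></spectrumList>``) from which traces are
    assembled by m/z matching within an absolute tolerance (default 0.01,
    the usual Orbitrap method-match tolerance); the nearest target wins a
    tie.
Sample metadata CSV
    One row per injection: subject, digestive compartment, run path and
    spiked amounts.

All writers are deterministic: fixed column order, fixed float formats, no
timestamps.  All readers reject malformed input instead of repairing it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
import numpy as np
from Bio import SeqIO
from lxml import etree

from .chromatograms import Chromatogram, PrmRun

__all__ = [
    "TransitionRecord",
    "SampleRecord",
    "Spectrum",
    "COMPARTMENTS",
    "read_fasta",
    "write_fasta",
    "read_transitions",
    "write_transitions",
    "read_run",
    "write_run",
    "read_spectra",
    "write_spectra",
    "assemble_run_from_spectra",
    "read_samples",
    "write_samples",
]

COMPARTMENTS = ("feed", "gastric", "intestinal", "stool")

_TRANSITION_COLUMNS = [
    "analyte_id",
    "analyte_kind",
    "precursor_mz",
    "precursor_charge",
    "fragment_label",
    "fragment_mz",
    "activation",
    "rt_start_min",
    "rt_end_min",
]

_SAMPLE_COLUMNS = [
    "subject_id",
    "compartment",
    "injection",
    "run_path",
    "spiked_target",
    "spiked_sis",
    "spiked_peg",
    "note",
]


@dataclass(frozen=True)
class TransitionRecord:
    """One precursor→fragment transition with its acquisition window."""

    analyte_id: str
    analyte_kind: str  # "peptide" | "peg"
    precursor_mz: float
    precursor_charge: int
    fragment_label: str  # e.g. "y2".."y7" or "DP7".."DP17"
    fragment_mz: float
    activation: str  # "HCD" | "CID"
    rt_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.analyte_kind not in ("peptide", "peg"):
            raise ValueError(f"unknown analyte kind {self.analyte_kind!r}")
        if self.fragment_mz <= 0 or self.precursor_mz <= 0:
            raise ValueError(f"{self.analyte_id}/{self.fragment_label}: m/z must be positive")
        if self.activation not in ("HCD", "CID"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not self.rt_window[0] < self.rt_window[1]:
            raise ValueError(f"{self.analyte_id}: rt_window start must precede end")

    @property
    def transition_id(self) -> str:
        return f"{self.analyte_id}/{self.fragment_label}"


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one injected sample replicate."""

    subject_id: str
    compartment: str
    injection: int
    run_path: str
    spiked_target: float | None = None
    spiked_sis: float | None = None
    spiked_peg: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment {self.compartment!r} not in {COMPARTMENTS}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into an ordered ``{id: SEQUENCE}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().strip()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records.items():
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transition lists


def write_transitions(transitions: list[TransitionRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRANSITION_COLUMNS)
        for t in transitions:
            writer.writerow(
                [
                    t.analyte_id,
                    t.analyte_kind,
                    f"{t.precursor_mz:.4f}",
                    t.precursor_charge,
                    t.fragment_label,
                    f"{t.fragment_mz:.4f}",
                    t.activation,
                    f"{t.rt_window[0]:.2f}",
                    f"{t.rt_window[1]:.2f}",
                ]
            )


def read_transitions(path) -> list[TransitionRecord]:
    transitions = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _TRANSITION_COLUMNS:
            missing = set(_TRANSITION_COLUMNS) - set(reader.fieldnames or [])
            raise ValueError(f"{path}: bad transition header, missing {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                transitions.append(
                    TransitionRecord(
                        analyte_id=row["analyte_id"],
                        analyte_kind=row["analyte_kind"],
                        precursor_mz=float(row["precursor_mz"]),
                        precursor_charge=int(row["precursor_charge"]),
                        fragment_label=row["fragment_label"],
                        fragment_mz=float(row["fragment_mz"]),
                        activation=row["activation"],
                        rt_window=(float(row["rt_start_min"]), float(row["rt_end_min"])),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return transitions


# ---------------------------------------------------------------------------
# Run stores


def write_run(run: PrmRun, path) -> None:
    """Write a run as long-format TSV; times at 4 dp, intensities at 6 dp."""
    with open(path, "w", newline="") as fh:
        fh.write("transition_id\ttime_min\tintensity\n")
        for tid in run.transition_ids:
            chrom = run[tid]
            for t, y in zip(chrom.times, chrom.intensities):
                fh.write(f"{tid}\t{t:.4f}\t{y:.6f}\n")


def read_run(path, sample_id: str | None = None) -> PrmRun:
    times: dict[str, list[float]] = {}
    values: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ["transition_id", "time_min", "intensity"]:
            raise ValueError(f"{path}: bad run header {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                tid = row["transition_id"]
                t = float(row["time_min"])
                y = float(row["intensity"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            times.setdefault(tid, []).append(t)
            values.setdefault(tid, []).append(y)
    chroms = {}
    for tid in times:
        t = np.array(times[tid])
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{path}: unsorted or duplicate time points for transition {tid!r}"
            )
        chroms[tid] = Chromatogram(tid, t, np.array(values[tid]))
    return PrmRun(chromatograms=chroms, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Minimal spectrum-list XML


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS/MS scan: peak m/z values and intensities."""

    time_min: float
    mz: np.ndarray
    intensity: np.ndarray


def write_spectra(spectra: list[Spectrum], path) -> None:
    root = etree.Element("spectrumList")
    for spec in spectra:
        el = etree.SubElement(root, "spectrum", time_min=f"{spec.time_min:.4f}")
        for mz, y in zip(spec.mz, spec.intensity):
            etree.SubElement(el, "peak", mz=f"{mz:.4f}", intensity=f"{y:.6f}")
    etree.ElementTree(root).write(str(path), pretty_print=True)


def read_spectra(path) -> list[Spectrum]:
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "spectrumList":
        raise ValueError(f"{path}: expected <spectrumList> root, got <{root.tag}>")
    spectra = []
    for el in root.iter("spectrum"):
        try:
            time_min = float(el.get("time_min"))
            mz = np.array([float(p.get("mz")) for p in el.iter("peak")])
            inten = np.array([float(p.get("intensity")) for p in el.iter("peak")])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed spectrum element: {exc}") from exc
        spectra.append(Spectrum(time_min, mz, inten))
    spectra.sort(key=lambda s: s.time_min)
    return spectra


def assemble_run_from_spectra(
    spectra: list[Spectrum],
    transitions: list[TransitionRecord],
    tolerance: float = 0.01,
    sample_id: str | None = None,
) -> PrmRun:
    """Build per-transition traces from spectra by m/z matching.

    Every peak is assigned to its nearest target fragment m/z if the
    absolute difference is within ``tolerance``; intensities of multiple
    matched peaks in one scan are summed.  Unmatched peaks are dropped.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    targets = [(t.transition_id, t.fragment_mz) for t in transitions]
    n_scans = len(spectra)
    times = np.array([s.time_min for s in spectra])
    traces = {tid: np.zeros(n_scans) for tid, _ in targets}
    target_mz = np.array([mz for _, mz in targets])
    for i, spec in enumerate(spectra):
        for mz, y in zip(spec.mz, spec.intensity):
            deltas = np.abs(target_mz - mz)
            j = int(np.argmin(deltas))
            if deltas[j] <= tolerance:
                traces[targets[j][0]][i] += y
    chroms = {
        tid: Chromatogram(tid, times, trace) for tid, trace in traces.items()
    }
    return PrmRun(chromatograms=chroms, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Sample metadata


def write_samples(samples: list[SampleRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_SAMPLE_COLUMNS)
        for s in samples:
            writer.writerow(
                [
                    s.subject_id,
                    s.compartment,
                    s.injection,
                    s.run_path,
                    "" if s.spiked_target is None else repr(s.spiked_target),
                    "" if s.spiked_sis is None else repr(s.spiked_sis),
                    "" if s.spiked_peg is None else repr(s.spiked_peg),
                    s.note,
                ]
            )


def read_samples(path) -> list[SampleRecord]:
    samples = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _SAMPLE_COLUMNS:
            raise ValueError(f"{path}: bad sample-metadata header {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                samples.append(
                    SampleRecord(
                        subject_id=row["subject_id"],
                        compartment=row["compartment"],
                        injection=int(row["injection"]),
                        run_path=row["run_path"],
                        spiked_target=float(row["spiked_target"]) if row["spiked_target"] else None,
                        spiked_sis=float(row["spiked_sis"]) if row["spiked_sis"] else None,
                        spiked_peg=float(row["spiked_peg"]) if row["spiked_peg"] else None,
                        note=row["note"],
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    # Exactly one feed sample (any number of injections of it) per subject.
    feeds: dict[str, set[str]] = {}
    for s in samples:
        if s.compartment == "feed":
            feeds.setdefault(s.subject_id, set()).add(s.run_path.rsplit("_inj", 1)[0])
    subjects = {s.subject_id for s in samples}
    for subject in subjects:
        if subject not in feeds:
            raise ValueError(f"subject {subject!r} has no feed sample")
    return samples
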