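"""End-to-end orchestration: transitions → simulate → calibrate → quantify →
normalize → report.

A :class:`StudyConfig` (loadable from a YAML file) declares the analytes
(surrogate peptide, its isotope-labeled standard, and the PEG-28 dilution
marker), the standard series, integration and calibration settings, the
study design with its ground truth for simulation, and the random seed.
:func:`run_study` executes the whole chain in a working directory, writing
every intermediate artifact (transition list, run TSVs, calibration JSON,
per-injection quant CSV, survival CSV/JSON and a log of input hashes), and
each stage is also callable on its own so that the CLI subcommands compose
to the same result.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chromatograms import PrmRun
from .io import (
    SampleRecord,
    TransitionRecord,
    read_run,
    read_samples,
    read_transitions,
    write_run,
    write_samples,
    write_transitions,
)
from .masses import (
    ModifiedPeptide,
    PegOligomer,
    peg_mz,
    precursor_mz,
    round_half_up,
    y_ion_mz,
)
from .quantify import fit_calibration, invert_calibration, lod_loq, quantify_run
from .simulate import (
    AnalyteSignal,
    ResponseModel,
    SignalModel,
    StudyTruth,
    default_truth,
    simulate_digestion_study,
    simulate_standard_series,
)
from .survival import SampleQuant, build_survival_report, compartment_summaries

__all__ = [
    "AnalyteConfig",
    "SimulationSettings",
    "StudyDesign",
    "StudyConfig",
    "default_config",
    "load_config",
    "save_config",
    "build_transitions",
    "build_signal_model",
    "stage_transitions",
    "stage_simulate",
    "stage_calibrate",
    "stage_quantify",
    "stage_survive",
    "run_study",
]


@dataclass
class AnalyteConfig:
    """Definition of one targeted analyte."""

    analyte_id: str
    kind: str  # "peptide" | "peg"
    charge: int
    fragments: list[str]  # "y2".."y7" or "DP7".."DP17"
    activation: str
    rt_min: float
    rt_sd_min: float
    rt_window: tuple[float, float]
    calibration: str  # "linear" | "log"
    response: dict[str, float]  # {"slope": ...} or {"a": ..., "b": ...}
    recovery: float = 1.0
    sequence: str | None = None
    modifications: list[tuple[int, str]] = field(default_factory=list)
    n_units: int | None = None
    fragment_factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "peptide" and not self.sequence:
            raise ValueError(f"{self.analyte_id}: peptide analyte requires a sequence")
        if self.kind == "peg" and self.n_units is None:
            raise ValueError(f"{self.analyte_id}: PEG analyte requires n_units")
        if not self.fragments:
            raise ValueError(f"{self.analyte_id}: at least one fragment required")


@dataclass
class SimulationSettings:
    noise_rel: float = 0.01  # noise sd as a fraction of each trace's apex
    noise_floor: float = 10.0  # absolute noise sd, intensity units
    baseline: float = 0.0
    t_start: float = 0.0
    duration: float = 20.0
    dt: float = 0.02
    n_blanks: int = 3


@dataclass
class StudyDesign:
    target_id: str = "target_peptide"
    sis_id: str = "sis_peptide"
    peg_id: str = "peg28"
    n_injections: int = 4
    truth: StudyTruth = field(default_factory=default_truth)


@dataclass
class StudyConfig:
    analytes: list[AnalyteConfig]
    standard_series: dict[str, list[float]]
    tolerance_mz: float = 0.01
    baseline_mode: str = "flanking_median"
    seed: int = 1
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    study: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self) -> None:
        ids = [a.analyte_id for a in self.analytes]
        if len(ids) != len(set(ids)):
            raise ValueError("analyte ids must be unique")
        if self.tolerance_mz <= 0:
            raise ValueError("m/z match tolerance must be positive")
        for analyte in self.standard_series:
            if analyte not in ids:
                raise ValueError(f"standard series references unknown analyte {analyte!r}")

    def analyte(self, analyte_id: str) -> AnalyteConfig:
        for a in self.analytes:
            if a.analyte_id == analyte_id:
                return a
        raise KeyError(analyte_id)

    @property
    def windows(self) -> dict[str, tuple[float, float]]:
        return {a.analyte_id: tuple(a.rt_window) for a in self.analytes}


def default_config(seed: int = 1) -> StudyConfig:
    """The assay as published: LLIYDTSK (light and heavy) plus PEG-28.

    Precursors at m/z 476.7711 (z=2), 480.7782 (z=2) and 417.922 (z=3);
    y2–y7 quantifier ions under HCD for the peptides, the DP7–DP17 ladder
    (minus DP9) under CID for PEG-28; standard series 0.5–20, 0.01–1 and
    0.005–1 ng/µL; retention times 14.4 and 18.5 min; mean analytical
    recoveries 77.6% (peptides, shared with the labeled standard) and
    74.2% (PEG-28).  Response magnitudes are arbitrary instrument units.
    """
    y_ions = [f"y{k}" for k in range(2, 8)]
    dp_ions = [f"DP{n}" for n in range(7, 18) if n != 9]
    analytes = [
        AnalyteConfig(
            analyte_id="target_peptide",
            kind="peptide",
            sequence="LLIYDTSK",
            charge=2,
            fragments=list(y_ions),
            activation="HCD",
            rt_min=14.4,
            rt_sd_min=0.05,
            rt_window=(14.1, 14.7),
            calibration="linear",
            response={"slope": 8.0e4},
            recovery=0.776,
        ),
        AnalyteConfig(
            analyte_id="sis_peptide",
            kind="peptide",
            sequence="LLIYDTSK",
            modifications=[(7, "label_13C6_15N2_K")],
            charge=2,
            fragments=list(y_ions),
            activation="HCD",
            rt_min=14.4,
            rt_sd_min=0.05,
            rt_window=(14.1, 14.7),
            calibration="linear",
            response={"slope": 8.0e4},
            recovery=0.776,
        ),
        AnalyteConfig(
            analyte_id="peg28",
            kind="peg",
            n_units=28,
            charge=3,
            fragments=list(dp_ions),
            activation="CID",
            rt_min=18.5,
            rt_sd_min=0.05,
            rt_window=(18.2, 18.8),
            calibration="log",
            response={"a": 1.0e5, "b": 7.0e5},
            recovery=0.742,
        ),
    ]
    series = {
        "target_peptide": [0.5, 1.0, 2.0, 5.0, 10.0, 20.0],
        "sis_peptide": [0.01, 0.05, 0.1, 0.2, 0.5, 1.0],
        "peg28": [0.005, 0.01, 0.05, 0.1, 0.5, 1.0],
    }
    return StudyConfig(analytes=analytes, standard_series=series, seed=seed)


# ---------------------------------------------------------------------------
# Config (de)serialization


def save_config(config: StudyConfig, path) -> None:
    payload = asdict(config)
    payload["study"]["truth"] = {
        "feed_target": config.study.truth.feed_target,
        "feed_peg": config.study.truth.feed_peg,
        "sis_spike": config.study.truth.sis_spike,
        "cells": [asdict(c) for c in config.study.truth.cells],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    from .simulate import CompartmentTruth

    truth_raw = payload["study"].pop("truth")
    truth = StudyTruth(
        feed_target=truth_raw["feed_target"],
        feed_peg=truth_raw["feed_peg"],
        sis_spike=truth_raw["sis_spike"],
        cells=tuple(CompartmentTruth(**c) for c in truth_raw["cells"]),
    )
    analytes = []
    for a in payload["analytes"]:
        a = dict(a)
        a["rt_window"] = tuple(a["rt_window"])
        a["modifications"] = [tuple(m) for m in a.get("modifications", [])]
        analytes.append(AnalyteConfig(**a))
    return StudyConfig(
        analytes=analytes,
        standard_series=payload["standard_series"],
        tolerance_mz=payload.get("tolerance_mz", 0.01),
        baseline_mode=payload.get("baseline_mode", "flanking_median"),
        seed=payload.get("seed", 1),
        simulation=SimulationSettings(**payload.get("simulation", {})),
        study=StudyDesign(truth=truth, **payload["study"]),
    )


# ---------------------------------------------------------------------------
# Stage 1: transition list


def build_transitions(config: StudyConfig) -> list[TransitionRecord]:
    """Compute the full transition list from the analyte definitions."""
    if not config.analytes:
        raise ValueError("no analytes defined")
    transitions = []
    for a in config.analytes:
        if a.kind == "peptide":
            pep = ModifiedPeptide(a.sequence, a.modifications, a.charge)
            prec = precursor_mz(pep)
            for label in a.fragments:
                if not label.startswith("y"):
                    raise ValueError(f"{a.analyte_id}: unsupported fragment {label!r}")
                k = int(label[1:])
                frag = y_ion_mz(pep, k)
                transitions.append(
                    TransitionRecord(
                        analyte_id=a.analyte_id,
                        analyte_kind="peptide",
                        precursor_mz=round_half_up(prec, 4),
                        precursor_charge=a.charge,
                        fragment_label=label,
                        fragment_mz=round_half_up(frag, 4),
                        activation=a.activation,
                        rt_window=tuple(a.rt_window),
                    )
                )
        else:
            prec = peg_mz(PegOligomer(a.n_units, a.charge))
            for label in a.fragments:
                if not label.startswith("DP"):
                    raise ValueError(f"{a.analyte_id}: unsupported fragment {label!r}")
                n = int(label[2:])
                frag = peg_mz(PegOligomer(n, 1))
                transitions.append(
                    TransitionRecord(
                        analyte_id=a.analyte_id,
                        analyte_kind="peg",
                        precursor_mz=round_half_up(prec, 4),
                        precursor_charge=a.charge,
                        fragment_label=label,
                        fragment_mz=round_half_up(frag, 4),
                        activation=a.activation,
                        rt_window=tuple(a.rt_window),
                    )
                )
    return transitions


def build_signal_model(config: StudyConfig, seed: int | None = None) -> SignalModel:
    """Translate the analyte definitions into a simulation signal model."""
    analytes = {}
    for a in config.analytes:
        if a.calibration == "linear":
            response = ResponseModel("linear", (a.response["slope"],))
        else:
            response = ResponseModel("log", (a.response["a"], a.response["b"]))
        factors = a.fragment_factors or {
            label: 1.0 / len(a.fragments) for label in a.fragments
        }
        analytes[a.analyte_id] = AnalyteSignal(
            analyte_id=a.analyte_id,
            rt_min=a.rt_min,
            rt_sd_min=a.rt_sd_min,
            response=response,
            fragment_factors=factors,
            recovery=a.recovery,
        )
    sim = config.simulation
    return SignalModel(
        analytes=analytes,
        noise_sd=sim.noise_floor if sim.noise_rel > 0 else 0.0,
        noise_rel=sim.noise_rel,
        baseline=sim.baseline,
        seed=config.seed if seed is None else seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _log(workdir: Path, stage: str, inputs: list[Path], settings: str = "") -> None:
    line = f"stage={stage}"
    for p in inputs:
        line += f" {Path(p).name}={_sha256(p)}"
    if settings:
        line += f" {settings}"
    with open(workdir / "study.log", "a") as fh:
        fh.write(line + "\n")


def stage_transitions(config: StudyConfig, workdir) -> Path:
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    path = workdir / "transitions.tsv"
    write_transitions(build_transitions(config), path)
    _log(workdir, "transitions", [path], f"n={len(build_transitions(config))}")
    return path


# ---------------------------------------------------------------------------
# Stage 2: simulation


def stage_simulate(config: StudyConfig, workdir, seed: int | None = None) -> None:
    """Simulate standard series, blanks and the digestion study to disk."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    runs_dir = workdir / "runs"
    runs_dir.mkdir(exist_ok=True)
    transitions = build_transitions(config)
    model = build_signal_model(config, seed)
    sim = config.simulation
    run_kwargs = dict(t_start=sim.t_start, duration=sim.duration, dt=sim.dt)

    standards, blanks = simulate_standard_series(
        model,
        config.standard_series,
        transitions,
        n_blanks=sim.n_blanks,
        **run_kwargs,
    )
    with open(workdir / "standards.csv", "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["kind", "run_path", "analyte_id", "conc"])
        for i, (concs, run) in enumerate(standards, start=1):
            path = runs_dir / f"standard_L{i}.tsv"
            write_run(run, path)
            for analyte, conc in sorted(concs.items()):
                writer.writerow(["standard", f"runs/standard_L{i}.tsv", analyte, repr(conc)])
        for j, run in enumerate(blanks, start=1):
            path = runs_dir / f"blank_{j}.tsv"
            write_run(run, path)
            for analyte in sorted(config.standard_series):
                writer.writerow(["blank", f"runs/blank_{j}.tsv", analyte, "0.0"])

    design = config.study
    truth = design.truth
    runs = simulate_digestion_study(
        truth,
        model,
        transitions,
        target_id=design.target_id,
        sis_id=design.sis_id,
        peg_id=design.peg_id,
        n_injections=design.n_injections,
        **run_kwargs,
    )
    samples = []
    for (subject, compartment, inj), run in runs.items():
        rel = f"runs/{subject}_{compartment}_inj{inj}.tsv"
        write_run(run, workdir / rel)
        samples.append(
            SampleRecord(
                subject_id=subject,
                compartment=compartment,
                injection=inj,
                run_path=rel,
                spiked_target=truth.feed_target[subject] if compartment == "feed" else None,
                spiked_sis=truth.sis_spike,
                spiked_peg=truth.feed_peg if compartment == "feed" else None,
            )
        )
    write_samples(samples, workdir / "samples.csv")
    truth.to_json(workdir / "truth.json")
    _log(
        workdir,
        "simulate",
        [workdir / "standards.csv", workdir / "samples.csv", workdir / "truth.json"],
        f"seed={model.seed} noise_rel={sim.noise_rel}",
    )


# ---------------------------------------------------------------------------
# Stage 3: calibration


def stage_calibrate(config: StudyConfig, workdir) -> dict:
    workdir = Path(workdir)
    transitions = read_transitions(workdir / "transitions.tsv")
    with open(workdir / "standards.csv", newline="") as fh:
        rows = list(csv.DictReader(fh))
    # Collect responses per analyte per run.
    runs: dict[str, PrmRun] = {}
    for row in rows:
        if row["run_path"] not in runs:
            runs[row["run_path"]] = read_run(workdir / row["run_path"])
    responses = {
        path: quantify_run(run, transitions, config.windows, config.baseline_mode)
        for path, run in runs.items()
    }
    points: dict[str, list[tuple[float, float]]] = {}
    blank_responses: dict[str, list[float]] = {}
    for row in rows:
        analyte = row["analyte_id"]
        peak = responses[row["run_path"]].get(analyte)
        if peak is None:
            continue
        if row["kind"] == "standard":
            points.setdefault(analyte, []).append((float(row["conc"]), peak.total_area))
        else:
            blank_responses.setdefault(analyte, []).append(peak.total_area)

    calibration = {}
    for a in config.analytes:
        if a.analyte_id not in points:
            continue
        curve = fit_calibration(points[a.analyte_id], a.calibration, a.analyte_id)
        blank_concs = [
            invert_calibration(curve, resp)[0]
            for resp in blank_responses.get(a.analyte_id, [])
        ]
        lod = loq = None
        if len(blank_concs) >= 2:
            lod, loq = lod_loq(blank_concs)
        calibration[a.analyte_id] = {
            "model_kind": curve.model_kind,
            "params": list(curve.params),
            "r_squared": curve.r_squared,
            "conc_range": list(curve.conc_range),
            "response_range": list(curve.response_range),
            "lod": lod,
            "loq": loq,
        }
    with open(workdir / "calibration.json", "w") as fh:
        json.dump(calibration, fh, indent=1, sort_keys=True)
    _log(workdir, "calibrate", [workdir / "calibration.json"])
    return calibration


def _load_curves(workdir: Path) -> dict:
    from .quantify import CalibrationCurve

    with open(workdir / "calibration.json") as fh:
        raw = json.load(fh)
    curves = {}
    for analyte, c in raw.items():
        curves[analyte] = CalibrationCurve(
            analyte_id=analyte,
            model_kind=c["model_kind"],
            params=tuple(c["params"]),
            r_squared=c["r_squared"],
            conc_range=tuple(c["conc_range"]),
            response_range=tuple(c["response_range"]),
            lod=c["lod"],
            loq=c["loq"],
        )
    return curves


# ---------------------------------------------------------------------------
# Stage 4: per-sample quantitation


def stage_quantify(config: StudyConfig, workdir) -> pd.DataFrame:
    workdir = Path(workdir)
    transitions = read_transitions(workdir / "transitions.tsv")
    curves = _load_curves(workdir)
    samples = read_samples(workdir / "samples.csv")
    rows = []
    for s in samples:
        run = read_run(workdir / s.run_path, sample_id=s.run_path)
        peaks = quantify_run(run, transitions, config.windows, config.baseline_mode)
        for analyte_id, peak in peaks.items():
            curve = curves[analyte_id]
            conc, extrapolated = invert_calibration(curve, peak.total_area)
            flags = []
            if extrapolated:
                flags.append("extrapolated")
            if curve.loq is not None and conc < curve.loq:
                flags.append("below_loq")
            if peak.clipped_negative:
                flags.append("clipped")
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "compartment": s.compartment,
                    "injection": s.injection,
                    "analyte_id": analyte_id,
                    "area": peak.total_area,
                    "conc": conc,
                    "flags": ";".join(flags),
                }
            )
    quant = pd.DataFrame(rows).sort_values(
        ["subject_id", "compartment", "injection", "analyte_id"]
    )
    quant.to_csv(workdir / "quant.csv", index=False, float_format="%.10g")
    _log(workdir, "quantify", [workdir / "quant.csv"], f"n_rows={len(quant)}")
    return quant


# ---------------------------------------------------------------------------
# Stage 5: survival report


def _fmt(x, nd):
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{round_half_up(float(x), nd):.{nd}f}"


def stage_survive(config: StudyConfig, workdir) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    workdir = Path(workdir)
    quant = pd.read_csv(workdir / "quant.csv", keep_default_na=False)
    quant["conc"] = quant["conc"].astype(float)
    samples = read_samples(workdir / "samples.csv")
    curves = _load_curves(workdir)
    design = config.study
    expected_sis = {
        (s.subject_id, s.compartment): s.spiked_sis
        for s in samples
        if s.spiked_sis is not None
    }
    lod = curves[design.target_id].lod

    quants: list[SampleQuant] = []
    cells = quant.groupby(["subject_id", "compartment"])
    for (subject, compartment), cell in cells:
        pivot = cell.pivot_table(index="injection", columns="analyte_id", values="conc")
        target = pivot[design.target_id]
        sis = pivot[design.sis_id]
        peg = pivot[design.peg_id]
        exp_sis = expected_sis.get((subject, compartment), design.truth.sis_spike)
        mean_target = float(target.mean())
        not_detected = lod is not None and mean_target <= lod
        quants.append(
            SampleQuant(
                subject_id=subject,
                compartment=compartment,
                replicate_target=tuple(target),
                replicate_sis=tuple(sis),
                expected_sis=exp_sis,
                measured_peg=float(peg.mean()),
                not_detected=not_detected,
            )
        )
    report = build_survival_report(quants)
    summaries, tests = compartment_summaries(report)

    # Presentation CSV rounded the way such tables are printed:
    # concentrations 2 dp, factors 3 dp, percentages 1 dp, half-up.
    with open(workdir / "survival.csv", "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            [
                "subject_id",
                "compartment",
                "conc_ng_ul",
                "dilution_factor",
                "normalized_conc_ng_ul",
                "error_ng_ul",
                "cv_pct",
                "survival_pct",
                "nd",
            ]
        )
        for _, row in report.iterrows():
            writer.writerow(
                [
                    row["subject_id"],
                    row["compartment"],
                    "N/D" if row["nd"] else _fmt(row["conc"], 2),
                    _fmt(row["dilution_factor"], 3),
                    _fmt(row["normalized_conc"], 2),
                    _fmt(row["error"], 3),
                    _fmt(row["cv_percent"], 2),
                    _fmt(row["survival_percent"], 1),
                    "yes" if row["nd"] else "no",
                ]
            )
    payload = {
        "per_sample": report.replace({np.nan: None}).to_dict(orient="records"),
        "compartment_summary": summaries.to_dict(orient="records"),
        "paired_t_vs_feed": {
            comp: {
                "t": res.t if np.isfinite(res.t) else None,
                "p": res.p,
                "df": res.df,
                "degenerate": res.degenerate,
            }
            for comp, res in tests.items()
        },
    }
    with open(workdir / "survival.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=False)
    _log(workdir, "survive", [workdir / "survival.csv", workdir / "survival.json"])
    return report, summaries, tests


def run_study(
    config: StudyConfig, workdir, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Execute the full workflow in ``workdir`` and return the survival report."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log = workdir / "study.log"
    if log.exists():
        log.unlink()
    stage_transitions(config, workdir)
    stage_simulate(config, workdir, seed)
    stage_calibrate(config, workdir)
    stage_quantify(config, workdir)
    return stage_survive(config, workdir)
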