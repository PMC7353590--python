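"""Synthetic PRM runs and digestion studies with known ground truth.

The generator emulates the signal structure of a targeted LC-MS assay for
intact-protein survival:

* each analyte elutes as a Gaussian peak at a configured retention time
  (surrogate peptide and its isotope-labeled twin co-eluting mid-gradient,
  the PEG-28 dilution marker later);
* the peptide response (integrated peak area) is proportional to
  concentration, while the PEG response saturates and is modeled as
  ``area = a*ln(conc) + b``;
* each transition carries a fixed fraction of its analyte's response;
* analytical losses are a per-analyte recovery multiplier applied to the
  measured response (the surrogate and its labeled standard share it, which
  is exactly what internal-standard normalization exploits);
* additive Gaussian noise (an absolute floor plus a component proportional
  to each trace's apex height) and a flat baseline, clipped at zero
  intensity.

A digestion study is generated from a :class:`StudyTruth`: per subject and
compartment, the marker concentration is the feed marker divided by the
true dilution factor, and the target concentration is the feed target
times the true survival fraction divided by the dilution factor.  The
labeled-standard spike is constant across samples because it is added
after digestion.  All randomness derives from one study seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .chromatograms import Chromatogram, PrmRun
from .io import TransitionRecord

__all__ = [
    "ResponseModel",
    "AnalyteSignal",
    "SignalModel",
    "CompartmentTruth",
    "StudyTruth",
    "simulate_run",
    "simulate_standard_series",
    "simulate_digestion_study",
    "default_truth",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ResponseModel:
    """Maps concentration (ng/µL) to total integrated response (area units).

    ``kind='linear'``: area = slope * conc; ``kind='log'``: area =
    a * ln(conc) + b for conc > 0.  Zero concentration yields zero response
    under both kinds (a blank).
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "log"):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.kind == "linear" and self.params[0] <= 0:
            raise ValueError("response slope must be positive")

    def area(self, conc: float) -> float:
        if conc < 0:
            raise ValueError(f"negative concentration {conc}")
        if conc == 0:
            return 0.0
        if self.kind == "linear":
            return self.params[0] * conc
        a, b = self.params
        return a * math.log(conc) + b


@dataclass(frozen=True)
class AnalyteSignal:
    """Elution and response behavior of one analyte."""

    analyte_id: str
    rt_min: float
    rt_sd_min: float
    response: ResponseModel
    fragment_factors: dict[str, float]  # label -> share of total response
    recovery: float = 1.0

    def __post_init__(self) -> None:
        if self.rt_sd_min <= 0:
            raise ValueError(f"{self.analyte_id}: peak width must be positive")
        if any(f < 0 for f in self.fragment_factors.values()):
            raise ValueError(f"{self.analyte_id}: fragment factors must be non-negative")
        total = sum(self.fragment_factors.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(
                f"{self.analyte_id}: fragment factors must sum to 1, got {total}"
            )
        if not 0 < self.recovery <= 1.5:
            raise ValueError(f"{self.analyte_id}: implausible recovery {self.recovery}")


@dataclass(frozen=True)
class SignalModel:
    """Everything needed to turn concentrations into chromatograms."""

    analytes: dict[str, AnalyteSignal]
    noise_sd: float = 0.0  # absolute noise floor, intensity units
    noise_rel: float = 0.0  # proportional component, fraction of trace apex
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.noise_rel < 0 or self.baseline < 0:
            raise ValueError("noise terms and baseline must be non-negative")


def _gaussian(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2) / (sd * _SQRT_2PI)


def simulate_run(
    concentrations: dict[str, float],
    model: SignalModel,
    transitions: list[TransitionRecord],
    t_start: float = 0.0,
    duration: float = 20.0,
    dt: float = 0.02,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> PrmRun:
    """Simulate one injected sample as a set of per-transition traces.

    Each trace is ``baseline + factor * recovery * response(conc) *
    Gaussian(rt, sd) + noise``, evaluated on a regular time grid and
    clipped at zero.  With ``rng=None`` a generator seeded from
    ``model.seed`` is used, so identical inputs give identical runs.
    """
    for analyte_id, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {analyte_id!r}")
        sig = model.analytes[analyte_id]
        if not t_start <= sig.rt_min <= t_start + duration:
            raise ValueError(
                f"{analyte_id}: retention time {sig.rt_min} outside simulated window"
            )
    if rng is None:
        rng = np.random.default_rng(model.seed)
    times = t_start + np.arange(round(duration / dt) + 1) * dt
    chroms: dict[str, Chromatogram] = {}
    for trans in transitions:
        conc = concentrations.get(trans.analyte_id)
        if conc is None:
            continue
        sig = model.analytes[trans.analyte_id]
        factor = sig.fragment_factors[trans.fragment_label]
        peak = factor * sig.recovery * sig.response.area(conc) * _gaussian(
            times, sig.rt_min, sig.rt_sd_min
        )
        signal = model.baseline + peak
        sd = model.noise_sd + model.noise_rel * float(peak.max(initial=0.0))
        if sd > 0:
            signal = signal + rng.normal(0.0, sd, size=times.size)
        tid = trans.transition_id
        chroms[tid] = Chromatogram(tid, times, np.clip(signal, 0.0, None))
    return PrmRun(chromatograms=chroms, sample_id=sample_id)


def simulate_standard_series(
    model: SignalModel,
    series: dict[str, list[float]],
    transitions: list[TransitionRecord],
    n_blanks: int = 3,
    **run_kwargs,
) -> tuple[list[tuple[dict[str, float], PrmRun]], list[PrmRun]]:
    """Simulate the calibration series plus blank injections.

    ``series`` maps analyte id to its concentration ladder; level ``i`` of
    the standard mixture carries the i-th concentration of every analyte
    (the ladders must therefore have equal length).  Returns the standard
    runs paired with their known concentrations, and the blank runs.
    """
    lengths = {len(v) for v in series.values()}
    if not series or lengths == {0}:
        raise ValueError("standard series must be non-empty")
    if len(lengths) != 1:
        raise ValueError("all analytes must have the same number of standard levels")
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    n_levels = lengths.pop()
    standards = []
    for i in range(n_levels):
        concs = {analyte: levels[i] for analyte, levels in series.items()}
        run = simulate_run(
            concs, model, transitions, rng=rng, sample_id=f"standard_L{i + 1}", **run_kwargs
        )
        standards.append((concs, run))
    blanks = [
        simulate_run(
            {analyte: 0.0 for analyte in series},
            model,
            transitions,
            rng=rng,
            sample_id=f"blank_{j + 1}",
            **run_kwargs,
        )
        for j in range(n_blanks)
    ]
    return standards, blanks


@dataclass(frozen=True)
class CompartmentTruth:
    """Ground truth for one subject × compartment cell."""

    subject_id: str
    compartment: str
    dilution_factor: float
    survival_fraction: float

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")
        if not 0 <= self.survival_fraction <= 1:
            raise ValueError("survival fraction must lie in [0, 1]")
        if self.compartment == "feed" and self.dilution_factor != 1:
            raise ValueError("feed dilution factor must be 1")


@dataclass(frozen=True)
class StudyTruth:
    """True concentrations and survival for a whole digestion study."""

    feed_target: dict[str, float]  # subject -> target conc in feed, ng/µL
    feed_peg: float  # marker conc in feed, ng/µL
    sis_spike: float  # labeled-standard spike in every sample, ng/µL
    cells: tuple[CompartmentTruth, ...]

    def __post_init__(self) -> None:
        subjects = set(self.feed_target)
        seen = set()
        for cell in self.cells:
            if cell.subject_id not in subjects:
                raise ValueError(f"unknown subject {cell.subject_id!r} in truth cells")
            seen.add((cell.subject_id, cell.compartment))
        for subject in subjects:
            if (subject, "feed") not in seen:
                raise ValueError(f"subject {subject!r} missing its feed row")

    def cell(self, subject_id: str, compartment: str) -> CompartmentTruth:
        for c in self.cells:
            if (c.subject_id, c.compartment) == (subject_id, compartment):
                return c
        raise KeyError((subject_id, compartment))

    def target_conc(self, subject_id: str, compartment: str) -> float:
        c = self.cell(subject_id, compartment)
        return self.feed_target[subject_id] * c.survival_fraction / c.dilution_factor

    def peg_conc(self, subject_id: str, compartment: str) -> float:
        return self.feed_peg / self.cell(subject_id, compartment).dilution_factor

    def to_json(self, path) -> None:
        payload = {
            "feed_target": self.feed_target,
            "feed_peg": self.feed_peg,
            "sis_spike": self.sis_spike,
            "cells": [
                {
                    "subject_id": c.subject_id,
                    "compartment": c.compartment,
                    "dilution_factor": c.dilution_factor,
                    "survival_fraction": c.survival_fraction,
                }
                for c in self.cells
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StudyTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            feed_target=payload["feed_target"],
            feed_peg=payload["feed_peg"],
            sis_spike=payload["sis_spike"],
            cells=tuple(CompartmentTruth(**c) for c in payload["cells"]),
        )


def default_truth() -> StudyTruth:
    """A four-subject study shaped like the published feeding experiment.

    Feed concentrations, dilution factors and survival fractions follow the
    reported measurements: survival near 0.9 in the stomach, ~0.1–0.4 in
    the upper intestine, and near zero in stool (one subject with none
    detected); stool dilution factors straddle 1 in both directions.
    """
    factors = {
        "infant1": {"gastric": 1.004, "intestinal": 1.14, "stool": 0.45},
        "infant2": {"gastric": 1.25, "intestinal": 1.51, "stool": 1.14},
        "infant3": {"gastric": 1.14, "intestinal": 1.30, "stool": 0.76},
        "infant4": {"gastric": 1.01, "intestinal": 1.14, "stool": 1.23},
    }
    survival = {
        "infant1": {"gastric": 0.8507, "intestinal": 0.3005, "stool": 0.0},
        "infant2": {"gastric": 0.7862, "intestinal": 0.1324, "stool": 0.1206},
        "infant3": {"gastric": 0.9962, "intestinal": 0.3857, "stool": 0.0513},
        "infant4": {"gastric": 0.9011, "intestinal": 0.3810, "stool": 0.0495},
    }
    feed_target = {
        "infant1": 38.10,
        "infant2": 18.66,
        "infant3": 18.51,
        "infant4": 16.17,
    }
    cells = []
    for subject in feed_target:
        cells.append(CompartmentTruth(subject, "feed", 1.0, 1.0))
        for compartment in ("gastric", "intestinal", "stool"):
            cells.append(
                CompartmentTruth(
                    subject,
                    compartment,
                    factors[subject][compartment],
                    survival[subject][compartment],
                )
            )
    return StudyTruth(
        feed_target=feed_target, feed_peg=0.1, sis_spike=0.5, cells=tuple(cells)
    )


def simulate_digestion_study(
    truth: StudyTruth,
    model: SignalModel,
    transitions: list[TransitionRecord],
    target_id: str = "target_peptide",
    sis_id: str = "sis_peptide",
    peg_id: str = "peg28",
    n_injections: int = 4,
    **run_kwargs,
) -> dict[tuple[str, str, int], PrmRun]:
    """Simulate every subject × compartment × injection run of a study.

    Per-run seeds are spawned deterministically from ``model.seed`` in a
    fixed (subject, compartment, injection) order.
    """
    if n_injections < 1:
        raise ValueError("need at least one injection per sample")
    rng = np.random.default_rng(np.random.SeedSequence((model.seed, 9173)))
    runs: dict[tuple[str, str, int], PrmRun] = {}
    for subject in truth.feed_target:
        for compartment in ("feed", "gastric", "intestinal", "stool"):
            concs = {
                target_id: truth.target_conc(subject, compartment),
                sis_id: truth.sis_spike,
                peg_id: truth.peg_conc(subject, compartment),
            }
            for inj in range(1, n_injections + 1):
                sample_id = f"{subject}_{compartment}_inj{inj}"
                runs[(subject, compartment, inj)] = simulate_run(
                    concs, model, transitions, rng=rng, sample_id=sample_id, **run_kwargs
                )
    return runs
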