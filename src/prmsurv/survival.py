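"""The two-stage normalization chain and study-level survival statistics.

Measured surrogate-peptide concentrations are corrected in two steps:

1. **Internal-standard (SIS) normalization** — each measurement is scaled
   by ``expected_sis / measured_sis`` to remove per-sample analytical
   losses (extraction, clean-up, injection), since the isotope-labeled
   standard experiences the same losses as the surrogate peptide.
2. **Dilution normalization** — a non-digestible, non-absorbable marker
   (PEG-28) co-fed with the target tracks dilution by digestive
   secretions or concentration by water absorption.  The dilution factor
   is ``marker_feed / marker_sample`` and the corrected concentration is
   ``conc * factor``.

Percent survival in a compartment is the dilution-normalized target
concentration divided by the feed concentration, × 100.  Study summaries
report mean ± SE (sd/√n) per compartment and paired t-tests against feed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import COMPARTMENTS

__all__ = [
    "SampleQuant",
    "Summary",
    "PairedTResult",
    "sis_normalize",
    "recovery_percent",
    "dilution_factor",
    "dilution_normalize",
    "survival_percent",
    "summarize",
    "paired_t",
    "build_survival_report",
    "compartment_summaries",
]


def sis_normalize(measured: float, measured_sis: float, expected_sis: float) -> float:
    """Correct a measurement by the recovery of the isotope-labeled standard."""
    if measured_sis <= 0:
        raise ValueError(f"measured SIS concentration must be positive, got {measured_sis}")
    if expected_sis <= 0:
        raise ValueError(f"expected SIS concentration must be positive, got {expected_sis}")
    return measured * expected_sis / measured_sis

def recovery_percent(measured: float, spiked: float) -> float:
    """Measured / spiked × 100."""
    if spiked <= 0:
        raise ValueError(f"spiked amount must be positive, got {spiked}")
    return measured / spiked * 100.0


def dilution_factor(peg_feed: float, peg_sample: float) -> float:
    """Feed-to-sample ratio of the dilution marker (>1 = diluted, <1 = concentrated)."""
    if peg_feed <= 0 or peg_sample <= 0:
        raise ValueError("marker concentrations must be positive")
    return peg_feed / peg_sample


def dilution_normalize(conc: float, factor: float) -> float:
    """Scale a concentration back to feed terms by the dilution factor."""
    if factor <= 0:
        raise ValueError(f"dilution factor must be positive, got {factor}")
    return conc * factor


def survival_percent(normalized_conc: float, feed_conc: float) -> float:
    """Dilution-normalized concentration as a percentage of the feed."""
    if feed_conc <= 0:
        raise ValueError(f"feed concentration must be positive, got {feed_conc}")
    return normalized_conc / feed_conc * 100.0


@dataclass(frozen=True)
class Summary:
    mean: float
    error: float | None  # sd / sqrt(n)
    cv_percent: float | None  # sd / mean * 100; None when mean == 0
    n: int


def summarize(values: list[float]) -> Summary:
    """Mean, standard error and CV of replicate values (sample sd, n-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(arr.mean())
    if arr.size < 2:
        return Summary(mean=mean, error=None, cv_percent=None, n=1)
    sd = float(arr.std(ddof=1))
    cv = sd / mean * 100.0 if mean != 0 else None
    return Summary(mean=mean, error=sd / math.sqrt(arr.size), cv_percent=cv, n=arr.size)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # all differences equal and nonzero (sd = 0)


def paired_t(reference: list[float], compartment: list[float]) -> PairedTResult:
    """Classical paired Student's t-test on subject-matched values."""
    a = np.asarray(reference, dtype=float)
    b = np.asarray(compartment, dtype=float)
    if a.size != b.size:
        raise ValueError("paired t-test requires equally long, matched vectors")
    if a.size < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    diffs = b - a
    if float(diffs.std(ddof=1)) == 0.0:
        if float(diffs.mean()) == 0.0:
            return PairedTResult(t=0.0, p=1.0, df=a.size - 1)
        return PairedTResult(
            t=math.copysign(math.inf, float(diffs.mean())),
            p=0.0,
            df=a.size - 1,
            degenerate=True,
        )
    res = stats.ttest_rel(b, a)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue), df=a.size - 1)


@dataclass(frozen=True)
class SampleQuant:
    """Per subject × compartment measurements entering the normalization chain.

    ``replicate_target`` holds the raw per-injection target concentrations;
    ``replicate_sis`` the matching per-injection SIS concentrations.
    """

    subject_id: str
    compartment: str
    replicate_target: tuple[float, ...]
    replicate_sis: tuple[float, ...]
    expected_sis: float
    measured_peg: float
    not_detected: bool = False

    def __post_init__(self) -> None:
        if len(self.replicate_target) < 1:
            raise ValueError("need at least one replicate measurement")
        if len(self.replicate_target) != len(self.replicate_sis):
            raise ValueError("target and SIS replicate counts differ")
        if self.expected_sis <= 0:
            raise ValueError("expected SIS must be positive")

    def sis_normalized(self) -> list[float]:
        return [
            sis_normalize(t, s, self.expected_sis)
            for t, s in zip(self.replicate_target, self.replicate_sis)
        ]


def build_survival_report(quants: list[SampleQuant]) -> pd.DataFrame:
    """Table-style survival report: one row per subject × compartment.

    Columns: SIS-normalized mean concentration, dilution factor,
    dilution-normalized concentration, SE and CV over the replicate
    injections, percent survival relative to feed, and an ``nd`` flag for
    samples in which the target was not detected (reported as 0% survival).
    """
    by_cell = {(q.subject_id, q.compartment): q for q in quants}
    subjects = sorted({q.subject_id for q in quants})
    for subject in subjects:
        if (subject, "feed") not in by_cell:
            raise ValueError(f"subject {subject!r} has no feed measurement")
    rows = []
    for subject in subjects:
        feed = by_cell[(subject, "feed")]
        feed_conc = summarize(feed.sis_normalized()).mean
        for compartment in COMPARTMENTS:
            q = by_cell.get((subject, compartment))
            if q is None:
                continue
            factor = (
                1.0
                if compartment == "feed"
                else dilution_factor(feed.measured_peg, q.measured_peg)
            )
            if q.not_detected:
                rows.append(
                    {
                        "subject_id": subject,
                        "compartment": compartment,
                        "conc": np.nan,
                        "dilution_factor": factor,
                        "normalized_conc": np.nan,
                        "error": np.nan,
                        "cv_percent": np.nan,
                        "survival_percent": 0.0,
                        "nd": True,
                    }
                )
                continue
            normalized_reps = [
                dilution_normalize(c, factor) for c in q.sis_normalized()
            ]
            summ = summarize(normalized_reps)
            conc = summarize(q.sis_normalized()).mean
            rows.append(
                {
                    "subject_id": subject,
                    "compartment": compartment,
                    "conc": conc,
                    "dilution_factor": factor,
                    "normalized_conc": summ.mean,
                    "error": summ.error if summ.error is not None else np.nan,
                    "cv_percent": summ.cv_percent
                    if summ.cv_percent is not None
                    else np.nan,
                    "survival_percent": survival_percent(summ.mean, feed_conc),
                    "nd": False,
                }
            )
    return pd.DataFrame(rows)


def compartment_summaries(
    report: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, PairedTResult]]:
    """Study-level mean survival ± SE per compartment, and paired tests vs feed.

    Not-detected samples contribute 0% survival.  SE uses n = number of
    subjects.  The paired tests compare dilution-normalized concentrations
    (not-detected treated as 0) between feed and each digestive compartment.
    """
    summaries = []
    tests: dict[str, PairedTResult] = {}
    feed = report[report["compartment"] == "feed"].set_index("subject_id")
    for compartment in COMPARTMENTS:
        sub = report[report["compartment"] == compartment]
        if sub.empty:
            continue
        summ = summarize(list(sub["survival_percent"]))
        summaries.append(
            {
                "compartment": compartment,
                "mean_survival_percent": summ.mean,
                "se_survival_percent": summ.error,
                "n_subjects": summ.n,
            }
        )
        if compartment != "feed":
            sub = sub.set_index("subject_id")
            subjects = [s for s in feed.index if s in sub.index]
            ref = [feed.loc[s, "normalized_conc"] for s in subjects]
            comp = [
                0.0 if sub.loc[s, "nd"] else sub.loc[s, "normalized_conc"]
                for s in subjects
            ]
            tests[compartment] = paired_t(ref, comp)
    return pd.DataFrame(summaries), tests


def plot_survival(report: pd.DataFrame, path) -> None:
    """Bar chart of per-subject percent survival across compartments."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subjects = sorted(report["subject_id"].unique())
    fig, axes = plt.subplots(1, len(subjects), figsize=(3.2 * len(subjects), 3), sharey=True)
    if len(subjects) == 1:
        axes = [axes]
    for ax, subject in zip(axes, subjects):
        sub = report[report["subject_id"] == subject].set_index("compartment")
        comps = [c for c in COMPARTMENTS if c in sub.index]
        ax.bar(comps, [sub.loc[c, "survival_percent"] for c in comps], color="0.85", edgecolor="k")
        ax.set_title(subject)
        ax.set_ylabel("% survival")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
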