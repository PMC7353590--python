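"""Bundled small datasets: fixture protein database, candidate evidence, and
the published per-subject survival table.

``reference_proteins.synthetic.fasta`` is a synthetic stand-in for the
background database a uniqueness checker would query: two real-looking
human IgG heavy-constant fragments plus three short synthetic carrier
sequences that embed the three antibody-variable-region tryptic peptides
known to occur elsewhere in the human proteome (under their UniProt-style
ids).  It exists so the uniqueness classification of the ten candidate
peptides is reproducible offline.

``candidate_evidence.tsv`` holds the detection matrix of the ten
variable-region tryptic peptides over four replicate injections at six
standard concentrations (2–25 ng/µL).  The ``mean_abundance`` column is
synthetic (the source reports only the qualitative ordering of peak
abundances); it preserves that ordering.

``published_study_values.csv`` holds the reported per-subject
concentrations (already internal-standard-normalized and averaged over
four injections), dilution factors, dilution-normalized concentrations,
standard errors and CVs for the four-infant feeding study, with ``N/D``
marking the one stool sample in which the target was not detected.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .digest import CandidateEvidence
from .io import read_fasta

__all__ = [
    "CANDIDATE_CONCENTRATIONS",
    "load_reference_proteins",
    "load_candidate_evidence",
    "load_published_study",
]

#: Standard concentrations (ng/µL) of the candidate detection matrix.
CANDIDATE_CONCENTRATIONS = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0)


def _data_path(name: str) -> str:
    return str(resources.files("prmsurv").joinpath("data", name))


def load_reference_proteins() -> dict[str, str]:
    """The bundled synthetic background protein database."""
    return read_fasta(_data_path("reference_proteins.synthetic.fasta"))


def load_candidate_evidence(
    database: dict[str, str] | None = None,
) -> list[CandidateEvidence]:
    """Candidate surrogate peptides with detection counts and uniqueness.

    Uniqueness is computed on the fly against ``database`` (default: the
    bundled fixture database) by substring containment.
    """
    from .digest import uniqueness_check

    if database is None:
        database = load_reference_proteins()
    df = pd.read_csv(_data_path("candidate_evidence.tsv"), sep="\t")
    candidates = []
    for _, row in df.iterrows():
        detected = {
            conc: int(row[f"det_{int(conc)}"]) for conc in CANDIDATE_CONCENTRATIONS
        }
        candidates.append(
            CandidateEvidence(
                sequence=row["sequence"],
                modification=None if pd.isna(row["modification"]) else row["modification"],
                missed_cleavages=int(row["missed_cleavages"]),
                detected_at=detected,
                is_unique=uniqueness_check(row["sequence"], database).is_unique,
                mean_peak_abundance=float(row["mean_abundance"]),
            )
        )
    return candidates


def load_published_study() -> pd.DataFrame:
    """The reported four-infant study table as a tidy DataFrame.

    Columns: ``subject_id, compartment, conc, dilution_factor,
    normalized_conc, error, cv_percent, nd`` — concentrations in ng/µL,
    ``nd`` flags the not-detected cell (its concentrations are NaN).
    """
    df = pd.read_csv(_data_path("published_study_values.csv"))
    nd = df["conc_ng_ul"].astype(str).str.strip() == "N/D"
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "compartment": df["compartment"],
            "conc": pd.to_numeric(df["conc_ng_ul"], errors="coerce"),
            "dilution_factor": df["dilution_factor"].astype(float),
            "normalized_conc": pd.to_numeric(df["normalized_conc_ng_ul"], errors="coerce"),
            "error": pd.to_numeric(df["error_ng_ul"], errors="coerce"),
            "cv_percent": pd.to_numeric(df["cv_pct"], errors="coerce"),
            "nd": nd,
        }
    )
    return out


def published_survival(report: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percent survival per subject × compartment from the published table.

    Survival = dilution-normalized concentration ÷ feed concentration × 100;
    the not-detected cell contributes 0%.
    """
    df = load_published_study() if report is None else report
    feed = df[df["compartment"] == "feed"].set_index("subject_id")["normalized_conc"]
    surv = []
    for _, row in df.iterrows():
        if row["nd"]:
            surv.append(0.0)
        else:
            surv.append(row["normalized_conc"] / feed[row["subject_id"]] * 100.0)
    out = df.copy()
    out["survival_percent"] = np.asarray(surv)
    return out
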