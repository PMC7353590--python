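"""In-silico tryptic digestion, peptide uniqueness, and surrogate ranking.

Quantifying an intact protein by a surrogate tryptic peptide requires
(1) enumerating the peptides trypsin can produce, (2) checking that a
candidate occurs in no other protein of the relevant background database,
and (3) ranking candidates by the selection criteria used in targeted
proteomics: detected at every calibration level, unique, unmodified, no
missed cleavages, and highest chromatographic peak abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DigestPeptide",
    "UniquenessResult",
    "CandidateEvidence",
    "RankedCandidate",
    "tryptic_digest",
    "uniqueness_check",
    "select_surrogate",
]

_CLEAVE_AFTER = frozenset("KR")


@dataclass(frozen=True)
class DigestPeptide:
    """A fully tryptic peptide with its coordinates in the parent protein."""

    sequence: str
    parent_id: str
    start: int  # 0-based
    end: int  # half-open
    missed_cleavages: int


def tryptic_digest(
    protein: str,
    max_missed: int = 2,
    parent_id: str = "",
    keep_kp_intact: bool = False,
) -> list[DigestPeptide]:
    """Fully specific tryptic peptides with up to ``max_missed`` missed cleavages.

    Cleavage occurs after every K or R; with ``keep_kp_intact`` the common
    variant that leaves K|P and R|P bonds uncut is applied instead.
    Output is ordered by start position, then peptide length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    if not protein:
        raise ValueError("protein sequence must be non-empty")
    cuts = [0]
    for i, res in enumerate(protein[:-1]):
        if res in _CLEAVE_AFTER and not (keep_kp_intact and protein[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(protein))

    peptides = []
    n_frag = len(cuts) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + 2 + max_missed, n_frag + 1)):
            start, end = cuts[i], cuts[j]
            peptides.append(
                DigestPeptide(
                    sequence=protein[start:end],
                    parent_id=parent_id,
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end - p.start))
    return peptides


@dataclass(frozen=True)
class UniquenessResult:
    peptide: str
    status: str  # "unique" | "not_unique" | "too_short"
    matches: tuple[str, ...] = ()

    @property
    def is_unique(self) -> bool:
        return self.status == "unique"


def uniqueness_check(
    peptide: str,
    database: dict[str, str],
    min_length: int = 6,
    il_equivalent: bool = False,
) -> UniquenessResult:
    """Substring-containment uniqueness of a peptide against a protein database.

    A peptide is unique iff it occurs in no database protein.  Peptides
    shorter than ``min_length`` (default six residues, the usual floor for
    uniqueness checkers) get status ``too_short`` and are never unique.
    With ``il_equivalent`` the isobaric residues I and L are interchangeable.
    """
    if not database:
        raise ValueError("protein database must be non-empty")
    if len(peptide) < min_length:
        return UniquenessResult(peptide, "too_short")
    needle = peptide.replace("I", "L") if il_equivalent else peptide
    matches = []
    for prot_id, seq in database.items():
        haystack = seq.replace("I", "L") if il_equivalent else seq
        if needle in haystack:
            matches.append(prot_id)
    if matches:
        return UniquenessResult(peptide, "not_unique", tuple(sorted(matches)))
    return UniquenessResult(peptide, "unique")


@dataclass(frozen=True)
class CandidateEvidence:
    """Detection evidence for one surrogate-peptide candidate.

    ``detected_at`` maps each standard concentration (ng/µL) to the number
    of replicate injections (0..n_replicates) in which the peptide was seen.
    """

    sequence: str
    modification: str | None
    missed_cleavages: int
    detected_at: dict[float, int]
    is_unique: bool
    mean_peak_abundance: float
    n_replicates: int = 4

    def __post_init__(self) -> None:
        for conc, count in self.detected_at.items():
            if not 0 <= count <= self.n_replicates:
                raise ValueError(
                    f"{self.sequence}: detection count {count} at {conc} ng/µL "
                    f"outside 0..{self.n_replicates}"
                )


@dataclass(frozen=True)
class RankedCandidate:
    candidate: CandidateEvidence
    flags: dict[str, bool] = field(compare=False)
    rank: int = 0

    @property
    def passes(self) -> bool:
        return all(self.flags.values())

    @property
    def reasons(self) -> tuple[str, ...]:
        return tuple(name for name, ok in self.flags.items() if not ok)


def _sort_key(cand: CandidateEvidence, flags: dict[str, bool]):
    n_fail = sum(not ok for ok in flags.values())
    # Passers (n_fail == 0) first; within a tier: highest abundance, then
    # shorter sequence, then lexicographic (a decided, documented tie-break).
    return (
        0 if n_fail == 0 else 1,
        n_fail,
        -cand.mean_peak_abundance,
        len(cand.sequence),
        cand.sequence,
    )


def select_surrogate(
    candidates: list[CandidateEvidence],
    concentrations: list[float],
) -> list[RankedCandidate]:
    """Rank surrogate candidates by the standard hard criteria, then abundance.

    Hard criteria: unique in the background database, unmodified, zero
    missed cleavages, and detected (count >= 1) at every concentration of
    the standard series.  Any failure demotes a candidate below all
    passers; the returned list is a total order with per-criterion flags.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    for cand in candidates:
        missing = [c for c in concentrations if c not in cand.detected_at]
        if missing:
            raise ValueError(
                f"{cand.sequence}: no detection evidence at {missing} ng/µL"
            )
    scored = []
    for cand in candidates:
        flags = {
            "unique": cand.is_unique,
            "unmodified": cand.modification is None,
            "no_missed_cleavage": cand.missed_cleavages == 0,
            "detected_at_all_levels": all(
                cand.detected_at[c] >= 1 for c in concentrations
            ),
        }
        scored.append((cand, flags))
    scored.sort(key=lambda cf: _sort_key(*cf))
    return [
        RankedCandidate(candidate=cand, flags=flags, rank=i)
        for i, (cand, flags) in enumerate(scored)
    ]
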