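"""Tryptic digestion, uniqueness checking and surrogate ranking."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from prmsurv.datasets import CANDIDATE_CONCENTRATIONS, load_candidate_evidence
from prmsurv.digest import (
    CandidateEvidence,
    select_surrogate,
    tryptic_digest,
    uniqueness_check,
)

PROTEINS = st.text(alphabet=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=1, max_size=30)


def brute_force_tryptic(protein: str, max_missed: int) -> set[tuple[int, int]]:
    """Every substring that is a fully specific tryptic peptide."""
    cuts = {0, len(protein)}
    for i, res in enumerate(protein[:-1]):
        if res in "KR":
            cuts.add(i + 1)
    out = set()
    for start, end in itertools.combinations(sorted(cuts), 2):
        internal = sum(
            1 for i in range(start, end - 1) if protein[i] in "KR"
        )
        if internal <= max_missed:
            out.add((start, end))
    return out


class TestTrypticDigest:
    def test_single_cleavage_site(self):
        seqs = {p.sequence for p in tryptic_digest("LLIYDTSKLASGVPSR", max_missed=0)}
        assert seqs == {"LLIYDTSK", "LASGVPSR"}

    def test_missed_cleavage_adds_spanning_peptide(self):
        seqs = {p.sequence for p in tryptic_digest("LLIYDTSKLASGVPSR", max_missed=1)}
        assert "LLIYDTSKLASGVPSR" in seqs

    def test_no_cleavage_sites_yields_whole_protein(self):
        peptides = tryptic_digest("MNQPW", max_missed=2)
        assert len(peptides) == 1 and peptides[0].sequence == "MNQPW"

    def test_keep_kp_intact_option(self):
        with_rule = {p.sequence for p in tryptic_digest("AKPGGR", max_missed=0, keep_kp_intact=True)}
        without = {p.sequence for p in tryptic_digest("AKPGGR", max_missed=0)}
        assert with_rule == {"AKPGGR"}
        assert without == {"AK", "PGGR"}

    def test_negative_max_missed_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("GG", max_missed=-1)

    @given(PROTEINS, st.integers(min_value=0, max_value=3))
    def test_matches_brute_force_enumeration(self, protein, max_missed):
        got = {(p.start, p.end) for p in tryptic_digest(protein, max_missed)}
        assert got == brute_force_tryptic(protein, max_missed)

    @given(PROTEINS)
    def test_zero_missed_peptides_tile_the_protein(self, protein):
        parts = [p.sequence for p in tryptic_digest(protein, max_missed=0)]
        assert "".join(parts) == protein

    @given(PROTEINS, st.integers(min_value=0, max_value=3))
    def test_missed_cleavage_counts_recount(self, protein, max_missed):
        for p in tryptic_digest(protein, max_missed):
            internal = sum(1 for res in p.sequence[:-1] if res in "KR")
            assert p.missed_cleavages == internal
            assert protein[p.start : p.end] == p.sequence


class TestUniqueness:
    def test_surrogate_is_unique(self, reference_db):
        assert uniqueness_check("LLIYDTSK", reference_db).is_unique

    def test_shared_peptide_names_its_carrier(self, reference_db):
        res = uniqueness_check("DIQMTQSPSTLSASVGDR", reference_db)
        assert res.status == "not_unique"
        assert res.matches == ("P01602",)

    def test_short_peptide_is_ineligible(self, reference_db):
        res = uniqueness_check("LLIYD", reference_db)
        assert res.status == "too_short" and not res.is_unique

    def test_il_equivalence_flag(self):
        db = {"prot": "AAILGGK"}
        assert uniqueness_check("AAILGG", db, il_equivalent=False).status == "not_unique"
        assert uniqueness_check("AALIGG", db, il_equivalent=False).status == "unique"
        assert uniqueness_check("AALIGG", db, il_equivalent=True).status == "not_unique"

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            uniqueness_check("LLIYDTSK", {})

    @given(st.data())
    def test_matches_naive_substring_scan(self, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        db = {
            f"p{i}": "".join(rng.choice("ACDGK") for _ in range(rng.randint(6, 25)))
            for i in range(5)
        }
        peptide = "".join(rng.choice("ACDGK") for _ in range(6))
        naive = sorted(
            pid
            for pid, seq in db.items()
            if any(seq[i : i + 6] == peptide for i in range(len(seq) - 5))
        )
        res = uniqueness_check(peptide, db)
        assert list(res.matches) == naive
        assert res.is_unique == (not naive)


def _candidate(seq, abundance, modification=None, missed=0, unique=True, counts=4):
    return CandidateEvidence(
        sequence=seq,
        modification=modification,
        missed_cleavages=missed,
        detected_at={c: counts for c in CANDIDATE_CONCENTRATIONS},
        is_unique=unique,
        mean_peak_abundance=abundance,
    )


class TestSurrogateSelection:
    def test_published_candidates_rank_surrogate_first(self):
        candidates = load_candidate_evidence()
        ranked = select_surrogate(candidates, list(CANDIDATE_CONCENTRATIONS))
        assert ranked[0].candidate.sequence == "LLIYDTSK"
        assert ranked[0].passes
        # The runner-up on detection was disqualified by its fixed modification.
        vtn = next(r for r in ranked if r.candidate.sequence == "VTNMDPADTATYYCAR")
        assert not vtn.passes and "unmodified" in vtn.reasons
        # Only one candidate satisfies every hard criterion.
        assert sum(r.passes for r in ranked) == 1

    def test_single_clean_candidate_passes(self):
        ranked = select_surrogate([_candidate("AAAGGK", 10.0)], list(CANDIDATE_CONCENTRATIONS))
        assert ranked[0].passes and ranked[0].reasons == ()

    def test_failers_rank_below_all_passers(self):
        weak_passer = _candidate("AAAGGK", 1.0)
        strong_failer = _candidate("CCCGGK", 1e9, unique=False)
        ranked = select_surrogate([strong_failer, weak_passer], list(CANDIDATE_CONCENTRATIONS))
        assert ranked[0].candidate.sequence == "AAAGGK"

    def test_tie_break_shorter_then_lexicographic(self):
        a = _candidate("GGKAAK", 5.0)
        b = _candidate("GGK", 5.0)
        c = _candidate("AAK", 5.0)
        ranked = select_surrogate([a, b, c], list(CANDIDATE_CONCENTRATIONS))
        assert [r.candidate.sequence for r in ranked] == ["AAK", "GGK", "GGKAAK"]

    def test_order_is_total_and_shuffle_invariant(self):
        candidates = load_candidate_evidence()
        baseline = [r.candidate.sequence for r in select_surrogate(candidates, list(CANDIDATE_CONCENTRATIONS))]
        rng = random.Random(7)
        for _ in range(5):
            shuffled = list(candidates)
            rng.shuffle(shuffled)
            order = [r.candidate.sequence for r in select_surrogate(shuffled, list(CANDIDATE_CONCENTRATIONS))]
            assert order == baseline

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            select_surrogate([], list(CANDIDATE_CONCENTRATIONS))

    def test_detection_gap_rejected(self):
        cand = _candidate("AAAGGK", 1.0)
        with pytest.raises(ValueError, match="no detection evidence"):
            select_surrogate([cand], [99.0])


def test_published_uniqueness_column_reproduced(reference_db):
    """The three shared peptides hit their carriers; the other seven are unique."""
    expected_not_unique = {
        "DIQMTQSPSTLSASVGDR": ("P01602",),
        "SRLTISK": ("A0A0B4J1V2",),
        "NQVVLK": ("Q07020",),
    }
    for cand in load_candidate_evidence(reference_db):
        res = uniqueness_check(cand.sequence, reference_db)
        if cand.sequence in expected_not_unique:
            assert res.matches == expected_not_unique[cand.sequence]
        else:
            assert res.is_unique, cand.sequence
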