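"""Pick the surrogate peptide that will stand in for the intact antibody.

Digests a variable-region fragment in silico, checks each candidate's
uniqueness against the bundled background database, and ranks the ten
observed candidates by the hard criteria (unique, unmodified, fully
cleaved, detected at every standard level) and then by peak abundance.
The winner is the peptide whose measured amount will represent the
intact protein in every digestive sample.
"""

from prmsurv.datasets import (
    CANDIDATE_CONCENTRATIONS,
    load_candidate_evidence,
    load_reference_proteins,
)
from prmsurv.digest import select_surrogate, tryptic_digest, uniqueness_check

# In-silico digestion of a light-chain fragment containing the surrogate.
fragment = "DIQMTQSPSTLSASVGDRLLIYDTSKLASGVPSR"
peptides = tryptic_digest(fragment, max_missed=1, parent_id="VL_fragment")
print("tryptic peptides (<=1 missed cleavage):")
for p in peptides:
    print(f"  {p.sequence:<36} missed={p.missed_cleavages}")

database = load_reference_proteins()
print("\nuniqueness against the background database:")
for p in peptides:
    res = uniqueness_check(p.sequence, database)
    extra = f" matches={list(res.matches)}" if res.matches else ""
    print(f"  {p.sequence:<36} {res.status}{extra}")

ranked = select_surrogate(load_candidate_evidence(), list(CANDIDATE_CONCENTRATIONS))
print("\ncandidate ranking (detection matrix + abundance):")
for r in ranked:
    verdict = "PASS" if r.passes else "fail: " + ", ".join(r.reasons)
    print(f"  {r.rank + 1:>2}. {r.candidate.sequence:<22} {verdict}")
print(f"\nselected surrogate: {ranked[0].candidate.sequence}")
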