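"""Build the PRM transition list for the default assay and print it.

The assay targets the surrogate peptide LLIYDTSK (doubly charged), its
13C6,15N2-labeled internal standard, and the PEG 28-mer dilution marker
(triply charged).  Fragment m/z values are the singly protonated y2-y7
ions for the peptides and the DP7-DP17 oligomer ladder (minus DP9) for
PEG; every heavy y-ion sits exactly 8.0142 Da above its light twin.
"""

from prmsurv.pipeline import build_transitions, default_config

transitions = build_transitions(default_config())
print(f"{'analyte':<16}{'fragment':<10}{'precursor m/z':<15}{'fragment m/z':<14}activation")
for t in transitions:
    print(
        f"{t.analyte_id:<16}{t.fragment_label:<10}{t.precursor_mz:<15.4f}"
        f"{t.fragment_mz:<14.4f}{t.activation}"
    )
print(f"\n{len(transitions)} fragment transitions across 3 precursors.")
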