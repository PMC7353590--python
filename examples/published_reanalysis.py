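"""Recompute the published four-infant study numbers from their printed inputs.

The bundled table holds, per subject and compartment, the internal-
standard-normalized concentration and the PEG-28 dilution factor.
Multiplying them reproduces the normalized-concentration column;
dividing by each subject's feed value gives percent survival, and
averaging over subjects gives the per-compartment summary.
"""

from prmsurv.datasets import load_published_study, published_survival
from prmsurv.survival import dilution_normalize, summarize

df = load_published_study()
print("normalized concentration recomputed as conc x dilution factor:")
for _, row in df[df["compartment"] != "feed"].iterrows():
    if row["nd"]:
        print(f"  {row['subject_id']:<9}{row['compartment']:<12}N/D")
        continue
    product = dilution_normalize(row["conc"], row["dilution_factor"])
    print(
        f"  {row['subject_id']:<9}{row['compartment']:<12}"
        f"{row['conc']:6.2f} x {row['dilution_factor']:<6.3g}= {product:6.2f}"
        f"   (printed {row['normalized_conc']:.2f})"
    )

surv = published_survival()
print("\nper-compartment survival (mean +/- SE over the four subjects):")
for compartment in ("gastric", "intestinal", "stool"):
    values = list(surv[surv["compartment"] == compartment]["survival_percent"])
    summ = summarize(values)
    print(f"  {compartment:<12}{summ.mean:5.1f}% +/- {summ.error:.1f}%")
print(
    "\nGastric survival is high (~88%), intestinal ~30%, and little intact\n"
    "target reaches stool; the N/D stool sample enters the mean as 0%."
)
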