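"""Run a complete synthetic digestion study end to end.

Four subjects are 'fed' a target protein plus the PEG-28 marker; gastric,
intestinal and stool samples are simulated with known survival fractions
and dilution factors, measured in quadruplicate, calibrated, quantified,
normalized (internal standard, then dilution factor) and summarized.
Because the ground truth is known, the printed survival can be compared
with the generating values directly.
"""

import tempfile

from prmsurv.pipeline import default_config, run_study

config = default_config(seed=2026)
with tempfile.TemporaryDirectory() as workdir:
    report, summaries, tests = run_study(config, workdir)

truth = config.study.truth
print("per-sample survival (measured vs generating truth):")
for _, row in report.iterrows():
    cell = truth.cell(row["subject_id"], row["compartment"])
    flag = " (N/D)" if row["nd"] else ""
    print(
        f"  {row['subject_id']:<9}{row['compartment']:<12}"
        f"measured {row['survival_percent']:6.1f}%   truth {100 * cell.survival_fraction:6.1f}%{flag}"
    )

print("\ncompartment means (+/- SE over subjects):")
for _, row in summaries.iterrows():
    print(
        f"  {row['compartment']:<12}{row['mean_survival_percent']:6.1f}% "
        f"+/- {row['se_survival_percent']:.1f}%"
    )

print("\npaired t-tests of normalized concentration vs feed:")
for compartment, res in tests.items():
    print(f"  {compartment:<12}t = {res.t:7.3f}, p = {res.p:.4f}")
print(
    "\nThe measured survivals track the generating truth to within the 1%\n"
    "simulated measurement noise; dilution by digestive fluid is corrected\n"
    "by the PEG-28 factor, so survival reflects degradation only."
)
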