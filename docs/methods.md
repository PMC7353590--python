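# Methods

## The measurement model

The quantity of interest is the fraction of an orally fed target protein
that is still intact when a digestive sample is drawn. The chain of
inference is:

    intact protein  →  unique surrogate tryptic peptide  →  summed PRM
    transition area  →  concentration (calibration)  →  SIS-corrected
    concentration  →  dilution-normalized concentration  →  % survival

Two multiplicative corrections make the last steps valid:

* **Internal-standard (SIS) correction.** A stable-isotope-labeled copy of
  the surrogate peptide is spiked at a known amount after proteolysis and
  experiences the same extraction and ionization losses as the light
  peptide. Scaling by `expected / measured` SIS removes per-injection
  analytical variation. Because both peptides share one recovery factor,
  the correction is exact for any loss that acts multiplicatively.
* **Dilution correction.** A non-digestible, non-absorbable marker
  (the PEG 28-mer) is co-fed with the target; any change in its
  concentration must be dilution by secretions or concentration by water
  absorption, not chemistry. The dilution factor `feed / sample` applied
  to the target concentration converts it back to feed terms. The same
  cancellation argument applies: the marker's own analytical recovery
  divides out of the ratio.

The two corrections commute (both are multiplicative); they are applied
SIS-first to mirror the analytical-then-physiological narrative of the
workflow. Percent survival is the dilution-normalized concentration over
the feed concentration × 100; a feed row has factor 1 and survival 100%
by construction.

## Mass scale

Monoisotopic residue masses to six decimal places; water 18.010565 Da,
ethylene-oxide repeat 44.026215 Da, proton 1.007276 Da (charging uses the
proton mass, not the hydrogen atom mass). Modification deltas:
carbamidomethyl +57.021464, oxidation +15.994915, phosphorylation
+79.966331, acetylation +42.010565, and the ¹³C₆,¹⁵N₂ lysine label
+8.014199 Da. Only y-ions are implemented: they are the quantifier ions
of tryptic peptides in practice and are the fragments that retain a
C-terminal-lysine label, which is what makes light/heavy pairs cleanly
separable (a constant 8.0142 Da shift across the whole series). b/a/c/x/z
ions, neutral losses and isotope envelopes are out of scope. Reported
m/z values are rounded half-up to 4 decimals (3 for the triply charged
PEG precursor), matching instrument-software print conventions. One
reference value (the DP14 PEG fragment) appears in the literature as
635.3848 where the computed value rounds to 635.3849; the tests treat
that single value as a print truncation and compare it at 1.1e-4.

## Digestion and surrogate selection

Cleavage is strictly after K/R (a keep-K|P/R|P option exists but is off
by default, mirroring the search-engine setting the workflow emulates),
fully specific termini, up to a configurable number of missed cleavages
(default 2). Uniqueness is substring containment against a protein
database — the behavior of web uniqueness checkers — with a six-residue
eligibility floor and optional I/L equivalence (off by default).
Selection applies four hard criteria (unique, unmodified, zero missed
cleavages, detected at every standard level) and ranks survivors by mean
peak abundance. Ties break by shorter sequence, then lexicographically;
this tie-break is a decision of this package, not an inference about any
particular laboratory's practice. Any modification is treated as
disqualifying because a variably occurring modification splits the
signal between modified and unmodified forms.

## Quantitation

Peak areas are trapezoidal integrals over a scheduled RT window (default
±0.3 min around the configured elution time). The default baseline is a
line through the medians of up to three points flanking each window edge;
`endpoints` and `none` modes exist for diagnostics and synthetic tests.
Negative baseline-subtracted areas are clipped to zero and flagged. The
analyte response is the sum over its transition list, standard PRM
practice; per-transition areas are retained for diagnostics.

Calibration is unweighted least squares: `area = m·c + b` for peptides,
`area = a·ln c + b` for PEG (the saturating response is modeled
empirically, not mechanistically). R² is `1 − SSres/SStot`. Inversion is
closed-form; responses outside the fitted range are inverted but flagged
as extrapolated. LOD/LOQ are blank mean + 3 sd and + 10 sd with the
sample (n−1) standard deviation, the convention used throughout the
package (SE = sd/√n, CV = sd/mean·100). Published R², LOD/LOQ and CV
values for the original assay cannot be recomputed without the
unpublished raw responses; the formulas are exercised on synthetic data
instead.

## Synthetic data

The generator emulates the assay's signal structure: Gaussian elution
peaks (defaults: peptides at 14.4 min, PEG at 18.5 min, sd 0.05 min),
per-transition response shares summing to one per analyte, linear peptide
response, logarithmic PEG response, per-analyte recovery multipliers
(defaults 0.776 for the co-processed peptides and 0.742 for PEG, the
reported mean recoveries), a flat baseline, and additive Gaussian noise
whose sd is a floor plus a fraction of each trace's apex (default 1% —
the source data constrain only replicate CVs of a few percent, so the
level is chosen once for test power, not realism). Traces are clipped at
zero. All randomness flows from one study seed through
`numpy.random.SeedSequence`, so identical configurations give
byte-identical artifacts.

A digestion study is generated from a ground-truth table: per subject and
compartment a dilution factor and a survival fraction; marker
concentration = feed marker ÷ factor; target = feed target × survival ÷
factor; SIS spike constant (it is added after digestion). The default
study mirrors the published four-infant experiment: feed concentrations
38.10/18.66/18.51/16.17 ng/µL, feed marker 0.1 ng/µL, SIS 0.5 ng/µL,
four injections per sample, standard series 0.5–20 (target), 0.01–1
(SIS) and 0.005–1 ng/µL (PEG), three blanks, and the published dilution
factors and survival fractions as truth (including one not-detected
stool sample).

What passing tests show — and do not show. Because standards and samples
share the time grid, window and baseline treatment, quadrature and
truncation factors cancel through the calibration, and a noise-free study
returns the generating survival fractions to ~1e-8 percentage points;
with 1% noise, within 3 points at a fixed seed. This validates the
estimator chain, not the chromatography: the generator has no RT drift,
chimeric interference, matrix suppression beyond a scalar recovery, or
isotope envelopes, so agreement here does not bound accuracy on real
instrument data.

## Numerical and design choices

* Simulation grid 0–20 min at 0.02 min; the default study (6 standards,
  3 blanks, 64 sample injections × 22 transitions) runs in a few seconds,
  a deliberately desk-scale problem size.
* Long-format run TSV is the canonical chromatogram store (times at 4 dp,
  intensities at 6 dp); a minimal spectrum-list XML reader assembles
  traces by nearest-target m/z matching within an absolute 0.01
  tolerance.
* Writers are deterministic (fixed column order and float formats, no
  timestamps); readers reject malformed input rather than repairing it.
* Report rounding: concentrations 2 dp, dilution factors 3 dp,
  percentages 1 dp, half-up.
* Not-detected samples (mean target ≤ LOD) report 0% survival with a
  distinct N/D flag and enter study means as 0.
* Paired t-tests compare feed and compartment normalized concentrations
  with subjects as the unit of replication (n = 4 in the default study);
  with so few subjects the exact sign-flip permutation test used as a
  test oracle has resolution 2/2ⁿ, which is why module tests compare
  rankings rather than p-values.
* The published stool summary is not exactly recoverable from the printed
  per-subject values (recomputation gives ≈5.5% with N/D as 0); the
  package reports what it computes and makes no claim about the original
  intermediate precision.

## Limitations

No vendor raw-file ingestion, spectral searching, RT alignment,
smoothing, or interference detection beyond tolerance matching; ELISA
comparison and pharmacokinetic transit modeling are out of scope. The
recovery multiplier is the only matrix-effect knob.
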