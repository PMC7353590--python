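"""Normalization chain and study statistics, including the published
worked examples and a sign-flip enumeration oracle for the paired t-test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prmsurv.datasets import load_published_study, published_survival
from prmsurv.survival import (
    SampleQuant,
    build_survival_report,
    compartment_summaries,
    dilution_factor,
    dilution_normalize,
    paired_t,
    recovery_percent,
    sis_normalize,
    summarize,
    survival_percent,
)

POS = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestSisNormalize:
    def test_published_worked_example(self):
        """15.16 ng/µL at 78% SIS recovery normalizes to ~19.43 ng/µL."""
        assert sis_normalize(15.16, 0.39, 0.5) == pytest.approx(19.43, rel=1e-3)

    def test_identity_when_sis_fully_recovered(self):
        assert sis_normalize(12.3, 0.5, 0.5) == 12.3

    def test_factor_two_correction(self):
        assert sis_normalize(10, 0.25, 0.5) == pytest.approx(20.0)

    def test_nonpositive_sis_rejected(self):
        with pytest.raises(ValueError):
            sis_normalize(10, 0.0, 0.5)


class TestRecovery:
    def test_published_recovery_rate(self):
        assert recovery_percent(19.43, 50) == pytest.approx(38.9, abs=0.05)

    @pytest.mark.parametrize("measured,expected", [(50, 100.0), (0, 0.0)])
    def test_edge_values(self, measured, expected):
        assert recovery_percent(measured, 50) == expected

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(ValueError):
            recovery_percent(10, 0)


class TestDilution:
    def test_published_marker_example(self):
        """Feed marker 0.1, sample 0.074 ng/µL: 1.35-fold dilution."""
        assert dilution_factor(0.1, 0.074) == pytest.approx(1.351, abs=5e-4)

    def test_equal_concentrations(self):
        assert dilution_factor(0.1, 0.1) == 1.0

    def test_concentration_gives_factor_below_one(self):
        assert dilution_factor(0.1, 0.2) == 0.5

    @pytest.mark.parametrize("feed,sample", [(0, 1), (1, 0), (-1, 1)])
    def test_nonpositive_rejected(self, feed, sample):
        with pytest.raises(ValueError):
            dilution_factor(feed, sample)

    @pytest.mark.parametrize(
        "conc,factor,expected",
        [(10.04, 1.14, 11.45), (1.97, 1.14, 2.25)],
    )
    def test_normalization_matches_published_cells(self, conc, factor, expected):
        assert dilution_normalize(conc, factor) == pytest.approx(expected, abs=5e-3)

    def test_unit_factor_is_identity(self):
        assert dilution_normalize(3.14, 1.0) == 3.14

    @given(POS, POS)
    def test_chain_identity_on_marker(self, feed, sample):
        """Normalizing the marker by its own dilution factor returns the feed value."""
        factor = dilution_factor(feed, sample)
        assert dilution_normalize(sample, factor) == pytest.approx(feed, rel=1e-12)


class TestSurvivalPercent:
    def test_published_gastric_cell(self):
        assert survival_percent(32.41, 38.10) == pytest.approx(85.07, abs=5e-3)

    def test_feed_is_hundred_percent(self):
        assert survival_percent(38.10, 38.10) == 100.0

    @given(POS, POS, POS)
    def test_homogeneous_in_scale(self, conc, feed, k):
        assert survival_percent(k * conc, k * feed) == pytest.approx(
            survival_percent(conc, feed), rel=1e-9
        )

    def test_nonpositive_feed_rejected(self):
        with pytest.raises(ValueError):
            survival_percent(1.0, 0.0)


class TestSummarize:
    def test_published_gastric_summary(self):
        """The four gastric survival values average 88.4% with SE 4.4%."""
        surv = published_survival()
        gastric = surv[surv["compartment"] == "gastric"]["survival_percent"]
        summ = summarize(list(gastric))
        assert round(summ.mean, 1) == 88.4
        assert round(summ.error, 1) == 4.4

    def test_constant_values(self):
        summ = summarize([5, 5, 5, 5])
        assert (summ.mean, summ.error, summ.cv_percent) == (5.0, 0.0, 0.0)

    @given(st.lists(POS, min_size=2, max_size=10), POS)
    def test_scale_invariance_of_cv(self, values, k):
        base = summarize(values)
        scaled = summarize([k * v for v in values])
        assert scaled.mean == pytest.approx(k * base.mean, rel=1e-9)
        if base.cv_percent is not None:
            assert scaled.cv_percent == pytest.approx(base.cv_percent, rel=1e-6)

    def test_zero_mean_flags_cv(self):
        assert summarize([-1.0, 1.0]).cv_percent is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


def signflip_p(diffs: np.ndarray) -> float:
    """Exact sign-flip permutation p-value for mean difference = 0."""
    observed = abs(diffs.mean())
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=len(diffs)):
        total += 1
        if abs((diffs * np.array(signs)).mean()) >= observed - 1e-12:
            count += 1
    return count / total


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_t([1, 1, 1, 1], [2, 2, 2, 2])
        assert res.degenerate and math.isinf(res.t) and res.p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1, 2], [1, 2, 3])

    def test_ranking_agrees_with_signflip_oracle(self):
        """t p-values order datasets the same way as exact sign-flip enumeration."""
        rng = np.random.default_rng(17)
        datasets = []
        for shift in [0.0, 0.5, 1.0, 2.0, 4.0]:
            a = rng.normal(0, 1, 8)
            b = a + shift + rng.normal(0, 0.5, 8)
            datasets.append((a, b))
        t_ps = [paired_t(list(a), list(b)).p for a, b in datasets]
        perm_ps = [signflip_p(b - a) for a, b in datasets]
        # The enumeration p has resolution 2/2^n and ties at the extremes, so
        # require concordant ordering wherever the oracle distinguishes.
        for i in range(len(datasets)):
            for j in range(i + 1, len(datasets)):
                if perm_ps[i] != perm_ps[j]:
                    assert (t_ps[i] < t_ps[j]) == (perm_ps[i] < perm_ps[j])


class TestSurvivalReport:
    def _quants(self):
        return [
            SampleQuant("s1", "feed", (40.0, 40.0), (0.5, 0.5), 0.5, 0.1),
            SampleQuant("s1", "gastric", (18.0, 22.0), (0.5, 0.5), 0.5, 0.05),
        ]

    def test_normalization_chain_by_construction(self):
        report = build_survival_report(self._quants())
        gastric = report[report["compartment"] == "gastric"].iloc[0]
        assert gastric["dilution_factor"] == pytest.approx(2.0)
        assert gastric["normalized_conc"] == pytest.approx(40.0)
        assert gastric["survival_percent"] == pytest.approx(100.0)

    def test_not_detected_reported_as_zero_survival(self):
        quants = self._quants() + [
            SampleQuant("s1", "stool", (0.0, 0.0), (0.5, 0.5), 0.5, 0.2, not_detected=True)
        ]
        report = build_survival_report(quants)
        stool = report[report["compartment"] == "stool"].iloc[0]
        assert stool["nd"] and stool["survival_percent"] == 0.0
        assert np.isnan(stool["normalized_conc"])

    def test_missing_feed_rejected(self):
        with pytest.raises(ValueError, match="no feed"):
            build_survival_report(
                [SampleQuant("s1", "gastric", (1.0,), (0.5,), 0.5, 0.1)]
            )

    def test_compartment_summaries_structure(self):
        quants = []
        for s in ("s1", "s2"):
            quants.append(SampleQuant(s, "feed", (40.0,), (0.5,), 0.5, 0.1))
            quants.append(SampleQuant(s, "gastric", (18.0,), (0.5,), 0.5, 0.05))
        report = build_survival_report(quants)
        summaries, tests = compartment_summaries(report)
        assert set(summaries["compartment"]) == {"feed", "gastric"}
        assert "gastric" in tests


def test_published_table_is_internally_consistent():
    """conc x dilution factor reproduces the printed normalized column.

    The printed inputs are rounded (2 dp concentrations, 2-3 dp factors), so
    each product must agree either within 0.5% or within the interval implied
    by half-ulp rounding of both printed inputs.
    """
    df = load_published_study()
    checked = 0
    for _, row in df[~df["nd"]].iterrows():
        product = dilution_normalize(row["conc"], row["dilution_factor"])
        printed = row["normalized_conc"]
        rel = abs(product - printed) / printed
        # printed half-ulps: concentration 0.005, factor depends on dp shown
        f_ulp = 0.0005 if row["dilution_factor"] != round(row["dilution_factor"], 2) else 0.005
        lo = (row["conc"] - 0.005) * (row["dilution_factor"] - f_ulp)
        hi = (row["conc"] + 0.005) * (row["dilution_factor"] + f_ulp)
        consistent = lo - 0.005 <= printed <= hi + 0.005
        assert rel <= 0.005 or consistent, (row["subject_id"], row["compartment"])
        checked += 1
    assert checked == 15  # every cell with a printed concentration
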