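"""Peak integration, calibration fitting/inversion and detection limits."""

import math

import numpy as np
import pytest

from prmsurv.chromatograms import Chromatogram
from prmsurv.io import TransitionRecord
from prmsurv.quantify import (
    fit_calibration,
    integrate_peak,
    invert_calibration,
    lod_loq,
    quantify_run,
)
from prmsurv.simulate import (
    AnalyteSignal,
    ResponseModel,
    SignalModel,
    simulate_standard_series,
)


def _gaussian_trace(height=1.0, center=14.4, sd=0.05, dt=0.002):
    t = np.arange(13.0, 16.0 + dt / 2, dt)
    y = height * np.exp(-0.5 * ((t - center) / sd) ** 2)
    return Chromatogram("x", t, y)


class TestIntegratePeak:
    def test_unit_gaussian_closed_form(self):
        """A unit-height Gaussian of sd 0.05 min integrates to sd*sqrt(2*pi)."""
        area, apex, clipped = integrate_peak(
            _gaussian_trace(), (13.8, 15.0), baseline_mode="none"
        )
        assert area == pytest.approx(0.05 * math.sqrt(2 * math.pi), rel=1e-2)
        assert apex == pytest.approx(14.4, abs=0.01)
        assert not clipped

    def test_all_zero_trace(self):
        t = np.linspace(0, 1, 50)
        area, _, _ = integrate_peak(Chromatogram("x", t, np.zeros(50)), (0.2, 0.8))
        assert area == 0.0

    def test_constant_trace_with_endpoint_baseline_is_zero(self):
        t = np.linspace(0, 1, 50)
        area, _, _ = integrate_peak(
            Chromatogram("x", t, np.full(50, 7.0)), (0.2, 0.8), baseline_mode="endpoints"
        )
        assert area == pytest.approx(0.0, abs=1e-12)

    def test_additive_over_disjoint_windows(self):
        chrom = _gaussian_trace()
        split = float(chrom.times[700])  # an exact grid point near the apex
        whole, _, _ = integrate_peak(chrom, (13.8, 15.0), baseline_mode="none")
        left, _, _ = integrate_peak(chrom, (13.8, split), baseline_mode="none")
        right, _, _ = integrate_peak(chrom, (split, 15.0), baseline_mode="none")
        assert left + right == pytest.approx(whole, rel=1e-9)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="outside trace"):
            integrate_peak(_gaussian_trace(), (0.0, 1.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            integrate_peak(_gaussian_trace(dt=0.5), (14.3, 14.5))

    def test_negative_area_clipped_and_flagged(self):
        t = np.linspace(0, 1, 101)
        y = np.full(101, 10.0)
        y[40:61] = 0.0  # a dip below the flanking level
        area, _, clipped = integrate_peak(Chromatogram("x", t, y), (0.4, 0.6))
        assert area == 0.0 and clipped


class TestCalibration:
    def test_exact_linear_fit(self):
        points = [(c, 2 * c + 1) for c in [0.5, 1, 2, 5, 10, 20]]
        curve = fit_calibration(points, "linear")
        assert curve.params == pytest.approx((2.0, 1.0), abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_log_fit(self):
        points = [(c, 3 * math.log(c) + 5) for c in [0.005, 0.01, 0.05, 0.1, 0.5, 1.0]]
        curve = fit_calibration(points, "log")
        assert curve.params == pytest.approx((3.0, 5.0), abs=1e-10)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_never_increases_r_squared(self):
        rng = np.random.default_rng(5)
        concs = [0.5, 1, 2, 5, 10, 20]
        clean = [(c, 2 * c) for c in concs]
        noisy = [(c, 2 * c + rng.normal(0, 0.5)) for c in concs]
        assert (
            fit_calibration(noisy, "linear").r_squared
            <= fit_calibration(clean, "linear").r_squared
        )

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_calibration([(1, 1), (2, 2)], "linear")

    def test_zero_conc_under_log_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_calibration([(0, 1), (1, 2), (2, 3)], "log")

    def test_invert_linear_example(self):
        curve = fit_calibration([(c, 2 * c + 1) for c in [1, 2, 5]], "linear")
        conc, extrapolated = invert_calibration(curve, 5.0)
        assert conc == pytest.approx(2.0, abs=1e-12)
        assert not extrapolated

    def test_invert_log_example(self):
        curve = fit_calibration([(c, 3 * math.log(c) + 5) for c in [0.5, 1, 2]], "log")
        conc, _ = invert_calibration(curve, 5.0)
        assert conc == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("kind", ["linear", "log"])
    def test_invert_predict_identity(self, kind):
        concs = [0.5, 1, 2, 5, 10, 20]
        if kind == "linear":
            points = [(c, 4 * c + 2) for c in concs]
        else:
            points = [(c, 4 * math.log(c) + 2) for c in concs]
        curve = fit_calibration(points, kind)
        for c in concs:
            conc, extrapolated = invert_calibration(curve, curve.predict(c))
            assert conc == pytest.approx(c, rel=1e-9)
            assert not extrapolated

    def test_extrapolation_flagged(self):
        curve = fit_calibration([(c, 2 * c) for c in [1, 2, 5]], "linear")
        _, extrapolated = invert_calibration(curve, 1e6)
        assert extrapolated


class TestSyntheticSeriesRecovery:
    def _model(self, noise_rel):
        return SignalModel(
            analytes={
                "pep": AnalyteSignal(
                    "pep", 14.4, 0.05, ResponseModel("linear", (1000.0,)), {"y2": 1.0}
                )
            },
            noise_rel=noise_rel,
            seed=42,
        )

    def _transitions(self):
        return [
            TransitionRecord("pep", "peptide", 476.7711, 2, "y2", 234.1448, "HCD", (14.1, 14.7))
        ]

    def _fit_slope(self, noise_rel):
        model = self._model(noise_rel)
        standards, _ = simulate_standard_series(
            model, {"pep": [0.5, 1, 2, 5, 10, 20]}, self._transitions(), n_blanks=0,
            t_start=13.0, duration=3.0, dt=0.005,
        )
        points = []
        for concs, run in standards:
            peaks = quantify_run(run, self._transitions(), {"pep": (14.1, 14.7)}, "none")
            points.append((concs["pep"], peaks["pep"].total_area))
        return fit_calibration(points, "linear").params[0]

    def test_noise_free_slope_recovered(self):
        assert self._fit_slope(0.0) == pytest.approx(1000.0, rel=5e-3)

    def test_one_percent_noise_slope_within_two_percent(self):
        assert self._fit_slope(0.01) == pytest.approx(1000.0, rel=0.02)


class TestLodLoq:
    def test_zero_spread_blanks(self):
        assert lod_loq([10, 10, 10]) == (10.0, 10.0)

    def test_analytic_example(self):
        # mean 10, sample sd exactly 2
        blanks = [8.0, 10.0, 12.0, 10.0, 8.0, 12.0]
        sd = np.std(blanks, ddof=1)
        lod, loq = lod_loq(blanks)
        assert lod == pytest.approx(10 + 3 * sd)
        assert loq == pytest.approx(10 + 10 * sd)
        assert lod <= loq

    def test_single_blank_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            lod_loq([1.0])
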