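"""Peak integration, calibration fitting/inversion, and LOD/LOQ.

Concentration read-out follows standard targeted-proteomics practice: the
response of an analyte is the summed area of all its transitions over the
scheduled retention-time window, a calibration curve maps response to
concentration, and detection limits come from blank injections as
``mean + 3*sd`` (LOD) and ``mean + 10*sd`` (LOQ), with the sample standard
deviation (n-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chromatograms import Chromatogram, PrmRun
from .io import TransitionRecord

__all__ = [
    "PeakArea",
    "CalibrationCurve",
    "integrate_peak",
    "quantify_run",
    "fit_calibration",
    "invert_calibration",
    "lod_loq",
]

BASELINE_MODES = ("flanking_median", "endpoints", "none")


@dataclass
class PeakArea:
    """Integrated response of one analyte in one run."""

    analyte_id: str
    transition_areas: dict[str, float]
    rt_apex: float
    window: tuple[float, float]
    clipped_negative: bool = False

    @property
    def total_area(self) -> float:
        return sum(self.transition_areas.values())


def _baseline(
    times: np.ndarray,
    intensities: np.ndarray,
    inside: np.ndarray,
    mode: str,
    n_flank: int = 3,
) -> np.ndarray:
    """Baseline level under the integration window, per in-window point."""
    t_in = times[inside]
    if mode == "none":
        return np.zeros(t_in.size)
    idx = np.flatnonzero(inside)
    lo, hi = idx[0], idx[-1]
    if mode == "endpoints":
        left = intensities[lo]
        right = intensities[hi]
    else:  # flanking_median: medians of up to n_flank points outside each edge
        left_pts = intensities[max(0, lo - n_flank) : lo]
        right_pts = intensities[hi + 1 : hi + 1 + n_flank]
        left = float(np.median(left_pts)) if left_pts.size else intensities[lo]
        right = float(np.median(right_pts)) if right_pts.size else intensities[hi]
    # Linear interpolation between the two anchor levels across the window.
    if t_in[-1] == t_in[0]:
        return np.full(t_in.size, (left + right) / 2.0)
    frac = (t_in - t_in[0]) / (t_in[-1] - t_in[0])
    return left + frac * (right - left)


def integrate_peak(
    chromatogram: Chromatogram,
    window: tuple[float, float],
    baseline_mode: str = "flanking_median",
) -> tuple[float, float, bool]:
    """Trapezoidal area of a trace over ``window`` minus a baseline.

    Returns ``(area, rt_apex, clipped)``; a baseline-subtracted area that
    comes out negative is clipped to zero and flagged.
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"unknown baseline mode {baseline_mode!r}")
    start, end = window
    if start >= end:
        raise ValueError("integration window start must precede end")
    t, y = chromatogram.times, chromatogram.intensities
    if t.size == 0 or start < t[0] or end > t[-1]:
        raise ValueError(
            f"{chromatogram.transition_id}: window {window} outside trace extent"
        )
    inside = (t >= start) & (t <= end)
    if inside.sum() < 3:
        raise ValueError(
            f"{chromatogram.transition_id}: fewer than 3 points inside window {window}"
        )
    base = _baseline(t, y, inside, baseline_mode)
    corrected = y[inside] - base
    area = float(np.trapezoid(corrected, t[inside]))
    apex = float(t[inside][np.argmax(y[inside])])
    clipped = area < 0
    return (0.0 if clipped else area), apex, clipped


def quantify_run(
    run: PrmRun,
    transitions: list[TransitionRecord],
    windows: dict[str, tuple[float, float]],
    baseline_mode: str = "flanking_median",
) -> dict[str, PeakArea]:
    """Summed transition areas per analyte, using per-analyte RT windows."""
    by_analyte: dict[str, list[TransitionRecord]] = {}
    for trans in transitions:
        by_analyte.setdefault(trans.analyte_id, []).append(trans)
    peaks: dict[str, PeakArea] = {}
    for analyte_id, trans_list in by_analyte.items():
        window = windows[analyte_id]
        areas: dict[str, float] = {}
        apexes: list[tuple[float, float]] = []
        clipped = False
        for trans in trans_list:
            if trans.transition_id not in run:
                continue
            area, apex, clip = integrate_peak(
                run[trans.transition_id], window, baseline_mode
            )
            areas[trans.fragment_label] = area
            apexes.append((area, apex))
            clipped = clipped or clip
        if not areas:
            continue
        # Apex of the most intense transition stands in for the analyte apex.
        rt_apex = max(apexes)[1]
        peaks[analyte_id] = PeakArea(
            analyte_id=analyte_id,
            transition_areas=areas,
            rt_apex=rt_apex,
            window=window,
            clipped_negative=clipped,
        )
    return peaks


@dataclass
class CalibrationCurve:
    """A fitted response model: linear ``m*c + b`` or ``a*ln(c) + b``."""

    analyte_id: str
    model_kind: str  # "linear" | "log"
    params: tuple[float, float]  # (m, b) or (a, b)
    r_squared: float
    conc_range: tuple[float, float]
    response_range: tuple[float, float]
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in ("linear", "log"):
            raise ValueError(f"unknown calibration model {self.model_kind!r}")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"R^2 must lie in [0, 1], got {self.r_squared}")
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValueError("LOD must not exceed LOQ")

    def predict(self, conc: float) -> float:
        if self.model_kind == "linear":
            m, b = self.params
            return m * conc + b
        a, b = self.params
        if conc <= 0:
            raise ValueError("log model defined only for positive concentrations")
        return a * math.log(conc) + b


def fit_calibration(
    points: list[tuple[float, float]],
    model_kind: str,
    analyte_id: str = "",
) -> CalibrationCurve:
    """Unweighted least-squares calibration fit with R² = 1 - SSres/SStot."""
    if model_kind not in ("linear", "log"):
        raise ValueError(f"unknown calibration model {model_kind!r}")
    concs = np.array([c for c, _ in points], dtype=float)
    resps = np.array([r for _, r in points], dtype=float)
    if np.unique(concs).size < 3:
        raise ValueError("calibration requires at least 3 distinct concentrations")
    if model_kind == "log":
        if np.any(concs <= 0):
            raise ValueError("log calibration requires strictly positive concentrations")
        x = np.log(concs)
    else:
        x = concs
    fit = stats.linregress(x, resps)
    predicted = fit.intercept + fit.slope * x
    ss_res = float(np.sum((resps - predicted) ** 2))
    ss_tot = float(np.sum((resps - resps.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(
        analyte_id=analyte_id,
        model_kind=model_kind,
        params=(float(fit.slope), float(fit.intercept)),
        r_squared=min(max(r2, 0.0), 1.0),
        conc_range=(float(concs.min()), float(concs.max())),
        response_range=(float(resps.min()), float(resps.max())),
    )


def invert_calibration(
    curve: CalibrationCurve, response: float
) -> tuple[float, bool]:
    """Concentration for a response; second element flags extrapolation.

    Linear: ``(resp - b) / m``; log: ``exp((resp - b) / a)``.
    """
    slope = curve.params[0]
    if slope == 0:
        raise ValueError(f"{curve.analyte_id}: degenerate calibration slope 0")
    lo, hi = curve.response_range
    extrapolated = not (min(lo, hi) <= response <= max(lo, hi))
    if curve.model_kind == "linear":
        conc = (response - curve.params[1]) / slope
    else:
        conc = math.exp((response - curve.params[1]) / slope)
    return conc, extrapolated


def lod_loq(blank_concentrations: list[float]) -> tuple[float, float]:
    """Detection and quantitation limits from blank measurements.

    LOD = blank mean + 3 sd, LOQ = blank mean + 10 sd (sample sd, n-1).
    """
    blanks = np.asarray(blank_concentrations, dtype=float)
    if blanks.size < 2:
        raise ValueError("LOD/LOQ require at least 2 blank measurements")
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    return mean + 3.0 * sd, mean + 10.0 * sd
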