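"""Photosensitizer photobleaching quantification from dual-wavelength
fluorescence imaging.

During a chlorin-e6 PDT procedure the treated site is imaged under 405- and
660-nm excitation; the ROI-mean fluorescence If decays with the delivered
light dose D (J/cm^2) approximately as a single exponential
If(D) = If1 * exp(-alpha * D).  This module segments the fluorescing area,
extracts dose-indexed intensity series, computes the photobleaching
efficiency PE = (If1 - If2) / If1 * 100%, fits the bleaching rate alpha,
and forms the red-to-blue ratio series R = If660 / If405 whose trend tracks
the depth at which bleaching occurs (rising R: superficial bleaching under
blue-light PDT; falling R: deep bleaching under red-light PDT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "AlignmentError",
    "BleachFit",
    "BleachMeasurement",
    "DoseSeries",
    "FluorescenceFrame",
    "InsufficientDataError",
    "NoFluorescenceError",
    "RatioSeries",
    "ROIMask",
    "dose_from_exposure",
    "fit_bleach_rate",
    "mean_intensity",
    "photobleaching_efficiency",
    "ratio_series",
    "red_blue_ratio",
    "segment_fluorescing_area",
]

EXCITATION_WAVELENGTHS = (405, 660)


class NoFluorescenceError(ValueError):
    """The frame contains no pixels above the segmentation threshold."""


class InsufficientDataError(ValueError):
    """Too few points to fit the decay model."""


class AlignmentError(ValueError):
    """Two dose series cannot be brought onto a common dose grid."""


@dataclass(frozen=True)
class FluorescenceFrame:
    """One 2-D fluorescence image with its acquisition metadata."""

    pixels: np.ndarray
    excitation_nm: int
    cumulative_dose: float  # delivered light dose so far (J/cm^2)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.excitation_nm not in EXCITATION_WAVELENGTHS:
            raise ValueError(
                f"excitation_nm must be one of {EXCITATION_WAVELENGTHS}"
            )
        if self.cumulative_dose < 0:
            raise ValueError("cumulative_dose must be >= 0")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask congruent with a frame."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class DoseSeries:
    """ROI-mean fluorescence intensity versus cumulative delivered dose."""

    doses: np.ndarray  # J/cm^2, strictly increasing, starting at 0
    intensities: np.ndarray  # a.u., > 0
    excitation_nm: int

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if d.shape != i.shape or d.ndim != 1:
            raise ValueError("doses and intensities must be 1-D of equal length")
        if len(d) == 0 or d[0] != 0:
            raise ValueError("dose grid must start at 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(i <= 0):
            raise ValueError("intensities must be positive")
        if self.excitation_nm not in EXCITATION_WAVELENGTHS:
            raise ValueError(
                f"excitation_nm must be one of {EXCITATION_WAVELENGTHS}"
            )
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class BleachFit:
    """Fitted single-exponential bleaching model If(D) = If1 exp(-alpha D)."""

    If1: float  # fitted initial intensity (a.u.)
    alpha: float  # photobleaching rate, 1/(J/cm^2)
    alpha_se: float  # standard error of alpha from the fit covariance
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class BleachMeasurement:
    """Before/after intensity pair with the derived bleaching efficiency."""

    If_before: float
    If_after: float
    pe: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "pe", photobleaching_efficiency(self.If_before, self.If_after)
        )


def segment_fluorescing_area(
    frame: FluorescenceFrame, threshold_fraction: float = 0.2
) -> ROIMask:
    """Segment the fluorescing area of a frame.

    Pixels at or above threshold_fraction times the 99th-percentile
    intensity (robust to hot pixels) are kept and the largest connected
    component is returned.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    px = frame.pixels
    p99 = np.percentile(px, 99)
    thr = threshold_fraction * p99
    if thr <= 0:
        raise NoFluorescenceError("frame has no signal above background")
    mask = px >= thr
    if not mask.any():
        raise NoFluorescenceError("no pixels above the segmentation threshold")
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ROIMask(mask)


def mean_intensity(frame: FluorescenceFrame, roi: ROIMask) -> float:
    """Arithmetic mean of the frame over the ROI (a.u.)."""
    if roi.mask.shape != frame.pixels.shape:
        raise ValueError("ROI shape does not match the frame")
    if roi.pixel_count == 0:
        raise ValueError("ROI is empty")
    return float(frame.pixels[roi.mask].mean())


def photobleaching_efficiency(If_before: float, If_after: float) -> float:
    """PE = (If1 - If2) / If1 * 100, the percent drop in ROI-mean
    fluorescence across the procedure."""
    if If_before <= 0:
        raise ValueError("If_before must be > 0")
    if If_after < 0:
        raise ValueError("If_after must be >= 0")
    return (If_before - If_after) / If_before * 100.0


def fit_bleach_rate(series: DoseSeries) -> BleachFit:
    """Fit If(D) = If1 exp(-alpha D) by nonlinear least squares.

    The fit is performed on the linear intensity scale so multiplicative
    noise does not over-weight the low-intensity tail; the log-linear
    regression of ln If on D only provides the starting point.
    """
    if len(series) < 3:
        raise InsufficientDataError("need at least 3 points to fit the decay")
    d = series.doses
    y = series.intensities
    slope, intercept = np.polyfit(d, np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(-slope))

    def model(dd, if1, alpha):
        return if1 * np.exp(-alpha * dd)

    popt, pcov = optimize.curve_fit(model, d, y, p0=p0, maxfev=10_000)
    if1, alpha = popt
    alpha_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    resid = y - model(d, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    return BleachFit(
        If1=float(if1),
        alpha=float(alpha),
        alpha_se=alpha_se,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_points=len(series),
    )


def red_blue_ratio(If_660: float, If_405: float) -> float:
    """R = If660 / If405, the red-to-blue fluorescence signal ratio."""
    if If_405 <= 0:
        raise ValueError("If_405 must be > 0")
    return If_660 / If_405


@dataclass(frozen=True)
class RatioSeries:
    """Dose-indexed red-to-blue ratio with its overall trend.

    trend is 'rising', 'falling' or 'flat' from the sign of the log-linear
    slope of R against dose.
    """

    doses: np.ndarray
    ratios: np.ndarray
    trend: str


def ratio_series(series_660: DoseSeries, series_405: DoseSeries) -> RatioSeries:
    """Red-to-blue ratio series on a common dose grid.

    If the two excitation series were sampled at different doses, both are
    linearly interpolated onto the coarser grid restricted to the overlap
    of their dose ranges.
    """
    if series_660.excitation_nm != 660 or series_405.excitation_nm != 405:
        raise ValueError("pass the 660-nm series first and the 405-nm second")
    d660, d405 = series_660.doses, series_405.doses
    if np.array_equal(d660, d405):
        grid = d660
        i660, i405 = series_660.intensities, series_405.intensities
    else:
        lo = max(d660[0], d405[0])
        hi = min(d660[-1], d405[-1])
        if hi <= lo:
            raise AlignmentError("dose ranges of the two series do not overlap")
        coarse = d660 if len(d660) <= len(d405) else d405
        grid = coarse[(coarse >= lo) & (coarse <= hi)]
        if len(grid) < 2:
            raise AlignmentError("fewer than 2 common dose points")
        i660 = np.interp(grid, d660, series_660.intensities)
        i405 = np.interp(grid, d405, series_405.intensities)
    ratios = i660 / i405
    if len(grid) >= 2:
        slope = np.polyfit(grid, np.log(ratios), 1)[0]
    else:
        slope = 0.0
    if slope > 1e-12:
        trend = "rising"
    elif slope < -1e-12:
        trend = "falling"
    else:
        trend = "flat"
    return RatioSeries(doses=np.asarray(grid), ratios=ratios, trend=trend)


def dose_from_exposure(fluence_rate_mw_cm2: float, duration_s: float) -> float:
    """Delivered light dose (J/cm^2) from fluence rate (mW/cm^2) and
    exposure time (s)."""
    if fluence_rate_mw_cm2 < 0 or duration_s < 0:
        raise ValueError("fluence rate and duration must be >= 0")
    return fluence_rate_mw_cm2 * duration_s / 1000.0
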