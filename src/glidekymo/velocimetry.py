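"""Orientation-based velocimetry on kymographs.

In a kymograph (space across, time down) a spot translocating at constant
velocity v draws a straight trace at angle ``alpha`` from the space axis with
``v = (pixel_size / frame_interval) * cot(alpha)``: vertical traces
(alpha = 90 deg) are stationary, alpha < 90 deg moves toward +x as time
advances.  Two estimators are provided, mirroring the field's practice:

* a batch estimator for kymographs dense with parallel traces — the power
  spectrum of the ROI is integrated into an angular histogram of structure
  orientations (the Fourier-components method used by the Fiji
  *Directionality* plugin) and the dominant off-vertical mode is read off a
  Gaussian fit, falling back to the raw histogram maximum when the fit is
  poor;

* a manual estimator for sparse kymographs — the slope of a hand-drawn
  straight segment.

Measurements are paired with the mean cell speed over the same time window,
so intracellular (cell-frame) and whole-cell velocities can be compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kymograph import Kymograph
from .tracking import VelocityTrace

__all__ = [
    "OrientationHistogram",
    "RoiSpec",
    "VelocityMeasurement",
    "orientation_histogram",
    "orientation_to_velocity",
    "estimate_batch_velocity",
    "measure_segment",
    "select_gliding_windows",
    "pair_with_cell_velocity",
    "detect_slope_reversal",
]


@dataclass
class OrientationHistogram:
    """Angular distribution of structure orientations in an image patch.

    Bin centres are degrees in [0, 180); weights are normalized to sum to 1.
    ``fit`` is (mu, sigma, amplitude, baseline, r_squared) of a
    Gaussian-plus-baseline fit around the circularly unwrapped peak.
    """

    bin_centers: np.ndarray
    weights: np.ndarray
    fit: tuple[float, float, float, float, float]

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    @property
    def peak_deg(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.weights))])


@dataclass
class RoiSpec:
    """A rectangular kymograph region: a time range and a column range.

    Batch ROIs must span 5-15 s (the measurement windows drawn over smooth
    sustained gliding); manual-segment ROIs (``batch=False``) may be any
    length.
    """

    t_range: tuple[float, float]  # (t0, t1) seconds
    col_range: tuple[int, int]  # (x0, x1) inclusive columns
    half: str = "leading"  # {"leading", "trailing"}
    batch: bool = True

    def __post_init__(self) -> None:
        t0, t1 = self.t_range
        if t1 <= t0:
            raise ValueError("ROI time range must be increasing")
        if self.batch and not (5.0 - 1e-9 <= t1 - t0 <= 15.0 + 1e-9):
            raise ValueError(f"batch ROI duration {t1 - t0:.2f} s outside the 5-15 s window")
        if self.col_range[1] <= self.col_range[0]:
            raise ValueError("ROI column range must be increasing")
        if self.half not in ("leading", "trailing"):
            raise ValueError("half must be 'leading' or 'trailing'")


@dataclass
class VelocityMeasurement:
    """One ROI-level myosin-velocity estimate.

    ``myosin_speed_um_s`` is signed: positive means motion toward +x of the
    registered frame as time advances (the caller maps +x onto the leading
    pole).  ``method`` records which tier produced the number.
    """

    roi: RoiSpec
    method: str  # {"gaussian-peak", "local-max", "manual-segment"}
    myosin_speed_um_s: float
    cell_speed_um_s: float = math.nan
    n_traces: int | str = "batch"

    def __post_init__(self) -> None:
        if self.method not in ("gaussian-peak", "local-max", "manual-segment"):
            raise ValueError(f"unknown method {self.method!r}")


def _gauss_baseline(x, mu, sigma, amp, base):
    return base + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _fit_peak(centers: np.ndarray, weights: np.ndarray, k0: int):
    """Gaussian+baseline fit with the histogram circularly rolled so bin k0
    sits at the centre.  Returns (mu mod 180, sigma, amp, base, r2)."""
    n = len(centers)
    delta = 180.0 / n
    shift = n // 2 - k0
    w = np.roll(weights, shift)
    x = centers[k0] + (np.arange(n) - n // 2) * delta
    p0 = [centers[k0], 2.0 * delta, max(w.max() - np.median(w), 1e-12), float(np.median(w))]
    try:
        popt, _ = curve_fit(
            _gauss_baseline,
            x,
            w,
            p0=p0,
            bounds=([x[0], delta / 4.0, 0.0, 0.0], [x[-1], 90.0, np.inf, np.inf]),
            maxfev=5000,
        )
        resid = w - _gauss_baseline(x, *popt)
        ss_tot = float(np.sum((w - w.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        mu = popt[0] % 180.0
        return (mu, float(popt[1]), float(popt[2]), float(popt[3]), r2)
    except RuntimeError:
        return (centers[k0], 0.0, 0.0, float(np.median(w)), 0.0)


def orientation_histogram(
    roi: np.ndarray,
    n_bins: int = 90,
    r_min_frac: float = 0.1,
    r_max_frac: float = 0.9,
) -> OrientationHistogram:
    """Fourier-components orientation histogram of an image patch.

    The patch (mean-subtracted) is apodized with a 2D Hann window, zero-padded
    to a square power of two, and its power spectrum integrated over an
    annulus (0.1-0.9 of Nyquist) into ``n_bins`` angular bins of width
    ``180/n_bins`` degrees.  Spectral orientations are rotated by 90 deg so
    bins report *structure* orientation: a patch of lines at angle alpha from
    the x axis peaks at alpha.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or min(roi.shape) < 16:
        raise ValueError("ROI must be 2D and at least 16x16 px")
    if not roi.any():
        raise ValueError("no signal: ROI is all zero")
    h, w = roi.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    patch = (roi - roi.mean()) * win
    n = 1 << max(6, int(math.ceil(math.log2(max(h, w)))))
    padded = np.zeros((n, n))
    padded[:h, :w] = patch
    power = np.abs(np.fft.fftshift(np.fft.fft2(padded))) ** 2

    fy, fx = np.mgrid[0:n, 0:n]
    fy = fy - n // 2
    fx = fx - n // 2
    r = np.hypot(fx, fy)
    nyquist = n / 2.0
    annulus = (r >= r_min_frac * nyquist) & (r <= r_max_frac * nyquist)
    phi = np.degrees(np.arctan2(fy, fx)) % 180.0  # spectral orientation
    alpha = (phi + 90.0) % 180.0  # structure orientation
    delta = 180.0 / n_bins
    bins = np.minimum((alpha[annulus] / delta).astype(int), n_bins - 1)
    weights = np.bincount(bins, weights=power[annulus], minlength=n_bins)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no signal: empty power spectrum in the annulus")
    weights = weights / total
    centers = (np.arange(n_bins) + 0.5) * delta
    fit = _fit_peak(centers, weights, int(np.argmax(weights)))
    return OrientationHistogram(bin_centers=centers, weights=weights, fit=fit)


def orientation_to_velocity(
    alpha: float, pixel_size: float, frame_interval: float, min_margin_deg: float = 2.0
) -> float:
    """Convert a trace orientation (degrees from the space axis) to um/s.

    ``v = (pixel_size / frame_interval) * cot(alpha)``; alpha = 90 deg is a
    stationary trace (0 um/s), alpha < 90 deg positive toward +x.  Angles
    within ``min_margin_deg`` of 0 or 180 are near-horizontal traces —
    velocities too fast to resolve — and raise ``ValueError``.
    """
    if not 0.0 < alpha < 180.0:
        raise ValueError(f"alpha must be in (0, 180), got {alpha}")
    if alpha < min_margin_deg or alpha > 180.0 - min_margin_deg:
        raise ValueError(f"trace too fast to resolve (alpha={alpha:.2f} deg)")
    if alpha == 90.0:
        return 0.0
    return (pixel_size / frame_interval) / math.tan(math.radians(alpha))


def _roi_rows(kymo: Kymograph, t_range: tuple[float, float]) -> tuple[int, int]:
    r0 = int(round(t_range[0] / kymo.frame_interval))
    r1 = int(round(t_range[1] / kymo.frame_interval))
    if r0 < 0 or r1 >= kymo.n_frames:
        raise ValueError(f"ROI time range {t_range} outside the kymograph")
    return r0, r1


def estimate_batch_velocity(
    kymo: Kymograph,
    roi: RoiSpec,
    trace: VelocityTrace | None = None,
    n_bins: int = 90,
    fit_r2_threshold: float = 0.5,
    vertical_margin_deg: float = 6.0,
    mode_factor: float = 1.5,
) -> VelocityMeasurement:
    """Batch myosin velocity from the dominant off-vertical trace orientation.

    The ROI's static background (per-column temporal mean — the stationary
    raphe signal) is removed, the orientation histogram computed, and the
    strongest mode further than ``vertical_margin_deg`` from vertical is
    located.  A Gaussian fit around that mode gives the orientation when its
    goodness of fit reaches ``fit_r2_threshold`` (method ``gaussian-peak``);
    otherwise the raw histogram maximum of the mode is used (``local-max``).

    Raises
    ------
    ValueError
        If no off-vertical bin exceeds ``mode_factor`` times the uniform
        level — there are no moving traces to measure.
    """
    r0, r1 = _roi_rows(kymo, roi.t_range)
    x0, x1 = roi.col_range
    if x0 < 0 or x1 >= kymo.width:
        raise ValueError(f"ROI column range {roi.col_range} outside the kymograph")
    raw = kymo.data[r0 : r1 + 1, x0 : x1 + 1].astype(float)

    # orientation content of the static-subtracted ROI (the per-column
    # temporal mean removes the stationary raphe signal, which would
    # otherwise dominate the spectrum with a vertical mode)
    sub = raw - raw.mean(axis=0, keepdims=True)
    hist = orientation_histogram(sub, n_bins=n_bins)
    off_vertical = np.abs(hist.bin_centers - 90.0) > vertical_margin_deg
    if not off_vertical.any():
        raise ValueError("vertical margin excludes every bin")
    # presence check against bin-count fluctuations: a genuine trace mode is
    # several bins wide, so a light circular smoothing must still leave it
    # above 1.5x the uniform level
    smoothed = np.convolve(np.pad(hist.weights, 1, mode="wrap"), np.ones(3) / 3, "valid")
    if smoothed[off_vertical].max() < mode_factor / n_bins:
        raise ValueError("no moving traces: no off-vertical mode above the uniform level")
    w_off = np.where(off_vertical, hist.weights, -np.inf)
    k_star = int(np.argmax(w_off))

    mu, sigma, amp, base, r2 = _fit_peak(hist.bin_centers, hist.weights, k_star)
    if r2 >= fit_r2_threshold and abs(mu - 90.0) > vertical_margin_deg / 2.0:
        alpha, method = mu, "gaussian-peak"
    else:
        alpha, method = float(hist.bin_centers[k_star]), "local-max"
    v = orientation_to_velocity(alpha, kymo.pixel_size, kymo.frame_interval)

    cell_v = math.nan
    if trace is not None:
        i0 = int(round(roi.t_range[0] / trace.frame_interval))
        i1 = int(round(roi.t_range[1] / trace.frame_interval))
        cell_v = float(np.mean(trace.smoothed[i0 : i1 + 1]))
    return VelocityMeasurement(
        roi=roi, method=method, myosin_speed_um_s=v, cell_speed_um_s=cell_v
    )


def measure_segment(
    kymo: Kymograph,
    p0: tuple[float, float],
    p1: tuple[float, float],
    half: str = "leading",
) -> VelocityMeasurement:
    """Velocity of a hand-drawn straight segment, endpoints (col, row).

    ``v = pixel_size * dcol / (frame_interval * drow)``.  Equal rows would be
    an infinitely fast trace and raise ``ValueError``.
    """
    (c0, r0), (c1, r1) = p0, p1
    if r1 == r0:
        raise ValueError("segment endpoints on the same row: infinite velocity")
    if r1 < r0:  # normalize to time increasing
        (c0, r0), (c1, r1) = (c1, r1), (c0, r0)
    v = kymo.pixel_size * (c1 - c0) / (kymo.frame_interval * (r1 - r0))
    roi = RoiSpec(
        t_range=(r0 * kymo.frame_interval, r1 * kymo.frame_interval),
        col_range=(int(min(c0, c1)), int(max(c0, c1)) + 1),
        half=half,
        batch=False,
    )
    return VelocityMeasurement(
        roi=roi, method="manual-segment", myosin_speed_um_s=float(v), n_traces=1
    )


def select_gliding_windows(
    trace: VelocityTrace, v_min: float = 0.5, t_min: float = 5.0
) -> list[tuple[float, float]]:
    """Maximal time windows of smooth sustained gliding.

    Returns ``(t0, t1)`` spans where the smoothed speed stays above ``v_min``
    (um/s) for at least ``t_min`` seconds — the windows batch ROIs are
    anchored to.
    """
    if len(trace.smoothed) == 0:
        raise ValueError("empty velocity trace")
    above = trace.smoothed > v_min
    dt = trace.frame_interval
    windows = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if (j - i) * dt >= t_min:
                windows.append((i * dt, j * dt))
            i = j + 1
        else:
            i += 1
    return windows


def pair_with_cell_velocity(
    measurements: list[VelocityMeasurement], trace: VelocityTrace
) -> pd.DataFrame:
    """Tidy table pairing each myosin measurement with the mean cell speed
    over the same time window (plus their ratio)."""
    rows = []
    dt = trace.frame_interval
    for m in measurements:
        t0, t1 = m.roi.t_range
        i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
        if i0 < 0 or i1 >= len(trace.smoothed):
            raise ValueError(f"measurement window ({t0}, {t1}) s outside the velocity trace")
        cell = float(np.mean(trace.smoothed[i0 : i1 + 1]))
        myo = abs(m.myosin_speed_um_s)
        rows.append(
            {
                "t0_s": t0,
                "t1_s": t1,
                "half": m.roi.half,
                "method": m.method,
                "myosin_speed_um_s": m.myosin_speed_um_s,
                "abs_myosin_speed_um_s": myo,
                "cell_speed_um_s": cell,
                "ratio_myosin_over_cell": myo / cell if cell > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of myosin and cell speeds, grouped by cell half."""
    return (
        pairs.groupby("half")
        .agg(
            n=("abs_myosin_speed_um_s", "size"),
            myosin_mean=("abs_myosin_speed_um_s", "mean"),
            myosin_sd=("abs_myosin_speed_um_s", "std"),
            cell_mean=("cell_speed_um_s", "mean"),
            cell_sd=("cell_speed_um_s", "std"),
        )
        .reset_index()
    )


def detect_slope_reversal(
    kymo: Kymograph,
    col_range: tuple[int, int] | None = None,
    window_s: float = 5.0,
    step_s: float = 0.5,
    n_bins: int = 90,
    vertical_margin_deg: float = 6.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Locate the time where the dominant kymograph slope changes sign.

    A window of ``window_s`` slides down the kymograph in steps of ``step_s``;
    in each, the dominant off-vertical orientation gives a signed velocity.
    The reversal estimate is the zero crossing (linear interpolation) between
    the last window of one sign and the first of the other.

    Returns ``(t_reversal, window_centers, signed_velocities)``.
    """
    dt = kymo.frame_interval
    w_rows = max(2, int(round(window_s / dt)))
    step = max(1, int(round(step_s / dt)))
    x0, x1 = col_range if col_range is not None else (0, kymo.width - 1)
    centers, vels = [], []
    for r0 in range(0, kymo.n_frames - w_rows + 1, step):
        sub = kymo.data[r0 : r0 + w_rows, x0 : x1 + 1].astype(float)
        sub = sub - sub.mean(axis=0, keepdims=True)
        try:
            hist = orientation_histogram(sub, n_bins=n_bins)
        except ValueError:
            continue
        off = np.abs(hist.bin_centers - 90.0) > vertical_margin_deg
        w_off = np.where(off, hist.weights, -np.inf)
        k = int(np.argmax(w_off))
        mu, _, _, _, r2 = _fit_peak(hist.bin_centers, hist.weights, k)
        alpha = mu if r2 >= 0.5 and abs(mu - 90.0) > vertical_margin_deg / 2.0 else float(
            hist.bin_centers[k]
        )
        try:
            v = orientation_to_velocity(alpha, kymo.pixel_size, dt)
        except ValueError:
            continue
        centers.append((r0 + (w_rows - 1) / 2.0) * dt)
        vels.append(v)
    centers_arr = np.asarray(centers)
    vels_arr = np.asarray(vels)
    sign = np.sign(vels_arr)
    crossings = np.where(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) == 0:
        raise ValueError("no slope sign change detected")
    i = int(crossings[0])
    t0, t1 = centers_arr[i], centers_arr[i + 1]
    v0, v1 = vels_arr[i], vels_arr[i + 1]
    t_rev = t0 + (0.0 - v0) * (t1 - t0) / (v1 - v0)
    return float(t_rev), centers_arr, vels_arr
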