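"""Space-time kymographs and Fourier stripe removal.

A kymograph collapses a registered movie into a 2D image: columns are pixels
along the (now stationary) cell axis, rows are frames, so a spot moving at
constant velocity draws a straight line whose slope encodes that velocity.
Rather than picking one pixel row, every row in a band across the cell width
is resliced and the per-pixel maximum taken, which keeps traces visible even
when the labelled structure wanders slightly across the cell width.

Interference patterns and abrupt axial (z) shifts of the cell print as
full-width horizontal stripes; they live entirely at zero spatial frequency
and are notched out in the 2D Fourier domain (the DC coefficient is kept so
mean brightness is preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CalibratedStack

__all__ = ["Kymograph", "build_kymograph", "fourier_stripe_filter"]


@dataclass
class Kymograph:
    """Calibrated space-time image: rows = time (down), columns = space."""

    data: np.ndarray  # (T, W)
    pixel_size: float  # um/px along the space axis
    frame_interval: float  # s per row
    row_band: tuple[int, int] = (0, 0)  # [y_min, y_max] rows combined

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2D (time x space)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


def build_kymograph(
    stack: CalibratedStack,
    row_band: tuple[int, int] | None = None,
    channel: str | None = None,
) -> Kymograph:
    """Maximum-projection kymograph over a band of image rows.

    ``K[t, x] = max over y in [y_min, y_max] of I[t, y, x]``.  ``row_band`` is
    inclusive; by default the full image height is combined.
    """
    if channel is None:
        if stack.data.shape[1] != 1:
            raise ValueError("multi-channel stack: specify the channel to reslice")
        frames = stack.data[:, 0]
    else:
        frames = stack.channel(channel)
    h = frames.shape[1]
    if row_band is None:
        row_band = (0, h - 1)
    y0, y1 = row_band
    if not (0 <= y0 <= y1 < h):
        raise ValueError(f"row band {row_band} invalid for height {h}")
    data = frames[:, y0 : y1 + 1, :].max(axis=1)
    return Kymograph(
        data=data,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        row_band=(y0, y1),
    )


def fourier_stripe_filter(kymo: Kymograph, mask_width: int = 2) -> Kymograph:
    """Notch out horizontal stripes in the Fourier domain.

    The centred 2D spectrum's vertical strip of width ``mask_width`` at zero
    spatial frequency (all temporal frequencies) is zeroed, except the DC
    coefficient which is preserved so overall brightness is unchanged.  For
    even widths the strip covers centred frequency columns {0, -1}; the
    mirrored partner columns are zeroed as well (a real image has a
    conjugate-symmetric spectrum, so a one-sided mask would leak back on
    inverse transform — the mask acts on +/- frequency pairs, as it does when
    painted on a Hartley-transform display).
    """
    if mask_width < 1:
        raise ValueError("mask_width must be >= 1")
    n_rows, n_cols = kymo.data.shape
    if mask_width >= n_cols:
        raise ValueError(f"mask_width {mask_width} must be smaller than image width {n_cols}")
    spec = np.fft.fftshift(np.fft.fft2(kymo.data))
    c_row, c_col = n_rows // 2, n_cols // 2  # location of DC after fftshift
    lo = c_col - (mask_width - 1) // 2 - (1 if mask_width % 2 == 0 else 0)
    hi = lo + mask_width  # exclusive
    dc = spec[c_row, c_col]
    cols = set(range(lo, hi))
    cols |= {2 * c_col - c for c in cols if 0 <= 2 * c_col - c < n_cols}
    spec[:, sorted(cols)] = 0.0
    spec[c_row, c_col] = dc
    filtered = np.real(np.fft.ifft2(np.fft.ifftshift(spec)))
    return Kymograph(
        data=filtered,
        pixel_size=kymo.pixel_size,
        frame_interval=kymo.frame_interval,
        row_band=kymo.row_band,
    )
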