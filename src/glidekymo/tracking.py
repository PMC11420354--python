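"""Chloroplast-landmark tracking and cell pose/velocity estimation.

The whole-cell motion of a gliding diatom is read from its two chloroplasts,
imaged in the autofluorescence channel: per frame the two strongest blobs at a
fixed diameter are detected (Laplacian-of-Gaussian response plus
intensity-weighted centroid refinement), linked over time by nearest
neighbour, and combined into a per-frame cell pose — centre (midpoint of the
two blob centres) and long-axis angle (the vector connecting them).  The
instantaneous cell speed is the frame-to-frame centre displacement over the
frame interval, smoothed with a centred moving average.

Angle convention: degrees counter-clockwise in the mathematical (y-up) sense,
wrapped to (-90, 90].  Image arrays are indexed [row, col] with positions
reported as (x=col, y=row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CalibratedStack

__all__ = [
    "SpotDetection",
    "ChloroplastTrack",
    "CellPose",
    "VelocityTrace",
    "detect_chloroplasts",
    "link_tracks",
    "compute_cell_pose",
    "compute_velocity_trace",
    "moving_average",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SpotDetection:
    """One sub-pixel blob detection in one frame."""

    frame: int
    center: tuple[float, float]  # (x, y) px
    diameter: float  # px
    intensity: float  # summed background-subtracted counts in the bounding circle


@dataclass
class ChloroplastTrack:
    """Per-frame centres of one chloroplast; gap frames are interpolated and flagged."""

    label: str  # "leading" | "trailing" | provisional "a"/"b"
    centers: np.ndarray  # (T, 2) px, (x, y)
    gap: np.ndarray  # (T,) bool, True where the centre was interpolated

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.gap = np.asarray(self.gap, dtype=bool)
        if len(self.centers) != len(self.gap):
            raise ValueError("centers and gap flags must be frame-aligned")


@dataclass
class CellPose:
    """Per-frame cell centre and long-axis angle derived from the two tracks."""

    center: np.ndarray  # (T, 2) px
    angle_deg: np.ndarray  # (T,) in (-90, 90]
    valid: np.ndarray  # (T,) bool


@dataclass
class VelocityTrace:
    """Instantaneous and smoothed cell speed, um/s."""

    speed: np.ndarray
    smoothed: np.ndarray
    window: int = 20
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if len(self.speed) != len(self.smoothed):
            raise ValueError("raw and smoothed traces must have equal length")


def _refine_centroid(
    frame: np.ndarray, y: int, x: int, radius: float
) -> tuple[float, float, float]:
    """Intensity-weighted centroid inside the bounding circle around (y, x).

    Local background (the minimum on the circle boundary region) is subtracted
    so the centroid is not dragged toward the window centre by a pedestal.
    Returns (x, y, summed intensity).
    """
    h, w = frame.shape
    r = int(math.ceil(radius))
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    patch = frame[y0:y1, x0:x1].astype(float)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
    if not mask.any():
        return float(x), float(y), 0.0
    bg = patch[mask].min()
    wts = np.where(mask, patch - bg, 0.0)
    total = wts.sum()
    if total <= 0:
        return float(x), float(y), 0.0
    cy = float((wts * yy).sum() / total)
    cx = float((wts * xx).sum() / total)
    return cx, cy, float(total)


def detect_chloroplasts(
    stack: CalibratedStack,
    spot_diameter: float,
    channel: str = "chloroplast",
    n_spots: int = 2,
    min_intensity_snr: float = 3.0,
) -> list[SpotDetection]:
    """Detect the two chloroplast blobs per frame at one fixed diameter.

    Parameters
    ----------
    spot_diameter:
        Bounding-circle diameter in micrometres; the assay uses the diameter
        of the larger chloroplast, typically 4.5-6.0 um (accepted range
        4.0-8.0).
    n_spots:
        Detections kept per frame (strongest non-overlapping LoG responses).

    Frames with fewer detections simply contribute fewer
    :class:`SpotDetection` entries (the linker flags them as gaps); a stack
    with no detections at all raises ``ValueError``.
    """
    if not 4.0 <= spot_diameter <= 8.0:
        raise ValueError(f"spot_diameter {spot_diameter} um outside the accepted 4-8 um range")
    frames = stack.channel(channel)
    d_px = spot_diameter / stack.pixel_size
    sigma = d_px * FWHM_TO_SIGMA
    detections: list[SpotDetection] = []
    for t, frame in enumerate(frames):
        f = frame.astype(float)
        # negated LoG: positive peaks at bright blobs of matching scale
        resp = -ndimage.gaussian_laplace(f, sigma)
        noise = 1.4826 * np.median(np.abs(resp - np.median(resp)))
        found: list[tuple[float, float]] = []
        masked = resp.copy()
        for _ in range(n_spots):
            idx = int(np.argmax(masked))
            y, x = np.unravel_index(idx, masked.shape)
            if masked[y, x] <= min_intensity_snr * noise or masked[y, x] <= 0:
                break
            cx, cy, total = _refine_centroid(f, int(y), int(x), d_px / 2.0)
            found.append((cx, cy))
            detections.append(SpotDetection(t, (cx, cy), d_px, total))
            # suppress this blob so the next argmax is non-overlapping
            yy, xx = np.ogrid[: resp.shape[0], : resp.shape[1]]
            masked[(yy - cy) ** 2 + (xx - cx) ** 2 <= d_px**2] = -np.inf
    if not detections:
        raise ValueError("no chloroplast detections in any frame")
    return detections


def link_tracks(
    detections: list[SpotDetection],
    n_frames: int,
    max_gap: int = 5,
    tie_tolerance: float = 1e-6,
) -> tuple[ChloroplastTrack, ChloroplastTrack]:
    """Link per-frame detections into two tracks by nearest neighbour.

    Each frame's detections are assigned to the two running tracks by
    minimizing the summed distance to the tracks' last known positions; gaps
    up to ``max_gap`` consecutive frames are closed by linear interpolation
    and flagged.  Leading/trailing labels are not assigned here (they depend
    on the pose; see :func:`label_leading_trailing`) — tracks come back
    labelled ``"a"`` and ``"b"``.

    Raises
    ------
    ValueError
        If the two possible assignments of a frame are ambiguous (cost
        difference below ``tie_tolerance`` while the alternatives differ), or
        a gap exceeds ``max_gap``.
    """
    per_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        per_frame.setdefault(d.frame, []).append(d)

    centers = np.full((n_frames, 2, 2), np.nan)  # (frame, track, xy)
    last = [None, None]  # last known (x, y) per track
    for t in range(n_frames):
        dets = sorted(per_frame.get(t, []), key=lambda d: -d.intensity)[:2]
        pts = [np.asarray(d.center, dtype=float) for d in dets]
        if len(pts) == 0:
            continue
        if last[0] is None and last[1] is None:
            # first populated frame: arbitrary but deterministic order (x, then y)
            pts.sort(key=lambda p: (p[0], p[1]))
            for k, p in enumerate(pts):
                centers[t, k] = p
                last[k] = p
            continue
        if len(pts) == 1:
            # assign to the nearer track; the other gets a gap
            dists = [
                np.linalg.norm(pts[0] - last[k]) if last[k] is not None else np.inf
                for k in (0, 1)
            ]
            k = int(np.argmin(dists))
            centers[t, k] = pts[0]
            last[k] = pts[0]
            continue
        # two detections: pick the pairing with smaller total distance
        def cost(order):
            return sum(
                np.linalg.norm(pts[i] - last[k])
                for k, i in enumerate(order)
                if last[k] is not None
            )

        c01, c10 = cost((0, 1)), cost((1, 0))
        if abs(c01 - c10) < tie_tolerance and np.linalg.norm(pts[0] - pts[1]) > tie_tolerance:
            raise ValueError(f"ambiguous track assignment at frame {t}")
        order = (0, 1) if c01 <= c10 else (1, 0)
        for k, i in enumerate(order):
            centers[t, k] = pts[i]
            last[k] = pts[i]

    tracks = []
    for k, lab in enumerate("ab"):
        xy = centers[:, k, :]
        gap = ~np.isfinite(xy[:, 0])
        if gap.all():
            raise ValueError(f"track {lab} has no detections")
        interior = np.where(~gap)[0]
        first, last_t = interior[0], interior[-1]
        runs = _gap_runs(gap, first, last_t)
        too_long = [r for r in runs if r[1] - r[0] + 1 > max_gap]
        if too_long:
            raise ValueError(
                f"track {lab}: gap of {too_long[0][1] - too_long[0][0] + 1} frames exceeds "
                f"max_gap={max_gap}"
            )
        filled = xy.copy()
        good = ~gap
        idx = np.arange(n_frames)
        for dim in range(2):
            filled[:, dim] = np.interp(idx, idx[good], xy[good, dim])
        tracks.append(ChloroplastTrack(lab, filled, gap))
    return tracks[0], tracks[1]


def _gap_runs(gap: np.ndarray, first: int, last: int) -> list[tuple[int, int]]:
    runs = []
    t = first
    while t <= last:
        if gap[t]:
            start = t
            while t <= last and gap[t]:
                t += 1
            runs.append((start, t - 1))
        else:
            t += 1
    return runs


def compute_cell_pose(track_a: ChloroplastTrack, track_b: ChloroplastTrack) -> CellPose:
    """Cell centre (midpoint of the two chloroplast centres) and axis angle.

    The angle of the vector connecting the two centres is reported CCW in the
    mathematical sense (y up) and wrapped to (-90, 90].  Frames where either
    track has a gap are marked invalid (centres are still the interpolated
    values, usable at the caller's discretion).
    """
    if len(track_a.centers) != len(track_b.centers):
        raise ValueError("tracks must be frame-aligned")
    ca, cb = track_a.centers, track_b.centers
    center = 0.5 * (ca + cb)
    d = cb - ca
    # image y grows downward -> negate dy for the mathematical convention
    ang = np.degrees(np.arctan2(-d[:, 1], d[:, 0]))
    ang = (ang + 90.0) % 180.0 - 90.0
    ang = np.where(ang == -90.0, 90.0, ang)
    valid = ~(track_a.gap | track_b.gap)
    return CellPose(center=center, angle_deg=ang, valid=valid)


def label_leading_trailing(
    track_a: ChloroplastTrack, track_b: ChloroplastTrack, pose: CellPose
) -> tuple[ChloroplastTrack, ChloroplastTrack]:
    """Return (leading, trailing) by projecting onto the net displacement.

    The track whose mean position projects further along the cell's net
    displacement vector is the leading one.  If the cell barely moved
    (net displacement < 1 px) the labels fall back to image order: the track
    further toward +x (then -y) is "leading".
    """
    net = pose.center[-1] - pose.center[0]
    if np.linalg.norm(net) < 1.0:
        ref = np.array([1.0, 0.0])
    else:
        ref = net / np.linalg.norm(net)
    proj_a = float(np.mean(track_a.centers @ ref))
    proj_b = float(np.mean(track_b.centers @ ref))
    lead, trail = (track_a, track_b) if proj_a >= proj_b else (track_b, track_a)
    lead = ChloroplastTrack("leading", lead.centers, lead.gap)
    trail = ChloroplastTrack("trailing", trail.centers, trail.gap)
    return lead, trail


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with mirror (half-sample symmetric) edges.

    Even windows are rounded down to the next odd width so the kernel stays
    centred.  Mirror padding with a uniform odd kernel conserves the mean of
    the trace exactly — every sample contributes total weight 1.
    """
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError(f"window {window} exceeds trace length {len(x)}")
    w = window if window % 2 == 1 else window - 1
    if w <= 1:
        return x.copy()
    h = w // 2
    padded = np.pad(x, h, mode="symmetric")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(padded, kernel, mode="valid")


def compute_velocity_trace(
    pose: CellPose,
    pixel_size: float,
    frame_interval: float,
    window: int = 20,
) -> VelocityTrace:
    """Instantaneous and smoothed cell speed from the pose trace.

    speed[i] = ||center[i+1] - center[i]|| * pixel_size / frame_interval,
    with the final value repeated so the trace has one entry per frame; the
    smoothed trace is :func:`moving_average` of width ``window`` (default 20
    samples, i.e. 2 s at 10 fps).
    """
    c = pose.center
    if len(c) < 2:
        raise ValueError("need at least 2 frames for a velocity trace")
    step = np.linalg.norm(np.diff(c, axis=0), axis=1) * pixel_size / frame_interval
    speed = np.concatenate([step, step[-1:]])
    smooth = moving_average(speed, window)
    return VelocityTrace(speed=speed, smoothed=smooth, window=window, frame_interval=frame_interval)
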