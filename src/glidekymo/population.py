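"""Population motility assay: many-cell tracking and velocity distributions.

Low-magnification brightfield movies show cells as dark elongated blobs on a
bright background.  Each frame is inverted and the cells segmented by
thresholding; centroids are linked frame to frame by nearest neighbour into
per-cell traces.  A cell's mean velocity is its cumulative path length over
the observation time.  Traces are filtered (strictly longer than 30 s and
strictly more than 50 um travelled — about one cell length — by default)
before the distribution is summarized as median and interquartile range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import CalibratedStack

__all__ = [
    "MotilityTrace",
    "track_population",
    "filter_traces",
    "summarize_velocities",
]


@dataclass
class MotilityTrace:
    """One cell's position-vs-time record (positions in micrometres)."""

    cell_id: int
    t_s: np.ndarray  # (n,)
    positions_um: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.t_s) != len(self.positions_um):
            raise ValueError("times and positions must align")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self.t_s) > 1 else 0.0

    @property
    def path_length_um(self) -> float:
        if len(self.positions_um) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.positions_um, axis=0), axis=1).sum())

    @property
    def mean_velocity_um_s(self) -> float:
        d = self.duration_s
        return self.path_length_um / d if d > 0 else 0.0


def _detect_cells(frame: np.ndarray, background: float, min_area_px: int) -> np.ndarray:
    """Centroids (x, y px) of dark blobs in one brightfield frame.

    The inverted frame is lightly smoothed, and the threshold is the larger
    of Otsu's level and 6x the robust noise scale — Otsu alone splits the
    noise mode when cells cover only a tiny fraction of the field.
    """
    inverted = ndimage.gaussian_filter(background - frame.astype(float), 2.0)
    if not inverted.any():
        return np.empty((0, 2))
    noise = 1.4826 * np.median(np.abs(inverted - np.median(inverted)))
    thr = max(threshold_otsu(inverted), 6.0 * noise) if inverted.max() > 0 else np.inf
    labels, n = ndimage.label(inverted > thr)
    if n == 0:
        return np.empty((0, 2))
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.where(areas >= min_area_px)[0] + 1
    if len(keep) == 0:
        return np.empty((0, 2))
    # weight by contrast above threshold: baseline noise inside the mask and
    # mask-edge flicker then contribute nothing to the centroid
    weights = np.clip(inverted - thr, 0.0, None)
    coms = ndimage.center_of_mass(weights, labels, index=keep)  # (y, x)
    return np.array([(x, y) for y, x in coms])


def track_population(
    stack: CalibratedStack,
    min_area_um2: float = 50.0,
    max_step_um: float = 15.0,
) -> list[MotilityTrace]:
    """Detect and link cells across a single-channel movie.

    Nearest-neighbour linking with a per-frame step budget of ``max_step_um``;
    a cell not matched in a frame ends its trace, and unmatched detections
    open new traces.  Returns traces in micrometres; an empty movie yields an
    empty list.
    """
    if stack.data.shape[1] != 1:
        raise ValueError("population tracking expects a single-channel movie")
    frames = stack.data[:, 0]
    px = stack.pixel_size
    dt = stack.frame_interval
    min_area_px = max(1, int(round(min_area_um2 / px**2)))
    background = float(np.median(frames[0]))

    active: list[dict] = []  # {"id", "pos", "t", "xy": [...], "ts": [...]}
    finished: list[dict] = []
    next_id = 0
    for i, frame in enumerate(frames):
        dets = _detect_cells(frame, background, min_area_px) * px  # um
        t = i * dt
        unmatched = list(range(len(dets)))
        still_active = []
        for tr in active:
            if unmatched:
                d = np.linalg.norm(dets[unmatched] - tr["pos"], axis=1)
                j = int(np.argmin(d))
                if d[j] <= max_step_um:
                    k = unmatched.pop(j)
                    tr["pos"] = dets[k]
                    tr["xy"].append(dets[k])
                    tr["ts"].append(t)
                    still_active.append(tr)
                    continue
            finished.append(tr)
        for k in unmatched:
            next_id += 1
            still_active.append(
                {"id": next_id - 1, "pos": dets[k], "xy": [dets[k]], "ts": [t]}
            )
        active = still_active
    finished.extend(active)
    traces = [
        MotilityTrace(tr["id"], np.array(tr["ts"]), np.array(tr["xy"]))
        for tr in finished
        if len(tr["ts"]) >= 2
    ]
    traces.sort(key=lambda tr: tr.cell_id)
    return traces


def filter_traces(
    traces: list[MotilityTrace],
    min_duration_s: float = 30.0,
    min_distance_um: float = 50.0,
) -> list[MotilityTrace]:
    """Keep traces strictly longer than ``min_duration_s`` with a path length
    strictly greater than ``min_distance_um`` (about one cell length)."""
    return [
        tr
        for tr in traces
        if tr.duration_s > min_duration_s and tr.path_length_um > min_distance_um
    ]


def summarize_velocities(traces: list[MotilityTrace]) -> dict:
    """Median, quartiles and n of the per-cell mean-velocity distribution.

    Percentiles use linear interpolation between order statistics (the numpy
    default), so boxplot statistics are bit-reproducible.
    """
    if not traces:
        raise ValueError("no traces to summarize")
    v = np.array([tr.mean_velocity_um_s for tr in traces])
    q25, q50, q75 = np.percentile(v, [25.0, 50.0, 75.0])
    return {
        "n": len(v),
        "median_um_s": float(q50),
        "q25_um_s": float(q25),
        "q75_um_s": float(q75),
        "iqr_um_s": float(q75 - q25),
        "mean_um_s": float(v.mean()),
        "velocities_um_s": v,
    }
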