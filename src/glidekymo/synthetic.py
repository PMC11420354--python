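"""Ground-truthed synthetic movies of gliding diatoms.

Two generators:

* :func:`generate_gliding_movie` — a dual-channel TIRF-like movie of a single
  elongated cell gliding along its long axis.  Channel "gfp" carries a dim
  intensity ridge along the raphe line plus bright spots translocating at a
  prescribed velocity *in the cell frame* (the myosin analogue); channel
  "chloroplast" carries two bright Gaussian blobs (the autofluorescence
  landmarks used for tracking).  Optional additive noise and full-width
  horizontal stripe artefacts mimic the failure modes the downstream filters
  must handle.

* :func:`generate_population_movie` — a low-magnification brightfield-like
  movie of many dark elongated cells on a bright background, for the
  population motility assay.

Both return the rendered :class:`~glidekymo.io.CalibratedStack` together with
an exact ground truth (positions integrated analytically, not from pixels), so
every downstream estimate can be scored against known values.

Conventions: image x = column, y = row with y increasing downward; headings
and axis angles are degrees counter-clockwise in the mathematical (y-up)
sense, i.e. a heading of 0 moves the cell toward +x, a heading of 90 moves it
toward the top of the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CalibratedStack

__all__ = [
    "GlidingScenario",
    "GroundTruth",
    "PopulationGroundTruth",
    "generate_gliding_movie",
    "generate_population_movie",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _axis_unit(heading_deg: float) -> np.ndarray:
    """Unit vector of a heading in image coordinates (y down)."""
    th = math.radians(heading_deg)
    return np.array([math.cos(th), -math.sin(th)])


@dataclass
class GlidingScenario:
    """Full parameterization of one synthetic gliding movie.

    Units follow the microscope: micrometres, seconds.  The trajectory is a
    list of piecewise-constant-velocity segments ``(t_start, t_end, v, heading
    [deg])``; outside all segments the cell rests.  Myosin spots are
    ``(start_position_um, cell_frame_velocity_um_s, intensity, t_start,
    t_end)`` with positions measured along the cell axis from the cell centre
    (positive toward the heading direction).  Stripe events are
    ``((f0, f1), (r0, r1), amplitude)``: a constant offset added to rows
    ``r0:r1`` of the GFP channel in frames ``f0:f1``.
    """

    duration: float = 25.0
    frame_interval: float = 0.1
    pixel_size: float = 0.13
    fov: tuple[int, int] = (96, 768)  # (height, width) px
    cell_length: float = 40.0
    cell_width: float = 5.0
    trajectory: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(0.0, 25.0, 2.0, 0.0)]
    )
    chloroplast_diameters: tuple[float, float] = (4.5, 6.0)
    chloroplast_offsets: tuple[float, float] = (-10.0, 10.0)
    myosin_spots: list[tuple[float, float, float, float, float]] = field(default_factory=list)
    noise_sd: float = 20.0
    stripe_events: list[tuple[tuple[int, int], tuple[int, int], float]] = field(
        default_factory=list
    )
    rng_seed: int = 0
    # rendering constants, configurable but rarely touched
    start_center_um: tuple[float, float] | None = None  # None -> centre the path in FOV
    chloroplast_intensity: float = 1000.0
    ridge_intensity: float = 60.0
    raphe_sigma_um: float = 0.3
    spot_sigma_um: float = 0.25
    background: float = 100.0
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for t0, t1, v, _ in self.trajectory:
            if t1 <= t0:
                raise ValueError(f"segment ({t0}, {t1}) has non-positive duration")
            if abs(v) > 4.0 + 1e-12:
                raise ValueError(f"cell speed {v} um/s exceeds the 4 um/s envelope")
        for spot in self.myosin_spots:
            if abs(spot[1]) > 12.0 + 1e-12:
                raise ValueError(f"spot velocity {spot[1]} um/s exceeds the 12 um/s envelope")

    @property
    def n_frames(self) -> int:
        # frames at t = 0, dt, ..., duration inclusive
        return int(round(self.duration / self.frame_interval)) + 1

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Per-frame truth for a gliding movie (all positions in micrometres)."""

    t_s: np.ndarray  # (T,)
    center_um: np.ndarray  # (T, 2) image coords (x, y)
    angle_deg: np.ndarray  # (T,) axis angle, math convention, wrapped to (-90, 90]
    v_um_s: np.ndarray  # (T,) instantaneous cell speed
    spot_pos_um: np.ndarray  # (T, n_spots) along-axis position; NaN outside lifetime
    spot_v_um_s: np.ndarray  # (T, n_spots) cell-frame velocity; NaN outside lifetime
    events: dict = field(default_factory=dict)  # {"start": [...], "stop": [...], "reversal": [...]}


def _wrap_half(angle_deg: np.ndarray | float):
    """Wrap an angle to the half-open interval (-90, 90]."""
    a = (np.asarray(angle_deg) + 90.0) % 180.0 - 90.0
    return np.where(a == -90.0, 90.0, a)


def _displacement(trajectory, t: float) -> np.ndarray:
    """Exact integral of the piecewise-constant velocity up to time t."""
    d = np.zeros(2)
    for t0, t1, v, heading in trajectory:
        dt = min(t, t1) - t0
        if dt > 0:
            d += v * dt * _axis_unit(heading)
    return d


def _active_segment(trajectory, t: float):
    for seg in trajectory:
        if seg[0] <= t < seg[1]:
            return seg
    # final boundary is inclusive so the last frame of a movie that ends
    # mid-glide still reports the gliding speed
    t_max = max((seg[1] for seg in trajectory), default=None)
    if t_max is not None and t == t_max:
        for seg in trajectory:
            if seg[1] == t_max:
                return seg
    return None


def _segment_events(trajectory) -> dict:
    """Classify velocity-vector changes at segment boundaries."""
    events: dict = {"start": [], "stop": [], "reversal": []}
    moving = [(t0, t1, v * _axis_unit(h)) for t0, t1, v, h in sorted(trajectory) if v != 0]
    prev_end, prev_vec = None, None
    for t0, t1, vec in moving:
        if prev_end is None or t0 > prev_end + 1e-12:
            events["start"].append(t0)
            if prev_end is not None:
                events["stop"].append(prev_end)
        elif prev_vec is not None and float(np.dot(prev_vec, vec)) < 0:
            events["reversal"].append(t0)
        prev_end, prev_vec = t1, vec
    if prev_end is not None:
        events["stop"].append(prev_end)
    return events


def _add_gaussian(frame: np.ndarray, cx: float, cy: float, sigma: float, amp: float) -> None:
    """Accumulate an isotropic Gaussian, evaluated analytically at pixel centres."""
    h, w = frame.shape
    r = 4.0 * sigma
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = amp * np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    frame[y0:y1, x0:x1] += g


def _add_ridge(
    frame: np.ndarray,
    cx: float,
    cy: float,
    axis: np.ndarray,
    sigma_long: float,
    sigma_short: float,
    amp: float,
) -> None:
    """Accumulate an anisotropic Gaussian ridge oriented along ``axis``."""
    h, w = frame.shape
    r_l, r_s = 4.0 * sigma_long, 4.0 * sigma_short
    rx = abs(axis[0]) * r_l + abs(axis[1]) * r_s
    ry = abs(axis[1]) * r_l + abs(axis[0]) * r_s
    x0, x1 = max(0, int(cx - rx)), min(w, int(cx + rx) + 2)
    y0, y1 = max(0, int(cy - ry)), min(h, int(cy + ry) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    dx, dy = np.meshgrid(xs, ys)
    u = dx * axis[0] + dy * axis[1]
    v = -dx * axis[1] + dy * axis[0]
    g = amp * np.exp(-(u**2) / (2.0 * sigma_long**2) - v**2 / (2.0 * sigma_short**2))
    frame[y0:y1, x0:x1] += g


def generate_gliding_movie(scenario: GlidingScenario) -> tuple[CalibratedStack, GroundTruth]:
    """Render a dual-channel gliding-cell movie and its exact ground truth.

    Raises
    ------
    ValueError
        If the cell body lies fully outside the field of view in any frame
        (the error message names the first offending frame).
    """
    sc = scenario
    px = sc.pixel_size
    h, w = sc.fov
    times = sc.frame_times()
    n = len(times)

    # trajectory integration (exact, in um)
    disp = np.array([_displacement(sc.trajectory, t) for t in times])
    if sc.start_center_um is None:
        # centre the swept path in the FOV
        mid = 0.5 * (disp.min(axis=0) + disp.max(axis=0))
        start = np.array([w, h]) * px / 2.0 - mid
    else:
        start = np.asarray(sc.start_center_um, dtype=float)
    centers = start + disp

    headings = np.empty(n)
    speeds = np.empty(n)
    last_heading = sc.trajectory[0][3] if sc.trajectory else 0.0
    for i, t in enumerate(times):
        seg = _active_segment(sc.trajectory, t)
        if seg is None:
            speeds[i] = 0.0
            headings[i] = last_heading
        else:
            speeds[i] = abs(seg[2])
            headings[i] = seg[3]
            last_heading = seg[3]

    # cell-frame spot kinematics
    n_spots = len(sc.myosin_spots)
    spot_pos = np.full((n, n_spots), np.nan)
    spot_v = np.full((n, n_spots), np.nan)
    for j, (s0, v_cf, _amp, t0, t1) in enumerate(sc.myosin_spots):
        alive = (times >= t0) & (times <= t1)
        spot_pos[alive, j] = s0 + v_cf * (times[alive] - t0)
        spot_v[alive, j] = v_cf

    # FOV containment check (cell segment bounding box vs image rectangle)
    half = sc.cell_length / 2.0
    for i in range(n):
        a = _axis_unit(headings[i])
        p0 = (centers[i] - half * a) / px
        p1 = (centers[i] + half * a) / px
        lo = np.minimum(p0, p1)
        hi = np.maximum(p0, p1)
        if hi[0] < 0 or lo[0] > w - 1 or hi[1] < 0 or lo[1] > h - 1:
            raise ValueError(f"cell fully outside the field of view at frame {i}")

    rng = np.random.default_rng(sc.rng_seed)
    data = np.full((n, 2, h, w), sc.background, dtype=np.float32)
    sig_chl = [d * FWHM_TO_SIGMA / px for d in sc.chloroplast_diameters]
    sig_spot = sc.spot_sigma_um / px
    sig_long = sc.cell_length / 4.0 / px
    sig_raphe = sc.raphe_sigma_um / px

    # the structural (frustule) axis is the heading modulo 180: a directional
    # reversal flips the velocity, not the cell body
    for i in range(n):
        a = _axis_unit(float(_wrap_half(headings[i])))
        c_px = centers[i] / px
        gfp = data[i, 0]
        chl = data[i, 1]
        _add_ridge(gfp, c_px[0], c_px[1], a, sig_long, sig_raphe, sc.ridge_intensity)
        for j in range(n_spots):
            if np.isfinite(spot_pos[i, j]):
                p = c_px + spot_pos[i, j] / px * a
                _add_gaussian(gfp, p[0], p[1], sig_spot, sc.myosin_spots[j][2])
        for off, sig in zip(sc.chloroplast_offsets, sig_chl):
            p = c_px + off / px * a
            _add_gaussian(chl, p[0], p[1], sig, sc.chloroplast_intensity)

    for (f0, f1), (r0, r1), amp in sc.stripe_events:
        data[f0:f1, 0, r0:r1, :] += amp

    if sc.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(np.float32)
    if sc.noise_sd > 0:
        for i in range(n):  # per-frame chunks keep the working set small
            data[i] += sc.noise_sd * rng.standard_normal((2, h, w), dtype=np.float32)

    stack = CalibratedStack(
        data,
        pixel_size=px,
        frame_interval=sc.frame_interval,
        channels=("gfp", "chloroplast"),
    )
    truth = GroundTruth(
        t_s=times,
        center_um=centers,
        angle_deg=np.asarray(_wrap_half(headings), dtype=float),
        v_um_s=speeds,
        spot_pos_um=spot_pos,
        spot_v_um_s=spot_v,
        events=_segment_events(sc.trajectory),
    )
    return stack, truth


def standard_spot_train(
    duration: float,
    cell_length: float = 40.0,
    v_cell_frame: float = -6.0,
    intensity: float = 200.0,
    spawn_interval: float = 1.25,
) -> list[tuple[float, float, float, float, float]]:
    """Staggered myosin spots traversing the cell at one cell-frame velocity.

    Spots enter at one cell pole every ``spawn_interval`` seconds and travel
    to the other pole (the dense, parallel-trace regime of smooth sustained
    gliding).  Negative velocity runs from the +axis pole toward the -axis
    pole.
    """
    half = cell_length / 2.0
    transit = cell_length / abs(v_cell_frame)
    start = half if v_cell_frame < 0 else -half
    spots = []
    t = 0.0
    while t < duration:
        spots.append((start, v_cell_frame, intensity, t, min(t + transit, duration)))
        t += spawn_interval
    return spots


def reversal_spot_train(
    duration: float,
    t_event: float,
    cell_length: float = 40.0,
    speed: float = 6.0,
    intensity: float = 200.0,
    spawn_interval: float = 1.25,
) -> list[tuple[float, float, float, float, float]]:
    """Spot population for a quasi-instantaneous directional reversal.

    Before ``t_event`` spots run at ``-speed`` (cell gliding toward +axis);
    at the event every live spot reverses in place to ``+speed`` and fresh
    spots keep entering from the -axis pole, so the trace density is
    symmetric about the event.
    """
    half = cell_length / 2.0
    transit = cell_length / speed
    spots = []
    t = 0.0
    while t < t_event:
        t_end = min(t + transit, t_event)
        spots.append((half, -speed, intensity, t, t_end))
        if t_end == t_event:  # still alive at the event: reverse in place
            pos = half - speed * (t_event - t)
            exit_t = t_event + (half - pos) / speed
            spots.append((pos, speed, intensity, t_event, min(exit_t, duration)))
        t += spawn_interval
    t = t_event + spawn_interval
    while t < duration:
        spots.append((-half, speed, intensity, t, min(t + transit, duration)))
        t += spawn_interval
    return spots


@dataclass
class PopulationGroundTruth:
    """Truth for a population movie: positions in um, per-cell summaries."""

    t_s: np.ndarray  # (T,)
    positions_um: np.ndarray  # (T, n_cells, 2)
    mean_speeds_um_s: np.ndarray  # (n_cells,)
    path_lengths_um: np.ndarray  # (n_cells,)


def generate_population_movie(
    n_cells: int,
    duration: float,
    speeds: list[float] | np.ndarray,
    pixel_size: float = 0.91,
    frame_interval: float = 1.0,
    rng_seed: int = 0,
    fov: tuple[int, int] = (384, 384),
    cell_length: float = 40.0,
    cell_width: float = 5.0,
    background: float = 1000.0,
    cell_contrast: float = 500.0,
    noise_sd: float = 10.0,
    curvature_deg_s: float = 0.2,
) -> tuple[CalibratedStack, PopulationGroundTruth]:
    """Render a brightfield-like movie of dark elongated cells gliding.

    Cells start at non-overlapping random positions, head roughly toward the
    field centre and follow gently curved constant-speed paths (heading drifts
    at up to ``curvature_deg_s``).  The defaults mirror the low-magnification
    motility assay: 0.91 um/px at 1 frame per second.

    Raises
    ------
    ValueError
        If ``n_cells < 1``, or if non-overlapping initial placements cannot be
        found within 100 attempts per cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    speeds = np.asarray(speeds, dtype=float)
    if speeds.shape != (n_cells,):
        raise ValueError(f"need {n_cells} speeds, got {speeds.shape}")
    rng = np.random.default_rng(rng_seed)
    h, w = fov
    n = int(round(duration / frame_interval)) + 1
    times = np.arange(n) * frame_interval

    # non-overlapping initial placement
    margin = cell_length / 2.0 + 2.0  # um
    min_sep = cell_length
    starts: list[np.ndarray] = []
    for _ in range(n_cells):
        for attempt in range(100):
            cand = np.array(
                [
                    rng.uniform(margin, w * pixel_size - margin),
                    rng.uniform(margin, h * pixel_size - margin),
                ]
            )
            if all(np.linalg.norm(cand - s) > min_sep for s in starts):
                starts.append(cand)
                break
        else:
            raise ValueError("could not place cells without overlap after 100 attempts")

    centre = np.array([w, h]) * pixel_size / 2.0
    positions = np.zeros((n, n_cells, 2))
    headings = np.zeros((n, n_cells))
    for j, s in enumerate(starts):
        to_centre = centre - s
        base = math.degrees(math.atan2(-to_centre[1], to_centre[0]))
        h0 = base + rng.uniform(-30.0, 30.0)
        drift = rng.uniform(-curvature_deg_s, curvature_deg_s)
        headings[:, j] = h0 + drift * times
        pos = s.copy()
        for i, t in enumerate(times):
            positions[i, j] = pos
            pos = pos + speeds[j] * frame_interval * _axis_unit(headings[i, j])

    sig_l = cell_length / 4.0 / pixel_size
    sig_w = cell_width / 4.0 / pixel_size
    data = np.full((n, 1, h, w), background, dtype=np.float32)
    for i in range(n):
        for j in range(n_cells):
            p = positions[i, j] / pixel_size
            _add_ridge(
                data[i, 0], p[0], p[1], _axis_unit(headings[i, j]), sig_l, sig_w, -cell_contrast
            )
    if noise_sd > 0:
        for i in range(n):
            data[i] += noise_sd * rng.standard_normal((1, h, w), dtype=np.float32)

    steps = np.linalg.norm(np.diff(positions, axis=0), axis=2)  # (n-1, n_cells)
    path_lengths = steps.sum(axis=0)
    durations = (n - 1) * frame_interval
    stack = CalibratedStack(
        data,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channels=("brightfield",),
    )
    truth = PopulationGroundTruth(
        t_s=times,
        positions_um=positions,
        mean_speeds_um_s=path_lengths / durations if n > 1 else np.zeros(n_cells),
        path_lengths_um=path_lengths,
    )
    return stack, truth
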