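"""Shared fixtures: small synthetic scenarios and the full pipeline runs.

The two session-scoped pipeline runs (steady gliding and reversal) are
expensive relative to the rest of the suite, so every test that needs a
realistic movie shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

import glidekymo as gk
from glidekymo.synthetic import reversal_spot_train, standard_spot_train


def make_small_scenario(**overrides) -> gk.GlidingScenario:
    """A cheap noise-free scenario for unit tests (4 s, small FOV)."""
    kw = dict(
        duration=4.0,
        frame_interval=0.1,
        pixel_size=0.13,
        fov=(96, 320),
        cell_length=24.0,
        chloroplast_offsets=(-8.0, 8.0),
        trajectory=[(0.0, 4.0, 2.0, 0.0)],
        noise_sd=0.0,
        rng_seed=0,
    )
    kw.update(overrides)
    return gk.GlidingScenario(**kw)


def run_pipeline(scenario: gk.GlidingScenario, spot_diameter: float = 6.0) -> dict:
    """Run tracking -> registration -> kymograph on a gliding scenario."""
    stack, truth = gk.generate_gliding_movie(scenario)
    dets = gk.detect_chloroplasts(stack, spot_diameter)
    track_a, track_b = gk.link_tracks(dets, stack.n_frames)
    pose = gk.compute_cell_pose(track_a, track_b)
    trace = gk.compute_velocity_trace(
        pose, scenario.pixel_size, scenario.frame_interval, window=20
    )
    ref = gk.select_reference_frame(pose, scenario.fov)
    registered = gk.register_stack(stack, pose, ref, channel="gfp")
    kymo = gk.build_kymograph(registered, channel="gfp")
    filtered = gk.fourier_stripe_filter(kymo)
    return {
        "scenario": scenario,
        "stack": stack,
        "truth": truth,
        "detections": dets,
        "tracks": (track_a, track_b),
        "pose": pose,
        "trace": trace,
        "ref": ref,
        "registered": registered,
        "kymo": kymo,
        "kymo_filtered": filtered,
    }


def standard_scenario() -> gk.GlidingScenario:
    """The reference study conditions: 25 s at 10 fps and 130 nm/px, cell
    gliding at 2 um/s toward +x, myosin spots at -6 um/s in the cell frame,
    spot SNR 10, occasional stripe artefacts."""
    return gk.GlidingScenario(
        duration=25.0,
        frame_interval=0.1,
        pixel_size=0.13,
        fov=(96, 768),
        cell_length=40.0,
        trajectory=[(0.0, 25.0, 2.0, 0.0)],
        myosin_spots=standard_spot_train(25.0, cell_length=40.0, v_cell_frame=-6.0),
        noise_sd=20.0,
        stripe_events=[((50, 70), (0, 96), 80.0), ((150, 160), (30, 60), 120.0)],
        rng_seed=11,
    )


def reversal_scenario() -> gk.GlidingScenario:
    """Quasi-instantaneous reversal at t = 10.05 s: the cell flips direction
    and every live myosin spot reverses in place."""
    t_event = 10.05
    return gk.GlidingScenario(
        duration=20.0,
        frame_interval=0.1,
        pixel_size=0.13,
        fov=(96, 640),
        cell_length=40.0,
        trajectory=[(0.0, t_event, 2.0, 0.0), (t_event, 20.0, 2.0, 180.0)],
        myosin_spots=reversal_spot_train(20.0, t_event, cell_length=40.0, speed=6.0),
        noise_sd=20.0,
        rng_seed=5,
    )


@pytest.fixture(scope="session")
def standard_run() -> dict:
    return run_pipeline(standard_scenario())


@pytest.fixture(scope="session")
def reversal_run() -> dict:
    return run_pipeline(reversal_scenario())


def render_trace_kymograph(
    velocity_um_s: float,
    pixel_size: float = 0.13,
    frame_interval: float = 0.1,
    n_rows: int = 100,
    n_cols: int = 256,
    trace_sigma_px: float = 2.0,
    amplitude: float = 10.0,
    noise_sd: float = 2.0,
    spacing_px: float = 24.0,
    seed: int = 0,
) -> gk.Kymograph:
    """Kymograph of one parallel trace family at a known velocity.

    Traces are Gaussian line profiles entering at regular spacings, so every
    row holds several trace cross-sections; additive noise sets the SNR
    (amplitude / noise_sd).
    """
    rng = np.random.default_rng(seed)
    slope = velocity_um_s * frame_interval / pixel_size  # px per row
    data = np.zeros((n_rows, n_cols))
    x = np.arange(n_cols)
    span = abs(slope) * n_rows + n_cols
    offsets = np.arange(-span, span, spacing_px)
    for t in range(n_rows):
        centers = offsets + slope * t
        for c in centers:
            if -4 * trace_sigma_px < c < n_cols + 4 * trace_sigma_px:
                data[t] += amplitude * np.exp(-((x - c) ** 2) / (2 * trace_sigma_px**2))
    if noise_sd > 0:
        data += rng.normal(0, noise_sd, data.shape)
    return gk.Kymograph(data, pixel_size=pixel_size, frame_interval=frame_interval)
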