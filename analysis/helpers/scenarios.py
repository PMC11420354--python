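"""The study conditions shared by the analysis scripts.

These mirror the session-scoped fixtures the test suite uses: a 25 s steady
glide at 2 um/s with a -6 um/s myosin spot train, and a 20 s movie with a
quasi-instantaneous reversal at t = 10.05 s.
"""

import numpy as np

import glidekymo as gk
from glidekymo.synthetic import reversal_spot_train, standard_spot_train


def standard_scenario(seed_offset: int = 0) -> gk.GlidingScenario:
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
        rng_seed=11 + seed_offset,
    )


def reversal_scenario(seed_offset: int = 0) -> gk.GlidingScenario:
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
        rng_seed=5 + seed_offset,
    )


def population_speeds(seed: int, n_cells: int = 12) -> np.ndarray:
    """Log-normal per-cell gliding speeds, median ~1.5 um/s, capped at 4."""
    rng = np.random.default_rng(seed + 2000)
    return np.minimum(rng.lognormal(np.log(1.5), 0.4, n_cells), 4.0)
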