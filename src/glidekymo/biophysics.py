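"""Low-Reynolds-number drag estimates for a gliding diatom.

At micrometre scales and um/s speeds the Reynolds number is ~1e-6, so viscous
drag is given by Stokes-regime closed forms.  The cell body is modelled as a
hemispherically-capped cylinder (capsule); since the capsule has no exact
Stokes solution, its drag is approximated by axial translation of the prolate
spheroid with the same diameter and overall length (Oberbeck's closed form),
which reduces exactly to the Stokes sphere as length -> diameter.

Units: micrometres, um/s, mPa*s in; piconewtons out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DragModel", "stokes_drag", "drag_length_sweep"]


@dataclass
class DragModel:
    """Geometry and conditions for a drag estimate.

    shape: "sphere", "capsule" or "prolate"; ``length`` is the overall body
    length (tip to tip) for capsule/prolate and ignored for the sphere;
    viscosity defaults to water at 20 C.
    """

    shape: str
    diameter: float  # um
    velocity: float  # um/s
    length: float | None = None  # um, capsule/prolate only
    viscosity: float = 1.0  # mPa*s

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "capsule", "prolate"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.diameter <= 0 or self.viscosity <= 0:
            raise ValueError("diameter and viscosity must be positive")
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if self.shape in ("capsule", "prolate"):
            if self.length is None:
                raise ValueError(f"{self.shape} needs a length")
            if self.length < self.diameter:
                raise ValueError("length must be at least the diameter")


def _prolate_axial_drag_N(a_m: float, b_m: float, v_m_s: float, eta_pa_s: float) -> float:
    """Oberbeck drag (N) for a prolate spheroid (semi-axes a >= b) translating
    along its symmetry axis: F = 16 pi eta a e^3 v / [(1+e^2) L - 2e],
    with e the eccentricity and L = ln((1+e)/(1-e))."""
    if a_m == b_m:
        return 6.0 * math.pi * eta_pa_s * a_m * v_m_s
    e = math.sqrt(1.0 - (b_m / a_m) ** 2)
    if e < 1e-3:
        # series in e avoids catastrophic cancellation near the sphere limit:
        # (1+e^2) L - 2e = 8e^3/3 + 16e^5/15 + 24e^7/35 + O(e^9)
        denom = 8.0 * e**3 / 3.0 + 16.0 * e**5 / 15.0 + 24.0 * e**7 / 35.0
    else:
        big_l = math.log1p(e) - math.log1p(-e)
        denom = (1.0 + e**2) * big_l - 2.0 * e
    return 16.0 * math.pi * eta_pa_s * a_m * e**3 * v_m_s / denom


def stokes_drag(model: DragModel) -> float:
    """Viscous drag force in piconewtons.

    Sphere: ``6 pi eta r v``.  Capsule/prolate: prolate-spheroid axial
    translation with semi-major axis length/2 and semi-minor diameter/2.
    """
    eta = model.viscosity * 1e-3  # mPa*s -> Pa*s
    v = model.velocity * 1e-6  # um/s -> m/s
    b = model.diameter / 2.0 * 1e-6
    if model.shape == "sphere":
        force_n = 6.0 * math.pi * eta * b * v
    else:
        a = model.length / 2.0 * 1e-6
        force_n = _prolate_axial_drag_N(a, b, v, eta)
    return force_n * 1e12  # N -> pN


def drag_length_sweep(
    diameter: float = 6.0,
    velocity: float = 4.0,
    viscosity: float = 1.0,
    lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Capsule drag (pN) over a sweep of body lengths.

    Defaults cover the plausible cell range 6-50 um at the assay's fastest
    gliding speed; the maximum of the returned forces is the conservative
    bound on the drag a gliding cell must overcome.
    """
    if lengths is None:
        lengths = np.linspace(diameter, 50.0, 221)
    lengths = np.asarray(lengths, dtype=float)
    forces = np.array(
        [
            stokes_drag(DragModel("capsule", diameter, velocity, length=l, viscosity=viscosity))
            for l in lengths
        ]
    )
    return lengths, forces
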