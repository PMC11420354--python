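"""Rigid registration of the GFP channel into the cell's reference frame.

A reference frame is chosen where the cell is closest to horizontal and to
the field centre; every other frame is then translated so its cell centre
lands on the reference centre and rotated about that centre by the angle
difference, cancelling whole-cell motion so that only intracellular motion
remains.  Transforms are rigid with bilinear interpolation; pixels pulled in
from outside the canvas are zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CalibratedStack
from .tracking import CellPose

__all__ = ["ReferenceFrame", "select_reference_frame", "register_stack"]


@dataclass
class ReferenceFrame:
    index: int
    center: tuple[float, float]  # (x, y) px
    angle_deg: float  # in (-90, 90]


def pose_score(pose: CellPose, fov: tuple[int, int]) -> np.ndarray:
    """Per-frame badness score: |angle|/90 + centre offset / half-diagonal.

    Lower is better; invalid frames score +inf.
    """
    h, w = fov
    fov_center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    half_diag = math.hypot(w, h) / 2.0
    dist = np.linalg.norm(pose.center - fov_center, axis=1)
    score = np.abs(pose.angle_deg) / 90.0 + dist / half_diag
    return np.where(pose.valid, score, np.inf)


def select_reference_frame(pose: CellPose, fov: tuple[int, int]) -> ReferenceFrame:
    """Pick the valid frame minimizing :func:`pose_score`; ties -> earliest."""
    score = pose_score(pose, fov)
    if not np.isfinite(score).any():
        raise ValueError("no valid frames to select a reference from")
    idx = int(np.argmin(score))  # argmin returns the first minimum
    return ReferenceFrame(
        index=idx,
        center=(float(pose.center[idx, 0]), float(pose.center[idx, 1])),
        angle_deg=float(pose.angle_deg[idx]),
    )


def register_stack(
    stack: CalibratedStack,
    pose: CellPose,
    ref: ReferenceFrame,
    channel: str | None = None,
) -> CalibratedStack:
    """Map every frame into the reference cell frame (translate, then rotate).

    Frame i is translated by (ref.center - center_i) and then rotated about
    ``ref.center`` by (ref.angle - angle_i).  Frames with an invalid pose come
    out all-zero and are flagged False in ``frame_valid``.

    ``channel`` restricts the output to one channel (the usual case: register
    the GFP channel with the pose tracked on the chloroplast channel); by
    default all channels are transformed identically.
    """
    if len(pose.center) != stack.n_frames:
        raise ValueError("pose must cover every frame of the stack")
    if channel is not None:
        data = stack.channel(channel)[:, None]
        labels: tuple[str, ...] = (channel,)
    else:
        data = stack.data
        labels = stack.channels
    t, c, h, w = data.shape
    out = np.zeros_like(data, dtype=np.float32)
    cr = np.array(ref.center)  # (x, y)
    valid = pose.valid.copy()
    for i in range(t):
        if not valid[i]:
            continue
        dth = math.radians(ref.angle_deg - pose.angle_deg[i])
        cth, sth = math.cos(dth), math.sin(dth)
        # forward map (image coords, y down): p_out = M (p - c_ref) + c_ref with
        # p already translated by (c_ref - c_i); mathematical CCW rotation by
        # dth appears in y-down coordinates as M = [[c, s], [-s, c]].
        # Inverse map used for resampling: q_in = M^T (p_out - c_ref) + c_i.
        ci = pose.center[i]
        # build in (row, col) = (y, x) ordering for affine_transform
        # M^T on (x, y): [[c, -s], [s, c]] -> on (y, x): [[c, s], [-s, c]]
        a_yx = np.array([[cth, sth], [-sth, cth]])
        offset = np.array([ci[1], ci[0]]) - a_yx @ np.array([cr[1], cr[0]])
        for ch in range(c):
            out[i, ch] = ndimage.affine_transform(
                data[i, ch].astype(np.float64),
                a_yx,
                offset=offset,
                order=1,
                mode="constant",
                cval=0.0,
            )
    return CalibratedStack(
        out,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        channels=labels,
        frame_valid=valid,
    )
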