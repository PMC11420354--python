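"""Calibrated image stacks and result serialization.

A :class:`CalibratedStack` is the in-memory container every pipeline stage
consumes: a ``T x C x H x W`` intensity array plus the two calibration
constants the analysis needs (pixel size in micrometres, frame interval in
seconds).  Stacks round-trip through plain multi-page TIFF with an
ImageJ-compatible metadata block, so they open directly in Fiji.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "CalibratedStack",
    "read_stack",
    "write_stack",
    "write_results",
]


@dataclass
class CalibratedStack:
    """Time-lapse image stack with physical calibration.

    Parameters
    ----------
    data:
        Intensities, shape ``(T, C, H, W)``.  Single-channel movies use C=1.
    pixel_size:
        Micrometres per pixel (isotropic).
    frame_interval:
        Seconds between consecutive frames.
    channels:
        Unique channel labels, e.g. ``("gfp", "chloroplast")``.
    frame_valid:
        Optional boolean mask (length T); False marks frames that carry no
        usable content (e.g. emitted blank by registration).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channels: tuple[str, ...] = ("ch0",)
    frame_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # (T, H, W) convenience
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be (T, C, H, W), got shape {self.data.shape}")
        t, c, h, w = self.data.shape
        if min(t, h, w) < 1:
            raise ValueError("stack must have T, H, W >= 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if len(self.channels) != c:
            raise ValueError(f"{c} channels but {len(self.channels)} labels")
        if len(set(self.channels)) != c:
            raise ValueError("channel labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel(self, label: str) -> np.ndarray:
        """Return the (T, H, W) array for one named channel."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None
        return self.data[:, idx]


def write_stack(stack: CalibratedStack, path: str | os.PathLike) -> None:
    """Write a stack as ImageJ-style TIFF (TZCYX order, calibration in metadata).

    Integer data is written as 16-bit unsigned (clipped); float data as 32-bit
    float, which ImageJ also reads.
    """
    data = stack.data
    if np.issubdtype(data.dtype, np.integer):
        out = np.clip(data, 0, 65535).astype(np.uint16)
    else:
        out = data.astype(np.float32)
    # ImageJ axis order TCYXS; tifffile infers from shape + metadata axes
    tifffile.imwrite(
        os.fspath(path),
        out,
        imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={
            "axes": "TCYX",
            "unit": "um",
            "finterval": stack.frame_interval,
            "Labels": list(stack.channels),
        },
    )


def read_stack(
    path: str | os.PathLike,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channels: tuple[str, ...] | None = None,
) -> CalibratedStack:
    """Read a TIFF stack; calibration from metadata when present, else overrides.

    Raises
    ------
    ValueError
        If neither file metadata nor overrides provide a calibration value.
    """
    with tifffile.TiffFile(os.fspath(path)) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        px = None
        page = tif.pages[0]
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                px = den / num
        fi = meta.get("finterval")
        labels = meta.get("Labels")
    if pixel_size is not None:
        px = pixel_size
    if frame_interval is not None:
        fi = frame_interval
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata and no override given")
    if fi is None:
        raise ValueError(f"{path}: no frame interval in metadata and no override given")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    n_ch = data.shape[1]
    if channels is None:
        if labels and len(labels) >= n_ch:
            channels = tuple(labels[:n_ch])
        else:
            channels = tuple(f"ch{i}" for i in range(n_ch))
    return CalibratedStack(data, float(px), float(fi), channels)


def _canonical(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _canonical(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """SHA-256 over a canonical JSON serialization of a config object."""
    payload = json.dumps(_canonical(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def write_results(
    out_dir: str | os.PathLike,
    tables: dict | None = None,
    kymographs: dict | None = None,
    config=None,
    seed: int | None = None,
) -> dict:
    """Write CSV tables and TIFF kymographs plus a JSON manifest.

    ``tables`` maps name -> pandas DataFrame; ``kymographs`` maps
    name -> :class:`~glidekymo.kymograph.Kymograph`.  The manifest records the
    config hash and seed so a run is reproducible bit-for-bit.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"tables": {}, "kymographs": {}, "seed": seed}
    if config is not None:
        manifest["config_hash"] = config_hash(config)
        manifest["config"] = _canonical(config)
    for name, df in (tables or {}).items():
        path = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(path, index=False)
        manifest["tables"][name] = os.path.basename(path)
    for name, kymo in (kymographs or {}).items():
        path = os.path.join(out_dir, f"{name}.tif")
        tifffile.imwrite(
            path,
            np.asarray(kymo.data, dtype=np.float32),
            imagej=True,
            resolution=(1.0 / kymo.pixel_size, 1.0 / kymo.pixel_size),
            metadata={"unit": "um", "finterval": kymo.frame_interval},
        )
        manifest["kymographs"][name] = os.path.basename(path)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
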