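"""Mapping the FLUO digital plant onto the VIS and NIR frames.

The platform's sensors are co-mounted, so a fixed resize-plus-shift maps
the fluorescence frame onto each of the other two frames: the FLUO raster
is resized to a calibrated width (2900 px toward VIS, 380 px toward NIR,
proportional height) and the result is offset by calibrated shifts
((-290 + a, -122 + b) and (-30 + a, -12 + b) pixels).  The digital-plant
mask rides along: its resized, shifted footprint selects the pixels that
constitute the same plant in the target sensor.

Only coordinates are transformed — target images are never resampled, so
the NIR intensity statistics read genuine sensor values.  The mask itself
is resized nearest-neighbour into the resized frame (the same dense
footprint a resized mask image would have), then looked up in the target;
out-of-frame positions are counted, not read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .imaging_io import PlatformConfig, Sensor, SensorImage, round_half_away
from .segmentation import DigitalPlant, mask_from_coords

__all__ = [
    "RegistrationTransform",
    "SensorPlantPixels",
    "scale_coords",
    "resized_dims",
    "transfer_mask",
    "projected_area",
]


@dataclass(frozen=True)
class RegistrationTransform:
    """Resize-to-width plus pixel shift from the FLUO frame to a target.

    ``shift`` is the (dx, dy) the target pixels are displaced by; a scaled
    mask coordinate u lands on target pixel u - dx (see transfer_mask).
    """

    source_dims: tuple[int, int]  # FLUO (W, H)
    resize_width: float
    shift: tuple[float, float]

    def __post_init__(self) -> None:
        if self.resize_width <= 0:
            raise ValueError("resize width must be positive")
        if self.source_dims[0] <= 0 or self.source_dims[1] <= 0:
            raise ValueError("source dims must be positive")

    @property
    def scale(self) -> float:
        return self.resize_width / self.source_dims[0]

    @classmethod
    def for_vis(cls, cfg: PlatformConfig) -> "RegistrationTransform":
        return cls(cfg.fluo_dims, cfg.fluo_to_vis_width, cfg.vis_shift_total)

    @classmethod
    def for_nir(cls, cfg: PlatformConfig) -> "RegistrationTransform":
        return cls(cfg.fluo_dims, cfg.fluo_to_nir_width, cfg.nir_shift_total)

    @classmethod
    def for_sensor(cls, sensor: Sensor, cfg: PlatformConfig) -> "RegistrationTransform":
        if sensor is Sensor.VIS:
            return cls.for_vis(cfg)
        if sensor is Sensor.NIR:
            return cls.for_nir(cfg)
        return cls(cfg.fluo_dims, float(cfg.fluo_dims[0]), (0.0, 0.0))


@dataclass
class SensorPlantPixels:
    """Per-sensor channel values of one digital plant.

    ``values`` is (n,) uint8 for NIR or (n, 3) uint8 for VIS/FLUO, read at
    the in-bounds mask-mapped coordinates ``coords`` ((n, 2) int (x, y) in
    the target frame).  ``n_out_of_bounds`` counts resized-frame mask
    pixels whose mapped position fell outside the target raster, so that
    values + out-of-bounds = resized mask footprint.
    """

    sample_id: str
    das: int
    sensor: Sensor
    values: np.ndarray
    coords: np.ndarray
    n_out_of_bounds: int

    @property
    def n_pixels(self) -> int:
        return int(self.values.shape[0])


def scale_coords(coords: np.ndarray, t: RegistrationTransform) -> np.ndarray:
    """Map FLUO-frame (x, y) coordinates into the resized frame.

    (x, y) -> (round(x*s), round(y*s)) with s = resize_width/source_width,
    rounding half away from zero, applied once.
    """
    coords = np.asarray(coords)
    return round_half_away(coords * t.scale)


def resized_dims(t: RegistrationTransform) -> tuple[int, int]:
    """(W, H) of the resized frame: calibrated width, proportional height."""
    w = int(round_half_away(t.resize_width))
    h = int(round_half_away(t.source_dims[1] * t.scale))
    return (w, h)


def transfer_mask(
    plant: DigitalPlant,
    t: RegistrationTransform,
    target: SensorImage,
) -> SensorPlantPixels:
    """Read the target-sensor pixel values under the digital-plant mask.

    The FLUO mask is resized nearest-neighbour to the calibrated width
    (dense footprint, matching a resize of the mask image itself), each
    resized coordinate (u, v) is then read from the target at
    (u - dx, v - dy).  Coordinates outside the target are counted, not
    read; each target coordinate is read once.
    """
    if target.width <= 0 or target.height <= 0:
        raise ValueError("target image has zero dimensions")
    src_w, src_h = t.source_dims
    s = t.scale
    rw, rh = resized_dims(t)
    mask = mask_from_coords(plant.coords, (src_w, src_h))
    # nearest source pixel for every resized pixel (inverse mapping)
    src_x = np.clip(round_half_away(np.arange(rw) / s), 0, src_w - 1)
    src_y = np.clip(round_half_away(np.arange(rh) / s), 0, src_h - 1)
    resized = mask[np.ix_(src_y, src_x)]
    vs, us = np.nonzero(resized)
    dx, dy = t.shift
    tx = round_half_away(us - dx)
    ty = round_half_away(vs - dy)
    inb = (tx >= 0) & (tx < target.width) & (ty >= 0) & (ty < target.height)
    values = target.pixels[ty[inb], tx[inb]]
    coords = np.column_stack([tx[inb], ty[inb]])
    return SensorPlantPixels(
        sample_id=plant.sample_id,
        das=plant.das,
        sensor=target.sensor,
        values=values,
        coords=coords,
        n_out_of_bounds=int((~inb).sum()),
    )


def projected_area(plant: Optional[DigitalPlant]) -> Optional[int]:
    """Projected leaf area: pixel count in the native FLUO frame.

    None in, None out — a pot without a digital plant has no area.
    """
    if plant is None:
        return None
    return plant.area


def pixels_to_csv(px: SensorPlantPixels, path: str | Path) -> None:
    """Per-pixel sidecar: x, y plus value (NIR) or r, g, b (VIS/FLUO)."""
    if px.values.ndim == 1:
        df = pd.DataFrame({"x": px.coords[:, 0], "y": px.coords[:, 1], "value": px.values})
    else:
        df = pd.DataFrame(
            {
                "x": px.coords[:, 0],
                "y": px.coords[:, 1],
                "r": px.values[:, 0],
                "g": px.values[:, 1],
                "b": px.values[:, 2],
            }
        )
    df.to_csv(path, index=False)


def pixels_from_csv(path: str | Path, sample_id: str, das: int, sensor: Sensor) -> SensorPlantPixels:
    df = pd.read_csv(path)
    coords = df[["x", "y"]].to_numpy(dtype=np.int64)
    if "value" in df.columns:
        values = df["value"].to_numpy(dtype=np.uint8)
    else:
        values = df[["r", "g", "b"]].to_numpy(dtype=np.uint8)
    return SensorPlantPixels(sample_id, das, Sensor(sensor), values, coords, 0)
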