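"""Raster I/O, color-space conversion, platform constants and tray layouts.

A screening platform images each tray with three co-registered sensors: a
visible-light color camera (VIS, 2454x2056), a fluorescence color camera
(FLUO, 1390x1038) and a near-infrared camera (NIR, 320x254, one 8-bit
channel).  Chlorophyll fluorescence makes rosettes bright against soil in the
FLUO frame, which is why segmentation happens there; the VIS frame carries
leaf color and the NIR frame carries a reflectance signal that rises as leaf
water content falls.

This module holds the shared raster containers, the HSB (hue-saturation-
brightness) conversion used by both the segmentation threshold and the hue
profiling, the platform constants, and the tray-layout / inspection-label
tables.  HSB channels are kept as floats on the 0-255 scale: brightness is
exactly max(R, G, B) and hue occupies [0, 255), wrapping at red.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv

__all__ = [
    "Sensor",
    "SensorImage",
    "HSBImage",
    "PlatformConfig",
    "PotSlot",
    "TrayLayout",
    "InspectionStatus",
    "read_image",
    "write_image",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "randomize_layout",
    "read_layout_csv",
    "write_layout_csv",
    "read_labels_csv",
    "round_half_away",
]


class Sensor(str, enum.Enum):
    """The three platform cameras."""

    VIS = "VIS"
    FLUO = "FLUO"
    NIR = "NIR"


class InspectionStatus(str, enum.Enum):
    """Visual health scoring: wilted-or-dried vs healthy."""

    STRESSED = "stressed"
    HEALTHY = "healthy"


#: Native sensor resolutions (width, height) in pixels.
FULL_SCALE_DIMS = {
    Sensor.VIS: (2454, 2056),
    Sensor.FLUO: (1390, 1038),
    Sensor.NIR: (320, 254),
}


def round_half_away(x):
    """Round half away from zero (elementwise), returning int64.

    Used everywhere a geometric quantity is snapped to a pixel grid, so that
    a single rounding convention governs registration and rasterization.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(np.int64)


@dataclass
class SensorImage:
    """One 8-bit raster frame from a single sensor.

    ``pixels`` is (H, W, 3) uint8 for VIS/FLUO and (H, W) uint8 for NIR.
    """

    sensor: Sensor
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.sensor = Sensor(self.sensor)
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.sensor is Sensor.NIR:
            if self.pixels.ndim != 2:
                raise ValueError("NIR images carry exactly one channel")
        else:
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ValueError(f"{self.sensor.value} images must be RGB")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class HSBImage:
    """Hue/saturation/brightness planes of a color frame, floats on 0-255.

    brightness == max(R, G, B) exactly; hue lies in [0, 255) and wraps at
    red.  Float storage keeps the conversion losslessly invertible.
    """

    hue: np.ndarray
    saturation: np.ndarray
    brightness: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.hue, self.saturation, self.brightness)}
        if len(shapes) != 1:
            raise ValueError("HSB channel shapes differ")
        for name in ("hue", "saturation", "brightness"):
            a = getattr(self, name)
            if a.size and (a.min() < 0 or a.max() > 255):
                raise ValueError(f"{name} out of [0, 255]")

    @property
    def width(self) -> int:
        return self.hue.shape[1]

    @property
    def height(self) -> int:
        return self.hue.shape[0]


@dataclass(frozen=True)
class PlatformConfig:
    """Platform constants of the imaging deck and the analysis rules.

    ``c`` is the camera-setting offset added to the base brightness
    threshold; ``a`` and ``b`` are deck-configuration pixel offsets added to
    the registration shifts.  All default to 0 and are installation
    constants.  The remaining values are the analysis constants: the
    segmentation area/distance filters, the FLUO->VIS and FLUO->NIR resize
    widths and shifts, the number of hue classes, and the NIR index
    threshold separating stressed from non-stressed plants.
    """

    c: float = 0.0
    a: float = 0.0
    b: float = 0.0
    brightness_base: float = 25.0
    min_area: float = 1000.0
    max_center_dist: float = 300.0
    fluo_dims: tuple[int, int] = FULL_SCALE_DIMS[Sensor.FLUO]
    vis_dims: tuple[int, int] = FULL_SCALE_DIMS[Sensor.VIS]
    nir_dims: tuple[int, int] = FULL_SCALE_DIMS[Sensor.NIR]
    fluo_to_vis_width: float = 2900.0
    vis_shift: tuple[float, float] = (-290.0, -122.0)
    fluo_to_nir_width: float = 380.0
    nir_shift: tuple[float, float] = (-30.0, -12.0)
    nir_index_threshold: float = 120.0
    n_hue_classes: int = 65
    green_hue_window: tuple[float, float] = (57.0, 113.0)
    brown_hue_window: tuple[float, float] = (7.0, 56.0)

    def __post_init__(self) -> None:
        if self.fluo_to_vis_width <= 0 or self.fluo_to_nir_width <= 0:
            raise ValueError("resize widths must be positive")
        if self.min_area < 0:
            raise ValueError("min_area must be non-negative")
        if self.max_center_dist <= 0:
            raise ValueError("max_center_dist must be positive")
        if self.nir_index_threshold <= 0:
            raise ValueError("nir_index_threshold must be positive")

    @property
    def brightness_threshold(self) -> float:
        """Foreground threshold on FLUO brightness: base + c (strict >)."""
        return self.brightness_base + self.c

    @property
    def vis_shift_total(self) -> tuple[float, float]:
        return (self.vis_shift[0] + self.a, self.vis_shift[1] + self.b)

    @property
    def nir_shift_total(self) -> tuple[float, float]:
        return (self.nir_shift[0] + self.a, self.nir_shift[1] + self.b)

    def scaled(self, factor: float) -> "PlatformConfig":
        """A geometrically downscaled configuration for small test scenes.

        Lengths divide by ``factor``, areas by ``factor**2``; shift
        constants are snapped to whole pixels so that scaled scenes remain
        exactly co-registered on the integer grid.
        """

        def dims(d):
            return (int(round_half_away(d[0] / factor)), int(round_half_away(d[1] / factor)))

        def shift(s):
            return (float(round_half_away(s[0] / factor)), float(round_half_away(s[1] / factor)))

        return replace(
            self,
            min_area=self.min_area / factor**2,
            max_center_dist=self.max_center_dist / factor,
            fluo_dims=dims(self.fluo_dims),
            vis_dims=dims(self.vis_dims),
            nir_dims=dims(self.nir_dims),
            fluo_to_vis_width=self.fluo_to_vis_width / factor,
            vis_shift=shift(self.vis_shift),
            fluo_to_nir_width=self.fluo_to_nir_width / factor,
            nir_shift=shift(self.nir_shift),
        )


@dataclass(frozen=True)
class PotSlot:
    """One pot position: a grid slot, its theoretical center (FLUO frame,
    pixels) and the sample currently occupying it."""

    sample_id: str
    slot: tuple[int, int]
    center: tuple[float, float]


@dataclass
class TrayLayout:
    """Ordered pot slots of a tray; sample ids are unique."""

    slots: list[PotSlot]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.slots]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.slots]


def read_image(path: str | Path, sensor: Sensor | str) -> SensorImage:
    """Read a PNG or TIFF frame as a SensorImage.

    NIR inputs must be single-channel, or RGB with identical channels
    (which are collapsed); VIS/FLUO inputs must be color.
    """
    sensor = Sensor(sensor)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - any decode failure is fatal
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    if sensor is Sensor.NIR:
        if arr.ndim == 3:
            rgb = arr[..., :3]
            if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
                raise ValueError(f"{path!r}: NIR input has non-identical RGB channels")
            arr = rgb[..., 0]
        return SensorImage(sensor, arr)
    if arr.ndim == 2:
        raise ValueError(f"{path!r}: {sensor.value} input must be a color image")
    return SensorImage(sensor, arr[..., :3])


def write_image(img: SensorImage, path: str | Path) -> None:
    """Write a SensorImage as 8-bit PNG/TIFF (format from the suffix)."""
    Image.fromarray(img.pixels).save(path)


def rgb_to_hsb(img: SensorImage) -> HSBImage:
    """Convert a color frame to HSB with all channels on the 0-255 scale.

    Brightness is max(R, G, B); saturation and hue follow the standard HSV
    definitions, hue scaled so that 360 degrees span 0-255.
    """
    if img.sensor is Sensor.NIR:
        raise ValueError("NIR images have no color channels to convert")
    hsv = rgb2hsv(img.pixels)
    return HSBImage(
        hue=hsv[..., 0] * 255.0,
        saturation=hsv[..., 1] * 255.0,
        brightness=hsv[..., 2] * 255.0,
    )


def hsb_to_rgb(hue, saturation, brightness) -> np.ndarray:
    """Invert rgb_to_hsb: HSB on 0-255 back to uint8 RGB.

    Accepts scalars or same-shaped arrays; returns (..., 3) uint8.
    """
    h = np.asarray(hue, dtype=float) / 255.0
    s = np.asarray(saturation, dtype=float) / 255.0
    v = np.asarray(brightness, dtype=float) / 255.0
    hsv = np.stack(np.broadcast_arrays(h, s, v), axis=-1)
    rgb = hsv2rgb(hsv.reshape(-1, 1, 3)).reshape(hsv.shape)
    return round_half_away(rgb * 255.0).astype(np.uint8)


def randomize_layout(layout: TrayLayout, seed: int) -> TrayLayout:
    """Reassign samples to slots by a uniform seeded permutation.

    Slot coordinates (and their theoretical centers) stay put; only the
    sample-to-slot assignment moves, emulating the periodic in-chamber
    re-randomization of pots.
    """
    if len(layout) == 0:
        raise ValueError("cannot randomize an empty layout")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(layout))
    ids = layout.sample_ids
    slots = [replace(slot, sample_id=ids[perm[i]]) for i, slot in enumerate(layout.slots)]
    return TrayLayout(slots)


# ---------------------------------------------------------------------------
# Tabular interfaces (CSV with header, comma-separated, UTF-8)

LAYOUT_COLUMNS = ["sample_id", "line", "treatment", "slot_x", "slot_y", "center_x", "center_y"]
LABEL_COLUMNS = ["sample_id", "das", "status", "final_status"]


def read_layout_csv(path: str | Path) -> tuple[TrayLayout, pd.DataFrame]:
    """Read a tray-layout table.

    Returns the TrayLayout plus a sample table (sample_id, line, treatment);
    ``line`` may include ``soil-only`` rows that never yield a plant.
    """
    df = pd.read_csv(path)
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
    slots = [
        PotSlot(
            sample_id=str(r.sample_id),
            slot=(int(r.slot_x), int(r.slot_y)),
            center=(float(r.center_x), float(r.center_y)),
        )
        for r in df.itertuples()
    ]
    samples = df[["sample_id", "line", "treatment"]].astype({"sample_id": str})
    return TrayLayout(slots), samples


def write_layout_csv(layout: TrayLayout, samples: pd.DataFrame, path: str | Path) -> None:
    rows = []
    meta = samples.set_index("sample_id")
    for s in layout.slots:
        rows.append(
            {
                "sample_id": s.sample_id,
                "line": meta.loc[s.sample_id, "line"],
                "treatment": meta.loc[s.sample_id, "treatment"],
                "slot_x": s.slot[0],
                "slot_y": s.slot[1],
                "center_x": s.center[0],
                "center_y": s.center[1],
            }
        )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    """Read manual-inspection labels: one row per sample x DAS.

    ``status`` is stressed (wilted-or-dried) or healthy; ``final_status``
    (alive/dead) is set only on the last DAS of a sample, otherwise blank
    and normalized to "unknown".
    """
    df = pd.read_csv(path)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"labels CSV missing columns: {sorted(missing)}")
    df = df.astype({"sample_id": str, "das": int})
    df["final_status"] = df["final_status"].fillna("unknown")
    bad = set(df["status"]) - {"stressed", "healthy"}
    if bad:
        raise ValueError(f"unknown inspection statuses: {sorted(bad)}")
    return df
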