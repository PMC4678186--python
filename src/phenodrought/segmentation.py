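"""Digital-plant extraction from the fluorescence frame.

Rosette leaves fluoresce strongly under the FLUO camera while soil is
essentially dark, so a single brightness threshold separates plant from
background.  Connected foreground regions are labeled, then for each pot
the one region that is (a) large enough to be a rosette and (b) close
enough to the pot's theoretical center is kept as that pot's "digital
plant" — the pixel set every downstream sensor reuses as a mask.

Filtering happens in the native FLUO frame, before any resizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from skimage import measure

from .imaging_io import HSBImage, PlatformConfig

__all__ = [
    "LabeledRegion",
    "DigitalPlant",
    "threshold_fluo",
    "label_regions",
    "select_digital_plant",
    "mask_from_coords",
    "coords_from_mask",
    "write_mask_png",
    "regions_to_csv",
]


@dataclass
class LabeledRegion:
    """A maximal connected foreground component.

    ``coords`` is an (n, 2) int array of (x, y) pixel positions.
    """

    label: int
    coords: np.ndarray

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.coords[:, 0].mean()), float(self.coords[:, 1].mean()))


@dataclass
class DigitalPlant:
    """The selected foreground pixel set of one pot at one timepoint,
    in native FLUO-frame coordinates."""

    sample_id: str
    das: int
    coords: np.ndarray  # (n, 2) int, (x, y)

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.coords[:, 0].mean()), float(self.coords[:, 1].mean()))


def threshold_fluo(img: HSBImage, cfg: PlatformConfig) -> np.ndarray:
    """Foreground mask of a FLUO frame: brightness strictly above base + c.

    Returns a (H, W) boolean array.
    """
    return img.brightness > cfg.brightness_threshold


def label_regions(
    mask: np.ndarray,
    connectivity: int = 8,
    min_region_area: int = 0,
) -> list[LabeledRegion]:
    """Partition a foreground mask into maximal connected components.

    Label ids are dense from 1 in first-encounter (row-major scan) order.
    ``connectivity`` is 4 or 8; ``min_region_area`` optionally drops tiny
    speckle regions (e.g. algal noise in synthetic scenes) before the
    area/distance selection — off by default.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    width = mask.shape[1]
    regions = []
    for rp in measure.regionprops(lab):
        if rp.area < min_region_area:
            continue
        rows = rp.coords[:, 0]
        cols = rp.coords[:, 1]
        first = int((rows * width + cols).min())
        regions.append((first, np.column_stack([cols, rows])))
    regions.sort(key=lambda t: t[0])
    return [LabeledRegion(label=i, coords=c) for i, (_, c) in enumerate(regions, start=1)]


def select_digital_plant(
    regions: Iterable[LabeledRegion],
    pot_center: tuple[float, float],
    cfg: PlatformConfig,
    sample_id: str = "",
    das: int = 0,
) -> Optional[DigitalPlant]:
    """Pick the one region that is this pot's digital plant, or None.

    A region qualifies when area > min_area (strict) and the Euclidean
    distance from its centroid to the theoretical pot center is < the
    distance cap (strict).  Among qualifiers the nearest wins; ties break
    by larger area, then smaller label id.  None means a failed-germination
    or soil-only pot — absence is a value, not an error.
    """
    cx, cy = pot_center
    best = None
    best_key = None
    for reg in regions:
        if reg.area <= cfg.min_area:
            continue
        rx, ry = reg.centroid
        dist = float(np.hypot(rx - cx, ry - cy))
        if dist >= cfg.max_center_dist:
            continue
        key = (dist, -reg.area, reg.label)
        if best_key is None or key < best_key:
            best, best_key = reg, key
    if best is None:
        return None
    return DigitalPlant(sample_id=sample_id, das=das, coords=best.coords.copy())


def mask_from_coords(coords: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    """Boolean (H, W) mask from (x, y) coordinates; dims is (W, H)."""
    w, h = dims
    mask = np.zeros((h, w), dtype=bool)
    if coords.size:
        mask[coords[:, 1], coords[:, 0]] = True
    return mask


def coords_from_mask(mask: np.ndarray) -> np.ndarray:
    """(x, y) coordinates of foreground pixels, in row-major order."""
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys]).astype(np.int64)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 8-bit PNG: 0 background, 255 foreground."""
    from PIL import Image

    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


def regions_to_csv(regions: Iterable[LabeledRegion], path: str | Path) -> None:
    rows = [
        {
            "label": r.label,
            "area": r.area,
            "centroid_x": r.centroid[0],
            "centroid_y": r.centroid[1],
        }
        for r in regions
    ]
    pd.DataFrame(rows, columns=["label", "area", "centroid_x", "centroid_y"]).to_csv(path, index=False)
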