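"""Hue color-class profiles and the two-group Ward clustering.

Each digital plant's VIS pixels are binned into 65 equal hue classes
(half-open intervals over the 0-255 hue scale); the profile records the
percentage of pixels per class, so plant size cancels out.  Profiles feed
a Euclidean distance matrix, agglomerative Ward clustering, and a cut of
the tree into exactly two groups — the classifier's stressed vs healthy
split.  A healthy rosette is dominated by green hue classes, a wilted or
dried one by yellow/brown ones; the group whose centroid carries more mass
in the green hue window is labeled healthy.

The Ward variant is the classic Lance-Williams update applied to the
supplied (unsquared) distances; the squared-distance variant is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .imaging_io import PlatformConfig, Sensor, hsb_to_rgb
from .registration import SensorPlantPixels

__all__ = [
    "ColorProfile",
    "ClassRepresentative",
    "hue_class",
    "classify_hue",
    "class_representative",
    "profile_distance_matrix",
    "ward_cluster",
    "cut_two",
    "assign_health_labels",
    "profiles_to_csv",
]

N_CLASSES = 65


@dataclass
class ColorProfile:
    """65-entry hue-class percentage vector of one digital plant."""

    sample_id: str
    das: int
    percentages: np.ndarray  # (65,), sums to 100
    n_pixels: int

    def __post_init__(self) -> None:
        self.percentages = np.asarray(self.percentages, dtype=float)
        if self.percentages.shape != (N_CLASSES,):
            raise ValueError(f"profile must have exactly {N_CLASSES} entries")
        if self.percentages.min() < 0:
            raise ValueError("percentages must be non-negative")
        if abs(self.percentages.sum() - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")


@dataclass(frozen=True)
class ClassRepresentative:
    """Display color of a hue class: the interval's median hue rendered at
    full saturation and brightness."""

    index: int
    hue: int
    rgb: tuple[int, int, int]


def hue_class(hue, n_classes: int = N_CLASSES) -> np.ndarray:
    """Class index of a hue value on the 0-255 scale: floor(h*65/256).

    The 65 half-open intervals [i*256/65, (i+1)*256/65) tile [0, 256).
    """
    h = np.asarray(hue, dtype=float)
    if h.size and (h.min() < 0 or h.max() > 255):
        raise ValueError("hue out of [0, 255]")
    return np.floor(h * n_classes / 256.0).astype(np.int64)


def classify_hue(pixels: SensorPlantPixels, n_classes: int = N_CLASSES) -> ColorProfile:
    """Build the hue color-class profile of a VIS digital plant.

    Each pixel's hue (from the standard RGB->HSB conversion) lands in one
    of 65 equal classes; entries are percentages of the plant's pixels.
    """
    if pixels.sensor is not Sensor.VIS:
        raise ValueError("color profiles are computed on VIS pixels")
    if pixels.n_pixels == 0:
        raise ValueError("empty pixel set")
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(pixels.values.reshape(-1, 1, 3)).reshape(-1, 3)
    hue = hsv[:, 0] * 255.0
    counts = np.bincount(hue_class(hue, n_classes), minlength=n_classes)
    return ColorProfile(
        sample_id=pixels.sample_id,
        das=pixels.das,
        percentages=100.0 * counts / counts.sum(),
        n_pixels=int(counts.sum()),
    )


def class_representative(index: int, n_classes: int = N_CLASSES) -> ClassRepresentative:
    """Representative color of a class: midpoint hue at S = B = 255."""
    if not 0 <= index < n_classes:
        raise ValueError(f"class index must be in 0-{n_classes - 1}")
    lo = index * 256.0 / n_classes
    hi = (index + 1) * 256.0 / n_classes
    hue = int(round((lo + hi) / 2.0))
    rgb = hsb_to_rgb(min(hue, 255), 255, 255)
    return ClassRepresentative(index=index, hue=hue, rgb=tuple(int(v) for v in rgb))


def profile_distance_matrix(profiles: Sequence[ColorProfile]) -> np.ndarray:
    """Pairwise Euclidean distances between the 65-vectors; (n, n) symmetric."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    mat = np.vstack([p.percentages for p in profiles])
    return squareform(pdist(mat, metric="euclidean"))


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if d.min() < 0:
        raise ValueError("distances must be non-negative")
    return d


def ward_cluster(d: np.ndarray, squared_distances: bool = False) -> np.ndarray:
    """Agglomerative Ward hierarchy over a distance matrix.

    Returns a scipy linkage matrix whose heights are the Lance-Williams
    Ward criterion evaluated on the supplied distances as-is (the classic
    behaviour of applying Ward's update to unsquared dissimilarities).
    With ``squared_distances=True`` the heights are instead the Euclidean
    Ward distances (the update run on squared distances, square-rooted).
    Merge heights are non-decreasing in both variants.
    """
    d = _check_distance_matrix(d)
    y = squareform(d, checks=False)
    if squared_distances:
        return linkage(y, method="ward")
    # Ward's update on unsquared input d equals (scipy ward on sqrt(d))**2:
    # scipy computes sqrt(LW(y^2)), so feeding sqrt(d) yields sqrt(LW(d)).
    z = linkage(np.sqrt(y), method="ward")
    z[:, 2] **= 2
    return z


def cut_two(z: np.ndarray) -> np.ndarray:
    """Cut a dendrogram into its two top-level groups.

    Removing the final merge leaves two subtrees; every sample belongs to
    exactly one.  Group ids are 1 and 2, ordered by smallest member index.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0] + 1
    if n < 2:
        raise ValueError("need at least 2 samples to cut")
    raw = fcluster(z, t=2, criterion="maxclust")
    if len(set(raw)) != 2:  # degenerate heights; split at the last merge by hand
        raise ValueError("dendrogram did not yield two groups")
    first_group = raw[0]
    out = np.where(raw == first_group, 1, 2)
    return out


def assign_health_labels(
    groups: np.ndarray,
    profiles: Sequence[ColorProfile],
    cfg: PlatformConfig | None = None,
) -> dict[str, str]:
    """Map the two cluster groups to stressed/healthy by hue mass.

    The group whose centroid profile carries the larger summed percentage
    over the green hue window (~80-160 degrees) is healthy; the other is
    stressed.  If green masses tie, the group with the larger brown/yellow
    mass is stressed; identical centroids are degenerate and reported as
    an error rather than guessed.
    """
    cfg = cfg or PlatformConfig()
    groups = np.asarray(groups)
    if len(groups) != len(profiles):
        raise ValueError("group assignment and profiles differ in length")
    ids = sorted(set(int(g) for g in groups))
    if len(ids) != 2:
        raise ValueError("exactly two non-empty groups are required")

    def window_classes(window):
        lo, hi = window
        return np.arange(int(hue_class(lo)), int(hue_class(hi)) + 1)

    green = window_classes(cfg.green_hue_window)
    brown = window_classes(cfg.brown_hue_window)
    mat = np.vstack([p.percentages for p in profiles])
    centroids = {g: mat[groups == g].mean(axis=0) for g in ids}
    green_mass = {g: centroids[g][green].sum() for g in ids}
    brown_mass = {g: centroids[g][brown].sum() for g in ids}
    g1, g2 = ids
    if green_mass[g1] > green_mass[g2]:
        healthy = g1
    elif green_mass[g2] > green_mass[g1]:
        healthy = g2
    elif brown_mass[g1] > brown_mass[g2]:
        healthy = g2
    elif brown_mass[g2] > brown_mass[g1]:
        healthy = g1
    else:
        raise ValueError("identical group centroids; cannot assign health labels")
    return {
        p.sample_id: ("healthy" if g == healthy else "stressed")
        for p, g in zip(profiles, groups)
    }


def profiles_to_csv(profiles: Sequence[ColorProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "das": p.das, "n_pixels": p.n_pixels}
        row.update({f"c{i:02d}": p.percentages[i] for i in range(N_CLASSES)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def profiles_from_csv(path: str | Path) -> list[ColorProfile]:
    df = pd.read_csv(path)
    cols = [f"c{i:02d}" for i in range(N_CLASSES)]
    return [
        ColorProfile(
            sample_id=str(r["sample_id"]),
            das=int(r["das"]),
            percentages=r[cols].to_numpy(dtype=float),
            n_pixels=int(r["n_pixels"]),
        )
        for _, r in df.iterrows()
    ]
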