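"""Synthetic co-registered VIS/FLUO/NIR tray scenes with ground truth.

No raw platform images are publicly deposited, so every pipeline stage is
exercised on generated scenes instead: lobed-disk rosettes on soil,
rendered consistently into all three sensor frames by the *inverse* of
the registration transforms, so that the pipeline's forward transforms
recover them.  The generator emulates the physics the method relies on:

* FLUO: leaves fluoresce brightly (default brightness 120) against nearly
  dark soil (default 10), the contrast that makes fluorescence the
  segmentation sensor.  Optional algal speckles add FLUO-bright soil
  noise.
* VIS: healthy leaves sit in the green hue band (~85 +/- 5 on the 0-255
  hue scale); stressed plants drift linearly toward brown (~30) over the
  water-deficit days.
* NIR: leaf reflectance rises as water content falls — stressed plants
  drift +25% by the final deficit day, controls stay within +2%.

Per-DAS inspection labels flip to wilted-or-dried when a plant's mean hue
crosses into the brown window; the final alive/dead status follows the
plant's recovery flag.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging_io import (
    PlatformConfig,
    PotSlot,
    Sensor,
    SensorImage,
    TrayLayout,
    hsb_to_rgb,
    randomize_layout,
)
from .registration import RegistrationTransform

__all__ = [
    "PlantSpec",
    "TraySceneSpec",
    "SceneBundle",
    "usable_fluo_region",
    "make_cohort_spec",
    "generate_scene",
    "generate_timecourse",
    "inspection_labels",
    "write_dataset",
]

#: hue (0-255) below which a rosette visually reads as wilted/brown
WILT_HUE = 57.0


@dataclass
class PlantSpec:
    """Shape, health trajectory and sensor signal of one pot's plant."""

    sample_id: str
    center: tuple[float, float]  # FLUO frame, px
    radius: float  # FLUO px, mean lobed-disk radius
    n_lobes: int = 6
    lobe_depth: float = 0.12
    phase: float = 0.0
    stressed: bool = False
    hue_start: float = 85.0
    hue_end: float = 30.0
    hue_sd: float = 5.0
    fluo_brightness: float = 120.0
    nir_baseline: float = 100.0
    nir_drift: float = 0.25  # fractional Q3 increase by the final deficit day
    control_drift: float = 0.02
    germinated: bool = True
    recovers: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        for h in (self.hue_start, self.hue_end):
            if not 0 <= h <= 255:
                raise ValueError("hue values must lie in [0, 255]")
        if self.nir_drift < -1 or self.control_drift < -1:
            raise ValueError("drift fractions must be >= -1")

    def max_radius(self) -> float:
        return self.radius * (1.0 + self.lobe_depth)


@dataclass
class TraySceneSpec:
    """One tray's layout, plants, schedule, noise and platform constants."""

    config: PlatformConfig
    layout: TrayLayout
    plants: dict[str, PlantSpec]
    samples: pd.DataFrame  # sample_id, line, treatment
    das_list: tuple[int, ...] = (20, 21, 22, 26, 28)
    deficit_start: int = 22
    noise_sd: float = 2.0  # VIS/FLUO per-channel Gaussian sd
    nir_noise_sd: float = 1.0
    soil_hue: float = 30.0
    soil_saturation: float = 120.0
    soil_brightness: float = 90.0
    soil_fluo_brightness: float = 10.0
    soil_nir: float = 40.0
    algal_density: float = 0.0  # speckles per 1000 FLUO px, on soil

    def __post_init__(self) -> None:
        if len(self.das_list) == 0:
            raise ValueError("DAS list must not be empty")
        if tuple(sorted(self.das_list)) != tuple(self.das_list):
            raise ValueError("DAS list must be sorted")

    def deficit_fraction(self, das: int) -> float:
        """Progress through the water-deficit window, 0 before it starts."""
        final = self.das_list[-1]
        if das <= self.deficit_start or final <= self.deficit_start:
            return 0.0
        return min(1.0, (das - self.deficit_start) / (final - self.deficit_start))

    def hue_mean(self, plant: PlantSpec, das: int) -> float:
        f = self.deficit_fraction(das) if plant.stressed else 0.0
        return plant.hue_start + f * (plant.hue_end - plant.hue_start)

    def nir_level(self, plant: PlantSpec, das: int) -> float:
        drift = plant.nir_drift if plant.stressed else plant.control_drift
        return plant.nir_baseline * (1.0 + drift * self.deficit_fraction(das))

    def status(self, plant: PlantSpec, das: int) -> str:
        return "stressed" if self.hue_mean(plant, das) < WILT_HUE else "healthy"


@dataclass
class SceneBundle:
    """Rendered frames plus per-sample ground truth for one timepoint."""

    das: int
    images: dict[Sensor, SensorImage]
    gt_masks: dict[str, dict[Sensor, np.ndarray]]
    statuses: dict[str, str]


def usable_fluo_region(cfg: PlatformConfig) -> tuple[float, float, float, float]:
    """FLUO-frame rectangle (x_lo, x_hi, y_lo, y_hi) visible in all sensors."""
    x_lo, y_lo = 0.0, 0.0
    x_hi, y_hi = cfg.fluo_dims[0] - 1.0, cfg.fluo_dims[1] - 1.0
    for sensor, dims in ((Sensor.VIS, cfg.vis_dims), (Sensor.NIR, cfg.nir_dims)):
        t = RegistrationTransform.for_sensor(sensor, cfg)
        s = t.scale
        dx, dy = t.shift
        x_lo = max(x_lo, (0.0 + dx) / s)
        x_hi = min(x_hi, (dims[0] - 1.0 + dx) / s)
        y_lo = max(y_lo, (0.0 + dy) / s)
        y_hi = min(y_hi, (dims[1] - 1.0 + dy) / s)
    if x_lo >= x_hi or y_lo >= y_hi:
        raise ValueError("sensor geometries leave no common field of view")
    return x_lo, x_hi, y_lo, y_hi


def make_cohort_spec(
    n_plants: int = 48,
    n_stressed: int = 24,
    scale: float = 4.0,
    radius: float | None = None,
    das_list: tuple[int, ...] = (20, 21, 22, 26, 28),
    deficit_start: int = 22,
    seed: int = 0,
    lines: tuple[str, ...] = ("WT", "gtl1-5", "drs1"),
    n_soil_only: int = 0,
    n_failed_germination: int = 0,
    recover_fraction: float = 0.0,
    noise_sd: float = 2.0,
    hue_sd: float = 5.0,
    nir_drift: float = 0.25,
    algal_density: float = 0.0,
) -> TraySceneSpec:
    """A standard tray cohort at the study conditions.

    Plants are laid out on a grid inside the region all three sensors can
    see; which pots are stressed (water-limited) is a seeded random
    choice, and the sample-to-slot assignment is randomized the way tray
    positions were re-shuffled on the platform.  ``scale`` shrinks the
    sensor geometry (default 1/4 scale for fast tests); all platform
    constants shrink with it.
    """
    rng = np.random.default_rng(seed)
    cfg = PlatformConfig().scaled(scale) if scale != 1.0 else PlatformConfig()
    n_total = n_plants + n_soil_only
    region = usable_fluo_region(cfg)
    x_lo, x_hi, y_lo, y_hi = region
    if radius is None:
        # the achievable grid spacing bounds the rosette size, but the
        # spacing itself depends on the border margin the rosettes need;
        # a few fixed-point rounds settle both together
        radius = 0.36 * min(x_hi - x_lo, y_hi - y_lo) / (2 * 1.15)
        for _ in range(4):
            centers = _grid_centers(n_total, region, radius * 1.15 + 2.0)
            if len(centers) < n_total:
                radius *= 0.7
                continue
            radius = min(radius, 0.36 * _min_spacing(centers) / 1.15)
    margin = radius * 1.15 + 2.0
    centers = _grid_centers(n_total, region, margin)
    if len(centers) < n_total:
        raise ValueError("tray region too small for the requested pot count")
    spacing = _min_spacing(centers)
    if spacing < 2.0 * radius * 1.15:
        raise ValueError("pots too close for the requested rosette radius")

    stressed_ids = set(rng.choice(n_plants, size=n_stressed, replace=False).tolist())
    slots, plant_specs, sample_rows = [], {}, []
    for i in range(n_total):
        soil_only = i >= n_plants
        sid = f"soil{i - n_plants + 1:02d}" if soil_only else f"plant{i + 1:03d}"
        cx, cy = centers[i]
        slots.append(PotSlot(sample_id=sid, slot=(i % 8, i // 8), center=(cx, cy)))
        stressed = (not soil_only) and i in stressed_ids
        sample_rows.append(
            {
                "sample_id": sid,
                "line": "soil-only" if soil_only else lines[i % len(lines)],
                "treatment": "water-limited" if stressed else "well-watered",
            }
        )
        if soil_only:
            continue
        jitter = rng.uniform(-1.5, 1.5, size=2)
        plant_specs[sid] = PlantSpec(
            sample_id=sid,
            center=(cx + jitter[0], cy + jitter[1]),
            radius=radius * rng.uniform(0.9, 1.05),
            n_lobes=int(rng.integers(5, 9)),
            phase=float(rng.uniform(0, 2 * math.pi)),
            stressed=stressed,
            hue_sd=hue_sd,
            nir_drift=nir_drift,
            recovers=bool(rng.random() < recover_fraction) if stressed else True,
        )
    if n_failed_germination:
        germinable = [s for s in plant_specs if not plant_specs[s].stressed]
        for sid in germinable[:n_failed_germination]:
            plant_specs[sid].germinated = False
    layout = randomize_layout(TrayLayout(slots), seed=int(rng.integers(2**31)))
    # plants stay with their sample id; recompute centers from the shuffled slots
    for slot in layout.slots:
        if slot.sample_id in plant_specs:
            p = plant_specs[slot.sample_id]
            jitter = rng.uniform(-1.5, 1.5, size=2)
            p.center = (slot.center[0] + jitter[0], slot.center[1] + jitter[1])
    return TraySceneSpec(
        config=cfg,
        layout=layout,
        plants=plant_specs,
        samples=pd.DataFrame(sample_rows),
        das_list=tuple(das_list),
        deficit_start=deficit_start,
        noise_sd=noise_sd,
        algal_density=algal_density,
    )


def _grid_shape(n: int, w: float, h: float) -> tuple[int, int]:
    cols = max(1, math.ceil(math.sqrt(n * w / max(h, 1e-9))))
    rows = math.ceil(n / cols)
    while cols * rows < n:
        cols += 1
    return cols, rows


def _grid_centers(n, region, margin) -> list[tuple[float, float]]:
    x_lo, x_hi, y_lo, y_hi = region
    x_lo, x_hi = x_lo + margin, x_hi - margin
    y_lo, y_hi = y_lo + margin, y_hi - margin
    if x_lo > x_hi or y_lo > y_hi:
        return []
    cols, rows = _grid_shape(n, x_hi - x_lo, y_hi - y_lo)
    xs = np.linspace(x_lo, x_hi, cols) if cols > 1 else [(x_lo + x_hi) / 2]
    ys = np.linspace(y_lo, y_hi, rows) if rows > 1 else [(y_lo + y_hi) / 2]
    return [(float(x), float(y)) for y in ys for x in xs][:n]


def _min_spacing(centers) -> float:
    if len(centers) < 2:
        return math.inf
    arr = np.asarray(centers)
    d = np.sqrt(((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _sensor_grid(sensor: Sensor, cfg: PlatformConfig):
    """Per-sensor transform pieces: dims, scale, shift."""
    t = RegistrationTransform.for_sensor(sensor, cfg)
    dims = {Sensor.VIS: cfg.vis_dims, Sensor.FLUO: cfg.fluo_dims, Sensor.NIR: cfg.nir_dims}[sensor]
    return dims, t.scale, t.shift


def _membership(plant: PlantSpec, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    """Lobed-disk membership of continuous FLUO-frame points."""
    ddx = fx - plant.center[0]
    ddy = fy - plant.center[1]
    r2 = ddx * ddx + ddy * ddy
    theta = np.arctan2(ddy, ddx)
    rad = plant.radius * (1.0 + plant.lobe_depth * np.cos(plant.n_lobes * theta + plant.phase))
    return r2 <= rad * rad


def _plant_bbox(plant, dims, s, dx, dy):
    """Pixel bbox of a plant in a sensor frame (may be clipped empty)."""
    pad = plant.max_radius() + 2.0
    tx0 = int(max(0, math.floor((plant.center[0] - pad) * s - dx)))
    tx1 = int(min(dims[0] - 1, math.ceil((plant.center[0] + pad) * s - dx)))
    ty0 = int(max(0, math.floor((plant.center[1] - pad) * s - dy)))
    ty1 = int(min(dims[1] - 1, math.ceil((plant.center[1] + pad) * s - dy)))
    return tx0, tx1, ty0, ty1


def generate_scene(
    spec: TraySceneSpec,
    das: int,
    seed: int,
    sensors: tuple[Sensor, ...] = (Sensor.VIS, Sensor.FLUO, Sensor.NIR),
) -> SceneBundle:
    """Render one timepoint of the tray into the requested sensor frames.

    Deterministic given (spec, das, seed); each sensor has its own random
    stream, so rendering a subset of sensors leaves the others' pixel
    values unchanged.  Ground-truth masks are the analytic rosette shapes
    rasterized per sensor through the inverse registration transforms.
    """
    cfg = spec.config
    images: dict[Sensor, SensorImage] = {}
    gt_masks: dict[str, dict[Sensor, np.ndarray]] = {
        sid: {} for sid, p in spec.plants.items() if p.germinated
    }
    order = [sid for sid in spec.layout.sample_ids if sid in gt_masks]
    for sensor in sensors:
        sensor = Sensor(sensor)
        rng = np.random.default_rng([seed, das, list(Sensor).index(sensor)])
        dims, s, (dx, dy) = _sensor_grid(sensor, cfg)
        w, h = dims
        if sensor is Sensor.NIR:
            img = np.full((h, w), spec.soil_nir, dtype=float)
        elif sensor is Sensor.FLUO:
            soil = np.array(
                [spec.soil_fluo_brightness, 0.4 * spec.soil_fluo_brightness, 0.3 * spec.soil_fluo_brightness]
            )
            img = np.tile(soil, (h, w, 1))
        else:
            soil_rgb = hsb_to_rgb(spec.soil_hue, spec.soil_saturation, spec.soil_brightness)
            img = np.tile(soil_rgb.astype(float), (h, w, 1))
        for sid in order:
            plant = spec.plants[sid]
            tx0, tx1, ty0, ty1 = _plant_bbox(plant, dims, s, dx, dy)
            mask_full = np.zeros((h, w), dtype=bool)
            if tx1 >= tx0 and ty1 >= ty0:
                txs = np.arange(tx0, tx1 + 1)
                tys = np.arange(ty0, ty1 + 1)
                fx = (txs + dx) / s
                fy = (tys + dy) / s
                member = _membership(plant, fx[None, :], fy[:, None])
                mask_full[ty0 : ty1 + 1, tx0 : tx1 + 1] = member
            gt_masks[sid][sensor] = mask_full
            n_px = int(mask_full.sum())
            if n_px == 0:
                continue
            if sensor is Sensor.NIR:
                img[mask_full] = spec.nir_level(plant, das)
            elif sensor is Sensor.FLUO:
                b = plant.fluo_brightness
                img[mask_full] = [b, 0.25 * b, 0.1 * b]
            else:
                hue = np.clip(rng.normal(spec.hue_mean(plant, das), plant.hue_sd, n_px), 0.0, 255.0)
                img[mask_full] = hsb_to_rgb(hue, np.full(n_px, 200.0), np.full(n_px, 160.0)).astype(float)
        if sensor is Sensor.FLUO and spec.algal_density > 0:
            _paint_algae(img, spec, rng)
        sd = spec.nir_noise_sd if sensor is Sensor.NIR else spec.noise_sd
        if sd > 0:
            img = img + rng.normal(0.0, sd, img.shape)
        images[sensor] = SensorImage(sensor, np.clip(np.round(img), 0, 255).astype(np.uint8))
    statuses = {
        sid: spec.status(spec.plants[sid], das) for sid in order
    }
    return SceneBundle(das=das, images=images, gt_masks=gt_masks, statuses=statuses)


def _paint_algae(img: np.ndarray, spec: TraySceneSpec, rng: np.random.Generator) -> None:
    """FLUO-bright 1-8 px speckle blobs on the soil surface."""
    h, w = img.shape[:2]
    n = int(spec.algal_density * h * w / 1000.0)
    for _ in range(n):
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        r = rng.uniform(0.5, 1.6)
        x0, x1 = int(max(0, cx - r - 1)), int(min(w - 1, cx + r + 1))
        y0, y1 = int(max(0, cy - r - 1)), int(min(h - 1, cy + r + 1))
        if x1 < x0 or y1 < y0:
            continue
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        blob = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r * r
        region = img[y0 : y1 + 1, x0 : x1 + 1]
        region[blob] = [110.0, 30.0, 15.0]


def generate_timecourse(
    spec: TraySceneSpec,
    seed: int,
    sensors: tuple[Sensor, ...] = (Sensor.VIS, Sensor.FLUO, Sensor.NIR),
) -> dict[int, SceneBundle]:
    """Scenes over all DAS of the schedule (>= 3 timepoints required)."""
    if len(spec.das_list) < 3:
        raise ValueError("a time course needs at least 3 DAS")
    return {das: generate_scene(spec, das, seed, sensors) for das in spec.das_list}


def inspection_labels(spec: TraySceneSpec) -> pd.DataFrame:
    """Per-DAS manual-inspection labels plus final alive/dead status.

    Status flips to wilted-or-dried when the plant's mean hue crosses into
    the brown window; the final status (set only at the last DAS) is dead
    for stressed plants that do not recover.
    """
    rows = []
    last = spec.das_list[-1]
    for sid in spec.layout.sample_ids:
        plant = spec.plants.get(sid)
        if plant is None or not plant.germinated:
            continue
        for das in spec.das_list:
            final = "unknown"
            if das == last:
                final = "alive" if (not plant.stressed or plant.recovers) else "dead"
            rows.append(
                {
                    "sample_id": sid,
                    "das": das,
                    "status": spec.status(plant, das),
                    "final_status": final,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "das", "status", "final_status"])


def write_dataset(spec: TraySceneSpec, seed: int, outdir: str | Path) -> Path:
    """Write a pipeline-consumable dataset: images, layout, labels, truth.

    Layout: ``images/das_<d>/{vis,fluo,nir}.png``, ``layout.csv``,
    ``labels.csv`` and ground-truth masks under ``ground_truth/``.
    """
    from .imaging_io import write_layout_csv, write_image
    from .segmentation import write_mask_png

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_layout_csv(spec.layout, spec.samples, outdir / "layout.csv")
    inspection_labels(spec).to_csv(outdir / "labels.csv", index=False)
    for das in spec.das_list:
        bundle = generate_scene(spec, das, seed)
        ddir = outdir / "images" / f"das_{das}"
        ddir.mkdir(parents=True, exist_ok=True)
        for sensor, img in bundle.images.items():
            write_image(img, ddir / f"{sensor.value.lower()}.png")
        gdir = outdir / "ground_truth" / f"das_{das}"
        gdir.mkdir(parents=True, exist_ok=True)
        for sid, masks in bundle.gt_masks.items():
            for sensor, mask in masks.items():
                write_mask_png(mask, gdir / f"{sid}_{sensor.value.lower()}.png")
    return outdir
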