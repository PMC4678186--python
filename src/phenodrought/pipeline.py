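"""End-to-end orchestration: segmentation -> registration -> classifiers -> stats.

Each stage is a function over a RunConfig that reads its inputs from the
dataset / output directory and writes CSV intermediates, so stages compose:
running them one by one produces the same files as run_pipeline.  Pots
without a digital plant (soil-only, failed germination) are warnings, not
failures — they stay in the tray but drop out of the analysis.

Dataset layout consumed::

    <image_root>/images/das_<d>/{vis,fluo,nir}.png
    layout.csv   sample_id, line, treatment, slot_x, slot_y, center_x, center_y
    labels.csv   sample_id, das, status, final_status
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import color_classes as cc
from . import nir as nirmod
from . import registration as reg
from . import segmentation as seg
from . import stats as st
from .imaging_io import (
    PlatformConfig,
    Sensor,
    read_image,
    read_labels_csv,
    read_layout_csv,
    rgb_to_hsb,
)

log = logging.getLogger("phenodrought")

__all__ = ["RunConfig", "run_pipeline", "simulate", "STAGES"]


@dataclass
class RunConfig:
    """Structured configuration of one pipeline run."""

    image_root: Path
    layout_csv: Path
    labels_csv: Path
    out_dir: Path
    platform: PlatformConfig = field(default_factory=PlatformConfig)
    base_das: int | None = None  # None = automatic homogeneity-based choice
    base_tolerance: float = 0.02
    connectivity: int = 8
    min_region_area: int = 0
    ward_squared: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("image_root", "layout_csv", "labels_csv", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        platform = PlatformConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("platform", {}).items()
        })
        root = path.parent
        for key in ("image_root", "layout_csv", "labels_csv", "out_dir"):
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = root / raw[key]
        return cls(platform=platform, **raw)

    def to_yaml(self, path: str | Path) -> None:
        import os

        path = Path(path)
        data = dataclasses.asdict(self)
        data["platform"] = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(self.platform).items()
        }
        # store paths relative to the config file so the bundle is portable
        for key in ("image_root", "layout_csv", "labels_csv", "out_dir"):
            data[key] = os.path.relpath(Path(data[key]).absolute(), path.parent.absolute())
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _das_dirs(cfg: RunConfig) -> dict[int, Path]:
    root = cfg.image_root / "images"
    if not root.is_dir():
        raise FileNotFoundError(f"no images directory under {cfg.image_root}")
    out = {}
    for d in sorted(root.glob("das_*")):
        out[int(d.name.split("_", 1)[1])] = d
    if not out:
        raise FileNotFoundError(f"no das_<n> image directories under {root}")
    return dict(sorted(out.items()))


def _sensor_path(ddir: Path, sensor: Sensor, das: int) -> Path:
    for suffix in ("png", "tif", "tiff"):
        p = ddir / f"{sensor.value.lower()}.{suffix}"
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {sensor.value} image for DAS {das} in {ddir}")


def stage_segment(cfg: RunConfig) -> pd.DataFrame:
    """Extract every pot's digital plant from each FLUO frame.

    Soil-only pots are never assigned a plant, and a labeled region can
    only be claimed by the pot whose center it is nearest — a neighbour's
    rosette cannot stand in for an empty pot when pots sit closer together
    than the distance cap.
    """
    layout, samples = read_layout_csv(cfg.layout_csv)
    lines = samples.set_index("sample_id")["line"].to_dict()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    mask_root = cfg.out_dir / "masks"
    rows = []
    for das, ddir in _das_dirs(cfg).items():
        fluo = read_image(_sensor_path(ddir, Sensor.FLUO, das), Sensor.FLUO)
        mask = seg.threshold_fluo(rgb_to_hsb(fluo), cfg.platform)
        regions = seg.label_regions(mask, cfg.connectivity, cfg.min_region_area)
        mdir = mask_root / f"das_{das}"
        mdir.mkdir(parents=True, exist_ok=True)
        candidates = {}
        for slot in layout.slots:
            if lines.get(slot.sample_id) == "soil-only":
                continue
            plant = seg.select_digital_plant(
                regions, slot.center, cfg.platform, sample_id=slot.sample_id, das=das
            )
            if plant is not None:
                cx, cy = plant.centroid
                dist = float(np.hypot(cx - slot.center[0], cy - slot.center[1]))
                candidates[slot.sample_id] = (plant, dist)
        # resolve double claims: the nearer pot keeps the region
        best_claim: dict[tuple, tuple[str, float]] = {}
        for sid, (plant, dist) in candidates.items():
            key = (plant.area, tuple(plant.coords[0]))
            if key not in best_claim or dist < best_claim[key][1]:
                best_claim[key] = (sid, dist)
        winners = {sid for sid, _ in best_claim.values()}
        for slot in layout.slots:
            sid = slot.sample_id
            entry = candidates.get(sid)
            if entry is None or sid not in winners:
                if lines.get(sid) != "soil-only":
                    log.warning("no digital plant for %s at DAS %d", sid, das)
                rows.append({"sample_id": sid, "das": das, "found": False,
                             "area": np.nan, "centroid_x": np.nan, "centroid_y": np.nan})
                continue
            plant = entry[0]
            seg.write_mask_png(
                seg.mask_from_coords(plant.coords, cfg.platform.fluo_dims),
                mdir / f"{sid}.png",
            )
            cx, cy = plant.centroid
            rows.append({"sample_id": sid, "das": das, "found": True,
                         "area": plant.area, "centroid_x": cx, "centroid_y": cy})
    df = pd.DataFrame(rows)
    df.to_csv(cfg.out_dir / "segments.csv", index=False)
    return df


def _load_plant(cfg: RunConfig, sample_id: str, das: int) -> seg.DigitalPlant | None:
    p = cfg.out_dir / "masks" / f"das_{das}" / f"{sample_id}.png"
    if not p.exists():
        return None
    from PIL import Image

    mask = np.asarray(Image.open(p)) > 0
    return seg.DigitalPlant(sample_id=sample_id, das=das, coords=seg.coords_from_mask(mask))


def stage_register(cfg: RunConfig) -> pd.DataFrame:
    """Transfer every digital plant onto the VIS and NIR frames."""
    segments = pd.read_csv(cfg.out_dir / "segments.csv")
    pix_root = cfg.out_dir / "pixels"
    rows = []
    for das, ddir in _das_dirs(cfg).items():
        found = segments[(segments["das"] == das) & segments["found"]]
        targets = {
            Sensor.VIS: read_image(_sensor_path(ddir, Sensor.VIS, das), Sensor.VIS),
            Sensor.NIR: read_image(_sensor_path(ddir, Sensor.NIR, das), Sensor.NIR),
        }
        pdir = pix_root / f"das_{das}"
        pdir.mkdir(parents=True, exist_ok=True)
        for sample_id in found["sample_id"]:
            plant = _load_plant(cfg, str(sample_id), das)
            if plant is None:
                continue
            for sensor, target in targets.items():
                t = reg.RegistrationTransform.for_sensor(sensor, cfg.platform)
                px = reg.transfer_mask(plant, t, target)
                reg.pixels_to_csv(px, pdir / f"{sensor.value.lower()}_{sample_id}.csv")
                rows.append({"sample_id": sample_id, "das": das, "sensor": sensor.value,
                             "n_pixels": px.n_pixels, "n_out_of_bounds": px.n_out_of_bounds})
    df = pd.DataFrame(rows)
    df.to_csv(cfg.out_dir / "register.csv", index=False)
    return df


def stage_profile(cfg: RunConfig) -> pd.DataFrame:
    """65-bin hue color-class profile of every VIS digital plant."""
    register = pd.read_csv(cfg.out_dir / "register.csv")
    profiles = []
    for r in register[register["sensor"] == "VIS"].itertuples():
        px = reg.pixels_from_csv(
            cfg.out_dir / "pixels" / f"das_{r.das}" / f"vis_{r.sample_id}.csv",
            str(r.sample_id), int(r.das), Sensor.VIS,
        )
        profiles.append(cc.classify_hue(px))
    cc.profiles_to_csv(profiles, cfg.out_dir / "profiles.csv")
    return pd.read_csv(cfg.out_dir / "profiles.csv")


def stage_cluster(cfg: RunConfig) -> pd.DataFrame:
    """Per-DAS Ward clustering of the profiles, cut into two health groups."""
    profiles = cc.profiles_from_csv(cfg.out_dir / "profiles.csv")
    rows = []
    for das in sorted({p.das for p in profiles}):
        sub = [p for p in profiles if p.das == das]
        if len(sub) < 2:
            log.warning("fewer than 2 profiles at DAS %d; skipping clustering", das)
            continue
        d = cc.profile_distance_matrix(sub)
        z = cc.ward_cluster(d, squared_distances=cfg.ward_squared)
        groups = cc.cut_two(z)
        labels = cc.assign_health_labels(groups, sub, cfg.platform)
        for p, g in zip(sub, groups):
            rows.append({"sample_id": p.sample_id, "das": das, "group": int(g),
                         "health_label": labels[p.sample_id]})
    df = pd.DataFrame(rows)
    df.to_csv(cfg.out_dir / "cluster.csv", index=False)
    return df


def stage_nir(cfg: RunConfig) -> pd.DataFrame:
    """Q3, base reference, index and stress call for every sample x DAS."""
    register = pd.read_csv(cfg.out_dir / "register.csv")
    nir_rows = register[register["sensor"] == "NIR"]
    q3 = {}
    for r in nir_rows.itertuples():
        px = reg.pixels_from_csv(
            cfg.out_dir / "pixels" / f"das_{r.das}" / f"nir_{r.sample_id}.csv",
            str(r.sample_id), int(r.das), Sensor.NIR,
        )
        q3.setdefault(str(r.sample_id), {})[int(r.das)] = nirmod.third_quartile(px.values)
    series = pd.DataFrame(q3).T.sort_index(axis=1)
    series = series.dropna()  # base selection needs complete time series
    base = cfg.base_das if cfg.base_das is not None else nirmod.select_base_das(
        series, tolerance=cfg.base_tolerance
    )
    records = nirmod.index_records(series, base, cfg.platform)
    df = pd.DataFrame(
        [
            {"sample_id": r.sample_id, "das": r.das, "q3": r.q3, "base_das": r.base_das,
             "index": r.index, "call": r.call}
            for r in records
        ]
    )
    df.to_csv(cfg.out_dir / "nir.csv", index=False)
    return df


def stage_stats(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Agreement vs inspection, area summaries/tests and survival rates."""
    labels = read_labels_csv(cfg.labels_csv)
    _layout, samples = read_layout_csv(cfg.layout_csv)
    segments = pd.read_csv(cfg.out_dir / "segments.csv")
    cluster = pd.read_csv(cfg.out_dir / "cluster.csv")
    nir_df = pd.read_csv(cfg.out_dir / "nir.csv")

    insp = {(str(r.sample_id), int(r.das)): r.status for r in labels.itertuples()}
    agreement_rows = []
    for name, frame, col, to_binary in (
        ("cluster", cluster, "health_label", lambda v: v),
        ("nir", nir_df, "call", lambda v: "stressed" if v == "stressed" else "healthy"),
    ):
        for das in sorted(frame["das"].unique()):
            sub = frame[frame["das"] == das]
            pred = {str(r.sample_id): to_binary(getattr(r, col)) for r in sub.itertuples()}
            actual = {k: insp[(k, das)] for k in pred if (k, das) in insp}
            pred = {k: pred[k] for k in actual}
            if not pred:
                continue
            rec = st.agreement(pred, actual, das=int(das), classifier=name)
            gof = st.gof_chi2(rec.matches, rec.total)
            agreement_rows.append({"das": rec.das, "classifier": name, "matches": rec.matches,
                                   "total": rec.total, "percent": rec.percent, "p": gof.pvalue})
    agreement_df = pd.DataFrame(agreement_rows)
    agreement_df.to_csv(cfg.out_dir / "agreement.csv", index=False)

    plants = segments.merge(samples, on="sample_id", how="left")
    plants = plants[plants["line"] != "soil-only"]
    area_df = st.area_series(plants.rename(columns={"area": "area"}))
    area_df.to_csv(cfg.out_dir / "area_summary.csv", index=False)

    ttest_rows = []
    for das in sorted(plants["das"].unique()):
        sub = plants[(plants["das"] == das) & plants["found"]]
        x = sub[sub["treatment"] == "water-limited"]["area"].to_numpy()
        y = sub[sub["treatment"] == "well-watered"]["area"].to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            try:
                res = st.welch_t_test(x, y)
            except ValueError:
                continue
            ttest_rows.append({"das": int(das), "p": res.pvalue, "n_limited": len(x),
                               "n_watered": len(y)})
    ttest_df = pd.DataFrame(ttest_rows)
    ttest_df.to_csv(cfg.out_dir / "area_tests.csv", index=False)

    final = labels[labels["final_status"] != "unknown"][["sample_id", "final_status"]]
    final = final.merge(samples, on="sample_id", how="left")
    if len(final) and (final["treatment"] == "water-limited").any():
        survival_df = st.survival_summary(final)
    else:
        survival_df = pd.DataFrame(columns=["line", "n", "pct_alive", "pct_dead"])
    survival_df.to_csv(cfg.out_dir / "survival.csv", index=False)
    return {"agreement": agreement_df, "area_summary": area_df, "area_tests": ttest_df,
            "survival": survival_df}


def stage_report(cfg: RunConfig) -> Path:
    """Projected-leaf-area figure plus a short plain-text run summary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    area = pd.read_csv(cfg.out_dir / "area_summary.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    for (line, treatment), grp in area.groupby(["line", "treatment"]):
        grp = grp.sort_values("das")
        ax.errorbar(grp["das"], grp["mean"], yerr=grp["se"].fillna(0),
                    label=f"{line} / {treatment}", marker="o", capsize=2)
    ax.set_xlabel("days after sowing")
    ax.set_ylabel("projected leaf area (px)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig_path = cfg.out_dir / "area_series.png"
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)

    agreement = pd.read_csv(cfg.out_dir / "agreement.csv")
    with open(cfg.out_dir / "report.txt", "w") as fh:
        fh.write("phenodrought run summary\n")
        fh.write(agreement.to_string(index=False))
        fh.write("\n")
    return fig_path


STAGES = {
    "segment": stage_segment,
    "register": stage_register,
    "profile": stage_profile,
    "cluster": stage_cluster,
    "nir": stage_nir,
    "stats": stage_stats,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage in order and write a run log.

    Deterministic given config + seed; every stage's intermediates land in
    ``cfg.out_dir``.
    """
    if not cfg.layout_csv.exists():
        raise FileNotFoundError(f"layout CSV not found: {cfg.layout_csv}")
    if not cfg.labels_csv.exists():
        raise FileNotFoundError(f"labels CSV not found: {cfg.labels_csv}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name in ("segment", "register", "profile", "cluster", "nir"):
        out = STAGES[name](cfg)
        counts[name] = int(len(out))
        log.info("stage %-8s -> %d rows", name, counts[name])
    results = stage_stats(cfg)
    stage_report(cfg)
    import phenodrought

    with open(cfg.out_dir / "run_log.json", "w") as fh:
        json.dump(
            {
                "version": phenodrought.__version__,
                "seed": cfg.seed,
                "platform": dataclasses.asdict(cfg.platform),
                "counts": counts,
            },
            fh,
            indent=2,
            default=str,
        )
    return results


def simulate(
    out_dir: str | Path,
    seed: int = 0,
    n_plants: int = 24,
    n_stressed: int = 12,
    scale: float = 4.0,
    **cohort_kwargs,
) -> RunConfig:
    """Generate a synthetic dataset on disk plus a ready-to-run config."""
    from .synthetic import make_cohort_spec, write_dataset

    out_dir = Path(out_dir)
    spec = make_cohort_spec(
        n_plants=n_plants, n_stressed=n_stressed, scale=scale, seed=seed, **cohort_kwargs
    )
    write_dataset(spec, seed, out_dir)
    cfg = RunConfig(
        image_root=out_dir,
        layout_csv=out_dir / "layout.csv",
        labels_csv=out_dir / "labels.csv",
        out_dir=out_dir / "results",
        platform=spec.config,
        seed=seed,
    )
    cfg.to_yaml(out_dir / "config.yaml")
    return cfg
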