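import numpy as np
import pytest

from phenodrought.imaging_io import PlatformConfig, Sensor, SensorImage, rgb_to_hsb
from phenodrought.registration import (
    RegistrationTransform,
    projected_area,
    resized_dims,
    scale_coords,
    transfer_mask,
)
from phenodrought.segmentation import (
    DigitalPlant,
    label_regions,
    mask_from_coords,
    select_digital_plant,
    threshold_fluo,
)


def plant_from_coords(coords, sample_id="p", das=0):
    return DigitalPlant(sample_id=sample_id, das=das, coords=np.asarray(coords, dtype=np.int64))


class TestScaleCoords:
    def test_fluo_to_vis_frame_height(self, cfg):
        t = RegistrationTransform.for_vis(cfg)
        assert resized_dims(t) == (2900, 2166)  # round(1038 * 2900/1390)

    def test_origin_fixed(self, cfg):
        for t in (RegistrationTransform.for_vis(cfg), RegistrationTransform.for_nir(cfg)):
            assert tuple(scale_coords(np.array([[0, 0]]), t)[0]) == (0, 0)

    def test_identity_when_width_matches_source(self):
        t = RegistrationTransform((1390, 1038), 1390.0, (0.0, 0.0))
        coords = np.array([[3, 7], [100, 900], [1389, 1037]])
        assert np.array_equal(scale_coords(coords, t), coords)


class TestTransferMask:
    def test_identity_transform_reads_same_coordinates(self, rng):
        t = RegistrationTransform((40, 30), 40.0, (0.0, 0.0))
        target = SensorImage(Sensor.NIR, rng.integers(0, 256, (30, 40), dtype=np.uint8))
        coords = [[5, 5], [6, 5], [5, 6], [20, 17]]
        px = transfer_mask(plant_from_coords(coords), t, target)
        assert px.n_out_of_bounds == 0
        assert sorted(map(tuple, px.coords)) == sorted(map(tuple, coords))
        for (x, y), v in zip(px.coords, px.values):
            assert target.pixels[y, x] == v

    def test_out_of_bounds_counted_not_read(self):
        t = RegistrationTransform((40, 30), 40.0, (35.0, 0.0))  # shifts far right
        target = SensorImage(Sensor.NIR, np.zeros((30, 40), dtype=np.uint8))
        px = transfer_mask(plant_from_coords([[2, 2], [30, 2]]), t, target)
        # (2,2) -> (-33, 2) out; (30, 2) -> (-5, 2) out
        assert px.n_pixels == 0
        assert px.n_out_of_bounds == 2

    def test_conservation_of_pixel_counts(self, rng):
        t = RegistrationTransform((40, 30), 40.0, (10.0, -3.0))
        target = SensorImage(Sensor.NIR, rng.integers(0, 256, (30, 40), dtype=np.uint8))
        coords = np.unique(rng.integers(0, 30, (60, 2)), axis=0)
        px = transfer_mask(plant_from_coords(coords), t, target)
        assert px.n_pixels + px.n_out_of_bounds == len(coords)

    def test_translation_consistency(self, rng):
        base = rng.integers(0, 256, (60, 60), dtype=np.uint8)
        coords = np.column_stack(
            [rng.integers(20, 35, 40), rng.integers(20, 35, 40)]
        )
        t0 = RegistrationTransform((60, 60), 60.0, (0.0, 0.0))
        px0 = transfer_mask(plant_from_coords(coords), t0, SensorImage(Sensor.NIR, base))
        ox, oy = 4, -6
        shifted = np.roll(base, shift=(-oy, -ox), axis=(0, 1))
        t1 = RegistrationTransform((60, 60), 60.0, (float(ox), float(oy)))
        px1 = transfer_mask(plant_from_coords(coords), t1, SensorImage(Sensor.NIR, shifted))
        v0 = {tuple(c): v for c, v in zip(px0.coords, px0.values)}
        v1 = {(x + ox, y + oy): v for (x, y), v in zip(px1.coords, px1.values)}
        common = set(v0) & set(v1)
        assert len(common) >= 30
        assert all(v0[k] == v1[k] for k in common)

    def test_zero_dim_target_rejected(self):
        t = RegistrationTransform((4, 4), 4.0, (0.0, 0.0))
        with pytest.raises(Exception):
            transfer_mask(
                plant_from_coords([[0, 0]]),
                t,
                SensorImage(Sensor.NIR, np.zeros((0, 0), dtype=np.uint8)),
            )


class TestProjectedArea:
    def test_counts_coordinates(self):
        coords = np.column_stack([np.arange(1234), np.zeros(1234, dtype=int)])
        assert projected_area(plant_from_coords(coords)) == 1234

    def test_missing_plant_is_missing_value(self):
        assert projected_area(None) is None

    def test_rasterized_disk_area_close_to_analytic(self):
        r = 30
        xs, ys = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
        keep = xs**2 + ys**2 <= r * r
        coords = np.column_stack([xs[keep] + 50, ys[keep] + 50])
        area = projected_area(plant_from_coords(coords))
        assert abs(area - np.pi * r * r) / (np.pi * r * r) < 0.05


class TestSyntheticRoundTrip:
    @pytest.mark.parametrize("seed", range(3))
    def test_mask_transfer_recovers_sensor_ground_truth(self, seed):
        """Forward transfer of the segmented FLUO plant overlaps the
        generator's per-sensor ground truth (IoU >= 0.9; VIS >= 0.95)."""
        from phenodrought.synthetic import generate_scene, make_cohort_spec

        spec = make_cohort_spec(n_plants=6, n_stressed=3, radius=30, seed=seed)
        bundle = generate_scene(spec, spec.das_list[-1], seed)
        regions = label_regions(
            threshold_fluo(rgb_to_hsb(bundle.images[Sensor.FLUO]), spec.config)
        )
        for slot in spec.layout.slots:
            plant = select_digital_plant(regions, slot.center, spec.config, slot.sample_id, 0)
            assert plant is not None
            for sensor, floor in ((Sensor.VIS, 0.95), (Sensor.NIR, 0.9)):
                t = RegistrationTransform.for_sensor(sensor, spec.config)
                px = transfer_mask(plant, t, bundle.images[sensor])
                img = bundle.images[sensor]
                got = mask_from_coords(px.coords, (img.width, img.height))
                gt = bundle.gt_masks[slot.sample_id][sensor]
                iou = (got & gt).sum() / (got | gt).sum()
                assert iou >= floor, (sensor, slot.sample_id, iou)
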