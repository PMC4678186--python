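import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenodrought.color_classes import (
    ColorProfile,
    assign_health_labels,
    class_representative,
    classify_hue,
    cut_two,
    hue_class,
    profile_distance_matrix,
    ward_cluster,
)
from phenodrought.imaging_io import Sensor, hsb_to_rgb
from phenodrought.registration import SensorPlantPixels

from .oracles import linkage_merges, ward_lw_merges


def vis_pixels(rgb_values, sample_id="p", das=0):
    vals = np.asarray(rgb_values, dtype=np.uint8)
    coords = np.zeros((len(vals), 2), dtype=np.int64)
    return SensorPlantPixels(sample_id, das, Sensor.VIS, vals, coords, 0)


def profile_at(class_idx, sample_id="p", das=0, n_pixels=100):
    pct = np.zeros(65)
    pct[class_idx] = 100.0
    return ColorProfile(sample_id, das, pct, n_pixels)


class TestHueClassification:
    def test_hue_zero_maps_to_class_zero(self):
        assert hue_class(0.0) == 0

    def test_hue_255_maps_to_class_64(self):
        assert hue_class(255.0) == 64  # floor(255 * 65/256) = floor(64.75)

    def test_bins_tile_the_hue_range(self):
        classes = hue_class(np.linspace(0, 255, 10_000))
        assert classes.min() == 0 and classes.max() == 64
        assert np.all(np.diff(classes) >= 0)

    def test_uniform_hue_plant_is_one_class_at_100(self):
        px = vis_pixels([[0, 255, 0]] * 50)  # hue 85 -> class 21
        prof = classify_hue(px)
        assert prof.percentages[21] == pytest.approx(100.0)
        assert prof.percentages.sum() == pytest.approx(100.0)
        assert np.count_nonzero(prof.percentages) == 1

    def test_empty_pixels_rejected(self):
        with pytest.raises(ValueError):
            classify_hue(vis_pixels(np.zeros((0, 3))))

    def test_profile_size_invariance(self, rng):
        """Duplicating a plant's pixel multiset leaves the profile unchanged."""
        vals = rng.integers(0, 256, (200, 3), dtype=np.uint8)
        p1 = classify_hue(vis_pixels(vals))
        p2 = classify_hue(vis_pixels(np.vstack([vals, vals, vals])))
        assert np.allclose(p1.percentages, p2.percentages)


class TestClassRepresentative:
    def test_class_0_is_a_red_with_hue_2(self):
        rep = class_representative(0)
        assert rep.hue == 2  # midpoint of [0, 3.94)
        assert rep.rgb[0] == 255 and rep.rgb[0] > rep.rgb[1]

    def test_class_21_is_near_pure_green(self):
        rep = class_representative(21)  # contains hue 85
        r, g, b = rep.rgb
        assert g == 255 and r <= 10 and b <= 10

    def test_every_representative_inside_its_interval(self):
        for i in range(65):
            rep = class_representative(i)
            assert i * 256 / 65 <= rep.hue < (i + 1) * 256 / 65

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            class_representative(65)


class TestDistanceMatrix:
    def test_identical_profiles_distance_zero(self):
        d = profile_distance_matrix([profile_at(10, "a"), profile_at(10, "b")])
        assert d[0, 1] == 0.0

    def test_disjoint_pure_profiles(self):
        d = profile_distance_matrix([profile_at(10), profile_at(50)])
        assert d[0, 1] == pytest.approx(100.0 * np.sqrt(2))

    def test_symmetric_zero_diagonal_triangle(self, rng):
        pcts = rng.dirichlet(np.ones(65), size=5) * 100
        profs = [ColorProfile(f"s{i}", 0, p, 10) for i, p in enumerate(pcts)]
        d = profile_distance_matrix(profs)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            profile_distance_matrix([profile_at(3)])


class TestWardCluster:
    def test_two_points_merge_at_their_distance(self):
        d = np.array([[0.0, 7.0], [7.0, 0.0]])
        z = ward_cluster(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(7.0)

    def test_two_blobs_join_last(self, rng):
        pcts = np.vstack(
            [
                np.clip(rng.normal(0, 0.5, (4, 65)) + profile_at(20).percentages, 0, None),
                np.clip(rng.normal(0, 0.5, (4, 65)) + profile_at(50).percentages, 0, None),
            ]
        )
        pcts = pcts / pcts.sum(axis=1, keepdims=True) * 100
        profs = [ColorProfile(f"s{i}", 0, p, 10) for i, p in enumerate(pcts)]
        z = ward_cluster(profile_distance_matrix(profs))
        groups = cut_two(z)
        assert set(groups[:4]) != set(groups[4:])
        assert len(set(groups[:4])) == 1 and len(set(groups[4:])) == 1

    def test_merge_heights_monotone(self, rng):
        d = profile_distance_matrix(
            [ColorProfile(f"s{i}", 0, p, 10) for i, p in enumerate(rng.dirichlet(np.ones(65), 12) * 100)]
        )
        z = ward_cluster(d)
        assert np.all(np.diff(z[:, 2]) >= -1e-9)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_naive_lance_williams_oracle(self, n, rng):
        for _ in range(10):
            pts = rng.random((n, 4)) * 10
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            got = linkage_merges(ward_cluster(d))
            expected = ward_lw_merges(d)
            for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
                assert {ga, gb} == {ea, eb}
                assert gh == pytest.approx(eh, rel=1e-9)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative


class TestCutTwo:
    def test_two_samples_split_apart(self):
        z = ward_cluster(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert list(cut_two(z)) == [1, 2]

    def test_partition_covers_everyone(self, rng):
        pcts = rng.dirichlet(np.ones(65), 9) * 100
        profs = [ColorProfile(f"s{i}", 0, p, 10) for i, p in enumerate(pcts)]
        groups = cut_two(ward_cluster(profile_distance_matrix(profs)))
        assert len(groups) == 9
        assert set(groups) == {1, 2}


class TestHealthLabels:
    def _cohort(self, rng, n_green=4, n_brown=4):
        profs, groups = [], []
        for i in range(n_green):
            hue = rng.normal(85, 3)
            profs.append(profile_at(int(hue_class(hue)), f"g{i}"))
            groups.append(1)
        for i in range(n_brown):
            hue = rng.normal(30, 3)
            profs.append(profile_at(int(hue_class(hue)), f"b{i}"))
            groups.append(2)
        return np.array(groups), profs

    def test_green_group_labeled_healthy(self, rng):
        groups, profs = self._cohort(rng)
        labels = assign_health_labels(groups, profs)
        assert all(labels[f"g{i}"] == "healthy" for i in range(4))
        assert all(labels[f"b{i}"] == "stressed" for i in range(4))

    def test_labels_follow_profiles_not_group_ids(self, rng):
        groups, profs = self._cohort(rng)
        swapped = np.where(groups == 1, 2, 1)
        labels = assign_health_labels(swapped, profs)
        assert all(labels[f"g{i}"] == "healthy" for i in range(4))

    def test_single_group_rejected(self, rng):
        groups, profs = self._cohort(rng)
        with pytest.raises(ValueError):
            assign_health_labels(np.ones_like(groups), profs)

    def test_identical_centroids_degenerate(self):
        profs = [profile_at(0, "a"), profile_at(0, "b")]
        with pytest.raises(ValueError):
            assign_health_labels(np.array([1, 2]), profs)


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 255))
def test_hue_class_brackets_match_interval_arithmetic(h):
    i = int(hue_class(float(h)))
    assert i * 256 / 65 <= h < (i + 1) * 256 / 65
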