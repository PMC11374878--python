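"""Resampling, centroid-distance labeling, density volumetry, tract means."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tractometry.bundles import (
    BundleAtlas,
    BundleEntry,
    UNLABELED,
    bundle_volume,
    density_mask,
    label_tractogram,
    measure_subject,
    normalize_volume,
    resample_streamline,
    streamline_distance,
    tract_metric_mean,
)
from tractometry.dti import ScalarMap
from tractometry.tracking import Tractogram

EYE = np.eye(4)


def _line(p0, p1, n=2):
    return np.linspace(np.asarray(p0, float), np.asarray(p1, float), n)


class TestResample:
    def test_unit_segment_at_tenth_step(self):
        out = resample_streamline(_line((0, 0, 0), (1, 0, 0)), step=0.1)
        assert out.shape == (11, 3)
        np.testing.assert_allclose(out[:, 0], np.arange(11) / 10, atol=1e-12)

    def test_endpoints_preserved(self):
        s = np.array([[0, 0, 0], [1, 2, 0], [3, 1, 4.0]])
        out = resample_streamline(s, step=0.37)
        np.testing.assert_allclose(out[0], s[0], atol=1e-12)
        np.testing.assert_allclose(out[-1], s[-1], atol=1e-12)

    def test_semicircle_length_preserved(self):
        t = np.linspace(0, np.pi, 200)
        arc = np.column_stack([5 * np.cos(t), 5 * np.sin(t), np.zeros_like(t)])
        out = resample_streamline(arc, step=0.1)
        length = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
        assert length == pytest.approx(np.pi * 5, abs=0.1)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_streamline(np.zeros((3, 3)), step=0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(3, 20), st.integers(0, 100))
    def test_property_spacing_equidistant(self, n_pts, seed):
        rng = np.random.default_rng(seed)
        s = np.cumsum(rng.uniform(0.1, 1.0, size=(n_pts, 3)), axis=0)
        out = resample_streamline(s, n_points=15)
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        # equal arc-length parameter steps: spacing varies only with curvature
        assert out.shape == (15, 3)
        assert gaps.max() <= np.linalg.norm(np.diff(s, axis=0), axis=1).sum()


class TestStreamlineDistance:
    def test_identical_zero(self):
        s = _line((0, 0, 0), (10, 0, 0), 5)
        assert streamline_distance(s, s) == 0.0

    def test_flip_invariance(self):
        s = _line((0, 0, 0), (10, 3, 1), 7)
        assert streamline_distance(s, s[::-1]) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_offset_is_offset(self):
        a = _line((0, 0, 0), (10, 0, 0), 4)
        b = _line((0, 2, 0), (10, 2, 0), 4)
        assert streamline_distance(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_symmetry_property(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = np.cumsum(rng.uniform(-1, 1, size=(6, 3)), axis=0)
            b = np.cumsum(rng.uniform(-1, 1, size=(9, 3)), axis=0)
            assert streamline_distance(a, b) == pytest.approx(
                streamline_distance(b, a), abs=1e-12
            )

    def test_mismatched_counts_rejected_without_resampling(self):
        with pytest.raises(ValueError, match="point counts differ"):
            streamline_distance(np.zeros((3, 3)), np.zeros((4, 3)), n_points=None)


def _toy_atlas():
    return BundleAtlas(
        [
            BundleEntry("along_x", _line((0, 0, 0), (20, 0, 0)), 5.0, "association"),
            BundleEntry("along_y", _line((0, 0, 0), (0, 20, 0)), 5.0, "projection"),
            BundleEntry("diagonal", _line((0, 0, 10), (20, 20, 10)), 5.0, "other"),
        ]
    )


class TestLabeling:
    def test_centroid_maps_to_own_label(self):
        atlas = _toy_atlas()
        tg = Tractogram([e.centroid.copy() for e in atlas.entries])
        labeled = label_tractogram(tg, atlas)
        assert labeled.labels.tolist() == atlas.names

    def test_closest_wins_when_two_thresholds_satisfied(self):
        atlas = BundleAtlas(
            [
                BundleEntry("a", _line((0, 0, 0), (20, 0, 0)), 10.0),
                BundleEntry("b", _line((0, 3, 0), (20, 3, 0)), 10.0),
            ]
        )
        s = _line((0, 1, 0), (20, 1, 0))  # 1 mm from a, 2 mm from b
        labeled = label_tractogram(Tractogram([s]), atlas)
        assert labeled.labels[0] == "a"

    def test_beyond_every_threshold_unlabeled(self):
        labeled = label_tractogram(
            Tractogram([_line((0, 0, 50), (20, 0, 50))]), _toy_atlas()
        )
        assert labeled.labels[0] == UNLABELED

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        lines = [
            np.cumsum(rng.uniform(-2, 2, size=(rng.integers(3, 8), 3)), axis=0)
            + rng.uniform(0, 20, 3)
            for _ in range(60)
        ]
        labeled = label_tractogram(Tractogram(lines), _toy_atlas())
        counts = labeled.counts()
        assert sum(counts.values()) == 60

    def test_threshold_shrink_monotonicity(self):
        rng = np.random.default_rng(2)
        lines = [
            _line((0, rng.uniform(-4, 4), rng.uniform(-4, 4)),
                  (20, rng.uniform(-4, 4), rng.uniform(-4, 4)))
            for _ in range(40)
        ]
        tg = Tractogram(lines)

        def count_at(thr):
            atlas = BundleAtlas([BundleEntry("x", _line((0, 0, 0), (20, 0, 0)), thr)])
            return label_tractogram(tg, atlas).counts().get("x", 0)

        counts = [count_at(t) for t in (8.0, 5.0, 3.0, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_atlas_rejected(self):
        with pytest.raises(ValueError, match="no entries"):
            label_tractogram(Tractogram([]), BundleAtlas([]))


class TestDensityMask:
    def test_five_identical_streamlines_hit_threshold(self):
        s = _line((0.0, 2, 2), (9.0, 2, 2), 50)
        mask = density_mask([s] * 5, (10, 5, 5), EYE, min_fibers=5)
        assert mask.sum() == 10
        assert np.all(mask[:, 2, 2])

    def test_four_streamlines_below_threshold_empty(self):
        s = _line((0.0, 2, 2), (9.0, 2, 2), 50)
        assert density_mask([s] * 4, (10, 5, 5), EYE, min_fibers=5).sum() == 0

    def test_distinct_streamline_counting_ignores_point_density(self):
        """A streamline resampled to many points still counts once per voxel."""
        coarse = _line((0.0, 2, 2), (9.0, 2, 2), 10)
        fine = resample_streamline(coarse, step=0.01)
        m1 = density_mask([coarse] * 5, (10, 5, 5), EYE, min_fibers=5)
        m2 = density_mask([fine] * 5, (10, 5, 5), EYE, min_fibers=5)
        np.testing.assert_array_equal(m1, m2)

    def test_adding_streamlines_never_shrinks_mask(self):
        rng = np.random.default_rng(3)
        lines = [
            _line((0, rng.uniform(1, 3), rng.uniform(1, 3)),
                  (9, rng.uniform(1, 3), rng.uniform(1, 3)), 30)
            for _ in range(12)
        ]
        prev = np.zeros((10, 5, 5), dtype=bool)
        for k in range(5, 13):
            cur = density_mask(lines[:k], (10, 5, 5), EYE, min_fibers=5)
            assert np.all(cur[prev])
            prev = cur

    def test_empty_bundle_empty_mask(self):
        assert density_mask([], (4, 4, 4), EYE).sum() == 0


class TestVolumes:
    def test_forced_arithmetic(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:512] = True
        assert bundle_volume(mask, 1.25) == pytest.approx(1.0)  # 512 * 1.953125 mm^3
        assert bundle_volume(np.zeros((3, 3, 3), dtype=bool), 1.25) == 0.0
        assert bundle_volume(np.ones((64, 64, 64), dtype=bool), 1.0) == pytest.approx(262.144)

    @pytest.mark.parametrize(
        "raw,ref,expected", [(25.0, 1250.0, 2.0), (7.5, 7.5, 100.0), (23.0, 1117.0, 2.0591)]
    )
    def test_normalization(self, raw, ref, expected):
        assert normalize_volume(raw, ref) == pytest.approx(expected, abs=5e-5)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            normalize_volume(1.0, 0.0)

    def test_rigid_motion_invariance(self):
        """Volumes agree when bundle and grid move together (one voxel slack)."""
        rng = np.random.default_rng(4)
        lines = [
            _line((2, rng.uniform(4, 6), rng.uniform(4, 6)),
                  (12, rng.uniform(4, 6), rng.uniform(4, 6)), 40)
            for _ in range(20)
        ]
        base = density_mask(lines, (15, 11, 11), EYE, min_fibers=5)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.uniform(-3, 3, 3)
        motion = np.eye(4)
        motion[:3, :3], motion[:3, 3] = q, t
        moved_lines = [l @ q.T + t for l in lines]
        moved_grid = motion @ EYE
        moved = density_mask(moved_lines, (15, 11, 11), moved_grid, min_fibers=5)
        a, b = bundle_volume(base, 1.0), bundle_volume(moved, 1.0)
        layer = base.sum() ** (2 / 3) / 1000.0  # ~ one voxel layer in cm^3
        assert abs(a - b) <= max(layer, 0.05 * a)


class TestTractMetricMean:
    def test_constant_map_exact(self):
        cmap = np.full((10, 10, 10), 3.7)
        bundle = [_line((1, 1, 1), (8, 8, 8), 5)]
        assert tract_metric_mean(bundle, cmap, EYE) == pytest.approx(3.7, rel=1e-12)

    def test_linear_field_midpoint_value(self):
        """Trilinear interpolation is exact for fields linear in x."""
        x = np.arange(12, dtype=float)
        fmap = np.broadcast_to(x[:, None, None], (12, 5, 5)).copy()
        bundle = [_line((0.0, 2, 2), (10.0, 2, 2), 3)]
        assert tract_metric_mean(bundle, fmap, EYE) == pytest.approx(5.0, rel=1e-10)

    def test_matches_brute_force_oracle(self):
        """Hand-rolled trilinear oracle agrees to 1e-10 on a random map."""
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 1, size=(6, 6, 6))
        s = _line((0.7, 1.2, 2.9), (4.1, 3.8, 1.3), 4)
        got = tract_metric_mean([s], data, EYE, resample_step=0.25)

        pts = resample_streamline(s, step=0.25)
        vals = []
        for p in pts:
            i0 = np.floor(p).astype(int)
            t = p - i0
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((t[0] if dx else 1 - t[0])
                             * (t[1] if dy else 1 - t[1])
                             * (t[2] if dz else 1 - t[2]))
                        acc += w * data[i0[0] + dx, i0[1] + dy, i0[2] + dz]
            vals.append(acc)
        assert got == pytest.approx(np.mean(vals), abs=1e-10)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(0, 1, size=(8, 8, 8))
        s = np.cumsum(rng.uniform(0.2, 0.8, size=(6, 3)), axis=0)
        a = tract_metric_mean([s], data, EYE)
        b = tract_metric_mean([s[::-1]], data, EYE)
        assert a == pytest.approx(b, abs=1e-9)

    def test_out_of_grid_names_extent(self):
        with pytest.raises(ValueError, match="outside the map grid"):
            tract_metric_mean([_line((0, 0, 0), (30, 0, 0))], np.zeros((5, 5, 5)), EYE)


class TestMeasureSubject:
    @pytest.fixture()
    def labeled_tube(self):
        rng = np.random.default_rng(7)
        # cylinder of streamlines along x, radius ~2, length 16
        lines = []
        for _ in range(400):
            r, phi = np.sqrt(rng.uniform(0, 1)) * 2.0, rng.uniform(0, 2 * np.pi)
            y, z = 8 + r * np.cos(phi), 8 + r * np.sin(phi)
            lines.append(_line((2, y, z), (18, y, z), 60))
        tg = Tractogram(lines)
        atlas = BundleAtlas(
            [
                BundleEntry("tube", _line((2, 8, 8), (18, 8, 8)), 6.0),
                BundleEntry("absent", _line((0, 0, 0), (0, 0, 20)), 3.0),
            ]
        )
        return label_tractogram(tg, atlas), atlas

    def test_volume_near_cylinder_and_identities(self, labeled_tube):
        labeled, atlas = labeled_tube
        shape = (21, 17, 17)
        brain = np.ones(shape, dtype=bool)
        wm = np.zeros(shape, dtype=bool)
        wm[2:19, 5:12, 5:12] = True
        maps = {"fa": ScalarMap("fa", np.full(shape, 0.5))}
        sm = measure_subject(
            labeled, maps, brain, wm, EYE, 1.0, atlas, subject_id="s0", sex="F",
            min_fibers=5,
        )
        row = sm.per_tract.set_index("tract").loc["tube"]
        # rasterized-cylinder oracle: a voxel can receive streamline points
        # iff its rounding cell intersects the disk of radius 2 about (8, 8)
        area = 0
        for iy in range(17):
            for iz in range(17):
                dy = max(abs(iy - 8.0) - 0.5, 0.0)
                dz = max(abs(iz - 8.0) - 0.5, 0.0)
                area += np.hypot(dy, dz) <= 2.0
        n_slabs = 18 - 2 + 1  # x in [2, 18] rounds to 17 slabs
        oracle = area * n_slabs / 1000.0  # cm^3 at 1 mm voxels
        assert row.volume_cm3 == pytest.approx(oracle, rel=0.15)
        # normalization identities hold exactly
        assert row.volume_cm3 == pytest.approx(row.vol_pct_tbv * sm.tbv_cm3 / 100, abs=1e-12)
        assert row.volume_cm3 == pytest.approx(row.vol_pct_wmv * sm.wmv_cm3 / 100, abs=1e-12)
        assert row.fa == pytest.approx(0.5, rel=1e-12)

    def test_absent_bundle_zero_volume_nan_metrics(self, labeled_tube):
        labeled, atlas = labeled_tube
        shape = (21, 17, 17)
        sm = measure_subject(
            labeled, {"fa": ScalarMap("fa", np.zeros(shape))},
            np.ones(shape, dtype=bool), np.ones(shape, dtype=bool), EYE, 1.0, atlas,
        )
        row = sm.per_tract.set_index("tract").loc["absent"]
        assert row.volume_cm3 == 0.0
        assert np.isnan(row.fa)

    def test_grid_mismatch_rejected(self, labeled_tube):
        labeled, atlas = labeled_tube
        with pytest.raises(ValueError, match="grid"):
            measure_subject(
                labeled, {}, np.ones((4, 4, 4), dtype=bool), np.ones((5, 5, 5), dtype=bool),
                EYE, 1.0, atlas,
            )
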