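"""Bundle construction: assignment, filtering, morphology, overlap, sampling."""

import numpy as np
import pytest

import wmbold as w
from wmbold.bundles import _rasterize


def _grid_parcellation(labels, voxel_size=2.0, pseudo=(), wm=None):
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return w.Parcellation(np.asarray(labels), affine, frozenset(pseudo), wm)


@pytest.fixture
def two_parcel_grid():
    """10x10x10 grid at 2 mm: parcel 3 near x-low, parcel 7 near x-high."""
    labels = np.zeros((10, 10, 10), dtype=int)
    labels[0:2, 4:6, 4:6] = 3
    labels[8:10, 4:6, 4:6] = 7
    return _grid_parcellation(labels)


def _straight(p0, p1, n=20):
    t = np.linspace(0, 1, n)[:, None]
    return (1 - t) * np.asarray(p0, float) + t * np.asarray(p1, float)


class TestAssignStreamline:
    def test_endpoints_inside_parcels(self, two_parcel_grid):
        sl = _straight([2, 9, 9], [17, 9, 9])  # voxel (1,4,4) -> (8,4,4) in mm
        assert w.assign_streamline(sl, two_parcel_grid) == frozenset({3, 7})

    def test_self_loop_excluded(self, two_parcel_grid):
        sl = _straight([2, 8, 8], [2, 10, 10])
        assert w.assign_streamline(sl, two_parcel_grid) is None

    def test_nearest_label_search_within_radius(self):
        """Endpoint 1 mm outside parcel 5 on a hand-built 5^3 grid; exhaustive
        nearest-label check confirms the assigned parcel."""
        labels = np.zeros((5, 5, 5), dtype=int)
        labels[0, 2, 2] = 5
        labels[4, 2, 2] = 6
        parc = _grid_parcellation(labels)
        # parcel-5 voxel centre is (0,4,4) mm; endpoint 1 mm away at x=1
        sl = _straight([1.0, 4.0, 4.0], [8.0, 4.0, 4.0])
        pair = w.assign_streamline(sl, parc, search_radius_mm=2.0)
        assert pair == frozenset({5, 6})
        # exhaustive check: 5 is indeed the closest labelled voxel
        endpoint = np.array([1.0, 4.0, 4.0])
        dists = {
            int(labels[i, j, k]): np.linalg.norm(endpoint - 2.0 * np.array([i, j, k]))
            for i, j, k in np.argwhere(labels > 0)
        }
        assert min(dists, key=dists.get) == 5

    def test_unassignable_endpoint_returns_none(self, two_parcel_grid):
        sl = _straight([8, 8, 8], [17, 9, 9])  # start deep in background
        assert w.assign_streamline(sl, two_parcel_grid, search_radius_mm=2.0) is None

    def test_non_finite_coordinates_rejected(self, two_parcel_grid):
        sl = _straight([2, 9, 9], [17, 9, 9])
        sl[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            w.assign_streamline(sl, two_parcel_grid)

    def test_ground_truth_pairs_fully_recovered(self, small_geometry):
        _, parc, sls = small_geometry
        recovered = [
            w.assign_streamline(sl, parc) for sl in sls.streamlines
        ]
        expected = [sls.pairs[b] for b in sls.bundle_of_streamline]
        assert recovered == expected


class TestBuildBundleSet:
    def test_filter_boundary_exact(self, two_parcel_grid):
        """A bundle is retained iff its voxel count reaches the minimum."""
        sl = _straight([2, 9, 9], [17, 9, 9])
        n_vox = _rasterize(sl, two_parcel_grid).shape[0]
        kept = w.build_bundle_set([sl], two_parcel_grid, min_voxels=n_vox)
        assert len(kept) == 1 and kept.bundles[0].n_voxels == n_vox
        dropped = w.build_bundle_set([sl], two_parcel_grid, min_voxels=n_vox + 1)
        assert len(dropped) == 0

    def test_projection_vs_association_classification(self, small_geometry):
        _, parc, sls = small_geometry
        bs = w.build_bundle_set(sls.streamlines, parc, min_voxels=1)
        assert len(bs) == len(sls.pairs)
        by_pair = {b.parcel_pair: b.kind for b in bs.bundles}
        for pair, kind in zip(sls.pairs, sls.kinds):
            assert by_pair[pair] == kind

    def test_filter_property_min_voxels(self, small_geometry):
        _, parc, sls = small_geometry
        bs = w.build_bundle_set(sls.streamlines, parc, min_voxels=30)
        assert all(b.n_voxels >= 30 for b in bs.bundles)

    def test_volume_equals_voxel_count_times_voxel_volume(self, small_geometry):
        cfg, parc, sls = small_geometry
        bs = w.build_bundle_set(sls.streamlines, parc, min_voxels=1)
        voxvol = cfg.voxel_size_mm**3
        for b in bs.bundles:
            assert b.volume_mm3 == pytest.approx(b.n_voxels * voxvol)

    def test_empty_input_rejected(self, two_parcel_grid):
        with pytest.raises(ValueError):
            w.build_bundle_set([], two_parcel_grid)

    def test_all_filtered_gives_empty_set_not_error(self, two_parcel_grid):
        sl = _straight([2, 9, 9], [17, 9, 9])
        bs = w.build_bundle_set([sl], two_parcel_grid, min_voxels=10_000)
        assert len(bs) == 0


class TestMorphology:
    def _bundle(self, streamlines, parc):
        mask = np.unique(
            np.vstack([_rasterize(s, parc) for s in streamlines]), axis=0
        )
        return w.Bundle(0, frozenset({1, 2}), tuple(range(len(streamlines))),
                        mask, "association")

    def test_straight_streamline_along_si_axis(self, two_parcel_grid):
        sl = _straight([4, 4, 4], [4, 4, 14])
        b = self._bundle([sl], two_parcel_grid)
        _, length, angle = w.morphology(b, [sl], 8.0)
        assert length == pytest.approx(10.0)
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_straight_streamline_along_x(self, two_parcel_grid):
        sl = _straight([4, 4, 4], [14, 4, 4])
        b = self._bundle([sl], two_parcel_grid)
        _, length, angle = w.morphology(b, [sl], 8.0)
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_two_orthogonal_streamlines_give_45_degrees(self, two_parcel_grid):
        """Two equal-length orthogonal streamlines sharing a corner form an
        L whose principal axis is the diagonal, 45 deg from S-I."""
        a = _straight([4, 4, 4], [14, 4, 4])
        c = _straight([4, 4, 4], [4, 4, 14])
        b = self._bundle([a, c], two_parcel_grid)
        _, _, angle = w.morphology(b, [a, c], 8.0)
        assert angle == pytest.approx(45.0, abs=1.0)

    def test_single_point_streamline_excluded_from_length(self, two_parcel_grid):
        good = _straight([4, 4, 4], [4, 4, 14])
        degenerate = np.array([[5.0, 5.0, 5.0]])
        b = self._bundle([good], two_parcel_grid)
        _, length, _ = w.morphology(b, [good, degenerate], 8.0)
        assert length == pytest.approx(10.0)


class TestDiceAndSampling:
    def _mask_bundle(self, mask_rows):
        return w.Bundle(0, frozenset({1, 2}), (), np.asarray(mask_rows),
                        "association")

    def test_dice_identities(self):
        a = self._mask_bundle([[i, 0, 0] for i in range(10)])
        disjoint = self._mask_bundle([[i, 5, 5] for i in range(10)])
        assert w.dice(a, a) == 1.0
        assert w.dice(a, disjoint) == 0.0

    def test_dice_half_overlap(self):
        a = self._mask_bundle([[i, 0, 0] for i in range(100)])
        b = self._mask_bundle([[i, 0, 0] for i in range(50, 150)])
        assert w.dice(a, b) == pytest.approx(0.5)

    def test_dice_symmetric_and_bounded(self, small_geometry):
        _, parc, sls = small_geometry
        bs = w.build_bundle_set(sls.streamlines, parc, min_voxels=1)
        for a in bs.bundles:
            for b in bs.bundles:
                d = w.dice(a, b)
                assert 0.0 <= d <= 1.0
                assert d == pytest.approx(w.dice(b, a))

    def test_dice_empty_masks_error(self):
        empty = self._mask_bundle(np.empty((0, 3), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            w.dice(empty, empty)

    def test_sample_map_constant_and_two_level(self):
        b = self._mask_bundle([[i, 0, 0] for i in range(10)])
        vol = np.full((10, 10, 10), 3.5)
        assert w.sample_map(b, vol) == pytest.approx(3.5)
        vol2 = np.zeros((10, 10, 10))
        vol2[5:10, 0, 0] = 2.0
        assert w.sample_map(b, vol2) == pytest.approx(1.0)

    def test_sample_map_ignores_nans(self):
        """10-voxel mask, one NaN: mean over the finite 9 values."""
        b = self._mask_bundle([[i, 0, 0] for i in range(10)])
        vol = np.zeros((10, 10, 10))
        vol[:10, 0, 0] = np.arange(10, dtype=float)
        vol[0, 0, 0] = np.nan
        assert w.sample_map(b, vol) == pytest.approx(np.arange(1, 10).mean())

    def test_sample_map_all_non_finite_error(self):
        b = self._mask_bundle([[0, 0, 0]])
        vol = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            w.sample_map(b, vol)
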