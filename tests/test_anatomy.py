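"""Landmark detection, ROI construction, orientation, dentin zoning."""

import math
import warnings

import numpy as np
import pytest
from scipy import ndimage

import dentct
from dentct import anatomy
from dentct.anatomy import (
    LandmarkError,
    RoiError,
    build_cementum_roi,
    build_crown_roi,
    build_root_roi,
    detect_apical_enamel,
    detect_cej,
    ring_complete,
    subdivide_dentin,
)
from conftest import make_tube


def annulus2d(n=40, ri=8, ro=12, gap_at=None):
    c = (n - 1) / 2
    r = np.sqrt((np.arange(n)[:, None] - c) ** 2 + (np.arange(n)[None, :] - c) ** 2)
    ring = (r >= ri) & (r <= ro)
    if gap_at is not None:
        ring[gap_at] = False
    return ring


class TestRingCompleteness:
    def test_closed_annulus_is_ring(self):
        assert ring_complete(annulus2d())

    def test_one_voxel_gap_breaks_ring(self):
        ring = annulus2d()
        c = ring.shape[0] // 2
        col = np.flatnonzero(ring[c])
        ring[c, col[-1]] = False  # cut the ring on one side
        # keep cutting along the radial line until open
        ring[c, col[col > c]] = False
        assert not ring_complete(ring)

    def test_filled_disc_is_not_a_ring(self):
        disc = annulus2d(ri=0)
        assert not ring_complete(disc)

    def test_empty_slice_is_not_a_ring(self):
        assert not ring_complete(np.zeros((10, 10), bool))


class TestCejDetection:
    def test_first_complete_ring_scanning_rootward(self):
        k = 7
        stack = np.zeros((20, 40, 40), bool)
        for z in range(k, 20):
            stack[z] = annulus2d()
        # partial (sector-only) enamel below k
        partial = annulus2d()
        partial[:, :20] = False
        for z in range(3, k):
            stack[z] = partial
        assert detect_cej(stack) == k

    def test_full_tube_returns_slice_zero(self):
        stack = np.broadcast_to(annulus2d(), (15, 40, 40)).copy()
        assert detect_cej(stack) == 0

    def test_gap_on_every_slice_raises(self):
        ring = annulus2d()
        c = ring.shape[0] // 2
        ring[c, c:] = False
        stack = np.broadcast_to(ring, (10, 40, 40)).copy()
        with pytest.raises(LandmarkError):
            detect_cej(stack)

    def test_empty_mask_raises(self):
        with pytest.raises(LandmarkError):
            detect_cej(np.zeros((5, 10, 10), bool))


class TestApicalEnamel:
    def test_enamel_ending_at_j(self):
        stack = np.zeros((20, 10, 10), bool)
        stack[6:15, 4, 4] = True
        assert detect_apical_enamel(stack) == 6

    def test_single_voxel_slice(self):
        stack = np.zeros((10, 8, 8), bool)
        stack[5, 3, 3] = True
        assert detect_apical_enamel(stack) == 5

    def test_empty_raises(self):
        with pytest.raises(LandmarkError):
            detect_apical_enamel(np.zeros((4, 4, 4), bool))


class TestRoiArithmetic:
    def test_crown_roi_10um(self):
        roi = build_crown_roi(100, 10.0, n_slices=400)
        assert (roi.z_start, roi.z_stop) == (100, 150)

    def test_crown_roi_20um_gives_25_slices(self):
        roi = build_crown_roi(100, 20.0, n_slices=400)
        assert roi.n_slices == 25

    def test_crown_roi_insufficient_extent_names_shortfall(self):
        with pytest.raises(RoiError, match="exceed"):
            build_crown_roi(5, 10.0, n_slices=30)

    def test_root_roi_10um(self):
        roi = build_root_roi(200, 10.0, n_slices=400)
        assert (roi.z_start, roi.z_stop) == (215, 265)

    def test_root_roi_5um_skip_and_span(self):
        roi = build_root_roi(200, 5.0, n_slices=600)
        assert roi.z_start == 200 + 30
        assert roi.n_slices == 100

    def test_root_roi_short_volume_raises(self):
        with pytest.raises(RoiError):
            build_root_roi(200, 10.0, n_slices=240)

    def test_apical_direction_sign(self):
        roi = build_root_roi(200, 10.0, n_slices=400, direction=-1)
        assert (roi.z_start, roi.z_stop) == (135, 185)

    def test_um_extent_invariant_under_voxel_rescale(self):
        r10 = build_crown_roi(0, 10.0, n_slices=1000)
        r25 = build_crown_roi(0, 25.0, n_slices=1000)
        assert r10.n_slices * 10.0 == 500.0
        assert r25.n_slices * 25.0 == 500.0


class TestCementumRoi:
    def make_cementum_stack(self, n_ring):
        stack = np.zeros((100, 40, 40), bool)
        for z in range(5, 5 + n_ring):
            stack[z] = annulus2d()
        return stack

    def test_eighty_qualifying_slices_take_fifty_most_apical(self):
        roi = build_cementum_roi(self.make_cementum_stack(80))
        assert (roi.z_start, roi.z_stop) == (5, 55)
        assert roi.mask[roi.zslice].any()

    def test_thirty_qualifying_slices_clamp_to_thirty(self):
        roi = build_cementum_roi(self.make_cementum_stack(30))
        assert roi.n_slices == 30

    def test_ten_qualifying_slices_insufficient(self):
        with pytest.raises(RoiError, match="root structure"):
            build_cementum_roi(self.make_cementum_stack(10))


class TestDentinZones:
    def test_analytic_tube_zone_volumes_within_5pct(self):
        nz, n = 60, 160
        dentin = make_tube(nz, n, ri=20, ro=65)  # 450 μm wall at 10 μm
        pulp = make_tube(nz, n, ri=0, ro=19.999)
        zones = subdivide_dentin(dentin, np.zeros_like(dentin), pulp, 10.0)
        for m, (r0, r1) in ((zones.mantle, (50, 65)),
                            (zones.circumpulpal, (35, 50)),
                            (zones.proximal_pulpal, (20, 35))):
            expect = math.pi * (r1**2 - r0**2) * nz
            assert m.sum() == pytest.approx(expect, rel=0.05)

    def test_wall_exactly_300um_leaves_circumpulpal_empty(self):
        # flat wall with exact integer distances: 30 voxel layers = 300 μm
        shape = (10, 20, 80)
        dentin = np.zeros(shape, bool)
        dentin[:, :, 20:50] = True
        pulp = np.zeros(shape, bool)
        pulp[:, :, :20] = True
        with pytest.warns(UserWarning, match="circumpulpal"):
            zones = subdivide_dentin(dentin, np.zeros_like(dentin), pulp, 10.0)
        assert not zones.circumpulpal.any()
        assert zones.partition_ok(dentin)

    @pytest.mark.parametrize("ri,ro", [(15, 40), (10, 70), (25, 45)])
    def test_partition_property(self, ri, ro):
        dentin = make_tube(24, 160, ri=ri, ro=ro)
        pulp = make_tube(24, 160, ri=0, ro=ri - 0.001)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zones = subdivide_dentin(dentin, np.zeros_like(dentin), pulp, 10.0)
        assert zones.partition_ok(dentin)

    def test_cementum_excluded_from_mantle_shell_origin(self):
        # mantle shell starts at the dentin|cementum interface, not outside it
        dentin = make_tube(20, 160, ri=20, ro=50)
        cementum = make_tube(20, 160, ri=50.001, ro=56)
        pulp = make_tube(20, 160, ri=0, ro=19.999)
        zones = subdivide_dentin(dentin, cementum, pulp, 10.0)
        assert not (zones.mantle & cementum).any()
        # outermost dentin voxels belong to mantle
        outermost = dentin & ~make_tube(20, 160, ri=20, ro=48)
        assert (zones.mantle & outermost).sum() == outermost.sum()

    def test_empty_dentin_rejected(self):
        z = np.zeros((4, 10, 10), bool)
        with pytest.raises(ValueError):
            subdivide_dentin(z, z, z, 10.0)


class TestOrientation:
    def test_aligned_phantom_unchanged(self, small_tooth, no_warn):
        spec, vol, truth = small_tooth
        cal = dentct.CalibratedVolume(vol, spec.voxel_size_um)
        out = anatomy.orient_volume(cal)
        # rotation is essentially the identity: interiors agree closely
        assert np.abs(out.data - cal.data).mean() < 5.0

    def test_known_rotation_recovered_within_1deg(self, small_tooth):
        spec, vol, _ = small_tooth
        ang = np.deg2rad(10.0)
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        center = (np.array(vol.shape) - 1) / 2
        tilted = ndimage.affine_transform(
            vol, rot.T, offset=center - rot.T @ center, order=1
        )
        cal = dentct.CalibratedVolume(tilted, spec.voxel_size_um)
        out = anatomy.orient_volume(cal)
        axis = anatomy.estimate_root_axis(out.data)
        angle = np.degrees(np.arccos(min(1.0, abs(float(axis[0])))))
        assert angle < 1.0

    def test_orientation_idempotent(self, small_tooth):
        spec, vol, _ = small_tooth
        cal = dentct.CalibratedVolume(vol, spec.voxel_size_um)
        once = anatomy.orient_volume(cal)
        twice = anatomy.orient_volume(once)
        assert np.abs(twice.data - once.data).mean() < 5.0

    def test_degenerate_axis_rejected(self, small_tooth):
        spec, vol, _ = small_tooth
        cal = dentct.CalibratedVolume(vol, spec.voxel_size_um)
        lm = dentct.ToothLandmarks(cej_slice=10, apical_enamel_slice=5,
                                   root_axis=(0.0, 0.0, 0.0))
        with pytest.raises(LandmarkError):
            anatomy.orient_volume(cal, landmarks=lm)

    def test_landmark_invariant_ordering(self):
        with pytest.raises(ValueError):
            dentct.ToothLandmarks(cej_slice=10, apical_enamel_slice=20)
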