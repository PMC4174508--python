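import numpy as np
import pytest

from pvi_scarpipe.core import ImageVolume, make_affine
from pvi_scarpipe.enhancement_seg import (detect_mvo, filter_islands,
                                          segment_lge, segment_t2w,
                                          wall_search_region)
from pvi_scarpipe.signal_metrics import RoiSpec, ThresholdPolicy

from conftest import make_volume


def _roi_from(mask, label):
    return RoiSpec("v", np.argwhere(mask), label)


@pytest.fixture
def synthetic_lge():
    """Hand-built LGE scene: blood box, alternating-value air, wall shell
    with one bright scar patch and one dark no-reflow pocket."""
    shape = (30, 30, 10)
    spacing = (1.4, 1.4, 4.0)
    data = np.zeros(shape)
    cavity = np.zeros(shape, dtype=bool)
    cavity[8:22, 8:22, 3:7] = True
    data[cavity] = 100.0
    wall = np.zeros(shape, dtype=bool)
    wall[6:24, 6:24, 2:8] = True
    wall &= ~cavity
    data[wall] = 90.0
    air = ~(cavity | wall)
    # air with zero mean and SD exactly 10
    flip = np.indices(shape).sum(axis=0) % 2 == 0
    data[air & flip] = 10.0
    data[air & ~flip] = -10.0
    scar = np.zeros(shape, dtype=bool)
    scar[6:8, 10:20, 3:6] = True           # bright patch on one face
    data[scar] = 182.0                     # CNR (182-100)/10 = 8.2
    pocket = np.zeros(shape, dtype=bool)
    pocket[7:8, 12:18, 4:5] = True         # dark core inside the patch
    data[pocket] = 40.0                    # CNR -6
    vol = ImageVolume(data, make_affine(spacing), modality="lge",
                      timepoint="24h")
    masks = {"cavity": vol.with_data(cavity), "wall": wall, "air": air,
             "scar": scar & ~pocket, "pocket": pocket}
    return vol, masks


class TestWallSearchRegion:
    def test_zero_shell_is_empty(self, synthetic_lge):
        vol, masks = synthetic_lge
        region = wall_search_region(masks["cavity"], 0.0)
        assert not (region.data > 0).any()

    def test_negative_shell_rejected(self, synthetic_lge):
        _, masks = synthetic_lge
        with pytest.raises(ValueError):
            wall_search_region(masks["cavity"], -1.0)

    def test_empty_cavity_rejected(self):
        vol = make_volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            wall_search_region(vol, 5.0)

    def test_spherical_shell_matches_analytic_volume(self):
        shape, sp = (50, 50, 50), (1.0, 1.0, 1.0)
        grid = np.indices(shape).transpose(1, 2, 3, 0) - 24.5
        r = np.linalg.norm(grid, axis=-1)
        cavity = ImageVolume((r <= 10).astype(float), make_affine(sp))
        s = 5.0
        region = wall_search_region(cavity, s)
        measured = (region.data > 0).sum() * 1.0
        analytic = 4 / 3 * np.pi * ((10 + s) ** 3 - 10 ** 3)
        assert measured == pytest.approx(analytic, rel=0.10)

    def test_phantom_wall_inside_shell(self, default_phantom):
        spec, _, truth = default_phantom
        cavity = truth.mask("lge", "24h", "cavity")
        wall = truth.mask("lge", "24h", "wall").data > 0
        shell = spec.wall_thickness_mm + spec.thickening_mm \
            + max(cavity.spacing)
        region = wall_search_region(cavity, shell).data > 0
        assert (wall & region).sum() / wall.sum() >= 0.95


class TestSegmentLge:
    def test_noise_free_patch_recovered_exactly(self, synthetic_lge):
        vol, masks = synthetic_lge
        region = wall_search_region(masks["cavity"], 5.0)
        out = segment_lge(vol, _roi_from(masks["cavity"].data > 0, "blood"),
                          _roi_from(masks["air"], "air"), region,
                          ThresholdPolicy(), cavity_mask=masks["cavity"])
        assert np.array_equal(out.mask.data > 0, masks["scar"])
        assert out.volume_mm3 == pytest.approx(
            masks["scar"].sum() * vol.voxel_volume_mm3)

    def test_all_below_threshold_empty(self, synthetic_lge):
        vol, masks = synthetic_lge
        flat = vol.with_data(np.where(vol.data > 130, 90.0, vol.data))
        region = wall_search_region(masks["cavity"], 5.0)
        out = segment_lge(flat, _roi_from(masks["cavity"].data > 0, "blood"),
                          _roi_from(masks["air"], "air"), region,
                          ThresholdPolicy(), cavity_mask=masks["cavity"])
        assert not (out.mask.data > 0).any()
        assert out.percent_of_cavity == 0.0

    def test_small_island_removed_large_patch_kept(self, synthetic_lge):
        vol, masks = synthetic_lge
        data = np.where(vol.data > 130, 90.0, vol.data)
        data[6, 10:16, 3] = 182.0            # ~7 mm long patch
        data[23, 10, 5] = 182.0              # single-voxel (~1.4 mm) island
        vol2 = vol.with_data(data)
        region = wall_search_region(masks["cavity"], 5.0)
        out = segment_lge(vol2, _roi_from(masks["cavity"].data > 0, "blood"),
                          _roi_from(masks["air"], "air"), region,
                          ThresholdPolicy(), cavity_mask=masks["cavity"])
        got = out.mask.data > 0
        assert got[6, 10:16, 3].all()
        assert not got[23, 10, 5]

    def test_mask_monotone_in_threshold(self, synthetic_lge, rng):
        vol, masks = synthetic_lge
        noisy = vol.with_data(vol.data + rng.normal(0, 10, vol.shape))
        region = wall_search_region(masks["cavity"], 5.0)
        blood = _roi_from(masks["cavity"].data > 0, "blood")
        air = _roi_from(masks["air"], "air")
        prev = None
        for thr in (2.0, 3.5, 5.0):
            out = segment_lge(noisy, blood, air, region,
                              ThresholdPolicy(cnr_threshold=thr))
            cur = out.mask.data > 0
            if prev is not None:
                assert (cur & ~prev).sum() == 0      # never grows
            prev = cur

    def test_percent_invariant_under_global_scaling(self, synthetic_lge):
        vol, masks = synthetic_lge
        region = wall_search_region(masks["cavity"], 5.0)
        blood = _roi_from(masks["cavity"].data > 0, "blood")
        air = _roi_from(masks["air"], "air")
        p1 = segment_lge(vol, blood, air, region, ThresholdPolicy(),
                         cavity_mask=masks["cavity"]).percent_of_cavity
        scaled = vol.with_data(vol.data * 2.5)
        p2 = segment_lge(scaled, blood, air, region, ThresholdPolicy(),
                         cavity_mask=masks["cavity"]).percent_of_cavity
        assert p1 == pytest.approx(p2)

    def test_exclusion_mask_respected(self, synthetic_lge):
        vol, masks = synthetic_lge
        region = wall_search_region(masks["cavity"], 5.0)
        excl = vol.with_data(np.ones(vol.shape))
        out = segment_lge(vol, _roi_from(masks["cavity"].data > 0, "blood"),
                          _roi_from(masks["air"], "air"), region,
                          ThresholdPolicy(), exclusion_mask=excl)
        assert not (out.mask.data > 0).any()


class TestSegmentT2w:
    def _volume(self, ratio):
        shape = (24, 24, 8)
        data = np.zeros(shape)
        cavity = np.zeros(shape, dtype=bool)
        cavity[8:16, 8:16, 3:6] = True
        data[cavity] = 30.0
        wall = np.zeros(shape, dtype=bool)
        wall[6:18, 6:18, 2:7] = True
        wall &= ~cavity
        data[wall] = 0.87 * 100
        lv = np.zeros(shape, dtype=bool)
        lv[2:5, 2:5, 0:2] = True
        data[lv] = 100.0
        patch = np.zeros(shape, dtype=bool)
        patch[6:8, 8:14, 3:5] = True
        data[patch] = ratio * 100
        vol = ImageVolume(data, make_affine((1.5, 1.5, 5.0)),
                          modality="t2w", timepoint="24h")
        return vol, ImageVolume(cavity.astype(float),
                                make_affine((1.5, 1.5, 5.0))), lv, patch

    def test_ratio_above_threshold_exact_patch(self):
        vol, cavity, lv, patch = self._volume(1.5)
        region = wall_search_region(cavity, 4.0)
        out = segment_t2w(vol, _roi_from(lv, "lv_myocardium"), region,
                          ThresholdPolicy(), cavity_mask=cavity)
        assert np.array_equal(out.mask.data > 0, patch)

    def test_ratio_below_threshold_empty(self):
        vol, cavity, lv, _ = self._volume(1.3)
        region = wall_search_region(cavity, 4.0)
        out = segment_t2w(vol, _roi_from(lv, "lv_myocardium"), region,
                          ThresholdPolicy())
        assert not (out.mask.data > 0).any()


class TestDetectMvo:
    def test_noise_free_core_recovered(self, synthetic_lge):
        vol, masks = synthetic_lge
        region = wall_search_region(masks["cavity"], 5.0)
        out = detect_mvo(vol, _roi_from(masks["cavity"].data > 0, "blood"),
                         _roi_from(masks["air"], "air"), region,
                         ThresholdPolicy(), cavity_mask=masks["cavity"])
        assert np.array_equal(out.mask.data > 0, masks["pocket"])

    def test_no_dark_voxels_empty(self, synthetic_lge):
        vol, masks = synthetic_lge
        data = np.where(vol.data == 40.0, 182.0, vol.data)
        region = wall_search_region(masks["cavity"], 5.0)
        out = detect_mvo(vol.with_data(data),
                         _roi_from(masks["cavity"].data > 0, "blood"),
                         _roi_from(masks["air"], "air"), region,
                         ThresholdPolicy(), cavity_mask=masks["cavity"])
        assert not (out.mask.data > 0).any()

    def test_disjoint_from_enhancement(self, synthetic_lge):
        vol, masks = synthetic_lge
        region = wall_search_region(masks["cavity"], 5.0)
        blood = _roi_from(masks["cavity"].data > 0, "blood")
        air = _roi_from(masks["air"], "air")
        bright = segment_lge(vol, blood, air, region, ThresholdPolicy())
        dark = detect_mvo(vol, blood, air, region, ThresholdPolicy(),
                          cavity_mask=masks["cavity"])
        assert not ((bright.mask.data > 0) & (dark.mask.data > 0)).any()

    def test_open_dark_component_discarded(self, synthetic_lge):
        """A dark band connected to the shell's outer surface is air, not
        no-reflow, and must be rejected when a cavity trace is given."""
        vol, masks = synthetic_lge
        region = wall_search_region(masks["cavity"], 8.0)  # beyond the wall
        blood = _roi_from(masks["cavity"].data > 0, "blood")
        air = _roi_from(masks["air"], "air")
        out = detect_mvo(vol, blood, air, region, ThresholdPolicy(),
                         cavity_mask=masks["cavity"])
        got = out.mask.data > 0
        assert np.array_equal(got, masks["pocket"])   # air ring rejected


class TestFilterIslands:
    def test_idempotent(self, rng):
        mask = rng.random((20, 20, 10)) > 0.7
        vol = ImageVolume(mask.astype(float), make_affine((1.4, 1.4, 4.0)))
        once = filter_islands(vol, 3.0)
        twice = filter_islands(once, 3.0)
        assert np.array_equal(once.data, twice.data)

    def test_3d_mode_keeps_two_slice_speck(self):
        data = np.zeros((10, 10, 6))
        data[5, 5, 2:4] = 1.0              # two voxels across 4 mm slices
        vol = ImageVolume(data, make_affine((1.4, 1.4, 4.0)))
        assert not (filter_islands(vol, 3.0, "inplane").data > 0).any()
        assert (filter_islands(vol, 3.0, "3d").data > 0).any()
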