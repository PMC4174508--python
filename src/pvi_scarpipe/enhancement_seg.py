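"""Threshold segmentation of enhanced LA-wall tissue.

LGE enhancement is wall signal more than ``cnr_threshold`` air-noise SDs
above the blood pool; T2W enhancement is wall signal above
``eer_threshold`` times the LV-myocardium reference; no-reflow (MVO) is
signal equally far *below* the blood pool.  Small islands (caliper diameter
at or below ``min_island_diameter_mm``) are discarded, and volumes are
reported as a percent of the traced LA cavity volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .core import ImageVolume
from .signal_metrics import RoiSpec, ThresholdPolicy, roi_mean, roi_sd


@dataclass
class EnhancementMap:
    """A binary enhancement mask with its physical volume bookkeeping."""

    mask: ImageVolume                  # binary (0/1) on the source grid
    volume_mm3: float
    percent_of_cavity: float           # NaN when no cavity trace was supplied
    modality: str
    timepoint: str
    cavity_volume_mm3: float = float("nan")


def _mask_volume(mask: np.ndarray, vol: ImageVolume) -> float:
    return float(mask.sum()) * vol.voxel_volume_mm3


def wall_search_region(cavity_mask: ImageVolume, shell_mm: float) -> ImageVolume:
    """Candidate wall shell: within ``shell_mm`` outside the traced cavity."""
    if shell_mm < 0:
        raise ValueError("shell_mm must be non-negative")
    cav = cavity_mask.data > 0
    if not cav.any():
        raise ValueError("cavity mask is empty")
    if shell_mm == 0:
        return cavity_mask.with_data(np.zeros_like(cav))
    dist = ndimage.distance_transform_edt(~cav, sampling=cavity_mask.spacing)
    region = (dist > 0) & (dist <= shell_mm)
    return cavity_mask.with_data(region.astype(np.uint8))


def _feret_diameter_mm(coords_ijk: np.ndarray, vol: ImageVolume,
                       mode: str) -> float:
    """Caliper diameter of a voxel set (centers), in mm.

    ``inplane`` takes the maximum over axial slices of the 2D diameter, the
    analog of a caliper on the axial reading; ``3d`` is the full Feret
    diameter.  With thick slices the 3D form lets any two-slice speck exceed
    a few mm, which is why in-plane is the default.
    """
    world = np.atleast_2d(vol.voxel_to_world(coords_ijk.astype(float)))

    def _max_pairwise(pts: np.ndarray) -> float:
        if pts.shape[0] < 2:
            return 0.0
        if pts.shape[0] > 16:
            try:
                hull = ConvexHull(pts, qhull_options="QJ")
                pts = pts[hull.vertices]
            except (QhullError, ValueError):
                pass
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    if mode == "3d":
        return _max_pairwise(world)
    best = 0.0
    for k in np.unique(coords_ijk[:, 2]):
        sel = world[coords_ijk[:, 2] == k][:, :2]
        best = max(best, _max_pairwise(sel))
    return best


def filter_islands(mask_vol: ImageVolume, min_diameter_mm: float,
                   mode: str = "inplane") -> ImageVolume:
    """Drop 26-connected components whose caliper diameter is <= the cutoff.

    Idempotent: surviving components are unchanged.
    """
    mask = mask_vol.data > 0
    labels = measure.label(mask, connectivity=3)
    out = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        coords = region.coords
        if _feret_diameter_mm(coords, mask_vol, mode) > min_diameter_mm:
            out[tuple(coords.T)] = True
    return mask_vol.with_data(out.astype(np.uint8))


def _finish(vol: ImageVolume, mask: np.ndarray, region: ImageVolume,
            policy: ThresholdPolicy, cavity_mask: ImageVolume | None,
            exclusion_mask: ImageVolume | None) -> EnhancementMap:
    if exclusion_mask is not None:
        mask = mask & ~(exclusion_mask.data > 0)
    mvol = vol.with_data(mask.astype(np.uint8))
    mvol = filter_islands(mvol, policy.min_island_diameter_mm,
                          policy.island_diameter_mode)
    volume = _mask_volume(mvol.data > 0, vol)
    if cavity_mask is not None:
        cav_vol = _mask_volume(cavity_mask.data > 0, cavity_mask)
        pct = 100.0 * volume / cav_vol
    else:
        cav_vol, pct = float("nan"), float("nan")
    return EnhancementMap(mask=mvol, volume_mm3=volume, percent_of_cavity=pct,
                          modality=vol.modality, timepoint=vol.timepoint,
                          cavity_volume_mm3=cav_vol)


def segment_lge(volume: ImageVolume, blood_roi: RoiSpec, air_roi: RoiSpec,
                region: ImageVolume, policy: ThresholdPolicy,
                cavity_mask: ImageVolume | None = None,
                exclusion_mask: ImageVolume | None = None) -> EnhancementMap:
    """Bright enhancement on LGE: CNR above ``policy.cnr_threshold``."""
    if not (region.data > 0).any():
        raise ValueError("empty wall search region")
    blood = roi_mean(volume, blood_roi)
    air_sd = roi_sd(volume, air_roi)
    if air_sd <= 0:
        raise ValueError("degenerate air-noise estimate")
    thr = blood + policy.cnr_threshold * air_sd
    mask = (region.data > 0) & (volume.data > thr)
    return _finish(volume, mask, region, policy, cavity_mask, exclusion_mask)


def segment_t2w(volume: ImageVolume, lv_roi: RoiSpec, region: ImageVolume,
                policy: ThresholdPolicy,
                cavity_mask: ImageVolume | None = None,
                exclusion_mask: ImageVolume | None = None) -> EnhancementMap:
    """Edema on T2W: wall/LV signal ratio above ``policy.eer_threshold``."""
    if not (region.data > 0).any():
        raise ValueError("empty wall search region")
    lv = roi_mean(volume, lv_roi)
    if lv <= 0:
        raise ValueError("LV reference ROI is unusable (non-positive mean)")
    thr = policy.eer_threshold * lv
    mask = (region.data > 0) & (volume.data > thr)
    return _finish(volume, mask, region, policy, cavity_mask, exclusion_mask)


def detect_mvo(volume: ImageVolume, blood_roi: RoiSpec, air_roi: RoiSpec,
               region: ImageVolume, policy: ThresholdPolicy,
               cavity_mask: ImageVolume | None = None,
               exclusion_mask: ImageVolume | None = None) -> EnhancementMap:
    """No-reflow on LGE: signal below blood by ``policy.cnr_threshold`` SDs.

    Extracardiac air inside the search shell is equally dark, so when a
    cavity trace is supplied only *enclosed* dark components are kept: a
    component 26-connected to the shell's outer surface communicates with
    the air space and is discarded before island filtering.
    """
    if not (region.data > 0).any():
        raise ValueError("empty wall search region")
    blood = roi_mean(volume, blood_roi)
    air_sd = roi_sd(volume, air_roi)
    if air_sd <= 0:
        raise ValueError("degenerate air-noise estimate")
    thr = blood - policy.cnr_threshold * air_sd
    mask = (region.data > 0) & (volume.data < thr)
    if cavity_mask is not None and mask.any():
        outside = ~(region.data > 0) & ~(cavity_mask.data > 0)
        near_outside = ndimage.binary_dilation(
            outside, structure=ndimage.generate_binary_structure(3, 3))
        labels = measure.label(mask, connectivity=3)
        open_ids = np.unique(labels[near_outside & (labels > 0)])
        if open_ids.size:
            mask = mask & ~np.isin(labels, open_ids)
    return _finish(volume, mask, region, policy, cavity_mask, exclusion_mask)
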