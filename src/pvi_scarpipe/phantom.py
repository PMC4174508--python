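"""Synthetic LA phantom: paired multi-timepoint T2W/LGE volumes with a
known injury pattern.

The left atrium is modeled as an ellipsoidal cavity with four cylindrical
PV stubs; the wall is the shell of configurable thickness around the cavity
(thicker 24 h post-ablation), an LV-myocardium slab sits in the inferior
slices as the T2W reference tissue, and everything else is air.  Signal is
painted region-wise in arbitrary units — every downstream statistic is a
ratio — with per-segment cohort draws (EER of injured wall ~ N(1.52, 0.38),
uninjured ~ N(0.87, 0.18); scar CNR ~ N(8.2, 3.6) at 24 h and N(11.4, 4.1)
at 30 d) plus additive Gaussian voxel noise.  The 30-day volumes are
resampled under a known rigid transform so registration is verifiable
against planted truth.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import ImageVolume, make_affine, save_nifti
from .registration import RigidTransform
from .segment_model import QUADRANTS, SEGMENT_KEYS, VEINS, SegmentModel, \
    assign_segments_array
from .signal_metrics import RoiSpec

SEGMENT_LABELS = ("none", "edema_only", "edema_and_scar", "scar_only", "mvo")
EDEMA_LABELS = frozenset({"edema_only", "edema_and_scar"})
SCAR_LABELS = frozenset({"scar_only", "edema_and_scar"})

DEFAULT_GRIDS = {
    "t2w": {"shape": (64, 64, 28), "spacing": (1.5, 1.5, 5.0)},
    "lge": {"shape": (68, 68, 32), "spacing": (1.4, 1.4, 4.0)},
}
DEFAULT_TIMEPOINTS = {"t2w": ("pre", "24h"), "lge": ("24h", "30d")}

_DEFAULT_VEIN_DIRS = {
    "LSPV": (0.88, -0.13, 0.46),
    "LIPV": (0.88, -0.13, -0.46),
    "RSPV": (-0.88, -0.13, 0.46),
    "RIPV": (-0.88, -0.13, -0.46),
}


@dataclass
class SignalParams:
    """Region signal statistics, arbitrary units.

    Ratio-level parameters (``eer_*`` are wall/LV ratios, ``cnr_*`` are in
    units of the air-noise SD) are (mean, SD) pairs of the *per-segment*
    cohort draw; ``*_noise_sd`` is the additive per-voxel Gaussian noise.
    """

    t2w_lv_mean: float = 100.0
    t2w_blood_mean: float = 30.0
    t2w_noise_sd: float = 4.0
    eer_uninjured: tuple = (0.87, 0.18)
    eer_edema: tuple = (1.52, 0.38)
    lge_blood_mean: float = 100.0
    lge_air_sd: float = 10.0                 # CNR unit; also the LGE voxel noise
    lge_noise_sd: float | None = None        # override; None -> lge_air_sd
    lge_lv_offset_sd: float = -2.0       # LV slab CNR on LGE (nulled)
    cnr_uninjured: tuple = (-1.0, 0.6)
    cnr_scar_24h: tuple = (8.2, 3.6)
    cnr_scar_30d: tuple = (11.4, 4.1)
    cnr_mvo: float = -6.0

    def validate(self, policy_eer: float = 1.4, policy_cnr: float = 3.5) -> None:
        if self.eer_edema[0] <= policy_eer:
            raise ValueError("planted edema EER mean must exceed the edema "
                             "threshold")
        if self.cnr_scar_24h[0] <= policy_cnr or self.cnr_scar_30d[0] <= policy_cnr:
            raise ValueError("planted scar CNR mean must exceed the CNR "
                             "threshold")
        if self.cnr_mvo >= 0:
            raise ValueError("MVO mean must be below the blood mean")
        for v in (self.t2w_lv_mean, self.t2w_blood_mean, self.lge_blood_mean,
                  self.lge_air_sd):
            if v <= 0:
                raise ValueError("signal means and the air SD must be positive")

    def noise_free(self) -> "SignalParams":
        """Copy with every SD (cohort draw and voxel noise) set to zero.

        The air SD is kept positive (it is the CNR unit) but no voxel noise
        is added on LGE (``lge_noise_sd`` = 0).
        """
        return replace(self, t2w_noise_sd=0.0, lge_noise_sd=0.0,
                       eer_uninjured=(self.eer_uninjured[0], 0.0),
                       eer_edema=(self.eer_edema[0], 0.0),
                       cnr_uninjured=(self.cnr_uninjured[0], 0.0),
                       cnr_scar_24h=(self.cnr_scar_24h[0], 0.0),
                       cnr_scar_30d=(self.cnr_scar_30d[0], 0.0))


def default_injury_truth(rng: np.random.Generator | None = None) -> dict:
    """A realistic per-segment injury pattern.

    Most quadrants carry combined edema and scar (ablation encircles the
    ostia), a few carry one finding only, one is no-reflow, and one or more
    are spared; with an RNG the spared count varies and placement is
    shuffled, emulating between-patient variation in lesion extent.
    """
    labels = (["edema_and_scar"] * 12 + ["edema_only", "scar_only", "mvo",
                                         "none"])
    if rng is not None:
        extra_spared = int(rng.integers(0, 3))
        for i in range(extra_spared):
            labels[i] = "none"
        rng.shuffle(labels)
    return dict(zip(SEGMENT_KEYS, labels))


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject."""

    grids: dict = field(default_factory=lambda: {
        m: dict(g) for m, g in DEFAULT_GRIDS.items()})
    timepoints: dict = field(default_factory=lambda: {
        m: tuple(t) for m, t in DEFAULT_TIMEPOINTS.items()})
    la_center_mm: tuple = (48.0, 48.0, 85.0)
    la_radii_mm: tuple = (21.0, 17.0, 15.0)
    ostium_centers_mm: dict | None = None      # derived from vein dirs if None
    vein_axes: dict | None = None
    pv_stub_radius_mm: float = 5.0
    pv_stub_length_mm: float = 12.0
    wall_thickness_mm: float = 7.0
    thickening_mm: float = 3.7
    mvo_core_radius_mm: float = 6.0     # dark no-reflow core around the ostium
    lv_slab_mm: tuple = ((25.0, 70.0), (25.0, 70.0), (12.0, 38.0))
    segment_radius_mm: float = 10.0
    signal_params: SignalParams = field(default_factory=SignalParams)
    injury_truth: dict | None = None           # (vein, quadrant) -> label
    inter_scan_transform: RigidTransform | None = None
    rng_seed: int = 0
    subject_id: str = "phantom"

    def __post_init__(self) -> None:
        c = np.asarray(self.la_center_mm, float)
        r = np.asarray(self.la_radii_mm, float)
        if (r <= 0).any() or self.wall_thickness_mm <= 0 \
                or self.pv_stub_radius_mm <= 0 or self.thickening_mm < 0:
            raise ValueError("radii and thicknesses must be positive")
        if self.vein_axes is None:
            self.vein_axes = {v: _unit(d) for v, d in _DEFAULT_VEIN_DIRS.items()}
        else:
            self.vein_axes = {v: _unit(d) for v, d in self.vein_axes.items()}
        if self.ostium_centers_mm is None:
            self.ostium_centers_mm = {}
            for v, d in self.vein_axes.items():
                scale = 1.0 / math.sqrt(((d / r) ** 2).sum())
                self.ostium_centers_mm[v] = tuple(c + scale * d)
        if len(self.ostium_centers_mm) != 4 or len(self.vein_axes) != 4:
            raise ValueError("exactly 4 PV ostia are required")
        if self.injury_truth is None:
            self.injury_truth = default_injury_truth()
        if set(self.injury_truth) != set(SEGMENT_KEYS):
            raise ValueError("injury_truth must label exactly the 16 segments")
        for lab in self.injury_truth.values():
            if lab not in SEGMENT_LABELS:
                raise ValueError(f"unknown injury label {lab!r}")
        if self.inter_scan_transform is None:
            self.inter_scan_transform = RigidTransform.from_euler(
                (0.0, 0.0, math.radians(5.0)), (4.0, -3.0, 2.0),
                center_mm=self.la_center_mm)
        self.signal_params.validate()
        # the grid must hold the LA plus its (thickened) wall with >=3 voxels
        # of clearance on every axis
        for mod, g in self.grids.items():
            spacing = np.asarray(g["spacing"], float)
            shape = np.asarray(g["shape"], int)
            if (spacing <= 0).any():
                raise ValueError("spacings must be positive")
            extent = (shape - 1) * spacing
            needed = 2 * (r + self.wall_thickness_mm + self.thickening_mm
                          + 3 * spacing)
            if (extent < needed).any():
                raise ValueError(
                    f"{mod} grid too small to contain the LA and wall")

    def segment_model(self) -> SegmentModel:
        return SegmentModel.from_geometry(self.ostium_centers_mm,
                                          self.vein_axes,
                                          self.segment_radius_mm)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


@dataclass
class PhantomTruth:
    """Planted ground truth for one synthetic subject."""

    segment_labels: dict                       # (vein, quadrant) -> label
    masks: dict                                # (mod, tp) -> {name: ImageVolume}
    true_enhancement_volume_pct: dict          # (mod, tp) -> float
    true_mvo_volume_pct: dict                  # (mod, tp) -> float
    segment_draws: dict                        # (mod, tp) -> {key: ratio draw}
    inter_scan_transform: RigidTransform
    spec: PhantomSpec

    def mask(self, modality: str, timepoint: str, name: str) -> ImageVolume:
        return self.masks[(modality, timepoint)][name]


def truth_segment_calls(truth: PhantomTruth, modality: str,
                        timepoint: str) -> dict:
    """Expected per-segment positives for a modality/time-point.

    Edema labels are positive on 24-hour T2W; scar labels are positive on
    LGE, with no-reflow (MVO) counted as injury both acutely and — having
    developed into scar — at 30 days.  Pre-ablation images are all negative,
    as is 30-day T2W (edema has resolved).
    """
    if modality not in ("t2w", "lge"):
        raise ValueError(f"unknown modality {modality!r}")
    if timepoint not in ("pre", "24h", "30d"):
        raise ValueError(f"unknown timepoint {timepoint!r}")
    out = {}
    for key, lab in truth.segment_labels.items():
        if timepoint == "pre":
            pos = False
        elif modality == "t2w":
            pos = timepoint == "24h" and lab in EDEMA_LABELS
        else:
            pos = lab in SCAR_LABELS or lab == "mvo"
        out[key] = pos
    return out


# ------------------------------------------------------------------ masks

def _grid_template(spec: PhantomSpec, modality: str, timepoint: str) -> ImageVolume:
    g = spec.grids[modality]
    return ImageVolume(np.zeros(g["shape"]), make_affine(g["spacing"]),
                       modality=modality, timepoint=timepoint,
                       subject_id=spec.subject_id)


def _cavity(spec: PhantomSpec, w: np.ndarray) -> np.ndarray:
    c = np.asarray(spec.la_center_mm)
    r = np.asarray(spec.la_radii_mm)
    inside = (((w - c) / r) ** 2).sum(-1) <= 1.0
    for v in VEINS:
        o = np.asarray(spec.ostium_centers_mm[v])
        d = np.asarray(spec.vein_axes[v])
        rel = w - o
        ax = rel @ d
        rad2 = (rel ** 2).sum(-1) - ax ** 2
        inside |= ((ax >= -2.0) & (ax <= spec.pv_stub_length_mm)
                   & (rad2 <= spec.pv_stub_radius_mm ** 2))
    return inside


def _build_masks(spec: PhantomSpec, grid: ImageVolume,
                 thickness_mm: float, coord_fn=None) -> dict:
    """Anatomy masks on a voxel grid.

    ``coord_fn`` maps grid world coordinates back into the anatomy's
    reference frame; a repositioned acquisition (the 30-day scan) is
    generated by evaluating the same geometry through the inverse of the
    inter-scan transform, i.e. sampled natively on the moved grid rather
    than interpolated from another voxelization.
    """
    w = grid.world_grid()
    if coord_fn is not None:
        w = coord_fn(w.reshape(-1, 3)).reshape(w.shape)
    cav = _cavity(spec, w)
    dist_out = ndimage.distance_transform_edt(~cav, sampling=grid.spacing)
    wall = (dist_out > 0) & (dist_out <= thickness_mm)
    inner_wall = wall & (dist_out <= thickness_mm / 2.0)

    (x0, x1), (y0, y1), (z0, z1) = spec.lv_slab_mm
    lv = ((w[..., 0] >= x0) & (w[..., 0] <= x1)
          & (w[..., 1] >= y0) & (w[..., 1] <= y1)
          & (w[..., 2] >= z0) & (w[..., 2] <= z1)) & ~cav & ~wall

    tissue = cav | wall | lv
    air = ndimage.distance_transform_edt(~tissue,
                                         sampling=grid.spacing) > 8.0

    # blood core clear of the wall by at least one z-voxel of partial volume
    blood_margin = max(2.0, 1.2 * float(grid.spacing.max()))
    dist_in = ndimage.distance_transform_edt(cav, sampling=grid.spacing)
    blood = dist_in >= blood_margin

    model = spec.segment_model()
    seg_map = np.zeros(grid.shape, dtype=np.int16)
    wall_idx = np.argwhere(wall)
    if wall_idx.size:
        world = w.reshape(-1, 3)[np.ravel_multi_index(tuple(wall_idx.T),
                                                      grid.shape)]
        vi, qi = assign_segments_array(world, model)
        seg = np.where(vi >= 0, vi * 4 + qi + 1, 0).astype(np.int16)
        seg_map[tuple(wall_idx.T)] = seg

    as_vol = lambda a, dtype=np.uint8: grid.with_data(a.astype(dtype))
    masks = {"cavity": as_vol(cav), "wall": as_vol(wall),
             "inner_wall": as_vol(inner_wall), "blood": as_vol(blood),
             "lv_myocardium": as_vol(lv), "air": as_vol(air),
             "segment_map": as_vol(seg_map, np.int16),
             "wall_depth": grid.with_data(np.where(wall, dist_out, 0.0))}
    return masks, w


# ---------------------------------------------------------------- painting

def _draw(rng, stats) -> float:
    mean, sd = stats
    return float(rng.normal(mean, sd)) if sd > 0 else float(mean)


def _segment_draws(spec: PhantomSpec, rng, modality: str,
                   timepoint: str) -> dict:
    """Per-segment ratio-level draws (EER for T2W, CNR for LGE)."""
    p = spec.signal_params
    draws = {}
    for key in SEGMENT_KEYS:
        lab = spec.injury_truth[key]
        if modality == "t2w":
            injured = timepoint == "24h" and lab in EDEMA_LABELS
            draws[key] = _draw(rng, p.eer_edema if injured else p.eer_uninjured)
        else:
            if timepoint == "pre":
                draws[key] = _draw(rng, p.cnr_uninjured)
            elif timepoint == "24h":
                if lab in SCAR_LABELS or lab == "mvo":
                    draws[key] = _draw(rng, p.cnr_scar_24h)
                else:
                    draws[key] = _draw(rng, p.cnr_uninjured)
            else:                                  # 30d: MVO has become scar
                if lab in SCAR_LABELS or lab == "mvo":
                    draws[key] = _draw(rng, p.cnr_scar_30d)
                else:
                    draws[key] = _draw(rng, p.cnr_uninjured)
    return draws


def _paint_means(spec: PhantomSpec, masks: dict, ref_world: np.ndarray,
                 modality: str, timepoint: str, draws: dict) -> np.ndarray:
    """Noise-free region-mean volume in native signal units."""
    p = spec.signal_params
    grid = masks["cavity"]
    out = np.zeros(grid.shape, dtype=float)
    cav = masks["cavity"].data > 0
    wall = masks["wall"].data > 0
    inner = masks["inner_wall"].data > 0
    lv = masks["lv_myocardium"].data > 0
    seg_map = masks["segment_map"].data

    if modality == "t2w":
        to_native = lambda ratio: ratio * p.t2w_lv_mean
        out[cav] = p.t2w_blood_mean
        out[lv] = p.t2w_lv_mean
        out[wall] = to_native(p.eer_uninjured[0])
    else:
        to_native = lambda c: p.lge_blood_mean + c * p.lge_air_sd
        out[cav] = p.lge_blood_mean
        out[lv] = to_native(p.lge_lv_offset_sd)
        out[wall] = to_native(p.cnr_uninjured[0])

    for idx, key in enumerate(SEGMENT_KEYS):
        sel = wall & (seg_map == idx + 1)
        if not sel.any():
            continue
        out[sel] = to_native(draws[key])
        if (modality == "lge" and timepoint == "24h"
                and spec.injury_truth[key] == "mvo"):
            # dark no-reflow core near the ostium, enclosed by enhancing
            # scar: it stays clear of the epicardial wall surface
            thickness = spec.wall_thickness_mm + spec.thickening_mm
            depth = masks["wall_depth"].data
            max_depth = max(thickness - 3.0, thickness / 2.0)
            vox = np.argwhere(sel & (depth <= max_depth))
            if vox.shape[0] == 0:
                continue
            world = ref_world.reshape(-1, 3)[np.ravel_multi_index(
                tuple(vox.T), grid.shape)]
            o = np.asarray(spec.ostium_centers_mm[key[0]])
            d = np.linalg.norm(world - o, axis=1)
            # core extent measured from the territory's innermost wall
            # point (the stub lumen keeps the ostium center itself clear)
            core = d <= d.min() + spec.mvo_core_radius_mm / 2.0
            out[tuple(vox[core].T)] = to_native(p.cnr_mvo)
    return out


def _truth_enhancement(spec: PhantomSpec, masks: dict, means: np.ndarray,
                       modality: str,
                       eer_threshold: float = 1.4,
                       cnr_threshold: float = 3.5):
    """Rule applied to the noise-free means: the planted enhancement truth."""
    p = spec.signal_params
    wall = masks["wall"].data > 0
    if modality == "t2w":
        enh = wall & (means > eer_threshold * p.t2w_lv_mean)
        mvo = np.zeros_like(enh)
    else:
        enh = wall & (means > p.lge_blood_mean + cnr_threshold * p.lge_air_sd)
        mvo = wall & (means < p.lge_blood_mean - cnr_threshold * p.lge_air_sd)
    return enh, mvo


def generate_phantom(spec: PhantomSpec):
    """Generate all requested volumes and the planted truth.

    Returns ``(volumes, truth)`` where ``volumes`` maps
    ``(modality, timepoint)`` to an :class:`ImageVolume` and ``truth`` is a
    :class:`PhantomTruth`.  Fixed ``rng_seed`` gives identical voxel arrays.
    The 30-day scan emulates a repositioned acquisition: the same anatomy is
    sampled natively on the grid through ``inter_scan_transform`` (no
    interpolation of a previous voxelization) and given fresh noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    p = spec.signal_params
    T = spec.inter_scan_transform

    volumes, all_masks, pcts, mvo_pcts, all_draws = {}, {}, {}, {}, {}
    for modality in sorted(spec.timepoints):
        if modality == "t2w":
            noise_sd = p.t2w_noise_sd
        else:
            noise_sd = p.lge_air_sd if p.lge_noise_sd is None else p.lge_noise_sd
        for timepoint in spec.timepoints[modality]:
            grid = _grid_template(spec, modality, timepoint)
            thick = spec.wall_thickness_mm + (
                spec.thickening_mm if timepoint == "24h" else 0.0)
            coord_fn = T.inverse().apply if timepoint == "30d" else None
            masks, ref_world = _build_masks(spec, grid, thick, coord_fn)
            draws = _segment_draws(spec, rng, modality, timepoint)
            means = _paint_means(spec, masks, ref_world, modality, timepoint,
                                 draws)
            enh, mvo = _truth_enhancement(spec, masks, means, modality)
            masks["enhancement"] = grid.with_data(enh.astype(np.uint8))
            masks["mvo"] = grid.with_data(mvo.astype(np.uint8))

            noise = rng.normal(0.0, noise_sd, size=grid.shape) \
                if noise_sd > 0 else 0.0
            volumes[(modality, timepoint)] = grid.with_data(means + noise)
            all_masks[(modality, timepoint)] = masks
            cav_n = (masks["cavity"].data > 0).sum()
            enh_n = (masks["enhancement"].data > 0).sum()
            mvo_n = (masks["mvo"].data > 0).sum()
            pcts[(modality, timepoint)] = 100.0 * enh_n / cav_n
            mvo_pcts[(modality, timepoint)] = 100.0 * mvo_n / cav_n
            all_draws[(modality, timepoint)] = draws

    truth = PhantomTruth(segment_labels=dict(spec.injury_truth),
                         masks=all_masks,
                         true_enhancement_volume_pct=pcts,
                         true_mvo_volume_pct=mvo_pcts,
                         segment_draws=all_draws,
                         inter_scan_transform=T, spec=spec)
    return volumes, truth


# ----------------------------------------------------------- ROI utilities

def roi_from_mask(truth: PhantomTruth, modality: str, timepoint: str,
                  name: str, n: int, rng: np.random.Generator,
                  label: str) -> RoiSpec:
    """Random n-voxel ROI drawn from a truth mask."""
    mask = truth.mask(modality, timepoint, name).data > 0
    idx = np.argwhere(mask)
    if idx.shape[0] < n:
        raise ValueError(f"mask {name!r} has fewer than {n} voxels")
    sel = rng.choice(idx.shape[0], size=n, replace=False)
    return RoiSpec(volume_id=f"{modality}:{timepoint}",
                   voxel_indices=idx[np.sort(sel)], label=label)


def segment_wall_roi(truth: PhantomTruth, modality: str, timepoint: str,
                     key, n: int = 60, part: str = "all") -> RoiSpec:
    """Deterministic ~n-voxel wall ROI inside one segment territory.

    Voxels nearest the ostium center are taken (the phantom analog of
    sampling the ostial wall); ``part`` may restrict to the outer or inner
    half of the wall, or to voxels outside the planted no-reflow core
    (``non_mvo``, the enhancing rim used for scar CNR sampling).  If the
    restriction empties the segment, the full territory is used.
    """
    masks = truth.masks[(modality, timepoint)]
    seg_idx = SEGMENT_KEYS.index(tuple(key)) + 1
    base = (masks["segment_map"].data == seg_idx) & (masks["wall"].data > 0)
    inner = masks["inner_wall"].data > 0
    if part == "outer":
        sel = base & ~inner
    elif part == "inner":
        sel = base & inner
    elif part == "non_mvo":
        sel = base & ~(masks["mvo"].data > 0)
    elif part == "all":
        sel = base
    else:
        raise ValueError("part must be 'all', 'outer', 'inner' or 'non_mvo'")
    if not sel.any():
        sel = base
    idx = np.argwhere(sel)
    if idx.shape[0] == 0:
        raise ValueError(f"segment {key} has no wall voxels")
    grid = masks["wall"]
    world = np.atleast_2d(grid.voxel_to_world(idx.astype(float)))
    o = np.asarray(truth.spec.ostium_centers_mm[key[0]])
    order = np.argsort(np.linalg.norm(world - o, axis=1), kind="stable")
    return RoiSpec(volume_id=f"{modality}:{timepoint}",
                   voxel_indices=idx[order[:n]], label="wall")


# ------------------------------------------------------------------ output

def write_phantom(volumes: dict, truth: PhantomTruth, out_dir: str) -> None:
    """Write NIfTI volumes plus a JSON truth sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    for (mod, tp), vol in volumes.items():
        save_nifti(vol, os.path.join(out_dir, f"{mod}_{tp}.nii.gz"))
        for name, m in truth.masks[(mod, tp)].items():
            save_nifti(m, os.path.join(out_dir, f"{mod}_{tp}_{name}.nii.gz"))
    T = truth.inter_scan_transform
    sidecar = {
        "segment_labels": {f"{v}/{q}": lab for (v, q), lab
                           in truth.segment_labels.items()},
        "true_enhancement_volume_pct": {
            f"{m}/{t}": v for (m, t), v
            in truth.true_enhancement_volume_pct.items()},
        "true_mvo_volume_pct": {
            f"{m}/{t}": v for (m, t), v in truth.true_mvo_volume_pct.items()},
        "inter_scan_transform": {
            "euler_angles_rad": list(T.euler_angles_rad),
            "translation_mm": list(T.translation_mm),
            "center_mm": list(T.center_mm)},
        "rng_seed": truth.spec.rng_seed,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
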