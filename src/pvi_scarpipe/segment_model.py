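"""The 16-segment PV model: 4 quadrants around each of 4 PV ostia.

Territories extend ``radius_mm`` (default 10 mm) from each ostium center;
overlaps are resolved by nearest ostium.  Quadrants are centered on the four
anatomical directions: a point's offset from the ostium is projected onto the
vein's (anterior, superior) frame and classified by the angle
``atan2(superior, anterior)`` with boundaries on the diagonals (boundary
points go to anterior / superior).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import ImageVolume
from .enhancement_seg import EnhancementMap
from .signal_metrics import ThresholdPolicy

VEINS = ("LSPV", "LIPV", "RSPV", "RIPV")
QUADRANTS = ("anterior", "posterior", "superior", "inferior")
SEGMENT_KEYS = tuple(product(VEINS, QUADRANTS))

_Y = np.array([0.0, 1.0, 0.0])   # posterior -> anterior
_Z = np.array([0.0, 0.0, 1.0])   # inferior -> superior


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


@dataclass
class SegmentModel:
    """Geometry of the 16 PV territories."""

    ostium_centers_mm: dict        # vein -> (3,) world mm
    vein_axes: dict                # vein -> unit vector along the vein
    quadrant_frames: dict          # vein -> (anterior_vec, superior_vec)
    radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if set(self.ostium_centers_mm) != set(VEINS):
            raise ValueError(f"need exactly the 4 veins {VEINS}")
        for v in VEINS:
            a = np.asarray(self.vein_axes[v], float)
            ant, sup = (np.asarray(x, float) for x in self.quadrant_frames[v])
            for u in (a, ant, sup):
                if abs(np.linalg.norm(u) - 1) > 1e-6:
                    raise ValueError(f"{v}: frame vectors must be unit length")
            if max(abs(a @ ant), abs(a @ sup), abs(ant @ sup)) > 1e-6:
                raise ValueError(f"{v}: frame vectors must be orthogonal")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    @classmethod
    def from_geometry(cls, ostium_centers_mm: dict, vein_axes: dict,
                      radius_mm: float = 10.0) -> "SegmentModel":
        """Build quadrant frames from patient axes by Gram-Schmidt.

        The anterior frame vector is the patient +y axis orthogonalized
        against the vein axis; the superior vector is +z orthogonalized
        against both.
        """
        frames = {}
        axes = {}
        for v in VEINS:
            a = _unit(np.asarray(vein_axes[v], float))
            ant = _Y - (_Y @ a) * a
            if np.linalg.norm(ant) < 1e-6:
                ant = np.array([1.0, 0.0, 0.0]) - a[0] * a
            ant = _unit(ant)
            sup = _Z - (_Z @ a) * a - (_Z @ ant) * ant
            if np.linalg.norm(sup) < 1e-6:
                raise ValueError(f"{v}: degenerate quadrant frame")
            frames[v] = (ant, _unit(sup))
            axes[v] = a
        centers = {v: np.asarray(ostium_centers_mm[v], float) for v in VEINS}
        return cls(centers, axes, frames, radius_mm)

    @classmethod
    def from_policy(cls, ostium_centers_mm: dict, vein_axes: dict,
                    policy: ThresholdPolicy) -> "SegmentModel":
        return cls.from_geometry(ostium_centers_mm, vein_axes,
                                 policy.segment_radius_mm)

    def transformed(self, rigid) -> "SegmentModel":
        """Propagate the model geometry through a rigid transform.

        Used to carry segment territories defined on one scan onto a scan
        acquired in a different patient position: ostium centers map through
        the transform, axes and quadrant frames rotate with it.
        """
        r = rigid.rotation
        centers = {v: np.asarray(rigid.apply(self.ostium_centers_mm[v]))
                   for v in VEINS}
        axes = {v: r @ np.asarray(self.vein_axes[v]) for v in VEINS}
        frames = {v: (r @ np.asarray(self.quadrant_frames[v][0]),
                      r @ np.asarray(self.quadrant_frames[v][1]))
                  for v in VEINS}
        return SegmentModel(centers, axes, frames, self.radius_mm)


def _quadrant_from_angle(angle: np.ndarray) -> np.ndarray:
    """Quadrant index into QUADRANTS from atan2(superior, anterior)."""
    q = np.full(angle.shape, QUADRANTS.index("posterior"), dtype=int)
    q[np.abs(angle) <= np.pi / 4] = QUADRANTS.index("anterior")
    q[(angle > np.pi / 4) & (angle <= 3 * np.pi / 4)] = \
        QUADRANTS.index("superior")
    q[(angle < -np.pi / 4) & (angle >= -3 * np.pi / 4)] = \
        QUADRANTS.index("inferior")
    return q


def assign_segments_array(points_mm: np.ndarray, model: SegmentModel):
    """Vectorized territory assignment.

    Returns (vein_idx, quad_idx), both (N,), with -1 where the point is
    farther than ``radius_mm`` from every ostium.  Nearest ostium wins; exact
    distance ties go to the lexicographically first vein.
    """
    pts = np.atleast_2d(np.asarray(points_mm, float))
    vein_order = sorted(VEINS)                       # lexicographic tie-break
    d = np.stack([np.linalg.norm(pts - model.ostium_centers_mm[v], axis=1)
                  for v in vein_order], axis=1)
    nearest = np.argmin(d, axis=1)                   # first (lexicog.) on ties
    dmin = d[np.arange(len(pts)), nearest]
    vein_idx = np.full(len(pts), -1, dtype=int)
    quad_idx = np.full(len(pts), -1, dtype=int)
    for j, vname in enumerate(vein_order):
        sel = (nearest == j) & (dmin <= model.radius_mm)
        if not sel.any():
            continue
        off = pts[sel] - model.ostium_centers_mm[vname]
        a = np.asarray(model.vein_axes[vname])
        off = off - np.outer(off @ a, a)             # drop axial component
        ant, sup = model.quadrant_frames[vname]
        angle = np.arctan2(off @ sup, off @ ant)
        vein_idx[sel] = VEINS.index(vname)
        quad_idx[sel] = _quadrant_from_angle(angle)
    return vein_idx, quad_idx


def assign_segment(point_mm, model: SegmentModel):
    """Territory of a single world point: (vein, quadrant) or None."""
    v, q = assign_segments_array(np.atleast_2d(point_mm), model)
    if v[0] < 0:
        return None
    return VEINS[v[0]], QUADRANTS[q[0]]


@dataclass
class InjuryCallSet:
    """Binary injury calls for the 16 segments of one subject/image."""

    subject_id: str
    modality: str
    timepoint: str
    calls: dict                     # (vein, quadrant) -> bool | None

    def __post_init__(self) -> None:
        if set(self.calls) != set(SEGMENT_KEYS):
            raise ValueError("calls must cover exactly the 16 segments")

    def n_positive(self) -> int:
        return sum(bool(v) for v in self.calls.values() if v is not None)

    def as_dict(self) -> dict:
        return {f"{v}/{q}": self.calls[(v, q)] for v, q in SEGMENT_KEYS}


def call_segments(emap: EnhancementMap, model: SegmentModel,
                  policy: ThresholdPolicy | None = None,
                  subject_id: str = "") -> InjuryCallSet:
    """Per-segment calls from a (island-filtered) enhancement map.

    A segment is positive when a surviving enhanced component intersects its
    territory *sizably*: with a policy, the within-territory enhanced tissue
    must locally admit an inscribed diameter above
    ``min_island_diameter_mm`` (twice the distance-to-background transform),
    so a hairline of enhancement along a quadrant boundary — e.g. from
    interpolating a registered scan — does not flag the neighboring
    segment.  A component straddling two quadrants sizably marks both.
    Without a policy any intersecting voxel counts.
    """
    from scipy import ndimage

    mask = emap.mask.data > 0
    calls = {k: False for k in SEGMENT_KEYS}
    if mask.any():
        coords = np.argwhere(mask)
        world = np.atleast_2d(emap.mask.voxel_to_world(coords.astype(float)))
        v, q = assign_segments_array(world, model)
        for key_idx, key in enumerate(SEGMENT_KEYS):
            vi, qi = VEINS.index(key[0]), QUADRANTS.index(key[1])
            sub = coords[(v == vi) & (q == qi)]
            if sub.shape[0] == 0:
                continue
            if policy is None:
                calls[key] = True
                continue
            lo = np.maximum(sub.min(axis=0) - 2, 0)
            hi = np.minimum(sub.max(axis=0) + 3, np.array(mask.shape))
            box = np.zeros(tuple(hi - lo), dtype=bool)
            box[tuple((sub - lo).T)] = True
            width = 2.0 * ndimage.distance_transform_edt(
                box, sampling=emap.mask.spacing).max()
            calls[key] = bool(width > policy.min_island_diameter_mm)
    return InjuryCallSet(subject_id=subject_id, modality=emap.modality,
                         timepoint=emap.timepoint, calls=calls)


def merge_injury(*maps: EnhancementMap) -> EnhancementMap:
    """Voxelwise union of enhancement maps on the same grid.

    Used to fold no-reflow (MVO) regions into the LGE injury map, since
    acute no-reflow develops into scar.
    """
    if not maps:
        raise ValueError("need at least one map")
    base = maps[0]
    union = base.mask.data > 0
    for m in maps[1:]:
        if not base.mask.same_grid(m.mask):
            raise ValueError("enhancement maps are on different grids")
        union = union | (m.mask.data > 0)
    vol = float(union.sum()) * base.mask.voxel_volume_mm3
    cav = base.cavity_volume_mm3
    pct = 100.0 * vol / cav if np.isfinite(cav) else float("nan")
    return EnhancementMap(mask=base.mask.with_data(union.astype(np.uint8)),
                          volume_mm3=vol, percent_of_cavity=pct,
                          modality=base.modality, timepoint=base.timepoint,
                          cavity_volume_mm3=cav)
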