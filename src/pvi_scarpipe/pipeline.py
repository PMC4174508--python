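"""End-to-end orchestration: phantom cohort -> measurements -> registration
-> segmentation -> 16-segment calls -> cohort statistics.

The phantom path generates a cohort of synthetic subjects (default 7) with
known per-segment injury, runs every analysis stage, and reports both the
clinical-style summary statistics and the recovery of planted truth.  An
image path ingests NIfTI volumes plus a traced cavity and ROI masks and runs
the volumetric stages.  All randomness derives from one seed; results are
written as deterministically-serialized JSON.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import agreement_stats as ag
from .core import ImageVolume, load_nifti
from .enhancement_seg import (detect_mvo, segment_lge, segment_t2w,
                              wall_search_region)
from .phantom import (EDEMA_LABELS, SCAR_LABELS, PhantomSpec, SignalParams,
                      default_injury_truth, generate_phantom, roi_from_mask,
                      segment_wall_roi, truth_segment_calls, write_phantom)
from .registration import RigidTransform, register_rigid
from .segment_model import SEGMENT_KEYS, InjuryCallSet, call_segments, \
    merge_injury
from .signal_metrics import (CohortStats, RoiSpec, ThresholdPolicy,
                             derive_edema_threshold, eer, cnr, roi_mean,
                             roi_sd, wall_thickness)

log = logging.getLogger("pvi_scarpipe")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``phantom`` (generate a synthetic cohort) or ``images``
    (paths to NIfTI inputs) drives the run.
    """

    seed: int = 0
    n_subjects: int = 7
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    phantom: bool = True
    images: dict | None = None          # see ``_run_images``
    do_registration: bool = True
    registration_bins: int = 32
    thickness_cohort: tuple = ((7.0, 1.8), (10.7, 4.1))   # pre / 24 h, mm
    signal_params: SignalParams = field(default_factory=SignalParams)
    injury_truth: dict | None = None    # fixed pattern; None -> per-subject
    out_dir: str | None = None
    write_volumes: bool = False

    def __post_init__(self) -> None:
        if self.phantom == (self.images is not None):
            raise ValueError("exactly one of phantom mode or image inputs "
                             "must be configured")
        if self.phantom and self.n_subjects < 1:
            raise ValueError("need at least one subject")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "policy" in kw:
            kw["policy"] = ThresholdPolicy(**kw["policy"])
        if "signal_params" in kw:
            kw["signal_params"] = SignalParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kw["signal_params"].items()})
        if "thickness_cohort" in kw:
            kw["thickness_cohort"] = tuple(tuple(x)
                                           for x in kw["thickness_cohort"])
        return cls(**kw)


def _truncnorm(rng, mean, sd, floor):
    v = rng.normal(mean, sd)
    return float(max(v, floor))


def _rotation_error_deg(a: RigidTransform, b: RigidTransform) -> float:
    r = a.rotation @ b.rotation.T
    c = np.clip((np.trace(r) - 1) / 2, -1.0, 1.0)
    return math.degrees(math.acos(c))


def _translation_error_mm(a: RigidTransform, b: RigidTransform,
                          probe_mm) -> float:
    p = np.asarray(probe_mm, float)
    return float(np.linalg.norm(a.apply(p) - b.apply(p)))


def _measure_thickness(vol: ImageVolume, spec: PhantomSpec,
                       x_offset_mm: float = 0.0) -> float:
    """Posterior-wall caliper at the LA equator, ray pointing posterior."""
    c = np.asarray(spec.la_center_mm, float)
    start = np.array([c[0] + x_offset_mm, c[1], c[2]])
    return wall_thickness(vol, start, (0.0, -1.0, 0.0), max_range_mm=45.0)


def _subject_analysis(spec: PhantomSpec, config: RunConfig,
                      rng: np.random.Generator) -> dict:
    """All per-subject stages; returns a record of measurements and calls."""
    policy = config.policy
    volumes, truth = generate_phantom(spec)
    rec: dict = {"subject_id": spec.subject_id,
                 "truth_labels": {f"{v}/{q}": lab for (v, q), lab
                                  in truth.segment_labels.items()}}

    # --- reference ROIs --------------------------------------------------
    lv_roi = roi_from_mask(truth, "t2w", "24h", "lv_myocardium", 60, rng,
                           "lv_myocardium")
    rois = {}
    for (mod, tp) in volumes:
        rois[(mod, tp)] = {
            "blood": roi_from_mask(truth, mod, tp, "blood", 100, rng, "blood"),
            "air": roi_from_mask(truth, mod, tp, "air", 100, rng, "air"),
        }

    # --- EER / CNR per segment -------------------------------------------
    def _lv_mean(tp):
        return roi_mean(volumes[("t2w", tp)], lv_roi)

    eers = {}
    for tp in spec.timepoints.get("t2w", ()):
        vol = volumes[("t2w", tp)]
        lv = _lv_mean(tp)
        eers[tp] = {}
        for key in SEGMENT_KEYS:
            roi = segment_wall_roi(truth, "t2w", tp, key, n=60)
            eers[tp][f"{key[0]}/{key[1]}"] = eer(roi_mean(vol, roi), lv)
    rec["eer"] = eers

    cnrs = {}
    for tp in spec.timepoints.get("lge", ()):
        vol = volumes[("lge", tp)]
        blood = roi_mean(vol, rois[("lge", tp)]["blood"])
        air_sd = roi_sd(vol, rois[("lge", tp)]["air"])
        cnrs[tp] = {}
        for key in SEGMENT_KEYS:
            roi = segment_wall_roi(truth, "lge", tp, key, n=60,
                                   part="non_mvo")
            cnrs[tp][f"{key[0]}/{key[1]}"] = cnr(roi_mean(vol, roi), blood,
                                                 air_sd)
    rec["cnr"] = cnrs

    # --- wall thickness (with a repeat read at a jittered site) ----------
    thickness = {}
    for tp in spec.timepoints.get("t2w", ()):
        vol = volumes[("t2w", tp)]
        first = _measure_thickness(vol, spec)
        repeat = _measure_thickness(vol, spec,
                                    x_offset_mm=float(rng.uniform(-3, 3)))
        thickness[tp] = {"first": first, "repeat": repeat}
    rec["thickness_mm"] = thickness

    # --- registration of 30-day LGE onto 24-hour LGE ---------------------
    inter_scan = truth.inter_scan_transform
    if config.do_registration and ("lge", "30d") in volumes \
            and ("lge", "24h") in volumes:
        recovered = register_rigid(volumes[("lge", "24h")],
                                   volumes[("lge", "30d")],
                                   bins=config.registration_bins,
                                   seed=config.seed)
        planted = truth.inter_scan_transform
        rec["registration"] = {
            "rotation_error_deg": _rotation_error_deg(recovered, planted),
            "translation_error_mm": _translation_error_mm(
                recovered, planted, spec.la_center_mm),
        }
        inter_scan = recovered          # matched locations via registration

    # --- segmentation and 16-segment calls -------------------------------
    model = spec.segment_model()
    calls, pcts = {}, {}
    for (mod, tp), vol in volumes.items():
        cavity = truth.mask(mod, tp, "cavity")
        region = wall_search_region(cavity, policy.shell_mm)
        if mod == "t2w":
            emap = segment_t2w(vol, lv_roi, region, policy, cavity_mask=cavity)
            injury = emap
        else:
            blood_roi = rois[(mod, tp)]["blood"]
            air_roi = rois[(mod, tp)]["air"]
            emap = segment_lge(vol, blood_roi, air_roi, region, policy,
                               cavity_mask=cavity)
            mvo = detect_mvo(vol, blood_roi, air_roi, region, policy,
                             cavity_mask=cavity)
            injury = merge_injury(emap, mvo)
        # 30-day scans are in a different patient position: carry the
        # segment territories through the (recovered) inter-scan transform
        tp_model = model.transformed(inter_scan) if tp == "30d" else model
        calls[(mod, tp)] = call_segments(injury, tp_model, policy=policy,
                                         subject_id=spec.subject_id)
        pcts[(mod, tp)] = {
            "measured_pct": emap.percent_of_cavity,
            "true_pct": truth.true_enhancement_volume_pct[(mod, tp)],
        }
    rec["_calls"] = calls
    rec["_truth_calls"] = {
        (mod, tp): truth_segment_calls(truth, mod, tp)
        for (mod, tp) in volumes}
    rec["enhancement_pct"] = {f"{m}/{t}": v for (m, t), v in pcts.items()}

    if config.out_dir and config.write_volumes:
        write_phantom(volumes, truth,
                      os.path.join(config.out_dir, spec.subject_id))
    return rec


def _call_sets(records, mod, tp):
    return [r["_calls"][(mod, tp)] for r in records
            if (mod, tp) in r["_calls"]]


def _truth_sets(records, mod, tp):
    out = []
    for r in records:
        if (mod, tp) in r["_truth_calls"]:
            out.append(InjuryCallSet(
                subject_id=r["subject_id"], modality=mod, timepoint=tp,
                calls=dict(r["_truth_calls"][(mod, tp)])))
    return out


def _diag(test, reference) -> dict | None:
    """Diagnostic summary of pooled calls; None when the reference has only
    one class (sensitivity/specificity undefined)."""
    c = ag.confusion(test, reference)
    if c.n_pos == 0 or c.n_neg == 0:
        return None
    s = ag.diagnostic_summary(c)
    chi, chi_p = ag.chi_squared(c)
    return {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
            "n": c.n, "dropped": c.dropped,
            "sensitivity_pct": 100 * s.sensitivity,
            "specificity_pct": 100 * s.specificity,
            "accuracy_pct": 100 * s.accuracy,
            "sensitivity_ci_pct": [100 * v for v in s.ci["sensitivity"]],
            "specificity_ci_pct": [100 * v for v in s.ci["specificity"]],
            "chi2": chi, "chi2_p": chi_p,
            "kappa": ag.cohens_kappa(c)}


def _cohort_stats(values) -> dict | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if len(vals) < 2:
        return None
    s = CohortStats.from_values(vals)
    return {"mean": s.mean, "sd": s.sd, "n": s.n}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and optionally write) the results."""
    if config.phantom:
        results = _run_phantom(config)
    else:
        results = _run_images(config)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        out_path = os.path.join(config.out_dir, "results.json")
        with open(out_path, "w") as fh:
            fh.write(serialize_results(results))
        log.info("results written to %s", out_path)
    return results


def _run_phantom(config: RunConfig) -> dict:
    master = np.random.default_rng(config.seed)
    (pre_mu, pre_sd), (post_mu, post_sd) = config.thickness_cohort
    records = []
    for i in range(config.n_subjects):
        stage = f"subject S{i + 1:02d}"
        try:
            t_pre = _truncnorm(master, pre_mu, pre_sd, 3.5)
            t_post = max(_truncnorm(master, post_mu, post_sd, 4.0),
                         t_pre + 0.5)
            subj_seed = int(master.integers(2 ** 31))
            subj_rng = np.random.default_rng(
                int(master.integers(2 ** 31)))
            spec = PhantomSpec(
                wall_thickness_mm=t_pre, thickening_mm=t_post - t_pre,
                injury_truth=(dict(config.injury_truth)
                              if config.injury_truth is not None
                              else default_injury_truth(subj_rng)),
                signal_params=config.signal_params,
                segment_radius_mm=config.policy.segment_radius_mm,
                rng_seed=subj_seed, subject_id=f"S{i + 1:02d}")
            log.info("generating and analysing %s", spec.subject_id)
            records.append(_subject_analysis(spec, config, subj_rng))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed: {stage}: "
                               f"{exc}") from exc

    results: dict = {
        "config": {
            "seed": config.seed, "n_subjects": config.n_subjects,
            "policy": asdict(config.policy),
            "signal_params": asdict(config.signal_params),
            "registration_bins": config.registration_bins,
        },
        "subjects": [{k: v for k, v in r.items()
                      if not k.startswith("_")} for r in records],
    }

    # --- cohort EER / CNR -------------------------------------------------
    def _seg_values(records, field, tp, keep=None):
        out = []
        for r in records:
            labs = r["truth_labels"]
            for seg, v in r.get(field, {}).get(tp, {}).items():
                if keep is None or labs[seg] in keep:
                    out.append(v)
        return out

    eer_pre = _seg_values(records, "eer", "pre")
    eer_24h_inj = _seg_values(records, "eer", "24h", EDEMA_LABELS)
    cnr_24h_inj = _seg_values(records, "cnr", "24h", SCAR_LABELS)
    cnr_30d_inj = _seg_values(records, "cnr", "30d", SCAR_LABELS)

    results["cohort"] = {
        "eer_pre": _cohort_stats(eer_pre),
        "eer_24h_injured": _cohort_stats(eer_24h_inj),
        "cnr_24h_scar": _cohort_stats(cnr_24h_inj),
        "cnr_30d_scar": _cohort_stats(cnr_30d_inj),
        "eer_t_p": ag.t_test_two_sample(eer_24h_inj, eer_pre)[1]
        if eer_pre and eer_24h_inj else None,
        "cnr_t_p": ag.t_test_two_sample(cnr_30d_inj, cnr_24h_inj)[1]
        if cnr_24h_inj and cnr_30d_inj else None,
    }
    ctl = CohortStats.from_values(eer_pre)
    results["cohort"]["edema_threshold"] = derive_edema_threshold(
        ctl, config.policy.k_sd)

    # --- wall thickness ---------------------------------------------------
    th_pre = [r["thickness_mm"]["pre"]["first"] for r in records
              if "pre" in r.get("thickness_mm", {})]
    th_24h = [r["thickness_mm"]["24h"]["first"] for r in records
              if "24h" in r.get("thickness_mm", {})]
    pairs = [(r["thickness_mm"][tp]["first"], r["thickness_mm"][tp]["repeat"])
             for r in records for tp in r.get("thickness_mm", {})]
    thick = {
        "pre": _cohort_stats(th_pre), "24h": _cohort_stats(th_24h),
        "t_p": ag.t_test_two_sample(th_24h, th_pre)[1]
        if len(th_pre) > 1 and len(th_24h) > 1 else None,
    }
    if len(pairs) >= 3:
        bias, limits = ag.bland_altman(pairs)
        r_rep, _ = ag.pearson_r(pairs)
        thick["repeat_bias_mm"] = bias
        thick["repeat_limits_mm"] = list(limits)
        thick["repeat_icc"] = ag.icc_absolute(pairs)
        thick["repeat_r"] = r_rep
    results["thickness"] = thick

    # --- registration recovery -------------------------------------------
    reg = [r["registration"] for r in records if "registration" in r]
    if reg:
        results["registration"] = {
            "mean_rotation_error_deg": float(np.mean(
                [x["rotation_error_deg"] for x in reg])),
            "max_rotation_error_deg": float(np.max(
                [x["rotation_error_deg"] for x in reg])),
            "mean_translation_error_mm": float(np.mean(
                [x["translation_error_mm"] for x in reg])),
            "max_translation_error_mm": float(np.max(
                [x["translation_error_mm"] for x in reg])),
            "n": len(reg)}

    # --- per-quadrant agreement (measured vs measured, and vs truth) ------
    t2w24 = _call_sets(records, "t2w", "24h")
    lge24 = _call_sets(records, "lge", "24h")
    lge30 = _call_sets(records, "lge", "30d")
    agreement = {}

    def _add(name, test, ref):
        if test and ref:
            d = _diag(test, ref)
            if d is not None:
                agreement[name] = d

    _add("t2w24_vs_lge30", t2w24, lge30)
    _add("lge24_vs_lge30", lge24, lge30)
    if t2w24 and lge24:
        agreement["kappa_t2w24_vs_lge24"] = ag.cohens_kappa(
            ag.confusion(t2w24, lge24))
    for mod, tp, name in (("t2w", "24h", "t2w24_vs_truth"),
                          ("lge", "24h", "lge24_vs_truth"),
                          ("lge", "30d", "lge30_vs_truth")):
        _add(name, _call_sets(records, mod, tp),
             _truth_sets(records, mod, tp))
    if lge30:
        vals = [v for s in lge30 for v in s.calls.values() if v is not None]
        agreement["pct_quadrants_lge30"] = 100.0 * sum(vals) / len(vals)
    if t2w24:
        vals = [v for s in t2w24 for v in s.calls.values() if v is not None]
        agreement["pct_quadrants_t2w24"] = 100.0 * sum(vals) / len(vals)
    results["agreement"] = agreement

    # --- enhancement volumes ----------------------------------------------
    vol_section = {}
    for mod, tp in (("t2w", "24h"), ("lge", "24h"), ("lge", "30d")):
        key = f"{mod}/{tp}"
        meas = [r["enhancement_pct"][key]["measured_pct"] for r in records
                if key in r.get("enhancement_pct", {})]
        true = [r["enhancement_pct"][key]["true_pct"] for r in records
                if key in r.get("enhancement_pct", {})]
        if not meas:
            continue
        rel_err = [abs(m - t) / t for m, t in zip(meas, true) if t > 0]
        vol_section[key] = {
            "measured_pct": meas, "true_pct": true,
            "max_relative_error": max(rel_err) if rel_err else None,
            "mean_relative_error": (float(np.mean(rel_err))
                                    if rel_err else None)}
    t2w_pcts = [r["enhancement_pct"]["t2w/24h"]["measured_pct"]
                for r in records]
    lge24_pcts = [r["enhancement_pct"]["lge/24h"]["measured_pct"]
                  for r in records]
    lge30_pcts = [r["enhancement_pct"]["lge/30d"]["measured_pct"]
                  for r in records]
    if len(lge30_pcts) >= 3:
        r1, p1 = ag.pearson_r(list(zip(t2w_pcts, lge30_pcts)))
        r2, p2 = ag.pearson_r(list(zip(lge24_pcts, lge30_pcts)))
        vol_section["corr_t2w24_vs_lge30"] = {"r": r1, "p": p1}
        vol_section["corr_lge24_vs_lge30"] = {"r": r2, "p": p2}
    results["volumes"] = vol_section
    return results


def _run_images(config: RunConfig) -> dict:
    """Volumetric stages on user-supplied NIfTI inputs.

    ``config.images`` maps subject ids to entries with ``volumes``
    ({"modality/timepoint": path}), ``cavity`` (path per modality/timepoint),
    and ROI masks ``blood``/``air``/``lv`` (label NIfTI paths).
    """
    policy = config.policy
    out: dict = {"subjects": []}
    for subject_id, entry in sorted(config.images.items()):
        stage = f"subject {subject_id}"
        try:
            rec = {"subject_id": subject_id, "enhancement_pct": {}}
            for key, path in sorted(entry["volumes"].items()):
                mod, tp = key.split("/")
                vol = load_nifti(path, modality=mod, timepoint=tp,
                                 subject_id=subject_id)
                cavity = load_nifti(entry["cavity"][key])
                region = wall_search_region(cavity, policy.shell_mm)

                def _roi(name, label):
                    mask = load_nifti(entry[name][key])
                    return RoiSpec(volume_id=key,
                                   voxel_indices=np.argwhere(mask.data > 0),
                                   label=label)

                if mod == "t2w":
                    emap = segment_t2w(vol, _roi("lv", "lv_myocardium"),
                                       region, policy, cavity_mask=cavity)
                else:
                    emap = segment_lge(vol, _roi("blood", "blood"),
                                       _roi("air", "air"), region, policy,
                                       cavity_mask=cavity)
                rec["enhancement_pct"][key] = {
                    "measured_pct": emap.percent_of_cavity,
                    "volume_mm3": emap.volume_mm3}
            out["subjects"].append(rec)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed: {stage}: "
                               f"{exc}") from exc
    return out


def serialize_results(results: dict) -> str:
    """Deterministic JSON: sorted keys, floats at fixed precision."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            v = float(obj)
            return round(v, 10) if np.isfinite(v) else None
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    return json.dumps(_clean(results), indent=2, sort_keys=True) + "\n"
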