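"""Synthetic stand-in for the deposited raw-measurements workbook.

The real supplementary workbook is not redistributable here, so tests build
an equivalent table whose rows are drawn from the published cohort
distributions (EER 0.87±0.18 pre / 1.52±0.38 post; ostial CNR 8.2±3.6 at
24 h / 11.4±4.1 at 30 d; wall thickness 7.0±1.8 / 10.7±4.1 mm) and whose
per-quadrant call sheets realize a fixed, internally consistent 2x2x2
contingency chosen to match the published diagnostic proportions
(82/63/79% for T2W, 91% sensitivity and 84% accuracy for 24-hour LGE, 86%
of quadrants scarred at 30 days).  Everything is seeded and the planted
truth is returned alongside the rows so recomputation can be checked
exactly.
"""

import numpy as np

from pvi_scarpipe.segment_model import SEGMENT_KEYS
from pvi_scarpipe.supplementary_io import MeasurementRow

N_SUBJECTS = 7

# joint (t2w24, lge24) cell counts by 30-day reference status; see module
# docstring.  Within reference-positive (96) and reference-negative (16):
CELLS_REF_POS = {"tt_ll": 77, "tt_only": 2, "ll_only": 10, "neither": 7}
CELLS_REF_NEG = {"tt_ll": 2, "tt_only": 4, "ll_only": 7, "neither": 3}

TRUE_COUNTS = {
    "t2w_tp": 79, "t2w_fp": 6, "t2w_fn": 17, "t2w_tn": 10,
    "lge_tp": 87, "lge_fp": 9, "lge_fn": 9, "lge_tn": 7,
    "ref_pos": 96, "ref_neg": 16,
}

COHORTS = {
    ("eer", "t2w", "pre"): (0.87, 0.18, 60),
    ("eer", "t2w", "24h"): (1.52, 0.38, 44),
    ("cnr", "lge", "24h"): (8.2, 3.6, 40),
    ("cnr", "lge", "30d"): (11.4, 4.1, 28),
    ("thickness_mm", "t2w", "pre"): (7.0, 1.8, 11),
    ("thickness_mm", "t2w", "24h"): (10.7, 4.1, 11),
}


def build_rows(seed=0):
    """Return (rows, truth) for the synthetic workbook."""
    rng = np.random.default_rng(seed)
    rows = []

    for (kind, mod, tp), (mean, sd, n) in COHORTS.items():
        vals = rng.normal(mean, sd, n)
        if kind == "thickness_mm":
            vals = np.clip(vals, 2.0, None)
        for i, v in enumerate(vals):
            rows.append(MeasurementRow(
                subject=f"S{i % N_SUBJECTS + 1:02d}", timepoint=tp,
                modality=mod, location="wall", kind=kind, value=float(v)))

    # per-quadrant call sheets: lay the fixed contingency cells onto the
    # 7 x 16 segment slots in a seeded shuffle
    slots = [(f"S{s + 1:02d}", key) for s in range(N_SUBJECTS)
             for key in SEGMENT_KEYS]
    order = rng.permutation(len(slots))
    cells = (
        [("+", "+", "+")] * CELLS_REF_POS["tt_ll"]
        + [("+", "-", "+")] * CELLS_REF_POS["tt_only"]
        + [("-", "+", "+")] * CELLS_REF_POS["ll_only"]
        + [("-", "-", "+")] * CELLS_REF_POS["neither"]
        + [("+", "+", "-")] * CELLS_REF_NEG["tt_ll"]
        + [("+", "-", "-")] * CELLS_REF_NEG["tt_only"]
        + [("-", "+", "-")] * CELLS_REF_NEG["ll_only"]
        + [("-", "-", "-")] * CELLS_REF_NEG["neither"])
    assert len(cells) == len(slots)
    n_pre_pos = 9                       # ~8% of quadrants enhanced pre-PVI
    pre_pos = set(rng.choice(len(slots), size=n_pre_pos, replace=False))
    for slot_idx, cell in zip(order, cells):
        subject, (vein, quadrant) = slots[slot_idx]
        loc = f"{vein}/{quadrant}"
        t2w, lge, ref = cell
        rows.append(MeasurementRow(subject, "24h", "t2w", loc, "call",
                                   1.0 if t2w == "+" else 0.0))
        rows.append(MeasurementRow(subject, "24h", "lge", loc, "call",
                                   1.0 if lge == "+" else 0.0))
        rows.append(MeasurementRow(subject, "30d", "lge", loc, "call",
                                   1.0 if ref == "+" else 0.0))
        rows.append(MeasurementRow(subject, "pre", "t2w", loc, "call",
                                   1.0 if slot_idx in pre_pos else 0.0))
    return rows, TRUE_COUNTS
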