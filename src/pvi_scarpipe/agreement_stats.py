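"""Diagnostic-accuracy and agreement statistics for paired segment calls.

Pools per-quadrant binary calls across subjects into a 2x2 table and
computes sensitivity/specificity/accuracy with binomial CIs, Pearson's
chi-squared, Cohen's kappa, a two-way random absolute-agreement ICC,
Bland-Altman limits, Pearson correlation and the pooled two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .segment_model import SEGMENT_KEYS, InjuryCallSet


@dataclass
class ConfusionTable:
    """2x2 counts of test vs. reference calls; ``dropped`` counts segments
    missing (non-assessable) in either set."""

    tp: int
    fp: int
    fn: int
    tn: int
    dropped: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class DiagnosticSummary:
    sensitivity: float
    specificity: float
    accuracy: float
    ci: dict                       # {"sensitivity": (lo, hi), ...}
    ci_wilson: dict
    n_pos: int
    n_neg: int
    alpha: float = 0.05


def confusion(test: list[InjuryCallSet],
              reference: list[InjuryCallSet]) -> ConfusionTable:
    """Pool paired per-segment calls across subjects.

    Pairing is by subject id; a segment whose call is ``None`` (not
    assessable) in either set is dropped and counted in ``dropped``.
    """
    ref_by_subject = {c.subject_id: c for c in reference}
    tp = fp = fn = tn = dropped = 0
    matched = False
    for t in test:
        r = ref_by_subject.get(t.subject_id)
        if r is None:
            dropped += len(SEGMENT_KEYS)
            continue
        matched = True
        for key in SEGMENT_KEYS:
            tv, rv = t.calls[key], r.calls[key]
            if tv is None or rv is None:
                dropped += 1
            elif tv and rv:
                tp += 1
            elif tv and not rv:
                fp += 1
            elif not tv and rv:
                fn += 1
            else:
                tn += 1
    if not matched or tp + fp + fn + tn == 0:
        raise ValueError("no overlapping assessable segments")
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn, dropped=dropped)


def _wald_ci(p: float, n: int, alpha: float) -> tuple[float, float]:
    z = sstats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def _wilson_ci(p: float, n: int, alpha: float) -> tuple[float, float]:
    z = sstats.norm.ppf(1 - alpha / 2)
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def diagnostic_summary(c: ConfusionTable,
                       alpha: float = 0.05) -> DiagnosticSummary:
    """Sensitivity, specificity and accuracy with Wald CIs (clipped to
    [0, 1]); Wilson intervals are reported alongside."""
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("need both reference positives and negatives")
    sens = c.tp / c.n_pos
    spec = c.tn / c.n_neg
    acc = (c.tp + c.tn) / c.n
    ci = {"sensitivity": _wald_ci(sens, c.n_pos, alpha),
          "specificity": _wald_ci(spec, c.n_neg, alpha),
          "accuracy": _wald_ci(acc, c.n, alpha)}
    ciw = {"sensitivity": _wilson_ci(sens, c.n_pos, alpha),
           "specificity": _wilson_ci(spec, c.n_neg, alpha),
           "accuracy": _wilson_ci(acc, c.n, alpha)}
    return DiagnosticSummary(sensitivity=sens, specificity=spec, accuracy=acc,
                             ci=ci, ci_wilson=ciw, n_pos=c.n_pos,
                             n_neg=c.n_neg, alpha=alpha)


def chi_squared(c: ConfusionTable,
                continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 table, 1 df.

    Returns (0, 1) when a margin is empty (independence is then vacuous).
    """
    obs = np.array([[c.tp, c.fn], [c.fp, c.tn]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    exp = rows @ cols / obs.sum()
    diff = np.abs(obs - exp)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / exp).sum())
    return stat, float(sstats.chi2.sf(stat, df=1))


def cohens_kappa(c: ConfusionTable) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from the margins."""
    n = c.n
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fp) * (c.tp + c.fn)
          + (c.fn + c.tn) * (c.fp + c.tn)) / n ** 2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def icc_absolute(pairs) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    ``pairs`` is an (n, 2) array-like of repeated measurements (it also
    accepts k > 2 columns).
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 measurements")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def bland_altman(pairs) -> tuple[float, tuple[float, float]]:
    """Mean difference (second minus first) and mean +/- 2 SD limits."""
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 2:
        raise ValueError("need (n, 2) pairs with n >= 2")
    d = x[:, 1] - x[:, 0]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 2 * sd, bias + 2 * sd)


def pearson_r(pairs) -> tuple[float, float]:
    """Sample correlation; two-sided p from the t transform with n-2 df."""
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
        raise ValueError("need (n, 2) pairs with n >= 3")
    a, b = x[:, 0], x[:, 1]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.clip((a * b).sum() / denom, -1.0, 1.0))
    n = x.shape[0]
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * sstats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def t_test_two_sample(xs, ys) -> tuple[float, float]:
    """Pooled-variance two-sample Student t, two-sided p."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
           / (nx + ny - 2))
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(x.mean() - y.mean())), 0.0
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sstats.t.sf(abs(t), df=nx + ny - 2)
    return float(t), float(p)
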