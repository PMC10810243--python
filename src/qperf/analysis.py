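"""Defect thresholds and agreement statistics.

Optimal MBF cut-offs to detect stress perfusion defects are derived by
ROC analysis with the Youden index (J = sensitivity + specificity - 1) at
four resolutions — pixel, AHA segment, coronary territory and patient —
with low flow classified positive (``mbf < cutoff``).  Agreement with
reference defect masks is summarised by Dice overlap, Pearson correlation
of defect burdens, Bland-Altman bias with limits of agreement and a
proportional-bias regression, and Mann-Whitney comparison of MBF inside
versus outside defects.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "TERRITORIES",
    "ThresholdResult",
    "BlandAltman",
    "AgreementReport",
    "roc_youden",
    "segment_mbf",
    "segment_positive",
    "territory_summary",
    "patient_summary",
    "dice",
    "bland_altman",
    "mann_whitney",
    "threshold_map",
    "segment_burden",
]

#: coronary territories of the AHA 16-segment model
TERRITORIES = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "RCA": (3, 4, 9, 10, 15),
    "LCX": (5, 6, 11, 12, 16),
}
TERRITORY_ORDER = ("LAD", "RCA", "LCX")


@dataclass(frozen=True)
class ThresholdResult:
    """ROC-optimal cut-off and its operating characteristics."""

    cutoff: float
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BlandAltman:
    mean_bias: float
    loa_low: float
    loa_high: float
    prop_beta: float
    prop_p: float


@dataclass(frozen=True)
class AgreementReport:
    """Cohort agreement between reference and quantified defects."""

    dice: float
    pearson_r: float
    mean_bias: float
    loa_low: float
    loa_high: float
    prop_beta: float
    prop_p: float
    mannwhitney_u: float
    mannwhitney_p: float

    def as_dict(self) -> dict:
        return asdict(self)


def roc_youden(values, labels) -> ThresholdResult:
    """ROC/Youden-optimal MBF cut-off; low flow is the positive class.

    Candidate cut-offs are the midpoints of consecutive sorted unique
    values (plus the two one-sided extremes); the one maximising
    J = sensitivity + specificity - 1 is chosen, taking the middle
    candidate when several tie.  AUC is the trapezoidal area under the
    empirical ROC curve.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1D arrays of equal length")
    if not np.all(np.isfinite(v)):
        raise ValueError("MBF samples must be finite")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("both classes must be present for ROC analysis")

    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[-np.inf], mids, [np.inf]])
    pos = np.sort(v[y])
    neg = np.sort(v[~y])
    # prediction rule: positive iff value < cutoff (strict)
    sens = np.searchsorted(pos, cands, side="left") / len(pos)
    spec = 1.0 - np.searchsorted(neg, cands, side="left") / len(neg)
    j = sens + spec - 1.0
    tied = np.flatnonzero(j >= j.max() - 1e-12)
    finite_tied = tied[np.isfinite(cands[tied])]
    if finite_tied.size:
        tied = finite_tied
    pick = tied[(len(tied) - 1) // 2]
    cutoff = float(cands[pick])
    if not np.isfinite(cutoff):  # degenerate: no informative cut-off
        cutoff = float(np.median(v))

    auc = float(roc_auc_score(y, -v))
    tp = int((pos < cutoff).sum())
    tn = int((neg >= cutoff).sum())
    return ThresholdResult(
        cutoff=cutoff,
        auc=auc,
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        accuracy=(tp + tn) / len(v),
        youden_j=float(j[pick]),
    )


def _iter_slices(maps, labels):
    maps = maps if isinstance(maps, (list, tuple)) else [maps]
    labels = labels if isinstance(labels, (list, tuple)) else [labels]
    if len(maps) != len(labels):
        raise ValueError("need one label image per map")
    return maps, labels


def segment_mbf(maps, labels) -> np.ndarray:
    """Mean MBF of the valid pixels of each AHA segment.

    ``maps``/``labels`` are per-slice (one or a sequence of slices
    covering the 16 segments).  Returns a length-16 array indexed by
    segment ID - 1; empty segments are NaN.
    """
    maps, labels = _iter_slices(maps, labels)
    sums = np.zeros(16)
    counts = np.zeros(16, dtype=int)
    for pmap, lab in zip(maps, labels):
        lab_arr = lab.labels if hasattr(lab, "labels") else np.asarray(lab, int)
        sel = (lab_arr > 0) & pmap.valid_mask
        ids = lab_arr[sel] - 1
        np.add.at(sums, ids, pmap.mbf[sel])
        np.add.at(counts, ids, 1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def segment_positive(defect_masks, labels) -> np.ndarray:
    """Segment positivity: strictly more than half of its pixels in a defect.

    Returns a length-16 boolean array (False for segments absent from the
    supplied slices).
    """
    defect_masks = defect_masks if isinstance(defect_masks, (list, tuple)) else [defect_masks]
    labels = labels if isinstance(labels, (list, tuple)) else [labels]
    if len(defect_masks) != len(labels):
        raise ValueError("need one defect mask per label image")
    inside = np.zeros(16, dtype=int)
    totals = np.zeros(16, dtype=int)
    for mask, lab in zip(defect_masks, labels):
        lab_arr = lab.labels if hasattr(lab, "labels") else np.asarray(lab, int)
        mask = np.asarray(mask, bool)
        sel = lab_arr > 0
        ids = lab_arr[sel] - 1
        np.add.at(totals, ids, 1)
        np.add.at(inside, ids, mask[sel].astype(int))
    return (inside > totals / 2.0) & (totals > 0)


def territory_summary(segment_values, segment_flags):
    """Coronary-territory MBF and positivity from the 16 segments.

    Territory MBF is the mean of the two lowest segment values in the
    territory; a territory is positive if any of its segments is.  Returns
    ``(values, flags)`` as length-3 arrays ordered (LAD, RCA, LCX).
    """
    seg_v = np.asarray(segment_values, dtype=float)
    seg_f = np.asarray(segment_flags, dtype=bool)
    if seg_v.shape != (16,) or seg_f.shape != (16,):
        raise ValueError("expected 16 segment values and 16 flags")
    values = np.full(3, np.nan)
    flags = np.zeros(3, dtype=bool)
    for i, name in enumerate(TERRITORY_ORDER):
        idx = np.array(TERRITORIES[name]) - 1
        v = seg_v[idx]
        v = np.sort(v[np.isfinite(v)])
        if v.size:
            values[i] = v[: min(2, v.size)].mean()
        flags[i] = bool(seg_f[idx].any())
    return values, flags


def patient_summary(maps, territory_flags):
    """Patient MBF (mean over all valid myocardial pixels) and positivity."""
    maps = maps if isinstance(maps, (list, tuple)) else [maps]
    pooled = np.concatenate([m.values for m in maps])
    if pooled.size == 0:
        raise ValueError("no valid myocardial pixels")
    return float(pooled.mean()), bool(np.asarray(territory_flags, bool).any())


def dice(mask_a, mask_b) -> float:
    """Dice score coefficient, ``2|A∩B| / (|A| + |B|)``.

    Two empty masks agree perfectly and score 1.
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def bland_altman(burden_manual, burden_quant) -> BlandAltman:
    """Bland-Altman agreement of paired defect burdens (percent).

    Differences are ``manual - quant`` (a negative bias means the manual
    reading underestimates the quantified burden).  Proportional bias is
    the OLS slope of the differences on the pair means, with its two-sided
    p-value.
    """
    m = np.asarray(burden_manual, dtype=float)
    q = np.asarray(burden_quant, dtype=float)
    if m.shape != q.shape or m.ndim != 1 or len(m) < 3:
        raise ValueError("need paired burden vectors with n >= 3")
    d = m - q
    mean_bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (m + q) / 2.0
    if np.ptp(means) == 0:
        beta, p = 0.0, 1.0
    else:
        fit = stats.linregress(means, d)
        beta, p = float(fit.slope), float(fit.pvalue)
    return BlandAltman(
        mean_bias=mean_bias,
        loa_low=mean_bias - 1.96 * sd,
        loa_high=mean_bias + 1.96 * sd,
        prop_beta=beta,
        prop_p=p,
    )


def mann_whitney(group_a, group_b):
    """Two-sided Mann-Whitney U test; returns ``(U, p)`` for ``group_a``.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def threshold_map(grid, cutoff: float):
    """Binary defect map: cell positive iff MBF < cutoff; NaN stays NaN.

    Accepts a bullseye grid, a perfusion map or a plain array; returns a
    float array with values 1.0 / 0.0 / NaN.
    """
    if hasattr(grid, "mbf"):
        v = np.asarray(grid.mbf, dtype=float)
    elif hasattr(grid, "values") and not isinstance(grid, np.ndarray):
        v = np.asarray(grid.values, dtype=float)
    else:
        v = np.asarray(grid, dtype=float)
    out = np.where(np.isfinite(v), (v < cutoff).astype(float), np.nan)
    return out


def segment_burden(segment_flags) -> float:
    """Burden implied by dichotomised equal-weight segments, percent.

    With 16 segments each counting 1/16 of the myocardium, the reportable
    burden moves in steps of 100/16 = 6.25%.
    """
    f = np.asarray(segment_flags, dtype=bool)
    if f.size == 0:
        raise ValueError("no segment flags")
    return 100.0 * f.sum() / f.size
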