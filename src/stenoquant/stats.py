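"""Agreement and discrimination statistics.

* Bland–Altman 95 % limits of agreement, using the literal mean ± 2·SD of
  the paired differences (sample SD, denominator n−1);
* two-way random-effects intraclass correlation for absolute agreement,
  single measures — ICC(2,1) — from the two-way ANOVA mean squares, with
  the standard F-based 95 % confidence interval (Satterthwaite df);
* empirical ROC curves and AUC (equal to the Mann–Whitney statistic with
  ties counted ½), with DeLong (default) or Hanley–McNeil confidence
  intervals, and the paired DeLong test for comparing two AUCs measured on
  the same cases.

No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve


# --------------------------------------------------------------------------- descriptives
def descriptives(values) -> tuple[float, float, int]:
    """Mean, sample SD (n−1; NaN when n < 2) and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    return float(v.mean()), sd, int(v.size)


# --------------------------------------------------------------------------- limits of agreement
def limits_of_agreement(differences) -> tuple[float, float, float]:
    """Mean difference and mean ± 2·sample-SD limits (exactly 2, not 1.96)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("limits of agreement need at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 2.0 * sd, mean + 2.0 * sd


# --------------------------------------------------------------------------- ICC
@dataclass
class AgreementResult:
    """Limits-of-agreement plus ICC summary of paired measurements."""

    mean_difference: float
    loa_low: float
    loa_high: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    n: int


def _two_way_mean_squares(matrix: np.ndarray) -> tuple[float, float, float, int, int]:
    x = np.asarray(matrix, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 complete cases and 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc_two_way_random(
    matrix, measures: str = "single", alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC treating both cases and raters as random effects, absolute
    agreement; ``measures='single'`` gives ICC(2,1), ``'average'`` ICC(2,k).

    Cases with a missing rater are dropped (complete-matrix analysis).
    Returns (icc, ci_low, ci_high); all NaN when the total variance is zero.
    """
    if measures not in ("single", "average"):
        raise ValueError("measures must be 'single' or 'average'")
    msr, msc, mse, n, k = _two_way_mean_squares(matrix)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 and msr <= 0:
        return float("nan"), float("nan"), float("nan")
    icc1 = (msr - mse) / denom

    # F-based CI for ICC(2,1) with Satterthwaite degrees of freedom
    a = k * icc1 / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    b = 1.0 + k * icc1 * (n - 1.0) / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    if np.isfinite(a):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
        f_l = sps.f.ppf(1 - alpha / 2, n - 1.0, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1.0)
        lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        lo = hi = 1.0
    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    if measures == "average":
        conv = lambda r: k * r / (1.0 + (k - 1.0) * r) if np.isfinite(r) else r  # noqa: E731
        return float(conv(icc1)), float(conv(lo)), float(conv(hi))
    return float(icc1), lo, hi


def agreement(values_a, values_b, measures: str = "single") -> AgreementResult:
    """Joint Bland–Altman + ICC summary of two paired measurement series."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    mean, lo, hi = limits_of_agreement(a - b)
    icc, ci_lo, ci_hi = icc_two_way_random(np.column_stack([a, b]), measures=measures)
    return AgreementResult(mean, lo, hi, icc, ci_lo, ci_hi, int(a.size))


# --------------------------------------------------------------------------- ROC / AUC
@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values and their covariance pieces for one classifier."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(scores)
    auc = (tz[labels].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[labels] - tx) / n  # per-positive placements
    v10 = 1.0 - (tz[~labels] - ty) / m  # per-negative placements
    return auc, v01, v10


def _prepare(scores, labels, positive_direction: str) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = y == "positive"
    y = y.astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if positive_direction == "lower":
        s = -s  # smaller value = more diseased (MinD, MinA)
    elif positive_direction != "higher":
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    return s, y


def roc_auc(
    scores,
    labels,
    positive_direction: str = "higher",
    ci_method: str = "delong",
    alpha: float = 0.05,
) -> RocResult:
    """Empirical ROC curve and AUC with a 95 % confidence interval.

    The AUC equals the Mann–Whitney statistic (ties counted ½), which is
    the area under the trapezoidal empirical curve.  ``positive_direction``
    states whether larger scores indicate disease (Dred/Ared) or smaller
    ones do (MinD/MinA, which are inverted).
    """
    s, y = _prepare(scores, labels, positive_direction)
    auc, v01, v10 = _delong_components(s, y)
    m, n = int(y.sum()), int((~y).sum())
    if ci_method == "delong":
        var = (v01.var(ddof=1) / m if m > 1 else 0.0) + (v10.var(ddof=1) / n if n > 1 else 0.0)
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    else:
        raise ValueError("ci_method must be 'delong' or 'hanley-mcneil'")
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    return RocResult(
        auc=float(auc),
        ci_low=float(np.clip(auc - half, 0, 1)),
        ci_high=float(np.clip(auc + half, 0, 1)),
        n_pos=m,
        n_neg=n,
        fpr=fpr,
        tpr=tpr,
    )


def compare_auc_paired(
    scores_a,
    scores_b,
    labels,
    positive_direction_a: str = "higher",
    positive_direction_b: str = "higher",
) -> tuple[float, float, float]:
    """Paired DeLong test of two AUCs on the same cases.

    Returns (auc_a, auc_b, two-sided p).  The covariance of the two AUCs is
    estimated from the per-case placement values, so identical (or rank-
    equivalent) classifiers give a difference of exactly 0 and p = 1.
    """
    sa, y = _prepare(scores_a, labels, positive_direction_a)
    sb, y2 = _prepare(scores_b, labels, positive_direction_b)
    if len(sa) != len(sb):
        raise ValueError("paired scores must have equal length")
    auc_a, v01_a, v10_a = _delong_components(sa, y)
    auc_b, v01_b, v10_b = _delong_components(sb, y2)
    m, n = len(v01_a), len(v10_a)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s01 / m + s10 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p
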