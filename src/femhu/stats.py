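"""Diagnostic-statistics layer: T-score classification, Mann-Whitney AUC with
DeLong variance, Youden cutoffs, predictive values, correlated-AUC comparison,
Spearman correlation with Fisher-z confidence intervals, ICC(A,1) reliability,
and five-number box-plot summaries.

Conventions
-----------
* AUC is the pairwise Mann-Whitney probability (ties count 1/2), identical to
  the trapezoidal area under the empirical ROC curve.
* Candidate Youden cutoffs are the observed score values, so a reported
  cutoff is always a data value. Indexes that are *low* in disease (mean-HU,
  HUHA_Bone) use the rule "positive if score <= cutoff"; indexes *high* in
  disease (HUHA_Fat) use "positive if score > cutoff".
* ICC is the single-measure absolute-agreement coefficient from the two-way
  ANOVA decomposition; its interpretation bins are poor < 0.50, moderate
  0.50-0.75, good 0.76-0.90, excellent > 0.90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

POSITIVE_IF_LOW = "positive_if_low"
POSITIVE_IF_HIGH = "positive_if_high"


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95: tuple[float, float]
    direction: str
    cutoff: float
    sens: float
    spec: float
    ppv: float | None = None
    npv: float | None = None
    p_value: float | None = None  # AUC vs 0.5, DeLong variance


@dataclass(frozen=True)
class CorrResult:
    rho: float
    ci95: tuple[float, float]
    p_value: float
    category: str
    n: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    category: str


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# classification


def classify_tscore(t: float) -> tuple[str, str]:
    """WHO densitometric classes and the binary screening label.

    Returns ``(three_level, binary)`` with boundaries: T <= -2.5 osteoporosis
    (inclusive), T >= -1.0 normal (inclusive), osteopenia in between.
    """
    t = float(t)
    if not math.isfinite(t):
        raise ValueError("T-score must be finite")
    if t <= -2.5:
        return "osteoporosis", "osteoporosis"
    three = "normal" if t >= -1.0 else "osteopenia"
    return three, "non-osteoporosis"


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def _split(scores, labels, direction):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not (y.any() and (~y).any()):
        raise DegenerateInputError("both classes must be nonempty")
    if direction == POSITIVE_IF_LOW:
        s = -s
    elif direction != POSITIVE_IF_HIGH:
        raise ValueError(f"unknown direction {direction!r}")
    return s[y], s[~y]


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def auc_mann_whitney(scores, labels, direction: str = POSITIVE_IF_HIGH) -> RocResult:
    """Pairwise AUC with a DeLong-variance 95% CI (truncated to [0, 1])."""
    pos, neg = _split(scores, labels, direction)
    v10, v01, auc = _placements(pos, neg)
    m, n = len(pos), len(neg)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = math.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se)
    if se > 0:
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(
        auc=auc, ci95=(lo, hi), direction=direction, cutoff=math.nan, sens=math.nan,
        spec=math.nan, p_value=float(p),
    )


def youden_cutoff(scores, labels, direction: str = POSITIVE_IF_HIGH) -> tuple[float, float, float]:
    """Cutoff maximizing J = sens + spec - 1 over observed score values.

    Ties in J break toward higher sensitivity, then toward the smaller
    cutoff magnitude. Returns ``(cutoff, sens_percent, spec_percent)`` on the
    original score scale.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (y.any() and (~y).any()):
        raise DegenerateInputError("both classes must be nonempty")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for c in np.unique(s):
        pred = (s <= c) if direction == POSITIVE_IF_LOW else (s > c)
        sens = float(np.sum(pred & y)) / n_pos
        spec = float(np.sum(~pred & ~y)) / n_neg
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12), -abs(c))
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    _, cutoff, sens, spec = best
    return cutoff, 100.0 * sens, 100.0 * spec


def confusion_from_rates(
    n_pos: int, n_neg: int, sens: float, spec: float
) -> tuple[int, int, int, int, float, float]:
    """Reconstruct the integer confusion matrix from printed rates.

    ``tp = round(sens * n_pos / 100)`` (half away from zero), similarly for
    ``tn``; returns ``(tp, fp, fn, tn, ppv, npv)`` with predictive values in
    percent.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group counts must be positive")
    if not (0 <= sens <= 100 and 0 <= spec <= 100):
        raise ValueError("rates must lie in [0, 100]")
    tp = int(math.floor(sens * n_pos / 100.0 + 0.5))
    tn = int(math.floor(spec * n_neg / 100.0 + 0.5))
    fn = n_pos - tp
    fp = n_neg - tn
    if tp + fp == 0 or tn + fn == 0:
        raise DegenerateInputError("predictive value undefined (empty predicted class)")
    ppv = 100.0 * tp / (tp + fp)
    npv = 100.0 * tn / (tn + fn)
    return tp, fp, fn, tn, ppv, npv


def delong_test(
    scores_a,
    scores_b,
    labels,
    direction_a: str = POSITIVE_IF_HIGH,
    direction_b: str = POSITIVE_IF_HIGH,
) -> DelongResult:
    """DeLong comparison of two correlated AUCs measured on the same subjects."""
    pos_a, neg_a = _split(scores_a, labels, direction_a)
    pos_b, neg_b = _split(scores_b, labels, direction_b)
    v10a, v01a, auc_a = _placements(pos_a, neg_a)
    v10b, v01b, auc_b = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var_diff <= 1e-15:
        return DelongResult(auc_a=auc_a, auc_b=auc_b, z=0.0, p_value=1.0, degenerate=True)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return DelongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p_value=float(p))


# ---------------------------------------------------------------------------
# correlation


_RHO_BINS = [(0.20, "negligible"), (0.40, "weak"), (0.60, "moderate"), (0.80, "strong")]


def _rho_category(rho: float) -> str:
    a = abs(rho)
    for edge, name in _RHO_BINS:
        if a < edge:
            return name
    return "very strong"


def spearman_with_ci(x, y) -> CorrResult:
    """Spearman rho with a Fisher-z CI using the variance-inflated standard
    error sqrt((1 + rho^2/2) / (n - 3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input vector")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0:
        ci = (rho, rho)
    else:
        se = math.sqrt((1.0 + rho * rho / 2.0) / (n - 3))
        zr = math.atanh(rho)
        ci = (math.tanh(zr - 1.959963984540054 * se), math.tanh(zr + 1.959963984540054 * se))
    return CorrResult(rho=rho, ci95=ci, p_value=float(p), category=_rho_category(rho), n=n)


# ---------------------------------------------------------------------------
# reliability


def _icc_category(icc: float) -> str:
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def icc_two_way_mixed_absolute(ratings, alpha: float = 0.05) -> IccResult:
    """ICC(A,1): single-measure absolute agreement, two-way mixed model.

    ``ratings`` is an n_subjects x k_raters table with no missing cells.
    The CI follows the F-distribution construction of McGraw & Wong for
    absolute-agreement single measures.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 table")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings table is incomplete (non-finite cells)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise DegenerateInputError("zero total variance in ratings")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        ci = (icc, icc)
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if not np.isfinite(a):
            ci = (icc, icc)
        else:
            num_v = (a * msc + b * mse) ** 2
            den_v = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
            with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
                v = num_v / den_v if den_v > 0 else 1.0
                f_l = sps.f.ppf(1 - alpha / 2, n - 1.0, v)
                f_u = sps.f.ppf(1 - alpha / 2, v, n - 1.0)
                lower = n * (msr - f_l * mse) / (
                    f_l * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                upper = n * (f_u * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f_u * msr
                )
            # ICC ~ 1 with a vanishing error mean square overflows the
            # F-quantile construction; collapse the interval in that case.
            if not (np.isfinite(lower) and np.isfinite(upper)):
                ci = (icc, icc)
            else:
                ci = (float(min(lower, icc)), float(max(upper, icc)))
    return IccResult(icc=float(icc), ci95=ci, category=_icc_category(float(icc)))


# ---------------------------------------------------------------------------
# summaries / group tests


def boxplot_summary(values) -> tuple[float, float, float, float, float]:
    """Five-number summary (min, Q1, median, Q3, max); quartiles use the
    linear-interpolation convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return tuple(float(x) for x in q)


def group_difference_test(values, labels, method: str = "mannwhitney") -> float:
    """Two-sided group-difference p-value (Mann-Whitney by default, optional t-test)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (y.any() and (~y).any()):
        raise DegenerateInputError("both classes must be nonempty")
    a, b = v[y], v[~y]
    if np.all(v == v[0]):
        return 1.0
    if method == "mannwhitney":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if method == "ttest":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown method {method!r}")
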