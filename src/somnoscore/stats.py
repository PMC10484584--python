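"""Diagnostic agreement statistics for index-to-index comparison.

Covers the full evaluation toolbox for comparing a surrogate apnea-hypopnea
index against the polysomnographic reference:

* ICC(A,1) — two-way random effects, absolute agreement, single measurement —
  with the F-distribution confidence interval of McGraw & Wong;
* Bland-Altman bias and 95% limits of agreement with confidence intervals;
* ROC and precision-recall curves with trapezoidal AUC;
* binary diagnostic metrics at a severity cut (accuracy, sensitivity,
  specificity, LR+, LR-, Cohen's kappa) with Wilson continuity-corrected
  intervals for proportions, Simel log-method intervals for likelihood
  ratios, and Cohen's 1960 standard error for kappa;
* four-class severity metrics (accuracy, under-/overestimation fractions,
  off-by-more-than-one count);
* the Benjamini-Yekutieli step-up procedure for FDR control under arbitrary
  dependence; and paired-method significance tests (exact McNemar for
  proportions, subject-level bootstrap for kappa and likelihood ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

SEVERITY_CLASSES = ("None", "Mild", "Moderate", "Severe")
SEVERITY_CUTS = (5.0, 15.0, 30.0)


def severity_class(index: float) -> str:
    """Map an event index (events/h) to a severity class; bins [0,5), [5,15), [15,30), [30,inf)."""
    if index < 0 or not math.isfinite(index):
        raise ValueError(f"index must be a finite non-negative number, got {index}")
    return SEVERITY_CLASSES[int(np.searchsorted(SEVERITY_CUTS, index, side="right"))]


@dataclass
class ConfusionMatrix4:
    """4x4 severity cross-tabulation; rows = predicted class, cols = true class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 4x4 matrix")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_indices(cls, predicted: np.ndarray, true: np.ndarray) -> "ConfusionMatrix4":
        counts = np.zeros((4, 4), dtype=np.int64)
        for p, t in zip(predicted, true):
            counts[SEVERITY_CLASSES.index(severity_class(p)),
                   SEVERITY_CLASSES.index(severity_class(t))] += 1
        return cls(counts)


# ---------------------------------------------------------------------------
# proportions / likelihood ratios / kappa

def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction, clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    z = sps.norm.ppf(0.5 + level / 2.0)
    p = k / n
    q = 1.0 - p
    denom = 2.0 * (n + z * z)
    if k == 0:
        lo = 0.0
    else:
        lo = (2.0 * n * p + z * z - 1.0
              - z * math.sqrt(z * z - 2.0 - 1.0 / n + 4.0 * p * (n * q + 1.0))) / denom
    if k == n:
        hi = 1.0
    else:
        hi = (2.0 * n * p + z * z + 1.0
              + z * math.sqrt(z * z + 2.0 - 1.0 / n + 4.0 * p * (n * q - 1.0))) / denom
    return max(lo, 0.0), min(hi, 1.0)


def lr_ci(sens: float, spec: float, n_pos: int, n_neg: int,
          level: float = 0.95) -> dict:
    """Simel log-method confidence intervals for LR+ and LR-.

    Degenerate cells (sens or spec equal to 0 or 1) yield half-open or
    undefined intervals, flagged with ``inf``/``nan`` bounds rather than a
    continuity correction.
    """
    z = sps.norm.ppf(0.5 + level / 2.0)

    def _interval(num_p, num_n, den_p, den_n):
        # LR = (num_p/num_n) / (den_p/den_n), Simel SE on the log scale
        if num_p == 0:
            return 0.0, (0.0, math.nan)  # point mass at 0, open upper bound
        if den_p == 0:
            return math.inf, (math.nan, math.inf)
        lr = (num_p / num_n) / (den_p / den_n)
        se = math.sqrt((1.0 - num_p / num_n) / num_p + (1.0 - den_p / den_n) / den_p)
        return lr, (lr * math.exp(-z * se), lr * math.exp(z * se))

    k_sens = sens * n_pos
    k_spec = spec * n_neg
    lr_pos, ci_pos = _interval(k_sens, n_pos, n_neg - k_spec, n_neg)
    lr_neg, ci_neg = _interval(n_pos - k_sens, n_pos, k_spec, n_neg)
    return {"lr_pos": lr_pos, "lr_pos_ci": ci_pos,
            "lr_neg": lr_neg, "lr_neg_ci": ci_neg}


def cohen_kappa(counts: np.ndarray, level: float = 0.95) -> dict:
    """Cohen's kappa with the large-sample CI from Cohen's 1960 standard error."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be square")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p = counts / n
    p_o = np.trace(p)
    p_e = float(p.sum(axis=0) @ p.sum(axis=1))
    if p_e >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: expected agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return {"kappa": kappa, "se": se, "ci": (kappa - z * se, kappa + z * se)}


# ---------------------------------------------------------------------------
# agreement

@dataclass
class AgreementReport:
    n: int
    icc: float = math.nan
    icc_ci: tuple[float, float] = (math.nan, math.nan)
    bias: float = math.nan
    bias_ci: tuple[float, float] = (math.nan, math.nan)
    loa_lower: float = math.nan
    loa_lower_ci: tuple[float, float] = (math.nan, math.nan)
    loa_upper: float = math.nan
    loa_upper_ci: tuple[float, float] = (math.nan, math.nan)


def icc_absolute(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> AgreementReport:
    """ICC(A,1): two-way random effects, absolute agreement, single measurement.

    The two raters are the columns; the confidence interval follows
    McGraw & Wong's F-based construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need >= 3 paired measurements")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if abs(denom) < 1e-300:
        raise ValueError("ICC undefined: no variance in either rater")
    icc = (msr - mse) / denom

    alpha = 1.0 - level
    if icc >= 1.0 - 1e-12 or mse == 0:
        ci = (icc, icc)
    else:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
        v = ((a * msc + b * mse) ** 2
             / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
        ci = (lower, upper)
    return AgreementReport(n=n, icc=icc, icc_ci=ci)


def bland_altman(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> AgreementReport:
    """Bias and limits of agreement of the differences ``y - x`` with CIs.

    Bias CI uses the t-based standard error sd/sqrt(n); each limit of
    agreement uses the large-sample standard error sd*sqrt(3/n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need >= 3 paired measurements")
    d = y - x
    bias = d.mean()
    sd = d.std(ddof=1)
    z = sps.norm.ppf(0.5 + level / 2.0)
    t = sps.t.ppf(0.5 + level / 2.0, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    lower, upper = bias - z * sd, bias + z * sd
    return AgreementReport(
        n=n, bias=bias, bias_ci=(bias - t * se_bias, bias + t * se_bias),
        loa_lower=lower, loa_lower_ci=(lower - z * se_loa, lower + z * se_loa),
        loa_upper=upper, loa_upper_ci=(upper - z * se_loa, upper + z * se_loa),
    )


# ---------------------------------------------------------------------------
# curves

@dataclass
class CurveReport:
    kind: str  # "roc" | "pr"
    points: list[tuple[float, float, float]]  # (threshold, x, y)
    auc: float


def roc_pr_curves(scores: np.ndarray, labels: np.ndarray) -> tuple[CurveReport, CurveReport]:
    """ROC (FPR, TPR) and precision-recall curves over all distinct score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[math.inf], np.unique(scores)[::-1]])
    roc_pts, pr_pts = [], []
    for thr in thresholds:
        pred = scores >= thr
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        tpr = tp / n_pos
        fpr = fp / n_neg
        precision = tp / (tp + fp) if tp + fp else 1.0
        roc_pts.append((float(thr), fpr, tpr))
        pr_pts.append((float(thr), tpr, precision))
    fprs = np.array([p[1] for p in roc_pts])
    tprs = np.array([p[2] for p in roc_pts])
    roc_auc = float(np.trapezoid(tprs, fprs))
    recalls = np.array([p[1] for p in pr_pts])
    precisions = np.array([p[2] for p in pr_pts])
    pr_auc = float(np.trapezoid(precisions, recalls))
    return (CurveReport("roc", roc_pts, roc_auc), CurveReport("pr", pr_pts, pr_auc))


# ---------------------------------------------------------------------------
# classification metrics

@dataclass
class BinaryMetrics:
    cut: float
    n_pos: int
    n_neg: int
    prevalence: float
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    lr_pos: float
    lr_pos_ci: tuple[float, float]
    lr_neg: float
    lr_neg_ci: tuple[float, float]
    kappa: float
    kappa_ci: tuple[float, float]


def binarize(cm: ConfusionMatrix4, cut: float) -> np.ndarray:
    """Collapse the 4x4 table to 2x2 at a severity cut (rows/cols: neg, pos)."""
    if cut not in SEVERITY_CUTS:
        raise ValueError(f"cut must be one of {SEVERITY_CUTS}")
    j = SEVERITY_CUTS.index(cut) + 1
    c = cm.counts
    return np.array([
        [c[:j, :j].sum(), c[:j, j:].sum()],
        [c[j:, :j].sum(), c[j:, j:].sum()],
    ], dtype=np.int64)


def binary_metrics(cm: ConfusionMatrix4, cut: float, level: float = 0.95) -> BinaryMetrics:
    """All binary diagnostic metrics at a severity cut, with CIs."""
    b = binarize(cm, cut)
    n = b.sum()
    n_pos = int(b[:, 1].sum())
    n_neg = int(b[:, 0].sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("empty class after binarization: metrics undefined")
    tp, tn = int(b[1, 1]), int(b[0, 0])
    sens = tp / n_pos
    spec = tn / n_neg
    acc_k = tp + tn
    lrs = lr_ci(sens, spec, n_pos, n_neg, level)
    kap = cohen_kappa(b, level)
    return BinaryMetrics(
        cut=cut, n_pos=n_pos, n_neg=n_neg, prevalence=n_pos / n,
        accuracy=acc_k / n, accuracy_ci=wilson_ci(acc_k, int(n), level),
        sensitivity=sens, sensitivity_ci=wilson_ci(tp, n_pos, level),
        specificity=spec, specificity_ci=wilson_ci(tn, n_neg, level),
        lr_pos=lrs["lr_pos"], lr_pos_ci=lrs["lr_pos_ci"],
        lr_neg=lrs["lr_neg"], lr_neg_ci=lrs["lr_neg_ci"],
        kappa=kap["kappa"], kappa_ci=kap["ci"],
    )


@dataclass
class FourClassMetrics:
    n: int
    accuracy: float
    accuracy_ci: tuple[float, float]
    underestimated: float
    underestimated_ci: tuple[float, float]
    overestimated: float
    overestimated_ci: tuple[float, float]
    kappa: float
    kappa_ci: tuple[float, float]
    off_by_more_than_one: int


def fourclass_metrics(cm: ConfusionMatrix4, level: float = 0.95) -> FourClassMetrics:
    """Four-class severity metrics.

    With rows = predicted and columns = true class, cells above the diagonal
    (col > row) are underestimations and cells below are overestimations.
    """
    c = cm.counts
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    correct = int(np.trace(c))
    under = int(np.triu(c, k=1).sum())
    over = int(np.tril(c, k=-1).sum())
    rows, cols = np.indices(c.shape)
    off = int(c[np.abs(rows - cols) >= 2].sum())
    kap = cohen_kappa(c, level)
    return FourClassMetrics(
        n=n,
        accuracy=correct / n, accuracy_ci=wilson_ci(correct, n, level),
        underestimated=under / n, underestimated_ci=wilson_ci(under, n, level),
        overestimated=over / n, overestimated_ci=wilson_ci(over, n, level),
        kappa=kap["kappa"], kappa_ci=kap["ci"],
        off_by_more_than_one=off,
    )


# ---------------------------------------------------------------------------
# multiplicity

@dataclass
class MultiTestReport:
    family: str
    pvalues: list[float]
    alpha: float
    threshold: float
    significant: list[bool]


def benjamini_yekutieli(pvals, alpha: float = 0.05, family: str = "") -> MultiTestReport:
    """Benjamini-Yekutieli step-up FDR control under arbitrary dependence.

    Sorted p-values p(k) are compared against k*alpha/(m*c(m)) with
    c(m) = sum_{i<=m} 1/i; the critical threshold is the bound at the largest
    admissible k (or the k=1 bound when nothing is rejected).
    """
    pvals = [float(p) for p in pvals]
    if not pvals:
        raise ValueError("empty p-value list")
    if any(not 0 <= p <= 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    bounds = np.arange(1, m + 1) * alpha / (m * c_m)
    admissible = np.flatnonzero(sorted_p <= bounds)
    k_star = int(admissible[-1]) + 1 if admissible.size else 0
    threshold = (k_star if k_star else 1) * alpha / (m * c_m)
    significant = [p <= threshold if k_star else False for p in pvals]
    return MultiTestReport(family=family, pvalues=pvals, alpha=alpha,
                           threshold=threshold, significant=significant)


# ---------------------------------------------------------------------------
# paired-method comparison

def mcnemar_exact(n01: int, n10: int) -> float:
    """Exact two-sided McNemar p-value from the discordant counts."""
    n = n01 + n10
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * sps.binom.cdf(min(n01, n10), n, 0.5))


def compare_paired(a_correct, b_correct=None, *, kind: str = "proportion",
                   stat=None, a_pred=None, b_pred=None, truth=None,
                   n_boot: int = 10000, seed: int = 0) -> float:
    """Two-sided p-value for a paired method comparison.

    ``kind="proportion"``: exact McNemar on per-subject correctness vectors
    ``a_correct``/``b_correct``. Other kinds use a seeded subject-level
    bootstrap of ``stat(pred, truth)`` applied to ``a_pred``/``b_pred``.
    """
    if kind == "proportion":
        a = np.asarray(a_correct, dtype=bool)
        b = np.asarray(b_correct, dtype=bool)
        return mcnemar_exact(int((~a & b).sum()), int((a & ~b).sum()))
    if stat is None or a_pred is None or b_pred is None or truth is None:
        raise ValueError("bootstrap comparison needs stat, a_pred, b_pred, truth")
    a_pred = np.asarray(a_pred)
    b_pred = np.asarray(b_pred)
    truth = np.asarray(truth)
    n = truth.size
    rng = np.random.default_rng(seed)
    observed = stat(a_pred, truth) - stat(b_pred, truth)
    count = 0
    total = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            diff = stat(a_pred[idx], truth[idx]) - stat(b_pred[idx], truth[idx])
        except (ValueError, ZeroDivisionError):
            continue
        total += 1
        # center the bootstrap distribution at the observed difference and
        # test the null of zero difference (shift method)
        if abs(diff - observed) >= abs(observed):
            count += 1
    if total == 0:
        return 1.0
    return min(1.0, (count + 1) / (total + 1))
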