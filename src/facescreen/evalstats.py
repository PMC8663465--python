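"""ROC/Youden evaluation, classification metrics, covariate correlations and
the repeated-measures ANOVA sample-size calculation.

The screening models are judged by their ROC curve: the area under it
(equal to the probability that a random patient scores above a random
control, ties half-weighted) and the Youden index J = max(TPR - FPR), whose
argmax defines the operating threshold at which accuracy, precision, recall
and F-measure are reported.  Pearson correlations between facial features
(or model scores) and clinical covariates carry Fisher-z 95% confidence
intervals.  The power calculation inverts the noncentral-F power function
of a between-groups repeated-measures ANOVA to find the smallest balanced
sample size reaching a target power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import UndefinedCorrelationError


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray  # decreasing; a score >= threshold predicts patient
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_j: float
    youden_threshold: float


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float | None  # None when tp + fp = 0 (flagged undefined)
    recall: float
    f_measure: float | None


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    undefined: bool = False


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the repeated-measures ANOVA power calculation.

    ``f_effect`` is Cohen's f for the between-groups factor; ``m`` repeated
    measurements with pairwise correlation ``rho`` shrink the error term by
    the multiplier m / (1 + (m-1) rho).
    """

    f_effect: float
    alpha: float = 0.05
    power: float = 0.95
    k_groups: int = 2
    m_measurements: int = 1
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.alpha < self.power < 1:
            raise ValueError("power must lie in (alpha, 1)")
        if self.k_groups < 2 or self.m_measurements < 1:
            raise ValueError("need k >= 2 groups and m >= 1 measurements")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> RocResult:
    """ROC curve over every distinct score threshold, trapezoidal AUC, and
    the Youden-optimal threshold.

    With tied scores the curve steps through the tie jointly, so the
    trapezoid rule reproduces the pairwise concordance probability with
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC analysis needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    threshold, j = _youden(scores, tpr, fpr, thr)
    return RocResult(thr, tpr, fpr, auc, j, threshold)


def _youden(scores, tpr, fpr, thr) -> tuple[float, float]:
    j = tpr - fpr
    best = j.max()
    # among maximizers prefer the highest TPR
    candidates = np.flatnonzero(j >= best - 1e-12)
    idx = candidates[np.argmax(tpr[candidates])]
    cut = thr[idx]
    uniq = np.unique(scores)
    if not np.isfinite(cut):  # classify-nothing endpoint
        threshold = float(uniq[-1] + 1.0)
    else:
        below = uniq[uniq < cut]
        threshold = float((cut + below[-1]) / 2.0) if below.size else float(cut)
    return threshold, float(best)


def youden_threshold(roc: RocResult) -> tuple[float, float]:
    """(threshold, J) already computed alongside the ROC sweep."""
    return roc.youden_threshold, roc.youden_j


def classification_metrics(labels, predictions) -> ClassificationMetrics:
    """Confusion-matrix rates; precision (and hence F) is flagged undefined
    when nothing is predicted positive."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else None
    if precision is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(tp, fp, fn, tn, accuracy, precision, recall,
                                 f_measure)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson_ci(x, y, alpha: float = 0.05, variable: str = "") -> CorrelationResult:
    """Pearson r with two-sided t-test p-value and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise UndefinedCorrelationError(
            f"correlation undefined for zero-variance input {variable!r}"
        )
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if n > 3 and abs(r) < 1:
        z = sps.norm.ppf(1 - alpha / 2)
        zr = math.atanh(r)
        lo, hi = math.tanh(zr - z / math.sqrt(n - 3)), math.tanh(zr + z / math.sqrt(n - 3))
    else:
        lo, hi = -1.0, 1.0
    return CorrelationResult(variable, r, float(res.pvalue), lo, hi, n)


def correlate_with_covariates(values, covariate_table: pd.DataFrame,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Correlate a per-subject quantity (feature or model score) with every
    covariate column, one row per covariate in the clinical-table layout
    (variable, p, r, CI).  Rows are expected to be the patient group only.
    Constant covariates yield a flagged row rather than an error."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(covariate_table):
        raise ValueError("values and covariate table differ in length")
    rows = []
    for col in covariate_table.columns:
        y = covariate_table[col].to_numpy(dtype=float)
        try:
            res = pearson_ci(values, y, alpha=alpha, variable=col)
        except UndefinedCorrelationError:
            res = CorrelationResult(col, float("nan"), float("nan"),
                                    float("nan"), float("nan"), len(values),
                                    undefined=True)
        rows.append({"variable": res.variable, "p_value": res.p_value,
                     "r": res.r, "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "n": res.n, "undefined": res.undefined})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample size for the between-groups repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_power(spec: PowerSpec, n_total: int) -> float:
    """Power of the between-groups test at a given balanced total N.

    Noncentrality lambda = f^2 * N * m / (1 + (m-1) rho), tested against
    F(k-1, N-k) at level alpha (the G*Power convention for 'ANOVA: repeated
    measures, between factors').
    """
    k, m, rho = spec.k_groups, spec.m_measurements, spec.rho
    if n_total <= k:
        return 0.0
    lam = spec.f_effect ** 2 * n_total * m / (1.0 + (m - 1) * rho)
    df1, df2 = k - 1, n_total - k
    fcrit = sps.f.isf(spec.alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def rm_anova_sample_size(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest balanced total N (a multiple of k) reaching the target power."""
    if spec.f_effect <= 0:
        raise ValueError("target power unreachable with zero effect size")
    n = 2 * spec.k_groups
    while n <= n_max:
        if rm_anova_power(spec, n) >= spec.power:
            return n
        n += spec.k_groups
    raise ValueError(f"power {spec.power} not reached by N = {n_max}")
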