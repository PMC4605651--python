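"""Cohort-level statistics of ABS levels against clinical metadata.

Covers the statistics a transplant-monitoring analysis needs: Pearson
correlation with drug trough levels (Fisher r-to-z confidence interval),
one-sided Mann-Whitney U comparisons between rejection groups, the
c-statistic (ROC area) with a percentile-bootstrap interval, threshold
diagnostic metrics with continuity-corrected Wilson score intervals, and a
single-exponential trend fit for pre-/post-rejection ABS dynamics.

No multiple-testing correction is applied: the handful of group comparisons
is reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_auc_score, roc_curve

BIOPSY_GRADES = ("0", "1R", "2R", "3R", "NA")

#: rejection category labels
CAT_NONE = "none"
CAT_MILD = "mild_ACR"
CAT_MODSEV = "mod_severe_ACR"
CAT_CFDDNA = "elevated_cfdDNA"


class Unclassifiable(ValueError):
    """Neither a biopsy grade nor a cfdDNA value is available."""


def classify_rejection(
    biopsy_grade: Optional[str],
    cfddna_pct: Optional[float],
    cfddna_threshold: float = 1.0,
) -> FrozenSet[str]:
    """Rejection categories applicable to one sample (labels may overlap).

    Biopsy-based: grade 1R -> mild ACR, grade >= 2R -> moderate-to-severe
    ACR. cfdDNA-based: donor fraction above ``cfddna_threshold`` percent ->
    elevated cfdDNA. Biopsy and cfdDNA are independent assays, so a sample
    can carry both labels. A sample with at least one informative field and
    no rejection signal is labelled ``none``.
    """
    grade = None if biopsy_grade in (None, "", "NA") else str(biopsy_grade)
    has_cfddna = cfddna_pct is not None and not (
        isinstance(cfddna_pct, float) and math.isnan(cfddna_pct)
    )
    if grade is None and not has_cfddna:
        raise Unclassifiable("sample has neither biopsy grade nor cfdDNA fraction")
    if grade is not None and grade not in BIOPSY_GRADES:
        raise ValueError(f"unknown biopsy grade {grade!r}")
    labels = set()
    if grade == "1R":
        labels.add(CAT_MILD)
    elif grade in ("2R", "3R"):
        labels.add(CAT_MODSEV)
    if has_cfddna and cfddna_pct > cfddna_threshold:
        labels.add(CAT_CFDDNA)
    if not labels:
        labels.add(CAT_NONE)
    return frozenset(labels)


def pearson_with_fisher_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> Tuple[float, float, float]:
    """Pearson r with the Fisher r-to-z confidence interval.

    CI = tanh(atanh(r) ± z_{1-α/2} / sqrt(n-3)). For |r| = 1 the interval
    degenerates to the point estimate (atanh diverges).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return r, r, r
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z / math.sqrt(x.size - 3)
    lo = math.tanh(math.atanh(r) - half)
    hi = math.tanh(math.atanh(r) + half)
    return r, lo, hi


def mann_whitney_one_sided(
    a: Sequence[float], b: Sequence[float]
) -> Tuple[float, float]:
    """One-sided Mann-Whitney U test of ``a`` stochastically greater than ``b``.

    U is the rank-sum statistic for ``a`` with midrank tie handling. The
    p-value uses the exact null distribution when the groups are small
    (n_a*n_b <= 400) and tie-free, and the tie-corrected normal approximation
    (with continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (a.size * b.size <= 400) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="greater", method="exact" if use_exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def roc_c_statistic(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
) -> Tuple[float, float, float, pd.DataFrame]:
    """c-statistic (ROC area) with a percentile-bootstrap 95% interval.

    The c-statistic is the probability that a random positive sample scores
    above a random negative one, with half credit for ties. The bootstrap
    resamples samples with replacement; resamples that lose one of the
    classes are redrawn. Also returns the ROC points over all distinct
    thresholds (threshold, fpr, tpr).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = scores.size
    filled = 0
    attempts = 0
    while filled < n_boot and attempts < 50 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.all() or (~lab).all():
            continue
        boots[filled] = roc_auc_score(lab, scores[idx])
        filled += 1
    if filled < n_boot:
        raise RuntimeError("bootstrap could not draw two-class resamples")
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, float(lo), float(hi), points


def wilson_cc_interval(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Newcombe's efficient-score formulation; bounds are clamped to [0, 1],
    with lo = 0 at k = 0 and hi = 1 at k = n.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    if k == 0:
        lo = 0.0
    else:
        lo = (
            2 * n * p
            + z * z
            - 1.0
            - z * math.sqrt(z * z - 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) + 1.0))
        ) / (2.0 * (n + z * z))
    if k == n:
        hi = 1.0
    else:
        hi = (
            2 * n * p
            + z * z
            + 1.0
            + z * math.sqrt(z * z + 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) - 1.0))
        ) / (2.0 * (n + z * z))
    return max(0.0, lo), min(1.0, hi)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """2x2-table metrics at a fixed score threshold, with 95% intervals.

    PPV/NPV are ``None`` when the corresponding margin of the table is zero
    (no positive or no negative calls).
    """

    threshold: float
    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    ppv: Optional[float]
    ppv_ci: Optional[Tuple[float, float]]
    npv: Optional[float]
    npv_ci: Optional[Tuple[float, float]]
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv,
            "ppv_ci": None if self.ppv_ci is None else list(self.ppv_ci),
            "npv": self.npv,
            "npv_ci": None if self.npv_ci is None else list(self.npv_ci),
            "table": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


def binary_metrics_at_threshold(
    scores: Sequence[float],
    labels: Sequence[bool],
    threshold: float = 0.023,
    alpha: float = 0.05,
) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV calling positive at score >= threshold.

    Each point estimate gets a continuity-corrected Wilson interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    calls = scores >= threshold
    tp = int((calls & labels).sum())
    fp = int((calls & ~labels).sum())
    tn = int((~calls & ~labels).sum())
    fn = int((~calls & labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    return DiagnosticMetrics(
        threshold=float(threshold),
        sensitivity=sens,
        sensitivity_ci=wilson_cc_interval(tp, tp + fn, alpha),
        specificity=spec,
        specificity_ci=wilson_cc_interval(tn, tn + fp, alpha),
        ppv=ppv,
        ppv_ci=None if ppv is None else wilson_cc_interval(tp, tp + fp, alpha),
        npv=npv,
        npv_ci=None if npv is None else wilson_cc_interval(tn, tn + fn, alpha),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of y = a * exp(b * t)."""

    a: float
    b: float
    rss: float
    n: int

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("amplitude a must be positive")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(t, dtype=float))


def fit_exponential_trend(
    times: Sequence[float], values: Sequence[float]
) -> ExponentialFit:
    """Nonlinear least squares for y = a*exp(b*t), log-linear initialised.

    Times are in days; ``b`` is a per-day rate. Values must be positive
    (the log-linear initialisation requires it).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 points")
    if (y <= 0).any():
        raise ValueError("values must be positive")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    p0 = (math.exp(intercept), slope)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, b: a * np.exp(b * tt), t, y, p0=p0, maxfev=10000
        )
    except RuntimeError as err:
        raise RuntimeError(f"exponential fit did not converge: {err}") from err
    a, b = float(popt[0]), float(popt[1])
    rss = float(((y - a * np.exp(b * t)) ** 2).sum())
    return ExponentialFit(a=a, b=b, rss=rss, n=int(t.size))
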