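"""Metrics and statistical tests for system evaluation and comparison.

Per-label precision/recall/F1 and error rates from multiclass confusion
matrices; bootstrap percentile confidence intervals; one-sample t tests
against a fixed baseline; Cohen's kappa and the multiclass Matthews
correlation coefficient; the exact (binomial) McNemar test on paired
correctness; and a sign-flip permutation test on the accuracy difference.
All stochastic procedures are bit-reproducible given a seed.

Two sidedness conventions ship for McNemar because printed clinical-NLP
comparisons mix them: the default two-sided p is min(1, 2 * min-tail);
a one-sided mode reports the min tail alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Confusion matrix and derived metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    labels: list[str]
    matrix: np.ndarray  # gold rows x predicted columns

    @classmethod
    def from_pairs(
        cls, gold: Sequence, pred: Sequence, labels: Sequence | None = None
    ) -> "ConfusionMatrix":
        if len(gold) != len(pred):
            raise ValueError("gold and pred must have equal length")
        if labels is None:
            labels = sorted(set(gold) | set(pred))
        labels = [str(l) for l in labels]
        idx = {l: i for i, l in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=int)
        for g, p in zip(gold, pred):
            m[idx[str(g)], idx[str(p)]] += 1
        return cls(labels, m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.matrix)) / self.total

    def support(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def render(self) -> str:
        """Plain-text rendering, gold rows x predicted columns."""
        width = max(len(l) for l in self.labels) + 2
        head = " " * width + "".join(f"{l:>{width}}" for l in self.labels)
        rows = [
            f"{l:>{width}}" + "".join(f"{v:>{width}d}" for v in row)
            for l, row in zip(self.labels, self.matrix)
        ]
        return "\n".join([head, *rows])


@dataclass
class PRFReport:
    labels: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    macro_precision: float
    macro_recall: float
    macro_f1: float


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def prf(cm: ConfusionMatrix) -> PRFReport:
    """Per-label P/R/F1 plus unweighted macro averages.

    A zero denominator (no predicted or no gold instances of a label)
    yields 0 for that metric, with a warning.
    """
    m = cm.matrix
    tp = np.diag(m).astype(float)
    pred_sum = m.sum(axis=0).astype(float)
    gold_sum = m.sum(axis=1).astype(float)
    if np.any(pred_sum == 0) or np.any(gold_sum == 0):
        warnings.warn("label with zero predicted or gold instances; metric set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_sum > 0, tp / pred_sum, 0.0)
        recall = np.where(gold_sum > 0, tp / gold_sum, 0.0)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    return PRFReport(
        labels=list(cm.labels),
        precision=dict(zip(cm.labels, precision.tolist())),
        recall=dict(zip(cm.labels, recall.tolist())),
        f1=dict(zip(cm.labels, f1.tolist())),
        support=dict(zip(cm.labels, m.sum(axis=1).tolist())),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def error_rates(cm: ConfusionMatrix) -> dict[str, dict]:
    """Per-label absolute error (off-diagonal gold-row mass) and relative
    error (absolute / gold support; None when support is zero)."""
    out: dict[str, dict] = {}
    for i, label in enumerate(cm.labels):
        support = int(cm.matrix[i].sum())
        absolute = int(support - cm.matrix[i, i])
        relative = absolute / support if support > 0 else None
        out[label] = {"absolute": absolute, "relative": relative, "support": support}
    return out


# ---------------------------------------------------------------------------
# Resampling and tests
# ---------------------------------------------------------------------------

def bootstrap_ci(
    scores: Sequence[float] | np.ndarray,
    metric: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of *metric* over resampled units.

    Units are whatever the scores are per (reports for tagging metrics,
    mentions for coding metrics).  A resample on which the metric is
    undefined (raises or returns NaN) is redrawn, counted, and warned about.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 units to bootstrap")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    redraws = 0
    i = 0
    while i < n_boot:
        sample = scores[rng.integers(0, scores.size, scores.size)]
        try:
            value = float(metric(sample))
        except (ValueError, ZeroDivisionError):
            value = np.nan
        if np.isnan(value):
            redraws += 1
            if redraws > 10 * n_boot:
                raise ValueError("metric undefined on almost all resamples")
            continue
        estimates[i] = value
        i += 1
    if redraws:
        warnings.warn(f"{redraws} resamples redrawn (metric undefined)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def one_sample_t(values: Sequence[float], mu0: float = 0.5) -> tuple[float, float]:
    """Two-sided one-sample t test of the mean against *mu0*."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(values, ddof=1))
    if sd <= 1e-12 * max(1.0, float(np.abs(values).max())):
        raise ValueError("degenerate sample: zero standard deviation")
    result = stats.ttest_1samp(values, mu0)
    return float(result.statistic), float(result.pvalue)


def cohen_kappa(gold: Sequence, pred: Sequence) -> float:
    """Chance-corrected multiclass agreement (p_o - p_e) / (1 - p_e)."""
    cm = ConfusionMatrix.from_pairs(gold, pred)
    n = cm.total
    p_o = np.trace(cm.matrix) / n
    marg_gold = cm.matrix.sum(axis=1) / n
    marg_pred = cm.matrix.sum(axis=0) / n
    p_e = float(np.dot(marg_gold, marg_pred))
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def mcc(gold: Sequence, pred: Sequence) -> float:
    """Generalized multiclass Matthews correlation (covariance form).

    Returns 0 with a warning when a marginal has zero variance (all gold or
    all predictions in one class).
    """
    cm = ConfusionMatrix.from_pairs(gold, pred)
    m = cm.matrix.astype(float)
    s = m.sum()
    c = np.trace(m)
    t = m.sum(axis=1)  # gold marginal
    p = m.sum(axis=0)  # predicted marginal
    cov_gp = c * s - float(t @ p)
    cov_gg = s**2 - float(t @ t)
    cov_pp = s**2 - float(p @ p)
    if cov_gg == 0 or cov_pp == 0:
        warnings.warn("zero-variance marginal; MCC reported as 0 by convention")
        return 0.0
    return float(cov_gp / np.sqrt(cov_gg * cov_pp))


def mcnemar_exact(
    a_correct: Sequence[bool], b_correct: Sequence[bool], alternative: str = "two-sided"
) -> tuple[int, int, float]:
    """Exact McNemar test on paired correctness vectors.

    Returns (b, c, p) where b counts items only system A got right and c
    counts items only system B got right.  The exact binomial reference is
    Binomial(b + c, 1/2); two-sided p = min(1, 2 * min-tail), one-sided
    p = min-tail.  No discordant pairs yields p = 1 with a warning.
    """
    a = np.asarray(a_correct, dtype=bool)
    b_vec = np.asarray(b_correct, dtype=bool)
    if a.shape != b_vec.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(a & ~b_vec))
    c = int(np.sum(~a & b_vec))
    n = b + c
    if n == 0:
        warnings.warn("no discordant pairs; p = 1")
        return b, c, 1.0
    min_tail = float(stats.binom.cdf(min(b, c), n, 0.5))
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min_tail)
    elif alternative == "one-sided":
        p = min_tail
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return b, c, p


def permutation_test(
    a_correct: Sequence[bool],
    b_correct: Sequence[bool],
    n_perm: int = 10_000,
    seed: int = 0,
    smoothed: bool = False,
) -> float:
    """Sign-flip permutation test on the accuracy difference.

    Under the null the A/B outcomes of each item are exchangeable, so each
    item's (a_i - b_i) difference has its sign flipped independently with
    probability 1/2.  p is the raw proportion of permuted |differences| at
    least the observed |difference| (add-one smoothing by flag).
    """
    a = np.asarray(a_correct, dtype=float)
    b = np.asarray(b_correct, dtype=float)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must have equal length")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p estimate is coarse")
    d = a - b
    observed = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = np.abs((signs * d).mean(axis=1))
    hits = int(np.sum(null >= observed - 1e-12))
    if smoothed:
        return (hits + 1) / (n_perm + 1)
    return hits / n_perm


# ---------------------------------------------------------------------------
# System-level reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Metrics for one system's predictions against gold labels."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    kappa: float
    mcc: float
    per_label: PRFReport
    n: int


def evaluate_predictions(gold: Sequence, pred: Sequence) -> EvalReport:
    cm = ConfusionMatrix.from_pairs(gold, pred)
    report = prf(cm)
    return EvalReport(
        accuracy=cm.accuracy(),
        macro_precision=report.macro_precision,
        macro_recall=report.macro_recall,
        macro_f1=report.macro_f1,
        kappa=cohen_kappa(gold, pred),
        mcc=mcc(gold, pred),
        per_label=report,
        n=len(gold),
    )


@dataclass
class ComparisonReport:
    """Paired comparison of two systems on the same gold labels."""

    accuracy_a: float
    accuracy_b: float
    accuracy_difference: float  # |acc_a - acc_b|
    mcnemar_b: int
    mcnemar_c: int
    mcnemar_p: float
    mcnemar_p_one_sided: float
    permutation_p: float
    kappa_a: float
    kappa_b: float
    mcc_a: float
    mcc_b: float
    n: int

    def formatted(self) -> dict[str, float]:
        """Coding-table convention: 4 decimals."""
        return {
            "accuracy_a": round(self.accuracy_a, 4),
            "accuracy_b": round(self.accuracy_b, 4),
            "accuracy_difference": round(self.accuracy_difference, 4),
            "mcnemar_p": round(self.mcnemar_p, 4),
            "mcnemar_p_one_sided": round(self.mcnemar_p_one_sided, 4),
            "permutation_p": round(self.permutation_p, 4),
        }


def compare_systems(
    gold: Sequence,
    preds_a: Sequence,
    preds_b: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ComparisonReport:
    if not (len(gold) == len(preds_a) == len(preds_b)):
        raise ValueError("gold and both prediction lists must align")
    a_correct = np.asarray([p == g for p, g in zip(preds_a, gold)])
    b_correct = np.asarray([p == g for p, g in zip(preds_b, gold)])
    acc_a = float(a_correct.mean())
    acc_b = float(b_correct.mean())
    b, c, p_two = mcnemar_exact(a_correct, b_correct, "two-sided")
    _, _, p_one = mcnemar_exact(a_correct, b_correct, "one-sided")
    perm_p = permutation_test(a_correct, b_correct, n_perm=n_perm, seed=seed)
    return ComparisonReport(
        accuracy_a=acc_a,
        accuracy_b=acc_b,
        accuracy_difference=abs(acc_a - acc_b),
        mcnemar_b=b,
        mcnemar_c=c,
        mcnemar_p=p_two,
        mcnemar_p_one_sided=p_one,
        permutation_p=perm_p,
        kappa_a=cohen_kappa(gold, preds_a),
        kappa_b=cohen_kappa(gold, preds_b),
        mcc_a=mcc(gold, preds_a),
        mcc_b=mcc(gold, preds_b),
        n=len(gold),
    )
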