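"""Diagnostic-test evaluation statistics.

Confusion matrices per property, recall/specificity/precision/prevalence with
exact Clopper–Pearson 95% intervals, the Haldane–Anscombe zero-cell
correction, inverse-variance-weighted pooling across validation sets, Cohen's
kappa for inter-annotator agreement, and back-derivation of a confusion
matrix from printed summary statistics (n, prevalence, recall, precision).

Conventions
-----------
* Proportions are handled on [0, 1]; ``*_pct`` arguments are percentages.
* A metric with a zero denominator is *undefined* (``None``), never 0.
* After Haldane–Anscombe correction cell counts are half-integers; every
  downstream formula accepts floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "Proportion",
    "Metrics",
    "WeightedSummary",
    "AgreementResult",
    "clopper_pearson",
    "confusion",
    "metrics_from_matrix",
    "haldane_anscombe",
    "pool_inverse_variance",
    "cohen_kappa",
    "reconstruct_matrix",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN cells for one property on one validation set."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative cell {name}")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.tp, self.fp, self.fn, self.tn)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.tp, self.fp, self.fn, self.tn)


class Proportion(NamedTuple):
    """A point estimate with its 95% confidence interval."""

    point: float
    lower: float
    upper: float


@dataclass(frozen=True)
class Metrics:
    """Recall (Se), specificity (Sp), precision (PPV) and actual prevalence.

    ``None`` marks a metric whose denominator was zero (undefined)."""

    recall: Optional[Proportion]
    specificity: Optional[Proportion]
    precision: Optional[Proportion]
    actual_prevalence: Optional[Proportion]


@dataclass(frozen=True)
class WeightedSummary:
    pooled: float
    lower: float
    upper: float
    weights: tuple[float, ...]
    standard_errors: tuple[float, ...]


@dataclass(frozen=True)
class AgreementResult:
    """Percent agreement, chance agreement and Cohen's kappa.

    ``n_pos_1``/``n_pos_2`` are each annotator's positive counts (the N
    values reported alongside inter-rater tables); ``table`` is the 2x2
    agreement table (both-pos, 1-only, 2-only, both-neg)."""

    po: float
    pe: float
    kappa: Optional[float]
    n_pos_1: int
    n_pos_2: int
    table: tuple[int, int, int, int]


def clopper_pearson(x: float, n: float, alpha: float = 0.05) -> Proportion:
    """Exact binomial CI from beta quantiles.

    Accepts non-integer counts so Haldane–Anscombe-corrected cells can be
    used directly. At ``x == n`` the lower bound reduces to the closed form
    ``(alpha/2)**(1/n)``; at ``x == 0`` the upper bound is
    ``1 - (alpha/2)**(1/n)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return Proportion(x / n, lower, upper)


def confusion(gold: Sequence[bool], predicted: Sequence[bool]) -> ConfusionMatrix:
    """Cell counts from aligned gold and predicted boolean vectors."""
    g = np.asarray(gold, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if g.shape != p.shape:
        raise ValueError(f"length mismatch: gold {g.shape} vs predicted {p.shape}")
    if g.size == 0:
        raise ValueError("empty vectors")
    return ConfusionMatrix(
        tp=int(np.sum(g & p)),
        fp=int(np.sum(~g & p)),
        fn=int(np.sum(g & ~p)),
        tn=int(np.sum(~g & ~p)),
    )


def metrics_from_matrix(m: ConfusionMatrix, alpha: float = 0.05) -> Metrics:
    """Recall, specificity, precision and actual prevalence with exact CIs.

    recall = tp/(tp+fn); specificity = tn/(tn+fp); precision = tp/(tp+fp);
    actual prevalence = (tp+fn)/n — the reference-standard positive fraction.
    """
    if m.n <= 0:
        raise ValueError("empty confusion matrix")

    def prop(x: float, denom: float) -> Optional[Proportion]:
        if denom <= 0:
            return None
        return clopper_pearson(x, denom, alpha)

    return Metrics(
        recall=prop(m.tp, m.tp + m.fn),
        specificity=prop(m.tn, m.tn + m.fp),
        precision=prop(m.tp, m.tp + m.fp),
        actual_prevalence=prop(m.tp + m.fn, m.n),
    )


def haldane_anscombe(m: ConfusionMatrix) -> ConfusionMatrix:
    """Add 0.5 to every cell if any cell is zero; otherwise return unchanged."""
    if not m.has_zero_cell:
        return m
    return ConfusionMatrix(m.tp + 0.5, m.fp + 0.5, m.fn + 0.5, m.tn + 0.5)


#: Weight assigned to an estimate whose standard error is exactly zero even
#: after correction (p of 0 or 1 on its own denominator).
MAX_WEIGHT = 1e12


def pool_inverse_variance(
    estimates: Sequence[tuple[float, float, float]], z: float = 1.96
) -> WeightedSummary:
    """Inverse-variance-weighted mean of binomial proportions.

    Each estimate is ``(p, x, n)`` with ``p`` the proportion and ``n`` the
    metric's own denominator (pass Haldane–Anscombe-corrected values when the
    source matrix contained zeros). ``SE_i = sqrt(p_i(1-p_i)/n_i)``,
    ``w_i = 1/SE_i^2``, pooled = sum(w_i p_i)/sum(w_i), CI = pooled ±
    z*sqrt(1/sum(w_i)), truncated to [0, 1]. A zero SE gets weight
    :data:`MAX_WEIGHT`.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two estimates to pool")
    ses, weights, ps = [], [], []
    for p, _x, n in estimates:
        if n <= 0:
            raise ValueError("estimate denominator must be positive")
        if not 0 <= p <= 1:
            raise ValueError("proportion outside [0, 1]")
        se = math.sqrt(p * (1 - p) / n)
        ses.append(se)
        weights.append(1.0 / se**2 if se > 0 else MAX_WEIGHT)
        ps.append(p)
    wsum = sum(weights)
    pooled = sum(w * p for w, p in zip(weights, ps)) / wsum
    half = z * math.sqrt(1.0 / wsum)
    return WeightedSummary(
        pooled=pooled,
        lower=max(0.0, pooled - half),
        upper=min(1.0, pooled + half),
        weights=tuple(weights),
        standard_errors=tuple(ses),
    )


def cohen_kappa(ann1: Sequence[bool], ann2: Sequence[bool]) -> AgreementResult:
    """Cohen's kappa for two annotators' boolean labels.

    ``po`` is the fraction of identical labels, ``pe`` the chance agreement
    from the marginal positive rates, ``kappa = (po - pe)/(1 - pe)``;
    ``kappa`` is ``None`` when ``pe == 1`` (both annotators constant and
    identical).
    """
    a1 = np.asarray(ann1, dtype=bool)
    a2 = np.asarray(ann2, dtype=bool)
    if a1.shape != a2.shape:
        raise ValueError("length mismatch")
    n = a1.size
    if n == 0:
        raise ValueError("empty vectors")
    a = int(np.sum(a1 & a2))
    b = int(np.sum(a1 & ~a2))
    c = int(np.sum(~a1 & a2))
    d = int(np.sum(~a1 & ~a2))
    po = (a + d) / n
    p1, p2 = (a + b) / n, (a + c) / n
    pe = p1 * p2 + (1 - p1) * (1 - p2)
    kappa = None if pe == 1 else (po - pe) / (1 - pe)
    return AgreementResult(
        po=po, pe=pe, kappa=kappa, n_pos_1=a + b, n_pos_2=a + c, table=(a, b, c, d)
    )


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 → 4), unlike Python's banker rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_matrix(
    n: int, prevalence_pct: float, recall_pct: float, precision_pct: float
) -> ConfusionMatrix:
    """Back-derive integer TP/FP/FN/TN from printed summary statistics.

    With all percentages on (0, 100]:

    1. positives = round(prevalence * n)
    2. tp = round(recall * positives)
    3. predicted positives = round(tp / precision)
    4. fp = predicted positives - tp; fn = positives - tp; tn = n - rest

    Rounding is half-away-from-zero at each step; inconsistent inputs (any
    negative cell) raise :class:`ValueError`.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for name, v in (
        ("prevalence", prevalence_pct),
        ("recall", recall_pct),
        ("precision", precision_pct),
    ):
        if not 0 < v <= 100:
            raise ValueError(f"{name} must lie in (0, 100]")
    positives = _round_half_away(prevalence_pct / 100 * n)
    tp = _round_half_away(recall_pct / 100 * positives)
    predicted_pos = _round_half_away(tp / (precision_pct / 100))
    fp = predicted_pos - tp
    fn = positives - tp
    tn = n - tp - fp - fn
    if min(tp, fp, fn, tn) < 0:
        raise ValueError(
            f"inconsistent summary statistics: cells ({tp}, {fp}, {fn}, {tn})"
        )
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
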