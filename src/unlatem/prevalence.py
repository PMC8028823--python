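"""Apparent and misclassification-corrected prevalence.

The raw flagged fraction of a property in a classified corpus (*apparent*
prevalence) is biased by the classifier's error rates. The Rogan–Gladen
estimator corrects it to the *actual* prevalence

    p_true = (p_app + Sp - 1) / (Se + Sp - 1)

using the sensitivity Se and specificity Sp measured on a validation set,
clamped to [0, 1]. The correction is only defined for an informative
classifier (Se + Sp > 1). The CI for the corrected value uses the delta
method with Se/Sp treated as fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .detector import LABEL_COLUMNS, classify_corpus
from .evalstats import Proportion, clopper_pearson
from .lexicon import Lexicon

__all__ = [
    "PrevalenceEstimate",
    "apparent_prevalence",
    "rogan_gladen",
    "rogan_gladen_ci",
    "prevalence_report",
    "top_modifications",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Apparent (and optionally corrected) prevalence of one property in one
    group."""

    property: str
    group: str  # "overall" or a specialty cluster
    count: int
    denominator: int
    apparent: Proportion
    actual: Optional[Proportion] = None
    se: Optional[float] = None
    sp: Optional[float] = None


def apparent_prevalence(
    labels: pd.DataFrame, group_by: Optional[pd.Series] = None
) -> list[PrevalenceEstimate]:
    """Flagged fraction per property, with Clopper–Pearson CIs.

    ``labels`` holds the four boolean property columns; ``group_by``
    (aligned with ``labels``) splits the corpus, e.g. by specialty. Empty
    groups are omitted with a warning.
    """
    if labels.empty:
        raise ValueError("empty label table")
    groups: list[tuple[str, pd.DataFrame]]
    if group_by is None:
        groups = [("overall", labels)]
    else:
        aligned = group_by.loc[labels.index].astype(str)
        groups = [(name, sub) for name, sub in labels.groupby(aligned)]
    out: list[PrevalenceEstimate] = []
    for name, sub in groups:
        if sub.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"group {name!r} is empty, omitted", stacklevel=2)
            continue
        for prop in LABEL_COLUMNS:
            count = int(sub[prop].sum())
            out.append(
                PrevalenceEstimate(
                    property=prop,
                    group=str(name),
                    count=count,
                    denominator=len(sub),
                    apparent=clopper_pearson(count, len(sub)),
                )
            )
    return out


def rogan_gladen(p_app: float, se: float, sp: float) -> float:
    """Actual prevalence from apparent prevalence and classifier Se/Sp,
    clamped to [0, 1]. Raises for an uninformative classifier
    (Se + Sp <= 1)."""
    if not 0 <= p_app <= 1:
        raise ValueError("apparent prevalence outside [0, 1]")
    if se + sp <= 1:
        raise ValueError(
            f"uninformative classifier: Se + Sp = {se + sp:.3f} <= 1"
        )
    # algebraically (p_app + Sp - 1)/(Se + Sp - 1); this form avoids
    # cancellation so a perfect classifier returns p_app exactly
    return min(1.0, max(0.0, (p_app - (1.0 - sp)) / (se + sp - 1.0)))


def rogan_gladen_ci(
    p_app: float, n: int, se: float, sp: float, z: float = 1.96
) -> Proportion:
    """Delta-method CI for the corrected prevalence, Se/Sp treated as fixed.

    var(p_true) ~= p_app(1-p_app)/n / (Se+Sp-1)^2.
    """
    point = rogan_gladen(p_app, se, sp)
    if n <= 0:
        raise ValueError("n must be positive")
    sd = math.sqrt(p_app * (1 - p_app) / n) / (se + sp - 1.0)
    return Proportion(point, max(0.0, point - z * sd), min(1.0, point + z * sd))


def prevalence_report(
    records: pd.DataFrame,
    lexicon: Lexicon,
    se_sp: Mapping[str, tuple[float, float]],
    group_by: Optional[str] = None,
) -> pd.DataFrame:
    """Classify a corpus and tabulate apparent + corrected prevalence.

    ``se_sp`` maps property name → (Se, Sp) from a validation study (e.g. the
    pooled weighted values). ``group_by`` names a column of ``records``
    (typically ``specialty``). Rows are sorted by group then descending
    apparent prevalence. Columns: property, group, n_flagged, n,
    apparent_pct, apparent_lo, apparent_hi, actual_pct, actual_lo, actual_hi.
    """
    labels, _problems = classify_corpus(records, lexicon)
    grouping = (
        records[group_by] if group_by is not None and group_by in records else None
    )
    rows = []
    for est in apparent_prevalence(labels, grouping):
        row = {
            "property": est.property,
            "group": est.group,
            "n_flagged": est.count,
            "n": est.denominator,
            "apparent_pct": 100 * est.apparent.point,
            "apparent_lo": 100 * est.apparent.lower,
            "apparent_hi": 100 * est.apparent.upper,
            "actual_pct": float("nan"),
            "actual_lo": float("nan"),
            "actual_hi": float("nan"),
        }
        if est.property in se_sp:
            se, sp = se_sp[est.property]
            ci = rogan_gladen_ci(est.apparent.point, est.denominator, se, sp)
            row.update(
                actual_pct=100 * ci.point,
                actual_lo=100 * ci.lower,
                actual_hi=100 * ci.upper,
            )
        rows.append(row)
    report = pd.DataFrame(rows)
    return report.sort_values(
        ["group", "apparent_pct", "property"], ascending=[True, False, True]
    ).reset_index(drop=True)


def top_modifications(
    records: pd.DataFrame, labels: Optional[pd.DataFrame] = None, k: int = 10
) -> pd.DataFrame:
    """The ``k`` most frequent case-insensitive (default, modified) pairs.

    ``share`` is count / corpus size. Ties are broken lexicographically on
    the lowercased pair. When ``labels`` is given, only records flagged with
    at least one property are counted.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    subset = records
    if labels is not None:
        flagged = labels[list(LABEL_COLUMNS)].any(axis=1)
        subset = records.loc[labels.index[flagged]]
    total = len(records)
    pairs = pd.DataFrame(
        {
            "default_description": subset["default_description"]
            .astype(str)
            .str.casefold(),
            "modified_description": subset["modified_description"]
            .astype(str)
            .str.casefold(),
        }
    )
    counts = (
        pairs.groupby(["default_description", "modified_description"], sort=False)
        .size()
        .reset_index(name="count")
    )
    counts = counts.sort_values(
        ["count", "default_description", "modified_description"],
        ascending=[False, True, True],
    ).head(k)
    counts["share"] = counts["count"] / total if total else 0.0
    return counts.reset_index(drop=True)
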