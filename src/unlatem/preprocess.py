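"""Normalisation and filtering of diagnosis-record tables.

A corpus is a :class:`pandas.DataFrame` with the four columns
``icd10_code``, ``default_description``, ``modified_description`` and
``specialty``; :class:`DiagnosisRecord` is the single-row view. The
operations here mirror how validation sets are prepared from a raw
problem-list export: keep genuinely modified records, drop case-insensitive
duplicate description pairs, drop records whose "modification" is only
whitespace or casing, and optionally merge related specialties into
clusters.

All filters preserve input order, are idempotent, and never increase the
record count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "DiagnosisRecord",
    "normalize_text",
    "is_trivially_modified",
    "select_modified",
    "dedup_pairs",
    "clean_validation_sample",
    "cluster_specialties",
    "draw_validation_sample",
]

REQUIRED_COLUMNS = (
    "icd10_code",
    "default_description",
    "modified_description",
    "specialty",
)

# ICD-10 lexical shape: letter + 2 digits, optional subdivision.
_ICD10_RE = re.compile(r"^[A-Z]\d{2}(?:\.\d{1,4})?$", re.IGNORECASE)


@dataclass(frozen=True)
class DiagnosisRecord:
    """One problem-list row: a coded diagnosis and its free-text edit."""

    icd10_code: str
    default_description: str
    modified_description: str
    specialty: str = ""

    def __post_init__(self) -> None:
        if not str(self.default_description).strip():
            raise ValueError("default_description is empty")
        if not str(self.modified_description).strip():
            raise ValueError("modified_description is empty")

    @property
    def code_is_wellformed(self) -> bool:
        """True if the code has the ICD-10 lexical shape (unknown codes are
        flagged, never rejected)."""
        return bool(_ICD10_RE.match(str(self.icd10_code).strip()))


def normalize_text(text: str) -> str:
    """Lowercase, strip, and collapse internal whitespace runs to one space."""
    return re.sub(r"\s+", " ", str(text)).strip().lower()


def is_trivially_modified(default_description: str, modified_description: str) -> bool:
    """True iff the two descriptions are equal after normalisation.

    Such records are flagged "modified" in the EHR only because of stray
    spaces or casing; they carry no contextual property by construction.
    """
    return normalize_text(default_description) == normalize_text(modified_description)


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in ("default_description", "modified_description") if c not in records]
    if missing:
        raise KeyError(f"records table is missing column(s): {', '.join(missing)}")


def select_modified(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records whose modified description differs from the default.

    The comparison is an exact string comparison: a record differing only by
    a trailing space is still "modified" at this stage and is removed later
    by :func:`clean_validation_sample`.
    """
    _check_columns(records)
    mask = records["default_description"].astype(str) != records[
        "modified_description"
    ].astype(str)
    return records.loc[mask]


def dedup_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Drop case-insensitive duplicate (default, modified) description pairs,
    keeping the first occurrence."""
    _check_columns(records)
    key = (
        records["default_description"].astype(str).str.casefold()
        + "\x1f"
        + records["modified_description"].astype(str).str.casefold()
    )
    return records.loc[~key.duplicated(keep="first")]


def clean_validation_sample(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop trivially modified records; return (kept, number removed)."""
    _check_columns(records)
    trivial = [
        is_trivially_modified(d, m)
        for d, m in zip(
            records["default_description"], records["modified_description"]
        )
    ]
    mask = ~np.asarray(trivial, dtype=bool)
    kept = records.loc[mask]
    return kept, int(len(records) - len(kept))


def cluster_specialties(
    records: pd.DataFrame, mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Replace each specialty by its cluster label.

    ``mapping`` maps specialty → cluster (e.g. both "Audiology" and
    "Audiological center" → "audiology"). Specialties absent from the mapping
    pass through unchanged with a warning; ``mapping=None`` is the identity.
    """
    if "specialty" not in records:
        raise KeyError("records table is missing column(s): specialty")
    if not mapping:
        return records.copy()
    present = set(records["specialty"].astype(str))
    unmapped = sorted(present - set(mapping))
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} specialties not in cluster mapping, passed "
            f"through unchanged: {', '.join(unmapped[:5])}"
            + ("..." if len(unmapped) > 5 else ""),
            stacklevel=2,
        )
    out = records.copy()
    out["specialty"] = out["specialty"].astype(str).map(lambda s: mapping.get(s, s))
    return out


def draw_validation_sample(
    records: pd.DataFrame,
    n: int,
    seed: int,
    dedup: str = "before",
) -> pd.DataFrame:
    """Uniform sample of ``n`` records without replacement, seeded.

    ``dedup`` controls whether case-insensitive pair deduplication runs
    ``"before"`` the draw, ``"after"`` it (in which case fewer than ``n``
    records may return), or ``"none"``.
    """
    if dedup not in ("before", "after", "none"):
        raise ValueError("dedup must be 'before', 'after' or 'none'")
    pool = dedup_pairs(records) if dedup == "before" else records
    if n > len(pool):
        raise ValueError(f"cannot draw {n} from {len(pool)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    sample = pool.iloc[np.sort(idx)]
    if dedup == "after":
        sample = dedup_pairs(sample)
    return sample
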