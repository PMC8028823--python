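"""Contextual-property classification of description pairs.

Four boolean flags are assigned to a (default, modified) description pair:

* **uncertainty** — the modified description carries an uncertainty trigger
  the default lacks (the clinician made the diagnosis tentative);
* **removal of uncertainty** — the converse: the default carries an
  uncertainty trigger the modified description drops (the diagnosis was
  confirmed); by construction the two flags are never both true;
* **laterality** and **temporality** — a left/right or date trigger is
  present in the modified description; these depend only on the modified
  text.

A record can carry any subset of the flags (multi-label). Term order is
deliberately ignored: "maagpijn, verdenking griep" flags uncertainty even
though the uncertainty attaches to the flu, not the stomach ache — a known
limitation of the pure-regex design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .lexicon import Lexicon, match
from .preprocess import DiagnosisRecord, normalize_text

__all__ = [
    "LABEL_COLUMNS",
    "PropertyLabels",
    "detect_uncertainty",
    "detect_removal_of_uncertainty",
    "detect_laterality",
    "detect_temporality",
    "detect_removal_of_laterality",
    "classify",
    "classify_corpus",
]

LABEL_COLUMNS = ("uncertainty", "removal_of_uncertainty", "laterality", "temporality")


@dataclass(frozen=True)
class PropertyLabels:
    uncertainty: bool
    removal_of_uncertainty: bool
    laterality: bool
    temporality: bool

    def __post_init__(self) -> None:
        if self.uncertainty and self.removal_of_uncertainty:
            raise ValueError(
                "uncertainty and removal_of_uncertainty cannot both be true"
            )

    def as_dict(self) -> dict[str, bool]:
        return {c: bool(getattr(self, c)) for c in LABEL_COLUMNS}


def _has(lexicon: Lexicon, text: str, prop: str) -> bool:
    return bool(match(lexicon, normalize_text(text), prop))


def detect_uncertainty(
    default_description: str, modified_description: str, lexicon: Lexicon
) -> bool:
    """True iff the modified description has an uncertainty trigger and the
    default has none.

    When both sides carry a trigger (default "verdenking glaucoom", modified
    "glaucoom screening") nothing changed about the diagnosis's certainty, so
    the flag stays false. Any uncertainty trigger in the default suppresses
    the flag.
    """
    return _has(lexicon, modified_description, "uncertainty") and not _has(
        lexicon, default_description, "uncertainty"
    )


def detect_removal_of_uncertainty(
    default_description: str, modified_description: str, lexicon: Lexicon
) -> bool:
    """True iff the default has an uncertainty trigger and the modified
    description has none (e.g. "verdenking glaucoom" edited to "glaucoom")."""
    return _has(lexicon, default_description, "uncertainty") and not _has(
        lexicon, modified_description, "uncertainty"
    )


def detect_laterality(modified_description: str, lexicon: Lexicon) -> bool:
    """True iff the modified description contains a left/right trigger."""
    return _has(lexicon, modified_description, "laterality")


def detect_temporality(modified_description: str, lexicon: Lexicon) -> bool:
    """True iff the modified description contains a date or year trigger."""
    return _has(lexicon, modified_description, "temporality")


def detect_removal_of_laterality(
    default_description: str, modified_description: str, lexicon: Lexicon
) -> bool:
    """Diagnostic only: default has a laterality trigger the modified text
    drops. Not part of :class:`PropertyLabels`; pairs like "linkszijdige
    decompensatio" → "decompensatio cordis" are generalisations rather than a
    supported property, so this flag is exposed separately and off by default
    in :func:`classify`."""
    return _has(lexicon, default_description, "laterality") and not _has(
        lexicon, modified_description, "laterality"
    )


def classify(
    record: DiagnosisRecord | tuple[str, str], lexicon: Lexicon
) -> PropertyLabels:
    """Assign the four property flags to one record.

    ``record`` may be a :class:`DiagnosisRecord` or a plain
    ``(default_description, modified_description)`` pair.
    """
    if isinstance(record, DiagnosisRecord):
        default, modified = record.default_description, record.modified_description
    else:
        default, modified = record
    return PropertyLabels(
        uncertainty=detect_uncertainty(default, modified, lexicon),
        removal_of_uncertainty=detect_removal_of_uncertainty(
            default, modified, lexicon
        ),
        laterality=detect_laterality(modified, lexicon),
        temporality=detect_temporality(modified, lexicon),
    )


def classify_corpus(
    records: pd.DataFrame, lexicon: Lexicon
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Classify every row of a records table.

    Returns ``(labels, problems)``: ``labels`` has one boolean row per valid
    input record under the :data:`LABEL_COLUMNS`, indexed like ``records``;
    malformed rows (empty description after stripping) are skipped and
    reported in ``problems`` as ``(row position, message)`` — never silently
    dropped.
    """
    rows: dict = {}
    problems: list[tuple[int, str]] = []
    for pos, (idx, row) in enumerate(records.iterrows()):
        default = str(row["default_description"])
        modified = str(row["modified_description"])
        if not default.strip() or not modified.strip():
            problems.append((pos, "empty description"))
            continue
        rows[idx] = classify((default, modified), lexicon).as_dict()
    labels = pd.DataFrame.from_dict(rows, orient="index", columns=list(LABEL_COLUMNS))
    if labels.empty:
        labels = pd.DataFrame(columns=list(LABEL_COLUMNS), dtype=bool)
    return labels.astype(bool), problems
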