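"""Trigger-term lexicon for contextual-property detection.

The detector recognises three trigger-bearing properties in Dutch diagnosis
descriptions — uncertainty, laterality and temporality — via regular
expressions compiled from :class:`TriggerRule` entries. Each rule carries a
surface pattern, a match mode and optional *guard* patterns (pseudo-triggers):
a rule never fires inside a span matched by one of its own guards.

Two fidelity modes are shipped:

``paper_faithful``
    Reproduces the original algorithm's behaviour, including its documented
    error modes: the bare ``l``/``r`` laterality triggers fire inside unit
    strings such as ``mmol/l``, ``ad`` fires even when used for pregnancy
    duration, and ``mogelijk``/``waarschijnlijk`` assert uncertainty only at
    the start of a sentence.

``improved``
    Adds unit/pregnancy guards, lets ``mogelijk``/``waarschijnlijk`` fire
    anywhere, and extends temporality with historical phrases
    (``sinds``, ``in het verleden``).

Lexicons round-trip losslessly through YAML (:func:`save_lexicon` /
:func:`load_lexicon`) so the rule set can be restored or extended.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "PROPERTIES",
    "PAPER_FAITHFUL",
    "IMPROVED",
    "TriggerRule",
    "Lexicon",
    "default_lexicon",
    "match",
    "load_lexicon",
    "save_lexicon",
]

#: The trigger-bearing properties. "Removal of uncertainty" reuses the
#: uncertainty rules on the default description, so it has no rule set here.
PROPERTIES = ("uncertainty", "laterality", "temporality")

PAPER_FAITHFUL = "paper_faithful"
IMPROVED = "improved"
_FIDELITY_MODES = (PAPER_FAITHFUL, IMPROVED)

_MATCH_MODES = ("whole_word", "sentence_start", "regex")

#: Characters that end a sentence inside a description. Commas deliberately do
#: not: the original sentence-start rule misses "diabetes, mogelijk type 2".
_SENTENCE_BREAK = r"[.;!?]"


@dataclass(frozen=True)
class TriggerRule:
    """One trigger pattern for one property.

    Parameters
    ----------
    surface:
        Literal term (``whole_word``/``sentence_start`` modes, regex-escaped)
        or a raw regex fragment (``regex`` mode).
    property:
        One of :data:`PROPERTIES`.
    match_mode:
        ``whole_word`` — fires wherever the term appears delimited by
        non-word characters or string boundaries; ``sentence_start`` — fires
        only at the start of the string or after a sentence break;
        ``regex`` — ``surface`` is used verbatim.
    guards:
        Regex patterns; any rule match fully contained in a guard match is
        suppressed.
    note:
        Free text, conventionally the Dutch term plus an English gloss.
    """

    surface: str
    property: str
    match_mode: str = "whole_word"
    guards: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("rule surface must be non-empty")
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")
        if self.match_mode not in _MATCH_MODES:
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        object.__setattr__(self, "guards", tuple(self.guards))

    @property
    def pattern(self) -> str:
        if self.match_mode == "regex":
            return self.surface
        body = re.escape(self.surface)
        if self.match_mode == "sentence_start":
            return rf"(?:^|{_SENTENCE_BREAK}\s*)({body})(?!\w)"
        return rf"(?<!\w){body}(?!\w)"


@functools.lru_cache(maxsize=1024)
def _compile(pattern: str) -> re.Pattern[str]:
    return re.compile(pattern, re.IGNORECASE)


@dataclass(frozen=True)
class Lexicon:
    """A versioned collection of trigger rules plus a fidelity mode."""

    rules: tuple[TriggerRule, ...]
    version: str = "0"
    fidelity_mode: str = PAPER_FAITHFUL

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.fidelity_mode not in _FIDELITY_MODES:
            raise ValueError(f"unknown fidelity_mode {self.fidelity_mode!r}")
        seen = set()
        for rule in self.rules:
            key = (rule.surface, rule.property, rule.match_mode)
            if key in seen:
                raise ValueError(f"duplicate rule {key}")
            seen.add(key)
        for prop in PROPERTIES:
            if not any(r.property == prop for r in self.rules):
                raise ValueError(f"lexicon has no rule for property {prop!r}")

    def rules_for(self, property: str) -> tuple[TriggerRule, ...]:
        if property not in PROPERTIES:
            raise ValueError(f"unknown property {property!r}")
        return tuple(r for r in self.rules if r.property == property)

    def surfaces(self, property: str | None = None) -> set[str]:
        rules = self.rules if property is None else self.rules_for(property)
        return {r.surface for r in rules}


def match(lexicon: Lexicon, text: str, property: str) -> list[tuple[int, int]]:
    """All non-suppressed trigger spans for ``property`` in ``text``.

    Matching is case-insensitive and deterministic; spans are returned as
    ``(start, end)`` offsets into ``text``, sorted, duplicates removed.
    Overlapping matches from different rules are all reported. An unknown
    property name raises :class:`ValueError`.
    """
    rules = lexicon.rules_for(property)  # validates the property name
    spans: set[tuple[int, int]] = set()
    for rule in rules:
        pat = _compile(rule.pattern)
        hits = []
        for m in pat.finditer(text):
            hits.append(m.span(1) if pat.groups else m.span())
        if not hits:
            continue
        if rule.guards:
            guard_spans = [
                g.span()
                for guard in rule.guards
                for g in _compile(guard).finditer(text)
            ]
            hits = [
                (s, e)
                for s, e in hits
                if not any(gs <= s and e <= ge for gs, ge in guard_spans)
            ]
        spans.update(hits)
    return sorted(spans)


# ---------------------------------------------------------------------------
# Shipped rule set
# ---------------------------------------------------------------------------

_YEAR = r"(?<!\d)(?:19|20)\d{2}(?!\d)"
_NUMERIC_DATE = r"(?<!\d)\d{1,2}[-/.]\d{1,2}[-/.]\d{2,4}(?!\d)"
_MONTH_YEAR = (
    r"(?<!\w)(?:januari|februari|maart|april|mei|juni|juli|augustus"
    r"|september|oktober|november|december)\s+(?:19|20)\d{2}(?!\d)"
)

# Guards only active in improved mode.
_UNIT_GUARD = r"(?:\d|mmol)\s*/\s*l(?!\w)"  # "mmol/l", "5 mmol / l"
_PREGNANCY_GUARD = r"(?<!\w)ad\s*\d+(?:\+\d+)?\s*(?:weken|wkn|wk)?(?!\w)"


def default_lexicon(fidelity_mode: str = PAPER_FAITHFUL) -> Lexicon:
    """The shipped Dutch rule set.

    Uncertainty triggers cover the Dutch forms of *suspected*, *screening*,
    *possible*, *analysis* and *advice*. Terms with several clinical readings,
    such as *aanvraag* ("request"), are deliberately absent. Laterality covers
    left/right in full and abbreviated forms plus the eye (od/os) and right-ear
    (ad) Latin abbreviations. Temporality covers 4-digit years (1900–2099),
    numeric day-month-year dates with ``-``, ``/`` or ``.`` separators, and
    month-name + year.
    """
    if fidelity_mode not in _FIDELITY_MODES:
        raise ValueError(f"unknown fidelity_mode {fidelity_mode!r}")
    improved = fidelity_mode == IMPROVED
    possible_mode = "whole_word" if improved else "sentence_start"

    def rule(surface, prop, mode="whole_word", guards=(), note=""):
        return TriggerRule(surface, prop, mode, tuple(guards), note)

    rules: list[TriggerRule] = [
        # -- uncertainty -----------------------------------------------------
        rule("verdenking", "uncertainty", note="suspicion (suspected)"),
        rule("verdacht", "uncertainty", note="suspected"),
        rule("screening", "uncertainty", note="screening"),
        rule("analyse", "uncertainty", note="analysis / work-up"),
        rule("advies", "uncertainty", note="advice"),
        rule("mogelijk", "uncertainty", possible_mode, note="possible"),
        rule("waarschijnlijk", "uncertainty", possible_mode, note="probable"),
        # -- laterality ------------------------------------------------------
        rule("links", "laterality", note="left"),
        rule("rechts", "laterality", note="right"),
        rule("li", "laterality", note="left (abbrev.)"),
        rule("re", "laterality", note="right (abbrev.)"),
        rule(
            "l",
            "laterality",
            guards=(_UNIT_GUARD,) if improved else (),
            note="left (single letter; bare form also matches units like mmol/l)",
        ),
        rule("r", "laterality", note="right (single letter)"),
        rule("od", "laterality", note="oculus dexter (right eye)"),
        rule("os", "laterality", note="oculus sinister (left eye)"),
        rule(
            "ad",
            "laterality",
            guards=(_PREGNANCY_GUARD,) if improved else (),
            note="auris dextra (right ear); also misused for pregnancy duration",
        ),
        # -- temporality -----------------------------------------------------
        rule(_YEAR, "temporality", "regex", note="4-digit year 1900-2099"),
        rule(_NUMERIC_DATE, "temporality", "regex", note="numeric d-m-y date"),
        rule(_MONTH_YEAR, "temporality", "regex", note="Dutch month name + year"),
    ]
    if improved:
        rules += [
            rule("sinds", "temporality", note="since"),
            rule("in het verleden", "temporality", note="in the past"),
        ]
    return Lexicon(tuple(rules), version="1.0", fidelity_mode=fidelity_mode)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon to YAML (top-level keys per property)."""
    doc: dict = {"version": lexicon.version, "fidelity_mode": lexicon.fidelity_mode}
    for prop in PROPERTIES:
        doc[prop] = [
            {
                "surface": r.surface,
                "match_mode": r.match_mode,
                "guards": list(r.guards),
                "note": r.note,
            }
            for r in lexicon.rules_for(prop)
        ]
    Path(path).write_text(
        yaml.safe_dump(doc, allow_unicode=True, sort_keys=False), encoding="utf-8"
    )


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon written by :func:`save_lexicon`."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    rules = []
    for prop in PROPERTIES:
        for entry in doc.get(prop, []) or []:
            rules.append(
                TriggerRule(
                    surface=entry["surface"],
                    property=prop,
                    match_mode=entry.get("match_mode", "whole_word"),
                    guards=tuple(entry.get("guards", []) or []),
                    note=entry.get("note", ""),
                )
            )
    return Lexicon(
        tuple(rules),
        version=str(doc.get("version", "0")),
        fidelity_mode=doc.get("fidelity_mode", PAPER_FAITHFUL),
    )
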