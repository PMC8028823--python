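"""Gold-labelled synthetic diagnosis-record corpora.

Real problem-list exports are privacy-restricted, so every other module is
exercised on generated corpora: Dutch-style (default, modified) description
pairs built from a small diagnosis vocabulary with trigger terms inserted at
configurable per-property rates, each record carrying its gold
:class:`~unlatem.detector.PropertyLabels`.

Canonical records insert only triggers the detector is guaranteed to match,
so with ``adversarial_rate == 0`` the paper-faithful detector agrees with
the gold labels by construction — a green run establishes the detector's
internal consistency, not performance on real clinical text. Setting
``adversarial_rate > 0`` mixes in records reproducing the four documented
real-world error modes (unit strings like ``mmol/l``, ``ad`` as pregnancy
duration, mid-sentence ``mogelijk``, historical phrases such as ``in het
verleden``) whose gold labels follow the human reading, so the faithful
detector measurably errs on them. Adversarial records dilute the property
mix: the marginal gold rates stated in ``property_mix`` are exact only at
``adversarial_rate == 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detector import LABEL_COLUMNS

__all__ = ["FixtureSpec", "generate", "worked_examples", "DEFAULT_MIX"]

#: Default per-property gold rates: the actual prevalences measured on the
#: multicenter corpus (laterality 31.4%, uncertainty 9.9%, temporality 9.8%,
#: removal of uncertainty 1.3%).
DEFAULT_MIX: dict[str, float] = {
    "laterality": 0.314,
    "uncertainty": 0.099,
    "temporality": 0.098,
    "removal_of_uncertainty": 0.013,
}

#: (diagnosis term, plausible ICD-10 code) — terms are trigger-free.
_VOCAB: tuple[tuple[str, str], ...] = (
    ("glaucoom", "H40"),
    ("cataract", "H25"),
    ("hypertensie", "I10"),
    ("ooginfectie", "H44"),
    ("fractuur", "S42"),
    ("decompensatio cordis", "I50"),
    ("diabetes mellitus", "E11"),
    ("astma", "J45"),
)

_UNCERTAINTY_TEMPLATES = (
    "verdenking {base}",
    "mogelijk {base}",
    "waarschijnlijk {base}",
    "{base} screening",
    "analyse {base}",
)

_LATERALITY_TOKENS = ("links", "rechts", "li", "re", "od", "os")

#: Trigger-free edits so no-property records still differ from the default.
_BENIGN_SUFFIXES = ("ernstig", "gering", "type 2", "stadium ii", "chronisch")

_SPECIALTIES = (
    ("oogheelkunde", 0.30),
    ("orthopedie", 0.20),
    ("interne geneeskunde", 0.20),
    ("cardiologie", 0.15),
    ("klinische genetica", 0.15),
)

#: (icd10, specialty, default, modified, gold labels) for the documented
#: error modes; gold follows the human reading, so the paper-faithful
#: detector errs on every one of these.
_ADVERSARIAL: tuple[tuple[str, str, str, str, dict[str, bool]], ...] = (
    (
        "E11",
        "interne geneeskunde",
        "diabetes mellitus",
        "diabetes mellitus glucose 6 mmol/l",
        {},  # unit string, no laterality — faithful mode false-positives on "l"
    ),
    (
        "Z34",
        "gynaecologie",
        "zwangerschap",
        "zwangerschap ad 12 weken",
        {},  # "ad" = pregnancy duration here, not right ear
    ),
    (
        "J11",
        "interne geneeskunde",
        "griep",
        "griep, mogelijk pneumonie",
        {"uncertainty": True},  # mid-sentence "mogelijk" — faithful mode misses
    ),
    (
        "I10",
        "cardiologie",
        "hypertensie",
        "hypertensie in het verleden",
        {"temporality": True},  # historical phrase without a date
    ),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated corpus."""

    n: int = 1000
    property_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    adversarial_rate: float = 0.0
    seed: int = 0
    specialty_profile: Sequence[tuple[str, float]] = _SPECIALTIES

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        mix = dict(DEFAULT_MIX, **dict(self.property_mix))
        unknown = set(mix) - set(LABEL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown properties in mix: {sorted(unknown)}")
        for prop, rate in mix.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"rate for {prop} outside [0, 1]")
        if mix["uncertainty"] + mix["removal_of_uncertainty"] > 1:
            raise ValueError("uncertainty + removal rates exceed 1")
        if not 0 <= self.adversarial_rate <= 1:
            raise ValueError("adversarial_rate outside [0, 1]")
        object.__setattr__(self, "property_mix", mix)
        weights = [w for _s, w in self.specialty_profile]
        if not weights or min(weights) <= 0:
            raise ValueError("specialty weights must be positive")


def _empty_labels() -> dict[str, bool]:
    return {c: False for c in LABEL_COLUMNS}


def generate(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build ``(records, gold)`` tables of ``spec.n`` rows each.

    Byte-identical output for identical specs (one NumPy generator seeded
    from ``spec.seed`` drives every choice). Uncertainty and removal of
    uncertainty are sampled mutually exclusively from one uniform draw, so
    their marginal gold rates match ``property_mix`` exactly in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    mix = spec.property_mix
    specialties = [s for s, _w in spec.specialty_profile]
    weights = np.array([w for _s, w in spec.specialty_profile], dtype=float)
    weights /= weights.sum()

    rec_rows, gold_rows = [], []
    for _ in range(spec.n):
        if rng.random() < spec.adversarial_rate:
            code, specialty, default, modified, flags = _ADVERSARIAL[
                rng.integers(len(_ADVERSARIAL))
            ]
            gold = {**_empty_labels(), **flags}
            rec_rows.append((code, default, modified, specialty))
            gold_rows.append(gold)
            continue

        base, code = _VOCAB[rng.integers(len(_VOCAB))]
        gold = _empty_labels()
        u = rng.random()
        if u < mix["removal_of_uncertainty"]:
            gold["removal_of_uncertainty"] = True
        elif u < mix["removal_of_uncertainty"] + mix["uncertainty"]:
            gold["uncertainty"] = True
        gold["laterality"] = rng.random() < mix["laterality"]
        gold["temporality"] = rng.random() < mix["temporality"]

        default = base
        modified = base
        if gold["removal_of_uncertainty"]:
            default = f"verdenking {base}"
        elif gold["uncertainty"]:
            template = _UNCERTAINTY_TEMPLATES[rng.integers(len(_UNCERTAINTY_TEMPLATES))]
            modified = template.format(base=base)
        if gold["laterality"]:
            modified += " " + _LATERALITY_TOKENS[rng.integers(len(_LATERALITY_TOKENS))]
        if gold["temporality"]:
            if rng.random() < 0.5:
                modified += f" {rng.integers(1980, 2024)}"
            else:
                modified += (
                    f" {rng.integers(1, 29):02d}-{rng.integers(1, 13):02d}-"
                    f"{rng.integers(1980, 2024)}"
                )
        if modified == default:
            modified += " " + _BENIGN_SUFFIXES[rng.integers(len(_BENIGN_SUFFIXES))]

        specialty = specialties[rng.choice(len(specialties), p=weights)]
        rec_rows.append((code, default, modified, specialty))
        gold_rows.append(gold)

    records = pd.DataFrame(
        rec_rows,
        columns=[
            "icd10_code",
            "default_description",
            "modified_description",
            "specialty",
        ],
    )
    gold = pd.DataFrame(gold_rows, columns=list(LABEL_COLUMNS)).astype(bool)
    return records, gold


def worked_examples() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The fixed mini-corpus of canonical classification examples.

    Every pair exercises one documented behaviour: adding/removing an
    uncertainty trigger, retained uncertainty on both sides, laterality and
    temporality additions (alone and combined), and an unmodified-meaning
    pair with all-false labels. The paper-faithful detector reproduces every
    gold label here.
    """
    cases = [
        # (code, specialty, default, modified, gold flag overrides)
        ("H40", "oogheelkunde", "glaucoom", "glaucoom screening", {"uncertainty": True}),
        ("H40", "oogheelkunde", "verdenking glaucoom", "glaucoom", {"removal_of_uncertainty": True}),
        ("H40", "oogheelkunde", "verdenking glaucoom", "glaucoom screening", {}),
        ("H44", "oogheelkunde", "ooginfectie", "2015 ooginfectie links", {"laterality": True, "temporality": True}),
        ("H25", "oogheelkunde", "cataract", "cataract od", {"laterality": True}),
        ("H25", "oogheelkunde", "cataract", "cataract os", {"laterality": True}),
        ("H40", "oogheelkunde", "glaucoom", "glaucoom 2002", {"temporality": True}),
        ("I10", "cardiologie", "essentiele hypertensie", "verdenking hypertensie", {"uncertainty": True}),
        ("H40", "oogheelkunde", "glaucoom", "glaucoom", {}),
    ]
    records = pd.DataFrame(
        [(c, d, m, s) for c, s, d, m, _f in cases],
        columns=[
            "icd10_code",
            "default_description",
            "modified_description",
            "specialty",
        ],
    )
    gold = pd.DataFrame(
        [{**_empty_labels(), **flags} for *_rest, flags in cases],
        columns=list(LABEL_COLUMNS),
    ).astype(bool)
    return records, gold
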