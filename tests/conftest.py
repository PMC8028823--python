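import pandas as pd
import pytest

from unlatem import default_lexicon

# Printed per-dataset summary rows (n, prevalence %, recall %, specificity %,
# precision %) together with the error counts (fp, fn) the published error
# analysis reports for each row. The reconstruction tests must reproduce the
# (fp, fn) pairs exactly and round-trip the percentages to 0.05 points.
SUMMARY_ROWS = {
    ("laterality", "internal"): dict(
        n=980, prevalence=25.3, recall=100.0, specificity=99.0, precision=97.3,
        fp=7, fn=0,
    ),
    ("laterality", "multicenter"): dict(
        n=996, prevalence=29.2, recall=99.7, specificity=97.2, precision=93.5,
        fp=20, fn=1,
    ),
    ("temporality", "internal"): dict(
        n=980, prevalence=16.9, recall=97.6, specificity=99.5, precision=97.6,
        fp=4, fn=4,
    ),
    ("temporality", "multicenter"): dict(
        n=996, prevalence=9.4, recall=96.8, specificity=98.9, precision=90.1,
        fp=10, fn=3,
    ),
    ("uncertainty", "internal"): dict(
        n=980, prevalence=11.9, recall=99.1, specificity=98.5, precision=89.9,
        fp=13, fn=1,
    ),
    ("uncertainty", "multicenter"): dict(
        n=996, prevalence=10.2, recall=86.3, specificity=98.8, precision=88.9,
        fp=11, fn=14,
    ),
    ("removal_of_uncertainty", "internal"): dict(
        n=980, prevalence=0.9, recall=100.0, specificity=99.4, precision=60.0,
        fp=6, fn=0,
    ),
    ("removal_of_uncertainty", "multicenter"): dict(
        n=996, prevalence=1.4, recall=57.1, specificity=99.9, precision=88.9,
        fp=1, fn=6,
    ),
}


@pytest.fixture(scope="session")
def faithful_lexicon():
    return default_lexicon("paper_faithful")


@pytest.fixture(scope="session")
def improved_lexicon():
    return default_lexicon("improved")


@pytest.fixture()
def small_records():
    return pd.DataFrame(
        {
            "icd10_code": ["H40", "H25", "I10"],
            "default_description": ["glaucoom", "cataract", "hypertensie"],
            "modified_description": [
                "glaucoom screening",
                "cataract od",
                "hypertensie 2002",
            ],
            "specialty": ["oogheelkunde", "oogheelkunde", "cardiologie"],
        }
    )
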