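# Methods

## The detector

A record is a (default description, modified description) pair from a coded
problem list. Matching is pure regular-expression search over the normalized
text (lowercased, whitespace collapsed): no tokenizer, no stemming, no term
order. Each property has a list of trigger rules; a property flag only needs
one surviving match.

- **uncertainty** = modified has ≥1 uncertainty trigger AND default has none.
- **removal of uncertainty** = default has ≥1 uncertainty trigger AND
  modified has none. The symmetric contains/not-contains definitions force
  mutual exclusion: the two flags can never both be true, and swapping the
  pair swaps the flags.
- **laterality**, **temporality** = ≥1 trigger in the modified description;
  the default plays no role.

Any uncertainty trigger in the default suppresses the uncertainty flag, even
if the modified text uses a *different* trigger ("verdenking glaucoom" →
"glaucoom screening" is no change in certainty). This is the strictest
reading of the pair-relative definition and the one the worked examples
support.

"Removal of laterality" pairs exist in real data ("decompensatio cordis
links" → "decompensatio cordis") but are generalisations of the diagnosis
rather than a supported property; `detect_removal_of_laterality` is exposed
as a diagnostic but never enters `PropertyLabels`.

### Rule matching

Three match modes:

- `whole_word` — the escaped term delimited by non-word characters or string
  boundaries (`(?<!\w)term(?!\w)`). `/` is a non-word character, so the bare
  `l` trigger fires in `mmol/l` — deliberately, in faithful mode.
- `sentence_start` — only at the start of the string or after `.;!?`.
  Commas do not end a sentence, which is exactly why faithful mode misses
  "griep, mogelijk pneumonie".
- `regex` — the surface is a raw pattern (used for dates).

Guards are regex patterns attached to a rule; a trigger match fully contained
in a guard match is suppressed. Guards are monotone by construction: they can
only remove matches. All matching is case-insensitive and deterministic.

### The shipped lexicon

The full original rule inventory is not recoverable from the published
description, so the shipped set is the union of every named trigger, loadable
and extensible via YAML:

- uncertainty: `verdenking`, `verdacht`, `screening`, `analyse`, `advies`,
  `mogelijk`, `waarschijnlijk` (the last two sentence-start-only in faithful
  mode). `aanvraag` ("request") is deliberately excluded: it can mean a
  confirmation request (uncertainty) or a treatment request (not).
- laterality: `links`, `rechts`, `li`, `re`, `l`, `r`, `od`, `os`, `ad`.
- temporality: 4-digit years constrained to 1900–2099 (an unconstrained
  `\d{4}` would fire on dosages and codes), numeric day-month-year dates with
  `-`, `/` or `.` separators, Dutch month name + year.

`improved` mode adds: a unit guard on `l` (preceded by a digit or `mmol`
and a slash), a pregnancy-duration guard on `ad` (followed by a number,
optionally `weken`/`wkn`/`wk`), mid-sentence `mogelijk`/`waarschijnlijk`, and
the historical phrases `sinds` and `in het verleden`. Whether `?` or further
Latin abbreviations were original triggers is unknown and not guessed; users
can add them through the YAML config.

Text is UTF-8 throughout; diacritics are preserved and not folded — Dutch
clinical trigger terms do not hinge on them.

## Preprocessing

Mirrors how validation sets are prepared from a raw export: keep records
whose modified text differs from the default by exact string comparison;
drop case-insensitive duplicate (default, modified) pairs keeping the first;
drop records whose "modification" is only whitespace/casing (these carry no
contextual property by construction and would otherwise dilute specificity
denominators); optionally merge related specialties via a user-supplied
two-column mapping (the published clustering table is not available, so the
default is the identity with a warning for unmapped values). Validation
sampling is uniform without replacement from a caller-supplied seed; because
it is unstated whether deduplication preceded or followed the published
draw, `draw_validation_sample` exposes both orders (`dedup="before"` is the
default).

All filters preserve order, are idempotent, and never increase the count.

## Evaluation statistics

- **Confusion matrices** per property against a human reference standard;
  a metric with a zero denominator is reported as undefined, never 0.
- **Clopper–Pearson** exact intervals from beta quantiles. The choice is
  forced by the published bound for a 248/248 recall — 98.5% — which equals
  the closed form `0.025^(1/248)`; the implementation is checked against
  that closed form to 1e−9. Non-integer (corrected) counts are accepted.
- **Haldane–Anscombe**: +0.5 to every cell iff the matrix contains a zero,
  per matrix (the literal reading of the rule).
- **Inverse-variance pooling** across validation sets: binomial SE on the
  metric's own denominator (tp+fn for recall, tn+fp for specificity), weights
  `1/SE²`, CI `pooled ± 1.96·√(1/Σw)` truncated to [0, 1]. A degenerate
  estimate (p of exactly 0 or 1, hence SE = 0 even after correction) gets a
  capped weight of 1e12. Note: the published pooled "weighted mean" columns
  could not be reproduced from the published per-dataset rows under this
  standard weighting (e.g. weighted laterality recall prints 99.9 where this
  method gives ≈99.7); the exact original weighting formulas are not
  available, so pooled values are reported but not treated as reference
  values anywhere in the tests.
- **Cohen's kappa** with observed agreement po, chance agreement pe from the
  marginals, and each annotator's positive count. Published kappas were
  computed on rounded printed agreement, so tests assert a bracket, not
  equality.
- **`reconstruct_matrix`** inverts printed `(n, prevalence %, recall %,
  precision %)` to integer cells: positives = round(prev·n), tp =
  round(recall·positives), predicted positives = round(tp/precision), rest by
  subtraction; rounding is half-away-from-zero at each step. This order and
  rounding rule uniquely reproduce all eight published per-dataset rows'
  FP/FN error counts, which is the package's audit surface for published
  evaluation tables. Inconsistent inputs (any negative cell) raise.

## Prevalence correction

Apparent prevalence is the flagged fraction with a Clopper–Pearson CI,
overall or per specialty (group counts sum to the overall count). The
Rogan–Gladen estimator corrects it:

    p_true = (p_app + Sp − 1) / (Se + Sp − 1),  clamped to [0, 1]

defined only for informative classifiers (Se + Sp > 1); the implementation
uses the algebraically equal form `(p_app − (1 − Sp))/(Se + Sp − 1)` to avoid
cancellation so a perfect classifier returns `p_app` bit-exactly. The CI is
delta-method with Se/Sp treated as fixed: `var ≈ p_app(1−p_app)/n /
(Se+Sp−1)²` — the simplest defensible default given that the original
formula appendix is unavailable. Se/Sp default to the pooled values, with
per-dataset values as an option. Known discrepancy: the published corrected
prevalences exceed the apparent ones for every property, which this standard
estimator cannot produce under the published Se/Sp (laterality 24.1%
apparent maps to ≈23%, not the printed 24.5%); whatever variant produced
those numbers is not recoverable and is not guessed.

## The synthetic-data generator

`fixtures.generate` emulates the *structure* of a modified-description
corpus: a small trigger-free Dutch diagnosis vocabulary, uncertainty
templates, laterality tokens, year/date suffixes, and a benign-edit suffix so
every record differs from its default. Defaults are the stated world of the
application corpus: per-property rates laterality 0.314, uncertainty 0.099,
temporality 0.098, removal 0.013 (the corrected multicenter prevalences);
uncertainty and removal are drawn mutually exclusively from one uniform
variate so their marginals are exact in expectation. One seeded NumPy
generator drives every choice; identical specs are byte-identical.

The adversarial catalogue is fixed to the four *documented* error modes —
`mmol/l` unit strings, `ad` as pregnancy duration, mid-sentence `mogelijk`,
`in het verleden` — with gold labels per the human reading, so faithful mode
measurably errs on them and improved mode measurably recovers. Anything
beyond those would be invented ground truth. Consequently a green test on
generated corpora establishes the detector's internal consistency with its
own trigger inventory and its behaviour on the documented failure modes —
not performance on real clinical text, whose trigger variety, typos and
word-order effects the generator does not model. `adversarial_rate` defaults
to 0 so the stated property mix is exact; adversarial records dilute it.

## Numerical and interface choices

- Rounding half-away-from-zero in `reconstruct_matrix` (Python's built-in
  `round` is banker's rounding and does not reproduce the published rows).
- Ties in `top_modifications` break lexicographically on the lowercased pair.
- Overlapping trigger matches are all reported; flags need only existence.
- CLI exit codes: 0 ok, 1 usage/config, 2 data; warnings to stderr only.
- CSV floats at 4 decimals, JSON at full precision, keys sorted — identical
  inputs give byte-identical reports.

## Limitations

- Term order is ignored: "maagpijn, verdenking griep" flags uncertainty on
  the stomach-ache record although the flu is what is uncertain.
- Negation, experiencer and hypothetical status are out of scope, as are
  non-Dutch default lexicons (users may supply one via YAML).
- The generator does not model real lexical variety; performance numbers on
  synthetic corpora are not estimates of performance on hospital data.
- Published pooled columns and corrected prevalences are not reproducible
  from the published inputs (see above); the standard methods are
  implemented and the discrepancies documented rather than fitted.
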