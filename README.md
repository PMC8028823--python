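# unlatem

Rule-based detection of **un**certainty, **la**terality and **tem**porality in
Dutch modified diagnosis descriptions, with the evaluation statistics and
prevalence correction needed to use the detector on real problem-list data.

## The problem

Dutch hospital problem lists bind each diagnosis to a coded default
description (from the Diagnosis Thesaurus, mapped to ICD-10/SNOMED CT).
Clinicians frequently edit that description in free text, adding *contextual
properties* that change its meaning without changing the code:

- **uncertainty** — *glaucoom* → *glaucoom screening* (the diagnosis is
  tentative, but the code says glaucoma);
- **removal of uncertainty** — *verdenking glaucoom* → *glaucoom* (the
  suspected diagnosis was confirmed);
- **laterality** — *cataract* → *cataract od* (right eye);
- **temporality** — *glaucoom* → *glaucoom 2002* (a historical problem coded
  as current).

Anyone reusing coded problem-list data — cohort selection, registries,
decision support — silently inherits these discrepancies. `unlatem` flags
them with trigger-term regular expressions over the (default, modified)
description pair, in the NegEx/ConText family of rule-based clinical NLP.

A record is flagged **uncertain** iff the modified description contains an
uncertainty trigger (Dutch forms of *suspected*, *screening*, *possible*,
*analysis*, *advice*) and the default does not; **removal of uncertainty** is
the mirror image; laterality and temporality depend on the modified text
alone. Output is multi-label: *2015 ooginfectie links* is both laterality and
temporality.

Two fidelity modes are shipped. `paper_faithful` reproduces the original
rule set *including its documented error modes* (the bare `l` trigger fires
inside `mmol/l`; `ad` fires when used for pregnancy duration; `mogelijk` /
`waarschijnlijk` only count at the start of a sentence). `improved` guards
those cases and adds historical phrases (`sinds`, `in het verleden`) to
temporality. The lexicon round-trips through YAML so users can restore or
extend the rule set.

## Evaluation and prevalence statistics

For validating the detector against human annotation the package implements:

- per-property confusion matrices; recall (Se), specificity (Sp), precision
  (PPV) and reference-standard prevalence with exact Clopper–Pearson 95% CIs;
- the Haldane–Anscombe correction (add 0.5 to all cells of a matrix
  containing a zero);
- inverse-variance-weighted pooling of proportions across validation sets
  (`w_i = 1/SE_i²`, `SE_i = √(p_i(1−p_i)/n_i)`);
- Cohen's kappa with observed/chance agreement and per-annotator marginals;
- back-derivation of an integer confusion matrix from printed summary
  statistics `(n, prevalence, recall, precision)` — useful for auditing
  published evaluation tables;
- the Rogan–Gladen estimator `p_true = (p_app + Sp − 1)/(Se + Sp − 1)`,
  clamped to [0, 1], which corrects the raw flagged fraction of a corpus for
  the detector's misclassification, with a delta-method CI.

Because real problem-list exports are privacy-restricted, `unlatem.fixtures`
generates gold-labelled synthetic corpora: Dutch-style description pairs with
triggers inserted at configurable rates, plus an adversarial catalogue
reproducing the documented real-world error modes so the faithful detector
measurably errs on them.

## Worked example

```python
from unlatem import classify, default_lexicon

lex = default_lexicon("paper_faithful")
for pair in [("glaucoom", "glaucoom screening"),
             ("verdenking glaucoom", "glaucoom"),
             ("ooginfectie", "2015 ooginfectie links")]:
    print(pair, "->", classify(pair, lex))
```

prints

```
('glaucoom', 'glaucoom screening') -> PropertyLabels(uncertainty=True, removal_of_uncertainty=False, laterality=False, temporality=False)
('verdenking glaucoom', 'glaucoom') -> PropertyLabels(uncertainty=False, removal_of_uncertainty=True, laterality=False, temporality=False)
('ooginfectie', '2015 ooginfectie links') -> PropertyLabels(uncertainty=False, removal_of_uncertainty=False, laterality=True, temporality=True)
```

— screening makes the glaucoma tentative; dropping *verdenking* confirms it;
the eye infection is flagged for both its side and its year.

The same pipeline from the shell:

```bash
unlatem synth --n 1000 --seed 42 --adversarial 0.05 \
    --output records.csv --gold gold.csv
unlatem classify --input records.csv --output labeled.csv
unlatem evaluate --gold gold.csv --pred labeled.csv --report metrics.json
unlatem prevalence --input records.csv --by specialty \
    --se-sp metrics.json --output prevalence.csv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch: it generates two
validation-sized synthetic corpora and a 20,000-record application corpus,
classifies them in paper-faithful mode, scores the detector per property
(Haldane–Anscombe-corrected matrices, exact CIs, pooled Se/Sp), corrects the
apparent prevalences with the Rogan–Gladen estimator, and prints the summary
alongside the most frequent modifications.

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
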