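# emrminer

Tiered dictionary-based case detection for free-text electronic medical
records, with keyword-in-context (KWIC) review sheets and diagnostic-test
evaluation against manual gold-standard labels.

## The problem

Practice-management systems export clinical data as one free-text row per
visit event: an anonymous patient ID, a date, and an uncoded note mixing
clinician shorthand, misspellings, abbreviations, and drug-dispensing text.
Epidemiological work on such data needs *case detection*: finding every row
that refers to a condition or drug of interest, at near-manual accuracy but
without reading millions of rows.

`emrminer` implements a transparent, rule-based workflow for this. For each
category (e.g. a drug class, a syndrome, a specific diagnosis) the analyst
curates three dictionaries from the corpus's own word-frequency list:

1. an **inclusion** dictionary — words (correct spellings, misspellings,
   abbreviations) that flag a row as a candidate case;
2. an **exclusion** dictionary — word combinations identifying false
   positives among the candidates (negations: "no bute given", hypothetical
   use: "NSAID in future");
3. a **reinclusion** dictionary — word combinations rescuing rows the
   exclusion stage removed wrongly ("... but danilon dispensed").

Classification is pure set algebra on row ids:

```
final = (inclusion \ exclusion) ∪ reinclusion
```

Each stage is a token-exact search: a term matches where its tokens occur in
order, contiguously by default (a configurable `max_gap` allows intervening
tokens). Every stage emits a 5-column KWIC sheet (row number, preceding text,
matched term, following text, patient ID) for rapid human review, and a
stage-count summary (terms / cases / repeats) documents the data flow.

Against gold labels, a final case set is scored with a 2×2 contingency table
and percent metrics:

- sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP)
- PPV = 100·TP/(TP+FP), NPV = 100·TN/(TN+FN)
- F = 100·2·p·s/(p+s), the harmonic mean of the PPV and sensitivity
  proportions p and s

Because real exports of this kind are proprietary, the package includes a
synthetic corpus generator (`emrminer.synthetic_corpus`) that emulates the
data's structure — heavy-tailed rows-per-patient, template-based clinical and
dispensing clauses, misspellings, negations — and returns the *true*
dictionaries alongside the gold labels, so the entire pipeline is testable
end to end.

## Worked example

```sh
emrminer simulate --seed 42 --n-patients 50 --out-dir sim
emrminer classify --corpus sim/corpus.csv --dict-config sim/dictionaries.yaml \
    --category nsaid --out-dir cls
emrminer evaluate --results cls/results_nsaid.csv --gold sim/gold.csv \
    --category nsaid --corpus sim/corpus.csv --out-dir eval
```

prints

```
wrote 3170 rows for 50 patients to sim

category: nsaid
stage         terms  cases  repeats
inclusion        46    245      308
exclusion        28     41       41
reinclusion       6      6        6
final                  210

category: nsaid
tp 210  fp 0  fn 0  tn 2960  (total 3170)
sensitivity  100.0
specificity  100.0
ppv          100.0
npv          100.0
f_value      100.0
```

Reading the stage table: the 46 inclusion words were found 308 times in 245
distinct rows; the exclusion combinations removed 41 of those rows, and 6
were rescued by reinclusion, leaving 210 final cases
(245 − 41 + 6 = 210). Because the dictionaries here are the generator's own
complete ones, the final cases equal the gold positives exactly — all five
metrics are 100. With curated dictionaries on real data the `evaluate` step
additionally writes a discrepancies CSV listing every false positive and
false negative with its full note text for manual re-review.

The same operations are available as a library:

```python
>>> import emrminer as em
>>> ct = em.ConfusionTable(tp=1128, fp=19, fn=2, tn=16410)
>>> em.metrics(ct, rounding={"sensitivity": 2, "specificity": 2, "f_value": 1}).as_dict()
{'sensitivity': 99.82, 'specificity': 99.88, 'ppv': 98.3, 'npv': 99.99, 'f_value': 99.0}
```

(the F value uses the 3-decimal input-rounding convention by default; pass
`f_input_rounding=None` for the exact harmonic mean).

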