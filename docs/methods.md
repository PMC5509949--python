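# Methods

## Classification model

A *case* is one row of an EMR export: the unit classified is the row, never
the patient. For a category with inclusion set I, exclusion set E and
reinclusion set R (each the set of row ids matched by the corresponding
dictionary), the final classification is

    final = (I \ E) ∪ R.

The algebra has two consequences worth stating. First, rows matched by the
exclusion dictionary but not the inclusion dictionary are inert: subtracting
them changes nothing, so the exclusion search may run over the full corpus
without affecting results (we do, for simpler provenance reporting). Second,
a row matching all three stages ends positive — reinclusion deliberately wins,
since its purpose is to rescue rows the exclusion stage removed wrongly.

The reinclusion search is scoped, by default, to the rows the exclusion stage
matched, because reinclusion combinations are curated from the exclusion
output and only make sense there; `reinclusion_scope="full"` lifts the
restriction, at the cost of possibly reincluding rows that were never
excluded (the library warns when R ⊄ E).

Useful identities for auditing stage counts: with E ⊆ I, R ⊆ E and
R ∩ (I∖E) = ∅, |final| = |I| − |E| + |R|. The `StageSummary` reports, per
stage, the dictionary size, the number of distinct rows matched ("cases") and
the total number of hits ("repeats"); n_cases ≤ n_times always.

## Matching semantics

Text is tokenized into maximal runs of letters and digits plus a configurable
set of in-token characters, default `{/, +, -}` — clinical shorthand such as
"c/s" or "F+" must survive as single tokens. Case is folded by default.
Underscore and all other punctuation separate tokens.

A dictionary term is the token sequence its line tokenizes to. A term matches
where its tokens occur in order with at most `max_gap` intervening tokens
between consecutive term tokens; the default gap of 0 (contiguous phrase) is
the strictest, most auditable reading, and all distinct (start, end) spans
are reported, including overlapping ones. Matching is token-exact: "colic"
does not match inside "colicky". There is deliberately no stemming, stop-word
removal, or fuzzy matching — spelling and abbreviation variation belongs in
the inclusion dictionary, where each variant is an explicit, reviewable
entry. This is what keeps the method's behaviour fully explainable to a
clinical auditor.

## Evaluation conventions

Metrics are percentages derived from the 2×2 table; a metric whose
denominator is zero is reported as absent (`None`), never as 0 or 100, so
degenerate categories cannot silently pollute aggregate summaries.

Two reporting conventions are explicit options because published practice
varies:

* **Rounding** is half-away-from-zero (spreadsheet convention), not banker's
  rounding; display precision is configurable per metric (the bundled
  profiles use 1 or 2 decimals).
* **F-value input rounding**: `metrics` computes F from PPV and sensitivity
  proportions first rounded to 3 decimals by default, reproducing the common
  printed convention (0.983 and 0.998 give F = 99.0 where exact inputs give
  99.1). `f_input_rounding=None` gives the exact harmonic mean.

## Synthetic corpus generator

The generator stands in for proprietary practice-management exports. It
emulates the structural features the method depends on and assigns ground
truth by construction:

* **Volume structure.** Rows per patient are log-normal, parameterized by a
  target median (14) and mean (52.3), truncated at 1 — a heavy right tail in
  which a few patients contribute hundreds of rows. μ = ln(median) and
  σ² = 2·ln(mean/median) follow from the log-normal moment formulas.
* **Text structure.** Notes are template-based: a filler clause from a fixed
  clinical vocabulary plus, per category, a positive-mention clause
  ("administered <drug> iv", "dispensed <drug> to client", ...), a negation
  clause ("no <drug> given", "<drug> not option", "<drug> in future",
  "owner declined <drug>", ...), or a rescue clause ("no <x> given but <y>
  dispensed"). Template text mirrors the tendency of clinicians to reuse the
  same word combinations; hypothetical/future-use negations are included so
  the exclusion/reinclusion machinery is genuinely exercised.
* **Lexical variation.** Each mention is emitted as the canonical word, an
  edit-distance-1 misspelling (one substitution, deletion, transposition or
  insertion), or a truncation-style abbreviation, at configurable rates
  (defaults 0.10 and 0.08). Variants are collision-checked globally so a
  variant of one category can never act as an inclusion word of another, or
  collide with filler/template vocabulary.
* **Prevalence structure.** Per-row category prevalences default to
  6.4%, 1.3%, 0.13% and 0.04% — spanning the orders of magnitude from a
  common drug class down to a rare diagnosis. Positivity is an independent
  Bernoulli draw per row and category, so observed rates converge to the
  configured ones. A row can be positive for several categories (multi-tag
  gold labels). The negation rate (default 0.012 per row and category)
  controls gold-negative mentions; about 1% of no-content rows are empty,
  exercising empty-text handling in denominators.

Because every emitted variant, negation clause and rescue clause is recorded,
the generator returns the *true* dictionaries, and classifying its corpus
with them reproduces the gold labels exactly. Clause templates were designed
so that no exclusion or reinclusion combination can arise by accident across
clause boundaries under contiguous matching — this is what makes exact
recovery a theorem of the construction rather than a statistical tendency,
and it is verified empirically on ≥10,000-row corpora across five seeds.

**What the generator does not emulate:** real vocabulary coverage (its
clinical lexicon is a few dozen words), free word order inside clauses,
context-dependent negation ("if the colic returns, give bute"), or
inter-category textual correlation. Passing the end-to-end tests therefore
shows the *machinery* (search, set algebra, bookkeeping, evaluation) is
correct, not that any particular curated dictionary is complete on real data
— dictionary completeness is exactly the manual effort the workflow spends
its human time on.

## Numerical and design choices

* Row ids are 1-based file positions by default; an explicit row-number
  column overrides them. All outputs carry the original row id verbatim.
* CSV I/O is RFC-4180 via the standard library so note text (including
  embedded commas and newlines) round-trips byte-identically; empty notes are
  retained and classify as negative. Unparseable dates warn and are dropped
  (classification never uses dates).
* Gold tags: any non-empty cell is a positive tag; the tag string itself is
  not interpreted.
* KWIC context window defaults to 60 characters each side; 0 keeps the whole
  row, in which case pre + match + post reconstructs the row text exactly.
* Hits within a row are ordered by token position, then term; ties are
  therefore deterministic, and repeated runs produce byte-identical outputs.
* Inclusion terms may be multi-word (a strict generalization of the
  single-word curation practice; the default behaviour is unchanged).
* Only the simulator consumes randomness, from one explicit seed;
  classification and evaluation are fully deterministic.

## Problem sizes used in the automated checks

The test suite exercises: exact gold recovery on five ~20,000-row corpora
(400 patients each, seeds 1–5); matcher equivalence against exhaustive window
enumeration on all binary-alphabet corpora up to 12 tokens with all terms up
to 3 tokens and gaps 0–2; ablation monotonicity over 100 random generator
configurations (~300 rows each); and metric equivalence against brute-force
recounts on 1,000 random contingency tables. These sizes were chosen to make
the checks decisive while keeping the whole suite under a minute.

## Known limitations

* No linguistic NLP: no parsing, POS tagging, or learned negation detection;
  the method's accuracy is bounded by dictionary curation effort.
* No patient-level rollup, episode grouping, prevalence estimation or
  confidence intervals — the tool classifies rows and scores the
  classification, nothing more.
* The matcher enumerates all embeddings per (start, end) pair; with very
  large `max_gap` and highly repetitive tokens its worst case is exponential
  in term length (terms are short in practice; the default gap is 0).
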