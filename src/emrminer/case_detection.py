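"""The three-stage classification algebra.

Classification of one category proceeds row-wise in three stages:

1. **inclusion** — every row containing any inclusion word is a candidate;
2. **exclusion** — rows containing an exclusion word combination are removed
   from the candidates;
3. **reinclusion** — rows containing a reinclusion combination (searched, by
   default, only among the rows the exclusion stage matched) are added back.

The final case set is ``(inclusion ∖ exclusion) ∪ reinclusion``.  All three
stages operate on row ids, so a row matching inclusion, exclusion *and*
reinclusion terms ends positive — reinclusion exists precisely to rescue such
rows.  Alongside the sets, a :class:`StageSummary` records the per-stage
bookkeeping (terms in the dictionary, distinct rows matched, total hits) that
an auditor needs to follow the data flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .corpus_io import Corpus
from .dictionaries import CategoryDictionarySet, StageDictionary
from .errors import IntegrityError
from .text_engine import (
    DEFAULT_TOKENIZER,
    MatchResult,
    TokenizerConfig,
    kwic_search,
)

__all__ = [
    "CaseSet",
    "StageCounts",
    "StageSummary",
    "ClassificationResult",
    "stage_cases",
    "combine",
    "classify",
]

_FINAL = "final"


@dataclass(frozen=True)
class CaseSet:
    """The rows classified positive for a category at one stage (or finally)."""

    category: str
    stage: str
    row_ids: frozenset[int]

    def __len__(self) -> int:
        return len(self.row_ids)

    @classmethod
    def empty(cls, category: str, stage: str) -> "CaseSet":
        return cls(category=category, stage=stage, row_ids=frozenset())


@dataclass(frozen=True)
class StageCounts:
    n_terms: int
    n_times: int
    n_cases: int


@dataclass(frozen=True)
class StageSummary:
    """Per-stage bookkeeping: dictionary size, hit totals ("repeats"), and
    distinct rows, plus the final case count."""

    category: str
    inclusion: StageCounts
    exclusion: StageCounts
    reinclusion: StageCounts
    final_cases: int

    def rows(self) -> list[tuple[str, int, int, int]]:
        """(stage, terms, cases, repeats) rows for tabular reports."""
        return [
            (s, c.n_terms, c.n_cases, c.n_times)
            for s, c in (
                ("inclusion", self.inclusion),
                ("exclusion", self.exclusion),
                ("reinclusion", self.reinclusion),
            )
        ]

    def format(self) -> str:
        lines = [f"category: {self.category}", f"{'stage':<12}{'terms':>7}{'cases':>7}{'repeats':>9}"]
        for stage, terms, cases, times in self.rows():
            lines.append(f"{stage:<12}{terms:>7}{cases:>7}{times:>9}")
        lines.append(f"{'final':<12}{'':>7}{self.final_cases:>7}")
        return "\n".join(lines)


def stage_cases(
    corpus: Corpus,
    stage_dict: StageDictionary,
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
    max_gap: int = 0,
    scope: CaseSet | None = None,
) -> tuple[CaseSet, MatchResult]:
    """Run one dictionary stage: rows with ≥1 hit for any term of the stage.

    ``scope`` restricts the search to those rows (used for the reinclusion
    stage, whose candidates are drawn from the exclusion output).
    """
    if scope is not None:
        outside = set(scope.row_ids) - set(corpus.row_ids)
        if outside:
            raise IntegrityError(
                f"scope rows absent from corpus: {sorted(outside)[:5]}"
            )
    if not stage_dict.terms:
        empty = CaseSet.empty(stage_dict.category, stage_dict.stage)
        return empty, MatchResult.from_hits([])
    result = kwic_search(
        corpus,
        stage_dict.terms,
        config=tokenizer,
        max_gap=max_gap,
        window=60,
        row_ids=scope.row_ids if scope is not None else None,
    )
    case_set = CaseSet(
        category=stage_dict.category, stage=stage_dict.stage, row_ids=result.row_ids
    )
    return case_set, result


def combine(inclusion: CaseSet, exclusion: CaseSet, reinclusion: CaseSet) -> CaseSet:
    """``final = (inclusion ∖ exclusion) ∪ reinclusion``.

    Warns when reinclusion rows are not a subset of exclusion rows: the
    workflow derives reinclusions from the exclusion output, so stray rows
    usually mean the reinclusion search ran with the wrong scope.
    """
    if not (inclusion.category == exclusion.category == reinclusion.category):
        raise ValueError(
            "combine requires case sets of one category, got "
            f"{inclusion.category!r}/{exclusion.category!r}/{reinclusion.category!r}"
        )
    if not reinclusion.row_ids <= exclusion.row_ids:
        warnings.warn(
            f"{inclusion.category}: {len(reinclusion.row_ids - exclusion.row_ids)} "
            "reinclusion rows were never excluded"
        )
    final = (inclusion.row_ids - exclusion.row_ids) | reinclusion.row_ids
    return CaseSet(category=inclusion.category, stage=_FINAL, row_ids=frozenset(final))


@dataclass(frozen=True)
class ClassificationResult:
    """Everything one category's classification run produced: the final case
    set, the per-stage sets and match results, and the summary counts."""

    final: CaseSet
    summary: StageSummary
    stage_sets: dict[str, CaseSet]
    stage_matches: dict[str, MatchResult]


def classify(
    corpus: Corpus,
    dict_set: CategoryDictionarySet,
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
    max_gap: int = 0,
    reinclusion_scope: str = "exclusion",
) -> ClassificationResult:
    """Run the full three-stage classification for one category.

    ``reinclusion_scope`` is ``"exclusion"`` (search reinclusion combinations
    only among rows the exclusion stage matched — the default workflow) or
    ``"full"`` (search the whole corpus).
    """
    if reinclusion_scope not in ("exclusion", "full"):
        raise ValueError(f"unknown reinclusion scope {reinclusion_scope!r}")
    inc_set, inc_match = stage_cases(corpus, dict_set.inclusion, tokenizer, max_gap)
    exc_set, exc_match = stage_cases(corpus, dict_set.exclusion, tokenizer, max_gap)
    rein_scope = exc_set if reinclusion_scope == "exclusion" else None
    rein_set, rein_match = stage_cases(
        corpus, dict_set.reinclusion, tokenizer, max_gap, scope=rein_scope
    )
    final = combine(inc_set, exc_set, rein_set)
    summary = StageSummary(
        category=dict_set.category,
        inclusion=StageCounts(len(dict_set.inclusion), inc_match.n_times, inc_match.n_cases),
        exclusion=StageCounts(len(dict_set.exclusion), exc_match.n_times, exc_match.n_cases),
        reinclusion=StageCounts(len(dict_set.reinclusion), rein_match.n_times, rein_match.n_cases),
        final_cases=len(final),
    )
    return ClassificationResult(
        final=final,
        summary=summary,
        stage_sets={"inclusion": inc_set, "exclusion": exc_set, "reinclusion": rein_set},
        stage_matches={"inclusion": inc_match, "exclusion": exc_match, "reinclusion": rein_match},
    )
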