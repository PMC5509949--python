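"""Tokenization, word frequencies, and keyword-in-context search.

The search model is deliberately simple and auditable: text is split into
tokens (maximal runs of letters/digits plus a configurable set of in-token
characters such as ``/ + -``, which clinical shorthand like "c/s" or "F+"
requires); dictionary terms are token sequences; a term matches where its
tokens occur in order with at most ``max_gap`` intervening tokens between
consecutive term tokens (default 0 — a contiguous phrase).

Matching is token-exact: "colic" does not match inside "colicky".  There is
no stemming, stop-word removal, or spelling correction — spelling and
abbreviation variation is handled by enumerating variants in the
dictionaries, which keeps every match traceable to a curated term.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from .corpus_io import Corpus

__all__ = [
    "TokenizerConfig",
    "DEFAULT_TOKENIZER",
    "Term",
    "FrequencyEntry",
    "KwicHit",
    "MatchResult",
    "tokenize",
    "tokenize_spans",
    "word_frequencies",
    "write_frequencies",
    "match_term",
    "kwic_search",
]


@dataclass(frozen=True)
class TokenizerConfig:
    """Pure-function tokenization settings; hashable so corpora can cache
    their token streams per configuration."""

    case_fold: bool = True
    intra_token_chars: frozenset[str] = frozenset("/+-")
    strip_digits_only_tokens: bool = False


DEFAULT_TOKENIZER = TokenizerConfig()


@lru_cache(maxsize=32)
def _token_pattern(intra_token_chars: frozenset[str]) -> re.Pattern[str]:
    extra = "".join(re.escape(c) for c in sorted(intra_token_chars))
    # [^\W_] = unicode letter or digit; underscore is a separator
    return re.compile(rf"(?:[^\W_]|[{extra}])+" if extra else r"[^\W_]+")


def tokenize_spans(text: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> list[tuple[str, int, int]]:
    """Tokenize, returning ``(token, start_char, end_char)`` triples."""
    out = []
    for m in _token_pattern(config.intra_token_chars).finditer(text):
        tok = m.group()
        if config.case_fold:
            tok = tok.casefold()
        if config.strip_digits_only_tokens and tok.isdigit():
            continue
        out.append((tok, m.start(), m.end()))
    return out


def tokenize(text: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> list[str]:
    """Tokenize free text into an ordered list of tokens."""
    return [tok for tok, _, _ in tokenize_spans(text, config)]


@dataclass(frozen=True)
class Term:
    """A dictionary entry: a single word (1 token) or a combination of words
    (≥2 tokens), tokenized with the same tokenizer as the corpus."""

    tokens: tuple[str, ...]
    raw: str

    def __post_init__(self) -> None:
        if not self.tokens or any(not t for t in self.tokens):
            raise ValueError(f"term {self.raw!r} has empty token sequence")

    @classmethod
    def from_string(cls, raw: str, config: TokenizerConfig = DEFAULT_TOKENIZER) -> "Term":
        return cls(tokens=tuple(tokenize(raw, config)), raw=raw)

    def __str__(self) -> str:  # pragma: no cover
        return self.raw


@dataclass(frozen=True)
class FrequencyEntry:
    word: str
    n_occurrences: int
    n_rows: int


def word_frequencies(
    corpus: Corpus, config: TokenizerConfig = DEFAULT_TOKENIZER
) -> list[FrequencyEntry]:
    """The corpus word-frequency list — the surface from which inclusion
    dictionaries are curated.  Sorted by occurrence count descending, then
    alphabetically."""
    occurrences: Counter[str] = Counter()
    row_counts: Counter[str] = Counter()
    for tokens in _corpus_tokens(corpus, config):
        occurrences.update(tok for tok, _, _ in tokens)
        row_counts.update({tok for tok, _, _ in tokens})
    entries = [
        FrequencyEntry(word=w, n_occurrences=n, n_rows=row_counts[w])
        for w, n in occurrences.items()
    ]
    entries.sort(key=lambda e: (-e.n_occurrences, e.word))
    return entries


def write_frequencies(entries: Iterable[FrequencyEntry], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["word", "n_occurrences", "n_rows"])
        for e in entries:
            writer.writerow([e.word, e.n_occurrences, e.n_rows])


def match_term(
    tokens: Sequence[str], term: Term, max_gap: int = 0
) -> list[tuple[int, int]]:
    """All positions where ``term`` matches ``tokens``.

    A match is the term's tokens in order with at most ``max_gap`` intervening
    tokens between consecutive term tokens.  Returns distinct
    ``(start_index, end_index)`` pairs (inclusive token indices), sorted
    left-to-right; overlapping matches are all reported.
    """
    tt = term.tokens
    n = len(tokens)
    found: set[tuple[int, int]] = set()

    def walk(start: int, last: int, k: int) -> None:
        if k == len(tt):
            found.add((start, last))
            return
        for j in range(last + 1, min(n, last + max_gap + 2)):
            if tokens[j] == tt[k]:
                walk(start, j, k + 1)

    for i in range(n):
        if tokens[i] == tt[0]:
            walk(i, i, 1)
    return sorted(found)


@dataclass(frozen=True)
class KwicHit:
    """One keyword-in-context line: a matched term with the text before and
    after it, traceable to its source row."""

    row_id: int
    patient_id: str
    pre_context: str
    matched_text: str
    post_context: str
    term: Term
    token_start: int
    token_end: int


@dataclass(frozen=True)
class MatchResult:
    """Search outcome with the times-vs-cases distinction: ``n_times`` counts
    every hit, ``n_cases`` counts distinct rows with at least one hit."""

    hits: tuple[KwicHit, ...]
    n_times: int
    n_cases: int

    @classmethod
    def from_hits(cls, hits: Sequence[KwicHit]) -> "MatchResult":
        return cls(
            hits=tuple(hits),
            n_times=len(hits),
            n_cases=len({h.row_id for h in hits}),
        )

    @property
    def row_ids(self) -> frozenset[int]:
        return frozenset(h.row_id for h in self.hits)


def _corpus_tokens(
    corpus: Corpus, config: TokenizerConfig
) -> list[list[tuple[str, int, int]]]:
    # token streams are cached on the corpus per tokenizer config
    cached = corpus._token_cache.get(config)
    if cached is None:
        cached = [tokenize_spans(row.text, config) for row in corpus.rows]
        corpus._token_cache[config] = cached
    return cached


def kwic_search(
    corpus: Corpus,
    terms: Iterable[Term],
    config: TokenizerConfig = DEFAULT_TOKENIZER,
    max_gap: int = 0,
    window: int = 60,
    row_ids: frozenset[int] | set[int] | None = None,
) -> MatchResult:
    """Search every row (or the ``row_ids`` subset) for every term.

    Contexts are truncated to ``window`` characters each side; ``window=0``
    keeps the whole row, so pre + match + post reconstructs the row text.
    """
    term_list = list(terms)
    first_tokens = {t.tokens[0] for t in term_list}
    hits: list[KwicHit] = []
    all_tokens = _corpus_tokens(corpus, config)
    for row, spans in zip(corpus.rows, all_tokens):
        if row_ids is not None and row.row_id not in row_ids:
            continue
        token_set = {tok for tok, _, _ in spans}
        if not token_set & first_tokens:
            continue
        tokens = [tok for tok, _, _ in spans]
        row_hits: list[tuple[int, int, str, Term]] = []
        for term in term_list:
            if term.tokens[0] not in token_set:
                continue
            for s, e in match_term(tokens, term, max_gap):
                row_hits.append((s, e, term.raw, term))
        row_hits.sort(key=lambda h: (h[0], h[1], h[2]))
        for s, e, _, term in row_hits:
            mstart, mend = spans[s][1], spans[e][2]
            pre, post = row.text[:mstart], row.text[mend:]
            if window > 0:
                pre, post = pre[-window:], post[:window]
            hits.append(
                KwicHit(
                    row_id=row.row_id,
                    patient_id=row.patient_id,
                    pre_context=pre,
                    matched_text=row.text[mstart:mend],
                    post_context=post,
                    term=term,
                    token_start=s,
                    token_end=e,
                )
            )
    return MatchResult.from_hits(hits)
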