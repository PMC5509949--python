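"""Per-category inclusion / exclusion / reinclusion dictionaries.

Each category is classified by a triple of curated term lists:

* **inclusion** — words (typically single tokens, including misspellings and
  abbreviations) whose presence flags a row as a candidate positive;
* **exclusion** — word combinations that identify false-positive candidates
  (negations, hypothetical or future use) to be removed;
* **reinclusion** — word combinations that rescue rows wrongly removed by the
  exclusion stage.

Dictionary files are plain text, one term per line; ``#`` starts a comment
and blank lines are ignored.  A YAML config maps category → stage → file so a
classification run can cover any number of categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError
from .text_engine import DEFAULT_TOKENIZER, Term, TokenizerConfig

__all__ = [
    "STAGES",
    "StageDictionary",
    "CategoryDictionarySet",
    "load_stage_file",
    "load_dictionary_set",
    "load_config",
    "save_stage_file",
    "save_dictionary_set",
    "validate",
]

STAGES = ("inclusion", "exclusion", "reinclusion")


@dataclass(frozen=True)
class StageDictionary:
    category: str
    stage: str
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        seen = set()
        for t in self.terms:
            if t.tokens in seen:
                raise ValueError(f"duplicate term {t.raw!r} in {self.category}/{self.stage}")
            seen.add(t.tokens)

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def empty(cls, category: str, stage: str) -> "StageDictionary":
        return cls(category=category, stage=stage, terms=())


@dataclass(frozen=True)
class CategoryDictionarySet:
    """The full dictionary triple for one category."""

    category: str
    inclusion: StageDictionary
    exclusion: StageDictionary
    reinclusion: StageDictionary

    def __post_init__(self) -> None:
        for stage_dict in (self.inclusion, self.exclusion, self.reinclusion):
            if stage_dict.category != self.category:
                raise ValueError(
                    f"stage dictionary category {stage_dict.category!r} != {self.category!r}"
                )

    def stage(self, name: str) -> StageDictionary:
        return getattr(self, name)


def load_stage_file(
    path, category: str, stage: str, tokenizer: TokenizerConfig = DEFAULT_TOKENIZER
) -> StageDictionary:
    """Load one term-list file.  Duplicate terms (same token sequence) are
    collapsed with a warning; a line that tokenizes to nothing is an error
    naming the line."""
    path = Path(path)
    terms: list[Term] = []
    seen: set[tuple[str, ...]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                term = Term.from_string(stripped, tokenizer)
            except ValueError as exc:
                raise ConfigurationError(
                    f"{path}:{lineno}: line {stripped!r} tokenizes to nothing"
                ) from exc
            if term.tokens in seen:
                warnings.warn(f"{path}:{lineno}: duplicate term {stripped!r} collapsed")
                continue
            seen.add(term.tokens)
            terms.append(term)
    return StageDictionary(category=category, stage=stage, terms=tuple(terms))


def load_config(path) -> dict[str, dict[str, str]]:
    """Load a YAML config mapping category → stage → term-file path.  Paths
    are resolved relative to the config file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected mapping category -> stage -> file")
    out: dict[str, dict[str, str]] = {}
    for category, stages in raw.items():
        if not isinstance(stages, dict):
            raise ConfigurationError(f"{path}: category {category!r} must map stages to files")
        bad = set(stages) - set(STAGES)
        if bad:
            raise ConfigurationError(f"{path}: unknown stages {sorted(bad)} for {category!r}")
        out[str(category)] = {
            stage: str((path.parent / p).resolve()) for stage, p in stages.items()
        }
    return out


def load_dictionary_set(
    config: Mapping[str, str] | str | Path,
    category: str,
    tokenizer: TokenizerConfig = DEFAULT_TOKENIZER,
) -> CategoryDictionarySet:
    """Load the dictionary triple for one category.

    ``config`` is either a mapping stage → file path, or a path to a YAML
    config covering several categories.  The inclusion file is required;
    exclusion and reinclusion are optional (empty when absent).
    """
    if isinstance(config, (str, Path)):
        table = load_config(config)
        if category not in table:
            raise ConfigurationError(f"category {category!r} not in config {config}")
        mapping: Mapping[str, str] = table[category]
    else:
        mapping = config
    if "inclusion" not in mapping:
        raise ConfigurationError(f"category {category!r}: no inclusion dictionary configured")
    inclusion_path = Path(mapping["inclusion"])
    if not inclusion_path.exists():
        raise ConfigurationError(f"inclusion dictionary not found: {inclusion_path}")
    stages = {}
    for stage in STAGES:
        p = mapping.get(stage)
        if p is None:
            stages[stage] = StageDictionary.empty(category, stage)
        else:
            stages[stage] = load_stage_file(p, category, stage, tokenizer)
    return CategoryDictionarySet(category=category, **stages)


def save_stage_file(stage_dict: StageDictionary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in stage_dict.terms:
            fh.write(term.raw + "\n")


def save_dictionary_set(dict_set: CategoryDictionarySet, directory) -> dict[str, str]:
    """Write the three stage files into ``directory`` and return the stage →
    path mapping (the shape ``load_dictionary_set`` accepts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mapping = {}
    for stage in STAGES:
        path = directory / f"{dict_set.category}.{stage}.txt"
        save_stage_file(dict_set.stage(stage), path)
        mapping[stage] = str(path)
    return mapping


def _is_subsequence(needle: tuple[str, ...], haystack: tuple[str, ...]) -> bool:
    it = iter(haystack)
    return all(tok in it for tok in needle)


def validate(dict_set: CategoryDictionarySet) -> list[str]:
    """Curation lint.  Returns warnings, never raises: the workflow is
    permissive, but these patterns usually indicate a curation slip.

    * an exclusion combination containing no inclusion term as a subsequence
      can never coincide with the wording that made the row a candidate;
    * a reinclusion combination identical to an exclusion combination
      re-admits exactly what it removed;
    * reinclusions with an empty exclusion stage have nothing to rescue
      (reinclusion candidates are drawn from the exclusion output).
    """
    warnings_out: list[str] = []
    inclusion_tokens = [t.tokens for t in dict_set.inclusion.terms]
    for ex in dict_set.exclusion.terms:
        if not any(_is_subsequence(inc, ex.tokens) for inc in inclusion_tokens):
            warnings_out.append(
                f"{dict_set.category}: exclusion term {ex.raw!r} contains no inclusion word; "
                "it can never overlap an inclusion match"
            )
    exclusion_token_set = {t.tokens for t in dict_set.exclusion.terms}
    for re_term in dict_set.reinclusion.terms:
        if re_term.tokens in exclusion_token_set:
            warnings_out.append(
                f"{dict_set.category}: reinclusion term {re_term.raw!r} is identical to an "
                "exclusion term"
            )
    if dict_set.reinclusion.terms and not dict_set.exclusion.terms:
        warnings_out.append(
            f"{dict_set.category}: reinclusion dictionary present but exclusion is empty"
        )
    return warnings_out
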