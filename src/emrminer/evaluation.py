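"""Diagnostic-test evaluation against gold-standard manual labels.

A classifier's final case set for one category is scored against the manual
row-by-row classification with a two-by-two contingency table and the usual
percent metrics:

    sensitivity = 100·TP/(TP+FN)      specificity = 100·TN/(TN+FP)
    PPV         = 100·TP/(TP+FP)      NPV         = 100·TN/(TN+FN)
    F           = 100·2·p·s/(p+s)     with p, s the PPV and sensitivity
                                      expressed as proportions

Two reporting conventions matter enough to be explicit options.  First,
rounding is half-away-from-zero (spreadsheet style), not banker's rounding.
Second, the F value may be computed from PPV/sensitivity proportions that
were themselves first rounded (3 decimals by default, the convention of the
study this tool reproduces: 0.983 and 0.998 give F = 99.0, while unrounded
inputs give 99.1); pass ``f_input_rounding=None`` for the exact value.

Metrics with a zero denominator are *absent* (``None``), never silently 0 or
100 — substituting a number corrupts aggregate reporting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .case_detection import CaseSet
from .corpus_io import Corpus, GoldLabels
from .errors import IntegrityError

__all__ = [
    "ConfusionTable",
    "MetricsReport",
    "Discrepancy",
    "confusion",
    "metrics",
    "f_measure",
    "discrepancy_report",
    "write_discrepancies",
    "ABSTRACT_ROUNDING",
    "TABLE_ROUNDING",
]

#: Two-decimal sensitivity/specificity/NPV, one-decimal PPV and F — the mix
#: used in the study abstract this tool reproduces.
ABSTRACT_ROUNDING: Mapping[str, int] = {
    "sensitivity": 2,
    "specificity": 2,
    "ppv": 1,
    "npv": 2,
    "f_value": 1,
}
#: One decimal everywhere (summary-table style).
TABLE_ROUNDING = 1

_METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f_value")


@dataclass(frozen=True)
class ConfusionTable:
    """Two-by-two contingency table of predicted vs gold classification."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise IntegrityError(f"negative confusion cell in {self}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Percent metrics; ``None`` marks a metric undefined for this table."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f_value: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in _METRIC_NAMES}

    def format(self) -> str:
        parts = []
        for name, value in self.as_dict().items():
            parts.append(f"{name:<12} {'—' if value is None else value}")
        return "\n".join(parts)


def confusion(
    predicted: CaseSet, gold: GoldLabels, category: str, total_rows: int
) -> ConfusionTable:
    """Cross-tabulate a predicted case set against the gold positives for
    ``category``; ``total_rows`` is the corpus size (TN is its remainder)."""
    gold_pos = gold.positives(category)
    pred = predicted.row_ids
    tp = len(pred & gold_pos)
    fp = len(pred - gold_pos)
    fn = len(gold_pos - pred)
    tn = total_rows - tp - fp - fn
    if tn < 0:
        raise IntegrityError(
            f"total_rows={total_rows} smaller than tp+fp+fn={tp + fp + fn}"
        )
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _round_half_away(value: float, decimals: int) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def f_measure(ppv_prop: float, sens_prop: float) -> float:
    """Harmonic mean of PPV and sensitivity proportions, as a percentage."""
    if ppv_prop + sens_prop == 0:
        raise ZeroDivisionError("f_measure undefined when both proportions are 0")
    return 100.0 * 2.0 * ppv_prop * sens_prop / (ppv_prop + sens_prop)


def metrics(
    ct: ConfusionTable,
    rounding: int | Mapping[str, int] | None = 2,
    f_input_rounding: int | None = 3,
) -> MetricsReport:
    """Derive the percent metrics from a confusion table.

    ``rounding`` is decimals for every metric (int), a per-metric mapping, or
    ``None`` for unrounded values.  ``f_input_rounding`` rounds the PPV and
    sensitivity *proportions* before the F harmonic mean (default 3 decimals);
    ``None`` uses them exactly.
    """
    props = {
        "sensitivity": _ratio(ct.tp, ct.tp + ct.fn),
        "specificity": _ratio(ct.tn, ct.tn + ct.fp),
        "ppv": _ratio(ct.tp, ct.tp + ct.fp),
        "npv": _ratio(ct.tn, ct.tn + ct.fn),
    }
    values: dict[str, float | None] = {
        name: None if p is None else 100.0 * p for name, p in props.items()
    }
    p, s = props["ppv"], props["sensitivity"]
    if p is None or s is None:
        values["f_value"] = None
    else:
        if f_input_rounding is not None:
            p = _round_half_away(p, f_input_rounding)
            s = _round_half_away(s, f_input_rounding)
        values["f_value"] = f_measure(p, s) if (p + s) > 0 else None
    if rounding is not None:
        for name, value in values.items():
            if value is None:
                continue
            nd = rounding if isinstance(rounding, int) else rounding.get(name, 2)
            values[name] = _round_half_away(value, nd)
    return MetricsReport(**values)


@dataclass(frozen=True)
class Discrepancy:
    """One disagreement between automated and manual classification, carrying
    the full note text for re-review."""

    row_id: int
    direction: str  # "fp" (predicted only) or "fn" (gold only)
    text: str


def discrepancy_report(
    predicted: CaseSet, gold: GoldLabels, corpus: Corpus, category: str
) -> list[Discrepancy]:
    """Every disagreement, once, sorted by row id — the sheet a reviewer reads
    to find whether the machine or the manual pass erred."""
    gold_pos = gold.positives(category)
    out = [
        Discrepancy(row_id=r, direction="fp", text=corpus[r].text)
        for r in predicted.row_ids - gold_pos
    ] + [
        Discrepancy(row_id=r, direction="fn", text=corpus[r].text)
        for r in gold_pos - predicted.row_ids
    ]
    out.sort(key=lambda d: d.row_id)
    return out


def write_discrepancies(discrepancies: list[Discrepancy], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_number", "direction", "text"])
        for d in discrepancies:
            writer.writerow([d.row_id, d.direction, d.text])
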