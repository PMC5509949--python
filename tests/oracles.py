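"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the implementation: the matcher oracle
enumerates every strictly increasing index tuple, and the metrics oracle
recounts explicit labeled rows with plain float arithmetic.
"""

from itertools import product


def brute_force_matches(tokens, term_tokens, max_gap):
    """All (start, end) pairs where term_tokens embed in order into tokens
    with at most max_gap intervening tokens between consecutive term tokens,
    found by exhaustive enumeration of candidate index tuples."""
    candidates = [
        [i for i, tok in enumerate(tokens) if tok == tt] for tt in term_tokens
    ]
    found = set()
    for idx in product(*candidates):
        if all(0 < idx[k + 1] - idx[k] <= max_gap + 1 for k in range(len(idx) - 1)):
            found.add((idx[0], idx[-1]))
    return sorted(found)


def osa_distance(a, b):
    """Optimal-string-alignment edit distance by dynamic programming:
    substitutions, insertions, deletions, and adjacent transpositions each
    count as one edit."""
    d = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a) + 1):
        d[i][0] = i
    for j in range(len(b) + 1):
        d[0][j] = j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[len(a)][len(b)]


def recount_metrics(labeled_rows):
    """Unrounded percent metrics from explicit (predicted, gold) boolean
    pairs; a metric with a zero denominator is None."""
    tp = sum(1 for p, g in labeled_rows if p and g)
    fp = sum(1 for p, g in labeled_rows if p and not g)
    fn = sum(1 for p, g in labeled_rows if not p and g)
    tn = sum(1 for p, g in labeled_rows if not p and not g)

    def pct(num, den):
        return None if den == 0 else 100.0 * num / den

    sens = pct(tp, tp + fn)
    spec = pct(tn, tn + fp)
    ppv = pct(tp, tp + fp)
    npv = pct(tn, tn + fn)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f = None
    else:
        p, s = ppv / 100.0, sens / 100.0
        f = 100.0 * 2 * p * s / (p + s)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f_value": f,
        "cells": (tp, fp, fn, tn),
    }
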