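"""Independent brute-force oracles used only by the tests.

These are written directly from first principles (exhaustive enumeration,
literal metric definitions) and deliberately share no code with the package
paths they check.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# Alignment oracles: enumerate every monotone matching of query rows to
# target columns and score it by hand.


def monotone_matchings(m: int, n: int):
    """Yield every set of (i, j) pairs strictly increasing in both coords."""

    def rec(i_min: int, j_min: int):
        yield ()
        for i in range(i_min, m):
            for j in range(j_min, n):
                for rest in rec(i + 1, j + 1):
                    yield ((i, j),) + rest

    yield from rec(0, 0)


def brute_global_score(S: np.ndarray, gap: float) -> float:
    """Best global score: matched cells pay S, every unmatched row and
    column position pays one linear gap."""
    m, n = S.shape
    best = -np.inf
    for match in monotone_matchings(m, n):
        total = sum(S[i, j] for i, j in match)
        total -= gap * (m + n - 2 * len(match))
        best = max(best, total)
    return best


def brute_local_score(S: np.ndarray, gap: float) -> float:
    """Best local score: gaps are paid only between consecutive matched
    cells; the empty alignment scores zero."""
    m, n = S.shape
    best = 0.0
    for match in monotone_matchings(m, n):
        if not match:
            continue
        total = sum(S[i, j] for i, j in match)
        for (i1, j1), (i2, j2) in zip(match, match[1:]):
            total -= gap * ((i2 - i1 - 1) + (j2 - j1 - 1))
        best = max(best, total)
    return best


# ---------------------------------------------------------------------------
# Metric oracles: literal definitions over (score, label) lists.


def brute_sensitivity(labels: Sequence[str]) -> float | None:
    """TPs before the first FP over total TPs, for one ranked label list."""
    total = labels.count("TP")
    if total == 0:
        return None
    count = 0
    for lab in labels:
        if lab == "FP":
            break
        if lab == "TP":
            count += 1
    return count / total


def brute_average_precision(labels: Sequence[str]) -> float | None:
    hits = 0
    precisions = []
    for rank, lab in enumerate(labels, start=1):
        if lab == "TP":
            hits += 1
            precisions.append(hits / rank)
    if not precisions:
        return None
    return sum(precisions) / len(precisions)


def brute_p_at_k(labels: Sequence[str], k: int) -> float:
    return sum(1 for lab in labels[:k] if lab == "TP") / k


def brute_weighted_pr(
    rows: Iterable[tuple[float, str, float]],
) -> tuple[list[float], list[float], float]:
    """Threshold sweep over distinct scores of (score, label, weight) rows."""
    rows = list(rows)
    total_tp = sum(w for _, lab, w in rows if lab == "TP")
    recalls, precisions = [], []
    for threshold in sorted({s for s, _, _ in rows}, reverse=True):
        tp = sum(w for s, lab, w in rows if lab == "TP" and s >= threshold)
        fp = sum(w for s, lab, w in rows if lab == "FP" and s >= threshold)
        precisions.append(tp / (tp + fp))
        recalls.append(tp / total_tp)
    order = np.argsort(recalls)
    r = np.array(recalls)[order]
    p = np.array(precisions)[order]
    aupr = float(np.trapezoid(p, r))
    return recalls, precisions, aupr
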