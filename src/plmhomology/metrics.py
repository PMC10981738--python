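"""Retrieval evaluation for homology search.

True/false-positive labeling follows the SCOP-style convention used in
structure-search benchmarking: at family level a hit is a TP iff query and
target share a family; at superfamily level iff they share a superfamily but
not a family; at fold level iff they share a fold but not a superfamily.
Hits from different folds are FPs; same-fold hits from an excluded stratum
are ignored (neither TP nor FP). Alternatively, with TM-score ground truth,
TP iff TM-score strictly exceeds 0.5. Self-hits are always ignored.

Metrics:

* per-query sensitivity up to the first FP, averaged over queries ("AUROC");
* precision-recall with counts weighted by reciprocal stratum size, and its
  trapezoidal area (AUPR);
* mean average precision, MAP = (1/Q) Σ_q AveP(q);
* precision at k, averaged over queries.

Queries with zero true positives carry no signal for rank quality and are
excluded from AUROC/MAP means (they are reported separately).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pipeline import SearchResult
from .records import FoldLabel

LEVELS = ("family", "superfamily", "fold", "tm_score")
TM_TP_THRESHOLD = 0.5


@dataclass(frozen=True)
class JudgedHit:
    target_id: str
    score: float
    label: str  # "TP" | "FP" | "ignore"


def judge_fold_pair(q: FoldLabel, t: FoldLabel, level: str) -> str:
    if q.fold != t.fold:
        return "FP"
    if level == "family":
        return "TP" if q.family == t.family else "ignore"
    if level == "superfamily":
        return (
            "TP"
            if q.superfamily == t.superfamily and q.family != t.family
            else "ignore"
        )
    if level == "fold":
        return "TP" if q.superfamily != t.superfamily else "ignore"
    raise ValueError(f"unknown level {level!r}")


def judge_results(
    results: Iterable[SearchResult],
    level: str,
    fold_labels: Mapping[str, FoldLabel] | None = None,
    tm_scores: Mapping[tuple[str, str], float] | None = None,
) -> dict[str, list[JudgedHit]]:
    """Label every hit of every query TP/FP/ignore at the given level."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    judged: dict[str, list[JudgedHit]] = {}
    for res in results:
        hits: list[JudgedHit] = []
        for h in res.hits:
            if h.is_self or h.target_id == res.query_id:
                hits.append(JudgedHit(h.target_id, h.similarity, "ignore"))
                continue
            if level == "tm_score":
                if tm_scores is None:
                    raise ValueError("tm_score level requires a TM-score table")
                key = (res.query_id, h.target_id)
                if key not in tm_scores:
                    raise KeyError(f"missing label for {key}")
                label = "TP" if tm_scores[key] > TM_TP_THRESHOLD else "FP"
            else:
                if fold_labels is None:
                    raise ValueError(f"{level} level requires fold labels")
                for pid in (res.query_id, h.target_id):
                    if pid not in fold_labels:
                        raise KeyError(f"missing label for {pid}")
                label = judge_fold_pair(
                    fold_labels[res.query_id], fold_labels[h.target_id], level
                )
            hits.append(JudgedHit(h.target_id, h.similarity, label))
        judged[res.query_id] = hits
    return judged


def _effective(hits: Sequence[JudgedHit]) -> list[JudgedHit]:
    """Drop ignores; within equal scores order FPs before TPs (conservative,
    deterministic treatment of ties across the TP/FP boundary)."""
    kept = [h for h in hits if h.label != "ignore"]
    return sorted(kept, key=lambda h: (-h.score, h.label != "FP", h.target_id))


def sensitivity_to_first_fp(hits: Sequence[JudgedHit]) -> float | None:
    """Fraction of the query's TPs ranked above its first FP.

    Returns None for queries without any TP (excluded from the mean).
    """
    eff = _effective(hits)
    total_tp = sum(1 for h in eff if h.label == "TP")
    if total_tp == 0:
        return None
    found = 0
    for h in eff:
        if h.label == "FP":
            break
        found += 1
    return found / total_tp


def auroc(judged: Mapping[str, Sequence[JudgedHit]]) -> float:
    """Mean sensitivity-to-first-FP over queries with at least one TP."""
    sens = [sensitivity_to_first_fp(hits) for hits in judged.values()]
    eligible = [s for s in sens if s is not None]
    if not eligible:
        raise ValueError("no queries with true positives")
    return float(np.mean(eligible))


def average_precision(hits: Sequence[JudgedHit]) -> float | None:
    eff = _effective(hits)
    precisions = []
    tp = 0
    for rank, h in enumerate(eff, start=1):
        if h.label == "TP":
            tp += 1
            precisions.append(tp / rank)
    if not precisions:
        return None
    return float(np.mean(precisions))


def mean_average_precision(judged: Mapping[str, Sequence[JudgedHit]]) -> float:
    """MAP over queries with at least one relevant target."""
    aps = [average_precision(hits) for hits in judged.values()]
    eligible = [a for a in aps if a is not None]
    if not eligible:
        raise ValueError("no queries with true positives")
    return float(np.mean(eligible))


def precision_at_k(judged: Mapping[str, Sequence[JudgedHit]], k: int) -> float:
    """Mean over queries of (# TPs in the top k) / k; short lists count
    their absent tail as non-relevant."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = []
    for hits in judged.values():
        eff = _effective(hits)
        vals.append(sum(1 for h in eff[:k] if h.label == "TP") / k)
    if not vals:
        raise ValueError("no queries")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Weighted precision-recall


def stratum_sizes(
    fold_labels: Mapping[str, FoldLabel], level: str
) -> dict[str, int]:
    """Number of target-set proteins in each protein's stratum at ``level``."""
    key = {
        "family": lambda l: l.family,
        "superfamily": lambda l: l.superfamily,
        "fold": lambda l: l.fold,
    }.get(level)
    if key is None:
        raise ValueError(f"unknown level {level!r}")
    counts = Counter(key(l) for l in fold_labels.values())
    return {pid: counts[key(l)] for pid, l in fold_labels.items()}


def weighted_pr_curve(
    judged: Mapping[str, Sequence[JudgedHit]],
    weights: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall swept over score thresholds, with per-query weights.

    Each judged pair of query q counts with weight ``weights[q]`` (typically
    the reciprocal of q's stratum size, so strata contribute linearly rather
    than quadratically with their size); uniform unit weights reduce to the
    classic PR curve. Returns (recall, precision, aupr); the area is the
    trapezoid over achieved points.
    """
    rows: list[tuple[float, str, float]] = []
    for q, hits in judged.items():
        w = 1.0 if weights is None else float(weights[q])
        for h in hits:
            if h.label != "ignore":
                rows.append((h.score, h.label, w))
    if not rows:
        raise ValueError("no judged pairs")
    total_tp = sum(w for _, lab, w in rows if lab == "TP")
    if total_tp == 0:
        raise ValueError("no true positives")
    # conservative tie order: FPs before TPs at equal score
    rows.sort(key=lambda r: (-r[0], r[1] != "FP"))
    recalls, precisions = [], []
    tp = fp = 0.0
    for _, lab, w in rows:
        if lab == "TP":
            tp += w
        else:
            fp += w
        precisions.append(tp / (tp + fp))
        recalls.append(tp / total_tp)
    recall = np.array(recalls)
    precision = np.array(precisions)
    aupr = float(np.trapezoid(precision, recall))
    return recall, precision, aupr


# ---------------------------------------------------------------------------
# Easy / remote homolog quadrants


def quadrant_analysis(
    pairs: Iterable[tuple[float, float, bool]],
    identity_threshold: float = 0.3,
    tm_threshold: float = TM_TP_THRESHOLD,
) -> dict[str, int]:
    """Classify (tm_score, sequence_identity, retrieved) triples.

    "Easy" homolog pairs have identity > 0.3 and TM > 0.5; "remote" homolog
    pairs have identity < 0.3 but TM > 0.5. Pairs at or below the TM
    threshold are not homologs and fall in neither quadrant. Counts of
    recalled and missed pairs per quadrant are returned.
    """
    counts = {
        "easy_recalled": 0,
        "easy_missed": 0,
        "remote_recalled": 0,
        "remote_missed": 0,
        "non_homolog": 0,
    }
    for tm, identity, retrieved in pairs:
        if tm <= tm_threshold:
            counts["non_homolog"] += 1
            continue
        quadrant = "easy" if identity > identity_threshold else "remote"
        counts[f"{quadrant}_{'recalled' if retrieved else 'missed'}"] += 1
    return counts


def metric_report(
    judged: Mapping[str, Sequence[JudgedHit]],
    ks: Sequence[int] = (1, 10),
    weights: Mapping[str, float] | None = None,
) -> dict:
    """Convenience bundle: AUROC, AUPR, MAP and P@K in one dictionary."""
    _, _, aupr = weighted_pr_curve(judged, weights)
    sens = {
        q: sensitivity_to_first_fp(hits) for q, hits in judged.items()
    }
    return {
        "auroc": auroc(judged),
        "aupr": aupr,
        "map": mean_average_precision(judged),
        "p_at_k": {k: precision_at_k(judged, k) for k in ks},
        "per_query_sensitivity": sens,
        "queries_without_tp": sorted(q for q, s in sens.items() if s is None),
    }
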