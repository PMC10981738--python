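"""Search orchestration: pre-filter, batch similarity, per-query ranking.

The full pipeline: (1) the clan pre-filter retains candidate query-target
pairs, (2) similarities are predicted in a batched pass over the candidate
set only (the full n × m matrix is computed only with ``prefilter="none"``),
(3) each query's hits are sorted by similarity and emitted separately.
Ties are broken by ascending target id so output is deterministic and
invariant to input ordering. Self-hits in all-vs-all searches are kept but
flagged; evaluation excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clanfilter import (
    CandidatePairSet,
    assign_clans,
    prefilter_pairs,
    prefilter_pairs_family,
)
from .records import ClanMap, DomainAnnotation
from .similarity import (
    BilinearModel,
    cos_similarity_matrix,
    ss_predictor_similarity_matrix,
)

METHODS = ("ss_predictor", "cos", "euclidean")
PREFILTERS = ("clan", "family", "none")


@dataclass(frozen=True)
class SearchConfig:
    method: str = "ss_predictor"
    prefilter: str = "clan"
    top_k: int | None = None  # None means all
    align_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.prefilter not in PREFILTERS:
            raise ValueError(f"unknown prefilter {self.prefilter!r}")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1 or None")
        if not 0.0 <= self.align_threshold <= 1.0:
            raise ValueError("align_threshold must be in [0, 1]")


@dataclass(frozen=True)
class SearchHit:
    target_id: str
    similarity: float
    rank: int
    provenance: str = "all_pairs"
    is_self: bool = False


@dataclass(frozen=True)
class SearchResult:
    query_id: str
    hits: tuple[SearchHit, ...]


def _candidate_pairs(
    query_ids: Sequence[str],
    target_ids: Sequence[str],
    config: SearchConfig,
    annotations: Mapping[str, DomainAnnotation] | None,
    clan_map: ClanMap | None,
) -> CandidatePairSet | None:
    if config.prefilter == "none":
        return None
    if annotations is None:
        raise ValueError("prefilter requires domain annotations")

    def ann_of(pid: str) -> DomainAnnotation:
        ann = annotations.get(pid)
        return ann if ann is not None else DomainAnnotation(pid, frozenset())

    q_ann = [ann_of(q) for q in query_ids]
    t_ann = [ann_of(t) for t in target_ids]
    if config.prefilter == "family":
        return prefilter_pairs_family(q_ann, t_ann)
    if clan_map is None:
        raise ValueError("clan prefilter requires a clan map")
    return prefilter_pairs(assign_clans(q_ann, clan_map), assign_clans(t_ann, clan_map))


def _score_block(
    method: str,
    model: BilinearModel | None,
    Z1: np.ndarray,
    Z2: np.ndarray,
) -> np.ndarray:
    if method == "ss_predictor":
        if model is None:
            raise ValueError("ss_predictor method requires a trained model")
        return ss_predictor_similarity_matrix(model, Z1, Z2)
    if method == "cos":
        return cos_similarity_matrix(Z1, Z2)
    # euclidean
    d2 = (
        np.sum(Z1**2, axis=1)[:, None]
        + np.sum(Z2**2, axis=1)[None, :]
        - 2.0 * Z1 @ Z2.T
    )
    return 1.0 / (np.sqrt(np.maximum(d2, 0.0)) + 1.0)


def search(
    query_ids: Sequence[str],
    target_ids: Sequence[str],
    pooled: Mapping[str, np.ndarray],
    model: BilinearModel | None = None,
    config: SearchConfig = SearchConfig(),
    annotations: Mapping[str, DomainAnnotation] | None = None,
    clan_map: ClanMap | None = None,
) -> list[SearchResult]:
    """Run the search and return one ranked result per query.

    ``pooled`` maps protein id to its pooled embedding. With a pre-filter
    active, similarity is evaluated only on retained pairs; the retain-all
    fallback guarantees every query gets at least one hit when targets exist.
    """
    for pid in list(query_ids) + list(target_ids):
        if pid not in pooled:
            raise KeyError(f"missing embedding for {pid}")
    target_ids = sorted(set(target_ids))
    t_index = {t: i for i, t in enumerate(target_ids)}
    Z2 = (
        np.stack([pooled[t] for t in target_ids])
        if target_ids
        else np.zeros((0, 1))
    )

    candidates = _candidate_pairs(query_ids, target_ids, config, annotations, clan_map)
    per_query: dict[str, list[tuple[int, str]]] = {}
    if candidates is not None:
        for (qq, t), prov in candidates.provenance.items():
            per_query.setdefault(qq, []).append((t_index[t], prov))
    results: list[SearchResult] = []
    for q in sorted(set(query_ids)):
        z1 = np.asarray(pooled[q], float)[None, :]
        if candidates is None:
            cols = list(range(len(target_ids)))
            provenance = ["all_pairs"] * len(cols)
        else:
            kept = sorted(per_query.get(q, []))
            cols = [c for c, _ in kept]
            provenance = [p for _, p in kept]
        if not cols:
            results.append(SearchResult(q, ()))
            continue
        sims = _score_block(config.method, model, z1, Z2[cols])[0]
        order = sorted(
            range(len(cols)), key=lambda k: (-sims[k], target_ids[cols[k]])
        )
        hits = []
        for rank, k in enumerate(order, start=1):
            tid = target_ids[cols[k]]
            hits.append(
                SearchHit(tid, float(sims[k]), rank, provenance[k], tid == q)
            )
        if config.top_k is not None:
            hits = hits[: config.top_k]
        results.append(SearchResult(q, tuple(hits)))
    return results


def all_vs_all(
    dataset_ids: Sequence[str],
    pooled: Mapping[str, np.ndarray],
    model: BilinearModel | None = None,
    config: SearchConfig = SearchConfig(),
    annotations: Mapping[str, DomainAnnotation] | None = None,
    clan_map: ClanMap | None = None,
) -> list[SearchResult]:
    """Search a dataset against itself; self-pairs are kept but flagged."""
    return search(
        dataset_ids, dataset_ids, pooled, model, config, annotations, clan_map
    )


def select_align_candidates(
    results: Iterable[SearchResult], threshold: float = 0.3
) -> list[tuple[str, str]]:
    """Pairs whose similarity strictly exceeds ``threshold``, in rank order."""
    out: list[tuple[str, str]] = []
    for res in results:
        for hit in res.hits:
            if hit.similarity > threshold:
                out.append((res.query_id, hit.target_id))
    return out


def rerank_by_alignment(
    results: Iterable[SearchResult], alignments: Iterable
) -> list[SearchResult]:
    """Re-sort each query's aligned hits by alignment score (descending,
    ties by ascending target id); hits that were not aligned — i.e. fell
    below the alignment threshold — are dropped from the reranked list."""
    results = list(results)
    known = {(r.query_id, h.target_id) for r in results for h in r.hits}
    score_of: dict[tuple[str, str], float] = {}
    for aln in alignments:
        key = (aln.query_id, aln.target_id)
        if key not in known:
            raise KeyError(f"alignment for unknown pair {key}")
        score_of[key] = aln.score
    out = []
    for res in results:
        aligned = [
            (score_of[(res.query_id, h.target_id)], h)
            for h in res.hits
            if (res.query_id, h.target_id) in score_of
        ]
        aligned.sort(key=lambda sh: (-sh[0], sh[1].target_id))
        hits = tuple(
            SearchHit(h.target_id, s, rank, h.provenance, h.is_self)
            for rank, (s, h) in enumerate(aligned, start=1)
        )
        out.append(SearchResult(res.query_id, hits))
    return out


def write_results_tsv(results: Iterable[SearchResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\trank\tsimilarity\tprovenance\tself\n")
        for res in results:
            for h in res.hits:
                fh.write(
                    f"{res.query_id}\t{h.target_id}\t{h.rank}\t{h.similarity:.6f}"
                    f"\t{h.provenance}\t{int(h.is_self)}\n"
                )


def read_results_tsv(path: str | Path) -> list[SearchResult]:
    per_query: dict[str, list[SearchHit]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query\t"):
            raise ValueError(f"{path}: missing results header")
        for line in fh:
            q, t, rank, sim, prov, self_flag = line.rstrip("\n").split("\t")
            per_query.setdefault(q, []).append(
                SearchHit(t, float(sim), int(rank), prov, bool(int(self_flag)))
            )
    return [
        SearchResult(q, tuple(sorted(hits, key=lambda h: h.rank)))
        for q, hits in per_query.items()
    ]
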