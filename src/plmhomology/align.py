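"""Pairwise alignment with an embedding-derived substitution matrix.

The substitution score of query residue i against target residue j is the
dot product of their per-residue embeddings; this dense m × n matrix replaces
a static amino-acid matrix inside Needleman-Wunsch (global) or
Smith-Waterman (local) dynamic programming with a linear gap penalty
(constant cost per gapped position, no separate open cost), keeping the
complexity at O(mn). Alignment scores are used to rerank search hits.

Traceback is deterministic: move precedence diagonal > up > left; the local
starting cell is the maximum-score cell with smallest (i, j) on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

DEFAULT_GAP = 3.0
_TOL = 1e-9


@dataclass(frozen=True)
class AlignmentResult:
    """A DP-optimal pairwise alignment.

    ``pairs`` holds 0-based (query_index, target_index) matches, strictly
    increasing in both coordinates. ``score`` is the raw DP optimum unless
    ``normalize="aligned_length"`` divided it by the number of aligned pairs.
    """

    query_id: str
    target_id: str
    mode: str
    score: float
    pairs: tuple[tuple[int, int], ...]
    query_aligned: str = ""
    target_aligned: str = ""


def substitution_matrix(
    E_q: np.ndarray, E_t: np.ndarray, shift: float = 0.0, scale: float = 1.0
) -> np.ndarray:
    """Dot-product substitution scores: S[i, j] = E_q[i] · E_t[j].

    An optional uniform affine rescale (``scale * S + shift``) is applied;
    the default is the raw dot product. Embedding rows are used exactly as
    provided (no cosine re-normalisation).
    """
    E_q, E_t = np.asarray(E_q, float), np.asarray(E_t, float)
    if E_q.ndim != 2 or E_t.ndim != 2 or E_q.shape[1] != E_t.shape[1]:
        raise ValueError(
            f"dimension mismatch: {E_q.shape} vs {E_t.shape}"
        )
    return scale * (E_q @ E_t.T) + shift


def _dp_global(S: np.ndarray, gap: float) -> np.ndarray:
    m, n = S.shape
    H = np.empty((m + 1, n + 1))
    cols = np.arange(n + 1, dtype=float)
    H[0] = -gap * cols
    for i in range(1, m + 1):
        prev = H[i - 1]
        # candidate best without using a left move, per column
        cand = np.empty(n + 1)
        cand[0] = -gap * i
        cand[1:] = np.maximum(prev[:-1] + S[i - 1], prev[1:] - gap)
        # fold in left moves via a running max of cand[j'] - gap*(j - j')
        chain = np.maximum.accumulate(cand + gap * cols) - gap * cols
        H[i] = chain
    return H


def _dp_local(S: np.ndarray, gap: float) -> np.ndarray:
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    cols = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        prev = H[i - 1]
        cand = np.zeros(n + 1)
        cand[1:] = np.maximum(
            0.0, np.maximum(prev[:-1] + S[i - 1], prev[1:] - gap)
        )
        chain = np.maximum.accumulate(cand + gap * cols) - gap * cols
        H[i] = np.maximum(chain, 0.0)
    return H


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _TOL * max(1.0, abs(a), abs(b))


def align_global(
    S: np.ndarray,
    gap: float = DEFAULT_GAP,
    query_id: str = "",
    target_id: str = "",
) -> AlignmentResult:
    """Needleman-Wunsch with linear gaps over a precomputed score matrix."""
    S = np.asarray(S, float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("substitution matrix must be non-empty 2-D")
    if gap < 0:
        raise ValueError("gap penalty must be >= 0")
    m, n = S.shape
    H = _dp_global(S, gap)
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and _close(h, H[i - 1, j - 1] + S[i - 1, j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and _close(h, H[i - 1, j] - gap):
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return AlignmentResult(
        query_id, target_id, "global", float(H[m, n]), tuple(pairs)
    )


def align_local(
    S: np.ndarray,
    gap: float = DEFAULT_GAP,
    query_id: str = "",
    target_id: str = "",
) -> AlignmentResult:
    """Smith-Waterman with linear gaps: cells floored at zero, score is the
    matrix maximum, traceback runs from the max cell back to the first zero."""
    S = np.asarray(S, float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("substitution matrix must be non-empty 2-D")
    if gap < 0:
        raise ValueError("gap penalty must be >= 0")
    H = _dp_local(S, gap)
    score = float(H.max())
    pairs: list[tuple[int, int]] = []
    if score > 0:
        flat = np.argwhere(H == H.max())
        i, j = map(int, flat[np.lexsort((flat[:, 1], flat[:, 0]))][0])
        while H[i, j] > 0:
            h = H[i, j]
            if (
                i > 0
                and j > 0
                and _close(h, H[i - 1, j - 1] + S[i - 1, j - 1])
            ):
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif i > 0 and _close(h, H[i - 1, j] - gap):
                i -= 1
            elif j > 0 and _close(h, H[i, j - 1] - gap):
                j -= 1
            else:  # cell restarted from zero
                break
        pairs.reverse()
    return AlignmentResult(query_id, target_id, "local", score, tuple(pairs))


def format_alignment(
    result: AlignmentResult, query_seq: str, target_seq: str
) -> AlignmentResult:
    """Attach gapped display strings covering the aligned region."""
    if not result.pairs:
        return result
    q_out, t_out = [], []
    (qi0, tj0) = result.pairs[0]
    qi, tj = qi0, tj0
    for qi1, tj1 in result.pairs:
        while qi < qi1:
            q_out.append(query_seq[qi])
            t_out.append("-")
            qi += 1
        while tj < tj1:
            q_out.append("-")
            t_out.append(target_seq[tj])
            tj += 1
        q_out.append(query_seq[qi1])
        t_out.append(target_seq[tj1])
        qi, tj = qi1 + 1, tj1 + 1
    return AlignmentResult(
        result.query_id,
        result.target_id,
        result.mode,
        result.score,
        result.pairs,
        "".join(q_out),
        "".join(t_out),
    )


def align_pair(
    query_id: str,
    target_id: str,
    residue_embeddings,
    mode: str = "global",
    gap: float = DEFAULT_GAP,
    normalize: str = "none",
) -> AlignmentResult:
    """Align one pair from a per-residue embedding lookup (store or dict)."""
    get = (
        residue_embeddings.residue
        if hasattr(residue_embeddings, "residue")
        else residue_embeddings.__getitem__
    )
    S = substitution_matrix(get(query_id), get(target_id))
    fn = {"global": align_global, "local": align_local}.get(mode)
    if fn is None:
        raise ValueError(f"unknown alignment mode {mode!r}")
    result = fn(S, gap, query_id, target_id)
    if normalize == "aligned_length" and result.pairs:
        result = AlignmentResult(
            result.query_id,
            result.target_id,
            result.mode,
            result.score / len(result.pairs),
            result.pairs,
        )
    elif normalize not in ("none", "aligned_length"):
        raise ValueError(f"unknown normalization {normalize!r}")
    return result


def write_alignments_tsv(
    alignments: Iterable[AlignmentResult], path: str | Path
) -> None:
    """Serialize alignments; coordinates are 0-based, end-exclusive."""
    with open(path, "w") as fh:
        fh.write(
            "query\ttarget\tmode\tscore\tq_start\tq_end\tt_start\tt_end"
            "\tq_aligned\tt_aligned\n"
        )
        for a in alignments:
            if a.pairs:
                qs, ts = a.pairs[0]
                qe, te = a.pairs[-1][0] + 1, a.pairs[-1][1] + 1
            else:
                qs = ts = qe = te = 0
            fh.write(
                f"{a.query_id}\t{a.target_id}\t{a.mode}\t{a.score:.6f}"
                f"\t{qs}\t{qe}\t{ts}\t{te}\t{a.query_aligned}\t{a.target_aligned}\n"
            )
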