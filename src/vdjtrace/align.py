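"""Pairwise alignment primitives for germline segment assignment.

Two models are used:

* ``semi_global_score`` — Needleman–Wunsch with free end gaps on the *query*
  side only: the germline segment must be aligned end-to-end (overhangs of
  the segment beyond the query are penalized as gaps), while unaligned query
  prefix/suffix is free. This is the scorer behind V/J gene assignment.
  Default costs: match +1, mismatch −1, gap −2.
* ``best_ungapped_offset`` — gapless placement of a segment on a query at
  the offset maximizing matches − mismatches, with segment overhang beyond
  the query penalized like gaps. Used to map conserved-anchor coordinates
  from the germline onto a consensus (somatic hypermutation introduces
  substitutions, not indels, so anchor mapping is a gapless problem).

Batched kernels (one segment against thousands of consensus sequences) are
numba-compiled; per-sample calling cost is dominated by these loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def pack_queries(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length sequences into a padded int8 matrix + lengths."""
    if not seqs:
        return np.zeros((0, 0), np.int8), np.zeros(0, np.int64)
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    mat = np.zeros((len(seqs), int(lens.max())), dtype=np.int8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode(s)
    return mat, lens


@njit(cache=True)
def _dp_batch(Q, qlens, g, match, mismatch, gap):  # pragma: no cover - numba
    n, L = Q.shape
    M = g.shape[0]
    out = np.empty(n, np.int32)
    row = np.empty(L + 1, np.int32)
    for q in range(n):
        ql = qlens[q]
        for j in range(ql + 1):
            row[j] = 0  # free query-prefix gap
        for i in range(1, M + 1):
            diag = row[0]
            row[0] = gap * i  # germline prefix gap is penalized
            for j in range(1, ql + 1):
                s = diag + (match if Q[q, j - 1] == g[i - 1] else mismatch)
                up = row[j] + gap
                left = row[j - 1] + gap
                diag = row[j]
                best = s
                if up > best:
                    best = up
                if left > best:
                    best = left
                row[j] = best
        best = row[0]
        for j in range(1, ql + 1):  # free query-suffix gap
            if row[j] > best:
                best = row[j]
        out[q] = best
    return out


@njit(cache=True)
def _offset_batch(Q, qlens, g, overhang_pen):  # pragma: no cover - numba
    """Best gapless offset of g on each query; overhanging g bases penalized."""
    n, _ = Q.shape
    M = g.shape[0]
    offsets = np.empty(n, np.int64)
    scores = np.empty(n, np.int64)
    for q in range(n):
        ql = qlens[q]
        best_s = -(1 << 60)
        best_o = 0
        for off in range(-M + 1, ql):
            s = 0
            lo = 0 if off >= 0 else -off
            hi = M if off + M <= ql else ql - off
            if hi <= lo:
                continue
            for i in range(lo, hi):
                if Q[q, off + i] == g[i]:
                    s += 1
                else:
                    s -= 1
            s -= overhang_pen * (M - (hi - lo))
            if s > best_s:
                best_s = s
                best_o = off
        offsets[q] = best_o
        scores[q] = best_s
    return offsets, scores


def semi_global_score(
    query: str, segment: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Score of the best semi-global alignment (free end gaps on the query)."""
    if not query:
        raise ValueError("empty query")
    if not segment:
        raise ValueError("empty segment")
    Q, lens = pack_queries([query])
    return int(_dp_batch(Q, lens, encode(segment), match, mismatch, gap)[0])


def batch_scores(
    queries: list[str],
    segments: list[str],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> np.ndarray:
    """(n_queries, n_segments) semi-global score matrix."""
    Q, lens = pack_queries(queries)
    out = np.empty((len(queries), len(segments)), dtype=np.int32)
    for k, seg in enumerate(segments):
        out[:, k] = _dp_batch(Q, lens, encode(seg), match, mismatch, gap)
    return out


def best_ungapped_offset(query: str, segment: str, overhang_pen: int = 2) -> tuple[int, int]:
    """Best gapless placement offset of ``segment`` on ``query``.

    Returns (offset, score); offset may be negative (segment overhangs the
    query start). Score = matches − mismatches − overhang_pen·(overhang).
    """
    Q, lens = pack_queries([query])
    off, sc = _offset_batch(Q, lens, encode(segment), overhang_pen)
    return int(off[0]), int(sc[0])


#: margin reported when only a single candidate exists
NO_COMPETITOR_MARGIN = 1 << 30


@dataclass(frozen=True)
class SegmentAssignment:
    name: str
    score: int
    margin: int
    ambiguous: bool


def rank_candidates(names: list[str], scores: np.ndarray, ambiguity_margin: int) -> SegmentAssignment:
    """Pick the best-scoring candidate; ties go to the lexicographically
    smallest name and are flagged ambiguous, as is any margin below
    ``ambiguity_margin``."""
    order = sorted(range(len(names)), key=lambda i: (-int(scores[i]), names[i]))
    best = order[0]
    if len(order) == 1:
        margin = NO_COMPETITOR_MARGIN
        tie = False
    else:
        margin = int(scores[best]) - int(scores[order[1]])
        tie = margin == 0
    return SegmentAssignment(
        name=names[best],
        score=int(scores[best]),
        margin=margin,
        ambiguous=tie or margin < ambiguity_margin,
    )


def assign_segment(
    query_nt: str,
    candidates,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    ambiguity_margin: int = 5,
) -> SegmentAssignment:
    """Assign the best-matching germline segment to a query sequence.

    ``candidates`` is a non-empty list of :class:`~vdjtrace.germline.GermlineSegment`
    of one segment type.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidate segments")
    if not query_nt:
        raise ValueError("empty query")
    types = {c.seg_type for c in cands}
    if len(types) != 1:
        raise ValueError(f"candidates mix segment types: {sorted(types)}")
    scores = batch_scores([query_nt], [c.sequence_nt for c in cands], match, mismatch, gap)[0]
    return rank_candidates([c.name for c in cands], scores, ambiguity_margin)
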