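"""Half-open interval algebra on numpy arrays.

All functions operate on parallel ``starts``/``ends`` int64 arrays encoding
0-based half-open intervals on a single chromosome.  Chromosome grouping is
the caller's responsibility.  These primitives back the exon merging, intron
derivation and TE intersection steps of the annotation pipeline and are
validated against brute-force per-nucleotide oracles in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "subtract",
    "union_length",
    "overlap_pairs",
    "coverage_of",
    "IntervalIndex",
]


def _as_arrays(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.shape != e.shape:
        raise ValueError("starts and ends must have equal length")
    if np.any(e < s):
        raise ValueError("interval end < start")
    return s, e


def merge(starts, ends, *, bookended: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals; ``bookended=True`` also joins touching intervals
    (distance-0 merge, bedtools ``merge`` default)."""
    s, e = _as_arrays(starts, ends)
    if s.size == 0:
        return s, e
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    cummax = np.maximum.accumulate(e)
    if bookended:
        new_block = s[1:] > cummax[:-1]
    else:
        new_block = s[1:] >= cummax[:-1]
    block = np.concatenate(([0], np.cumsum(new_block)))
    n_blocks = block[-1] + 1
    out_s = np.full(n_blocks, np.iinfo(np.int64).max, dtype=np.int64)
    out_e = np.zeros(n_blocks, dtype=np.int64)
    np.minimum.at(out_s, block, s)
    np.maximum.at(out_e, block, e)
    return out_s, out_e


def subtract(span: tuple[int, int], starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """``span`` minus the union of the given intervals (gap intervals)."""
    lo, hi = int(span[0]), int(span[1])
    ms, me = merge(starts, ends)
    keep = (me > lo) & (ms < hi)
    ms, me = np.clip(ms[keep], lo, hi), np.clip(me[keep], lo, hi)
    gap_s = np.concatenate(([lo], me))
    gap_e = np.concatenate((ms, [hi]))
    nonempty = gap_e > gap_s
    return gap_s[nonempty], gap_e[nonempty]


def union_length(starts, ends) -> int:
    ms, me = merge(starts, ends)
    return int(np.sum(me - ms))


class IntervalIndex:
    """Query structure over a fixed interval set (one chromosome).

    Intervals are sorted by start; a running max of ends bounds the candidate
    window for each query so that enumeration is near-linear for genomic data.
    """

    def __init__(self, starts, ends):
        s, e = _as_arrays(starts, ends)
        self.order = np.argsort(s, kind="stable")
        self.starts = s[self.order]
        self.ends = e[self.order]
        self.cummax_end = (
            np.maximum.accumulate(self.ends) if s.size else self.ends
        )

    def overlapping(self, qstart: int, qend: int) -> np.ndarray:
        """Original indices of intervals overlapping [qstart, qend)."""
        if self.starts.size == 0:
            return np.empty(0, dtype=np.int64)
        hi = np.searchsorted(self.starts, qend, side="left")
        lo = np.searchsorted(self.cummax_end[:hi], qstart, side="right")
        window = slice(lo, hi)
        mask = self.ends[window] > qstart
        return self.order[window][mask]


def overlap_pairs(
    a_starts, a_ends, b_starts, b_ends
) -> tuple[np.ndarray, np.ndarray]:
    """All index pairs (i, j) with a_i overlapping b_j by >= 1 nt."""
    a_s, a_e = _as_arrays(a_starts, a_ends)
    idx = IntervalIndex(b_starts, b_ends)
    ai, bj = [], []
    for i in range(a_s.size):
        js = idx.overlapping(int(a_s[i]), int(a_e[i]))
        if js.size:
            ai.append(np.full(js.size, i, dtype=np.int64))
            bj.append(js)
    if not ai:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(ai), np.concatenate(bj)


def coverage_of(q_starts, q_ends, starts, ends) -> np.ndarray:
    """Per-query nt covered by the *union* of the second interval set.

    Uses prefix sums over the merged set: O((n+m) log m).
    """
    qs, qe = _as_arrays(q_starts, q_ends)
    ms, me = merge(starts, ends, bookended=False)
    if ms.size == 0 or qs.size == 0:
        return np.zeros(qs.size, dtype=np.int64)
    lengths = me - ms
    prefix = np.concatenate(([0], np.cumsum(lengths)))
    # covered(x) = total covered nt in (-inf, x)
    def covered_upto(x):
        k = np.searchsorted(ms, x, side="left")  # blocks fully starting >= x excluded
        base = prefix[np.maximum(k - 1, 0)] * (k > 0)
        partial = np.where(
            k > 0,
            np.minimum(np.maximum(x - ms[np.maximum(k - 1, 0)], 0), lengths[np.maximum(k - 1, 0)]),
            0,
        )
        return base + partial

    return (covered_upto(qe) - covered_upto(qs)).astype(np.int64)
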