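"""Seed-and-extend ungapped read mapping against a SeedIndex.

Per read: canonical k-mer seeds are taken on a fixed stride, seed hits vote
for (diagonal, strand) candidates, and the best-supported diagonals are
scored by ungapped extension (match +1, mismatch -4) with the maximal
scoring window found Kadane-style. Bases outside the window become soft
clips. Reads with no sufficiently supported diagonal, too short a matched
span, or mismatch density above 10% in the span are unmapped. Ties go to
the smallest (target, position).

The inner loop is compiled with numba; all reads of one batch share a
padded code matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._seq import encode
from .index import SeedIndex

# extension / acceptance defaults
MISMATCH_PENALTY = 4
MIN_SEED_VOTES = 2
MAX_MISMATCH_FRAC = 0.10
MIN_SPAN = 20
MAX_HITS = 16
SEED_STRIDE = 12

_MAX_DIAGS = 160
_MAX_CAND = 4


@dataclass(frozen=True)
class AlignmentRecord:
    """Mapping of one mate: target/pos/strand plus soft-clip structure."""

    read_id: str
    mate_index: int
    target: str | None
    pos: int | None
    strand: str | None
    matched_span: int
    clip_left: int
    clip_right: int
    edit_distance: int

    @property
    def mapped(self) -> bool:
        return self.target is not None


@njit(cache=True)
def _map_batch(
    reads,
    lens,
    k,
    stride,
    sorted_hash,
    hit_pos,
    hit_strand,
    genome,
    max_hits,
    min_votes,
    penalty,
    max_mm_frac,
    min_span,
):
    n = reads.shape[0]
    out_gstart = np.full(n, -1, dtype=np.int64)
    out_strand = np.zeros(n, dtype=np.int8)
    out_clip_l = np.zeros(n, dtype=np.int32)
    out_clip_r = np.zeros(n, dtype=np.int32)
    out_span = np.zeros(n, dtype=np.int32)
    out_nm = np.zeros(n, dtype=np.int32)

    G = genome.shape[0]
    nh = sorted_hash.shape[0]
    mask = np.uint64((1 << (2 * k)) - 1) if 2 * k < 64 else np.uint64(0xFFFFFFFFFFFFFFFF)

    diag_d = np.empty(_MAX_DIAGS, dtype=np.int64)
    diag_s = np.empty(_MAX_DIAGS, dtype=np.int8)
    diag_v = np.empty(_MAX_DIAGS, dtype=np.int32)
    oriented = np.empty(reads.shape[1], dtype=np.uint8)

    for r in range(n):
        L = lens[r]
        if L < k:
            continue
        nd = 0
        off = 0
        last = L - k
        while True:
            # hash the seed at `off`
            fh = np.uint64(0)
            rh = np.uint64(0)
            ok = True
            for j in range(k):
                b = reads[r, off + j]
                if b > 3:
                    ok = False
                    break
                fh = ((fh << np.uint64(2)) | np.uint64(b)) & mask
                rh = rh | (np.uint64(3 - b) << np.uint64(2 * j))
            if ok:
                if fh <= rh:
                    ch = fh
                    st = 1
                else:
                    ch = rh
                    st = 0
                # binary search [lo, hi)
                lo = 0
                hi = nh
                while lo < hi:
                    mid = (lo + hi) // 2
                    if sorted_hash[mid] < ch:
                        lo = mid + 1
                    else:
                        hi = mid
                hi2 = lo
                while hi2 < nh and sorted_hash[hi2] == ch:
                    hi2 += 1
                cnt = hi2 - lo
                if 0 < cnt <= max_hits:
                    for t in range(lo, hi2):
                        p = hit_pos[t]
                        if hit_strand[t] == st:
                            d = p - off
                            s = np.int8(1)
                        else:
                            d = p - (L - k - off)
                            s = np.int8(-1)
                        found = False
                        for q in range(nd):
                            if diag_d[q] == d and diag_s[q] == s:
                                diag_v[q] += 1
                                found = True
                                break
                        if not found and nd < _MAX_DIAGS:
                            diag_d[nd] = d
                            diag_s[nd] = s
                            diag_v[nd] = 1
                            nd += 1
            if off == last:
                break
            off += stride
            if off > last:
                off = last

        if nd == 0:
            continue

        # pick up to _MAX_CAND candidate diagonals by votes (ties: smaller diag)
        best_score = -1
        best_d = np.int64(0)
        best_s = np.int8(0)
        best_i0 = 0
        best_i1 = 0
        used = np.zeros(nd, dtype=np.uint8)
        for c in range(_MAX_CAND if nd > _MAX_CAND else nd):
            sel = -1
            for q in range(nd):
                if used[q]:
                    continue
                if sel == -1 or diag_v[q] > diag_v[sel] or (
                    diag_v[q] == diag_v[sel] and diag_d[q] < diag_d[sel]
                ):
                    sel = q
            if sel == -1 or diag_v[sel] < min_votes:
                break
            used[sel] = 1
            d = diag_d[sel]
            s = diag_s[sel]
            # orient the read to the target strand
            if s == 1:
                for i in range(L):
                    oriented[i] = reads[r, i]
            else:
                for i in range(L):
                    b = reads[r, L - 1 - i]
                    oriented[i] = 3 - b if b <= 3 else b
            # Kadane max-scoring window of the ungapped alignment
            cur = 0
            cur_start = 0
            sc_best = -1
            i0 = 0
            i1 = 0
            for i in range(L):
                gp = d + i
                if 0 <= gp < G and genome[gp] == oriented[i]:
                    step = 1
                else:
                    step = -penalty
                if cur <= 0:
                    cur = step
                    cur_start = i
                else:
                    cur += step
                if cur > sc_best:
                    sc_best = cur
                    i0 = cur_start
                    i1 = i + 1
                elif cur == sc_best and cur_start == i0 and i + 1 > i1:
                    i1 = i + 1
            if sc_best > best_score or (
                sc_best == best_score and d + i0 < best_d + best_i0
            ):
                best_score = sc_best
                best_d = d
                best_s = s
                best_i0 = i0
                best_i1 = i1

        if best_score < 0:
            continue
        span = best_i1 - best_i0
        if span < min_span:
            continue
        # mismatches within the chosen window
        nm = 0
        if best_s == 1:
            for i in range(best_i0, best_i1):
                gp = best_d + i
                if not (0 <= gp < G) or genome[gp] != reads[r, i]:
                    nm += 1
        else:
            for i in range(best_i0, best_i1):
                gp = best_d + i
                b = reads[r, L - 1 - i]
                ob = 3 - b if b <= 3 else b
                if not (0 <= gp < G) or genome[gp] != ob:
                    nm += 1
        if nm > max_mm_frac * span:
            continue
        out_gstart[r] = best_d + best_i0
        out_strand[r] = best_s
        out_clip_l[r] = best_i0
        out_clip_r[r] = L - best_i1
        out_span[r] = span
        out_nm[r] = nm

    return out_gstart, out_strand, out_clip_l, out_clip_r, out_span, out_nm


def map_codes(
    reads: np.ndarray,
    index: SeedIndex,
    lens: np.ndarray | None = None,
    stride: int = SEED_STRIDE,
    min_votes: int = MIN_SEED_VOTES,
    min_span: int = MIN_SPAN,
) -> pd.DataFrame:
    """Map a (n, max_len) uint8 code matrix; returns one row per read.

    Columns: tid (-1 = unmapped), pos, strand (+1/-1/0), clip_left,
    clip_right, span, nm. Clips are reported in the aligned (target)
    orientation, SAM-style.
    """
    if lens is None:
        lens = np.full(reads.shape[0], reads.shape[1], dtype=np.int64)
    gstart, strand, cl, cr, span, nm = _map_batch(
        np.ascontiguousarray(reads),
        np.asarray(lens, dtype=np.int64),
        index.k,
        stride,
        index.sorted_hash,
        index.hit_pos,
        index.hit_strand,
        index.genome,
        MAX_HITS,
        min_votes,
        MISMATCH_PENALTY,
        MAX_MISMATCH_FRAC,
        min_span,
    )
    mapped = strand != 0
    tid = np.full(len(gstart), -1, dtype=np.int64)
    pos = np.zeros(len(gstart), dtype=np.int64)
    if mapped.any():
        t, p = index.target_of(gstart[mapped])
        tid[mapped] = t
        pos[mapped] = p
    return pd.DataFrame(
        {
            "tid": tid,
            "pos": pos,
            "strand": strand.astype(np.int8),
            "clip_left": cl,
            "clip_right": cr,
            "span": span,
            "nm": nm,
            "length": np.asarray(lens, dtype=np.int64),
        }
    )


def map_read(read: str, index: SeedIndex, read_id: str = "read", mate_index: int = 1,
             **kwargs) -> AlignmentRecord:
    """Map a single read string to an AlignmentRecord."""
    codes = encode(read)[None, :]
    row = map_codes(codes, index, **kwargs).iloc[0]
    if row.tid < 0:
        return AlignmentRecord(read_id, mate_index, None, None, None, 0, 0, len(read), 0)
    return AlignmentRecord(
        read_id=read_id,
        mate_index=mate_index,
        target=index.names[int(row.tid)],
        pos=int(row.pos),
        strand="+" if row.strand > 0 else "-",
        matched_span=int(row.span),
        clip_left=int(row.clip_left),
        clip_right=int(row.clip_right),
        edit_distance=int(row.nm),
    )
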