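"""Exact k-mer seed index over a set of target sequences.

K-mers are stored under their canonical 2-bit encoding (the smaller of the
forward and reverse-complement integer codes), so a query hits the same
entry regardless of strand; a strand bit records which orientation was
canonical at each indexed position. Lookups are binary searches into a
sorted hash array, O(log n) with O(1) expected candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode

SENTINEL = 4  # separator between concatenated targets; never part of a k-mer


def _rolling_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward hash, reverse-complement hash and validity per k-mer start."""
    g = codes.astype(np.uint64)
    n = len(g) - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=bool)
    fh = np.zeros(n, dtype=np.uint64)
    rh = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        b = g[j : j + n]
        fh = (fh << np.uint64(2)) | b
        rh = rh | ((np.uint64(3) - b) << np.uint64(2 * j))
    bad = (codes > 3).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return fh, rh, valid


@dataclass
class SeedIndex:
    """Canonical k-mer index over one or more named targets."""

    names: list[str]
    k: int
    genome: np.ndarray  # uint8 codes, targets separated by SENTINEL
    bounds: np.ndarray  # global start of each target
    lengths: np.ndarray
    sorted_hash: np.ndarray = field(repr=False)
    hit_pos: np.ndarray = field(repr=False)  # global k-mer starts, hash-sorted
    hit_strand: np.ndarray = field(repr=False)  # 1 where the forward k-mer is canonical

    @property
    def n_kmers(self) -> int:
        return len(self.sorted_hash)

    def target_of(self, gpos: np.ndarray | int):
        """Map global coordinates to (target index, local position)."""
        gpos = np.asarray(gpos)
        tid = np.searchsorted(self.bounds, gpos, side="right") - 1
        return tid, gpos - self.bounds[tid]

    def query(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (target, position, strand) occurrences of one k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"query length must equal k={self.k}")
        fh, rh, valid = _rolling_hashes(encode(kmer), self.k)
        if not valid[0]:
            return []
        canon = min(int(fh[0]), int(rh[0]))
        qstrand = int(fh[0]) <= int(rh[0])
        lo = np.searchsorted(self.sorted_hash, canon, side="left")
        hi = np.searchsorted(self.sorted_hash, canon, side="right")
        out = []
        for t in range(lo, hi):
            tid, pos = self.target_of(int(self.hit_pos[t]))
            strand = "+" if bool(self.hit_strand[t]) == qstrand else "-"
            out.append((self.names[int(tid)], int(pos), strand))
        return out


def build_index(targets: dict[str, str], k: int = 31) -> SeedIndex:
    """Index every k-mer of every target (both strands, canonical form)."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if k > 31:
        raise ValueError("k must be <= 31 (2-bit packing in 64 bits)")
    if not targets:
        raise ValueError("no targets to index")
    names = list(targets)
    if len(set(names)) != len(names):
        raise ValueError("duplicate target labels")

    parts, bounds, lengths = [], [], []
    pos = 0
    for name in names:
        codes = encode(targets[name])
        bounds.append(pos)
        lengths.append(len(codes))
        parts.append(codes)
        parts.append(np.full(1, SENTINEL, dtype=np.uint8))
        pos += len(codes) + 1
    genome = np.concatenate(parts)

    fh, rh, valid = _rolling_hashes(genome, k)
    canon = np.minimum(fh, rh)
    strand = (fh <= rh).astype(np.uint8)
    idx = np.flatnonzero(valid)
    order = np.argsort(canon[idx], kind="stable")
    idx = idx[order]
    return SeedIndex(
        names=names,
        k=k,
        genome=genome,
        bounds=np.asarray(bounds, dtype=np.int64),
        lengths=np.asarray(lengths, dtype=np.int64),
        sorted_hash=canon[idx],
        hit_pos=idx.astype(np.int64),
        hit_strand=strand[idx],
    )
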