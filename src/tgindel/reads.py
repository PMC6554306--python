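"""Paired-end short-read simulation.

Emulates a whole-genome shotgun design: fragments drawn uniformly across
all haplotype sequences in proportion to length, insert size Normal
(truncated below at the read length), 2 x ``read_length`` reads from the
fragment ends (mate 2 on the opposite strand), i.i.d. substitution errors,
fixed Q30 base qualities. ``coverage`` is total depth over the whole
(di)ploid genome, so the number of pairs is
``round(coverage * total_bases / (2 * read_length))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import _BASES, encode


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 125
    insert_mean: int = 350
    insert_sd: float = 50.0
    coverage: float = 10.0
    substitution_error_rate: float = 0.0
    seed: int = 0
    provenance_names: bool = False

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution error rate must be in [0, 1)")


def n_pairs_for(params: ReadSimParams, total_bases: int) -> int:
    return int(round(params.coverage * total_bases / (2 * params.read_length)))


def simulate_read_arrays(
    haplotypes: dict[str, dict[str, str]], params: ReadSimParams
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate pairs in memory.

    Returns ``(r1, r2, meta)``: two (n_pairs, read_length) uint8 code
    matrices and a per-pair provenance table (haplotype, contig, fragment
    start, insert size, whether mate 1 is the reverse-strand read).
    """
    rng = np.random.default_rng(params.seed)
    units = [
        (hap, contig, encode(seq))
        for hap, contigs in haplotypes.items()
        for contig, seq in contigs.items()
    ]
    if not units:
        raise ValueError("empty genome")
    lengths = np.array([len(c) for _, _, c in units], dtype=np.int64)
    min_frag = int(params.insert_mean + 3 * params.insert_sd)
    if (lengths < min_frag).any():
        short = [u[1] for u, n in zip(units, lengths) if n < min_frag]
        raise ValueError(f"contig(s) shorter than insert_mean + 3*insert_sd: {short}")

    total = int(lengths.sum())
    n = n_pairs_for(params, total)
    rl = params.read_length

    ins = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n)).astype(np.int64)
    np.clip(ins, rl, lengths.min(), out=ins)
    # weight units by valid fragment-start count, not raw length: weighting
    # by length over-samples the interior of short contigs (a fragment must
    # fit, so the start range is length - insert + 1)
    weights = (lengths - params.insert_mean + 1).clip(min=1).astype(float)
    unit_idx = rng.choice(len(units), size=n, p=weights / weights.sum())
    start = np.floor(rng.random(n) * (lengths[unit_idx] - ins + 1)).astype(np.int64)
    flip = rng.random(n) < 0.5

    r1 = np.empty((n, rl), dtype=np.uint8)
    r2 = np.empty((n, rl), dtype=np.uint8)
    offs = np.arange(rl)
    for ui, (_, _, codes) in enumerate(units):
        sel = np.flatnonzero(unit_idx == ui)
        if sel.size == 0:
            continue
        s = start[sel]
        fwd = codes[s[:, None] + offs]
        rev = codes[(s + ins[sel] - rl)[:, None] + offs]
        rev = 3 - rev[:, ::-1]  # mate on the opposite strand
        r1[sel] = fwd
        r2[sel] = rev
    # randomly choose which mate is the forward-strand read
    fl = np.flatnonzero(flip)
    if fl.size:
        tmp = r1[fl].copy()
        r1[fl] = r2[fl]
        r2[fl] = tmp

    e = params.substitution_error_rate
    if e > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < e
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shift) % 4

    meta = pd.DataFrame(
        {
            "haplotype": pd.Categorical.from_codes(
                unit_idx, categories=[f"{h}:{c}" for h, c, _ in units]
            ),
            "start": start,
            "insert": ins,
            "mate1_reverse": flip,
        }
    )
    return r1, r2, meta


def read_names(meta: pd.DataFrame, provenance: bool = False) -> list[str]:
    if not provenance:
        return [f"r{i:07d}" for i in range(len(meta))]
    return [
        f"r{i:07d}|{row.haplotype}|{row.start}|{row.insert}"
        for i, row in enumerate(meta.itertuples())
    ]


def write_fastq_pair(
    r1: np.ndarray, r2: np.ndarray, names: list[str], path_r1, path_r2
) -> None:
    """Write the two mates as Phred+33 FASTQ with fixed Q30 qualities."""
    for mat, path, mate in ((r1, path_r1, 1), (r2, path_r2, 2)):
        qual = "?" * mat.shape[1] if mat.size else ""
        with open(path, "w") as fh:
            out = []
            for name, row in zip(names, mat):
                out.append(f"@{name}/{mate}\n{_BASES[row].tobytes().decode()}\n+\n{qual}\n")
                if len(out) >= 20000:
                    fh.write("".join(out))
                    out = []
            fh.write("".join(out))


def simulate_reads(
    haplotypes: dict[str, dict[str, str]],
    params: ReadSimParams,
    path_r1,
    path_r2,
) -> pd.DataFrame:
    """Simulate pairs and write them to a FASTQ file pair; returns provenance."""
    r1, r2, meta = simulate_read_arrays(haplotypes, params)
    write_fastq_pair(r1, r2, read_names(meta, params.provenance_names), path_r1, path_r2)
    return meta
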