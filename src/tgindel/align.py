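"""Paired-end mapping facade: FASTQ in, alignment tables (and SAM) out.

The heavy lifting lives in :mod:`tgindel.index` (seed index) and
:mod:`tgindel.mapper` (extension kernel); this module handles read pairing,
batch orchestration and SAM interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from ._seq import _BASES, _CODE
from .index import SeedIndex, build_index  # re-exported
from .mapper import AlignmentRecord, map_codes, map_read  # re-exported

__all__ = [
    "SeedIndex",
    "build_index",
    "AlignmentRecord",
    "map_read",
    "PairedAlignments",
    "read_fastq_codes",
    "map_pairs",
    "write_sam",
    "read_sam",
]


def read_fastq_codes(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a FASTQ file into (names, code matrix, length vector)."""
    names: list[str] = []
    seqs: list[bytes] = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            names.append(rec.name)
            seqs.append(rec.sequence.encode("ascii"))
    if not seqs:
        return names, np.empty((0, 0), dtype=np.uint8), np.empty(0, dtype=np.int64)
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    width = int(lens.max())
    mat = np.full((len(seqs), width), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = _CODE[np.frombuffer(s, dtype=np.uint8)]
    return names, mat, lens


@dataclass
class PairedAlignments:
    """Both mates' alignments plus the read sequences they came from."""

    index: SeedIndex
    names: list[str]
    r1: np.ndarray = field(repr=False)
    r2: np.ndarray = field(repr=False)
    aln1: pd.DataFrame = field(repr=False)
    aln2: pd.DataFrame = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.names)

    def codes(self, mate: int) -> np.ndarray:
        return self.r1 if mate == 1 else self.r2

    def aln(self, mate: int) -> pd.DataFrame:
        return self.aln1 if mate == 1 else self.aln2

    def oriented_read(self, mate: int, row: int) -> np.ndarray:
        """Read codes in the aligned (target) orientation."""
        aln = self.aln(mate)
        L = int(aln["length"].iat[row])
        codes = self.codes(mate)[row, :L]
        if int(aln["strand"].iat[row]) < 0:
            out = codes[::-1].copy()
            acgt = out < 4
            out[acgt] = 3 - out[acgt]
            return out
        return codes

    def record(self, mate: int, row: int) -> AlignmentRecord:
        aln = self.aln(mate)
        tid = int(aln["tid"].iat[row])
        if tid < 0:
            L = int(aln["length"].iat[row])
            return AlignmentRecord(self.names[row], mate, None, None, None, 0, 0, L, 0)
        return AlignmentRecord(
            read_id=self.names[row],
            mate_index=mate,
            target=self.index.names[tid],
            pos=int(aln["pos"].iat[row]),
            strand="+" if aln["strand"].iat[row] > 0 else "-",
            matched_span=int(aln["span"].iat[row]),
            clip_left=int(aln["clip_left"].iat[row]),
            clip_right=int(aln["clip_right"].iat[row]),
            edit_distance=int(aln["nm"].iat[row]),
        )


def map_pairs(
    r1_source,
    r2_source,
    index: SeedIndex,
    names: list[str] | None = None,
    **kwargs,
) -> PairedAlignments:
    """Map both mates of a read-pair set independently.

    ``r1_source``/``r2_source`` are FASTQ paths or uint8 code matrices (in
    which case ``names`` may be given). Mates are joined by record order;
    desynchronized FASTQ inputs (mismatched names or counts) raise.
    """
    if isinstance(r1_source, (str,)) or hasattr(r1_source, "__fspath__"):
        n1, m1, l1 = read_fastq_codes(r1_source)
        n2, m2, l2 = read_fastq_codes(r2_source)
        base1 = [n.rsplit("/", 1)[0] for n in n1]
        base2 = [n.rsplit("/", 1)[0] for n in n2]
        if len(base1) != len(base2):
            raise ValueError(
                f"desynchronized mates: {len(base1)} R1 records vs {len(base2)} R2"
            )
        for i, (a, b) in enumerate(zip(base1, base2)):
            if a != b:
                raise ValueError(f"desynchronized mates at record {i}: {a!r} vs {b!r}")
        names = base1
    else:
        m1, m2 = np.asarray(r1_source), np.asarray(r2_source)
        l1 = np.full(m1.shape[0], m1.shape[1], dtype=np.int64)
        l2 = np.full(m2.shape[0], m2.shape[1], dtype=np.int64)
        if names is None:
            names = [f"r{i:07d}" for i in range(m1.shape[0])]
    aln1 = map_codes(m1, index, lens=l1, **kwargs)
    aln2 = map_codes(m2, index, lens=l2, **kwargs)
    return PairedAlignments(index=index, names=names, r1=m1, r2=m2, aln1=aln1, aln2=aln2)


def _sam_header(index: SeedIndex) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": name, "LN": int(length)}
                for name, length in zip(index.names, index.lengths)
            ],
        }
    )


def write_sam(paired: PairedAlignments, path) -> None:
    """Serialize both mates as text SAM (soft clips in CIGAR, NM tag)."""
    header = _sam_header(paired.index)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in range(paired.n_pairs):
            for mate in (1, 2):
                aln = paired.aln(mate)
                other = paired.aln(2 if mate == 1 else 1)
                a = pysam.AlignedSegment(header)
                a.query_name = paired.names[row]
                tid = int(aln["tid"].iat[row])
                strand = int(aln["strand"].iat[row])
                flag = 1 | (64 if mate == 1 else 128)
                if tid < 0:
                    flag |= 4
                elif strand < 0:
                    flag |= 16
                if int(other["tid"].iat[row]) < 0:
                    flag |= 8
                elif int(other["strand"].iat[row]) < 0:
                    flag |= 32
                a.flag = flag
                L = int(aln["length"].iat[row])
                if tid >= 0:
                    a.reference_id = tid
                    a.reference_start = int(aln["pos"].iat[row])
                    cl = int(aln["clip_left"].iat[row])
                    cr = int(aln["clip_right"].iat[row])
                    span = int(aln["span"].iat[row])
                    cig = []
                    if cl:
                        cig.append((4, cl))
                    cig.append((0, span))
                    if cr:
                        cig.append((4, cr))
                    a.cigartuples = cig
                    seq_codes = paired.oriented_read(mate, row)
                else:
                    seq_codes = paired.codes(mate)[row, :L]
                a.query_sequence = _BASES[seq_codes].tobytes().decode()
                a.query_qualities = pysam.qualitystring_to_array("?" * L)
                if tid >= 0:
                    a.set_tag("NM", int(aln["nm"].iat[row]))
                out.write(a)


def read_sam(path, index: SeedIndex) -> PairedAlignments:
    """Read a (possibly external) SAM with soft-clipped CIGARs back into tables."""
    names: list[str] = []
    rows1, rows2 = [], []
    seqs1, seqs2 = [], []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        tid_map = {name: i for i, name in enumerate(index.names)}
        for seg in fh:
            mate = 2 if seg.is_read2 else 1
            if mate == 1:
                names.append(seg.query_name)
            seq = seg.query_sequence or ""
            L = len(seq)
            if seg.is_unmapped:
                row = dict(tid=-1, pos=0, strand=0, clip_left=0, clip_right=0,
                           span=0, nm=0, length=L)
                codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            else:
                cl = cr = span = 0
                for op, n in seg.cigartuples or []:
                    if op == 4:
                        if span == 0:
                            cl = n
                        else:
                            cr = n
                    elif op in (0, 7, 8):
                        span += n
                row = dict(
                    tid=tid_map.get(seg.reference_name, -1),
                    pos=seg.reference_start,
                    strand=-1 if seg.is_reverse else 1,
                    clip_left=cl,
                    clip_right=cr,
                    span=span,
                    nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    length=L,
                )
                codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
                if seg.is_reverse:  # store in read orientation, as map_pairs does
                    codes = codes[::-1].copy()
                    acgt = codes < 4
                    codes[acgt] = 3 - codes[acgt]
            (rows1 if mate == 1 else rows2).append(row)
            (seqs1 if mate == 1 else seqs2).append(codes)

    def pack(seqs):
        if not seqs:
            return np.empty((0, 0), dtype=np.uint8)
        width = max(len(s) for s in seqs)
        mat = np.full((len(seqs), width), 4, dtype=np.uint8)
        for i, s in enumerate(seqs):
            mat[i, : len(s)] = s
        return mat

    return PairedAlignments(
        index=index,
        names=names,
        r1=pack(seqs1),
        r2=pack(seqs2),
        aln1=pd.DataFrame(rows1),
        aln2=pd.DataFrame(rows2),
    )
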