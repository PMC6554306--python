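"""Evidence screening: classify read pairs and extract split reads.

The screen separates the two evidence streams the junction caller is built
on: anchored pairs (one mate on the transgene monomer, the other telling us
where in the genome — or failing to map at all) and soft-clipped reads
whose clipped piece may span a junction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import _BASES
from .align import PairedAlignments
from .mapper import AlignmentRecord

MIN_CLIP = 20

PAIR_CLASSES = (
    "both_reference",
    "both_transgene",
    "anchored_tg_ref",
    "anchored_tg_unmapped",
    "both_unmapped",
    "split_candidate",
)


@dataclass(frozen=True)
class PairClass:
    read_id: str
    pair_class: str
    anchor: AlignmentRecord | None = None
    partner: AlignmentRecord | None = None
    split_candidate: bool = False


def _state(rec: AlignmentRecord, transgene_targets: set[str]) -> str:
    if not rec.mapped:
        return "unmapped"
    return "transgene" if rec.target in transgene_targets else "reference"


def classify_pair(
    mate1: AlignmentRecord,
    mate2: AlignmentRecord,
    transgene_targets: set[str],
    min_clip: int = MIN_CLIP,
) -> PairClass:
    """Deterministic pair classification (total over all mate states).

    Decision table: a transgene-mapped mate makes the pair anchored
    (anchored_tg_ref / anchored_tg_unmapped) or both_transgene; two
    reference mates are both_reference (flagged as split candidates when a
    clip qualifies, so a read can feed both evidence streams); a reference
    mate with an unmapped partner is split_candidate when its clip
    qualifies, otherwise both_reference; two unmapped mates are
    both_unmapped.
    """
    if mate1.read_id != mate2.read_id:
        raise ValueError(f"mismatched read ids: {mate1.read_id!r} vs {mate2.read_id!r}")
    s1, s2 = _state(mate1, transgene_targets), _state(mate2, transgene_targets)

    def has_clip(rec: AlignmentRecord) -> bool:
        return rec.mapped and max(rec.clip_left, rec.clip_right) >= min_clip

    split = has_clip(mate1) or has_clip(mate2)
    states = {s1, s2}
    if states == {"transgene"}:
        cls = "both_transgene"
    elif states == {"transgene", "reference"}:
        cls = "anchored_tg_ref"
    elif states == {"transgene", "unmapped"}:
        cls = "anchored_tg_unmapped"
    elif states == {"unmapped"}:
        cls = "both_unmapped"
    elif states == {"reference", "unmapped"}:
        cls = "split_candidate" if split else "both_reference"
    else:  # both on the reference
        cls = "both_reference"

    anchor = partner = None
    if cls.startswith("anchored"):
        anchor, partner = (mate1, mate2) if s1 == "transgene" else (mate2, mate1)
    return PairClass(mate1.read_id, cls, anchor, partner, split_candidate=split)


def classify_pairs(
    paired: PairedAlignments, transgene_targets: set[str], min_clip: int = MIN_CLIP
) -> pd.DataFrame:
    """Vectorized pair classification; one row per pair.

    Columns: pair_class, split_candidate, anchor_mate (0 when not anchored).
    """
    tg_tids = np.array(
        [i for i, n in enumerate(paired.index.names) if n in transgene_targets]
    )
    out = []
    for mate in (1, 2):
        aln = paired.aln(mate)
        tid = aln["tid"].to_numpy()
        state = np.where(tid < 0, 0, np.where(np.isin(tid, tg_tids), 2, 1))
        clip = (
            np.maximum(aln["clip_left"].to_numpy(), aln["clip_right"].to_numpy())
            >= min_clip
        ) & (tid >= 0)
        out.append((state, clip))
    (st1, c1), (st2, c2) = out
    split = c1 | c2
    lohi = np.minimum(st1, st2) * 4 + np.maximum(st1, st2)
    # state codes: 0 unmapped, 1 reference, 2 transgene
    cls = np.full(len(st1), "both_reference", dtype=object)
    cls[lohi == 0 * 4 + 0] = "both_unmapped"
    ref_un = lohi == 0 * 4 + 1
    cls[ref_un & split] = "split_candidate"
    cls[ref_un & ~split] = "both_reference"
    cls[lohi == 0 * 4 + 2] = "anchored_tg_unmapped"
    cls[lohi == 1 * 4 + 2] = "anchored_tg_ref"
    cls[lohi == 2 * 4 + 2] = "both_transgene"
    anchor_mate = np.where(st1 == 2, 1, np.where(st2 == 2, 2, 0))
    return pd.DataFrame(
        {
            "pair_class": pd.Categorical(cls, categories=list(PAIR_CLASSES)),
            "split_candidate": split,
            "anchor_mate": anchor_mate,
        }
    )


@dataclass(frozen=True)
class SplitRead:
    read_id: str
    mapped_part: AlignmentRecord
    clipped_seq: str
    clip_side: str  # {left, right}


def extract_split_reads(
    paired: PairedAlignments, min_clip: int = MIN_CLIP
) -> pd.DataFrame:
    """One row per qualifying clipped read end, clipped sequence verbatim.

    The clipped sequence is reported in the aligned (target) orientation so
    it continues the target sequence across the junction. ``boundary`` is
    the target coordinate of the seam: ``pos`` for a left clip, ``pos +
    span`` for a right clip.
    """
    if min_clip < 15:
        raise ValueError("min_clip must be >= 15")
    rows = []
    for mate in (1, 2):
        aln = paired.aln(mate)
        tid = aln["tid"].to_numpy()
        cl = aln["clip_left"].to_numpy()
        cr = aln["clip_right"].to_numpy()
        keep = (tid >= 0) & ((cl >= min_clip) | (cr >= min_clip))
        for row in np.flatnonzero(keep):
            oriented = paired.oriented_read(mate, int(row))
            span = int(aln["span"].iat[row])
            pos = int(aln["pos"].iat[row])
            for side, size in (("left", int(cl[row])), ("right", int(cr[row]))):
                if size < min_clip:
                    continue
                if side == "left":
                    piece = oriented[: int(cl[row])]
                    boundary = pos
                else:
                    piece = oriented[int(cl[row]) + span :]
                    boundary = pos + span
                rows.append(
                    {
                        "read_id": paired.names[int(row)],
                        "mate": mate,
                        "row": int(row),
                        "tid": int(tid[row]),
                        "pos": pos,
                        "strand": int(aln["strand"].iat[row]),
                        "span": span,
                        "clip_side": side,
                        "boundary": boundary,
                        "clipped_seq": _BASES[piece].tobytes().decode(),
                    }
                )
    columns = [
        "read_id", "mate", "row", "tid", "pos", "strand", "span",
        "clip_side", "boundary", "clipped_seq",
    ]
    return pd.DataFrame(rows, columns=columns)
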