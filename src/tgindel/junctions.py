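"""Insertion-locus clustering, breakpoint refinement and junction typing.

Anchored pairs localize the insertion to cluster windows on the reference;
split reads refine each breakpoint to base pair (the modal clip boundary
whose clipped piece re-maps to the transgene); reads clipped on the
transgene monomer type the array-internal junctions (head-to-tail,
head-to-head 5'-5', transgene-vector). The position of the orientation
switch *within* the array is reported as presence/absence only — short
reads cannot place it among near-identical copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import _BASES
from .align import PairedAlignments
from .index import build_index
from .mapper import map_codes

MIN_CLUSTER_SUPPORT = 3
MIN_SPLIT = 2
CONTEXT_BP = 60
CLIP_K = 15
_COORD_TOL = 3  # bp tolerance when matching clip coordinates to monomer ends

JUNCTION_TYPES = (
    "genome_tg_left",
    "genome_tg_right",
    "tg_head_to_tail",
    "tg_head_to_head",
    "tg_tail_to_tail",
    "tg_vector",
    "vector_tg",
    "tg_unexplained",
)


@dataclass(frozen=True)
class AnchorCluster:
    chrom: str
    tid: int
    window: tuple[int, int]
    side: str  # {left_of_insertion, right_of_insertion}
    n_support: int


@dataclass
class JunctionCall:
    type: str
    ref_target: str | None = None
    ref_pos: int | None = None
    tg_offset: int | None = None
    orientation: str = "+"
    split_support: int = 0
    pair_support: int = 0
    junction_seq: str = ""
    resolved: bool = False

    def __post_init__(self) -> None:
        if self.type not in JUNCTION_TYPES:
            raise ValueError(f"unknown junction type {self.type!r}")


@dataclass
class InsertionModel:
    left: JunctionCall | None = None
    right: JunctionCall | None = None
    internal: list[JunctionCall] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    #: the switch index inside the array is not identifiable from short reads
    switch_position_resolved: bool = False

    @property
    def has_orientation_switch(self) -> bool:
        return any(j.type in ("tg_head_to_head", "tg_vector", "vector_tg")
                   for j in self.internal)

    @property
    def implied_deletion(self) -> tuple[int, int] | None:
        if self.left is None or self.right is None:
            return None
        if self.left.ref_pos is None or self.right.ref_pos is None:
            return None
        return int(self.left.ref_pos), int(self.right.ref_pos)

    @property
    def deletion_length(self) -> int | None:
        iv = self.implied_deletion
        return None if iv is None else iv[1] - iv[0]

    def junctions(self) -> list[JunctionCall]:
        out = [j for j in (self.left, self.right) if j is not None]
        return out + list(self.internal)


def cluster_anchors(
    paired: PairedAlignments,
    classes: pd.DataFrame,
    insert_mean: float,
    insert_sd: float,
    min_cluster_support: int = MIN_CLUSTER_SUPPORT,
) -> list[AnchorCluster]:
    """Group anchored-pair reference partners into insertion-side clusters.

    Partners are linked when consecutive positions are within
    insert_mean + 3*insert_sd; the side of the insertion follows from the
    partner strand (a forward partner reads toward the insertion on its
    right, so it sits left of the insertion).
    """
    gap = insert_mean + 3 * insert_sd
    anchored = classes["pair_class"] == "anchored_tg_ref"
    if not anchored.any():
        return []
    anchor_mate = classes["anchor_mate"].to_numpy()
    rows = np.flatnonzero(anchored.to_numpy())
    partner_mate = np.where(anchor_mate[rows] == 1, 2, 1)

    tids = np.empty(len(rows), dtype=np.int64)
    pos = np.empty(len(rows), dtype=np.int64)
    strand = np.empty(len(rows), dtype=np.int64)
    span = np.empty(len(rows), dtype=np.int64)
    for mate in (1, 2):
        aln = paired.aln(mate)
        sel = partner_mate == mate
        rr = rows[sel]
        tids[sel] = aln["tid"].to_numpy()[rr]
        pos[sel] = aln["pos"].to_numpy()[rr]
        strand[sel] = aln["strand"].to_numpy()[rr]
        span[sel] = aln["span"].to_numpy()[rr]

    clusters: list[AnchorCluster] = []
    for tid in np.unique(tids):
        for side_strand, side in ((1, "left_of_insertion"), (-1, "right_of_insertion")):
            sel = (tids == tid) & (strand == side_strand)
            if not sel.any():
                continue
            p = np.sort(pos[sel])
            ends = np.flatnonzero(np.diff(p) > gap)
            starts = np.concatenate([[0], ends + 1])
            stops = np.concatenate([ends, [len(p) - 1]])
            max_span = int(span[sel].max())
            for a, b in zip(starts, stops):
                n = b - a + 1
                if n < min_cluster_support:
                    continue
                clusters.append(
                    AnchorCluster(
                        chrom=paired.index.names[int(tid)],
                        tid=int(tid),
                        window=(int(p[a]), int(p[b]) + max_span),
                        side=side,
                        n_support=int(n),
                    )
                )
    clusters.sort(key=lambda c: (c.tid, c.window))
    return clusters


def build_clip_index(targets: dict[str, str], k: int = CLIP_K):
    """Secondary index (smaller k) for re-mapping short clipped pieces."""
    return build_index(targets, k=k)


def remap_clips(splits: pd.DataFrame, clip_index) -> pd.DataFrame:
    """Map every clipped piece against the clip index; appends columns.

    Added columns: c_tid, c_pos, c_strand, c_span (c_tid = -1 unmapped).
    """
    out = splits.copy()
    if len(splits) == 0:
        for col in ("c_tid", "c_pos", "c_strand", "c_span"):
            out[col] = np.empty(0, dtype=np.int64)
        return out
    seqs = splits["clipped_seq"].tolist()
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    mat = np.full((len(seqs), int(lens.max())), 4, dtype=np.uint8)
    from ._seq import encode

    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode(s)
    res = map_codes(mat, clip_index, lens=lens, stride=4, min_votes=1, min_span=15)
    out["c_tid"] = res["tid"].to_numpy()
    out["c_pos"] = res["pos"].to_numpy()
    out["c_strand"] = res["strand"].to_numpy()
    out["c_span"] = res["span"].to_numpy()
    return out


def translate_shared_locus(
    splits: pd.DataFrame,
    endo_tid: int,
    endo_clip_tid: int,
    locus: tuple[int, int],
    mono_tid: int,
    mono_clip_tid: int,
    shared_start: int,
) -> pd.DataFrame:
    """Lift split evidence from the endogenous shared locus onto the monomer.

    The monomer's shared segment and its endogenous locus are identical up
    to marker SNPs, so split pieces without a marker in range map
    ambiguously and tie-break to the endogenous contig. Junction typing
    needs them in monomer coordinates; the homology is known (same
    orientation), so the lift is a constant offset. Applied to both the
    mapped part and the re-mapped clip.
    """
    out = splits.copy()
    lo, hi = locus
    shift = shared_start - lo
    sel = (
        (out["tid"] == endo_tid)
        & (out["pos"] < hi)
        & (out["pos"] + out["span"] > lo)
    )
    out.loc[sel, "tid"] = mono_tid
    out.loc[sel, "pos"] += shift
    out.loc[sel, "boundary"] += shift
    if "c_tid" in out.columns:
        csel = (
            (out["c_tid"] == endo_clip_tid)
            & (out["c_pos"] < hi)
            & (out["c_pos"] + out["c_span"] > lo)
        )
        out.loc[csel, "c_tid"] = mono_clip_tid
        out.loc[csel, "c_pos"] += shift
    return out


def _junction_seq(paired: PairedAlignments, split_row, context_bp: int) -> str:
    oriented = paired.oriented_read(int(split_row.mate), int(split_row.row))
    aln = paired.aln(int(split_row.mate))
    cl = int(aln["clip_left"].iat[int(split_row.row)])
    span = int(aln["span"].iat[int(split_row.row)])
    i = cl if split_row.clip_side == "left" else cl + span
    w = min(context_bp, i, len(oriented) - i)
    return _BASES[oriented[i - w : i + w]].tobytes().decode()


def refine_breakpoint(
    cluster: AnchorCluster,
    splits: pd.DataFrame,
    paired: PairedAlignments,
    clip_index,
    transgene_clip_tids: set[int],
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    context_bp: int = CONTEXT_BP,
    min_split: int = MIN_SPLIT,
    tg_main_tids: set[int] | None = None,
    ref_clip_tid: int | None = None,
) -> JunctionCall:
    """Resolve one genome-transgene breakpoint from split reads.

    Qualifying splits sit on the cluster contig, clip toward the insertion,
    and their clipped piece re-maps to the transgene (or vector); the
    mirror-image observations — reads whose mapped part is on the transgene
    and whose clip re-maps into the cluster window — vote for the same
    boundary. The call is the modal boundary (ties toward the smaller
    coordinate); with no qualifying split the cluster-edge estimate from
    pair evidence is returned, flagged unresolved.
    """
    jtype = "genome_tg_left" if cluster.side == "left_of_insertion" else "genome_tg_right"
    want_side = "right" if cluster.side == "left_of_insertion" else "left"
    slack = insert_mean + 3 * insert_sd
    lo, hi = cluster.window[0] - _COORD_TOL, cluster.window[1] + slack
    if cluster.side == "right_of_insertion":
        lo, hi = cluster.window[0] - slack, cluster.window[1] + _COORD_TOL

    cand = splits[
        (splits["tid"] == cluster.tid)
        & (splits["clip_side"] == want_side)
        & (splits["boundary"] >= lo)
        & (splits["boundary"] <= hi)
    ]
    use = cand[cand["c_tid"].isin(list(transgene_clip_tids))]
    if len(use) == 0:
        use = cand
    # mirror-image splits (mapped on the transgene, clip re-mapped into the
    # window). Junction microhomology shifts their boundary by the homology
    # run, so they only corroborate the forward mode, or stand in for it
    # when no forward split exists.
    rev = pd.DataFrame()
    if tg_main_tids and ref_clip_tid is not None and "c_tid" in splits.columns:
        rev = splits[
            splits["tid"].isin(list(tg_main_tids)) & (splits["c_tid"] == ref_clip_tid)
        ].copy()
        if len(rev):
            rev["boundary"] = np.where(
                cluster.side == "left_of_insertion",
                rev["c_pos"] + rev["c_span"],
                rev["c_pos"],
            )
            rev = rev[(rev["boundary"] >= lo) & (rev["boundary"] <= hi)]
    if len(use) == 0 and len(rev):
        use = rev
        rev = pd.DataFrame()

    if len(use) == 0:
        ref_pos = cluster.window[1] if cluster.side == "left_of_insertion" else cluster.window[0]
        return JunctionCall(
            type=jtype,
            ref_target=cluster.chrom,
            ref_pos=int(ref_pos),
            pair_support=cluster.n_support,
            resolved=False,
        )

    counts = Counter(int(b) for b in use["boundary"])
    top = max(counts.values())
    ref_pos = min(b for b, c in counts.items() if c == top)
    support = top
    if len(rev):
        support += int((rev["boundary"].sub(ref_pos).abs() <= _COORD_TOL).sum())
    at_mode = use[use["boundary"] == ref_pos]
    # prefer a reference-anchored split as the representative: its re-mapped
    # clip carries the transgene-side offset
    fwd = at_mode[at_mode["tid"] == cluster.tid]
    pick_from = fwd if len(fwd) else at_mode
    best = pick_from.loc[pick_from["clipped_seq"].str.len().idxmax()]

    tg_offset = None
    orientation = "+"
    if len(fwd) and int(best.c_tid) >= 0:
        if int(best.c_strand) >= 0:
            tg_offset = int(best.c_pos) if want_side == "right" else int(best.c_pos + best.c_span)
            orientation = "+"
        else:
            tg_offset = int(best.c_pos + best.c_span) if want_side == "right" else int(best.c_pos)
            orientation = "-"

    return JunctionCall(
        type=jtype,
        ref_target=cluster.chrom,
        ref_pos=int(ref_pos),
        tg_offset=tg_offset,
        orientation=orientation,
        split_support=int(support),
        pair_support=cluster.n_support,
        junction_seq=_junction_seq(paired, best, context_bp),
        resolved=support >= min_split,
    )


def discover_split_junctions(
    splits: pd.DataFrame,
    paired: PairedAlignments,
    transgene_clip_tids: set[int],
    reference_tids: set[int],
    context_bp: int = CONTEXT_BP,
    min_split: int = MIN_SPLIT,
) -> list[JunctionCall]:
    """Genome-transgene junction candidates from split reads alone.

    Anchored-pair clusters can miss a junction when few fragments straddle
    it cleanly; reads clipping into the transgene witness it directly.
    Confirmed splits (clip re-maps to the transgene/vector) on a reference
    contig are grouped by boundary (within a small tolerance); groups with
    >= min_split support become calls.
    """
    if len(splits) == 0 or "c_tid" not in splits.columns:
        return []
    cand = splits[
        splits["tid"].isin(list(reference_tids))
        & splits["c_tid"].isin(list(transgene_clip_tids))
    ]
    calls = []
    for side, jtype in (("right", "genome_tg_left"), ("left", "genome_tg_right")):
        rows = cand[cand["clip_side"] == side]
        if not len(rows):
            continue
        groups: dict[tuple[int, int], list] = {}
        for row in rows.itertuples():
            key = None
            for (t, b) in groups:
                if t == row.tid and abs(b - row.boundary) <= _COORD_TOL:
                    key = (t, b)
                    break
            if key is None:
                groups[(int(row.tid), int(row.boundary))] = [row]
            else:
                groups[key].append(row)
        for (tid, _), grp in groups.items():
            if len(grp) < min_split:
                continue
            counts = Counter(int(r.boundary) for r in grp)
            top = max(counts.values())
            ref_pos = min(b for b, c in counts.items() if c == top)
            at_mode = [r for r in grp if r.boundary == ref_pos]
            best = max(at_mode, key=lambda r: len(r.clipped_seq))
            if int(best.c_strand) >= 0:
                tg_off = int(best.c_pos) if side == "right" else int(best.c_pos + best.c_span)
                orient = "+"
            else:
                tg_off = int(best.c_pos + best.c_span) if side == "right" else int(best.c_pos)
                orient = "-"
            calls.append(
                JunctionCall(
                    type=jtype,
                    ref_target=paired.index.names[tid],
                    ref_pos=int(ref_pos),
                    tg_offset=tg_off,
                    orientation=orient,
                    split_support=int(top),
                    pair_support=0,
                    junction_seq=_junction_seq(paired, best, context_bp),
                    resolved=top >= min_split,
                )
            )
    return calls


def type_internal_junctions(
    paired: PairedAlignments,
    splits: pd.DataFrame,
    clip_index,
    monomer_target: str,
    monomer_length: int,
    vector_targets: set[str] = frozenset(),
    context_bp: int = CONTEXT_BP,
    min_split: int = MIN_SPLIT,
) -> list[JunctionCall]:
    """Type array-internal junctions from transgene-anchored split reads.

    A split whose mapped part and clipped piece both land on the monomer is
    co-linear (head-to-tail when it wraps end->start) or inverted
    (head-to-head when both sides converge at the 5' end, tail-to-tail at
    the 3' end). Clips landing on a catalogued vector give the
    transgene-vector junctions, oriented in array space via the mapped
    strand. Unexplained configurations are reported verbatim rather than
    forced into a type.
    """
    names = paired.index.names
    mono_tid = names.index(monomer_target)
    clip_names = clip_index.names
    clip_mono = {i for i, n in enumerate(clip_names) if n == monomer_target}
    clip_vec = {i for i, n in enumerate(clip_names) if n in vector_targets}
    L = monomer_length

    cand = splits[(splits["tid"] == mono_tid) & (splits["c_tid"] >= 0)]
    votes: dict[tuple, list] = {}
    for row in cand.itertuples():
        c_tid = int(row.c_tid)
        b_m = int(row.boundary)
        if int(row.c_strand) >= 0:
            c0 = int(row.c_pos) if row.clip_side == "right" else int(row.c_pos + row.c_span)
        else:
            c0 = int(row.c_pos + row.c_span) if row.clip_side == "right" else int(row.c_pos)
        if c_tid in clip_vec:
            # array-space order of (monomer, vector) flips with mapped strand
            mono_first = (row.clip_side == "right") == (int(row.strand) > 0)
            jtype = "tg_vector" if mono_first else "vector_tg"
            key = (jtype, b_m, c0)
        elif c_tid in clip_mono:
            colinear = int(row.c_strand) > 0
            near0_m, nearL_m = b_m <= _COORD_TOL, b_m >= L - _COORD_TOL
            near0_c, nearL_c = c0 <= _COORD_TOL, c0 >= L - _COORD_TOL
            if colinear and (
                (row.clip_side == "right" and nearL_m and near0_c)
                or (row.clip_side == "left" and near0_m and nearL_c)
            ):
                jtype, key = "tg_head_to_tail", ("tg_head_to_tail", 0, 0)
            elif not colinear and near0_m and near0_c:
                jtype, key = "tg_head_to_head", ("tg_head_to_head", 0, 0)
            elif not colinear and nearL_m and nearL_c:
                jtype, key = "tg_tail_to_tail", ("tg_tail_to_tail", 0, 0)
            else:
                jtype, key = "tg_unexplained", ("tg_unexplained", b_m, c0)
        else:
            continue
        votes.setdefault(key, []).append(row)

    # merge keys of one type whose coordinates agree within tolerance
    # (junction microhomology jitters the clip boundary by a base or two)
    merged: dict[tuple, list] = {}
    for (jtype, b_m, c0), rows in sorted(
        votes.items(), key=lambda kv: (-len(kv[1]), kv[0])
    ):
        home = None
        for (mt, mb, mc) in merged:
            if mt == jtype and abs(mb - b_m) <= _COORD_TOL and abs(mc - c0) <= _COORD_TOL:
                home = (mt, mb, mc)
                break
        if home is None:
            merged[(jtype, b_m, c0)] = list(rows)
        else:
            merged[home].extend(rows)

    calls = []
    for (jtype, b_m, c0), rows in sorted(merged.items(), key=lambda kv: -len(kv[1])):
        best = max(rows, key=lambda r: len(r.clipped_seq))
        calls.append(
            JunctionCall(
                type=jtype,
                ref_target=None,
                ref_pos=None,
                tg_offset=int(best.boundary),
                orientation="+" if int(best.c_strand) >= 0 else "-",
                split_support=len(rows),
                junction_seq=_junction_seq(paired, best, context_bp),
                resolved=len(rows) >= min_split,
            )
        )
    return calls


def validate_expected_model(
    expected: InsertionModel,
    observed: list[JunctionCall],
    tolerance_bp: int = 5,
) -> dict:
    """Compare an expected junction configuration with observed calls."""
    discrepancies = []
    obs_types = {j.type for j in observed}
    for exp in expected.junctions():
        match = None
        for obs in observed:
            if obs.type != exp.type:
                continue
            if exp.ref_pos is not None and obs.ref_pos is not None:
                if abs(obs.ref_pos - exp.ref_pos) > tolerance_bp:
                    continue
            match = obs
            break
        if match is None:
            discrepancies.append(f"missing expected junction {exp.type}")
    expected_types = {j.type for j in expected.junctions()}
    unexpected = sorted(obs_types - expected_types)
    return {
        "pass": not discrepancies and not unexpected,
        "discrepancies": discrepancies,
        "unexpected_types": unexpected,
    }
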