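"""Depth- and marker-based quantification of a TgINDEL allele.

Three estimates characterize the allele:

* deletion/zygosity — mean depth inside the junction-implied interval over
  mean depth in the flanks (~0.5 for a hemizygous deletion, ~0 homozygous);
* copy number from marker alleles — transgene:endogenous allele-read ratio
  at marker SNPs in the shared segment, scaled by the endogenous copy
  count (a 35-fold ratio at a diploid locus means 70 transgene copies);
* copy number from depth — transgene depth over monomer-unique sequence
  relative to the diploid genome baseline.

The tet-operator count follows as copies x sites-per-monomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import PairedAlignments

ZYGOSITY_NONE_MIN = 0.8
ZYGOSITY_HEMI = (0.35, 0.65)
ZYGOSITY_HOMO_MAX = 0.1
SITES_PER_MONOMER = 7


@dataclass
class DepthProfile:
    """Binned read-start counts on one target."""

    target: str
    bin_size: int
    counts: np.ndarray
    read_length: int
    target_length: int

    @property
    def total_starts(self) -> int:
        return int(self.counts.sum())

    def starts_in(self, start: int, end: int) -> int:
        """Read starts in [start, end), resolved to bin boundaries exactly
        only when start/end are multiples of bin_size; otherwise pro-rated."""
        edges = np.arange(len(self.counts) + 1) * self.bin_size
        lo = np.clip((np.minimum(edges[1:], end) - np.maximum(edges[:-1], start))
                     / self.bin_size, 0, 1)
        return float((self.counts * lo).sum())

    def mean_depth(self, start: int = 0, end: int | None = None) -> float:
        end = self.target_length if end is None else end
        if end <= start:
            raise ValueError("empty interval")
        return self.starts_in(start, end) * self.read_length / (end - start)


def compute_depth(
    paired: PairedAlignments, target: str, bin_size: int = 1000, read_length: int | None = None
) -> DepthProfile:
    """Bin read starts of every mapped mate on one target."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    tid = paired.index.names.index(target)
    tlen = int(paired.index.lengths[tid])
    nbins = (tlen + bin_size - 1) // bin_size
    counts = np.zeros(nbins, dtype=np.int64)
    rl = read_length
    for mate in (1, 2):
        aln = paired.aln(mate)
        sel = aln["tid"].to_numpy() == tid
        pos = aln["pos"].to_numpy()[sel]
        np.add.at(counts, np.clip(pos // bin_size, 0, nbins - 1), 1)
        if rl is None and sel.any():
            rl = int(np.median(aln["length"].to_numpy()[sel]))
    return DepthProfile(
        target=target,
        bin_size=bin_size,
        counts=counts,
        read_length=int(rl or 0),
        target_length=tlen,
    )


@dataclass
class DeletionCall:
    interval: tuple[int, int]
    depth_ratio: float
    zygosity: str  # {none, hemizygous, homozygous, ambiguous}
    flank_bp: int
    edge_flagged: bool = False

    @staticmethod
    def zygosity_from_ratio(ratio: float) -> str:
        if ratio >= ZYGOSITY_NONE_MIN:
            return "none"
        if ZYGOSITY_HEMI[0] <= ratio <= ZYGOSITY_HEMI[1]:
            return "hemizygous"
        if ratio <= ZYGOSITY_HOMO_MAX:
            return "homozygous"
        return "ambiguous"


def call_deletion(
    profile: DepthProfile,
    candidate: tuple[int, int],
    flank_bp: int = 50000,
    exclude_bp: int = 350,
) -> DeletionCall:
    """Depth ratio inside the candidate interval vs its flanks -> zygosity.

    Flanks exclude ``exclude_bp`` (one insert length) nearest each
    breakpoint, where fragments straddling the junction dilute the signal.
    At a contig edge the genome-wide mean stands in for the missing flank
    and the call is flagged.
    """
    start, end = candidate
    if not 0 <= start < end <= profile.target_length:
        raise ValueError("candidate interval outside the target")
    inside = profile.mean_depth(start + exclude_bp, end - exclude_bp) \
        if end - start > 2 * exclude_bp else profile.mean_depth(start, end)

    flanks = []
    edge = False
    left_hi = start - exclude_bp
    left_lo = max(0, left_hi - flank_bp)
    if left_hi - left_lo > 0:
        flanks.append(profile.mean_depth(left_lo, left_hi))
        edge |= left_hi - left_lo < flank_bp
    else:
        edge = True
    right_lo = end + exclude_bp
    right_hi = min(profile.target_length, right_lo + flank_bp)
    if right_hi - right_lo > 0:
        flanks.append(profile.mean_depth(right_lo, right_hi))
        edge |= right_hi - right_lo < flank_bp
    else:
        edge = True
    baseline = float(np.mean(flanks)) if flanks else profile.mean_depth()
    ratio = inside / baseline if baseline > 0 else float("inf")
    return DeletionCall(
        interval=(start, end),
        depth_ratio=float(ratio),
        zygosity=DeletionCall.zygosity_from_ratio(ratio),
        flank_bp=flank_bp,
        edge_flagged=edge,
    )


@dataclass
class MarkerCounts:
    """Per-marker allele-discriminating read votes plus pooled totals."""

    per_marker: pd.DataFrame  # columns: marker, transgene, endogenous, other
    pooled_transgene: int
    pooled_endogenous: int
    pooled_other: int

    @property
    def pooled_ratio(self) -> float:
        if self.pooled_endogenous == 0:
            return float("inf")
        return self.pooled_transgene / self.pooled_endogenous


def count_marker_alleles(
    paired: PairedAlignments,
    markers: list[dict],
    monomer_target: str,
    endogenous_contig: str | None,
) -> MarkerCounts:
    """Vote each marker-overlapping read by its base at the marker.

    Each marker exists at two coordinates: ``monomer_pos`` on the transgene
    monomer and ``endogenous_pos`` on the endogenous-locus contig; votes
    are collected at both. A read voting for both alleles across linked
    markers is counted under "other" at every marker it touches (the
    conflict rule), as are non-allelic bases.
    """
    names = paired.index.names
    sites = []
    for mi, m in enumerate(markers):
        sites.append((mi, names.index(monomer_target), int(m["monomer_pos"]), m))
        if endogenous_contig is not None and m.get("endogenous_pos") is not None:
            sites.append((mi, names.index(endogenous_contig), int(m["endogenous_pos"]), m))

    base_codes = {b: i for i, b in enumerate("ACGT")}
    read_votes: dict[tuple[int, int], list[tuple[int, str]]] = {}
    for mate in (1, 2):
        aln = paired.aln(mate)
        tid = aln["tid"].to_numpy()
        pos = aln["pos"].to_numpy()
        span = aln["span"].to_numpy()
        cl = aln["clip_left"].to_numpy()
        strand = aln["strand"].to_numpy()
        lens = aln["length"].to_numpy()
        codes = paired.codes(mate)
        for mi, t, p, m in sites:
            hit = np.flatnonzero((tid == t) & (pos <= p) & (p < pos + span))
            for row in hit:
                # oriented-read index of the marker base
                oi = int(cl[row] + (p - pos[row]))
                if strand[row] > 0:
                    b = int(codes[row, oi])
                else:
                    b = int(codes[row, lens[row] - 1 - oi])
                    b = 3 - b if b <= 3 else b
                if b == base_codes[m["transgene_base"]]:
                    vote = "transgene"
                elif b == base_codes[m["endogenous_base"]]:
                    vote = "endogenous"
                else:
                    vote = "other"
                read_votes.setdefault((mate, int(row)), []).append((mi, vote))

    n = len(markers)
    counts = {k: np.zeros(n, dtype=np.int64) for k in ("transgene", "endogenous", "other")}
    for _, vlist in read_votes.items():
        kinds = {v for _, v in vlist}
        conflict = "transgene" in kinds and "endogenous" in kinds
        for mi, vote in vlist:
            counts["other" if conflict else vote][mi] += 1
    per_marker = pd.DataFrame(
        {
            "marker": np.arange(n),
            "offset": [m["offset"] for m in markers],
            "transgene": counts["transgene"],
            "endogenous": counts["endogenous"],
            "other": counts["other"],
        }
    )
    return MarkerCounts(
        per_marker=per_marker,
        pooled_transgene=int(counts["transgene"].sum()),
        pooled_endogenous=int(counts["endogenous"].sum()),
        pooled_other=int(counts["other"].sum()),
    )


@dataclass
class CopyNumberEstimate:
    method: str  # {marker_ratio, depth_ratio}
    point: float
    interval: tuple[float, float]
    endogenous_copies: int = 2
    lower_bound_only: bool = False

    @property
    def rounded(self) -> int:
        return int(round(self.point))


def copy_number_from_markers(
    counts: MarkerCounts, endogenous_copies: int = 2, ci: float = 0.95
) -> CopyNumberEstimate:
    """Copy number = endogenous_copies x (transgene : endogenous reads).

    The sampling interval uses the normal approximation to the log of a
    ratio of Poisson totals (var = 1/n_tg + 1/n_endo), an approximation
    that is adequate once both counts exceed ~10.
    """
    t, e = counts.pooled_transgene, counts.pooled_endogenous
    if e == 0:
        point = float("inf") if t else 0.0
        return CopyNumberEstimate(
            "marker_ratio", point, (float(endogenous_copies * t), float("inf")),
            endogenous_copies, lower_bound_only=True,
        )
    point = endogenous_copies * t / e
    if t == 0:
        return CopyNumberEstimate("marker_ratio", 0.0, (0.0, 0.0), endogenous_copies)
    z = stats.norm.ppf(0.5 + ci / 2)
    sd_log = np.sqrt(1 / t + 1 / e)
    return CopyNumberEstimate(
        "marker_ratio",
        float(point),
        (float(point * np.exp(-z * sd_log)), float(point * np.exp(z * sd_log))),
        endogenous_copies,
    )


def _pooled_depth(profile: DepthProfile, intervals) -> tuple[float, float]:
    """(mean depth, read starts) pooled over an interval list."""
    if not intervals:
        return profile.mean_depth(), float(profile.total_starts)
    starts = sum(profile.starts_in(a, b) for a, b in intervals)
    span = sum(b - a for a, b in intervals)
    return starts * profile.read_length / span, starts


def copy_number_from_depth(
    tg_profile: DepthProfile,
    baseline: DepthProfile,
    tg_intervals: list[tuple[int, int]] | None = None,
    baseline_intervals: list[tuple[int, int]] | None = None,
    ci: float = 0.95,
) -> CopyNumberEstimate:
    """Copy number = 2 x mean transgene depth / mean diploid baseline depth.

    ``tg_intervals`` restricts the transgene profile to monomer-unique
    sequence (the monomer minus its shared segment) so endogenous
    cross-mapping cannot inflate or deflate the estimate.
    """
    tg, n_tg = _pooled_depth(tg_profile, tg_intervals)
    base, n_base = _pooled_depth(baseline, baseline_intervals)
    if base == 0:
        raise ValueError("baseline depth is zero")
    point = 2 * tg / base
    z = stats.norm.ppf(0.5 + ci / 2)
    sd_log = np.sqrt(1 / max(n_tg, 1) + 1 / max(n_base, 1))
    return CopyNumberEstimate(
        "depth_ratio",
        float(point),
        (float(point * np.exp(-z * sd_log)), float(point * np.exp(z * sd_log))),
    )


def count_operator_sites(copies: int, sites_per_monomer: int = SITES_PER_MONOMER) -> int:
    """Total tet-operator (tTA binding) sites carried by the array."""
    if copies < 0 or sites_per_monomer < 0:
        raise ValueError("inputs must be non-negative")
    return copies * sites_per_monomer
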