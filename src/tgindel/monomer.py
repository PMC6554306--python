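"""Transgene monomer construction.

A monomer is one unit copy of the transgene construct: an ordered list of
named segments (promoter, a host-gene fragment shared with an endogenous
locus, the ORF, UTR, polyadenylation signal). The shared segment carries
marker SNPs — fixed base differences between the transgene-borne copy and
the endogenous locus — that later allow allele-specific read counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import check_dna, random_dna

#: segment order and lengths of the default tau-style construct:
#: TRE promoter, Prnp fragment (shared with the endogenous prion locus),
#: tau cDNA ORF, Mapt 3'UTR, SV40 polyadenylation signal.
TAU_SEGMENT_SPEC = [
    ("TRE_promoter", 500),
    ("Prnp_shared", 2000),
    ("tau_ORF", 1200),
    ("Mapt_UTR", 2000),
    ("SV40_polyA", 300),
]
TAU_SHARED_SEGMENT = "Prnp_shared"

#: tTA-style construct: a long CaMKII promoter fragment shared with the
#: endogenous CaMKIIa locus, the tTA ORF, and a polyadenylation signal.
TTA_SEGMENT_SPEC = [
    ("CaMKII_promoter_shared", 4000),
    ("tTA_ORF", 1008),
    ("SV40_polyA", 292),
]
TTA_SHARED_SEGMENT = "CaMKII_promoter_shared"


@dataclass(frozen=True)
class Marker:
    """One marker SNP inside the shared segment.

    ``offset`` is 0-based within the shared segment; the transgene copy
    carries ``transgene_base`` where the endogenous locus carries
    ``endogenous_base``.
    """

    offset: int
    transgene_base: str
    endogenous_base: str


@dataclass(frozen=True)
class TransgeneMonomer:
    """One transgene copy: ordered (name, sequence) segments plus markers."""

    segments: tuple[tuple[str, str], ...]
    shared_segment: str
    markers: tuple[Marker, ...] = field(default=())

    @property
    def sequence(self) -> str:
        return "".join(seq for _, seq in self.segments)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.segments)

    def segment_interval(self, name: str) -> tuple[int, int]:
        """Half-open [start, end) of a segment within the monomer."""
        start = 0
        for seg_name, seq in self.segments:
            if seg_name == name:
                return start, start + len(seq)
            start += len(seq)
        raise KeyError(name)

    @property
    def shared_interval(self) -> tuple[int, int]:
        return self.segment_interval(self.shared_segment)

    def marker_monomer_positions(self) -> list[int]:
        """Marker offsets lifted to monomer coordinates."""
        start, _ = self.shared_interval
        return [start + m.offset for m in self.markers]

    def endogenous_shared_sequence(self) -> str:
        """The shared segment as it appears at the endogenous locus."""
        start, end = self.shared_interval
        seq = list(self.sequence[start:end])
        for m in self.markers:
            seq[m.offset] = m.endogenous_base
        return "".join(seq)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        if self.shared_segment not in names:
            raise ValueError(f"shared segment {self.shared_segment!r} not among segments")
        for name, seq in self.segments:
            check_dna(seq, f"segment {name!r}")
        start, end = self.shared_interval
        shared_len = end - start
        offsets = [m.offset for m in self.markers]
        if len(set(offsets)) != len(offsets):
            raise ValueError("marker offsets are not distinct")
        for m in self.markers:
            if not 0 <= m.offset < shared_len:
                raise ValueError("marker offset outside the shared segment")
            if m.transgene_base == m.endogenous_base:
                raise ValueError("marker with identical transgene and endogenous base")
            if self.sequence[start + m.offset] != m.transgene_base:
                raise ValueError("marker transgene_base disagrees with the monomer sequence")


def build_monomer(
    segment_spec=TAU_SEGMENT_SPEC,
    shared_segment: str = TAU_SHARED_SEGMENT,
    marker_count: int = 5,
    marker_spacing: int = 20,
    seed: int | np.random.Generator = 0,
) -> TransgeneMonomer:
    """Build a (seeded) random monomer from a segment specification.

    ``segment_spec`` entries are ``(name, length)`` for random sequence or
    ``(name, explicit_sequence)``. Markers are placed on a regular grid of
    ``marker_spacing`` bp (>= 20) within the shared segment, centred so the
    set spans as much of the segment as the spacing allows; each marker's
    endogenous base is drawn uniformly among the three non-transgene bases.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    segments = []
    for name, spec in segment_spec:
        if isinstance(spec, int):
            if spec <= 0:
                raise ValueError(f"segment {name!r} has non-positive length")
            segments.append((name, random_dna(spec, rng)))
        else:
            segments.append((name, str(spec).upper()))

    shared_len = dict((n, len(s)) for n, s in segments).get(shared_segment)
    if shared_len is None:
        raise ValueError(f"shared segment {shared_segment!r} not among segments")
    if marker_count < 0:
        raise ValueError("marker_count must be >= 0")
    if marker_spacing < 20:
        raise ValueError("marker_spacing must be >= 20 bp")
    span = (marker_count - 1) * marker_spacing if marker_count else 0
    if span >= shared_len or marker_count > shared_len:
        raise ValueError("marker set does not fit inside the shared segment")

    shared_seq = dict(segments)[shared_segment]
    first = (shared_len - span) // 2
    markers = []
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i in range(marker_count):
        off = first + i * marker_spacing
        tg = shared_seq[off]
        endo = others[tg][rng.integers(0, 3)]
        markers.append(Marker(offset=off, transgene_base=tg, endogenous_base=endo))

    return TransgeneMonomer(
        segments=tuple(segments),
        shared_segment=shared_segment,
        markers=tuple(markers),
    )
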