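"""Diploid transgenic genome construction and the machine-readable truth record.

A TgINDEL allele replaces a reference interval [start, end) on the carrier
haplotype with a rendered transgene array. The truth record captures
everything a scorer needs: the allele, the marker catalog in both
coordinate systems (monomer offset and endogenous-locus position), the
canonical (microhomology-trimmed) deletion interval, and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

from .arrays import ArrayModel, render_array
from .monomer import Marker, TransgeneMonomer


@dataclass(frozen=True)
class TgIndelAllele:
    """One transgene insertion/deletion allele on a diploid genome."""

    chrom: str
    deletion_start: int
    deletion_end: int
    array: ArrayModel
    carrier_haplotype: int = 1
    zygosity: str = "hemizygous"  # {hemizygous, homozygous}

    @property
    def deletion_length(self) -> int:
        return self.deletion_end - self.deletion_start

    def __post_init__(self) -> None:
        if not 0 <= self.deletion_start < self.deletion_end:
            raise ValueError("deletion interval must satisfy 0 <= start < end")
        if self.carrier_haplotype not in (1, 2):
            raise ValueError("carrier_haplotype must be 1 or 2")
        if self.zygosity not in ("hemizygous", "homozygous"):
            raise ValueError("zygosity must be hemizygous or homozygous")


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def canonical_deletion(reference: str, allele: TgIndelAllele, array_seq: str) -> tuple[int, int]:
    """Trim junction microhomology to the canonical breakpoint representation.

    If the array begins with the same bases as the deleted reference
    segment (or ends with its last bases), the breakpoints are ambiguous;
    the canonical form trims the common prefix/suffix, which is exactly
    where maximal read extension places the junctions.
    """
    deleted = reference[allele.deletion_start:allele.deletion_end]
    p = _common_prefix(deleted, array_seq)
    s = _common_prefix(deleted[p:][::-1], array_seq[p:][::-1])
    return allele.deletion_start + p, allele.deletion_end - s


@dataclass
class TruthRecord:
    """Serializable ground truth for a simulated TgINDEL genome."""

    chrom: str
    deletion_start: int
    deletion_end: int
    canonical_start: int
    canonical_end: int
    zygosity: str
    carrier_haplotype: int
    n_copies: int
    copy_count_convention: str  # {all_copies, complete_copies_only}
    switch_index: int
    has_switch: bool
    spacer_length: int
    five_prime_partial: int
    three_prime_partial: int
    monomer_length: int
    array_length: int
    shared_segment: str
    shared_interval: tuple[int, int]
    markers: list[dict] = field(default_factory=list)
    endogenous_locus: dict | None = None  # {contig, start} of the shared segment copy
    seed: int | None = None

    @property
    def canonical_deletion_length(self) -> int:
        return self.canonical_end - self.canonical_start

    @property
    def deletion_length(self) -> int:
        return self.deletion_end - self.deletion_start

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "TruthRecord":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            data = json.loads(text if text.lstrip().startswith("{") else open(text).read())
        data["shared_interval"] = tuple(data["shared_interval"])
        return cls(**data)


def apply_tgindel(
    reference: dict[str, str],
    allele: TgIndelAllele,
    monomer: TransgeneMonomer,
    endogenous_locus: tuple[str, int] | None = None,
    copy_count_convention: str = "all_copies",
    seed: int | None = None,
) -> tuple[dict[str, dict[str, str]], TruthRecord]:
    """Build the diploid genome carrying the allele, plus its truth record.

    Returns ``(haplotypes, truth)`` where ``haplotypes`` maps haplotype name
    ("hap1"/"hap2") to {contig: sequence}. The carrier haplotype has the
    deletion interval replaced by the rendered array; under homozygosity
    both haplotypes carry it. ``endogenous_locus`` = (contig, position)
    states where the monomer's shared segment, with endogenous marker
    alleles, has been placed in the reference (for marker bookkeeping).
    """
    chrom_seq = reference.get(allele.chrom)
    if chrom_seq is None:
        raise ValueError(f"contig {allele.chrom!r} absent from reference")
    if allele.deletion_end > len(chrom_seq):
        raise ValueError("deletion interval extends past the end of the contig")

    array_seq = render_array(monomer, allele.array)
    carrier_chrom = (
        chrom_seq[: allele.deletion_start] + array_seq + chrom_seq[allele.deletion_end:]
    )

    haps: dict[str, dict[str, str]] = {}
    for idx, name in ((1, "hap1"), (2, "hap2")):
        carries = allele.zygosity == "homozygous" or idx == allele.carrier_haplotype
        haps[name] = {
            contig: (carrier_chrom if (carries and contig == allele.chrom) else seq)
            for contig, seq in reference.items()
        }

    can_start, can_end = canonical_deletion(chrom_seq, allele, array_seq)
    shared_start, shared_end = monomer.shared_interval
    markers = [
        {
            "offset": m.offset,
            "monomer_pos": shared_start + m.offset,
            "transgene_base": m.transgene_base,
            "endogenous_base": m.endogenous_base,
            "endogenous_pos": (endogenous_locus[1] + m.offset) if endogenous_locus else None,
        }
        for m in monomer.markers
    ]
    truth = TruthRecord(
        chrom=allele.chrom,
        deletion_start=allele.deletion_start,
        deletion_end=allele.deletion_end,
        canonical_start=can_start,
        canonical_end=can_end,
        zygosity=allele.zygosity,
        carrier_haplotype=allele.carrier_haplotype,
        n_copies=allele.array.n_copies,
        copy_count_convention=copy_count_convention,
        switch_index=allele.array.switch_index,
        has_switch=allele.array.has_switch,
        spacer_length=len(allele.array.spacer),
        five_prime_partial=allele.array.five_prime_partial,
        three_prime_partial=allele.array.three_prime_partial,
        monomer_length=monomer.total_length,
        array_length=len(array_seq),
        shared_segment=monomer.shared_segment,
        shared_interval=(shared_start, shared_end),
        markers=markers,
        endogenous_locus=(
            {"contig": endogenous_locus[0], "start": endogenous_locus[1]}
            if endogenous_locus
            else None
        ),
        seed=seed,
    )
    return haps, truth
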