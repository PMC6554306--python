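"""Study fixtures: YAML-encoded allele architectures and their realization.

The two shipped fixtures encode the characterized rTg4510 alleles — the
~70-copy tau array in a 243,608 bp Fgf14 deletion and the ~7-copy tTA
array (vector fragment at the orientation switch) in a 508,119 bp
Vipr2–Ptprn2 deletion — on synthetic working loci. ``build_fixture``
realizes a fixture into reference, monomer, diploid haplotypes, truth
record and annotation for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from ._seq import random_dna
from .annotate import TranscriptModel
from .arrays import ArrayModel
from .genome import TgIndelAllele, TruthRecord, apply_tgindel
from .monomer import TransgeneMonomer, build_monomer
from .reads import ReadSimParams

FIXTURE_FILES = {
    "fgf14_tgindel": "data/fgf14_tgindel.yaml",
    "vipr2_ptprn2_tgindel": "data/vipr2_ptprn2_tgindel.yaml",
}

VECTOR_NAME = "cloning_vector"


def load_fixture_config(name_or_path) -> dict:
    """Load a fixture YAML by shipped name or filesystem path."""
    key = str(name_or_path)
    if key in FIXTURE_FILES:
        text = resources.files("tgindel").joinpath(FIXTURE_FILES[key]).read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@dataclass
class Fixture:
    """A fully realized simulated study."""

    name: str
    config: dict
    reference: dict[str, str]
    monomer: TransgeneMonomer
    allele: TgIndelAllele
    haplotypes: dict[str, dict[str, str]]
    truth: TruthRecord
    read_params: ReadSimParams
    vector_catalog: dict[str, str] = field(default_factory=dict)
    transcripts: list[TranscriptModel] = field(default_factory=list)
    annotation_contig: str | None = None

    @property
    def transgene_target(self) -> str:
        return "transgene_monomer"

    def align_targets(self) -> dict[str, str]:
        """Targets for the primary mapping: reference contigs + monomer."""
        return {**self.reference, self.transgene_target: self.monomer.sequence}

    def clip_targets(self) -> dict[str, str]:
        """Targets for clipped-piece re-mapping: adds the vector catalog."""
        return {**self.align_targets(), **self.vector_catalog}


def _transcripts_from_config(ann: dict, contig: str) -> list[TranscriptModel]:
    out = []
    for gene in ann.get("genes", []):
        for tx in gene["transcripts"]:
            out.append(
                TranscriptModel(
                    gene=gene["name"],
                    transcript_id=tx["id"],
                    chrom=contig,
                    strand=tx["strand"],
                    exons=tuple(tuple(e) for e in tx["exons"]),
                    biotype=gene.get("biotype", "protein_coding"),
                )
            )
    return out


def build_fixture(name_or_path, seed: int) -> Fixture:
    """Realize a fixture architecture with a run seed.

    The seed drives every random choice (reference sequence, monomer
    segments, marker alleles, vector sequence); read simulation derives its
    own child seed so genome and reads are independently reproducible.
    """
    cfg = name_or_path if isinstance(name_or_path, dict) else load_fixture_config(name_or_path)
    master = np.random.default_rng(seed)
    sub = master.integers(0, 2**31 - 1, size=4)
    ref_rng = np.random.default_rng(sub[0])
    mono_rng = np.random.default_rng(sub[1])
    vec_rng = np.random.default_rng(sub[2])

    reference = {c["name"]: random_dna(int(c["length"]), ref_rng) for c in cfg["contigs"]}

    mcfg = cfg["monomer"]
    monomer = build_monomer(
        segment_spec=[(n, v) for n, v in mcfg["segments"]],
        shared_segment=mcfg["shared_segment"],
        marker_count=int(mcfg.get("marker_count", 5)),
        marker_spacing=int(mcfg.get("marker_spacing", 20)),
        seed=mono_rng,
    )

    endo = cfg.get("endogenous_locus")
    endo_tuple = None
    if endo:
        contig, pos = endo["contig"], int(endo["position"])
        shared = monomer.endogenous_shared_sequence()
        seq = reference[contig]
        if pos + len(shared) > len(seq):
            raise ValueError("endogenous locus does not fit on its contig")
        reference[contig] = seq[:pos] + shared + seq[pos + len(shared):]
        endo_tuple = (contig, pos)

    acfg = cfg["array"]
    spacer_len = int(acfg.get("spacer_length", 0))
    spacer = random_dna(spacer_len, vec_rng) if spacer_len else ""
    array = ArrayModel(
        n_copies=int(acfg["n_copies"]),
        switch_index=int(acfg.get("switch_index", 0)),
        spacer=spacer,
        five_prime_partial=int(acfg.get("five_prime_partial", 0)),
        three_prime_partial=int(acfg.get("three_prime_partial", 0)),
    )

    alcfg = cfg["allele"]
    allele = TgIndelAllele(
        chrom=alcfg["contig"],
        deletion_start=int(alcfg["deletion_start"]),
        deletion_end=int(alcfg["deletion_end"]),
        array=array,
        carrier_haplotype=int(alcfg.get("carrier_haplotype", 1)),
        zygosity=alcfg.get("zygosity", "hemizygous"),
    )
    haps, truth = apply_tgindel(
        reference,
        allele,
        monomer,
        endogenous_locus=endo_tuple,
        copy_count_convention=cfg.get("copy_count_convention", "all_copies"),
        seed=seed,
    )

    rcfg = cfg.get("reads", {})
    params = ReadSimParams(
        read_length=int(rcfg.get("read_length", 125)),
        insert_mean=int(rcfg.get("insert_mean", 350)),
        insert_sd=float(rcfg.get("insert_sd", 50)),
        coverage=float(rcfg.get("coverage", 10.0)),
        substitution_error_rate=float(rcfg.get("substitution_error_rate", 0.0)),
        seed=int(sub[3]),
    )

    ann = cfg.get("annotation") or {}
    ann_contig = ann.get("annotation_contig", allele.chrom)
    transcripts = _transcripts_from_config(ann, ann_contig)

    return Fixture(
        name=cfg.get("name", str(name_or_path)),
        config=cfg,
        reference=reference,
        monomer=monomer,
        allele=allele,
        haplotypes=haps,
        truth=truth,
        read_params=params,
        vector_catalog={VECTOR_NAME: spacer} if spacer else {},
        transcripts=transcripts,
        annotation_contig=ann_contig,
    )


def toy_fixture_config(
    n_copies: int = 10,
    switch_index: int = 0,
    spacer_length: int = 0,
    zygosity: str = "hemizygous",
    coverage: float = 30.0,
    error_rate: float = 0.0,
    contig_length: int = 30000,
    deletion: tuple[int, int] = (10000, 18000),
    monomer_segments=None,
    marker_count: int = 5,
    marker_spacing: int = 150,
    endo_contig_length: int = 8000,
) -> dict:
    """A small, fast fixture config for property tests and replicates."""
    if monomer_segments is None:
        monomer_segments = [
            ["promoter", 300],
            ["shared", 900],
            ["orf", 500],
            ["polyA", 200],
        ]
    shared = monomer_segments[1][0]
    return {
        "name": f"toy_{n_copies}x",
        "contigs": [
            {"name": "chrT", "length": contig_length},
            {"name": "chrE", "length": endo_contig_length},
        ],
        "endogenous_locus": {"contig": "chrE", "position": 2000},
        "monomer": {
            "segments": monomer_segments,
            "shared_segment": shared,
            "marker_count": marker_count,
            "marker_spacing": marker_spacing,
        },
        "array": {
            "n_copies": n_copies,
            "switch_index": switch_index,
            "spacer_length": spacer_length,
        },
        "allele": {
            "contig": "chrT",
            "deletion_start": deletion[0],
            "deletion_end": deletion[1],
            "zygosity": zygosity,
        },
        "reads": {
            "read_length": 125,
            "insert_mean": 350,
            "insert_sd": 50,
            "coverage": coverage,
            "substitution_error_rate": error_rate,
        },
        "quant": {"sites_per_monomer": 7},
    }


def build_toy_fixture(seed: int, **kwargs) -> Fixture:
    return build_fixture(toy_fixture_config(**kwargs), seed)
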