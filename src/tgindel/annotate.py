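"""Gene/transcript disruption classification for a called deletion.

Per transcript, the deletion is classified as: fully_deleted (transcript
span contained in the deletion), promoter_and_first_exon_lost (promoter
window plus first exon removed, later exons retained — the configuration
that silences a splice variant while leaving downstream variants intact),
five_/three_prime_truncated (strand-aware end overlap; a deletion wholly
internal to the transcript is assigned to the end nearer the overlap
midpoint), or intact. Genes roll up to their worst-case transcript;
predicted/uncharacterized genes are tallied separately from the headline
disrupted count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PROMOTER_BP = 2000

DISRUPTION_ORDER = [
    "fully_deleted",
    "promoter_and_first_exon_lost",
    "five_prime_truncated",
    "three_prime_truncated",
    "intact",
]
_RANK = {c: i for i, c in enumerate(DISRUPTION_ORDER)}


@dataclass(frozen=True)
class TranscriptModel:
    gene: str
    transcript_id: str
    chrom: str
    strand: str  # {+, -}
    exons: tuple[tuple[int, int], ...]
    promoter_bp: int = PROMOTER_BP
    biotype: str = "protein_coding"  # "predicted" genes are counted separately

    def __post_init__(self) -> None:
        ex = list(self.exons)
        if ex != sorted(ex) or any(a >= b for a, b in ex):
            raise ValueError("exons must be sorted, non-empty, half-open")
        for (_, e0), (s1, _) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ValueError("exons must not overlap")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1]

    @property
    def promoter_window(self) -> tuple[int, int]:
        # may extend past the contig bounds; harmless for interval overlap
        if self.strand == "+":
            return self.tss - self.promoter_bp, self.tss
        return self.tss, self.tss + self.promoter_bp

    @property
    def first_exon(self) -> tuple[int, int]:
        return self.exons[0] if self.strand == "+" else self.exons[-1]


def _covers(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_disruption(
    transcript: TranscriptModel,
    deletion: tuple[int, int],
    chrom: str | None = None,
) -> str:
    """Classify the impact of a deletion interval on one transcript."""
    if chrom is not None and chrom != transcript.chrom:
        raise ValueError(
            f"deletion contig {chrom!r} does not match transcript contig "
            f"{transcript.chrom!r}"
        )
    span = transcript.span
    if _covers(deletion, span):
        return "fully_deleted"
    prom = transcript.promoter_window
    touches = _overlap(deletion, span) > 0 or _overlap(deletion, prom) > 0
    if not touches:
        return "intact"
    if _covers(deletion, prom) and _covers(deletion, transcript.first_exon):
        return "promoter_and_first_exon_lost"
    if _overlap(deletion, span) == 0:
        # promoter-only overlap: 5' regulatory loss by definition
        return "five_prime_truncated"
    # which transcript end does the removed material sit toward?
    lo, hi = max(deletion[0], span[0]), min(deletion[1], span[1])
    mid = (lo + hi) / 2
    left_half = mid <= (span[0] + span[1]) / 2
    if transcript.strand == "+":
        return "five_prime_truncated" if left_half else "three_prime_truncated"
    return "three_prime_truncated" if left_half else "five_prime_truncated"


@dataclass
class DisruptionReport:
    per_transcript: pd.DataFrame  # gene, transcript, biotype, class
    per_gene: pd.DataFrame  # gene, biotype, worst_class
    deletion: tuple[int, int] = (0, 0)
    chrom: str = ""

    @property
    def counts(self) -> dict[str, int]:
        annotated = self.per_gene[self.per_gene["biotype"] != "predicted"]
        predicted = self.per_gene[self.per_gene["biotype"] == "predicted"]
        return {
            "genes_total": int(len(self.per_gene)),
            "genes_disrupted_annotated": int((annotated["worst_class"] != "intact").sum()),
            "genes_disrupted_predicted": int((predicted["worst_class"] != "intact").sum()),
        }


def build_disruption_report(
    transcripts: list[TranscriptModel],
    deletion: tuple[int, int],
    chrom: str,
) -> DisruptionReport:
    rows = []
    for t in transcripts:
        if t.chrom != chrom:
            cls = "intact"
        else:
            cls = classify_disruption(t, deletion)
        rows.append(
            {"gene": t.gene, "transcript": t.transcript_id, "biotype": t.biotype, "class": cls}
        )
    per_tx = pd.DataFrame(rows, columns=["gene", "transcript", "biotype", "class"])
    if len(per_tx):
        worst = (
            per_tx.assign(rank=per_tx["class"].map(_RANK))
            .groupby("gene", sort=True)
            .agg(biotype=("biotype", "first"), rank=("rank", "min"))
            .reset_index()
        )
        worst["worst_class"] = worst.pop("rank").map(dict(enumerate(DISRUPTION_ORDER)))
    else:
        worst = pd.DataFrame(columns=["gene", "biotype", "worst_class"])
    return DisruptionReport(per_transcript=per_tx, per_gene=worst, deletion=deletion, chrom=chrom)


def count_disrupted_genes(report: DisruptionReport) -> int:
    """Headline count: annotated (non-predicted) genes not left intact."""
    return report.counts["genes_disrupted_annotated"]


# ---------------------------------------------------------------------------
# annotation I/O

def read_gff3(path, promoter_bp: int = PROMOTER_BP) -> list[TranscriptModel]:
    """Load a gene -> mRNA -> exon GFF3 hierarchy (other features ignored)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for gene in db.features_of_type("gene"):
        gname = gene.attributes.get("Name", [gene.id])[0]
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
            )
            if not exons:
                continue
            out.append(
                TranscriptModel(
                    gene=gname,
                    transcript_id=mrna.id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=tuple(exons),
                    promoter_bp=promoter_bp,
                    biotype=biotype,
                )
            )
    return out


def read_bed12(path, promoter_bp: int = PROMOTER_BP) -> list[TranscriptModel]:
    """Load transcripts from BED12 (name field = gene|transcript[|biotype])."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            parts = f[3].split("|")
            gene = parts[0]
            tx = parts[1] if len(parts) > 1 else parts[0]
            biotype = parts[2] if len(parts) > 2 else "protein_coding"
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            out.append(
                TranscriptModel(
                    gene=gene, transcript_id=tx, chrom=chrom, strand=f[5],
                    exons=exons, promoter_bp=promoter_bp, biotype=biotype,
                )
            )
    return out


def write_gff3(transcripts: list[TranscriptModel], path) -> None:
    """Write transcripts as a minimal gene -> mRNA -> exon GFF3."""
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gname, txs in genes.items():
            chrom, strand, bt = txs[0].chrom, txs[0].strand, txs[0].biotype
            gs = min(t.span[0] for t in txs)
            ge = max(t.span[1] for t in txs)
            fh.write(
                f"{chrom}\t.\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
                f"ID=gene:{gname};Name={gname};biotype={bt}\n"
            )
            for t in txs:
                s, e = t.span
                fh.write(
                    f"{chrom}\t.\tmRNA\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent=gene:{gname}\n"
                )
                for i, (es, ee) in enumerate(t.exons):
                    fh.write(
                        f"{chrom}\t.\texon\t{es + 1}\t{ee}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.e{i};Parent={t.transcript_id}\n"
                    )
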