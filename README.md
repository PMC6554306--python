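# tgindel

Characterize **transgene insertion/deletion (TgINDEL) alleles** from
paired-end whole-genome sequencing.

Transgenic mouse lines made by pronuclear injection carry the construct as
a multimeric array integrated at a random genomic site, and the integration
event often deletes host sequence around the insertion point. The
best-known case is the rTg4510 tauopathy model: its tau-transgene allele is
a ~70-copy array replacing ~244 kb of *Fgf14*, and its tTA-driver allele is
a ~7-copy array replacing ~508 kb across *Vipr2*–*Ptprn2*. Such alleles
disrupt genes and add hundreds of synthetic regulatory sites, so any lab
using a classic transgenic line needs them mapped precisely. `tgindel`
does that from one ordinary short-read library, and ships a synthetic-data
module that simulates transgenic diploid genomes end to end so the whole
pipeline is testable without any external data.

## What it computes

Given reads, a reference genome and the transgene monomer sequence:

* **Insertion junctions** — read pairs with one mate on the monomer anchor
  the insertion locus; soft-clipped reads whose clipped piece re-maps to
  the other side resolve each genome–transgene breakpoint to base pair
  (modal clip boundary, microhomology-normalized).
* **Deletion and zygosity** — the interval between the left and right
  junctions is the replaced segment; mean read depth inside over the flanks
  calls zygosity (≈0.5 → hemizygous, ≈0 → homozygous).
* **Array copy number**, two ways. Marker SNPs distinguish the transgene's
  embedded host-gene fragment from the endogenous locus; with an
  endogenous diploid locus,
  `copies = 2 · (transgene allele reads / endogenous allele reads)`, so a
  35-fold read ratio means 70 copies. Independently,
  `copies = 2 · depth(monomer-unique) / depth(genome baseline)`.
* **Internal array structure** — head-to-tail seams, the head-to-head
  (5′–5′) junction marking an internal orientation switch, and
  transgene–vector junctions when a cloning-vector fragment sits at the
  inversion point. The switch's position *within* the array is reported as
  unresolvable (short reads cannot phase near-identical copies).
* **Gene disruption** — each annotated transcript is classified against
  the called deletion (fully deleted, promoter+first-exon lost, 5′/3′
  truncated, intact) and genes roll up to a disrupted-gene count.
* **Consensus monomer** — per-position majority vote over the monomer
  pileup, plus a tet-operator tally (copies × sites per monomer).

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

The shipped fixture `fgf14_tgindel` encodes the 70-copy / 243,608 bp
hemizygous allele architecture on a synthetic 1 Mb locus. One command
simulates it at 10× coverage and runs the full characterization:

```bash
tgindel run --config fgf14_tgindel --out out/ --seed 1
```

prints

```json
{
 "deletion_length": 243608,
 "zygosity": "hemizygous",
 "copy_number_marker": 71,
 "copy_number_depth": 71,
 "junction_types": [
  "genome_tg_left",
  "genome_tg_right",
  "tg_head_to_head",
  "tg_head_to_tail",
  "tg_unexplained"
 ]
}
```

Reading: both genome–transgene breakpoints were recovered exactly, so the
implied deletion length equals the simulated truth (243,608 bp); depth
inside the interval is half the flanking depth (hemizygous); both
copy-number estimators land at 71 against a true 70 (the marker estimator's
95% sampling interval at 10× spans roughly ±8 copies); the head-to-head
junction shows the array's internal orientation switch, head-to-tail seams
show the tandem array itself, and one weakly-supported unexplained split
configuration is reported verbatim rather than forced into a type.
`out/` holds the full report (`report.json`, schema-validated, with a
truth-scoring section), junction sequences as FASTA (primer-design ready),
per-marker allele counts, pair-class tables and the simulated
FASTA/FASTQ/truth files.

The same stages are available as library calls (`tgindel.build_fixture`,
`tgindel.run_pipeline`, and the per-stage functions `map_pairs`,
`classify_pairs`, `cluster_anchors`, `refine_breakpoint`,
`count_marker_alleles`, `copy_number_from_markers`, ...) and as separate
`tgindel simulate` / `tgindel align` subcommands; external soft-clipped
SAM alignments can replace the built-in mapper.

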