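# Methods

## The problem

Classic pronuclear-injection transgenesis integrates the injected construct
as a multimeric array at an essentially random genomic site, and the
recombination event frequently deletes host sequence flanking the
integration point. The resulting allele — a transgene insertion coupled to
a deletion (TgINDEL) — can disrupt genes and carry hundreds of synthetic
regulatory elements, confounding any phenotype attributed to the transgene
product. `tgindel` characterizes such alleles from ordinary paired-end
whole-genome sequencing: where the array landed, how much host sequence it
replaced, the zygosity of the replacement, how many transgene copies the
array holds, whether the array's internal orientation switches, and which
annotated genes the deletion disrupts.

## Evidence model

All inference runs off one short-read library mapped against the reference
genome plus a single transgene monomer sequence:

* **Anchored pairs.** A read pair with one mate on the monomer and the
  other on the reference localizes an array edge. Reference partners on the
  forward strand read toward an insertion on their right (left-of-insertion
  cluster); reverse-strand partners mark the right side. Partners are
  single-linkage clustered with a gap threshold of
  `insert_mean + 3·insert_sd`.
* **Split reads.** A read crossing a junction aligns to one side with the
  remainder soft-clipped; re-mapping the clipped piece to the other target
  confirms the junction and the breakpoint is read off at base-pair
  resolution as the modal clip boundary (ties toward the smaller reference
  coordinate). Junctions are called both from anchor clusters (pair
  evidence + splits) and directly from boundary-clustered confirmed splits,
  so a junction that few fragments happen to straddle cleanly is still
  recovered; the two routes are merged within a 3 bp tolerance. The
  mirror-image observations — reads mapped on the monomer whose clip
  re-maps to the reference — corroborate support but do not set the modal
  coordinate, because junction microhomology places their boundary at the
  other end of the homology run.
* **Internal junctions.** Reads clipped on the monomer whose clips re-map
  to the monomer type the array's internal structure: co-linear wraps
  (monomer end -> start) are head-to-tail seams; opposite-orientation
  convergence at the 5' end is the head-to-head (5'-5') junction marking an
  orientation switch; clips landing on a catalogued cloning-vector sequence
  give the transgene-vector junctions. Unexplained split configurations are
  reported verbatim rather than forced into a type.

The position of the orientation switch *within* the array is reported as
presence/absence only. The copies are near-identical, so short reads cannot
phase the switch to a copy index; the model object carries an explicit
`switch_position_resolved = False`.

### Breakpoint representation

When the array's terminal bases coincide with the first (or last) deleted
reference bases, the junction has microhomology and several breakpoint
representations describe the same sequence. Maximal read extension lands on
the trimmed representation (common prefix/suffix between the deleted
segment and the array removed — the same normalization VCF applies to
replacements), so truth records store both the nominal and the trimmed
canonical interval and exactness is defined against the canonical one. For
random flanks the expected trim is ~0.3 bp per junction.

### Shared-segment homology

Transgene constructs embed host-gene fragments (a prion-gene fragment in
the tau construct, a CaMKII promoter fragment in the tTA construct) that
are also present at their endogenous locus. Reads from the array's shared
segment whose span covers no marker SNP map ambiguously and tie-break to
the endogenous contig; split evidence falling inside the known shared locus
is therefore lifted back onto monomer coordinates (a constant offset —
the homology is co-linear) before junction typing. Without the lift, the
junctions adjacent to a shared segment at the monomer's 5' end are
systematically misplaced onto the endogenous locus.

## Quantification

* **Deletion and zygosity.** Mean start-counted depth inside the
  junction-implied interval over the mean of its flanks, excluding one
  insert length next to each breakpoint (junction-straddling fragments
  dilute the signal). Thresholds: ratio >= 0.8 no deletion; 0.35–0.65
  hemizygous; <= 0.1 homozygous; otherwise ambiguous. Flanks default to
  50 kb and clamp at contig edges (flagged).
* **Copy number from marker alleles.** Marker SNPs distinguish the
  transgene-borne copy of the shared segment from the endogenous locus.
  Every read whose aligned span covers a marker votes by its base; a read
  voting both alleles across linked markers is discarded to "other"
  (conflict rule). Copy number = endogenous_copies ×
  (pooled transgene votes / pooled endogenous votes); a 35-fold pooled
  ratio at a diploid locus is 70 copies. The 95% sampling interval uses the
  normal approximation to the log of a ratio of Poisson totals
  (var = 1/n_tg + 1/n_endo), adequate once both counts exceed ~10. The
  estimator's information limit is the number of distinct endogenous-locus
  reads overlapping any marker, so the shipped fixtures spread their
  markers across the shared segment (~1 per 100–150 bp) rather than
  clustering them at the minimum 20 bp spacing; at 10x total coverage this
  gives a standard error of ~4 copies on a 70-copy array and ~0.45 copies
  on a 7-copy array. Per-marker tables are always emitted alongside the
  pooled estimate.
* **Copy number from depth.** 2 × mean monomer depth / mean diploid
  baseline depth, restricted to monomer-unique sequence (monomer minus the
  shared segment) so endogenous cross-mapping cannot bias it, with one read
  length trimmed where a unique interval abuts the monomer end (reads
  starting there cross a copy junction and register their start on the far
  side of the wrap, depressing start-counted depth).
* **Operator sites.** Rounded copy number × tet-operator sites per monomer
  (default 7, the tandem repeat count of a standard TRE).

## Gene disruption

Transcripts (GFF3 gene->mRNA->exon or BED12) are classified against the
called deletion in decision order: `fully_deleted` (span contained);
`promoter_and_first_exon_lost` (promoter window — default 2 kb upstream of
the TSS, strand-aware — plus first exon covered, later exons retained);
`five_/three_prime_truncated` (strand-aware end overlap; a deletion wholly
internal to the span is assigned to the nearer end by overlap midpoint, and
a promoter-only overlap counts as 5' impact); else `intact`. Genes roll up
to the worst transcript class; genes with biotype `predicted` are tallied
separately from the headline disrupted-gene count.

## Read mapping

A minimal seed-and-extend mapper (no external aligner): canonical 2-bit
k-mer index (k = 31; k = 15 for re-mapping clipped pieces) over reference +
monomer, seed hits on a stride of 12 vote for (diagonal, strand)
candidates (minimum 2 votes; 1 for short clips), and the best candidates
are scored by ungapped extension — match +1, mismatch −4, maximal-scoring
window by the Kadane recurrence — with out-of-window bases soft-clipped.
Reads with matched span < 20 bp or mismatch density > 10% are unmapped;
ties break to the smallest (target, position). Extension is ungapped: the
simulator's default error model is substitution-only, and indel-bearing
reads would simply lose a few terminal bases to clips. The inner loop is
numba-compiled; text SAM import/export (pysam) lets external soft-clipped
alignments stand in for the built-in mapper.

## The synthetic-data generator

The generator emulates the study design the alleles were characterized
under: 2 × 125 bp pairs, insert length Normal(350, 50) truncated at the
read length, uniform fragment sampling across both haplotypes, i.i.d.
substitution errors (default 0.1% in the fixtures), fixed Q30 qualities.
`coverage` is total depth over the diploid, so the pair count is
`round(coverage · total_bases / (2 · read_length))`; each haplotype base is
then covered `coverage`-fold, so a diploid reference position carries
2 × `coverage` reads (20 at the fixtures' 10x).
Fragment starts are drawn per contig in proportion to the number of valid
start positions (`length − insert + 1`), not raw length — raw-length
weighting over-samples the interior of short contigs by ~insert/length,
which measurably biases allele-ratio estimates on compact loci.

Default monomer: 6 kb, segments TRE promoter (500 bp), shared Prnp fragment
(2 kb), tau ORF (1.2 kb), UTR (2 kb), SV40 polyA (300 bp); the real
monomer length is not public, so these are explicitly synthetic
proportions. The tTA fixture instead gives its monomer a 4 kb shared CaMKII
promoter fragment (the original construct carries an 8.5 kb fragment), a
~1 kb ORF and a polyA. The first array block renders 3'->5'
(reverse-complemented) with the switch at a configurable index, an optional
vector spacer at the inversion point, and partial terminal copies.

The generator does **not** model PCR duplicates, GC or mappability bias,
quality decay, chimeric library artifacts, indel errors (an option exists,
default 0), or mosaicism. Passing tests therefore demonstrate correctness
of the inference logic under clean library statistics, not robustness to
every real-library pathology; on real data the depth-based calls in
particular would need GC/mappability normalization.

### Shipped fixtures and problem sizes

Two fixture files encode the characterized allele architectures on
synthetic working loci sized for desk-scale runs (the package's own choice
of locus scale):

* `fgf14_tgindel.yaml` — 70-copy array, switch at copy 30, no spacer,
  partial terminal copies, replacing a 243,608 bp interval of a 1 Mb
  contig; hemizygous; separate 100 kb contig carrying the endogenous shared
  locus; 20 marker SNPs spaced 100 bp. At 10x: ~95,000 pairs, full pipeline
  ~10 s single-core.
* `vipr2_ptprn2_tgindel.yaml` — 7-copy array, switch at copy 3 with a
  2.5 kb vector spacer, replacing 508,119 bp of a 1.2 Mb contig;
  hemizygous; 26 markers spaced 150 bp over the 4 kb shared segment; toy
  eight-gene annotation reproducing the disruption topology (3'-truncated,
  three contained, 5'-lost, one predicted gene, two intact flankers). At
  10x: ~85,000 pairs.

Copy-count convention: the fixtures count partial terminal copies in
`n_copies` (`copy_count_convention: all_copies` in the truth record);
truncations are kept inside terminal segments so every copy retains its
full marker set, making the marker-based expectation equal to `n_copies`.

## Known limitations

* Ungapped alignment only; indel-containing junctions would be resolved
  only to the clip boundary.
* The switch index within the array, and any structure deeper than one
  monomer from a junction, are unobservable by design at these read
  lengths.
* Start-counted depth is jittery at feature edges; intervals shorter than
  ~200 bp are excluded from depth-based copy number.
* The marker-ratio estimator's precision is bounded by endogenous-locus
  coverage; at 10x its 95% interval on a 70-copy array spans roughly ±8
  copies, so rounded estimates at that scale carry ±1–3 copies of seed-to-
  seed variation.
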