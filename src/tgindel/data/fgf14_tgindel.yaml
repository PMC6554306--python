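# Synthetic reconstruction of the tau-transgene TgINDEL allele: a ~70-copy
# head-to-tail tau-transgene array, with one internal orientation switch and
# partial terminal copies, replacing a 243,608 bp interval of an Fgf14-like
# locus; hemizygous carrier. Contig sizes are synthetic working-locus sizes,
# not the real chromosome.
name: fgf14_tgindel
contigs:
  - {name: chr14_fgf14_locus, length: 1000000}
  - {name: chr2_prnp_locus, length: 100000}
endogenous_locus: {contig: chr2_prnp_locus, position: 49000}
monomer:
  segments:
    - [TRE_promoter, 500]
    - [Prnp_shared, 2000]
    - [tau_ORF, 1200]
    - [Mapt_UTR, 2000]
    - [SV40_polyA, 300]
  shared_segment: Prnp_shared
  marker_count: 20
  marker_spacing: 100
array:
  n_copies: 70
  switch_index: 30
  spacer_length: 0
  five_prime_partial: 200
  three_prime_partial: 150
copy_count_convention: all_copies
allele:
  contig: chr14_fgf14_locus
  deletion_start: 380000
  deletion_end: 623608
  zygosity: hemizygous
  carrier_haplotype: 1
reads:
  read_length: 125
  insert_mean: 350
  insert_sd: 50
  coverage: 10.0
  substitution_error_rate: 0.001
quant:
  sites_per_monomer: 7
annotation:
  # four Fgf14-like splice-variant analogs; the deletion removes the
  # promoters and first exons of V2/X1/X2 and leaves V1 intact
  genes:
    - name: Fgf14
      biotype: protein_coding
      transcripts:
        - id: V1
          strand: "+"
          exons: [[650000, 650200], [700000, 700180], [740000, 740220], [779000, 780500]]
        - id: V2
          strand: "+"
          exons: [[390000, 390160], [700000, 700180], [740000, 740220], [779000, 780500]]
        - id: X1
          strand: "+"
          exons: [[405000, 405140], [700000, 700180], [740000, 740220], [779000, 780500]]
        - id: X2
          strand: "+"
          exons: [[462000, 462180], [700000, 700180], [740000, 740220], [779000, 780500]]
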