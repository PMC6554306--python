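# Synthetic reconstruction of the tTA-transgene TgINDEL allele: a ~7-copy
# tTA-transgene array with a cloning-vector fragment at its internal
# orientation switch, replacing a 508,119 bp gene-rich interval
# (Vipr2...Ptprn2-like topology); hemizygous carrier. The monomer carries a
# long CaMKII promoter fragment shared with an endogenous locus.
name: vipr2_ptprn2_tgindel
contigs:
  - {name: chr12_vipr2_ptprn2_locus, length: 1200000}
  - {name: chr18_camk2a_locus, length: 100000}
endogenous_locus: {contig: chr18_camk2a_locus, position: 48000}
monomer:
  segments:
    - [CaMKII_promoter_shared, 4000]
    - [tTA_ORF, 1008]
    - [SV40_polyA, 292]
  shared_segment: CaMKII_promoter_shared
  marker_count: 26
  marker_spacing: 150
array:
  n_copies: 7
  switch_index: 3
  spacer_length: 2500
  five_prime_partial: 0
  three_prime_partial: 0
copy_count_convention: all_copies
allele:
  contig: chr12_vipr2_ptprn2_locus
  deletion_start: 340000
  deletion_end: 848119
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
  # toy chromosome-12 topology: the deletion truncates Vipr2 at its 3' end,
  # removes Wdr60/Esyt2/Ncapg2 entirely, takes the 5' end of Ptprn2, and
  # covers one predicted gene (counted separately); two flanking genes are
  # intact -> five disrupted annotated genes
  genes:
    - name: Dpp6
      biotype: protein_coding
      transcripts:
        - id: Dpp6-201
          strand: "+"
          exons: [[150000, 150200], [200000, 200300], [250000, 251000]]
    - name: Vipr2
      biotype: protein_coding
      transcripts:
        - id: Vipr2-201
          strand: "+"
          exons: [[300000, 300220], [320000, 320150], [355000, 356000]]
    - name: Wdr60
      biotype: protein_coding
      transcripts:
        - id: Wdr60-201
          strand: "-"
          exons: [[400000, 400500], [430000, 430200], [449000, 450000]]
    - name: Esyt2
      biotype: protein_coding
      transcripts:
        - id: Esyt2-201
          strand: "+"
          exons: [[520000, 520400], [545000, 545250], [569000, 570000]]
    - name: Ncapg2
      biotype: protein_coding
      transcripts:
        - id: Ncapg2-201
          strand: "+"
          exons: [[640000, 640300], [670000, 670220], [699000, 700000]]
    - name: Gm20658
      biotype: predicted
      transcripts:
        - id: Gm20658-201
          strand: "+"
          exons: [[750000, 750400], [779000, 780000]]
    - name: Ptprn2
      biotype: protein_coding
      transcripts:
        - id: Ptprn2-201
          strand: "+"
          exons: [[840000, 840300], [880000, 880200], [919000, 920000]]
    - name: Wdr86
      biotype: protein_coding
      transcripts:
        - id: Wdr86-201
          strand: "-"
          exons: [[950000, 950300], [980000, 981000]]
  annotation_contig: chr12_vipr2_ptprn2_locus
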