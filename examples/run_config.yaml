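# mnasefrag run configuration template.
#
# Exactly one of `simulator:` or `inputs:` must be present.  Unknown keys
# are rejected; omitted keys take the defaults shown here.

seed: 1                      # single seed governing the whole run
output_dir: mnasefrag_out

simulator:                   # synthetic-data mode
  chrom_length: 300000       # bp, one chromosome
  n_tfbs: 12                 # TF binding sites, each centered in an NDR
  n_orfs: 60                 # genes for metric-coupled analyses
  n_centromeres: 1           # ~90% A+T point centromeres
  n_fragments: 50000         # fragments emitted per sample (IP and input)
  repeat_length: 165         # nucleosomal repeat, bp
  ndr_half_width: 90         # bp each side of the TFBS midpoint
  ndr_half_width_jitter: 25  # seeded per-NDR width variation, bp
  digestion_extent: 5.0      # per-end exponential trimming scale, bp
  baseline_spanning_fraction: 0.05   # input's share of spanning protections
  target_enrichment: 2.5     # designed IP/input supernuc/nuc ratio-of-ratios
  coupling: 0.8              # Pearson coupling of gene metrics to enrichment

# inputs:                    # user-data mode (alternative to simulator)
#   ip_fragments: ip.bed
#   input_fragments: input.bed
#   fragment_format: BED3    # or BEDPE
#   genome_fasta: genome.fa
#   features_bed: features.bed
#   metrics_tsv: metrics.tsv # header: gene_id <metric> ...
#   chrom_lengths: {}        # optional when genome_fasta given

analyses:
  sizes:
    enabled: true
    nucleosomal: [141, 250]        # bp, inclusive
    supernucleosomal: [251, 428]
  vplot:
    enabled: true
    x_half_width: 1000             # bp from anchor
    x_bin: 5
    y_min: 25                      # fragment length window, bp
    y_max: 424
    y_bin: 1
    anchor_mode: midpoint          # or five_prime / three_prime
  profiles:
    enabled: true
    flank: 1000                    # bp each side of the anchor
    pseudocount: 0.5               # counts, post depth-scaling
    quintiles: true
  heatmap:
    enabled: true
    flank: 1000
    metric: expression             # column of the metric table
  ndr:
    enabled: true
  bendability:
    enabled: true
    window: 39                     # bp, odd
    pfm_flank: 200
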