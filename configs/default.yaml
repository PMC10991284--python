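# Desk-scale synthetic study configuration: four genotypes, five
# replicates each, one planted repressive motif, three planted
# super-enhancer clusters, a late-trajectory signature suppression in
# CK, and a clone-evenness gradient.  All values are overridable.
n_chroms: 2
chrom_length: 2000000
n_peaks: 400
n_samples_per_group: 5
groups: [WT, C, K, CK]
reference_group: WT
n_genes: 120
n_tads_per_chrom: 8
n_motifs: 12
planted_motif_effects:
  motif_0: -1.0
n_se_clusters: 3
se_cluster_size: 3
se_peak_multiplier: 8.0
nb_dispersion: 0.05
base_mean: 100.0
n_cells_per_group: 400
pseudotime_shift:
  WT: 0.0
  C: 0.05
  K: 0.1
  CK: 0.2
signature_effect: 1.0
n_signature_genes: 20
signature_late_suppression:
  CK: -0.5
n_clones: 50
clone_evenness: 0.5
clone_total_reads: 10000
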