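# bench-default: the benchmark operating point for the paired
# untreated/DASHed simulation.  One contaminant transcript at ~60% of cell
# UMIs and 95% of ambient UMIs; 2,000 cells + 5,000 empty droplets over
# 1,000 genes; 6M reads per arm; per-molecule cut probability 0.999.

n_cells = 2000
n_empty = 5000
n_genes = 1000

n_types = 8
rare_type_prop = 0.02
markers_per_type = 25
marker_fold = 8.0
program_sigma = 1.0
contaminant_name = 16S
stem_marker_name = piwi-1
stem_marker_share = 0.05
n_nonstem_types = 1

cell_median_molecules = 2000.0
cell_sigma_log = 0.35
empty_median_molecules = 400.0
empty_sigma_log = 0.6

p_contaminant = 0.60
p_concentration = 200.0
ambient_contaminant = 0.95

sigma0 = 0.15
pre_cycles = 10
post_cycles = 10
epsilon = 0.999
total_reads = 6000000

seed = 0
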