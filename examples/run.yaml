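# A desk-scale synthetic three-group study: two parental niches 4 sigma
# apart on env1, a hybrid displaced on env2. Remove the `synthetic` block
# and supply occurrence_csv / raster_paths to run on real data instead.
synthetic:
  n_rows: 50
  n_cols: 50
  cell_size: 1.0            # km (planar synthetic grid)
  layers:
    - {name: env1, kind: continuous, autocorr_length: 4.0}
    - {name: env2, kind: continuous, autocorr_length: 4.0}
  correlation: [[1.0, 0.3], [0.3, 1.0]]
  scenario_kind: three_group
  separation: 4.0
  sigma: 0.5
  n_per_group_raw: 700
  n_all_species: 2000
  fail_fraction: 0.1        # planted checklist-metadata violation rate

n_per_group: 150            # balanced sample per group (1500 at study scale)
n_background: 300           # target-group background points (10000 at study scale)
thin_min_distance: 0.3      # km
vif_method: both            # intersection of vifstep and vifcor
vif_threshold: 10.0
r_threshold: 0.9
feature_classes: [linear, quadratic]
beta: 1.0
n_replicates: 10            # 80/20 validation replicates
test_fraction: 0.2
n_iter: 99                  # permutation replicates per test
alpha: 0.05
master_seed: 1
outdir: nichekit_run
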