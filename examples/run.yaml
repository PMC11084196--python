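# Demo pipeline configuration: all-synthetic inputs, completes in seconds.
#   hsascreen run --config examples/run.yaml
seed: 7
out_dir: hsascreen_run
n_ligands: 300
n_clusters: 5
sites_per_cluster: 10
site_jitter: 1
k: 5
linkage: average
top_m: 3
occupancy_specs:
  - {name: prednisone, K: 1.0e+3, ligand_conc: 2.5e-3}
  - {name: warfarin_site2, K: 5.0e+4, ligand_conc: 1.0e-3}
  - {name: levothyroxine, K: 1.0e+5, ligand_conc: 1.5e-5, hsa_conc: 4.0e-5, n_sites: 4}
run_spr: true
spr_baseline: {ka1: 2.7e+2, kd1: 2.16e-5, ka2: 8.9e+2, kd2: 2.6e-3}
spr_rmax: 100.0
spr_noise_sd: 0.0
analyte_concs: [2.5e-6, 5.0e-6, 1.0e-5, 2.0e-5, 4.0e-5]
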