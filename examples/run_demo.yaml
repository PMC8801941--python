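# End-to-end demo: simulate -> qc -> score -> screen (both conditions) -> shift
# Run with:  sigcorr run --config examples/run_demo.yaml
out_dir: scratch/demo_run
seed: 7

simulate:
  n_genes: 600
  n_cells_per_cluster: {Lc: 400, Sg: 200, Im: 200}
  conditions: [Nt, O50t]
  mito_genes: 10
  mito_fraction: 0.05
  cluster_sigma: 0.3
  planted_mc_cells: 4000
  modules:
    - name: Senescence_like
      n_genes: 10
      loading: 0.277
      latent_factor_id: f
      condition_mean_shift: {O50t: 1.5}
    - name: Androgen_like
      n_genes: 10
      loading: -0.277
      latent_factor_id: f
    - name: Collagen_like
      n_genes: 10
      loading: 0.277
      latent_factor_id: f
      condition_mean_shift: {O50t: 2.0}

qc:
  min_features: 100     # scaled to the simulation (600 genes, not a full genome)
  max_features: 7000
  max_percent_mt: 20.0
  min_cells: 3

score:
  signatures:
    Senescence_like: [Senescence_like_g01, Senescence_like_g02, Senescence_like_g03,
                      Senescence_like_g04, Senescence_like_g05, Senescence_like_g06,
                      Senescence_like_g07, Senescence_like_g08, Senescence_like_g09,
                      Senescence_like_g10]
    Androgen_like: [Androgen_like_g01, Androgen_like_g02, Androgen_like_g03,
                    Androgen_like_g04, Androgen_like_g05, Androgen_like_g06,
                    Androgen_like_g07, Androgen_like_g08, Androgen_like_g09,
                    Androgen_like_g10]
    Collagen_like: [Collagen_like_g01, Collagen_like_g02, Collagen_like_g03,
                    Collagen_like_g04, Collagen_like_g05, Collagen_like_g06,
                    Collagen_like_g07, Collagen_like_g08, Collagen_like_g09,
                    Collagen_like_g10]

screen:
  target: Senescence_like
  candidates: [Androgen_like, Collagen_like]
  cluster: Lc
  conditions: [Nt, O50t]

shift:
  floor: 0.1
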