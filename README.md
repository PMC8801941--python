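# sigcorr

Signature-correlation screening for single-cell RNA-seq, with a
negative-binomial simulator that plants known, recoverable correlation
structure so every stage of the analysis can be verified at desk scale.

The pipeline implements the analysis pattern of correlating gene-signature
activity (scored as the **percentage of a cell's total counts** falling in a
gene set) against candidate pathway scores, per cell cluster and condition:

- **`sigcorr.synthetic`** — NB count simulator: discrete clusters, log-normal
  library sizes, mitochondrial genes, gene modules driven by shared per-cell
  latent factors (planting inter-module score correlations, condition-specific
  mean shifts and correlation sign flips), plus a `PlantedTruth` ledger holding
  the Monte-Carlo target correlation for every module pair and condition.
- **`sigcorr.matrix_io`** — 10x-style MTX triplet (genes × cells), GMT / TSV
  signature files, cell-annotation TSVs.
- **`sigcorr.qc`** — cell filter (detected genes strictly > 200 and < 7,000,
  mito percentage strictly < 20), gene filter (detected in ≥ 3 cells),
  depth normalization `ln(1 + 10,000·count/total)`.
- **`sigcorr.scoring`** — per-cell percentage-of-counts signature scores
  (computed on raw counts; exactly depth-invariant; any gene partition's
  scores sum to 100 per cell).
- **`sigcorr.screen`** — Pearson r (t-transform p-values), threshold-ranked
  screen tables, top-k TF–target-gene correlation ranking (with a mean
  normalized-expression ≥ 0.5 filter and a default Hmgb4/Spz1/Tfam exclusion
  list), and cross-condition correlation-shift / sign-flip detection.
- **`sigcorr.de`** — per-cluster two-sided Wilcoxon rank-sum DE between
  conditions, prefiltered on `|log_fc| ≥ 0.25` and `max(pct) ≥ 0.2`, survivors
  filtered on raw `p ≤ 0.05` (a BH column is emitted but deliberately unused —
  mirroring the upstream convention; treat raw-p gene lists accordingly).
- **`sigcorr.enrichment`** — competitive gene-set test with a variance
  inflation factor `1 + (m−1)·ρ̄` estimated from inter-gene expression
  correlation (a simplified reimplementation of the CAMERA-style competitive
  test: competitive null + VIF + two-sided normal test, without the moderated
  t machinery).
- **`sigcorr.lr`** — permutation ligand–receptor pairing between ordered
  cluster pairs (score = mean of sender-ligand and receiver-receptor means;
  add-one permutation p from cluster-label shuffles).
- **`sigcorr.pipeline` / `sigcorr.cli`** — YAML-driven stage chaining with a
  JSON manifest (per-stage seeds, parameters, output checksums, row counts).

## CLI

Every stage is a subcommand of `sigcorr` (see `sigcorr --help` /
`sigcorr <cmd> --help`):

```bash
sigcorr simulate --config sim.yaml --seed 7 --out data/          # synthetic data
sigcorr qc --in data/ --out qc/ --min-features 200 --max-features 7000 \
           --max-pct-mt 20 --min-cells 3
sigcorr score --in qc/ --signatures sigs.gmt --annotation qc/annotation.tsv \
              --out scores.tsv
sigcorr screen --scores scores.tsv --target Senescence_signature \
               --cluster Lc --condition O50t --r-min 0.32 --out screen.tsv
sigcorr tf-screen --norm qc/ --annotation qc/annotation.tsv --target Star \
                  --tf-list tfs.txt --out tfs.tsv
sigcorr shift --a screen_Nt.tsv --b screen_O50t.tsv --out shift.tsv
sigcorr de --norm qc/ --annotation qc/annotation.tsv --cluster Lc \
           --a O50t --b Nt --out de.tsv
sigcorr gse --stats stats.tsv --sets sets.gmt --norm qc/ --out enrichment.tsv
sigcorr lr --norm qc/ --annotation qc/annotation.tsv --pairs pairs.tsv \
           --sender Lc --receiver Im --n-perm 1000 --seed 7 --out lr.tsv
```

An end-to-end chained run from one config file:

```bash
sigcorr run --config examples/run_demo.yaml
```

## Conventions worth knowing

- Matrices are genes × cells everywhere; transposed inputs are rejected.
- Mitochondrial genes are detected by the case-insensitive symbol prefix
  `mt-`.
- Signature scores are computed on **raw counts** (the percentage definition
  is depth-invariant by construction); gene–gene and TF–gene correlations use
  normalized expression.
- Screens threshold on r only; p-values and BH columns are reported for
  transparency, never used for filtering.
- All randomness is seeded; identical config + seed reproduces byte-identical
  outputs.
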