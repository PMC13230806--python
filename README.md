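# sf-endotyper

Endotype-discovery pipeline for synovial-fluid (SF) aptamer proteomics,
built around a fully synthetic data path so every stage is testable without
any external download:

- **`synthdata`** — synthetic SF-proteomic cohorts with a dominant
  intracellular-contamination factor (calibrated so PC1 of the standardized
  log abundance explains ~48% of variance), spin-status batch effects,
  optional planted discrete endotypes of configurable separation,
  clinical-covariate/protein links (radiographic severity, pain, a
  BMI-linked adipokine, a blood-staining marker), plus ground truth.
- **`preprocess`** — natural-log transform, median normalization,
  parametric empirical-Bayes batch adjustment (location/scale), the
  intracellular protein score (IPS), IPS residualization and per-protein
  standardization, all tracked by an order-enforcing transform ledger.
- **`endotype`** — unscaled PCA to 80% variance, best-of-n random-start
  k-means scan, the f(K) ratio-of-distortions statistic with the
  f(K) < 0.85 decision rule, majority-vote cluster number (silhouette,
  Calinski–Harabasz, Davies–Bouldin, gap statistic, f(K)-argmin), elbow
  diagnostics and a deterministic 2-D UMAP embedding.
- **`assoc`** — per-aptamer regression scans (linear / logistic /
  proportional-odds ordinal; effects per SD of log abundance), BH-FDR,
  Discovery/Replication replication calls, interaction tests, stratified
  reruns with cross-stratum effect correlation, duplicate-aptamer
  deduplication.
- **`enrich`** — preranked set enrichment on the signed −ln(p) rank metric:
  weighted running-sum enrichment scores, gene-label-permutation NES and
  p-values, BH adjustment, leading edges.
- **`power`** — Monte-Carlo operating characteristics of the detection
  procedure (detection probability vs sample size / endotype count /
  separation / informative fraction).
- **`io_cli`** — TSV/GMT readers and writers, YAML run configuration, an
  end-to-end orchestrator with a hash manifest, and the `sf-endotyper` CLI.

## CLI

```bash
sf-endotyper simulate --seed 1 --out cohort/            # synthetic cohort (TSV/GMT)
sf-endotyper preprocess --matrix cohort/abundance.tsv \
    --meta cohort/metadata.tsv --annot cohort/annotation.tsv \
    --ips-regress on --out pre/
sf-endotyper cluster --matrix pre/processed.tsv --kmax 9 --seed 17 --out clu/
sf-endotyper associate --matrix pre/processed.tsv --meta cohort/metadata.tsv \
    --annot cohort/annotation.tsv --outcome advanced_kl --family binary \
    --covars age,sex --dataset combined --out assoc/
sf-endotyper enrich --assoc assoc/assoc.tsv --gmt cohort/gene_sets.gmt \
    --nperm 1000 --seed 11 --out enr/
sf-endotyper power --grid grid.yaml --reps 50 --seed 5 --out pow/
sf-endotyper run --seed 1 --out run/                    # full pipeline + manifest
```

`simulate --config cfg.yaml` accepts any `CohortConfig` field (cohort
sizes, aptamer counts, `k_endotypes`, `endotype_separation`,
`frac_informative`, `ips_variance_share`, batch and clinical knobs). A
power grid YAML lists `scenarios: [[n, k, separation, frac_informative], ...]`.

## Reproducibility

Every stochastic operation takes an explicit seed; the orchestrator fans a
single global seed out to per-stage substreams and writes a manifest of
SHA-256 hashes over all text outputs, so identical configs reproduce
identical numbers.
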