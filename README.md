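# etiohet

Supervised discovery of etiologically distinct disease sub-types from
genomic profiles and risk-factor data.

Standard unsupervised clustering picks the partition of cases that best
separates the genomic profiles (largest between-cluster dissimilarity `G`).
This package instead generates a large ensemble of candidate partitions by
restarted k-means and selects the one that maximizes a case-only
**etiologic-heterogeneity statistic `D*`**: the average chi-square-type
deviation of fitted sub-type membership probabilities (from a polytomous
logistic regression of the candidate labels on the risk factors) from the
overall class proportions,

    D* = (1/N) Σ_i Σ_j (u_ji − π_j)² / π_j,   0 ≤ D* ≤ m − 1.

Permutation tests assess whether any heterogeneity is present and whether
`m+1` sub-types add significant heterogeneity over `m`.  Post-hoc tools
characterize the selected sub-types: risk-profile tables, mutation
associations, cross-platform congruence of labelings, competitive gene-set
enrichment and survival summaries.

## Layout

| module | contents |
| --- | --- |
| `etiohet.riskmetrics` | `K`, `K_j`, `K_jk`, `D`, `D*`; the membership model (`fit_subtype_model`) |
| `etiohet.hetclust` | restarted k-means ensembles, `G`, `D*` scoring, solution selection, random benchmark |
| `etiohet.inference` | permutation tests for heterogeneity and for the number of sub-types |
| `etiohet.prep` | expression/methylation/copy-number matrix filtering, standardization, merging, top-k features |
| `etiohet.posthoc` | risk profiles, mutation tables, label alignment/congruence, competitive GSEA, survival |
| `etiohet.synthdata` | synthetic populations with exact risk oracles, risk-biased case sampling, genomic/mutation/survival generators |
| `etiohet.scenarios` | packaged end-to-end scenarios with planted ground truth |
| `etiohet.workbench` / `etiohet.cli` | TSV/GMT/YAML I/O, case alignment, the `etiohet` command line |

## Command line

Every command reads a YAML config (`--config`) and writes TSV/JSON outputs
plus a `_meta` block with the config hash and master seed; identical seeds
reproduce byte-identical results.

```sh
etiohet simulate --config scenario.yaml   # synthetic dataset with known truth
etiohet prep     --config run.yaml        # standardize + top-k features
etiohet cluster  --config run.yaml        # restart ensemble, D*/G scoring, selection
etiohet test-het --config run.yaml        # permutation test for heterogeneity
etiohet test-k   --config run.yaml        # m+1 vs m sub-types
etiohet posthoc  --config run.yaml --labels labels.tsv
```

A minimal run config:

```yaml
genomic: {path: genomic.tsv}          # samples x features TSV
clinical:
  path: risk.tsv                      # case_id + covariate columns
  categorical:
    smoking: [never, former, current]
    gender: [male, female]
  continuous: [age]
m: 2
n_restarts: 1000
B: 1000
seed: 7
output_dir: out
```

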