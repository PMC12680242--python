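# attrbench

Benchmarking toolkit for the interpretability of deep-learning
genotype-to-phenotype models. It quantifies feature attribution along three
axes and combines them into a single score:

- **Attribution recall** — sensitivity, measured against synthetic
  *spike-in SNPs* with known additive, dominant, recessive, and epistatic
  effects, generated under Hardy–Weinberg equilibrium with controlled
  phenotype correlation.
- **Attribution precision** — specificity, measured against *permutation
  decoys*: within-chunk sample-index permutations of the real genotypes
  that preserve per-SNP allele distributions while destroying any
  genotype–phenotype correspondence.
- **Ensemble consistency** — stability of per-SNP importance across an
  ensemble of independently trained models, summarized by the median
  relative standard deviation (RSD) and its scaled MAD.

The three are aggregated as the geometric mean of top-1% micro-averaged
recall, top-1% precision, and the half-life-transformed median RSD
(S = 2^(−x/τ), τ = median of the median RSDs across method variants).

The toolkit is self-contained: it includes a synthetic cohort generator
(HWE genotypes, polygenic phenotype with age/sex nuisance effects,
sex-stratified 80/10/10 splits), a NumPy feed-forward regression network
(ReLU, batch norm, dropout; Adam on MAE + L2; best-validation-Pearson
checkpointing), a per-SNP GWAS linear baseline, and four attribution
algorithms — Saliency, Gradient SHAP, DeepLIFT (rescale), Integrated
Gradients — each optionally wrapped in SmoothGrad noise averaging.
No deep-learning framework is required.

## Package layout

| module                  | contents                                                    |
| ----------------------- | ----------------------------------------------------------- |
| `attrbench.cohort`      | genotype/covariate/phenotype simulation, adjustment, splits |
| `attrbench.spikein`     | spike-in SNP generators + constraint machinery              |
| `attrbench.decoys`      | deterministic within-chunk permutation decoys               |
| `attrbench.models`      | MLP regressor, training loop, ensembles, GWAS baseline      |
| `attrbench.attributions`| the four attribution methods, SmoothGrad, aggregation       |
| `attrbench.metrics`     | top-K, recall, precision, RSD consistency, composite        |
| `attrbench.bench`       | end-to-end orchestration, profiles, reports                 |
| `attrbench.plink`       | minimal PLINK 1 bed/bim/fam reader/writer                   |
| `attrbench.cli`         | `attrbench` command-line interface                          |

## CLI

```bash
attrbench run-all --profile desk --seed 1 --out-dir out/       # full report
attrbench simulate-cohort --seed 1 --out-dir out/              # PLINK + TSV
attrbench spike-in --seed 1 --out-dir out/                     # + diagnostics
attrbench gwas --seed 1 --out-dir out/
attrbench bench-recall / bench-precision / bench-consistency
```

All commands accept `--config <yaml>` to override any `RunConfig` field,
`--profile {desk,paper}`, `--seed`, and `--out-dir`. Exit codes: 0 success,
2 configuration error, 3 stage failure. Every random draw derives from the
master seed through named `SeedSequence` children, so `report.json` is
byte-identical across reruns with the same seed.

Two profiles ship: `desk` (n=2,000 samples, 1,000 SNPs, 40 spike-ins,
64/32/16 network, M=3 ensemble; minutes on one CPU) and `paper`
(300k × 500k, 1000/200/50 network, M=10; biobank-scale hardware required).
The desk profile inflates spike-in correlation targets so the small network
can learn them; the reference constraint suite (|ρ| ∈ [0.018, 0.070],
MAF ∈ [0.05, 0.20], recessive expected hom-alt count ≥ 1200, dominant
carrier fraction 10–14%, epistatic marginal |r| < 0.01) is the default and
is verified at the 240,000-sample reference scale in the acceptance tests.

## Python API sketch

```python
import numpy as np
from attrbench import desk_profile, run_all

report = run_all(desk_profile(master_seed=1))
print(report.composite["saliency|raw"])
open("report.json", "w").write(report.to_json())
```

Lower-level pieces compose freely, e.g. generating spike-ins against your
own standardized phenotype:

```python
from attrbench.spikein import build_spikein_set
spikes = build_spikein_set(y, counts=(100, 100, 100, 100), seed=7)
spikes.diagnostics_frame()  # per-SNP realized correlations, class means, alpha
```
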