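# scase

Moderated beta-binomial modeling of allele-specific expression (ASE) in
single cells.

Single-cell RNA-seq of F1 hybrids (or any sample with phased variants)
yields, for every gene *i* and cell *j*, a reference-allele count
*m<sub>ij</sub>* out of *n<sub>ij</sub>* total allelic reads.  These counts
are sparse and noisy, and per-cell allelic ratios are overdispersed
relative to binomial sampling.  `scase` models them as

&nbsp;&nbsp;&nbsp;&nbsp;*m<sub>ij</sub>* | *n<sub>ij</sub>* ~ BetaBinomial(*n<sub>ij</sub>*, α<sub>i</sub>, β<sub>i</sub>),
&nbsp;&nbsp;μ<sub>i</sub> = α<sub>i</sub>/(α<sub>i</sub>+β<sub>i</sub>),
&nbsp;&nbsp;θ<sub>i</sub> = 1/(α<sub>i</sub>+β<sub>i</sub>),

where μ<sub>i</sub> is the mean allelic ratio and θ<sub>i</sub> the allelic
dispersion.  Per-gene dispersion estimates are stabilized by empirical-Bayes
shrinkage toward a local-regression trend of log θ̂ against log mean
coverage, with genes of intrinsically tiny dispersion exempted so that
moderation does not destroy the power to detect their imbalance.  On top of
this the package provides:

* **mean test** — likelihood-ratio test of μ<sub>i</sub> against a background
  ratio *x* (0.5, or an empirically estimated mapping-bias value), χ²₁.
* **var test** — deviation of the moderated dispersion θ̂<sup>WL</sup> from
  the trend expectation θ̄<sup>SH</sup>, calibrated by parametric permutation
  (500 replicates by default).
* **group-mean / group-var tests** — changes in allelic mean or dispersion
  across discrete cell groups (cell types, pseudotime tertiles).
* **monoallelic classification** — monoallelic (α < 1 or β < 1), random
  monoallelic expression (both < 1, |α−β| < 0.5, confirmed by the var
  test), and incomplete X inactivation (biallelic ratios in ≥ 15% of cells,
  ≥ 5 cells).
* **simulation & benchmarking** — a zero-inflated negative-binomial totals
  generator with beta-binomial allelic counts, pseudotime bins and U-shaped
  RME genes, plus sensitivity/specificity scoring stratified by expression
  and dispersion.

Intended users: groups quantifying cis-regulatory variation, imprinting,
X-inactivation escape, or allelic variance dynamics from droplet scRNA-seq
with allele-resolved counts.

## Worked example

```python
import numpy as np
from scase import (SimulationSpec, simulate_imbalance_dataset, ShrinkageConfig,
                   TestConfig, estimate_dispersion, test_mean)

# 300 genes x 500 cells; genes 0-19 skewed to the reference allele
spec = SimulationSpec(n_genes=300, n_cells=500, seed=0)
ar = np.full(300, 0.5); ar[:20] = 0.7
ds, truth = simulate_imbalance_dataset(spec, ar, theta=0.02, seed=1)

params, disp = estimate_dispersion(ds, ShrinkageConfig(low_theta_threshold=0.005))
res = test_mean(ds, disp, TestConfig(null_ratio=0.5))
print(f"tested {int(res['tested'].sum())} genes, "
      f"{int((res['fdr'] < 0.05).sum())} imbalanced at FDR 0.05")
print(res.loc[res['fdr'] < 0.05, ['mu_hat', 'log2fc', 'fdr']].head(3).round(4))
```

Output:

```
tested 289 genes, 21 imbalanced at FDR 0.05
         mu_hat  log2fc  fdr
gene_id
g00000   0.7026  1.2400  0.0
g00001   0.7009  1.2286  0.0
g00002   0.7054  1.2594  0.0
```

All 20 spiked genes are recovered (plus one balanced gene, consistent
with the 5% FDR target); `mu_hat` is the fitted allelic ratio and
`log2fc` the allelic odds relative to the null ratio, so a gene at
μ̂ ≈ 0.70 reports log2fc ≈ 1.24.

The same pipeline is available from the shell:

```sh
scase simulate --spec spec.yaml --outdir sim/
scase estimate --ref sim/ref.mtx --total sim/total.mtx \
      --genes sim/genes.tsv --cells sim/cells.tsv --outdir out/
scase test --which mean --ref sim/ref.mtx --total sim/total.mtx \
      --genes sim/genes.tsv --cells sim/cells.tsv --outdir out/ --low-theta 0.005
scase benchmark --results out/mean_results.tsv --truth sim/truth.tsv --out report.json
```

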