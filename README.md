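# mcpca

Population-structure inference from low-coverage sequencing data via
**maximally correlated PCA**: instead of eigen-decomposing the raw genotype
(or dosage) correlation matrix, the method searches per-SNP standardized
transformations of discretized dosage values that maximize the Ky Fan
*q*-norm (the sum of the top *q* eigenvalues) of the transformed covariance
matrix, and embeds the samples with the resulting top-*q* components.

The package covers the full pipeline:

- **io_formats** — Beagle genotype-likelihood text (ANGSD `-doGlf 2`
  dialect), VCF with GP/PL/DS fields (via `cyvcf2`), dosage/genotype TSV,
  score TSV + JSON run reports.
- **dosage** — likelihood→posterior conversion (uniform or HWE prior),
  posterior-mean dosage `DS = Pr(1|Data) + 2 Pr(2|Data)`, folded-MAF site
  filtering.
- **discretize** — per-SNP binning into ordered categories: equal width
  (`intv`), equal frequency (`freq`, tie-safe) and exact Jenks/Fisher 1-D
  optimal partitioning (`jenks`), with Freedman–Diaconis automatic bin
  counts.
- **core** — the block-coordinate Ky Fan optimizer (`fit_mcpca`) with
  monotone objective trajectory, plus `kyfan`, `transformed_covariance`,
  `standardize_transform`.
- **baselines** — correlation/covariance PCA and polynomial-kernel KPCA
  with comparable explained-variance accounting.
- **simulate** — Balding–Nichols multi-population (optionally admixed)
  genotypes, Gamma read depths, depth-driven Phred qualities, Bernoulli
  genotype perturbation, read-based genotype likelihoods, a two-group
  nonlinear classification scenario, and an `ms`-output parser for
  externally simulated haplotypes.

## CLI

```sh
# simulate the three genotype regimes (true / observed / dosage + Beagle GL)
mcpca simulate --out sim/ --n-per-pop 50 --p-sites 2000 --mean-depth 5 --seed 1

# fit an embedding; input format (Beagle GL / VCF / TSV) is auto-detected
mcpca fit sim/dosage.tsv --method mcpca --discretize jenks --bins auto --q 10 --seed 1
mcpca fit sim/true_genotypes.tsv --method pca --q 10
mcpca fit sim/dosage.tsv --method kpca --q 10 --kernel-degree 2

# aggregate explained-variance fractions across replicate reports
mcpca report run1.scores.tsv.report.json run2.scores.tsv.report.json --out table.tsv
```

Every `fit` writes `<prefix>.<method>.scores.tsv` plus a companion
`.report.json` with eigenvalues, the objective trajectory, the explained
fraction, the seed and the full config echo.

## Library example

```python
import numpy as np
from mcpca import (SimConfig, sim_admixed_genotypes, discretize_matrix,
                   fit_mcpca, pca)

X, pops, _ = sim_admixed_genotypes(SimConfig(n_per_pop=50, p_sites=1000, seed=0))
D = discretize_matrix(X, method="jenks", m="auto").drop_degenerate()
res = fit_mcpca(D, q=10, seed=0)
print(res.explained_fraction, ">=", pca(X, q=10).explained_fraction)
scores = res.scores  # n x 10 sample embedding
```
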