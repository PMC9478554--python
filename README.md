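# woolgs

Genomic selection for traits recorded at several ages, built around the
design questions a breeding program faces before committing to a SNP
array: **how many markers are enough**, and **does a multi-trait model pay
off**? The motivating application is wool and body-weight traits of Angora
rabbits measured at 70, 140 and 210 days of age in a population of ~629
genotyped animals.

The package provides:

* **`woolgs.genio`** — genotype/phenotype I/O (PLINK bed/bim/fam, VCF with
  dosages, a plain CSV dialect), marker QC (MAF > 0.05, missing rate < 0.1,
  exact Hardy-Weinberg p > 1e-6) and seed-controlled marker subsampling.
* **`woolgs.grm`** — VanRaden genomic relationship matrices
  `G = WW'/(2Σp(1−p))`, GRM-vs-GRM correlations, stabilization, GCTA-format
  persistence.
* **`woolgs.reml`** — REML-GBLUP: a univariate model
  `y = Xb + Zu + e`, `u ~ N(0, G σ²_u)` fit by exact eigen-rotation and 1-D
  profiling, and a trivariate model `vec(U) ~ N(0, Σ_u ⊗ G)` with per-cell
  missing records, fit by EM + average-information REML with a log-Cholesky
  refinement. Heritabilities with delta-method SEs; GEBVs for all
  individuals, phenotyped or not.
* **`woolgs.simulate`** — a synthetic-population generator (LD-structured
  founder haplotypes, a multi-generation closed breeding pool with half/full-
  sib families, pleiotropic QTL with controlled heritabilities and genetic
  correlations, sex/batch effects) that returns true breeding values for
  recovery tests.
* **`woolgs.evaluate`** — corrected phenotypes, k-fold cross-validation with
  the three multi-trait leave-out strategies (`mvLMM`, `mvLMM23`, `mvLMM3`),
  replicated marker-density scans, and Welch t-test comparisons.
* **`woolgs.cli`** — a `woolgs` command with `simulate`, `qc`, `grm`, `fit`,
  `cv`, `density-scan` and `compare` subcommands, YAML configs and run
  manifests.

## Worked example

```python
import numpy as np
from woolgs import (SimConfig, simulate_population, vanraden_grm, stabilize,
                    fit_uvlmm, fit_mvlmm, make_folds, run_cv)

cfg = SimConfig(seed=1)          # 629 rabbits, 10K SNPs, h2 = (0.05, 0.30, 0.30)
geno, pheno, truth = simulate_population(cfg)
G = stabilize(vanraden_grm(geno, on_monomorphic="drop"))

for col in pheno.trait_columns("WSW"):          # WSW_70, WSW_140, WSW_210
    fit = fit_uvlmm(pheno.values[col], pheno, G)
    print(f"{col}: h2 = {fit.h2:.3f} +- {fit.se_h2:.3f}")

mv = fit_mvlmm(pheno.values[pheno.trait_columns('WSW')], pheno, G)
print("genetic correlations:", np.round(mv.genetic_corr[np.triu_indices(3, 1)], 2))

folds = make_folds(geno.individual_ids, n_folds=10, seed=1)
Gcv = vanraden_grm(geno, on_monomorphic="drop")
uv = run_cv(pheno, Gcv, "uvLMM", folds)
mv_cv = run_cv(pheno, Gcv, "mvLMM", folds)
print("age-70 accuracy  uv:", round(uv.mean_accuracy(0), 3),
      " mv:", round(mv_cv.mean_accuracy(0), 3))
```

Output from this exact script (seed 1):

```
WSW_70: h2 = 0.044 +- 0.036
WSW_140: h2 = 0.264 +- 0.066
WSW_210: h2 = 0.295 +- 0.064
genetic correlations: [0.79 0.92 0.97]
age-70 accuracy  uv: 0.092  mv: 0.146
```

Read: the three ages were simulated at true heritabilities 0.05/0.30/0.30
with genetic correlation 0.8; the univariate fits recover them within
roughly one standard error, the trivariate fit recovers the strong
cross-age correlations, and for the low-heritability age the multi-trait
model predicts better than the single-trait model (0.146 vs 0.092) because
it borrows information from the genetically correlated later ages — the
central practical argument for multi-trait genomic evaluation of
longitudinally recorded traits.

The same pipeline runs from the shell:

```bash
woolgs simulate --config sim.yaml --out data/
woolgs qc --geno data/genotypes.bed --out qc/
woolgs grm --geno qc/genotypes_qc.csv --out qc/pop
woolgs fit --model mv --grm qc/pop --pheno data/phenotypes.csv --trait WSW --out fit/
woolgs cv --geno data/genotypes.bed --pheno data/phenotypes.csv --out cv/
```

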