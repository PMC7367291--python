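# sugibs

Robust genome-wide ancestry inference for heterogeneous genotype datasets.

When cohorts genotyped or imputed under different protocols are analyzed
together, the standard tools misbehave: PCA on frequency-standardized
genotypes is dragged around by individual outliers during fitting, and
projecting new samples onto a PCA reference space produces "shrinkage" and
"shifting" artefacts whenever the new data carry missing genotypes or
genotyping/imputation errors.  This package implements **SUGIBS** — the
spectral decomposition of an **u**nnormalized **g**enomic relationship
matrix generalized by an **IBS** similarity-degree matrix — whose
construction uses no sample statistics (no allele frequencies), making the
fit robust to outliers, and whose projection step rescales every external
individual by its own identity-by-state similarity to the reference panel,
cancelling missingness and error artefacts individual by individual.

It is aimed at statistical geneticists building reference ancestry spaces
(for cohort integration, ancient-DNA placement, or stratification correction
in GWAS) from PLINK-format genotype panels.

## The model

With genotypes coded `aa = -1, Aa = 0, AA = +1` (missing → 0) in the
`M x N` matrix `X`, let `G = (1/M) X'X` and let `D` be the diagonal matrix
of IBS similarity degrees `d_ii = Σ_j w_ij` (PLINK's allele-sharing counts,
unnormalized).  SUGIBS components are generalized eigenvectors

    G v_k = λ_k D v_k,

computed from the SVD of `X D^(-1/2)` and skipping the first component
(the average SNP pattern).  With loadings `L_k = U_k Σ_k^(-1)`, reference
scores are `V_k = D^(-1) X' L_k`, and a new panel `X~` projects as
`V~_k = D~^(-1) X~' L_k`, where `D~` holds each new individual's summed IBS
similarity to the reference panel — the per-individual robustness
correction.  PCA, uncentered PCA (UPCA) and classical MDS on IBS distances
are included as comparators, plus simulators (drift/admixture, case-control
GWAS with stratification, artefact injection, outlier scenarios), a
vectorized logistic likelihood-ratio GWAS scan, and evaluation harnesses.
See `docs/methods.md` for the full account.

## Worked example

Simulate a two-population admixed cohort, fit a SUGIBS space, and check that
the leading component recovers each individual's simulated ancestry
proportion:

```python
import numpy as np
from sugibs import simulate_drift, simulate_admixed, sugibs_fit, sugibs_project
from sugibs.simulate import inject_missing

drift = simulate_drift(m=3200, fst=0.05, tau=20, rng_seed=1)
cohort = simulate_admixed(drift, n=200, rng_seed=2)

model = sugibs_fit(cohort.genotypes, k=2, rng_seed=3)
r = np.corrcoef(model.reference_scores[:, 0], cohort.alpha)[0, 1]
print(f"|corr(component 1, alpha)| = {abs(r):.3f}")

# projection robustness: corrupt a copy with 5% byte-level missingness
corrupt = inject_missing(cohort.genotypes, rate=0.05, rng_seed=4)
proj = sugibs_project(model, corrupt, cohort.genotypes)
drift_err = np.abs(proj.scores - model.reference_scores).max()
rng_1 = np.ptp(model.reference_scores[:, 0])
print(f"max score displacement / axis range = {drift_err / rng_1:.4f}")
```

Output:

```
|corr(component 1, alpha)| = 0.991
max score displacement / axis range = 0.0525
```

The first line shows the leading SUGIBS component is essentially the
simulated admixture proportion; the second shows that masking 5% of all
genotype calls moves no individual by more than ~5% of the occupied axis
range, thanks to the reference-degree correction.

The same workflow is available from the shell:

```bash
sugibs simulate admixture --m 3200 --n 200 --fst 0.05 --seed 1 --out cohort/
sugibs fit cohort/panel --method sugibs --k 2 --seed 3 --out model/
sugibs project model/ cohort/panel --reference cohort/panel --out scores/
sugibs benchmark admixture --reps 20 --fst-list 0.001,0.005,0.01,0.05,0.1 --out bench/
```

Every command writes a `run_config.json` capturing parameters and seeds.

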