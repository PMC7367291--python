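# Methods

## The model

Given a reference panel of `N` individuals genotyped at `M` biallelic SNPs,
genotypes are coded additively as `aa = -1`, `Aa = 0`, `AA = +1` (with `A`
the second allele of the `.bim` record).  Two summaries of the panel drive
everything:

* the **unnormalized genomic relationship matrix** `G = (1/M) X'X`, where `X`
  is the `M x N` coded matrix with missing calls replaced by 0 — no centering
  by allele frequency and no variance standardization; and
* the **IBS similarity degree** of each individual,
  `d_ii = sum_j w_ij`, the row sum of the allele-sharing matrix `W` whose
  per-SNP entries follow the PLINK IBS table (identical homozygotes 2,
  opposite homozygotes 0, heterozygote-vs-anything-observed 1 except 2 for
  het–het, anything-vs-missing 0), *without* PLINK's missingness
  normalization.  The sum includes the self term `w_ii` (2 × the number of
  observed genotypes), which is what the defining sum `j = 1..N` implies and
  is required for projection self-consistency (below).

SUGIBS components are generalized eigenvectors of `(G, D)`, `D = diag(d)`:

    G v_k = lambda_k D v_k.

Substituting `v' = D^(1/2) v` converts this to an ordinary symmetric
eigenproblem whose eigenvectors are the right singular vectors of
`X_hat = X D^(-1/2)`, with `sigma = sqrt(M lambda)`.  Like PCA on uncentered
data, the leading generalized eigenvector carries only the average SNP
pattern, so component `k` of the ancestry space is generalized eigenvector
`k + 1`.  The SNP loading matrix is `L_k = U_k Sigma_k^(-1)` and the
reference scores are `V_k = D^(-1) X' L_k`, normalized so that
`V_k' D V_k = I`.

**Projection.**  A harmonized external panel `X~` (same variants, same allele
orientation) projects as

    V~_k = D~^(-1) X~' L_k,

where `D~` is the diagonal of *reference degrees*: each external individual's
summed IBS similarity to all `N` reference individuals.  Because a missing or
erroneous genotype depresses an individual's raw score `X~' L_k` and its
reference degree together, the per-individual rescaling by `1/d~_ii` cancels
the artefact to first order.  Projecting the reference panel onto its own
space reproduces the reference scores exactly (the expression reduces
algebraically to the fit-time formula), which the tests assert at 1e-10.

**Comparators.**  Three standard constructions are implemented with their
conventional behaviour deliberately preserved:

* *PCA*: per-SNP standardization `z = (g - (2p-1)) / sqrt(2p(1-p))` with `p`
  estimated from non-missing calls, mean imputation (`z = 0`) for missing
  data at fit and projection time, no degree correction.  Under corruption
  the projected scores shrink toward the origin or shift — this is the
  documented failure mode the degree correction exists to fix, so the
  comparator must reproduce it.
* *UPCA*: SVD of the raw coded matrix, uncentered and unstandardized; the
  first component (average SNP pattern) is discarded.  Insensitive to
  genotype errors but not to missingness.
* *Classical MDS* on the IBS allele-sharing distance
  `1 - W_ij / (2 M_ij)`, where `M_ij` counts SNPs observed in both samples
  (the convention of the tool it mirrors — note this pairwise-complete
  normalization intentionally differs from the SUGIBS degrees).  Torgerson
  double-centering, top-k eigenpairs, coordinates scaled by sqrt of the
  eigenvalues.  MDS has no out-of-sample projection.

**Component-count suggestion.**  A parallel-analysis-style rule: simulate
homogeneous null panels with the observed per-SNP allele frequencies under
HWE and linkage equilibrium, and count the leading observed SUGIBS singular
values exceeding the 95th percentile of the null spectrum at the same rank
(19 null replicates by default, so the cutoff is the null maximum).  The
count stops at the first null-like component: trailing exceedances without a
leading run are noise.

## Synthetic cohorts

The simulators generate every cohort the evaluation harnesses use; all are
seeded and reproducible, and all genotypes are drawn in SNP blocks to bound
memory.

* **Drift pairs** — ancestral frequencies `p ~ Uniform(0.1, 0.9)`; both
  populations drift for `tau = 20` generations of binomial resampling with
  `2 Ne` trials, `Ne = round(tau / (2 (1 - exp(-Fst))))`, inverting
  `Fst = -log(1 - tau / (2 Ne))`.  Frequencies absorbed at 0/1 are kept;
  downstream MAF filters may drop them.  The target `Fst` is the
  per-population divergence from the ancestor.
* **Admixed cohorts** — ancestry proportions `alpha ~ Beta(0.5, 0.5)` (mean
  0.5), individual frequencies `alpha p1 + (1 - alpha) p2`, genotypes
  `Binomial(2, p) - 1`.
* **Case-control cohorts** — disease probability
  `log(r) r^alpha / (2 (r-1))` with ancestral risk `r = 3`, which integrates
  to exactly 1/2 over `alpha`; status is drawn prospectively before any
  genotype.  Three SNP categories: *random* (drift at the target Fst, no
  disease effect), *differentiated* (population frequencies fixed at
  0.8/0.2 — the stratification bait), and *causal* (drift frequencies, case
  genotypes drawn from `p* = R p / (1 - p + R p)` through the same admixture
  formula; controls use `p`).  The default causal relative risk is
  `R = 1.5`: at the benchmark's design point (n = 1000, threshold P < 1e-4)
  this puts single-SNP power near 0.5, the operating point of the published
  stratification benchmarks this generator mirrors, whereas a per-allele
  relative risk of 3 saturates power at ~1 and would make the causal
  category uninformative.  `R` is an explicit parameter for users who want a
  different operating point.
* **Artefact injection** — missingness and genotype errors are applied to
  (SNP, sample-group) cells with groups of four consecutive samples,
  emulating byte-granular corruption of the packed binary format; errors are
  restricted to SNPs with MAF below 0.05 (imputation errors concentrate in
  rare variants) and change a call to a uniformly chosen different genotype.
* **Outlier scenario** — two main populations drifted at `Fst ~ 0.004` plus
  single individuals from populations at `Fst >= 0.05`.  Each outlier
  population also contributes *private variants* (monomorphic in the mains,
  segregating only there; count proportional to its divergence, frequencies
  `Uniform(0.01, 0.3)`).  Pure binomial drift from shared ancestral
  frequencies cannot create such variants, but mutation since divergence
  does, and unfiltered multi-population panels are full of them.  They are
  the feature that makes frequency-standardized PCA chase outliers: a
  variant carried only by one outlier gets a panel frequency near `1/(2N)`
  and therefore an enormous standardized value for that individual, while
  the unnormalized methods see a bounded `±1` entry.  Without private
  variants every method, PCA included, keeps the main populations separated;
  the harness defaults include them.

## The GWAS scan

Each SNP is tested by a nested-model likelihood-ratio test in logistic
regression: the null model holds an intercept plus the ancestry covariates,
the alternative adds the additive dosage; `2 (l1 - l0)` is referred to
chi-square with 1 df.  Covariates enter both models and are standardized
internally (the LRT is invariant to affine covariate maps; ancestry scores
arrive on scales from O(1) to O(1e-6) and the normal equations must stay
conditioned).  Missing dosages are mean-imputed per SNP.  The per-SNP fits
run in a compiled per-SNP IRLS kernel (each fit starts from the null
solution, converging in a few Newton steps; tolerance 1e-6 on the
coefficients, 50-iteration cap, non-converged SNPs reported as NaN and
excluded from summaries with a recorded count).  A relative ridge of 1e-9 on
the normal-equation diagonal keeps degenerate SNPs (monomorphic dosages)
solvable; their LRT collapses to ~0.  Against statsmodels' Newton optimizer
the statistics agree to ~1e-6.

The correction benchmark infers ancestry from the *random*-category SNPs
only (one component by default — the simulated structure is
one-dimensional), scans all SNPs once per method (none / PCA / MDS /
SUGIBS), and reports the per-category fraction significant at P < 1e-4.

## Variant filters and harmonization

Harmonization restricts panels to the intersection of variant ids after
excluding indels (any allele longer than one base), reference-monomorphic
variants, and allele-set conflicts; swapped-allele variants have target
genotype signs flipped.  No strand flipping is attempted — A/T and C/G
ambiguity cannot be resolved without frequencies, so mismatches are dropped
and reported.  MAF filtering uses non-missing counts with ties at the
threshold retained; sample missingness above 10% removes the sample
(strictly-greater comparison).  LD pruning is the sliding-window
greedy procedure on raw dosage r² (window 50, step 5, r² > 0.2 by default),
iterated to a fixed point, removing the later variant of a violating pair.

## Numerical choices

* **Decompositions.**  `randomized_svd` dispatches on size: panels whose
  short side is at most `max(4 (k + oversample), 1024)` get an exact
  decomposition — via an eigendecomposition of the small Gram matrix when
  the aspect ratio exceeds 4 (far faster than a divide-and-conquer SVD on a
  tall-skinny operand), LAPACK `gesdd` otherwise.  Above that size the
  seeded Halko range-finder runs with oversampling 10 and two power
  iterations.  The dispatch exists because a randomized range finder cannot
  separate structure from noise when the spectrum is nearly degenerate —
  precisely the near-detection-threshold regime the admixture experiments
  probe (measured there: mean |r| 0.81 exact vs 0.47 randomized) — while at
  desk scale exactness costs nothing.
* **Precision.**  Matrices beyond ~8M entries flow through float32 for the
  heavy products (IBS accumulations are integer-valued and exact in float32
  below 2^24 per block; Gram products lose ~1e-6 relative accuracy, far
  below what any consumer of panels that size resolves); eigendecompositions
  and all small-panel paths stay float64.  Large elementwise passes are
  written to touch each array once — allocation cost dominates arithmetic at
  this scale.
* **Sign convention.**  For every component the loading entry of largest
  magnitude is made positive, applied identically at fit and projection
  time, so runs and serialized models are comparable.
* **Degenerate inputs.**  Zero IBS degrees (all-missing samples), monomorphic
  SNPs under PCA, empty harmonization intersections, one-class status
  vectors and zero-range NRMSD axes all raise informative errors rather than
  propagating NaNs.

## Evaluation harnesses and their scales

* *Admixture detection*: 3,200 SNPs × 200 individuals per replicate across
  an Fst ladder; |corr(component 1, alpha)| per method.  Matches the design
  scale of the original experiment; 20+ replicates run in well under a
  minute.
* *Projection robustness*: a six-population reference (drift 0.1 from shared
  `Uniform(0.01, 0.99)` ancestral frequencies — the wider range supplies the
  rare-variant tail that genotype-error corruption targets), 40 reference
  and 25 target samples per population, 6,000 SNPs, top-8 axes, NRMSD
  between clean and corrupted projections of the same target individuals.
  The qualitative ordering (degree-corrected projection unaffected;
  uncorrected unnormalized projection hurt by missingness only; standardized
  PCA hurt by both) is scale-free and is what the tests assert.
* *Outlier robustness*: 100 + 100 main samples at Fst 0.004, four outliers
  at Fst 0.05–0.15, 50,000 shared SNPs plus private blocks; max over the
  top-2 components of |corr(component, main-population label)| on
  non-outlier samples.
* *Stratification benchmark*: 100k random + 20k differentiated + 5k causal
  SNPs on 1,000 individuals per replicate — a tenth of the original SNP
  count, which leaves all category proportions stable to the third decimal
  across replicates.

The generators emulate allele-frequency drift, admixture, artefact structure
and private variation, but not linkage disequilibrium (sites are
independent), mutation, selection, or relatedness.  Passing tests therefore
demonstrate the algebraic and statistical properties of the methods under
the stated population model, not performance on any particular real cohort.

## Known limitations

* Harmonization matches variants by id, not position, and drops rather than
  strand-flips ambiguous alleles.
* The component-count rule is a heuristic; its null ignores LD, so on real
  (pruned but residually correlated) data it will over-suggest components.
* The projection correction is first-order: individuals with extreme
  missingness (degree near zero) are rejected, not rescued.
* MDS cannot project new samples; it participates in fit-time comparisons
  only.
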