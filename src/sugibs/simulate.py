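"""Synthetic cohorts: drift pairs, admixture, case-control GWAS, artefacts.

The drift model is Balding-Nichols-style binomial resampling: ancestral
frequencies p ~ Uniform(0.1, 0.9), then for each of tau generations and each
population independently z ~ Binomial(2 Ne, p), p <- z / (2 Ne).  The
effective size for a target divergence is Ne = tau / (2 (1 - exp(-Fst))),
inverting Fst = -log(1 - tau / (2 Ne)).  Admixed individuals carry ancestry
proportions alpha ~ Beta(0.5, 0.5) (50% from each population on average) and
draw genotype counts from Binomial(2, alpha p1 + (1 - alpha) p2).

The case-control generator adds a disease with risk proportional to r^alpha,
ancestral risk r = 3: P(case | alpha) = log(r) r^alpha / (2 (r - 1)), whose
mean over alpha in [0, 1] is exactly 0.5.  SNPs come in three categories:
"random" (drift at the target Fst, no disease effect), "differentiated"
(population frequencies fixed at 0.8 / 0.2, no disease effect — the
stratification bait), and "causal" (drift frequencies, with case genotypes
drawn from the multiplicative-risk-updated frequencies
p* = R p / (1 - p + R p), R = 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, SampleRecord, VariantRecord, allele_frequency

__all__ = [
    "DriftPair",
    "AdmixedCohort",
    "CaseControlCohort",
    "fst_to_ne",
    "simulate_drift",
    "simulate_admixed",
    "disease_probability",
    "risk_update",
    "simulate_case_control",
    "inject_missing",
    "inject_errors",
    "simulate_outlier_scenario",
]

_GENO_CHUNK = 4096  # SNP rows per block when drawing large genotype matrices


@dataclass
class DriftPair:
    """Two populations drifted independently from shared ancestral frequencies."""

    p_anc: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    fst_target: float
    ne: int
    tau: int


@dataclass
class AdmixedCohort:
    """Admixed individuals with per-individual ancestry proportions."""

    genotypes: GenotypeMatrix
    alpha: np.ndarray
    individual_freqs: np.ndarray | None = None  # (M, N), optional


@dataclass
class CaseControlCohort:
    """Admixed cohort with disease status and per-SNP category labels."""

    cohort: AdmixedCohort
    status: np.ndarray  # (N,) in {0, 1}
    categories: np.ndarray  # (M,) in {"random", "differentiated", "causal"}
    r: float
    relative_risk: float
    p_star1: np.ndarray | None = None  # case-updated causal frequencies
    p_star2: np.ndarray | None = None


def fst_to_ne(fst: float, tau: int = 20) -> int:
    """Effective population size for a target divergence after ``tau``
    generations of drift: Ne = tau / (2 (1 - exp(-Fst))), rounded."""
    if fst <= 0:
        raise ValueError("fst must be positive")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    return int(round(tau / (2.0 * (1.0 - math.exp(-fst)))))


def simulate_drift(m: int, fst: float, tau: int = 20, rng_seed: int = 0) -> DriftPair:
    """Drift ancestral Uniform(0.1, 0.9) frequencies into two populations.

    Frequencies may be absorbed at 0 or 1; such SNPs are retained (downstream
    MAF filters may drop them).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(rng_seed)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    ne = fst_to_ne(fst, tau)
    p1 = p_anc.copy()
    p2 = p_anc.copy()
    for _ in range(tau):
        p1 = rng.binomial(2 * ne, p1) / (2.0 * ne)
        p2 = rng.binomial(2 * ne, p2) / (2.0 * ne)
    return DriftPair(p_anc=p_anc, p1=p1, p2=p2, fst_target=fst, ne=ne, tau=tau)


def _draw_genotypes(p_cols: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Binomial(2, p) counts mapped to the -1/0/+1 coding, drawn in SNP blocks
    to bound the float workspace."""
    m, n = p_cols.shape
    out = np.empty((m, n), dtype=np.int8)
    for lo in range(0, m, _GENO_CHUNK):
        hi = min(lo + _GENO_CHUNK, m)
        out[lo:hi] = rng.binomial(2, p_cols[lo:hi]).astype(np.int8) - 1
    return out


def _panel(values: np.ndarray, id_prefix: str = "snp", fid: str = "sim") -> GenotypeMatrix:
    m, n = values.shape
    variants = [
        VariantRecord("1", f"{id_prefix}{i + 1}", 0.0, i + 1, "A", "C")
        for i in range(m)
    ]
    samples = [SampleRecord(fid, f"ind{j + 1}") for j in range(n)]
    return GenotypeMatrix(values, variants, samples)


def simulate_admixed(
    drift: DriftPair,
    n: int,
    alpha_dist="beta",
    rng_seed: int = 0,
    keep_freqs: bool = False,
) -> AdmixedCohort:
    """Sample an admixed cohort from a drifted frequency pair.

    ``alpha_dist`` is either the string ``"beta"`` (Beta(0.5, 0.5), mean 0.5)
    or an explicit length-``n`` array of ancestry proportions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if isinstance(alpha_dist, str):
        if alpha_dist != "beta":
            raise ValueError(f"unknown alpha_dist {alpha_dist!r}")
        alpha = rng.beta(0.5, 0.5, size=n)
    else:
        alpha = np.asarray(alpha_dist, dtype=np.float64)
        if alpha.shape != (n,):
            raise ValueError("explicit alpha must have length n")
        if ((alpha < 0) | (alpha > 1)).any():
            raise ValueError("alpha must lie in [0, 1]")
    m = drift.p1.shape[0]
    values = np.empty((m, n), dtype=np.int8)
    freqs = np.empty((m, n)) if keep_freqs else None
    for lo in range(0, m, _GENO_CHUNK):
        hi = min(lo + _GENO_CHUNK, m)
        p_block = np.outer(drift.p1[lo:hi], alpha) + np.outer(
            drift.p2[lo:hi], 1.0 - alpha
        )
        values[lo:hi] = rng.binomial(2, p_block).astype(np.int8) - 1
        if keep_freqs:
            freqs[lo:hi] = p_block
    return AdmixedCohort(
        genotypes=_panel(values), alpha=alpha, individual_freqs=freqs
    )


def disease_probability(alpha: float, r: float = 3.0):
    """P(case) for an individual with ancestry proportion ``alpha`` under
    ancestral risk ``r``: log(r) r^alpha / (2 (r - 1)); integrates to 1/2
    over alpha in [0, 1]."""
    if r <= 1:
        raise ValueError("r must exceed 1")
    alpha = np.asarray(alpha, dtype=np.float64)
    if ((alpha < 0) | (alpha > 1)).any():
        raise ValueError("alpha must lie in [0, 1]")
    out = math.log(r) * np.power(r, alpha) / (2.0 * (r - 1.0))
    return float(out) if out.ndim == 0 else out


def risk_update(p, R: float = 3.0):
    """Case allele frequency under a multiplicative relative risk ``R``:
    p* = R p / (1 - p + R p).  Monotone in p with fixed points 0 and 1."""
    if R <= 0:
        raise ValueError("R must be positive")
    p = np.asarray(p, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p must lie in [0, 1]")
    out = R * p / (1.0 - p + R * p)
    return float(out) if out.ndim == 0 else out


def simulate_case_control(
    m_random: int,
    m_diff: int,
    m_causal: int,
    n: int,
    fst: float,
    rng_seed: int = 0,
    r: float = 3.0,
    relative_risk: float = 1.5,
    tau: int = 20,
) -> CaseControlCohort:
    """Simulate a stratified case-control cohort with three SNP categories.

    Ancestry proportions and case-control status are drawn first
    (status ~ Bernoulli(P(case | alpha))); only causal SNPs condition on
    status, through the risk-updated case frequencies.  The default causal
    relative risk of 1.5 puts single-SNP power at the benchmark's scan
    threshold near 0.5 for n = 1000, the operating point of the published
    stratification benchmarks this generator mirrors (a per-allele relative
    risk of 3 saturates power at ~1 for any n >= 1000 and makes the causal
    category uninformative).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if min(m_random, m_diff, m_causal) < 0:
        raise ValueError("SNP counts must be non-negative")
    rng = np.random.default_rng(rng_seed)
    alpha = rng.beta(0.5, 0.5, size=n)
    status = (rng.random(n) < disease_probability(alpha, r)).astype(np.int8)

    m_total = m_random + m_diff + m_causal
    values = np.empty((m_total, n), dtype=np.int8)
    categories = np.empty(m_total, dtype=object)
    row = 0

    def fill(p1: np.ndarray, p2: np.ndarray, label: str, case_p=None):
        nonlocal row
        mm = p1.shape[0]
        for lo in range(0, mm, _GENO_CHUNK):
            hi = min(lo + _GENO_CHUNK, mm)
            p_block = np.outer(p1[lo:hi], alpha) + np.outer(p2[lo:hi], 1.0 - alpha)
            if case_p is not None:
                p1c, p2c = case_p
                pc = np.outer(p1c[lo:hi], alpha) + np.outer(p2c[lo:hi], 1.0 - alpha)
                p_block = np.where(status[None, :] == 1, pc, p_block)
            values[row + lo : row + hi] = (
                rng.binomial(2, p_block).astype(np.int8) - 1
            )
        categories[row : row + mm] = label
        row += mm

    p_star1 = p_star2 = None
    if m_random:
        d = simulate_drift(m_random, fst, tau, rng_seed=int(rng.integers(2**31)))
        fill(d.p1, d.p2, "random")
    if m_diff:
        fill(np.full(m_diff, 0.8), np.full(m_diff, 0.2), "differentiated")
    if m_causal:
        d = simulate_drift(m_causal, fst, tau, rng_seed=int(rng.integers(2**31)))
        p_star1 = risk_update(d.p1, relative_risk)
        p_star2 = risk_update(d.p2, relative_risk)
        fill(d.p1, d.p2, "causal", case_p=(p_star1, p_star2))

    cohort = AdmixedCohort(genotypes=_panel(values), alpha=alpha)
    return CaseControlCohort(
        cohort=cohort,
        status=status,
        categories=categories.astype(str),
        r=r,
        relative_risk=relative_risk,
        p_star1=p_star1,
        p_star2=p_star2,
    )


def _group_cells(m: int, n: int, rate: float, group_size: int, rng) -> np.ndarray:
    """Boolean (M, N) selection mask drawn per (SNP, sample-group) cell,
    emulating byte-level artefacts (PLINK packs four samples per byte)."""
    n_groups = -(-n // group_size)
    hits = rng.random((m, n_groups)) < rate
    return np.repeat(hits, group_size, axis=1)[:, :n]


def inject_missing(
    g: GenotypeMatrix, rate: float, group_size: int = 4, rng_seed: int = 0
) -> GenotypeMatrix:
    """Mask (SNP, sample-group) cells as missing at the given rate, with
    groups of ``group_size`` consecutive samples masked together."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    out = g.copy()
    rng = np.random.default_rng(rng_seed)
    mask = _group_cells(*g.shape, rate, group_size, rng)
    out.values[mask] = MISSING
    return out


def inject_errors(
    g: GenotypeMatrix,
    rate: float,
    maf_ceiling: float = 0.05,
    group_size: int = 4,
    rng_seed: int = 0,
) -> GenotypeMatrix:
    """Corrupt genotype calls of rare SNPs (MAF below ``maf_ceiling``).

    Selected non-missing calls are changed to a uniformly chosen *different*
    genotype among {-1, 0, +1}; selection works on (SNP, sample-group) cells
    as in :func:`inject_missing`.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    p = allele_frequency(g)
    rare = np.minimum(p, 1 - p) < maf_ceiling
    out = g.copy()
    if not rare.any():
        return out
    rng = np.random.default_rng(rng_seed)
    sub = out.values[rare]
    mask = _group_cells(sub.shape[0], sub.shape[1], rate, group_size, rng)
    mask &= sub != MISSING
    # shift by 1 or 2 (mod 3) over the {-1,0,1} alphabet: always a change
    shift = rng.integers(1, 3, size=int(mask.sum()))
    sub[mask] = ((sub[mask] + 1 + shift) % 3 - 1).astype(np.int8)
    out.values[rare] = sub
    return out


def simulate_outlier_scenario(
    n_main: int = 100,
    fst_close: float = 0.004,
    outlier_fsts=(0.05, 0.1, 0.1, 0.15),
    m: int = 50_000,
    tau: int = 20,
    private_frac: float = 0.05,
    rng_seed: int = 0,
) -> tuple[GenotypeMatrix, dict]:
    """Two closely related main populations plus single-individual outliers.

    The main pair drifts at ``fst_close`` from shared ancestral frequencies;
    each outlier individual is drawn from a further population drifted
    independently from the same ancestral frequencies at its own divergence.

    Each outlier population additionally contributes a block of *private*
    variants — monomorphic in the main populations and segregating only in the
    diverged one — sized ``round(m * private_frac * fst_o / 0.05)`` with
    private-allele frequencies Uniform(0.01, 0.3).  Pure binomial drift from
    shared ancestral frequencies cannot produce such variants, but mutation
    since divergence does, and unfiltered panels mixing divergent samples are
    full of them; they are the feature that makes frequency-standardized PCA
    chase outliers.  Set ``private_frac = 0`` for a drift-only panel.

    Returns the combined panel and a label dict with ``population`` (strings)
    and ``is_outlier`` / ``main_label`` arrays.
    """
    rng = np.random.default_rng(rng_seed)
    drift = simulate_drift(m, fst_close, tau, rng_seed=int(rng.integers(2**31)))
    n_out = len(outlier_fsts)
    cols = []
    pops = []
    for label, p in (("pop1", drift.p1), ("pop2", drift.p2)):
        cols.append(_draw_genotypes(np.repeat(p[:, None], n_main, axis=1), rng))
        pops += [label] * n_main
    for i, fst_o in enumerate(outlier_fsts):
        if fst_o > 0:
            ne = fst_to_ne(fst_o, tau)
            p_o = drift.p_anc.copy()
            for _ in range(tau):
                p_o = rng.binomial(2 * ne, p_o) / (2.0 * ne)
        else:
            p_o = drift.p_anc
        cols.append(_draw_genotypes(p_o[:, None], rng))
        pops.append(f"outlier{i + 1}")
    blocks = [np.concatenate(cols, axis=1)]
    n_total = 2 * n_main + n_out
    for i, fst_o in enumerate(outlier_fsts):
        m_priv = round(m * private_frac * fst_o / 0.05) if fst_o > 0 else 0
        if m_priv == 0:
            continue
        f = rng.uniform(0.01, 0.3, m_priv)
        vals = np.full((m_priv, n_total), -1, dtype=np.int8)
        vals[:, 2 * n_main + i] = (rng.binomial(2, f) - 1).astype(np.int8)
        blocks.append(vals)
    panel = _panel(np.concatenate(blocks, axis=0), fid="outlier_scenario")
    is_outlier = np.array([p.startswith("outlier") for p in pops])
    main_label = np.array(
        [1.0 if p == "pop1" else (-1.0 if p == "pop2" else np.nan) for p in pops]
    )
    labels = {
        "population": np.array(pops),
        "is_outlier": is_outlier,
        "main_label": main_label,
    }
    return panel, labels
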