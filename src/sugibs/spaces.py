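"""Ancestry latent spaces: SUGIBS, PCA, unnormalized PCA (UPCA), and MDS.

SUGIBS components are generalized eigenvectors of the pair (G, D), where
G = (1/M) X'X is the unnormalized genomic relationship matrix and D the
diagonal matrix of IBS similarity degrees:

    G v_k = lambda_k D v_k

Substituting v' = D^(1/2) v turns this into an ordinary symmetric eigenproblem
for D^(-1/2) G D^(-1/2), whose eigenvectors are the right singular vectors of
X_hat = X D^(-1/2) with sigma = sqrt(M * lambda).  The first generalized
eigenvector aggregates the average SNP pattern (as with PCA on uncentered
data) and is skipped, so component k of the space is generalized eigenvector
k+1.  Loadings are L_k = U_k Sigma_k^(-1); reference scores are
V_k = D^(-1) X' L_k, and a new panel projects as V~_k = D~^(-1) X~' L_k where
D~ holds each target sample's summed IBS similarity to the reference panel —
the per-individual correction that makes the projection robust to missing and
erroneous genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd as _sk_randomized_svd

from .genotype_io import MISSING, GenotypeMatrix, allele_frequency
from .similarity import (
    cross_ibs_degrees,
    ibs_degrees,
    ibs_matrix,
    pairwise_complete_counts,
)

__all__ = [
    "AncestryModel",
    "ProjectionResult",
    "MDSResult",
    "randomized_svd",
    "sugibs_fit",
    "sugibs_project",
    "pca_fit",
    "pca_project",
    "upca_fit",
    "upca_project",
    "mds_fit",
    "suggest_component_count",
    "save_model",
    "load_model",
]


@dataclass
class AncestryModel:
    """A fitted reference ancestry space.

    ``loadings`` maps a (harmonized) dosage matrix to scores; for SUGIBS and
    UPCA they are U_k Sigma_k^(-1) on raw dosages, for PCA they apply to
    genotypes standardized with the stored per-SNP ``mu``/``sigma``.
    """

    method: str  # "SUGIBS" | "PCA" | "UPCA"
    k: int
    loadings: np.ndarray  # (M, k)
    singular_values: np.ndarray  # (k,) descending, positive
    reference_scores: np.ndarray  # (N, k)
    variant_keys: list = field(default_factory=list)  # (id, a1, a2) tuples
    sample_keys: list = field(default_factory=list)  # (fid, iid) tuples
    mu: np.ndarray | None = None  # PCA only: per-SNP mean of the -1/0/1 coding
    sigma: np.ndarray | None = None  # PCA only: per-SNP sd sqrt(2 p (1-p))
    seed: int | None = None


@dataclass
class ProjectionResult:
    """Projected scores for a target panel (plus, for SUGIBS, the reference
    degrees that corrected them)."""

    scores: np.ndarray  # (N_target, k)
    method: str
    degrees: np.ndarray | None = None  # SUGIBS only


@dataclass
class MDSResult:
    """Classical (Torgerson) scaling of the IBS allele-sharing distance."""

    coordinates: np.ndarray  # (N, k), column-centered
    eigenvalues: np.ndarray  # (k,) descending


def randomized_svd(
    a: np.ndarray,
    k: int,
    oversample: int = 10,
    power_iters: int = 2,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded rank-k truncated SVD (Halko-style range finder).

    Returns ``(U, s, Vt.T)`` with singular values descending.  Deterministic
    for a fixed seed; with two power iterations the top singular values of a
    well-separated genotype spectrum agree with a dense SVD to ~1e-6 relative.
    """
    a = np.asarray(a)
    if k + oversample > min(a.shape):
        raise ValueError(
            f"k + oversample = {k + oversample} exceeds min(shape) = {min(a.shape)}"
        )
    if min(a.shape) <= max(4 * (k + oversample), 1024):
        # Matrices whose short side fits an exact decomposition get one: the
        # randomized range finder loses accuracy when the residual spectrum is
        # nearly degenerate (weak structure close to the noise edge), exactly
        # the regime where ancestry detection is interesting.
        return _exact_svd(a, k)
    u, s, vt = _sk_randomized_svd(
        a,
        n_components=k,
        n_oversamples=oversample,
        n_iter=power_iters,
        power_iteration_normalizer="QR",
        random_state=int(rng_seed) % (2**32),
    )
    return u, s, vt.T


def _svd_dispatch(a: np.ndarray, k: int, rng_seed: int):
    """Internal truncated SVD used by the fits: exact at desk scale,
    seeded randomized range-finder beyond it.  Unlike the public
    :func:`randomized_svd`, small panels need not accommodate oversampling."""
    if k > min(a.shape):
        raise ValueError(f"k = {k} exceeds min(shape) = {min(a.shape)}")
    if min(a.shape) <= max(4 * (k + 10), 1024):
        return _exact_svd(a, k)
    return randomized_svd(a, k, rng_seed=rng_seed)


def _exact_svd(a: np.ndarray, k: int):
    """Truncated exact SVD; strongly rectangular matrices go through an
    eigendecomposition of the small Gram matrix, which is much faster than
    LAPACK's divide-and-conquer SVD on a tall-skinny operand.  Beyond ~8M
    entries the Gram product runs in float32 (genotype Gram entries are
    well-scaled sums, and the downstream consumers of such panels need score
    accuracy far below the ~1e-6 this costs); the eigendecomposition itself
    stays in float64."""
    m, n = a.shape
    if a.size > (1 << 23):
        a = a.astype(np.float32, copy=False)
    if max(m, n) >= 4 * min(m, n):
        if m >= n:
            w, v = np.linalg.eigh((a.T @ a).astype(np.float64))
            w, v = w[::-1][:k], v[:, ::-1][:, :k]
            s = np.sqrt(np.maximum(w, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                # keep the tall product in a's dtype: mixed-dtype matmuls
                # silently upcast (and copy) the large operand
                u = (a @ v.astype(a.dtype)) / np.where(s > 0, s, 1.0)[None, :]
            return u.astype(np.float64), s, v
        w, u = np.linalg.eigh((a @ a.T).astype(np.float64))
        w, u = w[::-1][:k], u[:, ::-1][:, :k]
        s = np.sqrt(np.maximum(w, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (a.T @ u.astype(a.dtype)) / np.where(s > 0, s, 1.0)[None, :]
        return u, s, v.astype(np.float64)
    u, s, vt = np.linalg.svd(a.astype(np.float64), full_matrices=False)
    return u[:, :k], s[:k], vt[:k].T


def _fix_signs(loadings: np.ndarray, *score_blocks: np.ndarray):
    """Deterministic sign convention: per component, the loading entry of
    largest magnitude is positive.  Score blocks are flipped to match."""
    flip = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            flip[j] = -1.0
    loadings = loadings * flip
    return (loadings, *(b * flip for b in score_blocks))


def _check_k(k: int, m: int, n: int, skip_first: bool) -> None:
    need = k + 1 if skip_first else k
    if k < 1:
        raise ValueError("k must be >= 1")
    if need > min(m, n):
        raise ValueError(
            f"k={k} needs {need} singular triplets but min(M, N) = {min(m, n)}"
        )


def sugibs_fit(g: GenotypeMatrix, k: int = 8, rng_seed: int = 0) -> AncestryModel:
    """Fit a SUGIBS reference space with ``k`` components.

    Takes the top ``k+1`` singular triplets of X D^(-1/2) (randomized, seeded)
    and discards the first, which only carries the average SNP pattern.
    """
    m, n = g.shape
    _check_k(k, m, n, skip_first=True)
    d = ibs_degrees(g).astype(np.float64)
    if (d <= 0).any():
        bad = [g.samples[i].individual_id for i in np.flatnonzero(d <= 0)]
        raise ValueError(f"zero IBS similarity degree for sample(s) {bad}")
    xhat = g.dosage(np.float32 if g.values.size > (1 << 23) else np.float64)
    sq = np.sqrt(d).astype(xhat.dtype)
    xhat /= sq[None, :]  # X_hat = X D^(-1/2), formed in place
    u, s, _ = _svd_dispatch(xhat, k + 1, rng_seed)
    u_k, s_k = u[:, 1:], s[1:]
    if (s_k <= 0).any():
        raise ValueError("rank-deficient panel: non-positive singular values")
    loadings = u_k / s_k[None, :]
    # V_k = D^-1 X' L_k = D^(-1/2) X_hat' L_k, reusing the scaled matrix
    scores = (xhat.T @ loadings.astype(xhat.dtype)).astype(np.float64) / np.sqrt(
        d
    )[:, None]
    loadings, scores = _fix_signs(loadings, scores)
    return AncestryModel(
        method="SUGIBS",
        k=k,
        loadings=loadings,
        singular_values=s_k,
        reference_scores=scores,
        variant_keys=g.variant_keys(),
        sample_keys=[s_.key for s_ in g.samples],
        seed=rng_seed,
    )


def sugibs_project(
    model: AncestryModel, target: GenotypeMatrix, reference: GenotypeMatrix
) -> ProjectionResult:
    """Project a harmonized target panel onto a fitted SUGIBS space.

    Each target sample's raw score row X~' L_k is rescaled by the inverse of
    its own reference degree (summed IBS similarity to the reference panel),
    which absorbs score deflation from missing genotypes and errors.
    """
    if model.method != "SUGIBS":
        raise ValueError(f"model method is {model.method}, expected SUGIBS")
    _check_harmonized(model, target)
    _check_harmonized(model, reference, role="reference")
    cross = cross_ibs_degrees(reference, target)
    d = cross.degrees.astype(np.float64)
    if (d <= 0).any():
        bad = [target.samples[i].individual_id for i in np.flatnonzero(d <= 0)]
        raise ValueError(
            f"target sample(s) {bad} share no observed genotypes with the reference"
        )
    scores = (target.dosage().T @ model.loadings) / d[:, None]
    return ProjectionResult(scores=scores, method="SUGIBS", degrees=cross.degrees)


def pca_fit(g: GenotypeMatrix, k: int = 8, rng_seed: int = 0) -> AncestryModel:
    """PCA on frequency-standardized genotypes (EIGENSTRAT convention).

    Per SNP, z = (g - mu) / sigma with mu = 2 p - 1 (mean of the -1/0/+1
    coding at allele-2 frequency p) and sigma = sqrt(2 p (1 - p)); missing
    genotypes are mean-imputed (z = 0).  Monomorphic SNPs have sigma = 0 and
    must be removed upstream (MAF filter).
    """
    m, n = g.shape
    _check_k(k, m, n, skip_first=False)
    p = allele_frequency(g)
    sigma = np.sqrt(2.0 * p * (1.0 - p))
    if (sigma == 0).any():
        raise ValueError(
            "monomorphic SNP(s) present (sigma = 0); apply a MAF filter first"
        )
    mu = 2.0 * p - 1.0
    z = _standardize(g, mu, sigma)
    u, s, v = _svd_dispatch(z, k, rng_seed)
    if (s <= 0).any():
        raise ValueError("rank-deficient panel: non-positive singular values")
    loadings = u / s[None, :]
    scores = (z.T @ loadings.astype(z.dtype)).astype(np.float64)  # right singular vectors
    loadings, scores = _fix_signs(loadings, scores)
    return AncestryModel(
        method="PCA",
        k=k,
        loadings=loadings,
        singular_values=s,
        reference_scores=scores,
        variant_keys=g.variant_keys(),
        sample_keys=[s_.key for s_ in g.samples],
        mu=mu,
        sigma=sigma,
        seed=rng_seed,
    )


def pca_project(model: AncestryModel, target: GenotypeMatrix) -> ProjectionResult:
    """Project a harmonized target with the reference normalization constants.

    No degree correction is applied: under missing or erroneous genotypes the
    projected scores show the documented shrinkage/shifting, faithfully
    mirroring the standard PCA projection this method stands in for.
    """
    if model.method != "PCA":
        raise ValueError(f"model method is {model.method}, expected PCA")
    _check_harmonized(model, target)
    z = _standardize(target, model.mu, model.sigma)
    return ProjectionResult(scores=z.T @ model.loadings, method="PCA")


def upca_fit(g: GenotypeMatrix, k: int = 8, rng_seed: int = 0) -> AncestryModel:
    """PCA on raw (uncentered, unstandardized) dosages; the first component
    carries the average SNP pattern and is discarded, as in SUGIBS."""
    m, n = g.shape
    _check_k(k, m, n, skip_first=True)
    x = g.dosage(np.float32 if g.values.size > (1 << 23) else np.float64)
    u, s, _ = _svd_dispatch(x, k + 1, rng_seed)
    u_k, s_k = u[:, 1:], s[1:]
    if (s_k <= 0).any():
        raise ValueError("rank-deficient panel: non-positive singular values")
    loadings = u_k / s_k[None, :]
    scores = (x.T @ loadings.astype(x.dtype)).astype(np.float64)
    loadings, scores = _fix_signs(loadings, scores)
    return AncestryModel(
        method="UPCA",
        k=k,
        loadings=loadings,
        singular_values=s_k,
        reference_scores=scores,
        variant_keys=g.variant_keys(),
        sample_keys=[s_.key for s_ in g.samples],
        seed=rng_seed,
    )


def upca_project(model: AncestryModel, target: GenotypeMatrix) -> ProjectionResult:
    """Project raw dosages onto a UPCA space (no degree correction)."""
    if model.method != "UPCA":
        raise ValueError(f"model method is {model.method}, expected UPCA")
    _check_harmonized(model, target)
    return ProjectionResult(
        scores=target.dosage().T @ model.loadings, method="UPCA"
    )


def mds_fit(g: GenotypeMatrix, k: int = 8) -> MDSResult:
    """Classical MDS on the IBS allele-sharing distance.

    The distance is 1 - W_ij / (2 M_ij) with M_ij the count of SNPs observed
    in both samples (PLINK's convention for its ``--mds-plot``), which differs
    from the SUGIBS degrees on purpose: the comparator mimics the tool it
    stands in for.
    """
    n = g.n_samples
    if not (1 <= k <= n - 1):
        raise ValueError("k must satisfy 1 <= k <= N - 1")
    ibs = ibs_matrix(g)
    m_pair = pairwise_complete_counts(g)
    if (m_pair == 0).any():
        raise ValueError("some sample pair shares no observed SNPs")
    dist = 1.0 - ibs.W / (2.0 * m_pair)
    np.fill_diagonal(dist, 0.0)
    d2 = dist * dist
    # double-centering: B = -1/2 J D^2 J
    row = d2.mean(axis=1, keepdims=True)
    b = -0.5 * (d2 - row - row.T + d2.mean())
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals_k = vals[order]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals_k, 0.0))[None, :]
    coords, = _fix_signs(coords)
    return MDSResult(coordinates=coords, eigenvalues=vals_k)


def suggest_component_count(
    g: GenotypeMatrix, max_k: int = 8, n_null: int = 19, rng_seed: int = 0
) -> int:
    """Parallel-analysis-style component count for a SUGIBS space.

    Compares the observed SUGIBS singular spectrum with spectra of simulated
    homogeneous panels (per-SNP allele frequencies matched to the data,
    genotypes drawn under HWE and linkage equilibrium) and returns the number
    of leading components whose singular value exceeds the 95th percentile of
    the null at the same rank, capped at ``max_k``.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    m, n = g.shape
    kk = min(max_k, min(m, n) - 1)
    obs_model = sugibs_fit(g, k=kk, rng_seed=rng_seed)
    p = allele_frequency(g)
    rng = np.random.default_rng(rng_seed)
    null_spectra = np.empty((n_null, kk))
    for r in range(n_null):
        counts = rng.binomial(2, p[:, None], size=(m, n)).astype(np.int8)
        null = GenotypeMatrix(counts - 1, list(g.variants), list(g.samples))
        null_spectra[r] = sugibs_fit(
            null, k=kk, rng_seed=int(rng.integers(2**31))
        ).singular_values
    cutoff = np.percentile(null_spectra, 95, axis=0)
    exceed = obs_model.singular_values > cutoff
    count = 0
    for flag in exceed:  # leading run only: stop at the first null-like value
        if not flag:
            break
        count += 1
    return min(count, max_k)


# ---------------------------------------------------------------------------
# helpers and serialization
# ---------------------------------------------------------------------------

def _standardize(g: GenotypeMatrix, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    dt = np.float32 if g.values.size > (1 << 23) else np.float64
    z = (g.values.astype(dt) - mu[:, None].astype(dt)) / sigma[:, None].astype(dt)
    z[g.values == MISSING] = 0.0
    return z


def _check_harmonized(model: AncestryModel, panel: GenotypeMatrix, role: str = "target") -> None:
    if panel.variant_keys() != list(map(tuple, model.variant_keys)):
        raise ValueError(
            f"{role} panel variants do not match the model's variant keys; "
            "run harmonize() against the reference first"
        )


def save_model(model: AncestryModel, directory: str | Path) -> None:
    """Serialize a model to a directory of TSVs plus a JSON metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    k = model.k
    load_cols = {f"loading_{j + 1}": model.loadings[:, j] for j in range(k)}
    df = pd.DataFrame(
        {
            "variant_id": [vk[0] for vk in model.variant_keys],
            "allele1": [vk[1] for vk in model.variant_keys],
            "allele2": [vk[2] for vk in model.variant_keys],
            **load_cols,
        }
    )
    if model.mu is not None:
        df["mu"] = model.mu
        df["sigma"] = model.sigma
    df.to_csv(directory / "loadings.tsv", sep="\t", index=False)
    pd.DataFrame({"singular_value": model.singular_values}).to_csv(
        directory / "singular_values.tsv", sep="\t", index=False
    )
    scores = pd.DataFrame(
        model.reference_scores, columns=[f"score_{j + 1}" for j in range(k)]
    )
    scores.insert(0, "FID", [sk[0] for sk in model.sample_keys])
    scores.insert(1, "IID", [sk[1] for sk in model.sample_keys])
    scores.to_csv(directory / "reference_scores.tsv", sep="\t", index=False)
    meta = {"method": model.method, "k": model.k, "seed": model.seed}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> AncestryModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    df = pd.read_csv(directory / "loadings.tsv", sep="\t", dtype={"variant_id": str, "allele1": str, "allele2": str})
    k = meta["k"]
    loadings = df[[f"loading_{j + 1}" for j in range(k)]].to_numpy()
    mu = df["mu"].to_numpy() if "mu" in df else None
    sigma = df["sigma"].to_numpy() if "sigma" in df else None
    sv = pd.read_csv(directory / "singular_values.tsv", sep="\t")[
        "singular_value"
    ].to_numpy()
    sc = pd.read_csv(directory / "reference_scores.tsv", sep="\t", dtype={"FID": str, "IID": str})
    scores = sc[[f"score_{j + 1}" for j in range(k)]].to_numpy()
    return AncestryModel(
        method=meta["method"],
        k=k,
        loadings=loadings,
        singular_values=sv,
        reference_scores=scores,
        variant_keys=[
            (r.variant_id, r.allele1, r.allele2) for r in df.itertuples()
        ],
        sample_keys=[(r.FID, r.IID) for r in sc.itertuples()],
        mu=mu,
        sigma=sigma,
        seed=meta.get("seed"),
    )
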