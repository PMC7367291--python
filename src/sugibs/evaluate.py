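"""Evaluation metrics and end-to-end synthetic experiment harnesses.

Three harnesses mirror the method's validation experiments on fully synthetic
cohorts: (1) outlier robustness of the four space constructions, (2) NRMSD of
projected scores under byte-level missingness / rare-SNP error corruption,
and (3) admixture detection (correlation between the leading component and
the simulated ancestry proportion) across a ladder of Fst divergences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, filter_maf
from .simulate import (
    inject_errors,
    inject_missing,
    simulate_admixed,
    simulate_drift,
    simulate_outlier_scenario,
)
from .spaces import (
    mds_fit,
    pca_fit,
    pca_project,
    sugibs_fit,
    sugibs_project,
    upca_fit,
    upca_project,
)

__all__ = [
    "nrmsd",
    "detectable_fst",
    "ancestry_correlation",
    "run_experiment_admixture",
    "run_experiment_projection",
    "run_experiment_outliers",
]


def nrmsd(original_scores: np.ndarray, modified_scores: np.ndarray) -> np.ndarray:
    """Per-axis root-mean-square deviation between two score matrices,
    normalized by the range of the original axis (so axes and methods on
    different scales are comparable)."""
    orig = np.asarray(original_scores, dtype=np.float64)
    mod = np.asarray(modified_scores, dtype=np.float64)
    if orig.shape != mod.shape:
        raise ValueError("score matrices must have identical shapes")
    rng = orig.max(axis=0) - orig.min(axis=0)
    if (rng == 0).any():
        raise ValueError("an original axis has zero range")
    rmsd = np.sqrt(np.mean((orig - mod) ** 2, axis=0))
    return rmsd / rng


def detectable_fst(m: int, n: int) -> float:
    """Theoretical finest two-population divergence detectable from ``m``
    independent SNPs on ``n`` samples: 1 / sqrt(m n / 2)."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return 1.0 / np.sqrt(m * n / 2.0)


def ancestry_correlation(model_scores: np.ndarray, alpha: np.ndarray) -> float:
    """Absolute Pearson correlation between the first score column and the
    simulated ancestry proportions."""
    scores = np.atleast_2d(np.asarray(model_scores, dtype=np.float64))
    if scores.shape[0] == 1:
        scores = scores.T
    comp = scores[:, 0]
    alpha = np.asarray(alpha, dtype=np.float64)
    if comp.std() == 0 or alpha.std() == 0:
        raise ValueError("zero variance in scores or ancestry proportions")
    return float(abs(np.corrcoef(comp, alpha)[0, 1]))


def run_experiment_admixture(
    fst_list=(0.001, 0.005, 0.01, 0.05, 0.1),
    n_reps: int = 100,
    m: int = 3200,
    n: int = 200,
    rng_seed: int = 0,
    tau: int = 20,
) -> pd.DataFrame:
    """Admixture-detection sweep: for each Fst and replicate, simulate a
    two-population admixed cohort, fit SUGIBS / PCA / MDS with one component,
    and record |corr(component 1, alpha)|.

    Returns a long DataFrame (fst, method, rep, seed, abs_corr).
    """
    master = np.random.default_rng(rng_seed)
    rows = []
    for fst in fst_list:
        for rep in range(n_reps):
            seed = int(master.integers(2**31))
            sub = np.random.default_rng(seed)
            drift = simulate_drift(m, fst, tau, rng_seed=int(sub.integers(2**31)))
            cohort = simulate_admixed(drift, n, rng_seed=int(sub.integers(2**31)))
            g = cohort.genotypes
            fit_seed = int(sub.integers(2**31))

            sug = sugibs_fit(g, k=1, rng_seed=fit_seed)
            rows.append(_arow(fst, "SUGIBS", rep, seed,
                              ancestry_correlation(sug.reference_scores, cohort.alpha)))

            poly = filter_maf(g, 1e-9)  # PCA cannot handle fixed SNPs
            pca = pca_fit(poly, k=1, rng_seed=fit_seed)
            rows.append(_arow(fst, "PCA", rep, seed,
                              ancestry_correlation(pca.reference_scores, cohort.alpha)))

            mds = mds_fit(g, k=1)
            rows.append(_arow(fst, "MDS", rep, seed,
                              ancestry_correlation(mds.coordinates, cohort.alpha)))
    return pd.DataFrame(rows)


def _arow(fst, method, rep, seed, r):
    return {"fst": fst, "method": method, "rep": rep, "seed": seed, "abs_corr": r}


def _multipop_panel(
    m: int, n_per_pop: int, n_pops: int, fst: float, tau: int, rng
) -> GenotypeMatrix:
    """Multi-population panel: each population drifts independently from
    shared Uniform(0.01, 0.99) ancestral frequencies, giving several axes of
    structure plus a realistic rare-variant tail for the error corruption."""
    from .simulate import _draw_genotypes, _panel, fst_to_ne

    p_anc = rng.uniform(0.01, 0.99, size=m)
    ne = fst_to_ne(fst, tau)
    cols = []
    for _ in range(n_pops):
        p = p_anc.copy()
        for _ in range(tau):
            p = rng.binomial(2 * ne, p) / (2.0 * ne)
        cols.append(_draw_genotypes(np.repeat(p[:, None], n_per_pop, axis=1), rng))
    return _panel(np.concatenate(cols, axis=1))


def run_experiment_projection(
    reference_spec: dict | None = None,
    target_spec: dict | None = None,
    corruption: str = "missing",
    n_reps: int = 10,
    k: int = 8,
    rng_seed: int = 0,
    rate: float = 0.05,
    maf_ceiling: float = 0.05,
    group_size: int = 4,
) -> pd.DataFrame:
    """Projection-robustness harness.

    Simulates a multi-population reference panel and a target panel drawn from
    the same populations, fits PCA / UPCA / SUGIBS on the reference, projects
    a clean and a corrupted copy of the target, and reports the per-axis NRMSD
    between the two projections.  ``corruption`` is ``"missing"`` (byte-level
    5% masking by default), ``"errors"`` (5% rare-SNP genotype changes), or
    ``"none"``.

    Returns a long DataFrame (method, corruption, rep, axis, nrmsd).
    """
    ref_spec = {"m": 6000, "n_per_pop": 40, "n_pops": 6, "fst": 0.1, "tau": 20}
    if reference_spec:
        ref_spec.update(reference_spec)
    tgt_spec = {"n_per_pop": 25}
    if target_spec:
        tgt_spec.update(target_spec)
    if corruption not in ("missing", "errors", "none"):
        raise ValueError(f"unknown corruption {corruption!r}")

    master = np.random.default_rng(rng_seed)
    rows = []
    for rep in range(n_reps):
        seed = int(master.integers(2**31))
        rng = np.random.default_rng(seed)
        panel = _multipop_panel(
            ref_spec["m"],
            ref_spec["n_per_pop"] + tgt_spec["n_per_pop"],
            ref_spec["n_pops"],
            ref_spec["fst"],
            ref_spec["tau"],
            rng,
        )
        # interleave: first n_per_pop of each population -> reference
        npp = ref_spec["n_per_pop"] + tgt_spec["n_per_pop"]
        ref_cols, tgt_cols = [], []
        for pop in range(ref_spec["n_pops"]):
            start = pop * npp
            ref_cols += list(range(start, start + ref_spec["n_per_pop"]))
            tgt_cols += list(range(start + ref_spec["n_per_pop"], start + npp))
        reference = panel.take_samples(ref_cols)
        target = panel.take_samples(tgt_cols)
        # PCA needs polymorphic SNPs; restrict every method to the same set
        keep = _polymorphic_index(reference)
        reference = reference.take_variants(keep)
        target = target.take_variants(keep)

        if corruption == "missing":
            corrupted = inject_missing(target, rate, group_size, rng_seed=seed)
        elif corruption == "errors":
            corrupted = inject_errors(
                target, rate, maf_ceiling, group_size, rng_seed=seed
            )
        else:
            corrupted = target.copy()

        fit_seed = int(rng.integers(2**31))
        sug = sugibs_fit(reference, k=k, rng_seed=fit_seed)
        upc = upca_fit(reference, k=k, rng_seed=fit_seed)
        pca = pca_fit(reference, k=k, rng_seed=fit_seed)

        pairs = {
            "SUGIBS": (
                sugibs_project(sug, target, reference).scores,
                sugibs_project(sug, corrupted, reference).scores,
            ),
            "UPCA": (
                upca_project(upc, target).scores,
                upca_project(upc, corrupted).scores,
            ),
            "PCA": (
                pca_project(pca, target).scores,
                pca_project(pca, corrupted).scores,
            ),
        }
        for method, (clean, dirty) in pairs.items():
            vals = nrmsd(clean, dirty)
            for axis, v in enumerate(vals, start=1):
                rows.append(
                    {
                        "method": method,
                        "corruption": corruption,
                        "rep": rep,
                        "seed": seed,
                        "axis": axis,
                        "nrmsd": float(v),
                    }
                )
    return pd.DataFrame(rows)


def _polymorphic_index(g: GenotypeMatrix) -> np.ndarray:
    from .genotype_io import allele_frequency

    p = allele_frequency(g)
    return np.flatnonzero((p > 0) & (p < 1))


def run_experiment_outliers(
    n_main: int = 100,
    fst_close: float = 0.004,
    outlier_fsts=(0.05, 0.1, 0.1, 0.15),
    m: int = 50_000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Outlier-robustness harness.

    Builds a two-close-populations panel with single-individual outliers, fits
    all four methods with two components, and reports per method the maximum
    over the top-2 components of |corr(component, main-population label)|
    computed on the non-outlier samples only.
    """
    panel, labels = simulate_outlier_scenario(
        n_main=n_main,
        fst_close=fst_close,
        outlier_fsts=outlier_fsts,
        m=m,
        rng_seed=rng_seed,
    )
    main = ~labels["is_outlier"]
    y = labels["main_label"][main]

    fit_seed = rng_seed
    poly = filter_maf(panel, 1e-9)
    score_sets = {
        "SUGIBS": sugibs_fit(panel, k=2, rng_seed=fit_seed).reference_scores,
        "UPCA": upca_fit(panel, k=2, rng_seed=fit_seed).reference_scores,
        "PCA": pca_fit(poly, k=2, rng_seed=fit_seed).reference_scores,
        "MDS": mds_fit(panel, k=2).coordinates,
    }
    rows = []
    for method, scores in score_sets.items():
        best = 0.0
        for j in range(scores.shape[1]):
            comp = scores[main, j]
            if comp.std() == 0:
                continue
            best = max(best, abs(float(np.corrcoef(comp, y)[0, 1])))
        rows.append(
            {
                "method": method,
                "max_abs_corr_top2": best,
                "n_main": 2 * n_main,
                "n_outliers": len(outlier_fsts),
                "fst_close": fst_close,
                "seed": rng_seed,
            }
        )
    return pd.DataFrame(rows)
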