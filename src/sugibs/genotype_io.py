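"""PLINK 1 binary genotype I/O, panel harmonization, and variant/sample filters.

Genotypes are held SNP-major as an ``int8`` matrix with additive coding
``aa = -1``, ``Aa = 0``, ``AA = +1`` (``A`` being allele2 of the ``.bim``
record) and a distinct :data:`MISSING` sentinel.  The "missing counts as 0"
substitution used by the similarity and spectral machinery happens inside
those operations, never at I/O time, so PCA can apply its own mean-imputation
convention without information loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for an unobserved genotype call (distinct from the coded -1/0/+1).
MISSING = np.int8(-9)

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit PLINK codes, read low-to-high within a byte:
#   00 -> homozygous allele1 -> -1
#   01 -> missing
#   10 -> heterozygous      ->  0
#   11 -> homozygous allele2 -> +1
_CODE_TO_GENO = np.array([-1, MISSING, 0, 1], dtype=np.int8)
_GENO_TO_CODE = {-1: 0b00, int(MISSING): 0b01, 0: 0b10, 1: 0b11}

# byte -> 4 genotypes lookup, built once
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_GENO[(_b >> (2 * _k)) & 0b11]


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam triplet violates the PLINK 1 format."""


def _sib(prefix: Path, ext: str) -> Path:
    # prefix may itself contain dots; never use Path.with_suffix here
    return prefix.parent / (prefix.name + ext)


@dataclass(frozen=True)
class VariantRecord:
    """One ``.bim`` line: a biallelic (or indel/multiallelic) variant."""

    chromosome: str
    variant_id: str
    genetic_distance: float
    position: int
    allele1: str
    allele2: str

    def __post_init__(self):
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")


@dataclass(frozen=True)
class SampleRecord:
    """One ``.fam`` line."""

    family_id: str
    individual_id: str
    sex: int = 0
    phenotype: float = -9.0

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass
class GenotypeMatrix:
    """SNP-major additive-coded genotype panel with variant/sample metadata."""

    values: np.ndarray  # (M, N) int8 over {-1, 0, +1, MISSING}
    variants: list[VariantRecord] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (M, N) matrix")
        m, n = self.values.shape
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} rows")
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample records for {n} columns")
        v = self.values
        valid = ((v >= -1) & (v <= 1)) | (v == MISSING)
        if not valid.all():
            bad = np.unique(v[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (family_id, individual_id) pairs")

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def observed_mask(self) -> np.ndarray:
        """Boolean (M, N) mask of non-missing calls."""
        return self.values != MISSING

    def dosage(self, dtype=np.float64) -> np.ndarray:
        """Additive coding with MISSING substituted by 0 (the UG convention)."""
        x = self.values.astype(dtype)
        x[self.values == MISSING] = 0.0
        return x

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_keys(self) -> list[tuple[str, str, str]]:
        return [(v.variant_id, v.allele1, v.allele2) for v in self.variants]

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx], [self.variants[i] for i in idx], list(self.samples)
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx], list(self.variants), [self.samples[i] for i in idx]
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(), list(self.variants), list(self.samples)
        )


# ---------------------------------------------------------------------------
# PLINK binary I/O
# ---------------------------------------------------------------------------

def read_plink(path_prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 ``.bed/.bim/.fam`` triplet (SNP-major only).

    Raises
    ------
    PlinkFormatError
        If the magic bytes are wrong, the mode is not SNP-major, or the
        ``.bed`` length is inconsistent with ``ceil(N/4) * M + 3``.
    """
    prefix = Path(path_prefix)
    bim = _read_bim(_sib(prefix, ".bim"))
    fam = _read_fam(_sib(prefix, ".fam"))
    m, n = len(bim), len(fam)

    raw = np.fromfile(_sib(prefix, ".bed"), dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2:3].tobytes() != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not SNP-major (mode byte != 0x01)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if raw.size != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: {raw.size} bytes, expected {expected} "
            f"for {m} variants x {n} samples"
        )
    if m == 0 or n == 0:
        values = np.empty((m, n), dtype=np.int8)
    else:
        body = raw[3:].reshape(m, bytes_per_snp)
        values = _BYTE_LUT[body].reshape(m, bytes_per_snp * 4)[:, :n]
    return GenotypeMatrix(values, bim, fam)


def write_plink(g: GenotypeMatrix, path_prefix: str | Path) -> None:
    """Write a SNP-major PLINK 1 ``.bed/.bim/.fam`` triplet.

    ``read_plink(write_plink(g))`` is the identity (bit-exact ``.bed``: pad
    bits are written as zero, i.e. the code for homozygous allele1, and
    ignored on read).
    """
    prefix = Path(path_prefix)
    m, n = g.shape
    bytes_per_snp = (n + 3) // 4

    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    if m and n:
        lut = np.zeros(256, dtype=np.uint8)
        for geno, code in _GENO_TO_CODE.items():
            lut[np.int8(geno).view(np.uint8)] = code
        codes[:, :n] = lut[g.values.view(np.uint8)]
    packed = (
        codes.reshape(m, bytes_per_snp, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)

    with open(_sib(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())
    _write_bim(g.variants, _sib(prefix, ".bim"))
    _write_fam(g.samples, _sib(prefix, ".fam"))


def _read_bim(path: Path) -> list[VariantRecord]:
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
    )
    return [
        VariantRecord(r.chrom, r.vid, float(r.cm), int(r.pos), r.a1, r.a2)
        for r in df.itertuples()
    ]


def _read_fam(path: Path) -> list[SampleRecord]:
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    return [
        SampleRecord(r.fid, r.iid, int(r.sex), float(r.pheno))
        for r in df.itertuples()
    ]


def _write_bim(variants: Sequence[VariantRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            cm = int(v.genetic_distance) if v.genetic_distance == int(v.genetic_distance) else v.genetic_distance
            fh.write(
                f"{v.chromosome}\t{v.variant_id}\t{cm}\t{v.position}"
                f"\t{v.allele1}\t{v.allele2}\n"
            )


def _write_fam(samples: Sequence[SampleRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            pheno = int(s.phenotype) if s.phenotype == int(s.phenotype) else s.phenotype
            fh.write(f"{s.family_id}\t{s.individual_id}\t0\t0\t{s.sex}\t{pheno}\n")


# ---------------------------------------------------------------------------
# Harmonization and filters
# ---------------------------------------------------------------------------

def harmonize(
    reference: GenotypeMatrix, target: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix, dict]:
    """Restrict two panels to a shared, allele-consistent variant set.

    Excludes indels (any allele longer than one base), variants monomorphic in
    the reference genotypes, and variants whose allele sets cannot be
    reconciled; target variants recorded with swapped alleles relative to the
    reference have their genotype signs flipped.  No strand flipping is
    attempted: an (A,G)-vs-(T,C) mismatch is a conflict and is dropped.  The
    output variant order follows the reference and is identical in both
    panels.

    Returns ``(reference_sub, target_sub, report)`` where ``report`` lists the
    dropped/flipped variant ids by reason.
    """
    tgt_index = {v.variant_id: i for i, v in enumerate(target.variants)}
    obs = reference.observed_mask()

    report = {
        "dropped_indels": [],
        "dropped_monomorphic": [],
        "dropped_conflicts": [],
        "dropped_absent": [],
        "flipped": [],
    }
    ref_idx: list[int] = []
    tgt_idx: list[int] = []
    flip: list[bool] = []

    for i, v in enumerate(reference.variants):
        if v.variant_id not in tgt_index:
            report["dropped_absent"].append(v.variant_id)
            continue
        j = tgt_index[v.variant_id]
        t = target.variants[j]
        if max(len(v.allele1), len(v.allele2), len(t.allele1), len(t.allele2)) > 1:
            report["dropped_indels"].append(v.variant_id)
            continue
        row = reference.values[i]
        seen = row[obs[i]]
        if seen.size == 0 or (seen == seen[0]).all():
            report["dropped_monomorphic"].append(v.variant_id)
            continue
        if (t.allele1, t.allele2) == (v.allele1, v.allele2):
            flip.append(False)
        elif (t.allele1, t.allele2) == (v.allele2, v.allele1):
            flip.append(True)
            report["flipped"].append(v.variant_id)
        else:
            report["dropped_conflicts"].append(v.variant_id)
            continue
        ref_idx.append(i)
        tgt_idx.append(j)

    if not ref_idx:
        raise ValueError("no harmonizable variants shared between the panels")

    ref_out = reference.take_variants(ref_idx)
    tgt_values = target.values[np.asarray(tgt_idx)].copy()
    flip_arr = np.asarray(flip)
    if flip_arr.any():
        rows = tgt_values[flip_arr]
        observed = rows != MISSING
        rows[observed] = -rows[observed]
        tgt_values[flip_arr] = rows
    tgt_variants = [ref_out.variants[k] for k in range(len(ref_idx))]
    tgt_out = GenotypeMatrix(tgt_values, tgt_variants, list(target.samples))
    return ref_out, tgt_out, report


def allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant frequency of allele2 (the ``+1``-coded allele) among
    non-missing calls; 0 for all-missing variants."""
    obs = g.observed_mask()
    counts = obs.sum(axis=1)
    alt = ((g.values + 1) * obs).sum(axis=1)  # MISSING rows contribute 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts > 0, alt / (2.0 * np.maximum(counts, 1)), 0.0)
    return p


def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep variants with minor allele frequency ``>= threshold``.

    MAF is computed from non-missing genotypes; an all-missing variant has
    MAF 0 and is dropped for any positive threshold.
    """
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    p = allele_frequency(g)
    maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero(maf >= threshold)
    return g.take_variants(keep)


def filter_missingness(g: GenotypeMatrix, sample_threshold: float = 0.10) -> GenotypeMatrix:
    """Remove samples with a missing-genotype fraction above the threshold
    (default 10%)."""
    if not (0 < sample_threshold <= 1):
        raise ValueError("sample_threshold must lie in (0, 1]")
    miss_frac = (g.values == MISSING).mean(axis=0)
    keep = np.flatnonzero(miss_frac <= sample_threshold)
    if keep.size == 0:
        raise ValueError("every sample exceeds the missingness threshold")
    return g.take_samples(keep)


def _window_r2(values: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of raw dosages within a window,
    with missing calls excluded pairwise."""
    w = values.shape[0]
    obs = values != MISSING
    x = values.astype(np.float64)
    x[~obs] = 0.0
    r2 = np.zeros((w, w))
    for a in range(w):
        for b in range(a + 1, w):
            both = obs[a] & obs[b]
            n = int(both.sum())
            if n < 2:
                continue
            xa, xb = x[a, both], x[b, both]
            va = xa.var()
            vb = xb.var()
            if va == 0 or vb == 0:
                continue
            cov = ((xa - xa.mean()) * (xb - xb.mean())).mean()
            r2[a, b] = r2[b, a] = cov * cov / (va * vb)
    return r2


def ld_prune(
    g: GenotypeMatrix, window: int = 50, step: int = 5, r2_threshold: float = 0.2
) -> GenotypeMatrix:
    """Sliding-window LD pruning on raw genotype dosages, PLINK
    ``--indep-pairwise`` style, iterated to a fixed point.

    Within each window of ``window`` retained variants (advanced by ``step``),
    any pair with squared Pearson correlation above ``r2_threshold`` loses its
    later (higher-index) member.  The whole sweep repeats until no variant is
    removed.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not (1 <= step < window):
        raise ValueError("step must satisfy 1 <= step < window")
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")

    kept = list(range(g.n_variants))
    while True:
        removed_any = False
        start = 0
        while start < len(kept):
            idx = kept[start : start + window]
            if len(idx) < 2:
                break
            r2 = _window_r2(g.values[idx])
            alive = [True] * len(idx)
            for a in range(len(idx)):
                if not alive[a]:
                    continue
                for b in range(a + 1, len(idx)):
                    if alive[b] and r2[a, b] > r2_threshold:
                        alive[b] = False
            doomed = {idx[k] for k, ok in enumerate(alive) if not ok}
            if doomed:
                removed_any = True
                kept = [i for i in kept if i not in doomed]
            start += step
        if not removed_any:
            break
    return g.take_variants(kept)
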