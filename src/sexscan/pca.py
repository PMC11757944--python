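"""Genotype PCA and a quantitative sex-separation score.

Dosages are standardized per variant by the allele frequency — centered at
2p and scaled by sqrt(2p(1-p)) — and the leading components are taken from
the eigendecomposition of the sample-sample Gram matrix of the standardized
matrix (numerically identical to its singular decomposition, and the same
components a GRM eigendecomposition yields).  Missing genotypes are
mean-filled, i.e. contribute 0 after standardization.

Separation of the sexes is quantified as the maximum absolute point-biserial
correlation between sex and the first two components; a chromosome whose
SNPs alone reach a score >= 0.9 "clearly distinguishes" the sexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .genotypes import MISSING, GenotypeMatrix, SampleSheet, natural_key


@dataclass
class PcaResult:
    """Sample scores, per-component explained-variance fractions and the
    label of the variant subset the PCA ran on."""

    scores: np.ndarray                      # samples x k
    explained_variance_fraction: np.ndarray  # length k, decreasing
    variant_subset_label: str = "all"

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def standardize_dosages(gm: GenotypeMatrix,
                        subset: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """GCTA-style standardized dosage matrix and the kept-variant index.

    Zero-variance columns (allele frequency 0 or 1, or a constant column)
    are dropped; missing entries become 0 after centering.
    """
    if subset is None:
        sub_idx = np.arange(gm.n_variants)
    else:
        subset = np.asarray(subset)
        sub_idx = np.flatnonzero(subset) if subset.dtype == bool else subset
    d = gm.dosage[:, sub_idx].astype(float)
    miss = d == MISSING
    d[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    keep &= np.nanmax(np.where(np.isnan(d), -np.inf, d), axis=0) != \
        np.nanmin(np.where(np.isnan(d), np.inf, d), axis=0)
    d = d[:, keep]
    p = p[keep]
    x = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[np.isnan(x)] = 0.0
    return x, sub_idx[keep]


def _pca_from_standardized(x: np.ndarray, k: int,
                           label: str = "all") -> PcaResult:
    n = x.shape[0]
    gram = x @ x.T
    evals, evecs = eigh(gram)               # ascending
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    total = evals.sum()
    k = min(k, n, x.shape[1])
    s = np.sqrt(evals[:k])
    scores = evecs[:, :k] * s[None, :]
    # deterministic sign: the largest-magnitude variant loading is positive
    for j in range(k):
        if s[j] <= 0:
            continue
        loading = x.T @ evecs[:, j] / s[j]
        i = int(np.argmax(np.abs(loading)))
        if loading[i] < 0:
            scores[:, j] = -scores[:, j]
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(scores, frac, label)


def genotype_pca(gm: GenotypeMatrix, subset: np.ndarray | None = None,
                 k: int = 2, label: str = "all") -> PcaResult:
    """PCA of the standardized dosage matrix over an optional variant subset."""
    x, kept = standardize_dosages(gm, subset)
    if x.shape[1] < 1:
        raise ValueError("all variants in the subset are zero-variance")
    return _pca_from_standardized(x, k, label)


def separation_score(pca: PcaResult, sheet: SampleSheet) -> float:
    """Max |point-biserial correlation| between sex and the first two
    components; a constant component contributes 0."""
    y = sheet.female_mask.astype(float)
    if y.std() == 0:
        raise ValueError("separation score needs both sexes")
    best = 0.0
    for j in range(min(2, pca.k)):
        s = pca.scores[:, j]
        if s.std() == 0:
            continue
        r = np.corrcoef(s, y)[0, 1]
        best = max(best, abs(float(r)))
    return best


def per_chromosome_scan(gm: GenotypeMatrix, sheet: SampleSheet,
                        k: int = 2) -> pd.DataFrame:
    """Sex-separation score per chromosome and for the genome minus it.

    Columns: chrom, n_snps, score_chrom (PCA on that chromosome's SNPs
    alone), score_excluded (PCA on all other SNPs).  Chromosomes with < 2
    usable SNPs, or empty exclusion sets, yield NaN entries.
    """
    sheet.require_both_sexes()
    x, kept = standardize_dosages(gm)
    chroms_kept = gm.variants["chrom"].to_numpy()[kept]
    order = sorted(set(gm.variants["chrom"]), key=natural_key)
    rows = []
    for c in order:
        mask = chroms_kept == c
        n_c = int(mask.sum())
        score_c = np.nan
        if n_c >= 2:
            score_c = separation_score(
                _pca_from_standardized(x[:, mask], k, label=c), sheet)
        score_ex = np.nan
        if (~mask).sum() >= 2:
            score_ex = separation_score(
                _pca_from_standardized(x[:, ~mask], k, label=f"not_{c}"), sheet)
        rows.append((c, n_c, score_c, score_ex))
    return pd.DataFrame(rows, columns=["chrom", "n_snps", "score_chrom",
                                       "score_excluded"])
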