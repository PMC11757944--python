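"""Allelic chi-square association of genotype with binary sex.

The test is the classic 1-df Pearson chi-square on the 2x2 table of allele
counts (females/males x allele1/allele2), counting two alleles per
non-missing diploid genotype and applying no continuity correction.  Tiers
follow fixed genome-wide thresholds: significant below 1e-8, suggestive
below 1e-4 — no multiple-testing correction is applied on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix, SampleSheet

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NS = "ns"
TIER_NA = "na"  # test undefined (monomorphic or a sex with no data)


def allele_count_table(dosages_f, dosages_m) -> np.ndarray:
    """2x2 allele counts: rows (female, male), columns (allele1, allele2).

    Each non-missing diploid genotype contributes 2 alleles; dosage is the
    allele2 (alt) count.  Raises if a sex has no non-missing genotype.
    """
    table = np.empty((2, 2), dtype=np.int64)
    for row, dos in enumerate((dosages_f, dosages_m)):
        dos = np.asarray(dos)
        bad = ~np.isin(dos, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be in {0,1,2,MISSING}")
        obs = dos[dos != MISSING]
        if obs.size == 0:
            raise ValueError("a sex group has no non-missing genotypes")
        a2 = int(obs.sum())
        table[row] = (2 * obs.size - a2, a2)
    return table


def allelic_chisq(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Returns ``(nan, nan)`` when the test is undefined, i.e. an allele is
    absent in both sexes combined (monomorphic site).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p = _chisq_tables(table[None, :, :])
    return float(chi2[0]), float(p[0])


def _chisq_tables(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1-df Pearson chi-square over a stack of 2x2 tables."""
    tables = np.asarray(tables, dtype=float)
    rowsum = tables.sum(axis=2)                       # (n, 2)
    colsum = tables.sum(axis=1)                       # (n, 2)
    total = rowsum.sum(axis=1)                        # (n,)
    defined = (colsum > 0).all(axis=1) & (rowsum > 0).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = rowsum[:, :, None] * colsum[:, None, :] / total[:, None, None]
        chi2 = np.where(expected > 0,
                        (tables - expected) ** 2 / expected, 0.0).sum(axis=(1, 2))
    chi2 = np.where(defined, chi2, np.nan)
    p = np.where(defined, stats.chi2.sf(chi2, df=1), np.nan)
    # a zero statistic has p exactly 1
    p = np.where(defined & (chi2 == 0), 1.0, p)
    return chi2, p


def assign_tiers(p: np.ndarray, sig: float = 1e-8,
                 sugg: float = 1e-4) -> np.ndarray:
    tier = np.full(len(p), TIER_NS, dtype=object)
    tier[np.isnan(p)] = TIER_NA
    tier[p < sugg] = TIER_SUGGESTIVE
    tier[p < sig] = TIER_SIGNIFICANT
    return tier


def run_gwas(gm: GenotypeMatrix, sheet: SampleSheet,
             sig: float = 1e-8, sugg: float = 1e-4) -> pd.DataFrame:
    """Per-variant allelic chi-square of sex; returns the association table.

    Columns: chrom, pos, id, a1_f, a2_f, a1_m, a2_m, chi2, p, tier.
    Variants whose test is undefined carry tier ``"na"`` (never dropped).
    """
    sheet.require_both_sexes()
    fm, mm = sheet.female_mask, sheet.male_mask
    out = gm.variants[["chrom", "pos", "id"]].copy()
    if gm.n_variants == 0:
        for c in ("a1_f", "a2_f", "a1_m", "a2_m", "chi2", "p"):
            out[c] = pd.Series(dtype=float)
        out["tier"] = pd.Series(dtype=object)
        return out

    tables = np.empty((gm.n_variants, 2, 2), dtype=np.int64)
    for row, mask in enumerate((fm, mm)):
        d = gm.dosage[mask]
        obs = d != MISSING
        n = obs.sum(axis=0)
        a2 = np.where(obs, d, 0).sum(axis=0)
        tables[:, row, 0] = 2 * n - a2
        tables[:, row, 1] = a2
    chi2, p = _chisq_tables(tables)
    out["a1_f"], out["a2_f"] = tables[:, 0, 0], tables[:, 0, 1]
    out["a1_m"], out["a2_m"] = tables[:, 1, 0], tables[:, 1, 1]
    out["chi2"], out["p"] = chi2, p
    out["tier"] = assign_tiers(p, sig=sig, sugg=sugg)
    return out


def gwas_summary(assoc: pd.DataFrame) -> dict:
    """Counts of significant/suggestive variants and their chromosomes."""
    sig = assoc[assoc["tier"] == TIER_SIGNIFICANT]
    sugg = assoc[assoc["tier"].isin((TIER_SIGNIFICANT, TIER_SUGGESTIVE))]
    return {
        "n_variants": int(len(assoc)),
        "n_undefined": int((assoc["tier"] == TIER_NA).sum()),
        "n_significant": int(len(sig)),
        "n_suggestive_or_better": int(len(sugg)),
        "significant_by_chrom": sig.groupby("chrom").size().to_dict(),
    }


def qq_data(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p quantiles for a QQ plot.

    observed: sorted -log10(p), descending; expected at rank i (1-based):
    -log10((i - 0.5) / n).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    observed = -np.log10(np.sort(p))
    ranks = np.arange(1, p.size + 1)
    expected = -np.log10((ranks - 0.5) / p.size)
    return expected, observed
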