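"""Between-sex differentiation: per-site Weir-Cockerham FST and locus
density summaries.

At a sex-linked locus the two sexes behave like two partially diverged
populations, so the Weir & Cockerham (1984) per-site estimator — variance
components a (among populations), b (among individuals within populations)
and c (within individuals, from observed heterozygosity) — picks up the
signal; FST = a/(a+b+c).  Estimates above 0.25 are flagged as selection
signatures.  Negative estimates are kept as computed (vcftools behaviour),
and the estimate is NA exactly when a+b+c = 0 (monomorphic site).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SampleSheet, natural_key


def _group_stats(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (n, alt freq, het freq) over non-missing genotypes.

    ``dosage`` is (samples, variants); returns arrays of length n_variants.
    """
    obs = dosage != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, dosage, 0).sum(axis=0) / (2.0 * n)
        h = np.where(obs, dosage == 1, False).sum(axis=0) / n
    return n, p, h


def _wc_fst_components(nf, pf, hf, nm, pm, hm):
    """Weir-Cockerham (1984) two-population per-site variance components."""
    r = 2.0
    nbar = (nf + nm) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (nf ** 2 + nm ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (nf * pf + nm * pm) / (r * nbar)
        s2 = (nf * (pf - pbar) ** 2 + nm * (pm - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nf * hf + nm * hm) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(dosages_f, dosages_m) -> float:
    """Per-site Weir-Cockerham FST between two groups of diploid genotypes.

    Returns NaN when the denominator a+b+c is zero (monomorphic) or when a
    group is empty after removing missing genotypes.
    """
    df = np.asarray(dosages_f).reshape(-1, 1)
    dm = np.asarray(dosages_m).reshape(-1, 1)
    nf, pf, hf = _group_stats(df)
    nm, pm, hm = _group_stats(dm)
    if nf[0] == 0 or nm[0] == 0:
        return float("nan")
    a, b, c = _wc_fst_components(nf, pf, hf, nm, pm, hm)
    denom = a + b + c
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(a[0] / denom[0])


def fst_scan(gm: GenotypeMatrix, sheet: SampleSheet,
             threshold: float = 0.25) -> pd.DataFrame:
    """Per-variant FST between the sexes with signature flags.

    Columns: chrom, pos, id, fst, is_signature (fst > ``threshold``).
    """
    sheet.require_both_sexes()
    out = gm.variants[["chrom", "pos", "id"]].copy()
    if gm.n_variants == 0:
        out["fst"] = pd.Series(dtype=float)
        out["is_signature"] = pd.Series(dtype=bool)
        return out
    nf, pf, hf = _group_stats(gm.dosage[sheet.female_mask])
    nm, pm, hm = _group_stats(gm.dosage[sheet.male_mask])
    a, b, c = _wc_fst_components(nf, pf, hf, nm, pm, hm)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where((denom != 0) & (nf > 0) & (nm > 0), a / denom, np.nan)
    out["fst"] = fst
    out["is_signature"] = np.nan_to_num(fst, nan=-np.inf) > threshold
    return out


def signature_counts_by_chrom(fst_table: pd.DataFrame) -> dict[str, int]:
    sig = fst_table[fst_table["is_signature"]]
    return sig.groupby("chrom").size().to_dict()


def chromosome_enrichment(loci: pd.DataFrame | list,
                          lengths: dict[str, int]) -> pd.DataFrame:
    """Length-normalized share of loci per chromosome.

    ``density`` is loci per Mb, ``percentage`` the density share summing to
    100 across chromosomes (all chromosomes in ``lengths`` are reported,
    including ones with zero loci).
    """
    if isinstance(loci, pd.DataFrame):
        chroms = loci["chrom"]
    else:
        chroms = pd.Series([c for c, _ in loci], dtype=object)
    unknown = set(chroms) - set(lengths)
    if unknown:
        raise ValueError(f"loci on chromosomes without a length: {sorted(unknown)}")
    if any(l <= 0 for l in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    order = sorted(lengths, key=natural_key)
    counts = chroms.value_counts()
    out = pd.DataFrame({
        "chrom": order,
        "count": [int(counts.get(c, 0)) for c in order],
        "length_bp": [lengths[c] for c in order],
    })
    out["density_per_mb"] = out["count"] / (out["length_bp"] / 1e6)
    total = out["density_per_mb"].sum()
    out["percentage"] = (100.0 * out["density_per_mb"] / total if total > 0
                         else 0.0)
    return out


def window_density(loci: pd.DataFrame | list, lengths: dict[str, int],
                   window_bp: int = 1_000_000) -> pd.DataFrame:
    """Locus counts in non-overlapping tiling windows per chromosome.

    Windows are 0-based half-open [k*w, (k+1)*w); a locus at 0-based
    position ``pos0`` falls in window floor(pos0/w) — so a locus at exactly
    1,000,000 lands in the second 1-Mb window.  A DataFrame input may carry
    a ``pos0`` column or a 1-based ``pos`` column (converted); list input is
    (chrom, pos0) pairs.  Every window up to the chromosome length is
    reported, empty ones as 0.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if isinstance(loci, pd.DataFrame):
        if "pos0" in loci.columns:
            pairs = list(zip(loci["chrom"], loci["pos0"]))
        else:
            pairs = list(zip(loci["chrom"], loci["pos"] - 1))
    else:
        pairs = list(loci)
    for c, pos0 in pairs:
        if c not in lengths:
            raise ValueError(f"locus on unknown chromosome {c!r}")
        if not 0 <= pos0 < lengths[c]:
            raise ValueError(f"locus {c}:{pos0} outside chromosome length")
    rows = []
    for c in sorted(lengths, key=natural_key):
        n_windows = int(np.ceil(lengths[c] / window_bp))
        counts = np.zeros(n_windows, dtype=int)
        for cc, pos0 in pairs:
            if cc == c:
                counts[pos0 // window_bp] += 1
        for k in range(n_windows):
            rows.append((c, k * window_bp,
                         min((k + 1) * window_bp, lengths[c]), counts[k]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
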