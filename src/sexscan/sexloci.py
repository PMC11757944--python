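"""Heterozygote-count screen for sex-specific loci and ZW/XY inference.

At a fully sex-linked locus the heterogametic sex is heterozygous and the
homogametic sex homozygous.  Because ~10x data under-calls heterozygotes,
the screen demands at least ``c`` heterozygotes in the focal sex (default
25 of 40) while tolerating at most ``e`` heterozygotes in the other sex
(default 0).  Missing genotypes count as neither het nor hom: they cannot
satisfy ``c`` nor defeat ``e``.  The orientation of the surviving loci —
female-het (ZW) versus male-het (XY) — plus the sex of any sex-specific
sequences decides the heterogamety call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import TIER_SIGNIFICANT, TIER_SUGGESTIVE
from .genotypes import GenotypeMatrix, SampleSheet

ORIENT_F = "female_het"
ORIENT_M = "male_het"


@dataclass(frozen=True)
class ScreenParams:
    """Screen thresholds: ``min_het_focal`` (c) and ``max_het_other`` (e)."""

    min_het_focal: int = 25
    max_het_other: int = 0

    def __post_init__(self):
        if self.min_het_focal < 0 or self.max_het_other < 0:
            raise ValueError("screen thresholds must be non-negative")

    def validate_for(self, sheet: SampleSheet) -> None:
        if self.min_het_focal > max(sheet.n_female, sheet.n_male):
            raise ValueError(
                f"min_het_focal={self.min_het_focal} exceeds both sex sizes")


CALL_COLUMNS = ["id", "chrom", "pos", "orientation",
                "n_het_female", "n_het_male", "n_hom_other_sex"]


def screen_sex_specific(gm: GenotypeMatrix, sheet: SampleSheet,
                        params: ScreenParams = ScreenParams(),
                        variant_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Flag variants heterozygous in >= c focal-sex samples and in <= e
    samples of the other sex.

    ``variant_mask`` optionally restricts the screen (e.g. to GWAS hits).
    With c > e a variant matches at most one orientation.  Run this on
    unimputed genotypes: imputation can fabricate heterozygotes.
    """
    sheet.require_both_sexes()
    params.validate_for(sheet)
    het = gm.dosage == 1
    hom = (gm.dosage == 0) | (gm.dosage == 2)
    het_f = het[sheet.female_mask].sum(axis=0)
    het_m = het[sheet.male_mask].sum(axis=0)
    hom_f = hom[sheet.female_mask].sum(axis=0)
    hom_m = hom[sheet.male_mask].sum(axis=0)

    c, e = params.min_het_focal, params.max_het_other
    f_flag = (het_f >= c) & (het_m <= e)
    m_flag = (het_m >= c) & (het_f <= e)
    if variant_mask is not None:
        variant_mask = np.asarray(variant_mask, dtype=bool)
        f_flag &= variant_mask
        m_flag &= variant_mask

    rows = []
    for orient, flag, hom_other in ((ORIENT_F, f_flag, hom_m),
                                    (ORIENT_M, m_flag, hom_f)):
        for j in np.flatnonzero(flag):
            v = gm.variants.iloc[j]
            rows.append((v["id"], v["chrom"], int(v["pos"]), orient,
                         int(het_f[j]), int(het_m[j]), int(hom_other[j])))
    out = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def screen_input_selection(assoc: pd.DataFrame,
                           mode: str = "sex_associated_only") -> np.ndarray:
    """Boolean mask of variants the screen should see.

    ``sex_associated_only`` keeps variants below the suggestive threshold
    (GWAS-first order of operations); ``genome_wide`` keeps everything.
    """
    if mode == "genome_wide":
        return np.ones(len(assoc), dtype=bool)
    if mode == "sex_associated_only":
        return assoc["tier"].isin((TIER_SIGNIFICANT, TIER_SUGGESTIVE)).to_numpy()
    raise ValueError(f"unknown screen input mode {mode!r}")


@dataclass(frozen=True)
class SystemInference:
    """Heterogamety call from locus orientation + sequence-screen evidence."""

    system: str                      # "ZW" | "XY" | "inconclusive"
    n_female_het_loci: int
    n_male_het_loci: int
    fraction_majority: float
    sequence_evidence: str = "none"  # female_specific|male_specific|none|both

    def to_dict(self) -> dict:
        return {
            "system": self.system,
            "n_female_het_loci": self.n_female_het_loci,
            "n_male_het_loci": self.n_male_het_loci,
            "fraction_majority": self.fraction_majority,
            "sequence_evidence": self.sequence_evidence,
        }


def infer_system(calls: pd.DataFrame, majority_frac: float = 0.8,
                 seq_evidence: str = "none") -> SystemInference:
    """ZW iff >= ``majority_frac`` of flagged loci are female-het, or the
    sequence screen found only female-specific contigs; XY is the mirror;
    otherwise inconclusive."""
    if seq_evidence not in ("female_specific", "male_specific", "none", "both"):
        raise ValueError(f"unknown seq_evidence {seq_evidence!r}")
    n_f = int((calls["orientation"] == ORIENT_F).sum()) if len(calls) else 0
    n_m = int((calls["orientation"] == ORIENT_M).sum()) if len(calls) else 0
    total = n_f + n_m
    frac = max(n_f, n_m) / total if total else 0.0

    system = "inconclusive"
    if total and n_f / total >= majority_frac:
        system = "ZW"
    elif total and n_m / total >= majority_frac:
        system = "XY"
    elif seq_evidence == "female_specific":
        system = "ZW"
    elif seq_evidence == "male_specific":
        system = "XY"
    return SystemInference(system, n_f, n_m, frac, seq_evidence)
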