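"""Candidate sex-determination region calling.

Four evidence tracks are integrated per chromosome — enrichment of
significant and suggestive GWAS SNPs (length-normalized percentage shares),
enrichment of FST selection signatures, counts of heterozygote-screen loci
and the PCA sex-separation score.  Chromosomes are ranked by the mean of the
min-max-normalized tracks; the winner's significant SNPs are localized to
the shortest run of tiling windows holding at least ``min_contained`` of
them.  A cohort with no genome-wide-significant SNP, or no chromosome whose
own SNPs separate the sexes, yields an explicit no-call (no genetic sex
determination signal) rather than a forced candidate.

All intervals are 0-based half-open base-pair coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import TIER_SIGNIFICANT, TIER_SUGGESTIVE
from .genotypes import natural_key
from .popgen import chromosome_enrichment
from .sexloci import SystemInference

TRACKS = ["pct_sig_snps", "pct_sugg_snps", "pct_fst_signatures",
          "n_sex_specific_loci", "pca_separation_score"]


def build_evidence(assoc: pd.DataFrame, fst: pd.DataFrame,
                   sexloci: pd.DataFrame, pca_scan: pd.DataFrame,
                   lengths: dict[str, int]) -> pd.DataFrame:
    """Assemble the per-chromosome evidence table from the stage outputs."""
    order = sorted(lengths, key=natural_key)
    ev = pd.DataFrame({"chrom": order}).set_index("chrom")

    sig = assoc[assoc["tier"] == TIER_SIGNIFICANT]
    sugg = assoc[assoc["tier"].isin((TIER_SIGNIFICANT, TIER_SUGGESTIVE))]
    sigs = fst[fst["is_signature"]]
    for name, loci in (("pct_sig_snps", sig), ("pct_sugg_snps", sugg),
                       ("pct_fst_signatures", sigs)):
        enr = chromosome_enrichment(loci, lengths).set_index("chrom")
        ev[name] = enr["percentage"]
    counts = sexloci.groupby("chrom").size() if len(sexloci) else pd.Series(dtype=int)
    ev["n_sex_specific_loci"] = [int(counts.get(c, 0)) for c in order]
    scores = pca_scan.set_index("chrom")["score_chrom"]
    ev["pca_separation_score"] = [float(scores.get(c, np.nan)) for c in order]
    return ev.reset_index()


def _minmax(col: pd.Series) -> pd.Series:
    v = col.astype(float)
    lo, hi = v.min(), v.max()
    if not np.isfinite(lo) or not np.isfinite(hi):
        v = v.fillna(0.0)
        lo, hi = v.min(), v.max()
    if hi == lo:
        return pd.Series(0.5, index=col.index)  # constant track: equal share
    return (v - lo) / (hi - lo)


def rank_chromosomes(evidence: pd.DataFrame) -> pd.DataFrame:
    """Composite ranking: mean of min-max-normalized available tracks.

    Ties break by PCA score (descending) then natural chromosome order.
    Per-track ranks are reported alongside the composite.
    """
    if evidence.empty:
        raise ValueError("empty evidence table")
    ev = evidence.set_index("chrom")
    tracks = [t for t in TRACKS if t in ev.columns and ev[t].notna().any()]
    if not tracks:
        raise ValueError("no evidence tracks present")
    norm = pd.DataFrame({t: _minmax(ev[t]) for t in tracks})
    out = ev.copy()
    out["composite_score"] = norm.mean(axis=1)
    for t in tracks:
        out[f"rank_{t}"] = ev[t].rank(ascending=False, method="min")
    out = out.reset_index()
    out["_nat"] = out["chrom"].map(natural_key)
    pca = (out["pca_separation_score"].fillna(-1.0)
           if "pca_separation_score" in out.columns
           else pd.Series(0.0, index=out.index))
    out = (out.assign(_pca=pca)
           .sort_values(["composite_score", "_pca", "_nat"],
                        ascending=[False, False, True], kind="mergesort")
           .drop(columns=["_nat", "_pca"])
           .reset_index(drop=True))
    return out


def localize_region(sig_positions, chrom_length: int,
                    window_bp: int = 1_000_000,
                    min_contained: float = 0.9
                    ) -> tuple[int, int, float] | None:
    """Shortest run of tiling windows holding >= ``min_contained`` of the
    chromosome's significant SNPs.

    ``sig_positions`` are 0-based positions on one chromosome.  Among runs
    of equal (minimal) length the highest contained fraction wins, then the
    leftmost.  Returns (start, end, contained_fraction) with the end clipped
    to the chromosome length, or None when there are no positions.
    """
    pos = np.asarray(sorted(sig_positions), dtype=np.int64)
    if pos.size == 0:
        return None
    if (pos < 0).any() or (pos >= chrom_length).any():
        raise ValueError("significant position outside chromosome bounds")
    n_windows = int(np.ceil(chrom_length / window_bp))
    counts = np.bincount(pos // window_bp, minlength=n_windows)
    total = pos.size
    need = min_contained * total - 1e-12
    cum = np.concatenate([[0], np.cumsum(counts)])
    for run_len in range(1, n_windows + 1):
        run_counts = cum[run_len:] - cum[:-run_len]
        if run_counts.max() >= need:
            start_w = int(np.argmax(run_counts))  # leftmost among max
            contained = int(run_counts[start_w]) / total
            return (start_w * window_bp,
                    min((start_w + run_len) * window_bp, chrom_length),
                    contained)
    return (0, chrom_length, 1.0)


@dataclass
class RegionCall:
    """The integrated candidate-region call (or an explicit no-call)."""

    no_call: bool
    chromosome: str | None = None
    interval: tuple[int, int] | None = None
    contained_fraction: float | None = None
    system: SystemInference | None = None
    evidence: pd.DataFrame | None = None
    secondary_candidates: list[str] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "no_call": self.no_call,
            "chromosome": self.chromosome,
            "interval": list(self.interval) if self.interval else None,
            "contained_fraction": self.contained_fraction,
            "system": self.system.to_dict() if self.system else None,
            "secondary_candidates": self.secondary_candidates,
            "reasons": self.reasons,
        }


def call_sex_region(assoc: pd.DataFrame, evidence: pd.DataFrame,
                    system: SystemInference, lengths: dict[str, int],
                    window_bp: int = 1_000_000,
                    min_contained: float = 0.9,
                    pca_cutoff: float = 0.9,
                    secondary_frac: float = 0.7) -> RegionCall:
    """Rank chromosomes, localize the winner and attach the system call.

    No-call when there is no genome-wide-significant SNP or no chromosome
    reaches the PCA separation cutoff.  Chromosomes whose composite score is
    within ``secondary_frac`` of the top are reported as secondary
    candidates, never dropped.
    """
    reasons = []
    sig = assoc[assoc["tier"] == TIER_SIGNIFICANT]
    if sig.empty:
        reasons.append("no genome-wide-significant SNPs")
    pca = evidence["pca_separation_score"]
    if not (pca.dropna() >= pca_cutoff).any():
        reasons.append(f"no chromosome reaches PCA separation {pca_cutoff}")
    if reasons:
        return RegionCall(no_call=True, system=system, evidence=evidence,
                          reasons=reasons)

    ranked = rank_chromosomes(evidence)
    top = ranked.iloc[0]
    chrom = top["chrom"]
    secondary = list(
        ranked.loc[(ranked["composite_score"] >=
                    secondary_frac * top["composite_score"]) &
                   (ranked["chrom"] != chrom), "chrom"])
    pos0 = (sig.loc[sig["chrom"] == chrom, "pos"] - 1).to_numpy()
    loc = localize_region(pos0, lengths[chrom], window_bp=window_bp,
                          min_contained=min_contained)
    start, end, contained = loc
    return RegionCall(no_call=False, chromosome=chrom, interval=(start, end),
                      contained_fraction=contained, system=system,
                      evidence=ranked, secondary_candidates=secondary)
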