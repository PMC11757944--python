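"""Seeded synthetic cohorts with a planted sex-determination region.

The generator emulates the observable structure a re-sequencing sex study
consumes, not the sequences themselves: a diploid cohort of sexed
individuals genotyped at background SNPs in Hardy-Weinberg proportions plus
a recombination-suppressed region on one chromosome carrying fully and
partially sex-linked SNPs, degraded by depth-driven het->hom miscalls and
missing genotypes; and, for the sequence screen, contigs whose breadth of
coverage is high in one sex and (near) zero in the other.

Under a ZW system every fully linked SNP is truly heterozygous in females
and homozygous-reference in males; an XY system is the exact mirror.  A
miscalled heterozygote is always recorded hom-ref so that the homogametic
pattern is never spuriously broken.  Everything is driven by one integer
seed: identical config => byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (MISSING, GenotypeMatrix, SampleSheet, VARIANT_COLUMNS,
                        natural_key)
from .seqscreen import ContigSet, CoverageTable


def default_chrom_lengths(n_chrom: int = 22, length: int = 5_000_000
                          ) -> dict[str, int]:
    """Desk-scale stand-in genome: ``n_chrom`` chromosomes of equal length."""
    return {f"chr{i}": length for i in range(1, n_chrom + 1)}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 40 females + 40 males at mean
    depth ~10x, 22 chromosomes, one 1-Mb sex-determination interval on chr10
    with 100 fully and 100 partially sex-linked SNPs, background SNPs in
    Hardy-Weinberg proportions with MAF ~ U(0.05, 0.5).
    """

    n_female: int = 40
    n_male: int = 40
    chrom_lengths: dict[str, int] = field(default_factory=default_chrom_lengths)
    n_background_snps: int = 30_000
    sd_system: str = "ZW"          # {"ZW", "XY", "none"}
    sd_chrom: str = "chr10"
    sd_interval: tuple[int, int] = (2_000_000, 3_000_000)  # 0-based half-open
    n_sd_full: int = 100
    n_sd_partial: int = 100
    partial_linkage: tuple[float, float] = (0.6, 0.95)
    maf_background: tuple[float, float] = (0.05, 0.5)
    het_miscall_rate: float = 0.02
    missing_rate: float = 0.02
    mean_depth: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.sd_system not in ("ZW", "XY", "none"):
            raise ValueError("sd_system must be ZW, XY or none")
        if self.sd_system == "none":
            if self.n_sd_full or self.n_sd_partial:
                raise ValueError("no linked SNPs allowed when sd_system='none'")
        else:
            if self.sd_chrom not in self.chrom_lengths:
                raise ValueError(f"sd_chrom {self.sd_chrom!r} not in chrom_lengths")
            lo, hi = self.sd_interval
            if not (0 <= lo < hi <= self.chrom_lengths[self.sd_chrom]):
                raise ValueError("sd_interval outside sd_chrom")
        for p in (self.het_miscall_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")

    def mirrored(self) -> "SimConfig":
        """The same config with the heterogametic sex swapped (ZW <-> XY)."""
        other = {"ZW": "XY", "XY": "ZW"}.get(self.sd_system, "none")
        return dataclasses.replace(self, sd_system=other)


@dataclass
class TruthRecord:
    """Ground truth of a simulation, for recovery testing."""

    sd_system: str
    sd_chrom: str | None = None
    sd_interval: tuple[int, int] | None = None
    full_linked_ids: list[str] = field(default_factory=list)
    partial_linked_ids: list[str] = field(default_factory=list)
    sex_specific_contigs: list[str] = field(default_factory=list)
    decoy_contigs: list[str] = field(default_factory=list)
    false_positive_contigs: list[str] = field(default_factory=list)
    violator_contigs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("sd_interval") is not None:
            d["sd_interval"] = tuple(d["sd_interval"])
        return cls(**d)


def _sample_sheet(cfg: SimConfig) -> SampleSheet:
    ids = ([f"F{i:02d}" for i in range(1, cfg.n_female + 1)] +
           [f"M{i:02d}" for i in range(1, cfg.n_male + 1)])
    sex = tuple("F" * cfg.n_female + "M" * cfg.n_male)
    return SampleSheet(tuple(ids), sex)


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, SampleSheet, TruthRecord]:
    """Generate genotypes, a sample sheet and the ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    sheet = _sample_sheet(cfg)
    n_samples = len(sheet)
    chroms = list(cfg.chrom_lengths)
    lengths = np.asarray([cfg.chrom_lengths[c] for c in chroms], dtype=float)

    # background SNP positions, uniform over the genome
    per_chrom = rng.multinomial(cfg.n_background_snps, lengths / lengths.sum())
    rows: list[tuple] = []
    for c, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        pos0 = np.sort(rng.choice(cfg.chrom_lengths[c], size=n_c, replace=False))
        rows.extend((c, int(p) + 1, "background") for p in pos0)

    n_linked = cfg.n_sd_full + cfg.n_sd_partial
    if cfg.sd_system != "none" and n_linked:
        lo, hi = cfg.sd_interval
        if hi - lo < n_linked:
            raise ValueError("sd_interval too small for requested linked SNPs")
        pos0 = np.sort(rng.choice(hi - lo, size=n_linked, replace=False)) + lo
        kinds = np.array(["full"] * cfg.n_sd_full + ["partial"] * cfg.n_sd_partial)
        rng.shuffle(kinds)
        rows.extend((cfg.sd_chrom, int(p) + 1, k) for p, k in zip(pos0, kinds))

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "kind"])
    variants = variants.sort_values(
        ["chrom", "pos"],
        key=lambda s: (s.map(natural_key) if s.name == "chrom" else s),
        kind="mergesort").reset_index(drop=True)
    variants = variants.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    variants["id"] = [f"s{c}_{p}" for c, p in zip(variants["chrom"], variants["pos"])]
    m = len(variants)

    # true genotypes
    dosage = np.zeros((n_samples, m), dtype=np.int8)
    kind = variants["kind"].to_numpy()
    bg = kind == "background"
    p_bg = rng.uniform(*cfg.maf_background, size=int(bg.sum()))
    dosage[:, bg] = rng.binomial(2, p_bg[None, :], size=(n_samples, int(bg.sum())))

    het_sex = sheet.female_mask if cfg.sd_system == "ZW" else sheet.male_mask
    full = kind == "full"
    dosage[np.ix_(het_sex, full)] = 1
    dosage[np.ix_(~het_sex, full)] = 0
    partial = kind == "partial"
    if partial.any():
        q = rng.uniform(*cfg.partial_linkage, size=int(partial.sum()))
        het = rng.random((int(het_sex.sum()), int(partial.sum()))) < q[None, :]
        block = np.where(het, 1, 0).astype(np.int8)
        dosage[np.ix_(het_sex, partial)] = block
        dosage[np.ix_(~het_sex, partial)] = 0

    # depth-driven het->hom-ref miscalls, then missingness
    if cfg.het_miscall_rate > 0:
        flip = (dosage == 1) & (rng.random(dosage.shape) < cfg.het_miscall_rate)
        dosage[flip] = 0
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = MISSING

    depth = rng.poisson(cfg.mean_depth, size=dosage.shape).astype(np.int32)
    qual = np.full(dosage.shape, 99, dtype=np.int32)

    # ref/alt nucleotides (cosmetic but deterministic)
    nucs = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    vtab = pd.DataFrame({
        "chrom": variants["chrom"], "pos": variants["pos"],
        "id": variants["id"], "ref": nucs[ref_i], "alt": nucs[alt_i],
    })[VARIANT_COLUMNS]

    gm = GenotypeMatrix(list(sheet.sample_ids), vtab, dosage,
                        depth=depth, qual=qual)
    truth = TruthRecord(
        sd_system=cfg.sd_system,
        sd_chrom=cfg.sd_chrom if cfg.sd_system != "none" else None,
        sd_interval=cfg.sd_interval if cfg.sd_system != "none" else None,
        full_linked_ids=list(variants.loc[kind == "full", "id"]),
        partial_linked_ids=list(variants.loc[kind == "partial", "id"]),
    )
    return gm, sheet, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_contig_coverage(cfg: SimConfig,
                             n_w_contigs: int = 20,
                             n_shared_contigs: int = 200,
                             n_decoys: int = 20,
                             n_false_positives: int = 0,
                             n_high_n: int = 0,
                             n_low_complexity: int = 0,
                             n_short: int = 0,
                             n_cov_female: int = 5,
                             n_cov_male: int = 5,
                             contamination: float = 0.0,
                             with_sequences: bool = True,
                             ) -> tuple[ContigSet, CoverageTable, TruthRecord]:
    """Generate contigs + breadth tables for the sequence screen.

    Shared contigs are well covered (breadth ~ Beta(20,1)) in every sample;
    sex-specific contigs are well covered only in the heterogametic sex, with
    at most ``contamination`` breadth in the other; decoys miss coverage in
    exactly one heterogametic-sex sample (exercising the "all samples" rule);
    false positives pass round 1 but show high pooled opposite-sex breadth.
    ``n_high_n`` / ``n_low_complexity`` / ``n_short`` sex-specific contigs
    are emitted with N-rich, repeat or sub-kilobase sequences to exercise
    the marker-candidate filters.

    The per-sample cohort is ``n_cov_female`` + ``n_cov_male`` individuals
    (default 5 + 5); the pooled track holds the opposite sex.
    """
    for n in (n_w_contigs, n_shared_contigs, n_decoys, n_false_positives,
              n_high_n, n_low_complexity, n_short):
        if n < 0:
            raise ValueError("contig counts must be non-negative")
    if cfg.sd_system not in ("ZW", "XY"):
        raise ValueError("sequence screen simulation requires a ZW or XY system")
    if not 0.0 <= contamination <= 0.02:
        raise ValueError("contamination must be in [0, 0.02]")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    het_is_female = cfg.sd_system == "ZW"
    sex_tag = "W" if het_is_female else "Y"
    ids = ([f"{sex_tag}_{i:04d}" for i in range(n_w_contigs)] +
           [f"SH_{i:04d}" for i in range(n_shared_contigs)] +
           [f"DK_{i:04d}" for i in range(n_decoys)] +
           [f"FP_{i:04d}" for i in range(n_false_positives)])
    n_total = len(ids)
    spec_idx = np.arange(n_w_contigs)
    decoy_idx = np.arange(n_decoys) + n_w_contigs + n_shared_contigs
    fp_idx = np.arange(n_false_positives) + n_w_contigs + n_shared_contigs + n_decoys

    lengths = rng.integers(500, 3001, size=n_total)
    # plant marker-filter violators among the sex-specific contigs
    n_violators = n_high_n + n_low_complexity + n_short
    if n_violators > n_w_contigs:
        raise ValueError("more violators requested than sex-specific contigs")
    lengths[spec_idx] = rng.integers(1200, 3001, size=n_w_contigs)
    if n_short:
        short_rows = spec_idx[n_high_n + n_low_complexity:n_violators]
        lengths[short_rows] = rng.integers(500, 1000, size=n_short)
    violators: list[str] = []

    sequences: dict[str, str] = {}
    if with_sequences:
        for k, cid in enumerate(ids):
            sequences[cid] = _random_seq(rng, int(lengths[k]))
        for k in range(n_high_n):
            cid = ids[spec_idx[k]]
            seq = list(sequences[cid])
            n_sites = rng.choice(len(seq), size=int(0.3 * len(seq)), replace=False)
            for i in n_sites:
                seq[i] = "N"
            sequences[cid] = "".join(seq)
            violators.append(cid)
        for k in range(n_high_n, n_high_n + n_low_complexity):
            cid = ids[spec_idx[k]]
            sequences[cid] = "AT" * (len(sequences[cid]) // 2 + 1)
            sequences[cid] = sequences[cid][:lengths[spec_idx[k]]]
            violators.append(cid)
        for k in range(n_high_n + n_low_complexity, n_violators):
            violators.append(ids[spec_idx[k]])
        contigs = ContigSet.from_sequences(sequences)
        # keep declared order
        contigs.table = (contigs.table.set_index("id").loc[ids]
                         .reset_index())
    else:
        contigs = ContigSet(pd.DataFrame({
            "id": ids, "length": lengths,
            "n_fraction": 0.0, "entropy": 4.0}))

    n_het = n_cov_female if het_is_female else n_cov_male
    n_hom = n_cov_male if het_is_female else n_cov_female
    f_ids = [f"F{i:02d}" for i in range(1, n_cov_female + 1)]
    m_ids = [f"M{i:02d}" for i in range(1, n_cov_male + 1)]
    cov_sheet = SampleSheet(tuple(f_ids + m_ids),
                            tuple("F" * n_cov_female + "M" * n_cov_male))
    het_cols = f_ids if het_is_female else m_ids
    hom_cols = m_ids if het_is_female else f_ids

    # "covered" breadth: Beta(20,1)-shaped but guaranteed above the 0.9
    # presence threshold, so coverage of a planted contig is never ambiguous
    high = lambda size: 0.9 + 0.1 * rng.beta(20, 1, size=size)
    low = lambda size: (rng.uniform(0, contamination, size=size)
                        if contamination > 0 else np.zeros(size))

    breadth = pd.DataFrame(high((n_total, n_het + n_hom)),
                           index=ids, columns=het_cols + hom_cols)
    spec_like = np.concatenate([spec_idx, fp_idx]).astype(int)
    for j, col in enumerate(hom_cols):
        breadth.iloc[spec_like, breadth.columns.get_loc(col)] = low(len(spec_like))
        breadth.iloc[decoy_idx, breadth.columns.get_loc(col)] = low(len(decoy_idx))
    # decoys: one heterogametic-sex sample without coverage
    for k, row in enumerate(decoy_idx):
        miss_col = het_cols[k % n_het]
        breadth.loc[ids[row], miss_col] = 0.0

    pool_name = "male_pool" if het_is_female else "female_pool"
    pooled = pd.DataFrame(index=ids, columns=[pool_name], dtype=float)
    pooled[pool_name] = high(n_total)          # shared contigs: pool covers
    pooled.iloc[np.concatenate([spec_idx, decoy_idx]).astype(int), 0] = \
        low(n_w_contigs + n_decoys)
    if n_false_positives:
        pooled.iloc[fp_idx, 0] = rng.uniform(0.2, 0.9, size=n_false_positives)

    cov = CoverageTable(breadth, pooled, sheet=cov_sheet)
    truth = TruthRecord(
        sd_system=cfg.sd_system, sd_chrom=cfg.sd_chrom,
        sd_interval=cfg.sd_interval,
        sex_specific_contigs=[ids[i] for i in spec_idx],
        decoy_contigs=[ids[i] for i in decoy_idx],
        false_positive_contigs=[ids[i] for i in fp_idx],
        violator_contigs=violators,
    )
    return contigs, cov, truth
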