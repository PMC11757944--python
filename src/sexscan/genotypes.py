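"""Genotype containers, VCF I/O and SNP quality control.

The central object is :class:`GenotypeMatrix`, a samples x variants matrix of
alt-allele dosage codes (0 hom-ref, 1 het, 2 hom-alt, :data:`MISSING`), with
optional per-genotype depth (DP) and genotype-quality (GQ) layers.  Dosages
are the substrate of every downstream stage: the sex GWAS, the between-sex
FST scan, the heterozygote-count screen and the genotype PCA.

Coordinates are 1-based in VCF records (as the format requires) and 0-based
half-open everywhere inside the package; conversion happens only at the I/O
boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel dosage code for a missing genotype.  Never conflated with 0.
MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(label: str) -> tuple:
    """Sort key giving natural chromosome ordering ('chr2' < 'chr10')."""
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in _NAT_SPLIT.split(str(label)))


def natural_sorted(labels: Iterable[str]) -> list[str]:
    return sorted(labels, key=natural_key)


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSheet:
    """Phenotypic sexes (and cohort roles) of the sequenced individuals.

    Parameters
    ----------
    sample_ids
        Unique sample labels, in matrix order.
    sex
        One of ``"F"`` / ``"M"`` per sample.
    cohort_role
        Optional; ``"discovery"`` (default) or ``"validation"`` per sample.
    """

    sample_ids: tuple[str, ...]
    sex: tuple[str, ...]
    cohort_role: tuple[str, ...] = ()

    def __post_init__(self):
        ids = tuple(self.sample_ids)
        sx = tuple(self.sex)
        roles = tuple(self.cohort_role) or tuple("discovery" for _ in ids)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "sex", sx)
        object.__setattr__(self, "cohort_role", roles)
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        if len(sx) != len(ids) or len(roles) != len(ids):
            raise ValueError("sample_ids, sex and cohort_role lengths differ")
        bad = sorted(set(sx) - {"F", "M"})
        if bad:
            raise ValueError(f"sex must be 'F' or 'M', got {bad}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def female_mask(self) -> np.ndarray:
        return np.asarray([s == "F" for s in self.sex], dtype=bool)

    @property
    def male_mask(self) -> np.ndarray:
        return np.asarray([s == "M" for s in self.sex], dtype=bool)

    @property
    def n_female(self) -> int:
        return int(self.female_mask.sum())

    @property
    def n_male(self) -> int:
        return int(self.male_mask.sum())

    def require_both_sexes(self) -> None:
        if self.n_female == 0 or self.n_male == 0:
            raise ValueError("operation requires at least one sample of each sex")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        """Read a 2- or 3-column TSV: sample_id, sex in {F,M}[, cohort_role]."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         header=None)
        if df.iloc[0, 0] in ("sample_id", "sample"):
            df = df.iloc[1:].reset_index(drop=True)
        roles = tuple(df.iloc[:, 2]) if df.shape[1] >= 3 else ()
        return cls(tuple(df.iloc[:, 0]), tuple(df.iloc[:, 1]), roles)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "sex": self.sex,
                      "cohort_role": self.cohort_role}
                     ).to_csv(path, sep="\t", index=False)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV (chrom, length_bp) into an ordered dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if df.iloc[0, 0] in ("chrom", "chromosome"):
        df = df.iloc[1:].reset_index(drop=True)
    return {c: int(l) for c, l in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    pd.DataFrame({"chrom": list(lengths), "length_bp": list(lengths.values())}
                 ).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# variants and the genotype matrix


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic SNP (pos is 1-based, as printed in a VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosages plus optional DP/GQ layers.

    ``variants`` is a DataFrame with columns chrom, pos (1-based), id, ref,
    alt, one row per variant in matrix column order.  ``dosage`` holds codes
    in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        shape = (len(self.samples), len(self.variants))
        if self.dosage.shape != shape:
            raise ValueError(
                f"dosage shape {self.dosage.shape} != (samples, variants) {shape}")
        for name in ("depth", "qual"):
            layer = getattr(self, name)
            if layer is not None:
                layer = np.asarray(layer)
                if layer.shape != shape:
                    raise ValueError(f"{name} layer shape mismatch")
                setattr(self, name, layer)
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be in {0,1,2,MISSING}")
        missing = list(self.variants.columns) != VARIANT_COLUMNS
        if missing:
            raise ValueError(f"variants must have columns {VARIANT_COLUMNS}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given variant indices (bool mask or int index)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index],
            dosage=self.dosage[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            qual=None if self.qual is None else self.qual[:, index],
        )

    def allele_frequency(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing genotypes."""
        obs = self.dosage != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str | Path, sheet: SampleSheet,
             biallelic_only: bool = True) -> GenotypeMatrix:
    """Load GT (and DP/GQ when present) from a VCF into a GenotypeMatrix.

    Sample columns are reordered to follow ``sheet``; a sheet sample absent
    from the VCF header is a hard error.  Multi-allelic records are skipped
    (with a logged count) when ``biallelic_only``, otherwise raise.  A
    malformed or half-missing GT becomes MISSING.
    """
    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    absent = [s for s in sheet.sample_ids if s not in header_samples]
    if absent:
        raise ValueError(f"samples in sheet but not in VCF header: {absent}")
    order = np.asarray([header_samples.index(s) for s in sheet.sample_ids])

    has_dp = "DP" in [f["ID"] for f in _format_fields(vcf)]
    has_gq = "GQ" in [f["ID"] for f in _format_fields(vcf)]

    rows, dosages, depths, quals = [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if biallelic_only:
                n_multi += 1
                continue
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS} with biallelic_only=False")
        rows.append((v.CHROM, v.POS, v.ID or ".", v.REF, v.ALT[0]))
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(v.gt_types)[order].astype(np.int8)
        gt[gt == 3] = MISSING
        dosages.append(gt)
        if has_dp:
            dp = v.format("DP")
            dp = (np.full(len(order), -1, dtype=np.int32) if dp is None
                  else np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32)[order])
            depths.append(dp)
        if has_gq:
            gq = v.format("GQ")
            gq = (np.full(len(order), -1, dtype=np.int32) if gq is None
                  else np.where(gq[:, 0] < 0, -1, gq[:, 0]).astype(np.int32)[order])
            quals.append(gq)
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    n = len(variants)
    return GenotypeMatrix(
        samples=list(sheet.sample_ids),
        variants=variants,
        dosage=(np.vstack(dosages).T if n else
                np.empty((len(sheet), 0), dtype=np.int8)),
        depth=np.vstack(depths).T if (has_dp and n) else None,
        qual=np.vstack(quals).T if (has_gq and n) else None,
    )


def _format_fields(vcf: VCF) -> list[dict]:
    fields = []
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                fields.append(h)
        except KeyError:
            continue
    return fields


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a VCFv4.2 file that round-trips through :func:`read_vcf`."""
    path = Path(path)
    fmt_keys = ["GT"]
    header = ["##fileformat=VCFv4.2",
              "##source=sexscan",
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if gm.depth is not None:
        fmt_keys.append("DP")
        header.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">')
    if gm.qual is not None:
        fmt_keys.append("GQ")
        header.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">')
    if chrom_lengths:
        for c, l in chrom_lengths.items():
            header.append(f"##contig=<ID={c},length={l}>")
    else:
        for c in dict.fromkeys(gm.variants["chrom"]):
            header.append(f"##contig=<ID={c}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
            "FORMAT", *gm.samples]
    fmt = ":".join(fmt_keys)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("\t".join(cols) + "\n")
        for j, var in enumerate(gm.variants.itertuples(index=False)):
            fields = [var.chrom, str(var.pos), var.id or ".", var.ref,
                      var.alt, ".", "PASS", ".", fmt]
            for i in range(gm.n_samples):
                parts = [_GT_STR[int(gm.dosage[i, j])]]
                if gm.depth is not None:
                    d = int(gm.depth[i, j])
                    parts.append("." if d < 0 else str(d))
                if gm.qual is not None:
                    q = int(gm.qual[i, j])
                    parts.append("." if q < 0 else str(q))
                fields.append(":".join(parts))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# quality control


@dataclass(frozen=True)
class QCThresholds:
    """SNP filter thresholds (vcftools-style semantics).

    ``min_call_rate`` is the minimum fraction of non-missing genotypes
    (vcftools ``--max-missing 0.9`` keeps sites with >= 90% data).  Mean
    depth is the mean per-genotype DP over non-missing genotypes at a site.
    """

    min_maf: float = 0.05
    min_mean_depth: float = 6.0
    max_mean_depth: float = 300.0
    min_gq: float = 20.0
    min_call_rate: float = 0.9
    biallelic_only: bool = True

    def __post_init__(self):
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_mean_depth > self.max_mean_depth:
            raise ValueError("min_mean_depth > max_mean_depth")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")


def apply_qc_filters(gm: GenotypeMatrix, t: QCThresholds = QCThresholds()
                     ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the SNP QC cascade; returns filtered matrix + removal counts.

    Fixed order of operations:

    1. per-genotype GQ < ``min_gq`` -> set MISSING (count of masked genotypes
       reported as ``gq_masked_genotypes``);
    2. drop variants whose mean DP over non-missing genotypes falls outside
       [``min_mean_depth``, ``max_mean_depth``];
    3. drop variants with call rate < ``min_call_rate``;
    4. drop variants with MAF < ``min_maf`` (MAF over non-missing calls).

    Each removed variant is counted once, at the first filter that drops it.
    An empty result is a warning, not an error.
    """
    dosage = gm.dosage.copy()
    counts = {"gq_masked_genotypes": 0, "mean_depth": 0,
              "call_rate": 0, "maf": 0}

    if t.min_gq > 0:
        if gm.qual is None:
            raise ValueError("GQ filter active but matrix has no qual layer")
        mask = (gm.qual >= 0) & (gm.qual < t.min_gq) & (dosage != MISSING)
        counts["gq_masked_genotypes"] = int(mask.sum())
        dosage[mask] = MISSING

    work = GenotypeMatrix(gm.samples, gm.variants, dosage,
                          depth=gm.depth, qual=gm.qual)
    keep = np.ones(work.n_variants, dtype=bool)

    if np.isfinite(t.min_mean_depth) or np.isfinite(t.max_mean_depth):
        if work.depth is None:
            raise ValueError("depth filter active but matrix has no depth layer")
        obs = (work.dosage != MISSING) & (work.depth >= 0)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_dp = np.where(obs, work.depth, 0).sum(axis=0) / n
        ok = (mean_dp >= t.min_mean_depth) & (mean_dp <= t.max_mean_depth)
        ok &= n > 0
        counts["mean_depth"] = int((keep & ~ok).sum())
        keep &= ok

    cr_ok = work.call_rate() >= t.min_call_rate
    counts["call_rate"] = int((keep & ~cr_ok).sum())
    keep &= cr_ok

    maf = work.minor_allele_frequency()
    maf_ok = np.nan_to_num(maf, nan=-1.0) >= t.min_maf
    counts["maf"] = int((keep & ~maf_ok).sum())
    keep &= maf_ok

    if not keep.any():
        logger.warning("QC removed all %d variants", work.n_variants)
    return work.take_variants(keep), counts


def impute_missing(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace MISSING by the per-variant modal dosage (ties: lower code wins).

    A deterministic stand-in for statistical imputation; variants that are
    entirely missing are left missing with a warning.  No-op when nothing is
    missing.
    """
    if not gm.missing_mask.any():
        return gm
    dosage = gm.dosage.copy()
    all_missing = 0
    for j in np.flatnonzero(gm.missing_mask.any(axis=0)):
        col = dosage[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            all_missing += 1
            continue
        mode = int(np.argmax(np.bincount(obs, minlength=3)))
        col[col == MISSING] = mode
    if all_missing:
        logger.warning("%d variants entirely missing; left unimputed", all_missing)
    return replace(gm, dosage=dosage)
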