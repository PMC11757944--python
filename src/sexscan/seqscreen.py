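"""Coverage presence/absence screen for sex-specific sequences.

A contig assembled from the heterogametic sex carries candidate W (or Y)
material when every sample of that sex covers it with reads while no sample
of the other sex does.  "Covered" is made quantitative through breadth of
coverage: the fraction of contig positions with depth >= 1.  The screen has
two rounds — per-sample breadth over a small balanced cohort, then breadth
of a large pooled opposite-sex library — followed by marker-candidate
filters (length, N content, sequence complexity) that stand in for manual
curation before primer design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import SampleSheet


def n_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    return sequence.upper().count("N") / len(sequence)


def dinucleotide_entropy(sequence: str) -> float:
    """Shannon entropy (bits) of overlapping A/C/G/T dinucleotides.

    Homopolymers score 0; random sequence approaches 4 bits.  Pairs touching
    an ambiguous base are ignored.
    """
    s = sequence.upper()
    counts: dict[str, int] = {}
    for i in range(len(s) - 1):
        d = s[i:i + 2]
        if d[0] in "ACGT" and d[1] in "ACGT":
            counts[d] = counts.get(d, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


@dataclass
class ContigSet:
    """Assembled contigs under screening.

    ``table`` has columns id, length, n_fraction, entropy; ``sequences``
    maps contig id -> sequence when sequences are available.
    """

    table: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True)
        if (self.table["length"] < 1).any():
            raise ValueError("contig lengths must be >= 1")

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "ContigSet":
        rows = [(cid, len(seq), n_fraction(seq), dinucleotide_entropy(seq))
                for cid, seq in sequences.items()]
        return cls(pd.DataFrame(rows, columns=["id", "length", "n_fraction",
                                               "entropy"]),
                   dict(sequences))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ContigSet":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls.from_sequences(seqs)

    def to_fasta(self, path: str | Path, ids: list[str] | None = None) -> None:
        ids = self.ids if ids is None else ids
        records = [SeqRecord(Seq(self.sequences[c]), id=c, description="")
                   for c in ids]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class CoverageTable:
    """Per-sample (and pooled) breadth-of-coverage per contig.

    ``breadth``: DataFrame indexed by contig id, one column per sample, values
    in [0, 1].  ``pooled_breadth``: optional DataFrame indexed by contig id
    with pool columns (e.g. ``male_pool``) for the second screening round.
    ``sheet``: optional sample sheet describing the breadth columns.
    """

    breadth: pd.DataFrame
    pooled_breadth: pd.DataFrame | None = None
    sheet: SampleSheet | None = None

    def __post_init__(self):
        vals = self.breadth.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("breadth values must lie in [0, 1]")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 pooled_path: str | Path | None = None) -> "CoverageTable":
        """Read long-format TSV (contig, sample, breadth) [+ pooled TSV]."""
        long = pd.read_csv(path, sep="\t")
        breadth = long.pivot(index="contig", columns="sample", values="breadth")
        pooled = None
        if pooled_path is not None:
            plong = pd.read_csv(pooled_path, sep="\t")
            pooled = plong.pivot(index="contig", columns="pool", values="breadth")
        return cls(breadth, pooled)

    def to_tsv(self, path: str | Path,
               pooled_path: str | Path | None = None) -> None:
        long = (self.breadth.rename_axis("contig")
                .reset_index()
                .melt(id_vars="contig", var_name="sample", value_name="breadth"))
        long.to_csv(path, sep="\t", index=False)
        if pooled_path is not None and self.pooled_breadth is not None:
            plong = (self.pooled_breadth.rename_axis("contig")
                     .reset_index()
                     .melt(id_vars="contig", var_name="pool", value_name="breadth"))
            plong.to_csv(pooled_path, sep="\t", index=False)


def breadth_from_depth(depth_track: np.ndarray, min_depth: int = 1) -> float:
    """Breadth of coverage of one contig: fraction of positions with
    depth >= ``min_depth``."""
    depth_track = np.asarray(depth_track)
    if depth_track.size == 0:
        raise ValueError("empty depth track")
    if (depth_track < 0).any():
        raise ValueError("depths must be non-negative")
    return float((depth_track >= min_depth).mean())


def breadth_table_from_depth_tracks(tracks: pd.DataFrame,
                                    min_depth: int = 1) -> pd.DataFrame:
    """Aggregate a long depth track (contig, sample, pos0, depth) to breadth.

    Positions absent from the track are not imputed; the track must cover
    every contig position (0-based).
    """
    return (tracks.groupby(["contig", "sample"])["depth"]
            .apply(lambda d: float((np.asarray(d) >= min_depth).mean()))
            .unstack("sample"))


CALL_COLUMNS = ["contig", "specificity", "round_passed", "exclusion_reason"]


def round1_screen(cov: CoverageTable, sheet: SampleSheet,
                  present_min: float = 0.9,
                  absent_max: float = 0.05) -> pd.DataFrame:
    """First-round screen on the balanced per-sample cohort.

    A contig is ``female_specific`` iff breadth >= ``present_min`` in every
    female sample and <= ``absent_max`` in every male sample;
    ``male_specific`` is the mirror.  Both orientations are screened.
    """
    sheet.require_both_sexes()
    missing = [s for s in sheet.sample_ids if s not in cov.breadth.columns]
    if missing:
        raise ValueError(f"samples missing from coverage table: {missing}")
    b = cov.breadth[list(sheet.sample_ids)].to_numpy(dtype=float)
    fm, mm = sheet.female_mask, sheet.male_mask

    present_f = (b[:, fm] >= present_min).all(axis=1)
    absent_f = (b[:, fm] <= absent_max).all(axis=1)
    present_m = (b[:, mm] >= present_min).all(axis=1)
    absent_m = (b[:, mm] <= absent_max).all(axis=1)

    contigs = np.asarray(cov.breadth.index)
    rows = []
    for cid in contigs[present_f & absent_m]:
        rows.append((cid, "female_specific", 1, None))
    for cid in contigs[present_m & absent_f]:
        rows.append((cid, "male_specific", 1, None))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def round2_screen(candidates: pd.DataFrame, cov: CoverageTable,
                  absent_max: float = 0.05) -> pd.DataFrame:
    """Second-round screen against the pooled opposite-sex library.

    A round-1 candidate survives iff the pooled breadth of the opposite sex
    is <= ``absent_max``; removals keep a reason.  Output is always a subset
    of the input candidates.
    """
    if cov.pooled_breadth is None:
        raise ValueError("no pooled breadth track available for round 2")
    pool_col = {"female_specific": "male_pool", "male_specific": "female_pool"}
    rows = []
    for call in candidates.itertuples(index=False):
        col = pool_col[call.specificity]
        if col not in cov.pooled_breadth.columns:
            raise ValueError(f"pooled track '{col}' absent from coverage table")
        if call.contig not in cov.pooled_breadth.index:
            raise ValueError(f"candidate {call.contig} missing from pooled table")
        breadth = float(cov.pooled_breadth.loc[call.contig, col])
        if breadth <= absent_max:
            rows.append((call.contig, call.specificity, 2, None))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def filter_marker_candidates(calls: pd.DataFrame, contigs: ContigSet,
                             min_len: int = 1000,
                             max_n_fraction: float = 0.1,
                             min_entropy_bits: float = 1.5) -> pd.DataFrame:
    """Marker-candidate filter: keep calls on contigs longer than ``min_len``
    with N fraction <= ``max_n_fraction`` and dinucleotide entropy >=
    ``min_entropy_bits``.  Excluded calls are returned too, annotated with
    the first failing filter."""
    table = contigs.table.set_index("id")
    rows = []
    for call in calls.itertuples(index=False):
        info = table.loc[call.contig]
        if info["length"] <= min_len:
            reason = f"length {int(info['length'])} <= {min_len}"
        elif info["n_fraction"] > max_n_fraction:
            reason = f"n_fraction {info['n_fraction']:.3f} > {max_n_fraction}"
        elif info["entropy"] < min_entropy_bits:
            reason = f"entropy {info['entropy']:.3f} < {min_entropy_bits}"
        else:
            reason = None
        rows.append((call.contig, call.specificity, call.round_passed, reason))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def retained(calls: pd.DataFrame) -> pd.DataFrame:
    """Calls without an exclusion reason."""
    return calls[calls["exclusion_reason"].isna()].reset_index(drop=True)
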