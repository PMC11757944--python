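"""End-to-end orchestration: simulate/load -> QC -> GWAS -> FST -> screen ->
PCA -> region call -> sequence screen, with reproducible run directories.

`analyze_cohort` is the library entry point used by the CLI, the tests and
the acceptance script alike: it takes a genotype matrix + sample sheet and
returns every stage output plus the integrated region call.  `run_pipeline`
wraps it with file I/O, config echoing and a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, pca, popgen, regions, seqscreen, sexloci
from .genotypes import (GenotypeMatrix, QCThresholds, SampleSheet,
                        apply_qc_filters, impute_missing, read_chrom_lengths,
                        read_vcf, write_chrom_lengths, write_vcf)
from .simulate import SimConfig, TruthRecord, simulate_cohort, \
    simulate_contig_coverage

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    Either ``vcf``/``samples``/``lengths`` paths (analysis of existing data)
    or ``sim`` (a SimConfig for a synthetic run) must be provided.  Every
    threshold is echoed into the run report.
    """

    vcf: str | None = None
    samples: str | None = None
    lengths: str | None = None
    breadth: str | None = None
    pooled_breadth: str | None = None
    coverage_samples: str | None = None
    contigs_fasta: str | None = None
    sim: SimConfig | None = None
    simulate_coverage: bool = False

    qc: QCThresholds = field(default_factory=QCThresholds)
    impute: bool = False                      # modal imputation, off by default
    sig_p: float = 1e-8
    sugg_p: float = 1e-4
    fst_threshold: float = 0.25
    screen: sexloci.ScreenParams = field(default_factory=sexloci.ScreenParams)
    screen_mode: str = "sex_associated_only"
    window_bp: int = 1_000_000
    min_contained: float = 0.9
    pca_cutoff: float = 0.9
    majority_frac: float = 0.8
    present_min: float = 0.9
    absent_max: float = 0.05
    min_marker_len: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "sd_interval" in sim:
                sim["sd_interval"] = tuple(sim["sd_interval"])
            if "partial_linkage" in sim:
                sim["partial_linkage"] = tuple(sim["partial_linkage"])
            if "maf_background" in sim:
                sim["maf_background"] = tuple(sim["maf_background"])
            raw["sim"] = SimConfig(**sim)
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QCThresholds(**raw["qc"])
        if "screen" in raw and raw["screen"] is not None:
            raw["screen"] = sexloci.ScreenParams(**raw["screen"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d


def analyze_cohort(gm: GenotypeMatrix, sheet: SampleSheet,
                   lengths: dict[str, int],
                   cfg: PipelineConfig | None = None) -> dict:
    """Run every genotype-based stage on a QC'd cohort.

    Returns a dict with keys: assoc, fst, sexloci, pca_scan, evidence,
    system, region, window_density.  The heterozygote screen always runs on
    the (unimputed) input dosages.
    """
    cfg = cfg or PipelineConfig()
    assoc = association.run_gwas(gm, sheet, sig=cfg.sig_p, sugg=cfg.sugg_p)
    fst = popgen.fst_scan(gm, sheet, threshold=cfg.fst_threshold)
    mask = sexloci.screen_input_selection(assoc, mode=cfg.screen_mode)
    calls = sexloci.screen_sex_specific(gm, sheet, cfg.screen,
                                        variant_mask=mask)
    pca_scan = pca.per_chromosome_scan(gm, sheet)
    evidence = regions.build_evidence(assoc, fst, calls, pca_scan, lengths)
    system = sexloci.infer_system(calls, majority_frac=cfg.majority_frac)
    region = regions.call_sex_region(
        assoc, evidence, system, lengths, window_bp=cfg.window_bp,
        min_contained=cfg.min_contained, pca_cutoff=cfg.pca_cutoff)
    dens = popgen.window_density(
        calls[["chrom", "pos"]] if len(calls) else pd.DataFrame(
            columns=["chrom", "pos"], dtype=int),
        lengths, window_bp=cfg.window_bp)
    return {"assoc": assoc, "fst": fst, "sexloci": calls,
            "pca_scan": pca_scan, "evidence": evidence, "system": system,
            "region": region, "window_density": dens}


def run_seq_screen(contigs: seqscreen.ContigSet, cov: seqscreen.CoverageTable,
                   cov_sheet: SampleSheet, cfg: PipelineConfig) -> dict:
    round1 = seqscreen.round1_screen(cov, cov_sheet,
                                     present_min=cfg.present_min,
                                     absent_max=cfg.absent_max)
    round2 = (seqscreen.round2_screen(round1, cov, absent_max=cfg.absent_max)
              if cov.pooled_breadth is not None else round1)
    markers = seqscreen.filter_marker_candidates(
        round2, contigs, min_len=cfg.min_marker_len)
    specs = set(seqscreen.retained(markers)["specificity"]) | \
        set(round2["specificity"])
    seq_evidence = ("both" if len(specs) == 2 else
                    specs.pop() if specs else "none")
    return {"round1": round1, "round2": round2, "markers": markers,
            "seq_evidence": seq_evidence}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages, write artifacts + summary.json, return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    truth = None
    if cfg.sim is not None:
        gm, sheet, truth = simulate_cohort(cfg.sim)
        lengths = dict(cfg.sim.chrom_lengths)
        write_vcf(gm, outdir / "cohort.vcf", chrom_lengths=lengths)
        sheet.to_tsv(outdir / "samples.tsv")
        write_chrom_lengths(lengths, outdir / "chrom_lengths.tsv")
        truth.to_json(outdir / "truth.json")
    else:
        if not (cfg.vcf and cfg.samples and cfg.lengths):
            raise ValueError("need vcf+samples+lengths paths, or a sim config")
        sheet = SampleSheet.from_tsv(cfg.samples)
        gm = read_vcf(cfg.vcf, sheet, biallelic_only=cfg.qc.biallelic_only)
        lengths = read_chrom_lengths(cfg.lengths)

    n_input = gm.n_variants
    gm_qc, removals = apply_qc_filters(gm, cfg.qc)
    n_qc = gm_qc.n_variants
    gm_analysis = impute_missing(gm_qc) if cfg.impute else gm_qc

    res = analyze_cohort(gm_analysis, sheet, lengths, cfg)
    # the screen must see unimputed genotypes even when imputation is on
    if cfg.impute:
        mask = sexloci.screen_input_selection(res["assoc"], mode=cfg.screen_mode)
        res["sexloci"] = sexloci.screen_sex_specific(
            gm_qc, sheet, cfg.screen, variant_mask=mask)

    res["assoc"].to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    res["fst"].to_csv(outdir / "fst.tsv", sep="\t", index=False)
    res["sexloci"].to_csv(outdir / "sexloci.tsv", sep="\t", index=False)
    res["pca_scan"].to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
    res["evidence"].to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    res["window_density"].to_csv(outdir / "window_density.tsv", sep="\t",
                                 index=False)
    exp, obs = association.qq_data(res["assoc"]["p"].dropna())
    pd.DataFrame({"expected": exp, "observed": obs}).to_csv(
        outdir / "qq.tsv", sep="\t", index=False)

    seq_res = None
    if cfg.sim is not None and cfg.simulate_coverage and \
            cfg.sim.sd_system in ("ZW", "XY"):
        contigs, cov, cov_truth = simulate_contig_coverage(cfg.sim)
        cov.to_tsv(outdir / "breadth.tsv", outdir / "pooled_breadth.tsv")
        contigs.to_fasta(outdir / "contigs.fasta")
        seq_res = run_seq_screen(contigs, cov, cov.sheet, cfg)
    elif cfg.breadth is not None:
        cov = seqscreen.CoverageTable.from_tsv(cfg.breadth, cfg.pooled_breadth)
        cov_sheet = SampleSheet.from_tsv(cfg.coverage_samples)
        contigs = (seqscreen.ContigSet.from_fasta(cfg.contigs_fasta)
                   if cfg.contigs_fasta else
                   seqscreen.ContigSet(pd.DataFrame(
                       {"id": list(cov.breadth.index),
                        "length": cfg.min_marker_len + 1,
                        "n_fraction": 0.0, "entropy": 4.0})))
        seq_res = run_seq_screen(contigs, cov, cov_sheet, cfg)

    if seq_res is not None:
        seq_res["round2"].to_csv(outdir / "contig_calls.tsv", sep="\t",
                                 index=False)
        seq_res["markers"].to_csv(outdir / "marker_candidates.tsv", sep="\t",
                                  index=False)
        system = sexloci.infer_system(res["sexloci"],
                                      majority_frac=cfg.majority_frac,
                                      seq_evidence=seq_res["seq_evidence"])
        res["system"] = system
        res["region"].system = system

    with open(outdir / "region_call.json", "w") as fh:
        json.dump(res["region"].to_dict(), fh, indent=2, sort_keys=True)

    summary = {
        "seed": cfg.seed,
        "n_variants_input": int(n_input),
        "n_variants_after_qc": int(n_qc),
        "qc_removals": removals,
        "imputed": bool(cfg.impute),
        "gwas": association.gwas_summary(res["assoc"]),
        "n_fst_signatures": int(res["fst"]["is_signature"].sum()),
        "n_sex_specific_loci": {
            "female_het": int((res["sexloci"]["orientation"] ==
                               sexloci.ORIENT_F).sum()),
            "male_het": int((res["sexloci"]["orientation"] ==
                             sexloci.ORIENT_M).sum()),
        },
        "screen_mode": cfg.screen_mode,
        "system": res["system"].to_dict(),
        "region": res["region"].to_dict(),
    }
    if seq_res is not None:
        summary["sequence_screen"] = {
            "n_round1": int(len(seq_res["round1"])),
            "n_round2": int(len(seq_res["round2"])),
            "n_marker_candidates": int(len(seqscreen.retained(seq_res["markers"]))),
        }
    summary["region"]["evidence_table"] = "evidence.tsv"
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_clean(summary), fh, indent=2, sort_keys=True)
    if truth is not None:
        summary["truth"] = truth
    return summary


def _clean(obj):
    """Make a summary JSON-serializable (numpy scalars, NaN)."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, pd.DataFrame):
        return None
    return obj


_REPORT_SECTIONS = [
    ("Association (Manhattan/QQ data)", "gwas.tsv"),
    ("QQ quantiles", "qq.tsv"),
    ("Per-chromosome enrichment", "evidence.tsv"),
    ("PCA separation scores", "pca_scores.tsv"),
    ("Sex-specific locus window density", "window_density.tsv"),
    ("FST scan", "fst.tsv"),
    ("Sequence screen calls", "contig_calls.tsv"),
]


def make_report(run_dir: str | Path) -> Path:
    """Render a human-readable report.md from a completed run directory."""
    run_dir = Path(run_dir)
    lines = ["# sexscan run report", ""]
    summary_path = run_dir / "summary.json"
    if summary_path.exists():
        with open(summary_path) as fh:
            summary = json.load(fh)
        lines += ["```json", json.dumps(summary, indent=2, sort_keys=True),
                  "```", ""]
    else:
        lines += ["**summary.json missing — incomplete run**", ""]
    for title, fname in _REPORT_SECTIONS:
        path = run_dir / fname
        lines.append(f"## {title}")
        if not path.exists():
            lines += ["*section absent (stage not run)*", ""]
            continue
        df = pd.read_csv(path, sep="\t")
        head = df.head(25)
        lines += [head.to_string(index=False) if len(head) else "(empty)",
                  f"({len(df)} rows total; full table in {fname})", ""]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
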