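import numpy as np
import pandas as pd
import pytest

from sexscan.regions import (build_evidence, call_sex_region, localize_region,
                             rank_chromosomes)
from sexscan.sexloci import infer_system

MB = 1_000_000


def brute_force_localize(pos, length, w, frac):
    """Enumerate every contiguous window run; shortest, then most contained,
    then leftmost."""
    pos = sorted(pos)
    n_w = -(-length // w)
    best = None
    for run in range(1, n_w + 1):
        for s in range(n_w - run + 1):
            lo, hi = s * w, (s + run) * w
            inside = sum(lo <= p < hi for p in pos)
            if inside >= frac * len(pos) - 1e-12:
                cand = (run, -inside, s)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            break
    run, neg_in, s = best
    return s * w, min((s + run) * w, length), -neg_in / len(pos)


def concentrated_positions():
    """23 of 24 significant positions in [7,12) Mb, one stray at 20.5 Mb."""
    per_window = {7: 5, 8: 5, 9: 5, 10: 4, 11: 4}
    pos = []
    for wstart, n in per_window.items():
        pos.extend(wstart * MB + 100_000 * (k + 1) for k in range(n))
    pos.append(20 * MB + 500_000)
    return pos


def test_localization_of_concentrated_run():
    pos = concentrated_positions()
    start, end, contained = localize_region(pos, 22 * MB)
    assert (start, end) == (7 * MB, 12 * MB)
    assert contained == pytest.approx(23 / 24)
    assert round(contained * 100, 2) == 95.83
    assert brute_force_localize(pos, 22 * MB, MB, 0.9) == (start, end, contained)


def test_single_window_and_empty():
    start, end, contained = localize_region([100, 200, 900_000], 5 * MB)
    assert (start, end, contained) == (0, MB, 1.0)
    assert localize_region([], 5 * MB) is None


def test_uniform_positions_need_ceil_fraction_of_windows():
    pos = [k * MB + 500_000 for k in range(20)]
    start, end, contained = localize_region(pos, 20 * MB)
    assert (end - start) == 18 * MB          # ceil(0.9 * 20) windows
    assert (start, end) == (0, 18 * MB)      # leftmost among ties
    assert brute_force_localize(pos, 20 * MB, MB, 0.9) == (start, end, contained)


def test_localize_invariants():
    rng = np.random.default_rng(5)
    for _ in range(20):
        length = int(rng.integers(3, 25)) * MB
        pos = rng.integers(0, length, size=rng.integers(1, 40))
        prev_width = None
        for frac in (0.95, 0.9, 0.7, 0.5):
            start, end, contained = localize_region(pos, length,
                                                    min_contained=frac)
            assert contained >= frac - 1e-12     # containment guarantee
            width = end - start
            if prev_width is not None:
                assert width <= prev_width       # shrinking frac never widens
            prev_width = width


def test_out_of_bounds_position_rejected():
    with pytest.raises(ValueError):
        localize_region([5 * MB], 5 * MB)


def evidence_frame(**cols):
    chroms = ["chr1", "chr2", "chr3"]
    base = {"chrom": chroms,
            "pct_sig_snps": [10.0, 80.0, 10.0],
            "pct_sugg_snps": [10.0, 80.0, 10.0],
            "pct_fst_signatures": [10.0, 80.0, 10.0],
            "n_sex_specific_loci": [0, 30, 1],
            "pca_separation_score": [0.1, 0.95, 0.2]}
    base.update(cols)
    return pd.DataFrame(base)


def test_rank_puts_dominant_chromosome_first():
    ranked = rank_chromosomes(evidence_frame())
    assert ranked.iloc[0]["chrom"] == "chr2"
    assert ranked.iloc[0]["composite_score"] == pytest.approx(1.0)


def test_rank_constant_tracks_fall_to_tiebreak():
    ev = evidence_frame(pct_sig_snps=[5.0] * 3, pct_sugg_snps=[5.0] * 3,
                        pct_fst_signatures=[5.0] * 3,
                        n_sex_specific_loci=[2] * 3,
                        pca_separation_score=[0.3] * 3)
    ranked = rank_chromosomes(ev)
    # fully tied: natural chromosome order decides
    assert list(ranked["chrom"]) == ["chr1", "chr2", "chr3"]
    assert ranked["composite_score"].nunique() == 1


def test_rank_is_deterministic_composite_of_tracks():
    ev = evidence_frame(pca_separation_score=[0.95, 0.1, 0.2],
                        n_sex_specific_loci=[30, 0, 1])
    ranked = rank_chromosomes(ev).set_index("chrom")
    # direct evaluation of the min-max composite
    expect = np.zeros(3)
    for t in ["pct_sig_snps", "pct_sugg_snps", "pct_fst_signatures",
              "n_sex_specific_loci", "pca_separation_score"]:
        v = ev.set_index("chrom")[t].astype(float)
        expect += ((v - v.min()) / (v.max() - v.min())).to_numpy()
    expect /= 5
    for i, c in enumerate(ev["chrom"]):
        assert ranked.loc[c, "composite_score"] == pytest.approx(expect[i])
    with pytest.raises(ValueError):
        rank_chromosomes(pd.DataFrame())


def test_call_sex_region_recovers_planted_region(zw_small, zw_small_analysis):
    cfg, gm, sheet, truth = zw_small
    region = zw_small_analysis["region"]
    assert not region.no_call
    assert region.chromosome == truth.sd_chrom
    lo, hi = region.interval
    tlo, thi = truth.sd_interval
    jaccard = (min(hi, thi) - max(lo, tlo)) / (max(hi, thi) - min(lo, tlo))
    assert jaccard >= 0.5
    assert region.system.system == "ZW"
    assert region.contained_fraction >= 0.9


def test_contained_fraction_invariant_on_every_call(zw_small_analysis):
    region = zw_small_analysis["region"]
    assoc = zw_small_analysis["assoc"]
    sig = assoc[(assoc["tier"] == "significant") &
                (assoc["chrom"] == region.chromosome)]
    lo, hi = region.interval
    inside = ((sig["pos"] - 1 >= lo) & (sig["pos"] - 1 < hi)).mean()
    assert inside == pytest.approx(region.contained_fraction)


def test_null_cohort_yields_no_call(null_small):
    from sexscan.pipeline import analyze_cohort
    cfg, gm, sheet, _ = null_small
    res = analyze_cohort(gm, sheet, dict(cfg.chrom_lengths))
    region = res["region"]
    assert region.no_call
    assert region.reasons
    assert region.chromosome is None


def test_evidence_percentages_sum_to_100(zw_small_analysis):
    ev = zw_small_analysis["evidence"]
    for track in ("pct_sig_snps", "pct_sugg_snps", "pct_fst_signatures"):
        assert ev[track].sum() == pytest.approx(100.0, abs=1e-9)
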