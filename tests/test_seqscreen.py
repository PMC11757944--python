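import numpy as np
import pandas as pd
import pytest

from sexscan.genotypes import SampleSheet
from sexscan.seqscreen import (ContigSet, CoverageTable, breadth_from_depth,
                               dinucleotide_entropy, filter_marker_candidates,
                               n_fraction, retained, round1_screen,
                               round2_screen)
from sexscan.simulate import SimConfig, simulate_contig_coverage


def sheet_5v5():
    ids = tuple(f"F{i}" for i in range(5)) + tuple(f"M{i}" for i in range(5))
    return SampleSheet(ids, tuple("F" * 5 + "M" * 5))


def cov_table(rows, pooled_male=None):
    sheet = sheet_5v5()
    breadth = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))],
                           columns=list(sheet.sample_ids))
    pooled = None
    if pooled_male is not None:
        pooled = pd.DataFrame({"male_pool": pooled_male},
                              index=breadth.index)
    return CoverageTable(breadth, pooled, sheet=sheet)


def test_breadth_from_depth():
    assert breadth_from_depth([3, 3, 3]) == 1.0
    assert breadth_from_depth([0, 0, 2, 2]) == 0.5
    assert breadth_from_depth([1, 1, 1], min_depth=2) == 0.0
    with pytest.raises(ValueError):
        breadth_from_depth([])
    with pytest.raises(ValueError):
        breadth_from_depth([-1, 2])


def test_round1_requires_all_present_and_all_absent():
    rows = [
        [0.95] * 5 + [0.0] * 5,          # female-specific
        [0.95] * 4 + [0.5] + [0.0] * 5,  # one female below present_min
        [0.95] * 5 + [0.0] * 4 + [0.2],  # one male above absent_max
        [0.95] * 10,                     # shared
        [0.0] * 5 + [0.95] * 5,          # male-specific
    ]
    calls = round1_screen(cov_table(rows), sheet_5v5())
    by = calls.set_index("contig")["specificity"]
    assert by.to_dict() == {"c0": "female_specific", "c4": "male_specific"}


def test_round1_sample_mismatch_is_error():
    cov = cov_table([[0.9] * 10])
    other = SampleSheet(("X1", "X2"), ("F", "M"))
    with pytest.raises(ValueError, match="missing"):
        round1_screen(cov, other)


def test_round2_removes_pooled_covered_candidates():
    rows = [[0.95] * 5 + [0.0] * 5, [0.95] * 5 + [0.0] * 5]
    cov = cov_table(rows, pooled_male=[0.3, 0.0])
    r1 = round1_screen(cov, sheet_5v5())
    assert len(r1) == 2
    r2 = round2_screen(r1, cov)
    assert list(r2["contig"]) == ["c1"]
    assert set(map(tuple, r2[["contig", "specificity"]].values)) <= \
        set(map(tuple, r1[["contig", "specificity"]].values))


def test_round2_empty_candidates_and_missing_contig():
    cov = cov_table([[0.95] * 5 + [0.0] * 5], pooled_male=[0.0])
    assert len(round2_screen(round1_screen(cov, sheet_5v5()).iloc[:0], cov)) == 0
    bad = pd.DataFrame([{"contig": "zz", "specificity": "female_specific",
                         "round_passed": 1, "exclusion_reason": None}])
    with pytest.raises(ValueError, match="zz"):
        round2_screen(bad, cov)


def test_threshold_monotonicity_never_adds_calls():
    rng = np.random.default_rng(2)
    rows = rng.uniform(0, 1, size=(50, 10))
    cov = cov_table(rows.tolist())
    loose = round1_screen(cov, sheet_5v5(), present_min=0.8, absent_max=0.1)
    strict_p = round1_screen(cov, sheet_5v5(), present_min=0.9, absent_max=0.1)
    strict_a = round1_screen(cov, sheet_5v5(), present_min=0.8, absent_max=0.02)
    as_set = lambda df: set(map(tuple, df[["contig", "specificity"]].values))
    assert as_set(strict_p) <= as_set(loose)
    assert as_set(strict_a) <= as_set(loose)


def test_sequence_composition_metrics():
    assert n_fraction("ACGTNN") == pytest.approx(2 / 6)
    assert dinucleotide_entropy("A" * 100) == 0.0
    assert dinucleotide_entropy("ATATA") == pytest.approx(1.0)  # AT/TA equal
    rng = np.random.default_rng(0)
    rand = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    assert dinucleotide_entropy(rand) > 3.5


def test_marker_filters_annotate_each_exclusion():
    seqs = {
        "clean": "".join(np.array(list("ACGT"))[
            np.random.default_rng(1).integers(0, 4, 1500)]),
        "short": "ACGT" * 249 + "ACG",          # 999 bp
        "nrich": ("ACGT" * 500)[:1700] + "N" * 300,
        "polya": "A" * 2000,
    }
    contigs = ContigSet.from_sequences(seqs)
    calls = pd.DataFrame([
        {"contig": c, "specificity": "female_specific", "round_passed": 2,
         "exclusion_reason": None} for c in seqs])
    out = filter_marker_candidates(calls, contigs).set_index("contig")
    assert out.loc["clean", "exclusion_reason"] is None
    assert "length" in out.loc["short", "exclusion_reason"]
    assert "n_fraction" in out.loc["nrich", "exclusion_reason"]
    assert "entropy" in out.loc["polya", "exclusion_reason"]
    assert list(retained(out.reset_index())["contig"]) == ["clean"]


def test_exact_1000bp_is_excluded():
    contigs = ContigSet.from_sequences(
        {"edge": "".join(np.array(list("ACGT"))[
            np.random.default_rng(2).integers(0, 4, 1000)])})
    calls = pd.DataFrame([{"contig": "edge", "specificity": "female_specific",
                           "round_passed": 2, "exclusion_reason": None}])
    out = filter_marker_candidates(calls, contigs)
    assert out.iloc[0]["exclusion_reason"] is not None


def test_fasta_roundtrip(tmp_path):
    contigs = ContigSet.from_sequences({"a": "ACGTACGT", "b": "GGGCCCAT"})
    contigs.to_fasta(tmp_path / "c.fasta")
    back = ContigSet.from_fasta(tmp_path / "c.fasta")
    assert back.sequences == contigs.sequences


def test_simulated_screen_perfect_precision_recall():
    for seed in (1, 2):
        cfg = SimConfig(seed=seed)
        contigs, cov, truth = simulate_contig_coverage(
            cfg, n_w_contigs=20, n_shared_contigs=200, n_decoys=20)
        r1 = round1_screen(cov, cov.sheet)
        assert set(r1["contig"]) == set(truth.sex_specific_contigs)
        r2 = round2_screen(r1, cov)
        assert set(r2["contig"]) == set(truth.sex_specific_contigs)


def test_simulated_false_positives_removed_in_round2():
    cfg = SimConfig(seed=4)
    contigs, cov, truth = simulate_contig_coverage(
        cfg, n_w_contigs=10, n_shared_contigs=50, n_decoys=5,
        n_false_positives=8)
    r1 = round1_screen(cov, cov.sheet)
    assert set(truth.false_positive_contigs) <= set(r1["contig"])
    r2 = round2_screen(r1, cov)
    assert set(r2["contig"]) == set(truth.sex_specific_contigs)


def test_breadth_tsv_roundtrip(tmp_path):
    cfg = SimConfig(seed=6)
    _, cov, _ = simulate_contig_coverage(cfg, 5, 10, 2)
    cov.to_tsv(tmp_path / "b.tsv", tmp_path / "p.tsv")
    back = CoverageTable.from_tsv(tmp_path / "b.tsv", tmp_path / "p.tsv")
    assert np.allclose(back.breadth.sort_index(),
                       cov.breadth.sort_index())
    assert np.allclose(back.pooled_breadth.sort_index(),
                       cov.pooled_breadth.sort_index())
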