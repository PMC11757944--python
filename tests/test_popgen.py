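from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sexscan.genotypes import MISSING
from sexscan.popgen import (chromosome_enrichment, fst_scan,
                            weir_cockerham_fst, window_density)
from sexscan.simulate import SimConfig, simulate_cohort

from conftest import make_matrix, make_sheet


def wc_fst_oracle(dos_f, dos_m):
    """Exact-rational evaluation of the 1984 two-population variance
    components a, b, c; independent of the package implementation."""
    def stats(dos):
        obs = [int(d) for d in dos if d != MISSING]
        n = len(obs)
        if n == 0:
            return None
        p = Fraction(sum(obs), 2 * n)
        h = Fraction(sum(1 for d in obs if d == 1), n)
        return Fraction(n), p, h
    sf, sm = stats(dos_f), stats(dos_m)
    if sf is None or sm is None:
        return None
    (nf, pf, hf), (nm, pm, hm) = sf, sm
    r = Fraction(2)
    nbar = (nf + nm) / r
    nc = (r * nbar - (nf ** 2 + nm ** 2) / (r * nbar)) / (r - 1)
    pbar = (nf * pf + nm * pm) / (r * nbar)
    s2 = (nf * (pf - pbar) ** 2 + nm * (pm - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (nf * hf + nm * hm) / (r * nbar)
    if nbar == 1:
        return None
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


def test_fixed_difference_gives_one():
    assert weir_cockerham_fst([2] * 40, [0] * 40) == pytest.approx(1.0)


def test_zw_pattern_exceeds_signature_threshold():
    fst = weir_cockerham_fst([1] * 40, [0] * 40)
    assert fst == pytest.approx(wc_fst_oracle([1] * 40, [0] * 40), abs=1e-12)
    assert fst == pytest.approx(0.5, abs=1e-12)
    assert fst > 0.25


def test_identical_vectors_give_small_negative_estimate():
    v = [0, 0, 1, 1, 2, 0, 1, 0]
    fst = weir_cockerham_fst(v, v)
    assert fst == pytest.approx(wc_fst_oracle(v, v), abs=1e-12)
    assert fst <= 0


def test_monomorphic_and_empty_group_are_nan():
    assert np.isnan(weir_cockerham_fst([0, 0, 0], [0, 0]))
    assert np.isnan(weir_cockerham_fst([MISSING, MISSING], [0, 1]))


def test_estimator_matches_oracle_on_random_configurations():
    rng = np.random.default_rng(7)
    for _ in range(60):
        nf, nm = rng.integers(5, 51, size=2)
        dos_f = rng.choice([0, 1, 2, MISSING], size=nf, p=[.3, .3, .3, .1])
        dos_m = rng.choice([0, 1, 2, MISSING], size=nm, p=[.3, .3, .3, .1])
        expect = wc_fst_oracle(dos_f, dos_m)
        got = weir_cockerham_fst(dos_f, dos_m)
        if expect is None or np.isnan(expect):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expect, abs=1e-12)


def test_fst_scan_flags_linked_loci_and_vectorization_agrees():
    cfg = SimConfig(n_background_snps=400, n_sd_full=30, n_sd_partial=0,
                    het_miscall_rate=0.0, missing_rate=0.0, seed=9)
    gm, sheet, truth = simulate_cohort(cfg)
    table = fst_scan(gm, sheet)
    by_id = table.set_index("id")
    assert by_id.loc[truth.full_linked_ids, "is_signature"].all()
    # scalar and vectorized paths agree
    for j in np.random.default_rng(0).choice(gm.n_variants, 20, replace=False):
        expect = weir_cockerham_fst(gm.dosage[sheet.female_mask, j],
                                    gm.dosage[sheet.male_mask, j])
        got = table["fst"].iloc[j]
        assert (np.isnan(expect) and np.isnan(got)) or \
            got == pytest.approx(expect, abs=1e-12)


def test_null_scan_has_almost_no_signatures(null_small):
    cfg, gm, sheet, _ = null_small
    table = fst_scan(gm, sheet)
    assert table["is_signature"].mean() < 0.01


def test_permuting_sex_labels_destroys_signatures(zw_small):
    cfg, gm, sheet, _ = zw_small
    n_true = int(fst_scan(gm, sheet)["is_signature"].sum())
    rng = np.random.default_rng(17)
    counts = []
    sex = np.asarray(sheet.sex)
    for _ in range(20):
        perm = rng.permutation(len(sex))
        psheet = type(sheet)(sheet.sample_ids, tuple(sex[perm]))
        counts.append(int(fst_scan(gm, psheet)["is_signature"].sum()))
    assert np.mean(counts) < 0.05 * n_true


def test_empty_matrix_scan():
    gm = make_matrix(np.empty((4, 0), dtype=np.int8))
    assert len(fst_scan(gm, make_sheet(2, 2))) == 0


# ---------------------------------------------------------------------------
# enrichment and window density


def test_enrichment_forced_arithmetic():
    lengths = {"A": 10_000_000, "B": 10_000_000}
    out = chromosome_enrichment([("A", 1), ("A", 2), ("A", 3), ("B", 4)],
                                lengths).set_index("chrom")
    assert out.loc["A", "percentage"] == pytest.approx(75.0)
    assert out.loc["B", "percentage"] == pytest.approx(25.0)


def test_enrichment_length_normalization():
    lengths = {"A": 10_000_000, "B": 20_000_000}
    out = chromosome_enrichment([("A", 1), ("A", 2), ("B", 3), ("B", 4)],
                                lengths).set_index("chrom")
    assert out.loc["A", "percentage"] == pytest.approx(200 / 3)
    assert out.loc["B", "percentage"] == pytest.approx(100 / 3)
    assert out["percentage"].sum() == pytest.approx(100.0, abs=1e-9)


def test_enrichment_scale_invariance_and_errors():
    loci = [("A", 1), ("B", 2), ("B", 3)]
    base = chromosome_enrichment(loci, {"A": 5_000_000, "B": 7_000_000})
    scaled = chromosome_enrichment(loci, {"A": 15_000_000, "B": 21_000_000})
    assert np.allclose(base["percentage"], scaled["percentage"])
    with pytest.raises(ValueError):
        chromosome_enrichment(loci, {"A": 5_000_000, "B": 0})
    with pytest.raises(ValueError):
        chromosome_enrichment([("Z", 1)], {"A": 5_000_000})


def test_single_chromosome_concentration():
    out = chromosome_enrichment([("A", 5)], {"A": 1_000_000, "B": 1_000_000})
    assert out.set_index("chrom")["percentage"].tolist() == [100.0, 0.0]


def test_window_density_half_open_boundary():
    lengths = {"A": 3_000_000}
    out = window_density([("A", 500_000), ("A", 1_500_000)], lengths)
    assert out["count"].tolist() == [1, 1, 0]
    out = window_density([("A", 1_000_000)], lengths)
    assert out["count"].tolist() == [0, 1, 0]  # exactly 1 Mb -> second window


def test_window_density_empty_and_errors():
    out = window_density([], {"A": 2_500_000})
    assert out["count"].tolist() == [0, 0, 0]
    assert out["end"].tolist() == [1_000_000, 2_000_000, 2_500_000]
    with pytest.raises(ValueError):
        window_density([("A", 3_000_000)], {"A": 2_500_000})
    with pytest.raises(ValueError):
        window_density([("A", 1)], {"A": 2_500_000}, window_bp=0)
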