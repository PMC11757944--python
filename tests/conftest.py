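import numpy as np
import pandas as pd
import pytest

from sexscan.genotypes import (MISSING, GenotypeMatrix, SampleSheet,
                               VARIANT_COLUMNS)
from sexscan.pipeline import analyze_cohort
from sexscan.simulate import SimConfig, simulate_cohort


def make_matrix(dosage, chrom="chr1", depth=None, qual=None,
                sample_prefix="S"):
    """GenotypeMatrix from a (samples x variants) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    variants = pd.DataFrame({
        "chrom": [chrom] * m if isinstance(chrom, str) else chrom,
        "pos": np.arange(1, m + 1) * 100,
        "id": [f"v{j}" for j in range(m)],
        "ref": "A", "alt": "G",
    })[VARIANT_COLUMNS]
    return GenotypeMatrix([f"{sample_prefix}{i}" for i in range(n)],
                          variants, dosage, depth=depth, qual=qual)


def make_sheet(n_female, n_male):
    ids = ([f"S{i}" for i in range(n_female + n_male)])
    return SampleSheet(tuple(ids), tuple("F" * n_female + "M" * n_male))


@pytest.fixture(scope="session")
def zw_small():
    """A desk-scale ZW cohort with default noise: 3,000 background SNPs."""
    cfg = SimConfig(n_background_snps=3000, seed=11)
    gm, sheet, truth = simulate_cohort(cfg)
    return cfg, gm, sheet, truth


@pytest.fixture(scope="session")
def zw_small_analysis(zw_small):
    cfg, gm, sheet, truth = zw_small
    return analyze_cohort(gm, sheet, dict(cfg.chrom_lengths))


@pytest.fixture(scope="session")
def null_small():
    cfg = SimConfig(sd_system="none", n_sd_full=0, n_sd_partial=0,
                    n_background_snps=3000, seed=12)
    gm, sheet, truth = simulate_cohort(cfg)
    return cfg, gm, sheet, truth
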