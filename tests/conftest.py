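import numpy as np
import pandas as pd
import pytest

from caprigen.io import GenotypeMatrix, Pedigree, PedigreeEntry, VariantTable
from caprigen.simulate import SimConfig, simulate_study


def make_variants(n=5, chrom="1", start=100, step=100, qual=50.0):
    pos = np.arange(start, start + n * step, step)
    return VariantTable(pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "G", "qual": qual,
    }))


def make_gm(dosage, gq=None, dp=None, ids=None, variants=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    ids = ids or [f"s{i}" for i in range(dosage.shape[0])]
    variants = variants or make_variants(dosage.shape[1])
    return GenotypeMatrix(ids, variants, dosage, gq, dp)


@pytest.fixture(scope="session")
def small_study():
    """Scaled two-breed study used across integration tests."""
    cfg = SimConfig(
        n_founders_per_breed=30, n_generations=2, offspring_per_mating=3,
        n_variants=6000, n_chromosomes=2, array_size=600,
        seq_panel_size_per_breed=30, mosaic_switch_rate=0.05,
        ancestral_pool_size=16, seed=1,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def family_pedigree():
    """20-member pedigree: 8 founders, 6 matings x 2 offspring."""
    entries = {}
    for k in range(8):
        entries[f"F{k}"] = PedigreeEntry(None, None, "X", "M" if k % 2 == 0 else "F")
    k = 0
    for s, d in [("F0", "F1"), ("F2", "F3"), ("F4", "F5"),
                 ("F6", "F7"), ("F0", "F3"), ("F2", "F5")]:
        for _ in range(2):
            entries[f"C{k}"] = PedigreeEntry(s, d, "X", "M" if k % 2 else "F")
            k += 1
    return Pedigree(entries)
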