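import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from slafpop.digest import HAE_III, RSA_I
from slafpop.genotypes import GenotypeMatrix
from slafpop.simulate import (
    SimGenomeSpec,
    SimPopSpec,
    simulate_genome,
    simulate_population,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome genome with planted RsaI/HaeIII sites (~300 bp mean
    fragment), small enough for whole-suite reuse."""
    spec = SimGenomeSpec(
        chrom_plan=[("A01", "A", 300_000), ("C01", "C", 300_000)],
        site_rates={RSA_I: 1 / 600, HAE_III: 1 / 600},
        seed=7,
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def panel(small_genome):
    """Structured panel: 3 balanced groups, F_ST 0.25, 5% missing."""
    spec = SimPopSpec(
        n_accessions=40,
        n_markers_per_chrom=200,
        k_true=3,
        fst=0.25,
        ecotype_mix=(1 / 3, 1 / 3, 1 / 3),
        missing_rate=0.05,
        seed=13,
    )
    gm, truth = simulate_population(small_genome, spec)
    return gm, truth


def make_gm(dosages, positions=None, chrom="A01", ecotype=None):
    """Small helper to wrap a raw dosage array into a GenotypeMatrix."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=int), "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(d, markers, [f"s{i}" for i in range(n)], ecotype)


@pytest.fixture
def gm_factory():
    return make_gm
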