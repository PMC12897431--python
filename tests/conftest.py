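import numpy as np
import pytest

from breedkit.genodata import GenotypeMatrix, MarkerMap, SampleTable
from breedkit.simpop import SimConfig, simulate_panel


def make_matrix(dosage, positions=None, chromosomes=None, sample_ids=None, marker_ids=None):
    """Small hand-built GenotypeMatrix for fixtures."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    chromosomes = chromosomes if chromosomes is not None else ["1"] * m
    marker_ids = marker_ids if marker_ids is not None else [f"m{j}" for j in range(m)]
    sample_ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    markers = MarkerMap.from_arrays(
        marker_ids, chromosomes, positions, ["A"] * m, ["G"] * m
    )
    return GenotypeMatrix(
        samples=np.asarray(sample_ids, dtype=object), markers=markers, dosage=dosage
    )


@pytest.fixture(scope="session")
def five_breed_panel():
    """A 5-breed differentiated cohort: 600 markers on 3 chromosomes, 20/breed."""
    cfg = SimConfig(
        seed=41, n_breeds=5, fst=0.15, n_markers=600, n_chromosomes=3,
        chrom_length_bp=10_000_000, samples_per_breed=20, missing_rate=0.01,
    )
    g, s, truth, panel = simulate_panel(cfg)
    return g, s, truth, panel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
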