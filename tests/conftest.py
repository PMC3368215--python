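import numpy as np
import pytest

from ibdphase.io import GeneticMap, GenotypeMatrix
from ibdphase.model_core import ModelParams
from ibdphase.simulator import DemographyConfig, default_map, simulate_cohort


def uniform_map(m: int, length: float = 0.1, chrom: str = "1") -> GeneticMap:
    return GeneticMap(chrom, np.arange(1, m + 1) * 1000, np.linspace(0.0, length, m))


def matrix_from_dosages(dosages, freqs=None, gmap=None):
    """GenotypeMatrix with explicit frequencies (no flipping/dropping)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if freqs is None:
        obs = dosages != -1
        freqs = np.where(obs, dosages, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    return GenotypeMatrix(
        np.array([f"i{k}" for k in range(n)], dtype=object),
        np.array([f"m{j}" for j in range(m)], dtype=object),
        dosages,
        np.asarray(freqs, dtype=float),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact founder population with appreciable IBD sharing."""
    demo = DemographyConfig(
        n_founders=30, final_size=1000, generations=8, sample_size=30
    )
    gmap = default_map(m=500, length_morgans=0.2, seed=7)
    return simulate_cohort(demo, gmap, seed=7)


@pytest.fixture()
def default_params():
    return ModelParams()
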