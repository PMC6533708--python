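import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")

from brevipan.config import RunConfig
from brevipan.pipeline import cluster_proteomes
from brevipan.simulate import SimSpec, simulate_pangenome


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(
        n_genomes=4, n_spoilers=2, n_core_families=30, n_shell_families=8,
        n_unique_per_genome=2, n_niche_families=2, niche_min_pos=2,
        substitution_rate=0.02, plasmid_frac=0.3, seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_spec):
    """A small simulated pan-genome: (records, metas, truth)."""
    return simulate_pangenome(small_spec)


@pytest.fixture(scope="session")
def small_clustering(small_sim):
    """Full similarity -> MCL pipeline on the small pan-genome."""
    records, metas, _ = small_sim
    return cluster_proteomes(records, [m.genome_id for m in metas],
                             RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
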