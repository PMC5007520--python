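import numpy as np
import pytest

from genefam import simulate
from genefam.config import PipelineConfig
from genefam.io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
UNIFORM = np.full(20, 1 / 20)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_genome():
    """One small synthetic genome shared by read-only tests."""
    params = simulate.GenomeSimParams(seed=11)
    return params, simulate.generate_family_genome(params)


@pytest.fixture(scope="session")
def family_proteins(small_genome):
    _params, genome = small_genome
    fam = set(genome.truth.family_gene_ids)
    return [ProteinRecord(protein_id=g, sequence=s)
            for g, s in genome.proteins if g in fam]


def random_protein(length, rng):
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
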