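import numpy as np
import pytest

from endosym import synth
from endosym.io import GenomeRecord


def random_sequence(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def strain_set():
    """A mid-sized strain set with prophages, Cif pairs, and a biotin operon."""
    return synth.generate_strain_set(
        4,
        genome_length=120_000,
        n_prophages_range=(1, 2),
        cif_pair_rate=2.0,
        biotin_prob=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def annotations_by_genome(strain_set):
    _genomes, annotations, _truth = strain_set
    out = {}
    for a in annotations:
        out.setdefault(a.genome_id, []).append(a)
    for genes in out.values():
        genes.sort(key=lambda g: g.start)
    return out


@pytest.fixture(scope="session")
def random_genome():
    rng = np.random.default_rng(1234)
    return GenomeRecord("rand1", random_sequence(rng, 100_000), circular=True)
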