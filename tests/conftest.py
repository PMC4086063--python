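import pytest

from magedesign.fixtures import fixture_genome, make_fixture_genome
from magedesign.folding import ToyFoldingEvaluator


@pytest.fixture(scope="session")
def genome():
    """50-kb synthetic circular genome with 20 CDSs (in memory)."""
    return fixture_genome(50_000, 20, seed=1)


@pytest.fixture(scope="session")
def genome_files(tmp_path_factory):
    """Same fixture genome written as GenBank + replication config files."""
    out = tmp_path_factory.mktemp("fixture-genome")
    return make_fixture_genome(50_000, 20, seed=1, out_dir=out)


@pytest.fixture(scope="session")
def toy():
    """Toy Nussinov folding evaluator, pre-warmed so numba compiles once."""
    ev = ToyFoldingEvaluator()
    ev.evaluate("ACGTACGTACGT")
    return ev


def random_point_mutation(genome, rng):
    """A random single-base substitution Mutation on ``genome``."""
    from magedesign.mutation import Mutation

    pos = int(rng.integers(genome.length))
    ref = genome.sequence[pos]
    alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
    return Mutation(pos, ref, alt, label=f"{ref}{pos + 1}{alt}")
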