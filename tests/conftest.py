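import pytest

from m16s.fixtures import FixtureSpec, generate_references
from m16s.simulate import ZERO_MUTATION, simulate_shotgun
from m16s.taxonomy import TaxonomyLineage
from m16s.sequence_io import ReferenceSequence


@pytest.fixture(scope="session")
def small_pool():
    """Six genera x five species, default 16S-like geometry."""
    spec = FixtureSpec(n_genera=6, species_per_genus=5, seed=11)
    return generate_references(spec)


@pytest.fixture(scope="session")
def default_pool():
    """The default 10 x 10 fixture pool."""
    return generate_references(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def clean_reads(small_pool):
    """Mutation-free shotgun reads from the small pool (~600 reads)."""
    return simulate_shotgun(small_pool, coverage=3.3, model=ZERO_MUTATION, seed=5)


def random_lineage(rng) -> TaxonomyLineage:
    labels = [f"{r}{rng.integers(100)}" for r in ("P", "C", "O", "F", "G")]
    return TaxonomyLineage(*labels)


def random_reference(rng, rec_id: str, length: int = 60) -> ReferenceSequence:
    seq = "".join("ACGT"[i] for i in rng.integers(4, size=length))
    return ReferenceSequence(rec_id, random_lineage(rng), seq)
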