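import random

import pytest
from hypothesis import settings, HealthCheck

from forktrap.genome_io import CircularGenome
from forktrap.queries import reference_ter_queries

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def random_sequence(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def queries():
    return reference_ter_queries()


@pytest.fixture(scope="session")
def query_map(queries):
    return {q.name: q for q in queries}


@pytest.fixture()
def small_genome():
    rng = random.Random(42)
    return CircularGenome(name="small", sequence=random_sequence(rng, 2000), oric_position=100)


@pytest.fixture(scope="session")
def mg_like():
    from forktrap.synthetic_data import build_template

    return build_template("mg1655_like", length=150_000, seed=2)
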