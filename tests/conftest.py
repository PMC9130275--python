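import random

import pytest
from hypothesis import HealthCheck, settings

import dnaquine as dq
from dnaquine import fixtures as fx

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cloning_demo():
    return fx.run_cloning_demo(1)


@pytest.fixture(scope="session")
def lineage():
    return fx.make_lineage(1)


@pytest.fixture(scope="session")
def lut():
    return fx.make_blade_lut(1)


def random_sequence(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_molecule(rng: random.Random, n: int = 120, topology: str = dq.LINEAR,
                    n_features: int = 2) -> dq.DsDna:
    """A random molecule with a few plus/minus strand features."""
    seq = random_sequence(rng, n)
    feats = []
    for i in range(n_features):
        s = rng.randrange(0, n - 10)
        e = s + rng.randrange(6, min(30, n - s))
        strand = rng.choice("+-")
        feats.append(
            dq.Feature("CDS" if i % 2 == 0 else "misc_feature",
                       dq.Location.single(s, e, strand),
                       (("label", f"feat{i}"),))
        )
    return dq.from_sequence(seq, topology, name=f"rnd{rng.randrange(10**6)}",
                            features=feats)
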