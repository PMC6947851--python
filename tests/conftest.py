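import numpy as np
import pytest

from groupsep import (
    LocusAlignment,
    StrainMetadata,
    groups_from_metadata,
    scenario_config,
    simulate,
)


@pytest.fixture
def micro_alignment():
    """Tiny hand-checkable alignment with a gap and an ambiguity code."""
    return LocusAlignment(
        "toy", "hkg",
        {"s1": "ACGTACGT", "s2": "ACGAAC-T", "s3": "ACGTNCGT"},
    )


@pytest.fixture
def two_group_meta():
    return [
        StrainMetadata("a1", "A", "p1", 43.0, 44.7),
        StrainMetadata("a2", "A", "p1", 43.1, 44.8),
        StrainMetadata("b1", "B", "p2", 40.2, 44.5),
        StrainMetadata("b2", "B", "p2", 40.3, 44.6),
    ]


@pytest.fixture(scope="session")
def separated_data():
    cfg = scenario_config("separated", seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def paperlike_data():
    cfg = scenario_config("paperlike", seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def separated_groups(separated_data):
    _, meta, _ = separated_data
    return groups_from_metadata(meta)


def random_alignment(rng, n=6, length=30, alphabet="ACGT"):
    """Gap-free random alignment for oracle comparisons."""
    letters = np.array(list(alphabet))
    return LocusAlignment(
        "rand", "custom",
        {
            f"s{i}": "".join(rng.choice(letters, size=length))
            for i in range(n)
        },
    )
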