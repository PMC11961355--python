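import warnings

import pytest

from ghcluster.read_typing import TypingIndex, design_discriminating_probes
from ghcluster.simulate import (
    HaplotypeStructure,
    cluster_structures,
    make_paralog_families,
)

FAMILY_SEED = 1


@pytest.fixture(scope="session")
def families():
    return make_paralog_families(seed=FAMILY_SEED)


@pytest.fixture(scope="session")
def index(families):
    return TypingIndex.from_families(families)


@pytest.fixture(scope="session")
def structures():
    return cluster_structures()


@pytest.fixture(scope="session")
def probe_set(families):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return design_discriminating_probes(families.cds_by_type())


@pytest.fixture(scope="session")
def small_structure():
    """A 4-gene cluster used where full ~150 kb loci would be wastefully slow."""
    return HaplotypeStructure(
        name="S",
        genes=(("GH", None), ("CSH1", None), ("GH2", "a"), ("CSH4", "a")),
    )


@pytest.fixture(scope="session")
def anchor_structure():
    """A compact cluster containing every anchor family plus a 2-copy GH2."""
    return HaplotypeStructure(
        name="A",
        genes=(
            ("GH", None),
            ("CSH1", None),
            ("GH2", "a"),
            ("GH2", "b"),
            ("CSH3", None),
        ),
    )
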