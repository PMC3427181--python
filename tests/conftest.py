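import numpy as np
import pytest

from modevoprof import PhyloTree, ProteinAlignment, SimConfig, simulate_family


@pytest.fixture(scope="session")
def default_truth():
    """One simulated duplicated family under the default study conditions."""
    return simulate_family(SimConfig(seed=1))


@pytest.fixture()
def quartet_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture()
def small_alignment():
    return ProteinAlignment(
        ("A", "B", "C", "D"),
        ("ARND", "ARNA", "CRND", "CRNA"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
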