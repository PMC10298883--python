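import numpy as np
import pytest

from orfsub import interactome as it
from orfsub import synthetic_data as synth


@pytest.fixture(scope="session")
def study_network():
    """Synthetic network at the study's scale: 219-member roster, 177
    connected, planted censuses and the reference size distribution."""
    net, ledger = synth.gen_ppi_network(seed=101)
    return net, ledger


@pytest.fixture(scope="session")
def study_subinteractomes(study_network):
    net, _ = study_network
    census = it.partner_census(net)
    connected = sorted(net.orf_roster - census.orphan_orfs)
    return [it.subinteractome(net, orf) for orf in connected]


@pytest.fixture()
def toy_network():
    """Small hand-checkable network: roster {O1,O2,O3}, one ORF-ORF edge,
    one partner shared by two ORFs, one by three, plus private partners."""
    records = [
        it.InteractionRecord("O1", "O2", source="s1"),
        it.InteractionRecord("O1", "SHARED2", source="s1"),
        it.InteractionRecord("O2", "SHARED2", source="s2"),
        it.InteractionRecord("O1", "SHARED3", source="s1"),
        it.InteractionRecord("O2", "SHARED3", source="s1"),
        it.InteractionRecord("O3", "SHARED3", source="s1"),
        it.InteractionRecord("O1", "PRIV1", source="s2"),
        it.InteractionRecord("O3", "PRIV2", source="s2"),
    ]
    return it.aggregate([records], orf_roster={"O1", "O2", "O3", "O4"})


def make_subs(sizes):
    """Subinteractomes with the given partner counts (synthetic symbols)."""
    subs = []
    for i, s in enumerate(sizes):
        subs.append(
            it.Subinteractome(
                orf=f"ORF{i}",
                partners=frozenset(f"P{i}_{j}" for j in range(s)),
            )
        )
    return subs


@pytest.fixture(scope="session")
def printed_distribution_sizes():
    """One concrete size multiset realizing the reference histogram
    (63, 30, 40, 27, 6, 11) over <7, [7,15), [15,30), [30,70), [70,100], >100."""
    rng = np.random.default_rng(7)
    sizes = []
    for (lo, hi), count in (
        ((1, 6), 63), ((7, 14), 30), ((15, 29), 40),
        ((30, 69), 27), ((70, 100), 6), ((101, 140), 11),
    ):
        sizes.extend(int(x) for x in rng.integers(lo, hi + 1, size=count))
    return sizes
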