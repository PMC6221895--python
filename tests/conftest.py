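import pytest

import nssc


@pytest.fixture(scope="session")
def space2_9():
    return nssc.enumerate_states(2, 9)


@pytest.fixture(scope="session")
def island_9_1():
    return nssc.make_scenario([nssc.n_island(9, 1.0)], [])


@pytest.fixture(scope="session")
def single_deme_step():
    """Panmictic deme of size 1 growing to size 5 at T = 1 (backwards)."""
    return nssc.make_scenario(
        [nssc.ModelEpoch([1.0], [[0.0]]), nssc.ModelEpoch([5.0], [[0.0]])],
        [1.0],
    )


@pytest.fixture(scope="session")
def fixture_pair():
    return nssc.human_neanderthal_fixture()


def same(n, deme=0):
    return nssc.LineageConfiguration.same_deme(n, deme)


def diff(n, demes=(0, 1)):
    return nssc.LineageConfiguration.different_demes(n, demes)


def random_model(rng, n=None):
    """A random valid model: sizes in [0.1, 10], sparse non-negative M."""
    n = n or int(rng.integers(2, 6))
    sizes = rng.uniform(0.1, 10.0, n)
    M = rng.uniform(0.0, 3.0, (n, n)) * (rng.random((n, n)) < 0.7)
    # ensure every deme can shed lineages so absorption stays reachable
    for i in range(n):
        j = (i + 1) % n
        if M[i].sum() == 0:
            M[i, j] = rng.uniform(0.1, 1.0)
    return nssc.ModelEpoch(deme_sizes=sizes, migration=M)
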