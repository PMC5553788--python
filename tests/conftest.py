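import pytest

from arcpath.fixtures import FixtureBundle, make_fig3_bundle


@pytest.fixture(scope="session")
def fig3_bundle():
    return make_fig3_bundle()


@pytest.fixture(scope="session")
def fig3_network(fig3_bundle):
    net, _ = fig3_bundle.reconstruct()
    return net


def make_dual_reaction_bundle() -> FixtureBundle:
    """One arc A->P realized by two different reactions."""
    return FixtureBundle(
        reaction_records=[("R1", "A <=> P", ""), ("R2", "A + W <=> P", "")],
        pairs=[("R1", "A", "P", "main"), ("R2", "A", "P", "main")],
        thermo={"R1": -20.0, "R2": -22.0},
        masses={"A": 100.0, "P": 400.0, "W": 90.0},
        excluded=["W"],
        target="P",
    )


def make_extension_bundle() -> FixtureBundle:
    """Two start metabolites chained: the optimal one-arc path B->P can be
    extended by the arc A->B in a later solution."""
    return FixtureBundle(
        reaction_records=[("R1", "A <=> B", ""), ("R2", "B <=> P", "")],
        pairs=[("R1", "A", "B", "main"), ("R2", "B", "P", "main")],
        thermo={"R1": -20.0, "R2": -20.0},
        masses={"A": 100.0, "B": 120.0, "P": 400.0},
        target="P",
    )


@pytest.fixture()
def dual_reaction_network():
    net, _ = make_dual_reaction_bundle().reconstruct()
    return net


@pytest.fixture()
def extension_network():
    net, _ = make_extension_bundle().reconstruct()
    return net
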