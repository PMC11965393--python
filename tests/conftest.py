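import pytest

from domentropy import MolecularGraph, catalog_graph


def make_path(n: int) -> MolecularGraph:
    return MolecularGraph(
        f"P{n}", tuple(f"v{i + 1}" for i in range(n)),
        tuple((i, i + 1) for i in range(n - 1)),
    )


def make_cycle(n: int) -> MolecularGraph:
    return MolecularGraph(
        f"C{n}", tuple(f"v{i + 1}" for i in range(n)),
        tuple((i, (i + 1) % n) for i in range(n)),
    )


def make_complete(n: int) -> MolecularGraph:
    return MolecularGraph(
        f"K{n}", tuple(f"v{i + 1}" for i in range(n)),
        tuple((i, j) for i in range(n) for j in range(i + 1, n)),
    )


def make_star(n: int) -> MolecularGraph:
    """Star with one hub and n-1 leaves."""
    return MolecularGraph(
        f"S{n}", tuple(f"v{i + 1}" for i in range(n)),
        tuple((0, i) for i in range(1, n)),
    )


@pytest.fixture(scope="session")
def naphthalene() -> MolecularGraph:
    return catalog_graph("naphthalene")


@pytest.fixture(scope="session")
def benzene() -> MolecularGraph:
    return catalog_graph("benzene")
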