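"""Domination topological indices from the degree-pair edge partition.

Every index has the form ``sum over edges uv of phi(d_d(u), d_d(v))`` for a
symmetric functional ``phi`` of the endpoint domination degrees, so the edges
are first grouped into classes by the unordered degree pair ``(a, b)`` and
each index is evaluated classwise with multiplicities.

The ten functionals:

========  ===========================================------
DM1       a + b                  (first Zagreb)
DM2       a * b                  (second Zagreb)
DHM       (a + b)^2              (hyper Zagreb)
DF        a^2 + b^2              (forgotten)
DABC      sqrt((a + b - 2) / (a b))   (atom-bond connectivity)
DGA       2 sqrt(a b) / (a + b)  (geometric-arithmetic)
DAZ       (a b / (a b - 2))^3    (augmented Zagreb, product-minus-2 form)
DM1*      (a + b) / (a b)        (redefined first Zagreb)
DM2*      a b / (a + b)          (redefined second Zagreb)
DM3*      a b (a + b)            (redefined third Zagreb)
========  ===========================================------

DAZ keeps the denominator ``a*b - 2``; a class with ``a*b == 2`` is a domain
error.  DABC is zero on a class only when ``a + b == 2`` (two pendant-like
vertices each in a single minimal dominating set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .domination import domination_degrees, enumerate_minimal_dominating_sets
from .graph_core import GraphError, MolecularGraph

DegreePair = tuple[int, int]


class IndexDomainError(ValueError):
    """Functional undefined on some degree-pair class of the partition."""


def _dabc(a: int, b: int) -> float:
    return math.sqrt((a + b - 2) / (a * b))


def _daz(a: int, b: int) -> float:
    if a * b == 2:
        raise IndexDomainError(
            f"DAZ undefined on degree class ({a}, {b}): product equals 2"
        )
    return (a * b / (a * b - 2)) ** 3


INDEX_FUNCTIONS: dict[str, Callable[[int, int], float]] = {
    "DM1": lambda a, b: float(a + b),
    "DM2": lambda a, b: float(a * b),
    "DHM": lambda a, b: float((a + b) ** 2),
    "DF": lambda a, b: float(a * a + b * b),
    "DABC": _dabc,
    "DGA": lambda a, b: 2 * math.sqrt(a * b) / (a + b),
    "DAZ": _daz,
    "DM1*": lambda a, b: (a + b) / (a * b),
    "DM2*": lambda a, b: a * b / (a + b),
    "DM3*": lambda a, b: float(a * b * (a + b)),
}

#: Canonical index order used in tables and reports.
INDEX_NAMES: tuple[str, ...] = (
    "DM1", "DM2", "DHM", "DF", "DABC", "DGA", "DAZ", "DM1*", "DM2*", "DM3*"
)


@dataclass(frozen=True)
class EdgePartition:
    """Edges grouped by the unordered pair of endpoint domination degrees."""

    classes: tuple[tuple[DegreePair, int], ...]  # ((a, b), multiplicity), a <= b

    @property
    def m(self) -> int:
        """Total edge count."""
        return sum(mult for _, mult in self.classes)

    def as_dict(self) -> dict[DegreePair, int]:
        return dict(self.classes)


def edge_partition(
    graph: MolecularGraph, degrees: Sequence[int]
) -> EdgePartition:
    """Group the edges of ``graph`` by unordered endpoint degree pairs."""
    if len(degrees) != graph.n:
        raise GraphError("degree vector length does not match graph order")
    counts: dict[DegreePair, int] = {}
    for u, v in graph.edges:
        a, b = sorted((degrees[u], degrees[v]))
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return EdgePartition(tuple(sorted(counts.items())))


def compute_index(partition: EdgePartition, which: str) -> float:
    """Evaluate one domination index over a degree-pair partition."""
    try:
        phi = INDEX_FUNCTIONS[which]
    except KeyError:
        raise KeyError(
            f"unknown index {which!r}; choose from {', '.join(INDEX_NAMES)}"
        ) from None
    return sum(mult * phi(a, b) for (a, b), mult in partition.classes)


def edge_weights(partition: EdgePartition, which: str) -> list[float]:
    """Per-edge weights phi(a, b) of a functional, expanded by multiplicity.

    These are the information-functional weights the domination entropies are
    defined over.
    """
    phi = INDEX_FUNCTIONS[which]
    out: list[float] = []
    for (a, b), mult in partition.classes:
        out.extend([phi(a, b)] * mult)
    return out


def compute_all_indices(
    graph: MolecularGraph, partition: EdgePartition | None = None
) -> dict[str, float]:
    """Run the full chain MDS -> degrees -> partition -> all ten indices.

    A precomputed ``partition`` may be supplied to avoid re-enumeration.
    """
    if partition is None:
        mds = enumerate_minimal_dominating_sets(graph)
        partition = edge_partition(graph, domination_degrees(mds))
    return {name: compute_index(partition, name) for name in INDEX_NAMES}
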