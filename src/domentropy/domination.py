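"""Exact enumeration of minimal dominating sets and domination degrees.

A set ``D`` of vertices dominates a graph when every vertex lies in ``D`` or
is adjacent to a member of ``D`` (closed-neighborhood convention: a vertex
dominates itself).  ``D`` is *minimal* when no proper subset dominates —
equivalently, every member keeps a private closed neighbor.  The domination
degree ``d_d(v)`` of a vertex is the number of minimal dominating sets that
contain it; it is the basic quantity from which all indices and entropies in
this package are built.

Enumeration is exact: a dominating set is precisely a transversal (hitting
set) of the closed-neighborhood hypergraph ``{N[v] : v in V}``, so the
enumerator branches on the lowest-index vertex not yet dominated, adding in
turn each member of its closed neighborhood.  Branches in which some chosen
vertex has lost all private closed neighbors are pruned (private neighborhoods
only shrink as the set grows, so no minimal set lies below such a node).
Leaves are dominating sets; those passing the minimality test are collected
and deduplicated.  Sets are bitmasks internally and sorted vertex tuples at
the API surface.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .graph_core import GraphError, MolecularGraph

#: Refuse exact enumeration above this many vertices unless overridden.
DEFAULT_VERTEX_CAP = 32

VertexSet = tuple[int, ...]


class ResourceCapError(RuntimeError):
    """Graph exceeds the configured vertex cap for exact enumeration."""


@dataclass(frozen=True)
class MDSCollection:
    """The complete family of minimal dominating sets of a graph.

    ``sets`` is canonically (lexicographically) ordered; each member is a
    sorted tuple of internal vertex indices.
    """

    graph: MolecularGraph
    sets: tuple[VertexSet, ...]

    @property
    def count(self) -> int:
        return len(self.sets)

    def labeled(self) -> list[tuple[str, ...]]:
        """Member sets using display labels."""
        return [tuple(self.graph.labels[v] for v in s) for s in self.sets]


def _as_mask(graph: MolecularGraph, D: Iterable[int]) -> int:
    mask = 0
    for v in D:
        if not 0 <= v < graph.n:
            raise GraphError(f"vertex index {v} out of range for n={graph.n}")
        mask |= 1 << v
    return mask


def is_dominating(graph: MolecularGraph, D: Iterable[int]) -> bool:
    """True iff every vertex is in ``D`` or adjacent to a member of ``D``."""
    N = graph.closed_neighborhoods()
    mask = _as_mask(graph, D)
    covered = 0
    for v in range(graph.n):
        if mask >> v & 1:
            covered |= N[v]
    return covered == (1 << graph.n) - 1


def _is_minimal_mask(N: Sequence[int], n: int, mask: int) -> bool:
    full = (1 << n) - 1
    covered = 0
    for v in range(n):
        if mask >> v & 1:
            covered |= N[v]
    if covered != full:
        return False
    for d in range(n):
        if mask >> d & 1:
            rest = 0
            for x in range(n):
                if x != d and mask >> x & 1:
                    rest |= N[x]
            if N[d] & ~rest == 0:  # d has no private closed neighbor
                return False
    return True


def is_minimal_dominating(graph: MolecularGraph, D: Iterable[int]) -> bool:
    """True iff ``D`` dominates and every member has a private closed neighbor
    (so removing any single member breaks domination)."""
    return _is_minimal_mask(graph.closed_neighborhoods(), graph.n,
                            _as_mask(graph, D))


def enumerate_minimal_dominating_sets(
    graph: MolecularGraph, cap: int = DEFAULT_VERTEX_CAP
) -> MDSCollection:
    """Enumerate *all* minimal dominating sets of ``graph``.

    Raises :class:`ResourceCapError` when ``graph.n`` exceeds ``cap``
    (default 32); pass a larger ``cap`` to override.
    """
    n = graph.n
    if n > cap:
        raise ResourceCapError(
            f"{graph.name}: {n} vertices exceeds the enumeration cap {cap}; "
            f"pass cap={n} to override"
        )
    N = graph.closed_neighborhoods()
    full = (1 << n) - 1
    found: set[int] = set()

    def rec(members: list[int], mask: int, dominated: int) -> None:
        if dominated == full:
            if _is_minimal_mask(N, n, mask):
                found.add(mask)
            return
        # irredundance prune
        for d in members:
            rest = 0
            for x in members:
                if x != d:
                    rest |= N[x]
            if N[d] & ~rest == 0:
                return
        undom = ~dominated & full
        u = (undom & -undom).bit_length() - 1  # lowest-index undominated vertex
        cand = N[u]
        for x in range(n):
            if cand >> x & 1 and not mask >> x & 1:
                members.append(x)
                rec(members, mask | (1 << x), dominated | N[x])
                members.pop()

    rec([], 0, 0)
    sets = sorted(
        tuple(v for v in range(n) if mask >> v & 1) for mask in found
    )
    return MDSCollection(graph, tuple(sets))


def brute_force_mds(graph: MolecularGraph) -> MDSCollection:
    """Independent oracle: filter all 2^n subsets.  Refuses n > 16."""
    n = graph.n
    if n > 16:
        raise ResourceCapError(f"brute force limited to n <= 16, got {n}")
    N = graph.closed_neighborhoods()
    full = (1 << n) - 1

    def covered(mask: int) -> int:
        c = 0
        for v in range(n):
            if mask >> v & 1:
                c |= N[v]
        return c

    dominating = {mask for mask in range(1 << n) if covered(mask) == full}
    sets = []
    for mask in dominating:
        if all(
            (mask ^ (1 << d)) not in dominating
            for d in range(n)
            if mask >> d & 1
        ):
            sets.append(tuple(v for v in range(n) if mask >> v & 1))
    return MDSCollection(graph, tuple(sorted(sets)))


def domination_degrees(mds: MDSCollection) -> list[int]:
    """Per-vertex counts ``d_d(v)`` of minimal-dominating-set membership."""
    deg = [0] * mds.graph.n
    for s in mds.sets:
        for v in s:
            deg[v] += 1
    return deg


def random_connected_graph(n: int, p: float, seed: int) -> MolecularGraph:
    """Deterministic random connected graph fixture (rejection-sampled G(n, p)).

    Used by the property tests to exercise the enumerator against the
    brute-force oracle; not part of the scientific pipeline.
    """
    if not 2 <= n <= 16:
        raise GraphError("random_connected_graph requires 2 <= n <= 16")
    if not 0 < p <= 1:
        raise GraphError("edge probability must be in (0, 1]")
    rng = random.Random(seed)
    pairs = [(u, v) for u in range(n) for v in range(u + 1, n)]
    while True:
        edges = tuple(e for e in pairs if rng.random() < p)
        try:
            return MolecularGraph(
                f"random(n={n},p={p},seed={seed})",
                tuple(f"v{i + 1}" for i in range(n)),
                edges,
            )
        except GraphError:
            continue  # disconnected draw; resample
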