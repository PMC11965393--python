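"""Molecular graph data model, edge-list I/O, ring-fusion builder, and the
benzenoid catalog.

Graphs are hydrogen-suppressed carbon skeletons: simple, undirected,
connected.  Vertices carry display labels ("v1".."vn") and are addressed
internally by contiguous 0-based indices.

Benzenoid skeletons are assembled from hexagonal rings by
:func:`build_from_rings`.  A :class:`RingFusionSpec` lists the rings and, for
every ring after the first, which of its edges are glued to which edges of
earlier rings.  Gluing is by declaration only — corners merge exactly where a
fusion says so, never by geometric coincidence — which is what makes helicene
skeletons (whose planar drawings self-overlap) expressible: a helicene is
simply an ortho-fused chain with no fusion between its terminal rings.
Two convenience constructors cover the usual cases:

* :func:`chain_spec` — catacondensed chains/trees given by attachment edges,
* :func:`lattice_spec` — pericondensed systems given by axial hexagon
  coordinates, with fusion declarations derived from lattice adjacency.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import networkx as nx

from . import _catalog_data


class GraphError(ValueError):
    """Invalid molecular graph or ring-fusion specification."""


# --------------------------------------------------------------------------
# core graph type
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MolecularGraph:
    """A labeled, simple, connected, undirected graph of a carbon skeleton.

    Parameters
    ----------
    name:
        Display name of the molecule (or any text label).
    labels:
        Vertex display labels in index order.
    edges:
        Unordered vertex pairs as 0-based index tuples ``(u, v)`` with
        ``u < v``.
    """

    name: str
    labels: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n == 0:
            raise GraphError("graph has no vertices")
        if len(set(self.labels)) != n:
            raise GraphError("duplicate vertex labels")
        seen: set[tuple[int, int]] = set()
        for u, v in self.edges:
            if u == v:
                raise GraphError(f"self-loop at vertex {self.labels[u]!r}")
            if not (0 <= u < n and 0 <= v < n):
                raise GraphError(f"edge ({u}, {v}) out of range for n={n}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise GraphError(
                    f"parallel edge {self.labels[key[0]]!r}-{self.labels[key[1]]!r}"
                )
            seen.add(key)
        object.__setattr__(
            self, "edges", tuple(sorted((min(u, v), max(u, v)) for u, v in self.edges))
        )
        if n > 1 and not nx.is_connected(self.to_networkx()):
            comp = min(nx.connected_components(self.to_networkx()), key=len)
            names = sorted(self.labels[v] for v in comp)
            raise GraphError(f"graph is disconnected; smallest component: {names}")

    @property
    def n(self) -> int:
        """Number of vertices."""
        return len(self.labels)

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n))
        G.add_edges_from(self.edges)
        return G

    def closed_neighborhoods(self) -> list[int]:
        """Closed neighborhood N[v] of every vertex, as bitmasks."""
        N = [1 << v for v in range(self.n)]
        for u, v in self.edges:
            N[u] |= 1 << v
            N[v] |= 1 << u
        return N

    def degree(self, v: int) -> int:
        return sum(1 for e in self.edges if v in e)

    def relabel(self, name: str | None = None) -> "MolecularGraph":
        """Return a copy with fresh sequential labels v1..vn."""
        return MolecularGraph(
            name if name is not None else self.name,
            tuple(f"v{i + 1}" for i in range(self.n)),
            self.edges,
        )


# --------------------------------------------------------------------------
# edge-list I/O
# --------------------------------------------------------------------------

def read_edge_list(stream: TextIO | str, name: str = "graph") -> MolecularGraph:
    """Parse a plain-text edge list into a validated :class:`MolecularGraph`.

    One edge per line: two whitespace-separated vertex labels.  Blank lines
    and ``#`` comments are ignored.  Vertex order is first-appearance order.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphError(f"line {lineno}: expected two labels, got {line!r}")
        idx = []
        for lab in parts:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            idx.append(index[lab])
        u, v = idx
        if u == v:
            raise GraphError(f"line {lineno}: self-loop {parts[0]!r}")
        key = (min(u, v), max(u, v))
        if key in edges:
            raise GraphError(f"line {lineno}: duplicate edge {line!r}")
        edges.append(key)
    if not labels:
        raise GraphError("empty edge list")
    return MolecularGraph(name, tuple(labels), tuple(edges))


def write_edge_list(graph: MolecularGraph, stream: TextIO | None = None) -> str:
    """Write ``graph`` as a sorted plain-text edge list; returns the text."""
    lines = [f"# {graph.name}: {graph.n} vertices, {graph.m} edges"]
    lines += [f"{graph.labels[u]} {graph.labels[v]}" for u, v in sorted(graph.edges)]
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# --------------------------------------------------------------------------
# ring-fusion builder
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RingFusionSpec:
    """Hexagonal rings plus explicit edge-gluing declarations.

    ``fusions[k]`` lists, for ring ``k``, triples ``(p, pe, se)``: edge ``se``
    of ring ``k`` is identified with edge ``pe`` of the earlier ring ``p``
    (orientation reversed, so the two rings wind consistently).  Ring 0 has no
    fusions.  ``coords`` optionally records axial lattice positions for
    documentation; they play no role in the construction.
    """

    fusions: tuple[tuple[tuple[int, int, int], ...], ...]
    coords: tuple[tuple[int, int] | None, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.coords is None:
            object.__setattr__(self, "coords", (None,) * len(self.fusions))
        if len(self.coords) != len(self.fusions):
            raise GraphError("coords/fusions length mismatch")
        if len(self.fusions) == 0 or self.fusions[0] != ():
            raise GraphError("spec must start with one unfused ring")
        for k, fus in enumerate(self.fusions):
            if k > 0 and not fus:
                raise GraphError(f"ring {k} declares no fusion")
            for p, pe, se in fus:
                if not 0 <= p < k:
                    raise GraphError(f"ring {k} fuses to non-earlier ring {p}")
                if not (0 <= pe < 6 and 0 <= se < 6):
                    raise GraphError(f"ring {k}: edge index out of range")

    @property
    def n_rings(self) -> int:
        return len(self.fusions)


def chain_spec(attach_edges: Sequence[int],
               parents: Sequence[int] | None = None) -> RingFusionSpec:
    """Spec for a catacondensed system.

    ``attach_edges[i]`` is the edge of ring ``parents[i]`` (default: ring
    ``i``) to which ring ``i + 1`` is glued via its own edge 0.  For an
    unbranched chain, relative to the incoming fused edge, attachment 3 is a
    linear (anthracene-like) step and 2 / 4 are the two angular
    (phenanthrene-like) turns; a run of equal turns winds into a helicene.
    """
    if parents is None:
        parents = list(range(len(attach_edges)))
    fus: list[tuple[tuple[int, int, int], ...]] = [()]
    for p, e in zip(parents, attach_edges):
        fus.append(((p, e, 0),))
    return RingFusionSpec(tuple(fus))


_AX_OFF = [(2, 0), (1, 1), (-1, 1), (-2, 0), (-1, -1), (1, -1)]


def _hex_corners(q: int, r: int) -> list[tuple[int, int]]:
    cx, cy = 3 * q, 2 * r + q
    return [(cx + dx, cy + dy) for dx, dy in _AX_OFF]


def lattice_spec(cells: Sequence[tuple[int, int]]) -> RingFusionSpec:
    """Spec for a planar (peri- or catacondensed) system from axial hexagon
    coordinates.  Every lattice adjacency between a cell and an earlier cell
    becomes an explicit fusion declaration."""
    cells = list(cells)
    if len(set(cells)) != len(cells):
        raise GraphError("duplicate lattice cell")
    corner_lists = [_hex_corners(q, r) for q, r in cells]
    fus: list[tuple[tuple[int, int, int], ...]] = []
    for k, corners in enumerate(corner_lists):
        own_edges = {frozenset((corners[i], corners[(i + 1) % 6])): i for i in range(6)}
        decl = []
        for p in range(k):
            for pe in range(6):
                key = frozenset(
                    (corner_lists[p][pe], corner_lists[p][(pe + 1) % 6])
                )
                if key in own_edges:
                    decl.append((p, pe, own_edges[key]))
        if k > 0 and not decl:
            raise GraphError(f"cell {cells[k]} is not adjacent to any earlier cell")
        fus.append(tuple(decl))
    return RingFusionSpec(tuple(fus), tuple(cells))


def build_from_rings(spec: RingFusionSpec, name: str = "benzenoid") -> MolecularGraph:
    """Assemble the molecular graph of a ring-fusion specification.

    Each ring contributes six corner slots; declared fusions identify corner
    slots across rings (union-find), and every surviving corner class becomes
    one vertex.  The result is validated as a :class:`MolecularGraph`.
    """
    R = spec.n_rings
    parent = list(range(6 * R))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for k, fus in enumerate(spec.fusions):
        for p, pe, se in fus:
            # glue edge se of ring k onto edge pe of ring p, reversed
            union(6 * k + se, 6 * p + (pe + 1) % 6)
            union(6 * k + (se + 1) % 6, 6 * p + pe)

    roots: dict[int, int] = {}
    for slot in range(6 * R):
        r = find(slot)
        if r not in roots:
            roots[r] = len(roots)
    edges: set[tuple[int, int]] = set()
    for k in range(R):
        for i in range(6):
            u = roots[find(6 * k + i)]
            v = roots[find(6 * k + (i + 1) % 6)]
            if u == v:
                raise GraphError(f"ring {k}: fusion collapses an edge")
            edges.add((min(u, v), max(u, v)))
    labels = tuple(f"v{i + 1}" for i in range(len(roots)))
    return MolecularGraph(name, labels, tuple(sorted(edges)))


# --------------------------------------------------------------------------
# benzenoid catalog
# --------------------------------------------------------------------------

def catalog_codes() -> list[str]:
    """The 29 catalog identifiers, BH1..BH29."""
    return list(_catalog_data.ENTRIES)


def _resolve(name: str) -> str:
    key = name.strip().lower().replace(" ", "")
    for code, entry in _catalog_data.ENTRIES.items():
        if key == code.lower() or key == entry["name"].lower().replace(" ", ""):
            return code
    valid = ", ".join(
        f"{c} ({e['name']})" for c, e in _catalog_data.ENTRIES.items()
    )
    raise GraphError(f"unknown molecule {name!r}; valid identifiers: {valid}")


def catalog_graph(name: str) -> MolecularGraph:
    """Return the stored skeleton graph for a catalog molecule.

    ``name`` may be a BH-code ("BH2") or a compound name ("naphthalene"),
    case-insensitive.
    """
    code = _resolve(name)
    entry = _catalog_data.ENTRIES[code]
    n = entry["n"]
    return MolecularGraph(
        entry["name"],
        tuple(f"v{i + 1}" for i in range(n)),
        tuple(entry["edges"]),
    )


def catalog_info(name: str) -> dict:
    """Metadata for a catalog molecule: code, name, ring count, class, (n, m),
    and the ring-fusion recipe used to generate the frozen edge list."""
    code = _resolve(name)
    entry = dict(_catalog_data.ENTRIES[code])
    entry["code"] = code
    entry.pop("edges")
    return entry


def catalog_export() -> dict:
    """JSON-ready export: BH-code -> {name, vertices, edges}."""
    out = {}
    for code in catalog_codes():
        g = catalog_graph(code)
        out[code] = {
            "name": g.name,
            "vertices": list(g.labels),
            "edges": [[g.labels[u], g.labels[v]] for u, v in g.edges],
        }
    return out
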