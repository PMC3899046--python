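"""The d-dimensional unit hypercubic lattice with bi-directed edge labels.

The fiber walk grows on the hypercubic lattice whose vertices sit at the
integer points of R^d and whose edges have unit length.  The lattice is
conceptually infinite; this implementation materializes it lazily: whenever a
vertex is touched, its 2d axis neighbors (and the connecting unit edges) are
created on demand.  A walk run on a lazily grown lattice is indistinguishable
from one run on a pre-materialized window.

Vertex identity
---------------
A vertex id is its original integer coordinate tuple, which doubles as its
geometric position: vertex merges absorb a vertex into a fiber vertex without
moving anything, so positions of surviving vertices never change.  Absorbed
positions are recorded in ``Lattice.merged_into`` for auditing.

Edges are *bi-directed*: each edge carries a direction label per orientation,
a d-tuple with entries in {-1, 0, +1}.  Only the label of the stored
orientation ``u -> v`` is kept; the opposite label is its entrywise negation
(an invariant preserved by the entrywise sign-of-sum label recalculation used
during contraction).

All mutating methods optionally append inverse-operation records to a
*journal* list so that a walk can undo a step (and its merges) bit-exactly.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator, Optional

from .errors import (
    InvalidConfigurationError,
    InvalidEdgeError,
    UnknownVertexError,
)

#: A vertex id: the integer coordinate tuple of the original lattice site.
Vid = tuple
#: An edge label: a d-tuple with entries in {-1, 0, +1}, never all zero.
Label = tuple


def initial_label(from_pos: Vid, to_pos: Vid) -> Label:
    """Unit direction label of the original lattice edge ``from_pos -> to_pos``.

    The two positions must differ in exactly one coordinate by +-1.
    """
    try:
        diff = tuple(b - a for a, b in zip(from_pos, to_pos, strict=True))
    except ValueError as exc:  # mismatched dimensions
        raise InvalidEdgeError(f"{from_pos} and {to_pos} differ in dimension") from exc
    if sum(abs(c) for c in diff) != 1 or max(abs(c) for c in diff) != 1:
        raise InvalidEdgeError(f"{from_pos} and {to_pos} are not lattice-adjacent")
    return diff


def negate_label(label: Label) -> Label:
    return tuple(-c for c in label)


def unit_labels(dimension: int) -> list[Label]:
    """All 2d unit direction labels, lexicographically sorted."""
    labels = []
    for axis in range(dimension):
        for sign in (-1, 1):
            vec = [0] * dimension
            vec[axis] = sign
            labels.append(tuple(vec))
    labels.sort()
    return labels


class Edge:
    """A lattice edge between two vertices.

    ``label`` is the direction label of the stored orientation ``u -> v``;
    the reverse label is its entrywise negation.  ``contraction_count`` is the
    number of merges that caused this edge to exist (0 for original lattice
    edges).  ``self_avoiding`` marks edges joining two fiber vertices;
    ``in_fiber`` additionally marks edges traversed by the walk.
    """

    __slots__ = ("u", "v", "label", "length", "contraction_count",
                 "self_avoiding", "in_fiber")

    def __init__(self, u: Vid, v: Vid, label: Label, length: float,
                 contraction_count: int = 0, self_avoiding: bool = False,
                 in_fiber: bool = False):
        self.u = u
        self.v = v
        self.label = label
        self.length = length
        self.contraction_count = contraction_count
        self.self_avoiding = self_avoiding
        self.in_fiber = in_fiber

    def label_from(self, x: Vid) -> Label:
        """Outgoing direction label as seen from endpoint ``x``."""
        return self.label if x == self.u else negate_label(self.label)

    def other(self, x: Vid) -> Vid:
        return self.v if x == self.u else self.u

    def key(self) -> tuple:
        """Canonical (sorted) endpoint pair."""
        return (self.u, self.v) if self.u <= self.v else (self.v, self.u)

    def snapshot(self) -> tuple:
        return (self.u, self.v, self.label, self.length,
                self.contraction_count, self.self_avoiding, self.in_fiber)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flags = "".join(c for c, f in (("F", self.in_fiber),
                                       ("S", self.self_avoiding)) if f)
        return (f"Edge({self.u}->{self.v}, label={self.label}, "
                f"len={self.length:.3f}, c={self.contraction_count}{flags})")


class Lattice:
    """Mutable, lazily materialized hypercubic lattice."""

    def __init__(self, dimension: int, origin: Optional[Vid] = None):
        if dimension < 2:
            raise InvalidConfigurationError(
                f"lattice dimension must be >= 2, got {dimension}")
        self.dimension = dimension
        self.origin: Vid = tuple(origin) if origin is not None else (0,) * dimension
        if len(self.origin) != dimension:
            raise InvalidConfigurationError("origin dimension mismatch")
        self._adj: dict[Vid, dict[Vid, Edge]] = {}
        self._materialized: set[Vid] = set()
        #: absorbed original position -> absorbing fiber vertex id
        self.merged_into: dict[Vid, Vid] = {}
        self._unit_labels = unit_labels(dimension)
        self._add_vertex(self.origin, None)

    # ------------------------------------------------------------------
    # read access
    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_vertex(self, vid: Vid) -> bool:
        return vid in self._adj

    def vertices(self) -> Iterator[Vid]:
        return iter(self._adj)

    def edges(self) -> Iterator[Edge]:
        """Each edge exactly once."""
        for u, nbrs in self._adj.items():
            for v, e in nbrs.items():
                if u <= v:
                    yield e

    def position(self, vid: Vid) -> Vid:
        """Geometric position of a vertex (identical to its id)."""
        if vid not in self._adj:
            raise UnknownVertexError(vid)
        return vid

    def merged_from(self, vid: Vid) -> set[Vid]:
        """Original positions absorbed into ``vid``."""
        return {w for w, k in self.merged_into.items() if k == vid}

    def edge_between(self, u: Vid, v: Vid) -> Optional[Edge]:
        nbrs = self._adj.get(u)
        return None if nbrs is None else nbrs.get(v)

    def degree(self, vid: Vid) -> int:
        if vid not in self._adj:
            raise UnknownVertexError(vid)
        return len(self._adj[vid])

    def neighbors(self, vid: Vid) -> Iterator[Vid]:
        if vid not in self._adj:
            raise UnknownVertexError(vid)
        return iter(self._adj[vid])

    def incident_edges(self, vid: Vid,
                       journal: Optional[list] = None) -> list[tuple[Edge, Vid, Label]]:
        """All edges incident to ``vid`` as ``(edge, neighbor, outgoing label)``.

        Missing axis neighbors are materialized on demand.  The result is
        sorted by (outgoing label, neighbor id), which fixes the order in
        which seeded runs consume randomness.
        """
        if vid not in self._adj:
            raise UnknownVertexError(vid)
        self.materialize(vid, journal)
        entries = [(e.label_from(vid), nbr, e) for nbr, e in self._adj[vid].items()]
        entries.sort(key=lambda t: (t[0], t[1]))
        return [(e, nbr, lab) for lab, nbr, e in entries]

    # ------------------------------------------------------------------
    # journaled mutation primitives
    # ------------------------------------------------------------------
    def _add_vertex(self, vid: Vid, journal: Optional[list]) -> None:
        self._adj[vid] = {}
        if journal is not None:
            journal.append(("v+", vid))

    def add_edge(self, u: Vid, v: Vid, label: Label, length: float,
                 contraction_count: int, self_avoiding: bool,
                 journal: Optional[list], in_fiber: bool = False) -> Edge:
        edge = Edge(u, v, label, length, contraction_count, self_avoiding, in_fiber)
        self._adj[u][v] = edge
        self._adj[v][u] = edge
        if journal is not None:
            journal.append(("e+", u, v))
        return edge

    def del_edge(self, u: Vid, v: Vid, journal: Optional[list]) -> None:
        edge = self._adj[u][v]
        del self._adj[u][v]
        del self._adj[v][u]
        if journal is not None:
            journal.append(("e-", edge.snapshot()))

    def del_vertex(self, vid: Vid, journal: Optional[list]) -> None:
        """Remove an isolated vertex (all edges must be deleted first)."""
        assert not self._adj[vid], "vertex still has incident edges"
        del self._adj[vid]
        if journal is not None:
            journal.append(("v-", vid))

    def set_self_avoiding(self, edge: Edge, value: bool,
                          journal: Optional[list]) -> None:
        if journal is not None:
            journal.append(("sa", edge.u, edge.v, edge.self_avoiding))
        edge.self_avoiding = value

    def set_contraction_count(self, edge: Edge, value: int,
                              journal: Optional[list]) -> None:
        if journal is not None:
            journal.append(("cc", edge.u, edge.v, edge.contraction_count))
        edge.contraction_count = value

    def set_in_fiber(self, edge: Edge, value: bool,
                     journal: Optional[list]) -> None:
        if journal is not None:
            journal.append(("fib", edge.u, edge.v, edge.in_fiber))
        edge.in_fiber = value

    def record_merge(self, removed: Vid, kept: Vid,
                     journal: Optional[list]) -> None:
        self.merged_into[removed] = kept
        if journal is not None:
            journal.append(("mm", removed))

    def materialize(self, vid: Vid, journal: Optional[list] = None) -> None:
        """Ensure all 2d axis neighbors of ``vid`` and their unit edges exist.

        Neighbor positions already absorbed by a merge are skipped: their
        edges were inherited by the absorbing fiber vertex.
        """
        if vid in self._materialized:
            return
        if vid not in self._adj:
            self._add_vertex(vid, journal)
        nbrs = self._adj[vid]
        for lab in self._unit_labels:
            p = tuple(a + b for a, b in zip(vid, lab))
            if p in self.merged_into:
                continue
            if p not in self._adj:
                self._add_vertex(p, journal)
            if p not in nbrs:
                self.add_edge(vid, p, lab, 1.0, 0, False, journal)
        self._materialized.add(vid)
        if journal is not None:
            journal.append(("mat", vid))

    # ------------------------------------------------------------------
    # undo
    # ------------------------------------------------------------------
    def undo_op(self, op: tuple) -> None:
        """Apply the inverse of one journal record."""
        tag = op[0]
        if tag == "sa":
            self._adj[op[1]][op[2]].self_avoiding = op[3]
        elif tag == "cc":
            self._adj[op[1]][op[2]].contraction_count = op[3]
        elif tag == "fib":
            self._adj[op[1]][op[2]].in_fiber = op[3]
        elif tag == "e+":
            del self._adj[op[1]][op[2]]
            del self._adj[op[2]][op[1]]
        elif tag == "e-":
            u, v, label, length, cc, sa, fib = op[1]
            edge = Edge(u, v, label, length, cc, sa, fib)
            self._adj[u][v] = edge
            self._adj[v][u] = edge
        elif tag == "v+":
            assert not self._adj[op[1]]
            del self._adj[op[1]]
        elif tag == "v-":
            self._adj[op[1]] = {}
        elif tag == "mat":
            self._materialized.discard(op[1])
        elif tag == "mm":
            del self.merged_into[op[1]]
        else:  # pragma: no cover
            raise ValueError(f"unknown journal op {tag!r}")

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def to_node_link(self) -> dict:
        """Node-link snapshot (JSON-serializable) of the materialized window."""
        merged: dict[Vid, list] = {}
        for w, k in self.merged_into.items():
            merged.setdefault(k, []).append(list(w))
        return {
            "dimension": self.dimension,
            "origin": list(self.origin),
            "vertices": [
                {"id": list(v), "position": list(v),
                 "merged_from": sorted(merged.get(v, []))}
                for v in sorted(self._adj)
            ],
            "edges": [
                {"u": list(e.u), "v": list(e.v), "label": list(e.label),
                 "length": e.length, "contraction_count": e.contraction_count,
                 "self_avoiding": e.self_avoiding, "in_fiber": e.in_fiber}
                for e in sorted(self.edges(), key=lambda e: e.key())
            ],
        }


def create_lattice(dimension: int, seed_radius: int) -> Lattice:
    """A fully edged lattice window within Chebyshev distance ``seed_radius``.

    The window is a convenience for inspection and tests; walks grow the
    lattice on demand regardless of the initial window size.
    """
    if dimension < 2:
        raise InvalidConfigurationError(
            f"lattice dimension must be >= 2, got {dimension}")
    if seed_radius < 1:
        raise InvalidConfigurationError(
            f"seed_radius must be >= 1, got {seed_radius}")
    lat = Lattice(dimension)
    rng_range = range(-seed_radius, seed_radius + 1)
    for pos in itertools.product(rng_range, repeat=dimension):
        if pos not in lat._adj:
            lat._add_vertex(pos, None)
    for pos in itertools.product(rng_range, repeat=dimension):
        for axis in range(dimension):
            if pos[axis] + 1 <= seed_radius:
                q = pos[:axis] + (pos[axis] + 1,) + pos[axis + 1:]
                lab = initial_label(pos, q)
                lat.add_edge(pos, q, lab, 1.0, 0, False, None)
    for pos in itertools.product(rng_range, repeat=dimension):
        if max(abs(c) for c in pos) < seed_radius:
            lat._materialized.add(pos)
    return lat


def euclidean(u: Vid, v: Vid) -> float:
    """Euclidean distance between two vertex positions."""
    return math.dist(u, v)
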