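"""Reconstruction of the 2D expansion boundary of a fiber.

The boundary of the region consumed by the fiber's expansion is derived from
the face dual of the lattice faces adjacent to the fiber, refined by an
*intermediate lattice* that places vertices part-way along every lattice edge
incident to the walk.  On an uncontracted unit edge the intermediate vertex
sits at half-edge distance; on an edge created by c merges it sits at

    offset = L / (2 * (c + 1))

from the fiber endpoint, where L is the edge length.  This reduces to 0.5 on
unit edges, keeps the absolute offset at 0.5 on the axis-aligned contracted
classes (lengths 2 and 3), and leaves a gap of at least one lattice unit
across the length-sqrt(5)/3 self-avoiding classes - the gap that is too
narrow for another fiber to grow in between and expand.

The closed boundary polyline is assembled by taking, around every fiber
vertex, the star-shaped cell through its intermediate points and the dual
(face) points wedged between angularly consecutive incident edges, and
dissolving shared cell walls in a polygon union.  Dual edges shared by two
cells (the "non-unique" edges) vanish in the union; only the outer ring is
kept and enclosed pockets are counted separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

from .errors import (
    DegenerateInputError,
    InvalidInputError,
    UnsupportedDimensionError,
)
from .lattice import Edge, Vid
from .walk_core import WalkState

SELF_AVOIDING = "self_avoiding"
NON_SELF_AVOIDING = "non_self_avoiding"
MIXED = "mixed"

#: width of the connector strip laid along each fiber edge; safely below the
#: smallest intermediate offset (sqrt(2)/4) so the strip never leaves the
#: region already covered by the vertex cells
_STRIP_HALF_WIDTH = 0.15


@dataclass
class FaceRecord:
    """One lattice face adjacent to the fiber, with its dual point."""

    face_id: int
    vertices: list[Vid]
    edges: list[tuple[Vid, Vid]]
    classification: str
    dual_point: tuple[float, float]


@dataclass
class IntermediateVertex:
    """A vertex of the intermediate lattice on a walk-incident edge."""

    host_edge: tuple[Vid, Vid]   # (fiber endpoint, far endpoint)
    offset: float                # distance along the edge from the fiber endpoint
    position: tuple[float, float]


@dataclass
class BoundaryPolyline:
    """A closed 2D polyline (first point not repeated)."""

    points: np.ndarray
    closed: bool = True
    n_pockets: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def as_ring(self) -> np.ndarray:
        """Points with the first vertex appended again at the end."""
        return np.vstack([self.points, self.points[:1]])

    def to_shapely(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    @property
    def perimeter(self) -> float:
        d = np.diff(self.as_ring(), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def is_simple(self) -> bool:
        ring = self.to_shapely()
        return ring.is_valid and not ring.is_empty

    def contains_point(self, p) -> bool:
        from shapely.geometry import Point
        return self.to_shapely().contains(Point(p))


def _require_2d(state: WalkState) -> None:
    if state.config.dimension != 2:
        raise UnsupportedDimensionError(
            "the boundary is defined in 2D only "
            f"(got dimension {state.config.dimension})")


def intermediate_offset(edge: Edge) -> float:
    """Distance of the intermediate vertex from the fiber endpoint of an edge."""
    return edge.length / (2.0 * (edge.contraction_count + 1))


def build_intermediate_lattice(state: WalkState) -> list[IntermediateVertex]:
    """Intermediate vertices on every walk-incident, non-fiber lattice edge.

    Self-avoiding edges have two fiber endpoints and therefore carry one
    intermediate vertex per endpoint (coinciding at the midpoint of unit
    edges).
    """
    _require_2d(state)
    lat = state.lattice
    out: list[IntermediateVertex] = []
    seen: set[tuple] = set()
    for v in state.fiber.vertex_sequence:
        for e, nbr, _lab in lat.incident_edges(v, None):
            if e.in_fiber:
                continue
            key = (v, nbr)
            if key in seen:
                continue
            seen.add(key)
            off = intermediate_offset(e)
            ux = (nbr[0] - v[0]) / e.length
            uy = (nbr[1] - v[1]) / e.length
            out.append(IntermediateVertex(
                host_edge=(v, nbr), offset=off,
                position=(v[0] + off * ux, v[1] + off * uy)))
    return out


def _face_centroid(lat, v: Vid, a: Vid, b: Vid,
                   cap: int = 6) -> Optional[tuple[float, float]]:
    """Centroid of the lattice face left of the dart ``v -> a``.

    Traces the face with the planar rotation rule (next dart = angular
    predecessor of the reversed dart).  Returns None unless the trace
    closes within ``cap`` darts and re-enters ``v`` through ``b`` (the
    angular successor of ``a`` around ``v``), i.e. unless the face really
    fills the wedge between the two edges.
    """

    def pred(w: Vid, u: Vid) -> Vid:
        nbrs = sorted(lat._adj[w],
                      key=lambda q: math.atan2(q[1] - w[1], q[0] - w[0]))
        return nbrs[(nbrs.index(u) - 1) % len(nbrs)]

    cycle = [v]
    u, w = v, a
    for _ in range(cap):
        if w == v:
            break
        cycle.append(w)
        u, w = w, pred(w, u)
    else:
        return None
    if cycle[-1] != b:
        return None
    cx = sum(p[0] for p in cycle) / len(cycle)
    cy = sum(p[1] for p in cycle) / len(cycle)
    return (cx, cy)


def _vertex_cell(state: WalkState, v: Vid) -> Optional[Polygon]:
    """Star-shaped boundary cell around one fiber vertex.

    The cell runs through the intermediate point of every incident edge
    (half the length for fiber edges) and, between angularly consecutive
    edges spanning less than a half turn, the dual point of the enclosed
    face: its traced centroid, which on unit squares equals the
    parallelogram point of the two reaches.  The parallelogram point is the
    fallback where no small face closes the wedge.
    """
    lat = state.lattice
    entries = []
    for e, nbr, _lab in lat.incident_edges(v, None):
        dx, dy = nbr[0] - v[0], nbr[1] - v[1]
        reach = e.length / 2.0 if e.in_fiber else intermediate_offset(e)
        ux, uy = dx / e.length, dy / e.length
        entries.append((math.atan2(dy, dx), reach * ux, reach * uy, nbr))
    if len(entries) < 2:
        return None
    entries.sort(key=lambda t: t[0])
    pts: list[tuple[float, float]] = []
    n = len(entries)
    for i in range(n):
        ang_i, rx_i, ry_i, nbr_i = entries[i]
        ang_j, rx_j, ry_j, nbr_j = entries[(i + 1) % n]
        pts.append((v[0] + rx_i, v[1] + ry_i))
        gap = (ang_j - ang_i) % (2.0 * math.pi)
        if 1e-9 < gap < math.pi - 1e-6:
            dual = _face_centroid(lat, v, nbr_i, nbr_j)
            if dual is not None:
                da = (math.atan2(dual[1] - v[1], dual[0] - v[0]) - ang_i) \
                    % (2.0 * math.pi)
                if not (1e-9 < da < gap - 1e-9 and math.dist(dual, v) < 2.0):
                    dual = None
            if dual is None:
                dual = (v[0] + rx_i + rx_j, v[1] + ry_i + ry_j)
            pts.append(dual)
        elif gap >= math.pi - 1e-6:
            # edges (nearly) opposite or reflex: the sector still holds
            # lattice faces adjacent to v, so give the cell support there
            # (at the smaller reach) lest it pinch through the vertex
            r = min(math.hypot(rx_i, ry_i), math.hypot(rx_j, ry_j))
            k = max(1, math.ceil(gap / (0.5 * math.pi)) - 1)
            for m in range(1, k + 1):
                ang = ang_i + gap * m / (k + 1)
                pts.append((v[0] + r * math.cos(ang), v[1] + r * math.sin(ang)))
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly if not poly.is_empty else None


def _fiber_strip(u: Vid, v: Vid) -> Polygon:
    """Thin rectangle along a fiber edge, connecting adjacent vertex cells."""
    ux, uy = v[0] - u[0], v[1] - u[1]
    L = math.hypot(ux, uy)
    ux, uy = ux / L, uy / L
    px, py = -uy * _STRIP_HALF_WIDTH, ux * _STRIP_HALF_WIDTH
    return Polygon([(u[0] + px, u[1] + py), (v[0] + px, v[1] + py),
                    (v[0] - px, v[1] - py), (u[0] - px, u[1] - py)])


def extract_boundary(state: WalkState) -> BoundaryPolyline:
    """Closed boundary of the region consumed by the fiber and its expansion.

    Returns the outer ring (counter-clockwise, no repeated endpoint) of the
    union of all per-vertex boundary cells; enclosed trapped pockets are
    reported via ``n_pockets`` rather than carved out of the polyline.
    """
    _require_2d(state)
    if state.n_steps < 1:
        raise DegenerateInputError("boundary needs a walk of length >= 1")
    pieces = []
    for v in state.fiber.vertex_sequence:
        cell = _vertex_cell(state, v)
        if cell is not None:
            pieces.append(cell)
    verts = state.fiber.vertex_sequence
    for u, v in zip(verts[:-1], verts[1:]):
        pieces.append(_fiber_strip(u, v))
    union = unary_union(pieces)
    if union.geom_type == "MultiPolygon":  # should not happen; keep the fiber's part
        union = max(union.geoms, key=lambda g: g.area)
    union = orient(union, sign=1.0)
    coords = np.asarray(union.exterior.coords[:-1], dtype=float)
    return BoundaryPolyline(points=coords, closed=True,
                            n_pockets=len(union.interiors))


# ----------------------------------------------------------------------
# face classification
# ----------------------------------------------------------------------
def classify_face_edges(flags: list[str]) -> str:
    """Classify a face from its bounding-edge flags.

    ``flags`` holds one of ``"fiber"``, ``"sa"`` or ``"plain"`` per bounding
    edge.  A face is *self-avoiding* when every bounding edge is
    self-avoiding or a fiber edge, *non-self-avoiding* when none is, and
    *mixed* otherwise.
    """
    special = [f in ("fiber", "sa") for f in flags]
    if all(special):
        return SELF_AVOIDING
    if not any(special):
        return NON_SELF_AVOIDING
    return MIXED


def _edge_flag(e: Edge) -> str:
    if e.in_fiber:
        return "fiber"
    if e.self_avoiding:
        return "sa"
    return "plain"


def classify_faces(state: WalkState, max_face_len: int = 64) -> list[FaceRecord]:
    """Classify every lattice face sharing an edge or a vertex with the fiber.

    Faces are traced on the contracted lattice with the standard planar
    rotation-system rule (next edge = angular predecessor of the reversed
    edge).  The unbounded outer face is discarded by its orientation; face
    traces longer than ``max_face_len`` are treated as outer and skipped.
    """
    _require_2d(state)
    lat = state.lattice
    fiber_set = set(state.fiber.vertex_sequence)
    # materialize one ring beyond the fiber so every adjacent face closes
    for v in list(fiber_set):
        for _e, nbr, _lab in lat.incident_edges(v, None):
            lat.materialize(nbr, None)

    def sorted_nbrs(v: Vid) -> list[Vid]:
        return sorted(lat._adj[v],
                      key=lambda w: math.atan2(w[1] - v[1], w[0] - v[0]))

    records: list[FaceRecord] = []
    seen_darts: set[tuple[Vid, Vid]] = set()
    seen_faces: set[frozenset] = set()
    for start in sorted(fiber_set):
        for first in sorted(lat._adj[start]):
            if (start, first) in seen_darts:
                continue
            cycle: list[tuple[Vid, Vid]] = []
            u, v = start, first
            ok = False
            for _ in range(max_face_len):
                cycle.append((u, v))
                nbrs = sorted_nbrs(v)
                w = nbrs[(nbrs.index(u) - 1) % len(nbrs)]
                u, v = v, w
                if (u, v) == (start, first):
                    ok = True
                    break
            if not ok:
                continue
            area2 = sum(a[0] * b[1] - b[0] * a[1] for a, b in cycle)
            if area2 <= 0:  # outer face (clockwise under this rotation rule)
                for dart in cycle:
                    seen_darts.add(dart)
                continue
            key = frozenset(frozenset(d) for d in cycle)
            for dart in cycle:
                seen_darts.add(dart)
            if key in seen_faces:
                continue
            seen_faces.add(key)
            face_vertices = [d[0] for d in cycle]
            edges = [lat.edge_between(a, b) for a, b in cycle]
            flags = [_edge_flag(e) for e in edges]
            touches = any(fv in fiber_set for fv in face_vertices)
            if not touches:
                continue
            cx = sum(p[0] for p in face_vertices) / len(face_vertices)
            cy = sum(p[1] for p in face_vertices) / len(face_vertices)
            records.append(FaceRecord(
                face_id=len(records), vertices=face_vertices,
                edges=[d for d in cycle],
                classification=classify_face_edges(flags),
                dual_point=(cx, cy)))
    return records


# ----------------------------------------------------------------------
# right-angle avoidance
# ----------------------------------------------------------------------
@dataclass
class TurnCheck:
    """Verification record for one right-angle turn of the fiber.

    ``boundary_nearby`` is False when the boundary runs nowhere near the
    inner side of the turn (the region is locally thick there), in which
    case the check passes vacuously.
    """

    vertex: Vid
    boundary_nearby: bool
    inner_vertex_found: bool
    no_right_angle: bool

    @property
    def passed(self) -> bool:
        if not self.boundary_nearby:
            return True
        return self.inner_vertex_found and self.no_right_angle


@dataclass
class RightAngleReport:
    turns: list[TurnCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(t.passed for t in self.turns)


def check_right_angle_avoidance(state: WalkState,
                                boundary: BoundaryPolyline) -> RightAngleReport:
    """Verify that the boundary has no curvature singularity at fiber turns.

    For every 90-degree turn of the fiber the boundary must contribute a
    vertex on the inner side of the turn, and the two boundary segments
    meeting at the boundary vertex nearest the turn (inner side) must not be
    both axis-parallel and mutually perpendicular.
    """
    _require_2d(state)
    report = RightAngleReport()
    verts = state.fiber.vertex_sequence
    pts = boundary.points
    ring_n = len(pts)
    for i in range(1, len(verts) - 1):
        p0, p1, p2 = verts[i - 1], verts[i], verts[i + 1]
        a = np.array([p1[0] - p0[0], p1[1] - p0[1]], dtype=float)
        b = np.array([p2[0] - p1[0], p2[1] - p1[1]], dtype=float)
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        if abs(float(a @ b)) > 1e-9:
            continue  # not a right-angle turn
        d1, d2 = -a, b  # the two rays spanning the inner (90-degree) wedge
        rel = pts - np.array(p1, dtype=float)
        dist = np.hypot(rel[:, 0], rel[:, 1])
        inner = (rel @ d1 > 1e-9) & (rel @ d2 > 1e-9) & (dist <= 1.5)
        found = bool(inner.any())
        # does the boundary pass through the inner wedge near the turn at
        # all?  sample along every segment with an endpoint close to v
        nearby = found
        if not nearby:
            close = np.nonzero(dist <= 2.5)[0]
            ts = np.linspace(0.0, 1.0, 9)[1:-1]
            for idx in close:
                q0, q1 = pts[idx], pts[(idx + 1) % ring_n]
                for t in ts:
                    s = (1 - t) * q0 + t * q1
                    r = s - np.array(p1, dtype=float)
                    if (r @ d1 > 1e-9 and r @ d2 > 1e-9
                            and math.hypot(*r) <= 0.9):
                        nearby = True
                        break
                if nearby:
                    break
        no_right_angle = True
        if found:
            idx = int(np.argmin(np.where(inner, dist, np.inf)))
            q_prev = pts[(idx - 1) % ring_n]
            q = pts[idx]
            q_next = pts[(idx + 1) % ring_n]
            s1 = q - q_prev
            s2 = q_next - q
            axis1 = min(abs(s1[0]), abs(s1[1])) < 1e-9
            axis2 = min(abs(s2[0]), abs(s2[1])) < 1e-9
            perp = abs(float(s1 @ s2)) < 1e-9
            no_right_angle = not (axis1 and axis2 and perp)
        report.turns.append(TurnCheck(vertex=p1, boundary_nearby=nearby,
                                      inner_vertex_found=found,
                                      no_right_angle=no_right_angle))
    return report


# ----------------------------------------------------------------------
# cosmetic smoothing
# ----------------------------------------------------------------------
def smooth_boundary(boundary: BoundaryPolyline, iterations: int) -> BoundaryPolyline:
    """Subdivision smoothing of a closed boundary (cosmetic only).

    One iteration of cubic B-spline subdivision of the closed polyline: each
    vertex is replaced by its smoothed position (p[i-1] + 6 p[i] + p[i+1])/8
    and an edge midpoint is inserted after it, doubling the vertex count and
    cutting corners (a square becomes an octagon).  This is the curve
    restriction of Catmull-Clark subdivision.
    """
    if not boundary.closed:
        raise InvalidInputError("smoothing requires a closed polyline")
    pts = np.asarray(boundary.points, dtype=float)
    for _ in range(iterations):
        prev = np.roll(pts, 1, axis=0)
        nxt = np.roll(pts, -1, axis=0)
        refined = (prev + 6.0 * pts + nxt) / 8.0
        mids = (pts + nxt) / 2.0
        out = np.empty((2 * len(pts), 2), dtype=float)
        out[0::2] = refined
        out[1::2] = mids
        pts = out
    return BoundaryPolyline(points=pts, closed=True,
                            n_pockets=boundary.n_pockets)
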