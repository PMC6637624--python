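"""Quad-mesh subdivision machinery for biventricular surface models.

The deformable heart model is a coarse labeled quad mesh (``ControlMesh``)
refined by Catmull-Clark subdivision with infinitely sharp creases at the
valve rings and the right-ventricular insertions.  Subdivision is linear in
the control vertices, so it is represented explicitly as a sparse operator
``S`` with ``subdivided_vertices = S @ control_vertices``; downstream
contour fitting exploits this linearity.

Also provides the surface primitives the pipeline needs: exact
point-to-surface distances, divergence-theorem volumes, normal offsets
(used to synthesize the RV epicardium from the endocardium) and planar fan
caps over valve rings so cavity volumes are well defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "ControlMesh",
    "SubdividedSurface",
    "PolySurface",
    "MeshConstructionError",
    "OpenSurfaceError",
    "OrientationError",
    "catmull_clark",
    "surface_volume",
    "point_to_surface",
    "closest_point_on_surface",
    "offset_surface",
    "cap_valves",
    "vertex_normals",
    "triangulate_quads",
    "surface_triangles",
    "orient_consistently",
    "write_obj",
    "read_obj",
    "write_vtk",
]


class MeshConstructionError(ValueError):
    """A mesh violates a structural invariant (non-quad, non-manifold...)."""


class OpenSurfaceError(ValueError):
    """A closed surface was required but boundary edges are present."""


class OrientationError(ValueError):
    """Signed volume came out negative; the surface orientation is inward."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ControlMesh:
    """Coarse labeled quad mesh with crease tags.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 4) int array of vertex indices (counter-clockwise seen from
        outside).
    creases : set of frozenset pairs of vertex indices marked infinitely
        sharp.  Boundary edges are implicitly sharp and need not be listed.
    patch_label : length-F sequence of strings (e.g. ``lv_endo``,
        ``rv_septum``, ``rv_freewall``, ``epi``, ``valve_plane``).
    ring_label : mapping vertex index -> valve tag (``mitral``,
        ``tricuspid``, ``aortic``, ``pulmonary``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    creases: set = field(default_factory=set)
    patch_label: np.ndarray = None
    ring_label: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.patch_label is None:
            self.patch_label = np.array(["surface"] * len(self.faces))
        else:
            self.patch_label = np.asarray(self.patch_label, dtype=object)
        self.creases = {frozenset(e) for e in self.creases}
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self):
        if self.faces.ndim != 2 or self.faces.shape[1] != 4:
            raise MeshConstructionError("control mesh faces must be quads")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise MeshConstructionError("face references an invalid vertex index")
        counts = self.edge_face_count()
        worst = max(counts.values(), default=0)
        if worst > 2:
            raise MeshConstructionError(
                f"non-manifold edge shared by {worst} faces"
            )
        for e in self.creases:
            if tuple(sorted(e)) not in counts:
                raise MeshConstructionError(f"crease edge {sorted(e)} not in face set")

    def edge_face_count(self):
        counts = {}
        for f in self.faces:
            for i in range(4):
                e = (min(f[i], f[(i + 1) % 4]), max(f[i], f[(i + 1) % 4]))
                counts[e] = counts.get(e, 0) + 1
        return counts

    def boundary_edges(self):
        return {e for e, c in self.edge_face_count().items() if c == 1}

    def ring_vertices(self, tag):
        return sorted(v for v, t in self.ring_label.items() if t == tag)

    @property
    def n_vertices(self):
        return len(self.vertices)


@dataclass
class SubdividedSurface:
    """Catmull-Clark refinement of a :class:`ControlMesh`.

    ``vertices = operator @ control_vertices`` at every level; the operator
    is the vertex provenance (each row gives a subdivided vertex's ancestry
    weights over control vertices).
    """

    vertices: np.ndarray
    faces: np.ndarray
    level: int
    operator: sp.csr_matrix
    patch_label: np.ndarray
    ring_label: dict
    creases: set
    control: ControlMesh | None = None
    #: subdivided vertex index of each control vertex (control vertices
    #: survive every Catmull-Clark step as repositioned vertex points)
    control_vertex_map: np.ndarray | None = None

    def with_vertices(self, vertices):
        """Same topology and labels with replaced vertex coordinates."""
        return SubdividedSurface(
            vertices=np.asarray(vertices, float),
            faces=self.faces,
            level=self.level,
            operator=self.operator,
            patch_label=self.patch_label,
            ring_label=self.ring_label,
            creases=self.creases,
            control=self.control,
            control_vertex_map=self.control_vertex_map,
        )

    def with_control_vertices(self, control_vertices):
        return self.with_vertices(self.operator @ np.asarray(control_vertices, float))

    def faces_of_patch(self, labels):
        if isinstance(labels, str):
            labels = [labels]
        mask = np.isin(self.patch_label.astype(str), list(labels))
        return self.faces[mask]

    def subsurface(self, labels):
        """A PolySurface restricted to the given patch labels."""
        return PolySurface(self.vertices, [tuple(f) for f in self.faces_of_patch(labels)])

    def ring_vertices(self, tag):
        return sorted(v for v, t in self.ring_label.items() if t == tag)

    def boundary_edges(self):
        counts = {}
        for f in self.faces:
            for i in range(4):
                e = (min(f[i], f[(i + 1) % 4]), max(f[i], f[(i + 1) % 4]))
                counts[e] = counts.get(e, 0) + 1
        return {e for e, c in counts.items() if c == 1}


@dataclass
class PolySurface:
    """Lightweight surface with mixed quad/triangle faces (cap output)."""

    vertices: np.ndarray
    faces: list
    patch_label: list = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.faces = [f if isinstance(f, tuple) else tuple(f) for f in self.faces]
        if self.patch_label is None:
            self.patch_label = ["surface"] * len(self.faces)


# ---------------------------------------------------------------------------
# subdivision


def _sharp_edges(faces, creases):
    counts = {}
    for f in faces:
        for i in range(4):
            e = frozenset((int(f[i]), int(f[(i + 1) % 4])))
            counts[e] = counts.get(e, 0) + 1
    boundary = {e for e, c in counts.items() if c == 1}
    return set(creases) | boundary, counts


def _subdivide_once(n_vertices, faces, creases, patch_label, ring_label):
    """One Catmull-Clark step.

    Returns the (V+E+F) x V sparse step operator, child faces, child
    creases, child patch labels and child ring labels.  Rules: face points
    are face centroids; sharp (crease or boundary) edge points are edge
    midpoints, smooth edge points average the endpoints with the two
    adjacent face points; vertices with two sharp edges follow the cubic
    B-spline crease rule (1/8, 3/4, 1/8), three or more sharp edges pin
    the vertex (corner), otherwise the standard smooth vertex rule applies.
    """
    faces = np.asarray(faces, int)
    sharp, edge_counts = _sharp_edges(faces, creases)
    edges = sorted(tuple(sorted(e)) for e in edge_counts)
    edge_index = {frozenset(e): i for i, e in enumerate(edges)}
    nV, nE, nF = n_vertices, len(edges), len(faces)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # face points: rows [0, nF)
    for fi, f in enumerate(faces):
        for v in f:
            add(fi, int(v), 0.25)

    # adjacency for edge and vertex rules
    edge_faces = {}
    for fi, f in enumerate(faces):
        for i in range(4):
            e = frozenset((int(f[i]), int(f[(i + 1) % 4])))
            edge_faces.setdefault(e, []).append(fi)

    # edge points: rows [nF, nF+nE)
    for e, ei in ((e, edge_index[frozenset(e)]) for e in edges):
        a, b = e
        r = nF + ei
        if frozenset(e) in sharp:
            add(r, a, 0.5)
            add(r, b, 0.5)
        else:
            add(r, a, 0.25)
            add(r, b, 0.25)
            for fi in edge_faces[frozenset(e)]:
                for v in faces[fi]:
                    add(r, int(v), 0.25 * 0.25)

    # vertex points: rows [nF+nE, nF+nE+nV)
    vert_edges = {}
    vert_faces = {}
    for e in edges:
        a, b = e
        vert_edges.setdefault(a, []).append(e)
        vert_edges.setdefault(b, []).append(e)
    for fi, f in enumerate(faces):
        for v in f:
            vert_faces.setdefault(int(v), []).append(fi)

    for v in range(nV):
        r = nF + nE + v
        inc_e = vert_edges.get(v, [])
        inc_sharp = [e for e in inc_e if frozenset(e) in sharp]
        if len(inc_e) == 0:  # isolated vertex: keep
            add(r, v, 1.0)
        elif len(inc_sharp) >= 3:
            add(r, v, 1.0)  # corner
        elif len(inc_sharp) == 2:
            add(r, v, 0.75)
            for e in inc_sharp:
                other = e[0] if e[1] == v else e[1]
                add(r, other, 0.125)
        else:
            n = len(inc_e)
            # (F + 2R + (n-3)P)/n with F avg face point, R avg edge midpoint
            add(r, v, (n - 3.0) / n)
            for e in inc_e:
                other = e[0] if e[1] == v else e[1]
                add(r, v, 2.0 / n * 0.5 / n)
                add(r, other, 2.0 / n * 0.5 / n)
            fset = vert_faces.get(v, [])
            for fi in fset:
                for w in faces[fi]:
                    add(r, int(w), 1.0 / n / len(fset) * 0.25)

    step = sp.coo_matrix((vals, (rows, cols)), shape=(nF + nE + nV, nV)).tocsr()

    def fp(fi):
        return fi

    def ep(e):
        return nF + edge_index[frozenset(e)]

    def vp(v):
        return nF + nE + int(v)

    new_faces = []
    new_labels = []
    for fi, f in enumerate(faces):
        epts = [ep((int(f[i]), int(f[(i + 1) % 4]))) for i in range(4)]
        c = fp(fi)
        for i in range(4):
            new_faces.append((vp(f[i]), epts[i], c, epts[i - 1]))
            new_labels.append(patch_label[fi])
    new_faces = np.asarray(new_faces, int)
    new_labels = np.asarray(new_labels, dtype=object)

    new_creases = set()
    for e in creases:
        a, b = tuple(e)
        new_creases.add(frozenset((vp(a), ep((a, b)))))
        new_creases.add(frozenset((ep((a, b)), vp(b))))

    new_rings = {vp(v): t for v, t in ring_label.items()}
    for e in edges:
        a, b = e
        ta, tb = ring_label.get(a), ring_label.get(b)
        if ta is not None and ta == tb and frozenset(e) in (set(creases) | set()):
            new_rings[ep(e)] = ta
        elif ta is not None and ta == tb and frozenset(e) in sharp:
            new_rings[ep(e)] = ta

    return step, new_faces, new_creases, new_labels, new_rings


def catmull_clark(mesh: ControlMesh, levels: int = 2) -> SubdividedSurface:
    """Catmull-Clark subdivision with sharp creases.

    ``levels=0`` returns the control mesh geometry unchanged (identity
    operator).  Raises :class:`MeshConstructionError` on non-quad faces or
    non-manifold edges (checked by the ControlMesh itself).
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    mesh.validate()
    op = sp.identity(mesh.n_vertices, format="csr")
    faces = mesh.faces.copy()
    creases = set(mesh.creases)
    labels = np.asarray(mesh.patch_label, dtype=object)
    rings = dict(mesh.ring_label)
    n = mesh.n_vertices
    vmap = np.arange(mesh.n_vertices)
    for _ in range(levels):
        step, faces, creases, labels, rings = _subdivide_once(
            n, faces, creases, labels, rings
        )
        # vertex points occupy the trailing block of each step's rows
        vmap = (step.shape[0] - n) + vmap
        op = (step @ op).tocsr()
        n = step.shape[0]
    return SubdividedSurface(
        vertices=op @ mesh.vertices,
        faces=faces,
        level=levels,
        operator=op,
        patch_label=labels,
        ring_label=rings,
        creases=creases,
        control=mesh,
        control_vertex_map=vmap,
    )


# ---------------------------------------------------------------------------
# triangulation and generic face access


def _faces_of(surface):
    if isinstance(surface, (ControlMesh, SubdividedSurface)):
        return surface.vertices, surface.faces
    if isinstance(surface, PolySurface):
        return surface.vertices, surface.faces
    verts, faces = surface
    return np.asarray(verts, float), np.asarray(faces)


def triangulate_quads(vertices, faces):
    """Split quads along the shorter diagonal; triangles pass through.

    Returns (T, 3) triangle index array and the source face index of each
    triangle.  The shorter-diagonal rule is deterministic and preserves
    shape quality on near-planar quads.
    """
    V = np.asarray(vertices, float)
    lens = np.fromiter((len(f) for f in faces), int, count=len(faces))
    if np.any((lens != 3) & (lens != 4)):
        bad = int(lens[(lens != 3) & (lens != 4)][0])
        raise MeshConstructionError(f"face with {bad} vertices unsupported")
    out_tris = []
    out_src = []
    tri_ids = np.nonzero(lens == 3)[0]
    if len(tri_ids):
        out_tris.append(np.asarray([tuple(faces[i]) for i in tri_ids], int))
        out_src.append(tri_ids)
    quad_ids = np.nonzero(lens == 4)[0]
    if len(quad_ids):
        Q = np.asarray([tuple(faces[i]) for i in quad_ids], int)
        d02 = np.linalg.norm(V[Q[:, 0]] - V[Q[:, 2]], axis=1)
        d13 = np.linalg.norm(V[Q[:, 1]] - V[Q[:, 3]], axis=1)
        short02 = (d02 <= d13)[:, None]
        t1 = np.where(short02, Q[:, [0, 1, 2]], Q[:, [0, 1, 3]])
        t2 = np.where(short02, Q[:, [0, 2, 3]], Q[:, [1, 2, 3]])
        tris = np.empty((2 * len(Q), 3), int)
        tris[0::2] = t1
        tris[1::2] = t2
        out_tris.append(tris)
        out_src.append(np.repeat(quad_ids, 2))
    if not out_tris:
        return np.zeros((0, 3), int), np.zeros(0, int)
    return np.vstack(out_tris), np.concatenate(out_src)


def surface_triangles(surface, labels=None):
    """(verts, tris, tri_source_face) for any surface-like, optionally
    restricted to faces whose patch label is in ``labels``.

    For SubdividedSurface the triangulation indices are memoized on the
    control mesh (topology is shared across geometry updates).
    """
    verts, faces = _faces_of(surface)
    cache = None
    key = None
    ctrl = getattr(surface, "control", None)
    if isinstance(surface, SubdividedSurface) and ctrl is not None:
        if not hasattr(ctrl, "_tri_cache"):
            ctrl._tri_cache = {}
        cache = ctrl._tri_cache
        key = (len(faces), None if labels is None else tuple(sorted(
            [labels] if isinstance(labels, str) else list(labels))))
        if key in cache:
            tris, src = cache[key]
            return verts, tris, src
    if labels is not None:
        if isinstance(labels, str):
            labels = [labels]
        pl = getattr(surface, "patch_label", None)
        if pl is None:
            raise ValueError("surface carries no patch labels to filter on")
        keep = [i for i, l in enumerate(np.asarray(pl, dtype=object)) if str(l) in set(labels)]
        sel = [faces[i] for i in keep]
        tris, src = triangulate_quads(verts, sel)
        src = np.asarray([keep[s] for s in src], int)
    else:
        tris, src = triangulate_quads(verts, faces)
    if cache is not None:
        cache[key] = (tris, src)
    return verts, tris, src


def orient_consistently(faces):
    """Flip face windings so every interior edge is traversed in opposite
    directions by its two faces (consistent orientation), per connected
    component.  Returns a new face array; the global in/out choice per
    component is whatever the component's first face had."""
    faces = [list(f) for f in faces]
    edge_faces = {}
    for fi, f in enumerate(faces):
        n = len(f)
        for i in range(n):
            e = frozenset((f[i], f[(i + 1) % n]))
            edge_faces.setdefault(e, []).append(fi)
    visited = [False] * len(faces)
    for seed in range(len(faces)):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            f = faces[fi]
            n = len(f)
            directed = {(f[i], f[(i + 1) % n]) for i in range(n)}
            for i in range(n):
                e = frozenset((f[i], f[(i + 1) % n]))
                for gj in edge_faces[e]:
                    if gj == fi or visited[gj]:
                        continue
                    g = faces[gj]
                    m = len(g)
                    g_directed = {(g[k], g[(k + 1) % m]) for k in range(m)}
                    if directed & g_directed:  # same direction -> flip g
                        faces[gj] = g[::-1]
                    visited[gj] = True
                    stack.append(gj)
    return np.asarray([tuple(f) for f in faces], dtype=object if any(
        len(f) != len(faces[0]) for f in faces) else int)


# ---------------------------------------------------------------------------
# volume


def surface_volume(surface, labels=None) -> float:
    """Signed divergence-theorem volume of a closed oriented surface, mL.

    Quads are split along the shorter diagonal.  Raises
    :class:`OpenSurfaceError` naming the boundary edge count if the surface
    is not closed, and :class:`OrientationError` if the signed volume is
    negative (orientation should be flipped).
    """
    verts, tris, _ = surface_triangles(surface, labels)
    edges = np.sort(
        np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    n_boundary = int(np.sum(counts == 1))
    if n_boundary:
        raise OpenSurfaceError(f"surface is open: {n_boundary} boundary edges")
    a = verts[tris[:, 0]]
    b = verts[tris[:, 1]]
    c = verts[tris[:, 2]]
    vol_mm3 = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    if vol_mm3 < 0:
        raise OrientationError(
            f"signed volume {vol_mm3 / 1000.0:.3f} mL is negative; flip orientation"
        )
    return vol_mm3 / 1000.0


# ---------------------------------------------------------------------------
# exact closest point / distances


def _closest_on_tri_pairs(p, tri):
    """Closest point on triangle for paired arrays (Ericson's algorithm).

    p : (N, 3), tri : (N, 3, 3) -> (N, 3) closest points.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class _TriangleLocator:
    """Exact nearest-triangle queries via centroid KD-tree pruning.

    An upper bound from the k nearest centroids, plus the maximum
    centroid-to-corner radius, yields a provably sufficient candidate set.
    """

    def __init__(self, vertices, triangles):
        self.verts = np.asarray(vertices, float)
        self.tris = np.asarray(triangles, int)
        self.coords = self.verts[self.tris]  # (T, 3, 3)
        self.centroids = self.coords.mean(axis=1)
        self.radius = np.linalg.norm(
            self.coords - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.rmax = float(self.radius.max(initial=0.0))
        self.tree = cKDTree(self.centroids)

    def query(self, points):
        """Return (distances, closest points, triangle indices)."""
        P = np.atleast_2d(np.asarray(points, float))
        T = len(self.tris)
        k = min(8, T)
        _, idx = self.tree.query(P, k=k)
        idx = np.atleast_2d(idx.reshape(len(P), k))
        flat_p = np.repeat(P, k, axis=0)
        flat_t = self.coords[idx.ravel()]
        cp = _closest_on_tri_pairs(flat_p, flat_t)
        d = np.linalg.norm(cp - flat_p, axis=1).reshape(len(P), k)
        ub = d.min(axis=1)

        best_d = np.empty(len(P))
        best_cp = np.empty((len(P), 3))
        best_ti = np.empty(len(P), int)
        balls = self.tree.query_ball_point(P, ub + self.rmax + 1e-9)
        for i, cand in enumerate(balls):
            cand = np.asarray(cand, int)
            cps = _closest_on_tri_pairs(
                np.broadcast_to(P[i], (len(cand), 3)).copy(), self.coords[cand]
            )
            dd = np.linalg.norm(cps - P[i], axis=1)
            j = int(np.argmin(dd))
            best_d[i] = dd[j]
            best_cp[i] = cps[j]
            best_ti[i] = cand[j]
        return best_d, best_cp, best_ti


def closest_point_on_surface(points, surface, labels=None):
    """Exact closest points on a (label-restricted) triangulated surface.

    Returns ``(distances, closest_points, triangles, bary)`` where
    ``triangles`` is the (m, 3) vertex-index array of the triangulation hit
    by each point and ``bary`` the barycentric coordinates of each closest
    point in its triangle — the linear weights downstream fitting needs.
    """
    P = np.atleast_2d(np.asarray(points, float))
    if P.size == 0:
        return (np.zeros(0), np.zeros((0, 3)), np.zeros((0, 3), int), np.zeros((0, 3)))
    verts, tris, _ = surface_triangles(surface, labels)
    if len(tris) == 0:
        raise ValueError("surface has no faces (after label restriction)")
    loc = _TriangleLocator(verts, tris)
    d, cp, ti = loc.query(P)
    tri = tris[ti]
    bary = _barycentric(cp, verts[tri])
    return d, cp, tri, bary


def _barycentric(p, tri):
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0 = b - a
    v1 = c - a
    v2 = p - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, (d11 * d20 - d01 * d21) / denom, 0.0)
        w = np.where(denom != 0, (d00 * d21 - d01 * d20) / denom, 0.0)
    v = np.clip(v, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0 - v)
    u = 1.0 - v - w
    return np.stack([u, v, w], axis=1)


def point_to_surface(points, surface, labels=None):
    """Euclidean distance from each point to the nearest surface point, mm.

    ``labels`` restricts the computation to faces of the given patch
    labels, so each contour type is scored against its own surface.
    An empty point list yields an empty result.
    """
    P = np.atleast_2d(np.asarray(points, float))
    if P.size == 0:
        return np.zeros(0)
    d, _, _, _ = closest_point_on_surface(P, surface, labels)
    return d


# ---------------------------------------------------------------------------
# normals / offsets / caps


def vertex_normals(surface):
    """Area-weighted per-vertex normals (unit length).

    Face normals of the shorter-diagonal triangulation, weighted by
    triangle area, accumulated to the triangle's vertices.
    """
    verts, faces = _faces_of(surface)
    tris, _ = triangulate_quads(verts, faces)
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    fn = np.cross(b - a, c - a) / 2.0  # area-weighted
    normals = np.zeros_like(verts)
    for i in range(3):
        np.add.at(normals, tris[:, i], fn)
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    return normals / lens[:, None]


def offset_surface(surface, distance):
    """Move every vertex ``distance`` mm along its outward normal.

    Topology is unchanged.  Emits a warning (not an error) if the offset
    flips any face normal, the telltale of a self-intersecting result.
    """
    verts, faces = _faces_of(surface)
    n = vertex_normals(surface)
    new_verts = verts + distance * n
    tris, _ = triangulate_quads(verts, faces)
    fn_old = np.cross(verts[tris[:, 1]] - verts[tris[:, 0]], verts[tris[:, 2]] - verts[tris[:, 0]])
    fn_new = np.cross(
        new_verts[tris[:, 1]] - new_verts[tris[:, 0]],
        new_verts[tris[:, 2]] - new_verts[tris[:, 0]],
    )
    if np.any(np.einsum("ij,ij->i", fn_old, fn_new) < 0):
        warnings.warn("offset surface flipped face normals; result may self-intersect")
    if isinstance(surface, SubdividedSurface):
        return surface.with_vertices(new_verts)
    if isinstance(surface, PolySurface):
        return PolySurface(new_verts, faces, list(surface.patch_label))
    return new_verts, faces


def _ordered_boundary_loops(faces):
    """Directed boundary edges chained into closed loops."""
    directed = np.asarray(
        [(int(f[i]), int(f[(i + 1) % len(f)])) for f in faces for i in range(len(f))],
        int,
    )
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = [tuple(e) for e in directed[counts[inv] == 1]]
    nxt = {a: b for a, b in boundary}
    loops = []
    seen = set()
    for a, b in boundary:
        if a in seen:
            continue
        loop = [a]
        seen.add(a)
        cur = b
        while cur != a:
            loop.append(cur)
            seen.add(cur)
            if cur not in nxt:
                raise MeshConstructionError("boundary is not a set of closed loops")
            cur = nxt[cur]
        loops.append(loop)
    return loops


def cap_valves(surface, ring_tags=None):
    """Close tagged valve rings with planar triangle fans.

    Each tagged ring must be a single closed boundary loop; a new vertex is
    appended at the loop centroid and one triangle per boundary edge is
    fanned to it, oriented consistently with the surface (opposite to the
    directed boundary edges).  Returns a :class:`PolySurface`.  A surface
    with no tagged rings is returned unchanged (as PolySurface).
    """
    verts, faces = _faces_of(surface)
    ring_label = getattr(surface, "ring_label", {}) or {}
    if ring_tags is None:
        ring_tags = sorted(set(ring_label.values()))
    elif isinstance(ring_tags, str):
        ring_tags = [ring_tags]
    labels = list(getattr(surface, "patch_label", ["surface"] * len(faces)))
    if len(labels) != len(faces):
        labels = ["surface"] * len(faces)

    loops = _ordered_boundary_loops(faces)
    new_verts = list(np.asarray(verts, float))
    new_faces = list(faces)
    new_labels = list(labels)
    for tag in ring_tags:
        ring = set(v for v, t in ring_label.items() if t == tag)
        if not ring:
            raise MeshConstructionError(f"no vertices tagged {tag!r}")
        tag_loops = [lp for lp in loops if ring.issuperset(lp) and set(lp) & ring]
        # the loop must contain exactly the tagged ring
        tag_loops = [lp for lp in tag_loops if set(lp) == ring]
        if len(tag_loops) != 1:
            raise MeshConstructionError(
                f"ring {tag!r} is not a single closed boundary loop"
            )
        loop = tag_loops[0]
        centroid = np.mean([new_verts[v] for v in loop], axis=0)
        ci = len(new_verts)
        new_verts.append(centroid)
        for i in range(len(loop)):
            a, b = loop[i], loop[(i + 1) % len(loop)]
            # boundary directed edge is (a, b); cap triangle opposes it
            new_faces.append((b, a, ci))
            new_labels.append(f"cap_{tag}")
    return PolySurface(np.asarray(new_verts), new_faces, new_labels)


# ---------------------------------------------------------------------------
# IO: OBJ with JSON sidecar, legacy VTK


def write_obj(surface, path, sidecar=True):
    """Wavefront OBJ export, one object group per patch label; creases and
    ring tags persisted in a ``.json`` sidecar next to the OBJ."""
    path = Path(path)
    verts, faces = _faces_of(surface)
    labels = np.asarray(
        getattr(surface, "patch_label", ["surface"] * len(faces)), dtype=object
    )
    with open(path, "w") as fh:
        fh.write("# bivatlas surface export\n")
        for v in verts:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for lab in sorted(set(str(l) for l in labels)):
            fh.write(f"o {lab}\n")
            for f, l in zip(faces, labels):
                if str(l) == lab:
                    fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")
    if sidecar:
        meta = {
            "creases": sorted(sorted(e) for e in getattr(surface, "creases", set())),
            "ring_label": {str(k): v for k, v in (getattr(surface, "ring_label", {}) or {}).items()},
            "level": getattr(surface, "level", 0),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(meta, fh, indent=1)


def read_obj(path) -> ControlMesh:
    """Read a quad OBJ (+ sidecar) back into a ControlMesh."""
    path = Path(path)
    verts = []
    faces = []
    labels = []
    current = "surface"
    for line in open(path):
        t = line.split()
        if not t:
            continue
        if t[0] == "v":
            verts.append([float(x) for x in t[1:4]])
        elif t[0] == "o":
            current = t[1]
        elif t[0] == "f":
            faces.append([int(x.split("/")[0]) - 1 for x in t[1:]])
            labels.append(current)
    creases = set()
    rings = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.load(open(sidecar))
        creases = {frozenset(e) for e in meta.get("creases", [])}
        rings = {int(k): v for k, v in meta.get("ring_label", {}).items()}
    return ControlMesh(
        np.asarray(verts), np.asarray(faces, int), creases, np.asarray(labels, dtype=object), rings
    )


def write_vtk(surface, path):
    """Legacy ASCII VTK polydata export for visualization."""
    verts, faces = _faces_of(surface)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbivatlas surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} double\n")
        for v in verts:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        total = sum(len(f) + 1 for f in faces)
        fh.write(f"POLYGONS {len(faces)} {total}\n")
        for f in faces:
            fh.write(str(len(f)) + " " + " ".join(str(i) for i in f) + "\n")
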