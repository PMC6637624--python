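"""Synthetic biventricular geometry, populations and contour stacks.

Everything downstream of this module (slice correction, mesh fitting, the
shape atlas, morphometrics, risk models) is exercised against data whose
ground truth is known exactly:

* ``make_template`` builds a coarse labeled quad control mesh from paired
  analytic surfaces — a truncated prolate ellipsoid for the left ventricle
  (LV) endocardium and epicardium, and a crescent-shaped right ventricle
  (RV) formed by a second ellipsoidal sheet wrapping the septum.  Crease
  edges sit exactly at the four valve rings and the RV insertions.
* ``sample_population`` draws subjects with three planted modes of
  variation (overall size, end-systolic valve-plane excursion, and
  sphericity), optional binary risk factors with planted shape effects,
  and covariates (age, sex, height, weight) on the scale of an elderly
  population-imaging cohort.
* ``render_contours`` cuts each subject's true surfaces with a short-axis
  (SAX) stack and two long-axis (LAX) planes, samples labeled contour
  points, places valve landmarks on the valve rings in LAX planes, and
  degrades the result with per-slice breath-hold shifts and in-plane
  contour noise.

The ventricular systole (end-diastolic -> end-systolic reference shape) is
generated by rebuilding the template with contracted parameters, which
keeps the mesh topology identical across frames, thickens the LV wall at
end-systole and makes the valve plane descend toward the apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .contours import ContourSet, SlicePlane
from .mesh import (
    ControlMesh,
    MeshConstructionError,
    SubdividedSurface,
    cap_valves,
    catmull_clark,
    orient_consistently,
    surface_triangles,
    surface_volume,
)

__all__ = [
    "TemplateSpec",
    "PopulationSpec",
    "ImagingSpec",
    "FactorDef",
    "GroundTruthSubject",
    "Template",
    "make_template",
    "make_template_pair",
    "sample_population",
    "render_contours",
    "septal_shift_factor",
    "LABEL_PATCHES",
    "truncated_ellipsoid_volume_ml",
]

#: contour label -> surface patch labels it is scored against
LABEL_PATCHES = {
    "lv_endo": ("lv_endo",),
    "epi": ("epi",),
    "rv_endo": ("rv_septum", "rv_freewall"),
}

# fixed coarse resolution of the analytic template
_N_PHI = 20  # columns of the LV endo / epi tubes (6x6 grid caps)
_N_RINGS = 7  # tube rings, apex-cap boundary to base
_N_PSI = 16  # columns of the RV crescent tube (5x5 grid cap)
_N_RV_RINGS = 6
_THETA_CAP_DEG = 25.0  # polar angle covered by the apex grid cap


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class TemplateSpec:
    """Geometry of the analytic two-chamber template, all lengths in mm.

    ``lv_long_axis_mm`` is the full long axis (2a) of the LV endocardial
    ellipsoid; ``basal_truncation_fraction`` is the fraction of that axis
    kept below the basal (valve) plane.  ``rv_wrap_angle_deg`` is the
    angular extent of the septum the RV crescent wraps;
    ``rv_offset_mm`` the maximal free-wall-to-septum distance.
    ``valve_ring_radii_mm`` holds (mitral, tricuspid, aortic, pulmonary);
    a None entry means "as the analytic geometry dictates".
    """

    lv_long_axis_mm: float = 90.0
    lv_endo_radius_mm: float = 26.0
    lv_wall_mm: float = 10.0
    rv_wrap_angle_deg: float = 190.0
    rv_offset_mm: float = 34.0
    valve_ring_radii_mm: tuple = (None, None, 5.5, 5.0)
    basal_truncation_fraction: float = 0.85

    def validate(self):
        for name in ("lv_long_axis_mm", "lv_endo_radius_mm", "lv_wall_mm", "rv_offset_mm"):
            if getattr(self, name) <= 0:
                raise MeshConstructionError(f"{name} must be > 0")
        if not 90.0 < self.rv_wrap_angle_deg < 270.0:
            raise MeshConstructionError("rv_wrap_angle_deg must lie in (90, 270)")
        if not 0.5 < self.basal_truncation_fraction < 1.0:
            raise MeshConstructionError(
                "basal_truncation_fraction must lie in (0.5, 1)"
            )
        for r in self.valve_ring_radii_mm:
            if r is not None and r <= 0:
                raise MeshConstructionError("valve ring radii must be > 0")

    # derived quantities -----------------------------------------------
    @property
    def a(self):  # LV endo long semi-axis
        return self.lv_long_axis_mm / 2.0

    @property
    def z_cut(self):  # basal truncation plane height (apex at -a)
        return self.a * (2.0 * self.basal_truncation_fraction - 1.0)


@dataclass(frozen=True)
class FactorDef:
    """A binary risk factor with a planted shape effect.

    ``effect``: added to the subject's (size, excursion, sphericity) mode
    coefficients when positive.  ``covariate_dependence``: logit slopes on
    standardized (age, sex, height, weight).  ``shape_effect``: optional
    named direct displacement field ('septal_shift') of amplitude
    ``shape_effect_mm`` applied to positives.
    """

    name: str
    prevalence: float
    effect: tuple = (0.0, 0.0, 0.0)
    covariate_dependence: tuple = (0.0, 0.0, 0.0, 0.0)
    shape_effect: str | None = None
    shape_effect_mm: float = 0.0

    def validate(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence of {self.name!r} must be in [0, 1]")


def septal_shift_factor(prevalence=0.3, magnitude_mm=3.0, name="septal_shift"):
    """Volume-preserving preset: the septum is displaced toward the RV with
    compensating free-wall displacement holding both cavity volumes fixed.
    Invisible to mass/volume measures but visible to shape features."""
    return FactorDef(
        name=name,
        prevalence=prevalence,
        effect=(0.0, 0.0, 0.0),
        shape_effect="septal_shift",
        shape_effect_mm=magnitude_mm,
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Synthetic cohort recipe.

    ``mode_sds`` are the standard deviations of the three planted modes:
    log size scale (unitless), end-systolic valve-plane excursion (mm),
    log sphericity ratio (unitless).  ``shift_sd_mm`` is the per-slice
    in-plane breath-hold shift SD and ``noise_sd_mm`` the isotropic
    in-plane contour point noise SD.  ``seed`` fixes every draw.
    """

    n_subjects: int = 100
    seed: int = 0
    mode_sds: tuple = (0.06, 2.0, 0.05)
    factor_defs: tuple = ()
    shift_sd_mm: float = 2.5
    noise_sd_mm: float = 1.0
    covariate_shape_coupling: bool = True

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s < 0 for s in self.mode_sds):
            raise ValueError("mode_sds must be >= 0")
        if self.shift_sd_mm < 0 or self.noise_sd_mm < 0:
            raise ValueError("noise/shift SDs must be >= 0")
        for f in self.factor_defs:
            _as_factor(f).validate()


def _as_factor(f) -> FactorDef:
    if isinstance(f, FactorDef):
        return f
    return FactorDef(*f)


@dataclass(frozen=True)
class ImagingSpec:
    """Emulated acquisition geometry: SAX stack spacing/thickness follows a
    typical cine CMR protocol (8 mm short-axis slices); two LAX views
    (2-chamber and 4-chamber) are prescribed.  The LV outflow tract view is
    not emulated."""

    sax_spacing_mm: float = 8.0
    sax_thickness_mm: float = 8.0
    lax_thickness_mm: float = 6.0
    points_per_contour: int = 40
    extent_margin_mm: float = 1.0  # keeps planes off tangent degeneracies


@dataclass
class GroundTruthSubject:
    """One synthetic subject with full ground truth."""

    id: str
    control_ed: np.ndarray  # deformed control vertices, ED
    control_es: np.ndarray
    true_surface_ed: SubdividedSurface
    true_surface_es: SubdividedSurface
    factors: dict
    covariates: dict  # age_yr, sex (1=male), height_cm, weight_kg
    mode_coefficients: np.ndarray
    true_shifts: np.ndarray  # (n_sax_slices, 2) mm, shared by ED and ES
    sax_z: np.ndarray
    noise_sd_mm: float
    rng_seed: int


# ---------------------------------------------------------------------------
# template construction helpers


def _coons_interior(boundary_grid):
    """Fill the interior of an n x n grid whose perimeter is given, by
    transfinite (Coons) interpolation.  ``boundary_grid`` is an (n, n, 3)
    array with only the perimeter entries meaningful."""
    g = boundary_grid.copy()
    n = g.shape[0]
    for i in range(1, n - 1):
        u = i / (n - 1)
        for j in range(1, n - 1):
            v = j / (n - 1)
            g[i, j] = (
                (1 - u) * g[0, j]
                + u * g[n - 1, j]
                + (1 - v) * g[i, 0]
                + v * g[i, n - 1]
                - (1 - u) * (1 - v) * g[0, 0]
                - (1 - u) * v * g[0, n - 1]
                - u * (1 - v) * g[n - 1, 0]
                - u * v * g[n - 1, n - 1]
            )
    return g


def _grid_perimeter(n):
    """Perimeter (i, j) indices of an n x n grid in ring order."""
    idx = []
    idx += [(0, j) for j in range(n)]
    idx += [(i, n - 1) for i in range(1, n)]
    idx += [(n - 1, j) for j in range(n - 2, -1, -1)]
    idx += [(i, 0) for i in range(n - 2, 0, -1)]
    return idx


def _grid_cap(ring_points, n, project=None):
    """Quad-grid cap over a closed ring of 2*(n-1)*2 ... of len 4(n-1)
    points.  Returns (interior_vertices, faces_local) where faces index
    ring positions 0..len(ring)-1 first, then interior vertices."""
    ring_points = np.asarray(ring_points, float)
    m = len(ring_points)
    assert m == 4 * (n - 1), "ring length must match grid perimeter"
    grid = np.zeros((n, n, 3))
    per = _grid_perimeter(n)
    for k, (i, j) in enumerate(per):
        grid[i, j] = ring_points[k]
    grid = _coons_interior(grid)
    if project is not None:
        for i in range(1, n - 1):
            for j in range(1, n - 1):
                grid[i, j] = project(grid[i, j])
    # local vertex ids: ring positions then interior (row-major)
    vid = {}
    for k, (i, j) in enumerate(per):
        vid[(i, j)] = k
    interior = []
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            vid[(i, j)] = m + len(interior)
            interior.append(grid[i, j])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            faces.append(
                (vid[(i, j)], vid[(i + 1, j)], vid[(i + 1, j + 1)], vid[(i, j + 1)])
            )
    return np.asarray(interior), faces, vid


def _ellipsoid_tube(a, r, z_cut, n_phi, n_rings, theta_cap_deg):
    """Open ellipsoid-of-revolution tube from the apex-cap boundary ring to
    the basal plane, plus a grid cap over the apex.  Returns vertices,
    faces, the column-major ring index table and the top ring indices."""
    theta_base = math.acos(max(-1.0, min(1.0, -z_cut / a)))
    theta = np.linspace(math.radians(theta_cap_deg), theta_base, n_rings)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    rings = np.zeros((n_rings, n_phi, 3))
    for j, th in enumerate(theta):
        rings[j, :, 0] = r * math.sin(th) * np.cos(phi)
        rings[j, :, 1] = r * math.sin(th) * np.sin(phi)
        rings[j, :, 2] = -a * math.cos(th)
    verts = rings.reshape(-1, 3)
    idx = np.arange(n_rings * n_phi).reshape(n_rings, n_phi)
    faces = []
    for j in range(n_rings - 1):
        for i in range(n_phi):
            faces.append(
                (idx[j, i], idx[j, (i + 1) % n_phi], idx[j + 1, (i + 1) % n_phi], idx[j + 1, i])
            )

    def project(p):
        rad2 = p[0] ** 2 + p[1] ** 2
        z = -a * math.sqrt(max(0.0, 1.0 - rad2 / r**2))
        return np.array([p[0], p[1], z])

    n_grid = n_phi // 4 + 1
    cap_interior, cap_faces, _ = _grid_cap(rings[0], n_grid, project)
    base = len(verts)
    verts = np.vstack([verts, cap_interior])
    ring0 = idx[0]
    for f in cap_faces:
        faces.append(tuple(ring0[k] if k < n_phi else base + (k - n_phi) for k in f))
    return verts, faces, idx


def _rv_radius_profile(s, offset):
    """Free-wall bulge amplitude along the normalized long axis (0 at the
    RV apex end, 1 at the tricuspid ring)."""
    return offset * (0.35 + 0.65 * np.sqrt(np.clip(s, 0.0, 1.0)))


def _rv_ring(z, rho, d, wrap_rad):
    """One crescent ring of _N_PSI points: columns 0..8 trace the free
    wall from insertion to insertion, columns 9..15 the septal arc back."""
    pts = np.zeros((_N_PSI, 3))
    for c in range(9):
        t = c / 8.0
        ph = -wrap_rad / 2 + t * wrap_rad
        rad = rho + d * math.sin(math.pi * t)
        pts[c] = (rad * math.cos(ph), rad * math.sin(ph), z)
    for k in range(1, 8):
        ph = wrap_rad / 2 - k * wrap_rad / 8
        pts[8 + k] = (rho * math.cos(ph), rho * math.sin(ph), z)
    return pts


def _build_rv(spec: TemplateSpec):
    a_e = spec.a + spec.lv_wall_mm
    r_e = spec.lv_endo_radius_mm + spec.lv_wall_mm
    wrap = math.radians(spec.rv_wrap_angle_deg)
    z_b = -0.55 * spec.a
    z_t = spec.z_cut
    s = np.linspace(0.0, 1.0, _N_RV_RINGS)
    zs = z_b + s * (z_t - z_b)
    rings = []
    for sj, z in zip(s, zs):
        rho = r_e * math.sqrt(max(0.0, 1.0 - z**2 / a_e**2))
        d = _rv_radius_profile(sj, spec.rv_offset_mm)
        rings.append(_rv_ring(z, rho, d, wrap))
    rings = np.asarray(rings)
    verts = rings.reshape(-1, 3)
    idx = np.arange(_N_RV_RINGS * _N_PSI).reshape(_N_RV_RINGS, _N_PSI)
    faces = []
    labels = []
    for j in range(_N_RV_RINGS - 1):
        for i in range(_N_PSI):
            faces.append(
                (idx[j, i], idx[j, (i + 1) % _N_PSI], idx[j + 1, (i + 1) % _N_PSI], idx[j + 1, i])
            )
            labels.append("rv_septum" if i >= 8 else "rv_freewall")
    cap_interior, cap_faces, _ = _grid_cap(rings[0], _N_PSI // 4 + 1)
    base = len(verts)
    verts = np.vstack([verts, cap_interior])
    ring0 = idx[0]
    for f in cap_faces:
        faces.append(tuple(ring0[k] if k < _N_PSI else base + (k - _N_PSI) for k in f))
        labels.append("rv_freewall")
    creases = set()
    for col in (0, 8):  # RV insertions
        for j in range(_N_RV_RINGS - 1):
            creases.add(frozenset((int(idx[j, col]), int(idx[j + 1, col]))))
    tricuspid = [int(v) for v in idx[-1]]
    for i in range(_N_PSI):
        creases.add(frozenset((tricuspid[i], tricuspid[(i + 1) % _N_PSI])))
    # per-vertex column bookkeeping for the septal-shift displacement field
    col_of = {int(idx[j, i]): i for j in range(_N_RV_RINGS) for i in range(_N_PSI)}
    return verts, faces, labels, creases, tricuspid, col_of


def make_template(spec: TemplateSpec | None = None) -> ControlMesh:
    """Construct the coarse biventricular control mesh.

    Three labeled surface layers (LV endocardium, RV endocardium split into
    septal and free-wall patches, epicardium with a basal valve-plane
    roof), crease edges exactly at the four valve rings and RV insertions,
    and the aortic/pulmonary rings realized as small creased holes in the
    roof.  The mitral and tricuspid rings are the open basal boundaries of
    the endocardial layers.
    """
    spec = spec or TemplateSpec()
    spec.validate()
    a, r, w = spec.a, spec.lv_endo_radius_mm, spec.lv_wall_mm
    zc = spec.z_cut
    if spec.rv_offset_mm >= 2 * r:
        raise MeshConstructionError("rv_offset_mm too large: RV would engulf the LV")

    all_verts = []
    all_faces = []
    all_labels = []
    creases = set()
    rings = {}

    def add_component(verts, faces, labels):
        off = sum(len(v) for v in all_verts)
        all_verts.append(np.asarray(verts, float))
        all_faces.extend(tuple(int(x) + off for x in f) for f in faces)
        all_labels.extend(labels)
        return off

    # LV endocardium ------------------------------------------------------
    lv_verts, lv_faces, lv_idx = _ellipsoid_tube(a, r, zc, _N_PHI, _N_RINGS, _THETA_CAP_DEG)
    mit_r = spec.valve_ring_radii_mm[0]
    if mit_r is not None:  # scale the basal ring in-plane to the target radius
        top = lv_idx[-1]
        cur = float(np.hypot(*lv_verts[top[0], :2]))
        lv_verts[top, :2] *= mit_r / cur
    off_lv = add_component(lv_verts, lv_faces, ["lv_endo"] * len(lv_faces))
    mitral = [int(v) + off_lv for v in lv_idx[-1]]
    for i in range(_N_PHI):
        creases.add(frozenset((mitral[i], mitral[(i + 1) % _N_PHI])))
    rings.update({v: "mitral" for v in mitral})

    # epicardium with valve-plane roof ------------------------------------
    ep_verts, ep_faces, ep_idx = _ellipsoid_tube(
        a + w, r + w, zc, _N_PHI, _N_RINGS, _THETA_CAP_DEG
    )
    ep_labels = ["epi"] * len(ep_faces)
    # roof: 6x6 grid over the basal opening, two quads removed as the
    # aortic and pulmonary orifices
    n_grid = _N_PHI // 4 + 1
    top_ring = ep_verts[ep_idx[-1]]
    roof_interior, roof_faces, vid = _grid_cap(top_ring, n_grid)
    roof_interior = roof_interior.copy()
    roof_interior[:, 2] = zc  # keep the roof planar at the valve plane
    hole_a = [(1, 1), (2, 1), (2, 2), (1, 2)]  # aortic orifice quad
    hole_b = [(3, 3), (4, 3), (4, 4), (3, 4)]  # pulmonary orifice quad
    r_ao = spec.valve_ring_radii_mm[2] or 5.5
    r_pu = spec.valve_ring_radii_mm[3] or 5.0
    for hole, rad in ((hole_a, r_ao), (hole_b, r_pu)):
        ids = [vid[ij] - _N_PHI for ij in hole]  # interior-local ids
        centre = roof_interior[ids].mean(axis=0)
        ang = np.radians([225, 315, 45, 135])
        for k, i in enumerate(ids):
            roof_interior[i] = centre + rad * np.array(
                [math.cos(ang[k]), math.sin(ang[k]), 0.0]
            )
    drop = {tuple(sorted(vid[ij] for ij in hole_a)), tuple(sorted(vid[ij] for ij in hole_b))}
    base_local = len(ep_verts)
    ep_verts = np.vstack([ep_verts, roof_interior])
    ring_top = ep_idx[-1]
    for f in roof_faces:
        if tuple(sorted(f)) in drop:
            continue
        ep_faces.append(
            tuple(ring_top[k] if k < _N_PHI else base_local + (k - _N_PHI) for k in f)
        )
        ep_labels.append("valve_plane")
    off_ep = add_component(ep_verts, ep_faces, ep_labels)
    aortic = [vid[ij] for ij in hole_a]
    pulmonary = [vid[ij] for ij in hole_b]

    def roof_global(k):
        return off_ep + (ring_top[k] if k < _N_PHI else base_local + (k - _N_PHI))

    aortic = [roof_global(k) for k in aortic]
    pulmonary = [roof_global(k) for k in pulmonary]
    for loop, tag in ((aortic, "aortic"), (pulmonary, "pulmonary")):
        for i in range(4):
            creases.add(frozenset((loop[i], loop[(i + 1) % 4])))
        rings.update({v: tag for v in loop})

    # RV crescent ----------------------------------------------------------
    rv_verts, rv_faces, rv_labels, rv_creases, tricuspid, rv_cols = _build_rv(spec)
    tri_r = spec.valve_ring_radii_mm[1]
    if tri_r is not None:  # scale the tricuspid ring about its centroid
        ring_pts = rv_verts[tricuspid]
        c = ring_pts.mean(axis=0)
        half = 0.5 * max(
            np.ptp(ring_pts[:, 0]), np.ptp(ring_pts[:, 1])
        )
        rv_verts[tricuspid, :2] = c[:2] + (ring_pts[:, :2] - c[:2]) * (tri_r / half)
    off_rv = add_component(rv_verts, rv_faces, rv_labels)
    creases |= {frozenset(int(v) + off_rv for v in e) for e in rv_creases}
    rings.update({int(v) + off_rv: "tricuspid" for v in tricuspid})

    verts = np.vstack(all_verts)
    faces = orient_consistently(all_faces)
    mesh = ControlMesh(
        verts,
        np.asarray(faces, int),
        creases=creases,
        patch_label=np.asarray(all_labels, dtype=object),
        ring_label=rings,
    )
    _fix_outward_orientation(mesh)
    # bookkeeping used by downstream stages
    mesh.meta = {
        "spec": spec,
        "rv_cols": {v + off_rv: c for v, c in rv_cols.items()},
        "rv_vertex_range": (off_rv, off_rv + len(rv_verts)),
        "lv_vertex_range": (off_lv, off_lv + len(lv_verts)),
        "epi_vertex_range": (off_ep, off_ep + len(ep_verts)),
    }
    mesh.meta["lv_apex_vertex"] = _farthest_from(mesh, range(*mesh.meta["lv_vertex_range"]), mitral)
    mesh.meta["rv_apex_vertex"] = _farthest_from(
        mesh, range(*mesh.meta["rv_vertex_range"]), [v + off_rv for v in tricuspid]
    )
    return mesh


def _farthest_from(mesh, vertex_range, ring):
    """Vertex of the range farthest from the ring centroid along the
    centroid-to-component long axis (the apex definition)."""
    ids = np.asarray(list(vertex_range), int)
    c_ring = mesh.vertices[np.asarray(ring, int)].mean(axis=0)
    c_comp = mesh.vertices[ids].mean(axis=0)
    axis = c_comp - c_ring
    axis = axis / np.linalg.norm(axis)
    proj = (mesh.vertices[ids] - c_ring) @ axis
    return int(ids[np.argmax(proj)])


def _fix_outward_orientation(mesh: ControlMesh):
    """Flip each connected component so its capped volume is positive."""
    comp_faces = _components(mesh.faces)
    new_faces = mesh.faces.copy()
    for fids in comp_faces:
        sub = mesh.faces[fids]
        used = sorted(set(int(v) for f in sub for v in f))
        remap = {v: i for i, v in enumerate(used)}
        local = np.asarray([[remap[int(v)] for v in f] for f in sub], int)
        lverts = mesh.vertices[used]
        rl = {remap[v]: t for v, t in mesh.ring_label.items() if v in remap}
        from .mesh import PolySurface

        surf = PolySurface(lverts, [tuple(f) for f in local])
        surf.ring_label = rl
        capped = cap_valves(surf)
        a = capped.vertices
        tris, _ = _tri(capped)
        vol = np.einsum(
            "ij,ij->i", a[tris[:, 0]], np.cross(a[tris[:, 1]], a[tris[:, 2]])
        ).sum()
        if vol < 0:
            new_faces[fids] = sub[:, ::-1]
    mesh.faces = new_faces


def _tri(surface):
    from .mesh import triangulate_quads

    return triangulate_quads(surface.vertices, surface.faces)


def _components(faces):
    """Face index groups of connected components (shared-vertex)."""
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for f in faces:
        for v in f[1:]:
            union(int(f[0]), int(v))
    groups = {}
    for fi, f in enumerate(faces):
        groups.setdefault(find(int(f[0])), []).append(fi)
    return [np.asarray(g, int) for g in groups.values()]


# ---------------------------------------------------------------------------
# the ED/ES template pair


def _es_spec(spec: TemplateSpec) -> TemplateSpec:
    """End-systolic template parameters: radial and longitudinal
    contraction with wall thickening that conserves mid-wall myocardial
    cross-section, and a mildly contracted RV."""
    s_endo, s_long, s_rv = 0.70, 0.85, 0.74
    r_es = spec.lv_endo_radius_mm * s_endo
    r_epi = spec.lv_endo_radius_mm + spec.lv_wall_mm
    r_epi_es = math.sqrt(r_epi**2 - spec.lv_endo_radius_mm**2 + r_es**2)
    radii = list(spec.valve_ring_radii_mm)
    radii = [
        None if radii[0] is None else radii[0] * 0.92,
        None if radii[1] is None else radii[1] * 0.92,
        (radii[2] or 5.5) * 0.95,
        (radii[3] or 5.0) * 0.95,
    ]
    return replace(
        spec,
        lv_long_axis_mm=spec.lv_long_axis_mm * s_long,
        lv_endo_radius_mm=r_es,
        lv_wall_mm=r_epi_es - r_es,
        rv_offset_mm=spec.rv_offset_mm * s_rv,
        valve_ring_radii_mm=tuple(radii),
    )


@dataclass
class Template:
    """The deformable model: ED and ES control meshes on identical
    topology, their level-``level`` subdivisions, apex bookkeeping and the
    endo-epi clearance pairing used by constrained refinement."""

    spec: TemplateSpec
    es_spec: TemplateSpec
    control_ed: ControlMesh
    control_es: ControlMesh
    surface_ed: SubdividedSurface
    surface_es: SubdividedSurface
    level: int = 2

    def control(self, frame):
        return self.control_ed if frame == "ed" else self.control_es

    def surface(self, frame):
        return self.surface_ed if frame == "ed" else self.surface_es

    @property
    def meta(self):
        return self.control_ed.meta

    def subdiv_apex(self, which="rv"):
        cv = self.meta[f"{which}_apex_vertex"]
        return int(self.surface_ed.control_vertex_map[cv])

    def clearance_pairs(self):
        """(lv_endo subdiv ids, epi subdiv ids) nearest-neighbour pairing
        on the ED template, mitral ring excluded."""
        if not hasattr(self, "_pairs"):
            s = self.surface_ed
            lv_ids = _patch_vertex_ids(s, ("lv_endo",))
            lv_ids = np.asarray(
                [i for i in lv_ids if s.ring_label.get(i) != "mitral"], int
            )
            epi_ids = _patch_vertex_ids(s, ("epi",))
            from scipy.spatial import cKDTree

            tree = cKDTree(s.vertices[epi_ids])
            _, j = tree.query(s.vertices[lv_ids])
            self._pairs = (lv_ids, epi_ids[j])
        return self._pairs


def _patch_vertex_ids(surface, labels):
    mask = np.isin(surface.patch_label.astype(str), list(labels))
    return np.unique(surface.faces[mask])


def make_template_pair(spec: TemplateSpec | None = None, level: int = 2) -> Template:
    spec = spec or TemplateSpec()
    es = _es_spec(spec)
    ctrl_ed = make_template(spec)
    ctrl_es = make_template(es)
    # align the ES apex with the ED apex so the base descends (valve-plane
    # excursion), as in systole
    dz = -(spec.a - es.a)
    ctrl_es.vertices = ctrl_es.vertices + np.array([0.0, 0.0, dz])
    surf_ed = catmull_clark(ctrl_ed, level)
    surf_es = catmull_clark(ctrl_es, level)
    return Template(spec, es, ctrl_ed, ctrl_es, surf_ed, surf_es, level)


# ---------------------------------------------------------------------------
# analytic oracle


def truncated_ellipsoid_volume_ml(long_axis_mm, radius_mm, truncation_fraction):
    """Closed-form volume of a prolate ellipsoid truncated at the basal
    plane: V = pi r^2 * integral_{-a}^{zc} (1 - z^2/a^2) dz, in mL."""
    a = long_axis_mm / 2.0
    zc = a * (2.0 * truncation_fraction - 1.0)

    def anti(z):
        return z - z**3 / (3 * a**2)

    return math.pi * radius_mm**2 * (anti(zc) - anti(-a)) / 1000.0


# ---------------------------------------------------------------------------
# septal-shift displacement field


def _bump(x, centre, half_width):
    d = np.angle(np.exp(1j * (x - centre)))  # wrapped difference
    out = np.zeros_like(d)
    m = np.abs(d) < half_width
    out[m] = np.cos(0.5 * np.pi * d[m] / half_width) ** 2
    return out


def septal_shift_fields(template: Template):
    """Unit (per mm of septal displacement) control-vertex displacement
    fields (ED, ES) for the volume-preserving septal-shift effect.

    The septum (and the coincident RV septal sheet) moves toward the RV;
    the LV free wall moves inward with an amplitude root-found so the LV
    cavity volume is unchanged; the RV free wall moves inward and bulges
    laterally with a lateral amplitude root-found so the RV cavity volume
    is unchanged.  Calibrated at a 3 mm reference displacement.
    """
    if hasattr(template, "_septal_fields"):
        return template._septal_fields
    out = {}
    for frame in ("ed", "es"):
        ctrl = template.control(frame)
        spec = template.spec if frame == "ed" else template.es_spec
        out[frame] = _septal_field_for(ctrl, spec, template, frame)
    template._septal_fields = (out["ed"], out["es"])
    return template._septal_fields


def _septal_field_for(ctrl: ControlMesh, spec: TemplateSpec, template, frame):
    meta = template.meta
    wrap = math.radians(spec.rv_wrap_angle_deg)
    V = ctrl.vertices
    z = V[:, 2]
    z_lo, z_hi = z.min(), z.max()
    s = np.clip((z - z_lo) / (z_hi - z_lo), 0, 1)
    bz = np.sin(np.pi * s) ** 2
    phi = np.arctan2(V[:, 1], V[:, 0])

    lv_lo, lv_hi = meta["lv_vertex_range"]
    ep_lo, ep_hi = meta["epi_vertex_range"]
    rv_lo, rv_hi = meta["rv_vertex_range"]
    rv_cols = meta["rv_cols"]

    sept = np.zeros((len(V), 3))
    free = np.zeros((len(V), 3))
    rv_lat = np.zeros((len(V), 3))
    wall_ids = np.r_[np.arange(lv_lo, lv_hi), np.arange(ep_lo, ep_hi)]
    sept[wall_ids, 0] = _bump(phi[wall_ids], 0.0, wrap / 2) * bz[wall_ids]
    free[wall_ids, 0] = _bump(phi[wall_ids], math.pi, wrap / 2) * bz[wall_ids]
    for v in range(rv_lo, rv_hi):
        col = rv_cols.get(v)
        if col is None or col in (0, 8) or col > 8:  # septal arc + insertions
            sept[v, 0] = _bump(np.array([phi[v]]), 0.0, wrap / 2)[0] * bz[v]
        else:  # free-wall arc: partial follow + lateral bulge
            t = col / 8.0
            wgt = math.sin(math.pi * t) * bz[v]
            sept[v, 0] = 0.5 * wgt
            rv_lat[v, 1] = np.sign(V[v, 1]) * wgt

    surf = template.surface_ed if frame == "ed" else template.surface_es
    delta = 3.0  # calibration amplitude, mm

    def lv_vol(alpha):
        disp = delta * (sept + alpha * free)
        s2 = surf.with_control_vertices(V + disp)
        return surface_volume(cap_valves(_label_sub(s2, ("lv_endo",)), "mitral"))

    base_lv = surface_volume(
        cap_valves(_label_sub(surf.with_control_vertices(V), ("lv_endo",)), "mitral")
    )
    alpha = scipy.optimize.brentq(lambda a_: lv_vol(a_) - base_lv, 0.0, 4.0, xtol=1e-6)

    def rv_vol(gamma):
        disp = delta * (sept + alpha * free + gamma * rv_lat)
        s2 = surf.with_control_vertices(V + disp)
        return surface_volume(
            cap_valves(_label_sub(s2, ("rv_septum", "rv_freewall")), "tricuspid")
        )

    base_rv = surface_volume(
        cap_valves(
            _label_sub(surf.with_control_vertices(V), ("rv_septum", "rv_freewall")),
            "tricuspid",
        )
    )
    gamma = scipy.optimize.brentq(lambda g: rv_vol(g) - base_rv, 0.0, 6.0, xtol=1e-6)
    return sept + alpha * free + gamma * rv_lat


def _label_sub(surface: SubdividedSurface, labels):
    """Label-restricted PolySurface that keeps ring tags (for capping)."""
    from .mesh import PolySurface

    mask = np.isin(surface.patch_label.astype(str), list(labels))
    faces = [tuple(f) for f in surface.faces[mask]]
    ps = PolySurface(surface.vertices, faces, ["x"] * len(faces))
    ps.ring_label = surface.ring_label
    return ps


# ---------------------------------------------------------------------------
# population sampling


def _covariates(rng):
    age = rng.normal(62.0, 7.5)
    sex = 1.0 if rng.random() < 0.48 else 0.0
    height = rng.normal(170.0, 9.0)
    weight = rng.normal(76.0, 15.0)
    return {"age_yr": age, "sex": sex, "height_cm": height, "weight_kg": weight}


def _cov_standardized(cov):
    return np.array(
        [
            (cov["age_yr"] - 62.0) / 7.5,
            cov["sex"],
            (cov["height_cm"] - 170.0) / 9.0,
            (cov["weight_kg"] - 76.0) / 15.0,
        ]
    )


def _sax_grid(template_like_surfaces, imaging: ImagingSpec):
    zs = np.concatenate([s.vertices[:, 2] for s in template_like_surfaces])
    z_bot = zs.min() + imaging.extent_margin_mm
    z_top = zs.max() - imaging.extent_margin_mm
    extent = z_top - z_bot
    n = int(math.floor(extent / imaging.sax_spacing_mm)) + 1
    return z_bot + imaging.sax_spacing_mm * np.arange(n), extent


def sample_population(template: Template, spec: PopulationSpec, imaging: ImagingSpec | None = None):
    """Draw a deterministic synthetic cohort.

    Subject shapes are the template's control meshes deformed by the three
    planted modes (size, ES valve-plane excursion, sphericity), by factor
    effects over those modes, and — for factors declaring the
    ``septal_shift`` shape effect — by the volume-preserving septal
    displacement field.  Subjects with every factor negative form the
    reference (healthy) pool.
    """
    spec.validate()
    imaging = imaging or ImagingSpec()
    factors = [_as_factor(f) for f in spec.factor_defs]
    need_septal = any(f.shape_effect == "septal_shift" for f in factors)
    if need_septal:
        U_ed, U_es = septal_shift_fields(template)

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_subjects)
    apex = np.array([0.0, 0.0, -template.spec.a])
    z_ap = -template.spec.a
    z_base = template.control_es.vertices[:, 2].max()

    subjects = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        cov = _covariates(rng)
        c = rng.normal(0.0, np.asarray(spec.mode_sds))
        if spec.covariate_shape_coupling:
            c[0] += (
                0.05 * (cov["sex"] - 0.48)
                + 0.003 * (cov["height_cm"] - 170.0)
                - 0.0015 * (cov["age_yr"] - 62.0)
            )
        fstate = {}
        septal_mm = 0.0
        for f in factors:
            logit = math.log(f.prevalence / (1 - f.prevalence)) if 0 < f.prevalence < 1 else (
                math.inf if f.prevalence >= 1 else -math.inf
            )
            logit += float(np.dot(f.covariate_dependence, _cov_standardized(cov)))
            pos = rng.random() < 1.0 / (1.0 + math.exp(-logit))
            fstate[f.name] = int(pos)
            if pos:
                c = c + np.asarray(f.effect, float)
                if f.shape_effect == "septal_shift":
                    septal_mm += f.shape_effect_mm

        ed = template.control_ed.vertices.copy()
        es = template.control_es.vertices.copy()
        if septal_mm:
            ed = ed + septal_mm * U_ed
            es = es + septal_mm * U_es
        # ES valve-plane excursion: extra basal descent, apex pinned
        wgt = np.clip((es[:, 2] - z_ap) / (z_base - z_ap), 0.0, 1.0)
        es[:, 2] -= c[1] * wgt
        # sphericity: rounder (+) or more elongated (-), about the apex
        for arr in (ed, es):
            arr[:, :2] *= math.exp(c[2])
            arr[:, 2] = apex[2] + (arr[:, 2] - apex[2]) * math.exp(-c[2])
        # size
        for arr in (ed, es):
            arr[:] = apex + math.exp(c[0]) * (arr - apex)

        t_ed = template.surface_ed.with_control_vertices(ed)
        t_es = template.surface_es.with_control_vertices(es)
        sax_z, _ = _sax_grid([t_ed], imaging)
        shifts = rng.normal(0.0, spec.shift_sd_mm, (len(sax_z), 2))
        subjects.append(
            GroundTruthSubject(
                id=f"S{i:04d}",
                control_ed=ed,
                control_es=es,
                true_surface_ed=t_ed,
                true_surface_es=t_es,
                factors=fstate,
                covariates=cov,
                mode_coefficients=c,
                true_shifts=shifts,
                sax_z=sax_z,
                noise_sd_mm=spec.noise_sd_mm,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# contour rendering


def _section_loops(surface, labels, origin, normal):
    """Ordered intersection polylines of a label-restricted surface with a
    plane.  Returns a list of (closed, (k, 3) points)."""
    import trimesh

    verts, tris, _ = surface_triangles(surface, labels)
    tm = trimesh.Trimesh(vertices=verts, faces=tris, process=False)
    try:
        path = tm.section(plane_origin=origin, plane_normal=normal)
    except Exception:
        path = None
    if path is None:
        return []
    out = []
    # Path3D.discrete only reports closed cycles; iterate entities so open
    # long-axis cross-sections are kept too
    for ent in path.entities:
        pts = np.asarray(ent.discrete(path.vertices), float)
        closed = np.allclose(pts[0], pts[-1], atol=1e-9)
        if closed:
            pts = pts[:-1]
        if len(pts) >= 2:
            out.append((closed, pts))
    return out


def _resample(points, n, closed):
    """Arclength-uniform resampling of a polyline/polygon."""
    pts = np.asarray(points, float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        return np.repeat(pts[:1], n, axis=0)
    if closed:
        ti = total * np.arange(n) / n
    else:
        ti = total * np.arange(n) / (n - 1)
    out = np.empty((n, pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(ti, t, pts[:, d])
    return out


def _ring_loop_points(surface: SubdividedSurface, tag):
    """Ordered 3D polyline of a subdivided valve ring."""
    ring = set(surface.ring_vertices(tag))
    from .mesh import _ordered_boundary_loops

    loops = _ordered_boundary_loops([tuple(f) for f in surface.faces])
    for lp in loops:
        if set(lp) == ring:
            return surface.vertices[np.asarray(lp, int)]
    raise MeshConstructionError(f"ring {tag!r} is not a boundary loop")


def _ring_plane_crossings(ring_pts, origin, normal):
    """Intersection points of a closed ring polyline with a plane."""
    d = (ring_pts - origin) @ normal
    out = []
    n = len(ring_pts)
    for i in range(n):
        a, b = d[i], d[(i + 1) % n]
        if a == 0.0:
            out.append(ring_pts[i])
        elif a * b < 0:
            t = a / (a - b)
            out.append(ring_pts[i] + t * (ring_pts[(i + 1) % n] - ring_pts[i]))
    return np.asarray(out) if out else np.zeros((0, 3))


def render_contours(subject: GroundTruthSubject, imaging: ImagingSpec | None = None,
                    template: Template | None = None) -> ContourSet:
    """Sample labeled contour stacks from a subject's true surfaces.

    SAX slices at fixed spacing cover both ventricles; 2-chamber and
    4-chamber LAX planes are cut; valve points come from the valve rings in
    LAX planes only; the RV apex landmark is placed on the 4-chamber view.
    Per-slice true breath-hold shifts are applied in-plane to SAX slices
    (identically at ED and ES, as both frames share an acquisition), and
    isotropic in-plane Gaussian noise degrades every point.
    """
    imaging = imaging or ImagingSpec()
    rng = np.random.default_rng(subject.rng_seed)
    sd = subject.noise_sd_mm
    frames = {}
    for frame in ("ed", "es"):
        surf = subject.true_surface_ed if frame == "ed" else subject.true_surface_es
        slices = []
        # short-axis stack --------------------------------------------------
        for k, z in enumerate(subject.sax_z):
            plane = SlicePlane(
                origin=np.array([0.0, 0.0, z]),
                axis_u=np.array([1.0, 0.0, 0.0]),
                axis_v=np.array([0.0, 1.0, 0.0]),
                thickness_mm=imaging.sax_thickness_mm,
                kind="sax",
                slice_index=k,
                applied_shift=subject.true_shifts[k].copy(),
            )
            any_contour = False
            for label, patches in LABEL_PATCHES.items():
                loops = _section_loops(surf, patches, plane.origin, plane.normal)
                uvs = []
                for closed, pts in loops:
                    p = _resample(pts, imaging.points_per_contour, closed)
                    uv = plane.to_uv(p)
                    uv = uv + rng.normal(0.0, sd, uv.shape)
                    uv = uv + subject.true_shifts[k]
                    uvs.append(uv)
                if uvs:
                    plane.contours[label] = uvs
                    any_contour = True
                else:
                    plane.flags.append(f"empty:{label}")
            if not any_contour:
                plane.flags.append("missing_heart")
            slices.append(plane)
        # long-axis planes --------------------------------------------------
        lax_defs = [
            ("lax_2ch", np.array([1.0, 0.0, 0.0]),
             np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]),
             ("lv_endo", "epi"), ("mitral",)),
            ("lax_4ch", np.array([0.0, 1.0, 0.0]),
             np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]),
             ("lv_endo", "epi", "rv_endo"), ("mitral", "tricuspid")),
        ]
        for kind, normal, axu, axv, labels, valve_tags in lax_defs:
            plane = SlicePlane(
                origin=np.zeros(3),
                axis_u=axu,
                axis_v=axv,
                thickness_mm=imaging.lax_thickness_mm,
                kind=kind,
                slice_index=0,
            )
            for label in labels:
                loops = _section_loops(surf, LABEL_PATCHES[label], plane.origin, normal)
                uvs = []
                for closed, pts in loops:
                    p = _resample(pts, imaging.points_per_contour, closed)
                    uv = plane.to_uv(p)
                    uvs.append(uv + rng.normal(0.0, sd, uv.shape))
                if uvs:
                    plane.contours[label] = uvs
                else:
                    plane.flags.append(f"empty:{label}")
            for tag in valve_tags:
                ring_pts = _ring_loop_points(surf, tag)
                hits = _ring_plane_crossings(ring_pts, plane.origin, normal)
                if len(hits):
                    uv = plane.to_uv(hits)
                    plane.contours[tag] = [uv + rng.normal(0.0, sd, uv.shape)]
            if kind == "lax_4ch" and hasattr(surf.control, "meta"):
                apex_cv = surf.control.meta["rv_apex_vertex"]
                apex = surf.vertices[int(surf.control_vertex_map[apex_cv])]
                uv = plane.to_uv(apex[None, :])
                plane.contours["rv_apex"] = [uv + rng.normal(0.0, sd, uv.shape)]
            slices.append(plane)
        frames[frame] = slices
    zs = subject.sax_z
    return ContourSet(
        subject_id=subject.id,
        frames=frames,
        metadata={
            "sax_spacing_mm": imaging.sax_spacing_mm,
            "sax_z": list(map(float, zs)),
            "extent_mm": float(zs[-1] - zs[0]) if len(zs) > 1 else 0.0,
            "noise_sd_mm": sd,
        },
    )
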