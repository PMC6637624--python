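"""Derived global and regional shape measures of a fitted model.

All measures are pure functions of a fitted (or atlas-reconstructed)
model: cavity volumes and ejection fractions by closed-surface
integration, LV mass from the epicardial-endocardial volume difference at
a myocardial density of 1.05 g/mL, and the echo-inspired ratios —
longitudinal shortening, sphericity, eccentricity, relative wall
thickness (RWT) and mass-to-volume ratio (MVR).

3D operationalizations (the echo conventions leave these open):

* the septal plane is the least-squares plane through the RV septal-patch
  vertices, oriented toward the RV free wall;
* "mid-ventricle" is the cross-section at 50% of the base-apex axis;
* eccentricity chords are maximal cavity chords parallel/perpendicular to
  the septal-plane trace on the mid-ventricular cross-section;
* the posterior wall is the 60 degree sector opposite the septum at
  mid-ventricle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .mesh import cap_valves, point_to_surface, surface_volume
from .synthetic import LABEL_PATCHES, _label_sub, _section_loops

__all__ = [
    "DerivedMeasures",
    "cavity_volumes",
    "compute_volumes",
    "compute_measures",
    "rv_longitudinal_shortening",
    "lv_longitudinal_shortening",
    "rv_sphericity",
    "lv_sphericity",
    "rv_eccentricity",
    "lv_eccentricity",
    "lv_relative_wall_thickness",
    "lv_mass_to_volume",
    "measures_table",
]

MYOCARDIAL_DENSITY = 1.05  # g/mL


@dataclass
class DerivedMeasures:
    lv_edv: float
    lv_esv: float
    rv_edv: float
    rv_esv: float
    lv_ef: float
    rv_ef: float
    lv_mass: float
    rv_long_shortening: float
    rv_sphericity: float
    rv_eccentricity: float
    lv_eccentricity: float
    lv_sphericity: float
    lv_rwt: float
    lv_mvr: float
    lv_long_shortening: float

    def validate(self):
        for name in ("lv_edv", "lv_esv", "rv_edv", "rv_esv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("lv_ef", "rv_ef"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} out of (-1, 1)")

    def as_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# volumes


def _capped(surface, patches, ring):
    sub = _label_sub(surface, patches)
    sub.ring_label = surface.ring_label
    return cap_valves(sub, ring)


def cavity_volumes(surface) -> dict:
    """LV cavity, RV cavity and epicardium-enclosed volumes (mL) of one
    frame's surface, valve openings capped."""
    lv = surface_volume(_capped(surface, ("lv_endo",), "mitral"))
    rv = surface_volume(_capped(surface, LABEL_PATCHES["rv_endo"], "tricuspid"))
    epi = surface_volume(
        _capped(surface, ("epi", "valve_plane"), ["aortic", "pulmonary"])
    )
    return {"lv_ml": lv, "rv_ml": rv, "epi_ml": epi}


def compute_volumes(model) -> dict:
    """EDV, ESV, SV and EF of both ventricles plus LV mass (g).

    A negative EF (ESV > EDV) is allowed but flagged in the returned
    dict under ``flags``.
    """
    ed = cavity_volumes(model.surface("ed"))
    es = cavity_volumes(model.surface("es"))
    out = {
        "lv_edv": ed["lv_ml"],
        "lv_esv": es["lv_ml"],
        "rv_edv": ed["rv_ml"],
        "rv_esv": es["rv_ml"],
        "lv_sv": ed["lv_ml"] - es["lv_ml"],
        "rv_sv": ed["rv_ml"] - es["rv_ml"],
        "lv_ef": (ed["lv_ml"] - es["lv_ml"]) / ed["lv_ml"],
        "rv_ef": (ed["rv_ml"] - es["rv_ml"]) / ed["rv_ml"],
        "lv_mass": (ed["epi_ml"] - ed["lv_ml"]) * MYOCARDIAL_DENSITY,
        "flags": [],
    }
    if out["lv_ef"] < 0 or out["rv_ef"] < 0:
        out["flags"].append("negative_ejection_fraction")
    return out


# ---------------------------------------------------------------------------
# landmarks


def _ring_centroid(surface, tag):
    ids = surface.ring_vertices(tag)
    if not ids:
        raise ValueError(f"surface has no ring tagged {tag!r}")
    return surface.vertices[np.asarray(ids, int)].mean(axis=0)


def _apex(surface, which):
    ctrl = surface.control
    if ctrl is None or not hasattr(ctrl, "meta"):
        raise ValueError("surface carries no apex metadata")
    return surface.vertices[int(surface.control_vertex_map[ctrl.meta[f"{which}_apex_vertex"]])]


def _patch_vertices(surface, patches):
    mask = np.isin(surface.patch_label.astype(str), list(patches))
    return np.unique(surface.faces[mask])


def _septal_plane(surface):
    """(point, unit normal) of the least-squares septal plane, the normal
    oriented from the septum toward the RV free wall."""
    ids = _patch_vertices(surface, ("rv_septum",))
    if len(ids) < 3:
        raise ValueError("no septal patch vertices")
    P = surface.vertices[ids]
    c = P.mean(axis=0)
    _, sv, vt = np.linalg.svd(P - c, full_matrices=False)
    if sv[-1] > 0.9 * sv[-2]:
        raise ValueError("degenerate septal plane (no unique normal direction)")
    n = vt[-1]
    fw = surface.vertices[_patch_vertices(surface, ("rv_freewall",))].mean(axis=0)
    if (fw - c) @ n < 0:
        n = -n
    return c, n


# ---------------------------------------------------------------------------
# shortening


def _shortening(model, ring, which):
    surf_ed, surf_es = model.surface("ed"), model.surface("es")
    l_ed = np.linalg.norm(_ring_centroid(surf_ed, ring) - _apex(surf_ed, which))
    l_es = np.linalg.norm(_ring_centroid(surf_es, ring) - _apex(surf_es, which))
    return (l_ed - l_es) / l_ed


def rv_longitudinal_shortening(model) -> float:
    """(L_ED - L_ES)/L_ED with L the distance from the tricuspid-ring
    centroid to the RV apex."""
    return _shortening(model, "tricuspid", "rv")


def lv_longitudinal_shortening(model) -> float:
    """LV analogue: mitral-ring centroid to LV apex."""
    return _shortening(model, "mitral", "lv")


# ---------------------------------------------------------------------------
# sphericity / eccentricity


def rv_sphericity(model, frame="ed") -> float:
    """Base-apex length over the free-wall-to-septum distance.

    The denominator is the maximal perpendicular distance from
    mid-ventricular free-wall vertices to the septal surface (the nearest
    point on the septum), so it measures the cavity width regardless of
    how strongly the septum wraps."""
    surf = model.surface(frame)
    base = _ring_centroid(surf, "tricuspid")
    apex = _apex(surf, "rv")
    L = np.linalg.norm(base - apex)
    axis = (apex - base) / L
    fw = surf.vertices[_patch_vertices(surf, ("rv_freewall",))]
    s = (fw - base) @ axis / L
    band = fw[np.abs(s - 0.5) <= 0.2]
    if not len(band):
        raise ValueError("no free-wall vertices at mid-ventricle")
    width = float(np.max(point_to_surface(band, surf, ("rv_septum",))))
    return float(L / width)


def _mid_section_polygons(surf, patches, base, apex):
    mid = base + 0.5 * (apex - base)
    n = apex - base
    n = n / np.linalg.norm(n)
    loops = _section_loops(surf, patches, mid, n)
    polys = [p for closed, p in loops if closed and len(p) >= 3]
    if not polys:
        raise ValueError("empty mid-ventricular cross-section")
    return polys, mid, n


def _max_chord(poly2d, direction, n_offsets=101):
    """Maximal single-segment chord of a 2D polygon along a direction."""
    import shapely.geometry as geo

    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e2 = np.array([-d[1], d[0]])
    poly = geo.Polygon(poly2d).buffer(0)
    t = poly2d @ d
    c = poly2d @ e2
    span = t.max() - t.min()
    best = 0.0
    for off in np.linspace(c.min(), c.max(), n_offsets):
        a = (t.min() - span) * d + off * e2
        b = (t.max() + span) * d + off * e2
        inter = poly.intersection(geo.LineString([a, b]))
        if inter.is_empty:
            continue
        segs = getattr(inter, "geoms", [inter])
        for g in segs:
            if g.length > best:
                best = float(g.length)
    return best


def _eccentricity(model, frame, cavity_patches, base_tag, apex_which):
    surf = model.surface(frame)
    base = _ring_centroid(surf, base_tag)
    apex = _apex(surf, apex_which)
    polys, mid, nrm = _mid_section_polygons(surf, cavity_patches, base, apex)
    p0, n_sept = _septal_plane(surf)
    # septal trace direction within the cross-section plane
    trace = np.cross(nrm, n_sept)
    trace = trace / np.linalg.norm(trace)
    perp = np.cross(nrm, trace)
    poly = max(polys, key=len)
    uv = np.stack([(poly - mid) @ trace, (poly - mid) @ perp], axis=1)
    par = _max_chord(uv, np.array([1.0, 0.0]))
    per = _max_chord(uv, np.array([0.0, 1.0]))
    if per <= 0:
        raise ValueError("degenerate cross-section")
    return float(par / per)


def rv_eccentricity(model, frame="ed") -> float:
    """RV minor axis parallel to the septum over the minor axis
    perpendicular to it, on the mid-ventricular cross-section."""
    return _eccentricity(model, frame, LABEL_PATCHES["rv_endo"], "tricuspid", "rv")


def lv_eccentricity(model, frame="ed") -> float:
    """LV analogue of the eccentricity index."""
    return _eccentricity(model, frame, ("lv_endo",), "mitral", "lv")


def lv_sphericity(model) -> float:
    """EDV over the volume of the sphere whose diameter is the LV major
    axis (mitral-ring centroid to LV apex) in the 4-chamber view at ED."""
    surf = model.surface("ed")
    D = float(np.linalg.norm(_ring_centroid(surf, "mitral") - _apex(surf, "lv")))
    edv = surface_volume(_capped(surf, ("lv_endo",), "mitral"))
    return edv / (math.pi / 6.0 * D**3 / 1000.0)


# ---------------------------------------------------------------------------
# wall thickness


def lv_relative_wall_thickness(model) -> float:
    """2 x posterior wall thickness / ED mid-cavity diameter.

    Posterior wall thickness is the mean endocardium-to-epicardium
    distance over the 60 degree mid-ventricular sector opposite the RV;
    the diameter is the maximal mid-cavity chord along the
    septum-posterior direction.
    """
    surf = model.surface("ed")
    base = _ring_centroid(surf, "mitral")
    apex = _apex(surf, "lv")
    axis = apex - base
    L = np.linalg.norm(axis)
    axis = axis / L
    p0, n_sept = _septal_plane(surf)
    post = -(n_sept - (n_sept @ axis) * axis)
    post = post / np.linalg.norm(post)
    side = np.cross(axis, post)

    endo_ids = _patch_vertices(surf, ("lv_endo",))
    V = surf.vertices[endo_ids]
    s = (V - base) @ axis / L
    rel = V - (base + ((V - base) @ axis)[:, None] * axis)
    ang = np.arctan2(rel @ side, rel @ post)
    sel = (np.abs(s - 0.5) <= 0.15) & (np.abs(ang) <= math.radians(30))
    if not sel.any():
        raise ValueError("no posterior-sector endocardial vertices")
    t_post = float(np.mean(point_to_surface(V[sel], surf, ("epi",))))

    polys, mid, nrm = _mid_section_polygons(surf, ("lv_endo",), base, apex)
    poly = max(polys, key=len)
    trace = np.cross(nrm, n_sept)
    trace = trace / np.linalg.norm(trace)
    perp = np.cross(nrm, trace)
    uv = np.stack([(poly - mid) @ trace, (poly - mid) @ perp], axis=1)
    D = _max_chord(uv, np.array([0.0, 1.0]))  # along the septum-posterior axis
    return 2.0 * t_post / D


def lv_mass_to_volume(model) -> float:
    v = compute_volumes(model)
    return v["lv_mass"] / v["lv_edv"]


# ---------------------------------------------------------------------------


def compute_measures(model) -> DerivedMeasures:
    """The full derived-measure block of one model.  Frame-dependent
    ratios (sphericity, eccentricity, RWT) are evaluated at ED."""
    v = compute_volumes(model)
    m = DerivedMeasures(
        lv_edv=v["lv_edv"],
        lv_esv=v["lv_esv"],
        rv_edv=v["rv_edv"],
        rv_esv=v["rv_esv"],
        lv_ef=v["lv_ef"],
        rv_ef=v["rv_ef"],
        lv_mass=v["lv_mass"],
        rv_long_shortening=rv_longitudinal_shortening(model),
        rv_sphericity=rv_sphericity(model, "ed"),
        rv_eccentricity=rv_eccentricity(model, "ed"),
        lv_eccentricity=lv_eccentricity(model, "ed"),
        lv_sphericity=lv_sphericity(model),
        lv_rwt=lv_relative_wall_thickness(model),
        lv_mvr=lv_mass_to_volume(model),
        lv_long_shortening=lv_longitudinal_shortening(model),
    )
    return m


def measures_table(models, path=None):
    """Measures for a list of models as a DataFrame (units in the header);
    optionally written as CSV."""
    import pandas as pd

    rows = []
    for m in models:
        d = compute_measures(m).as_dict()
        d["subject_id"] = m.subject_id
        rows.append(d)
    df = pd.DataFrame(rows).set_index("subject_id")
    units = {
        "lv_edv": "mL", "lv_esv": "mL", "rv_edv": "mL", "rv_esv": "mL",
        "lv_ef": "fraction", "rv_ef": "fraction", "lv_mass": "g",
        "rv_long_shortening": "fraction", "rv_sphericity": "ratio",
        "rv_eccentricity": "ratio", "lv_eccentricity": "ratio",
        "lv_sphericity": "ratio", "lv_rwt": "ratio", "lv_mvr": "g/mL",
        "lv_long_shortening": "fraction",
    }
    df = df.rename(columns={k: f"{k} [{u}]" for k, u in units.items()})
    if path is not None:
        df.to_csv(path)
    return df
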