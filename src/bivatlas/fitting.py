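"""Template-to-contour mesh customization.

Per subject and frame the template control mesh is deformed so its
subdivided surface matches the (slice-shift-corrected) contour points:

1. ``linear_fit`` — closest-point association followed by a regularized
   linear least-squares solve for control-vertex displacements.  Because
   Catmull-Clark subdivision is linear in the control vertices, the
   surface position at any associated point is a sparse linear map of the
   unknowns; graph-Laplacian smoothing of the displacement field plays the
   role of the near-affine deformation penalty.  Association and solve are
   alternated for a few outer iterations.
2. ``constrained_refine`` — gradient-based refinement of the same
   objective plus a hinge penalty on the epicardial-endocardial clearance,
   enforcing the observable diffeomorphic contract: the fitted epicardium
   never crosses the endocardium.

The RV epicardium is not contoured; it is synthesized by offsetting the
fitted RV endocardium outward by the population-average RV wall thickness
(3 mm at ED, 5 mm at ES), used to complete the model, and excluded from
all subsequent analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .contours import ContourSet, polygon_area
from .mesh import (
    SubdividedSurface,
    closest_point_on_surface,
    offset_surface,
    point_to_surface,
)
from .synthetic import LABEL_PATCHES

__all__ = [
    "FitConfig",
    "FittedModel",
    "FitError",
    "associate_points",
    "linear_fit",
    "constrained_refine",
    "fit_subject",
    "slice_summation_volume",
    "fit_quality",
]

#: myocardial density, g/mL (field convention)
MYOCARDIAL_DENSITY = 1.05


class FitError(RuntimeError):
    """A fitting stage failed; the message names the stage."""


@dataclass(frozen=True)
class FitConfig:
    """Fitting hyperparameters.

    ``lambda_smooth`` weighs the mean squared displacement difference
    across control-mesh edges against the mean squared data residual
    (default 1, at which the noiseless self-fit error is well below
    0.1 mm).  ``stiff_multiplier`` scales it for the stiff LAX-only LV fit
    used by breath-hold correction.  RV wall offsets follow the
    population-average thickness at ED (3 mm) and ES (5 mm).
    """

    lambda_smooth: float = 1.0
    stiff_multiplier: float = 100.0
    outer_iterations: int = 5
    nonlinear_max_iter: int = 40
    tol_mm: float = 0.01
    clearance_min_mm: float = 1.0
    clearance_weight: float = 10.0
    rv_wall_offset_ed_mm: float = 3.0
    rv_wall_offset_es_mm: float = 5.0
    ridge: float = 1e-6
    correct_shifts_per_frame: bool = True

    def rv_offset(self, frame):
        return self.rv_wall_offset_ed_mm if frame == "ed" else self.rv_wall_offset_es_mm


@dataclass
class FittedModel:
    """Per-subject fitted surfaces on the shared template topology."""

    subject_id: str
    surfaces: dict  # 'ed'/'es' -> SubdividedSurface
    rv_epi: dict = field(default_factory=dict)  # synthesized, not analyzed
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    def surface(self, frame):
        return self.surfaces[frame]


# ---------------------------------------------------------------------------
# data association


def _gather_frame_points(contour_set: ContourSet, frame, labels=None, kinds=None):
    """(label, points3d) pairs pooled over the requested slices."""
    out = []
    for s in contour_set.slices(frame, kinds):
        for label in s.contours:
            if labels is not None and label not in labels:
                continue
            pts = s.points3d(label)
            if len(pts):
                out.append((label, pts))
    return out


def associate_points(labeled_points, surface: SubdividedSurface):
    """Closest-point correspondences between labeled points and the
    matching-label patches/rings of a subdivided surface.

    Returns ``(B, targets, labels)`` where ``B`` is a sparse
    (n_points x n_surface_vertices) matrix of barycentric weights such
    that ``B @ surface.vertices`` are the paired surface points.  Surface
    labels pair to their own patches, valve labels to their ring
    polylines, and ``rv_apex`` to the RV apex vertex.  Unknown labels
    raise ``KeyError`` naming the label.
    """
    ring_tags = {"mitral", "tricuspid", "aortic", "pulmonary"}
    # pool points by label so each patch is queried once
    pooled = {}
    for label, pts in labeled_points:
        pts = np.atleast_2d(pts)
        if len(pts):
            pooled.setdefault(label, []).append(pts)
    rows, cols, vals = [], [], []
    targets = []
    labels_out = []
    r = 0
    for label, chunks in pooled.items():
        pts = np.vstack(chunks)
        if label in LABEL_PATCHES:
            _, _, tris, bary = closest_point_on_surface(pts, surface, LABEL_PATCHES[label])
            n = len(pts)
            rows.extend(np.repeat(np.arange(r, r + n), 3).tolist())
            cols.extend(tris.ravel().tolist())
            vals.extend(bary.ravel().tolist())
        elif label in ring_tags:
            ring = surface.ring_vertices(label)
            if not ring:
                raise KeyError(f"surface has no ring tagged {label!r}")
            ridx, w = _closest_on_ring(pts, surface, label)
            for k in range(len(pts)):
                (i0, i1), (w0, w1) = ridx[k], w[k]
                rows += [r + k, r + k]
                cols += [int(i0), int(i1)]
                vals += [float(w0), float(w1)]
        elif label == "rv_apex":
            ctrl = surface.control
            if ctrl is None or not hasattr(ctrl, "meta"):
                raise KeyError("surface carries no RV apex metadata")
            apex = int(surface.control_vertex_map[ctrl.meta["rv_apex_vertex"]])
            rows.extend(range(r, r + len(pts)))
            cols.extend([apex] * len(pts))
            vals.extend([1.0] * len(pts))
        else:
            raise KeyError(f"contour label {label!r} matches no surface patch")
        targets.append(pts)
        labels_out.extend([label] * len(pts))
        r += len(pts)
    if r == 0:
        raise FitError("associate_points: no points to associate")
    B = sp.coo_matrix(
        (vals, (rows, cols)), shape=(r, len(surface.vertices))
    ).tocsr()
    return B, np.vstack(targets), np.asarray(labels_out, dtype=object)


def _ordered_ring(surface, tag):
    """Topologically ordered vertex ids of a valve ring (cached on the
    control mesh: the ordering depends only on topology)."""
    ctrl = surface.control
    cache = getattr(ctrl, "_ring_order_cache", None) if ctrl is not None else None
    key = (len(surface.vertices), tag)
    if cache is not None and key in cache:
        return cache[key]
    from bivatlas.mesh import _ordered_boundary_loops

    ring = set(surface.ring_vertices(tag))
    loops = _ordered_boundary_loops([tuple(f) for f in surface.faces])
    order = None
    for lp in loops:
        if set(lp) == ring:
            order = lp
            break
    if order is None:  # ring not a boundary: fall back to greedy chaining
        ids = sorted(ring)
        order = [ids[i] for i in _chain_loop(surface.vertices[np.asarray(ids, int)])]
    if ctrl is not None:
        if cache is None:
            ctrl._ring_order_cache = cache = {}
        cache[key] = order
    return order


def _closest_on_ring(pts, surface, tag):
    """Closest point on a closed ring polyline; returns per point the two
    ring vertex ids and their linear weights."""
    ring = _ordered_ring(surface, tag)
    P = surface.vertices[np.asarray(ring, int)]
    n = len(ring)
    a = P
    b = np.roll(P, -1, axis=0)
    out_idx, out_w = [], []
    for p in np.atleast_2d(pts):
        ab = b - a
        t = np.einsum("ij,ij->i", p - a, ab) / np.maximum(
            np.einsum("ij,ij->i", ab, ab), 1e-12
        )
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        i = int(np.argmin(d))
        out_idx.append((ring[i], ring[(i + 1) % n]))
        out_w.append((1.0 - t[i], t[i]))
    return out_idx, out_w


def _chain_loop(P):
    """Order loop points by greedy nearest-neighbour chaining."""
    n = len(P)
    left = set(range(1, n))
    order = [0]
    while left:
        last = P[order[-1]]
        i = min(left, key=lambda j: float(np.sum((P[j] - last) ** 2)))
        order.append(i)
        left.remove(i)
    return order


# ---------------------------------------------------------------------------
# linear fit


def _edge_laplacian(control):
    edges = sorted({tuple(sorted((int(f[i]), int(f[(i + 1) % 4])))) for f in control.faces
                    for i in range(4)})
    n = control.n_vertices
    i = np.array([e[0] for e in edges] + [e[1] for e in edges])
    j = np.array([e[1] for e in edges] + [e[0] for e in edges])
    K = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    deg = np.asarray(K.sum(axis=1)).ravel()
    K = sp.diags(deg) - K
    return K.tocsr(), len(edges)


def _objective(M, P, K, n_e, lam, ridge, c0, d):
    res = M @ (c0 + d) - P
    data = float(np.sum(res**2)) / len(P)
    smooth = lam / n_e * float(np.sum(d * (K @ d)))
    return data + smooth + ridge * float(np.sum(d**2))


def _kabsch(X, Y):
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    H = (X - cx).T @ (Y - cy)
    U, _, Vt = np.linalg.svd(H)
    Sg = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ Sg @ U.T
    return R, cy - R @ cx


def _rigid_register(surface, labeled_points, c0):
    """Rigidly register the template to the labeled points.

    Pose (in particular the azimuth, which closest-point iterations see
    poorly on near-surfaces-of-revolution) comes from landmark pairs —
    valve-ring centroids and the RV apex — followed by a few
    closest-point Kabsch polish iterations.
    """
    by_label = {}
    for label, pts in labeled_points:
        if len(pts):
            by_label.setdefault(label, []).append(np.atleast_2d(pts))
    src, dst = [], []
    cur = surface.with_control_vertices(c0)
    for tag in ("mitral", "tricuspid"):
        if tag in by_label and surface.ring_vertices(tag):
            dst.append(np.vstack(by_label[tag]).mean(axis=0))
            src.append(cur.vertices[np.asarray(cur.ring_vertices(tag), int)].mean(axis=0))
    ctrl = surface.control
    if "rv_apex" in by_label and hasattr(ctrl, "meta"):
        dst.append(np.vstack(by_label["rv_apex"]).mean(axis=0))
        src.append(cur.vertices[int(surface.control_vertex_map[ctrl.meta["rv_apex_vertex"]])])
    # overall contour centroid stabilizes the solution
    allpts = np.vstack([p for ps in by_label.values() for p in ps])

    # registration works on a point subsample: pose needs far fewer
    # points than the deformation solve
    sub_pts = [(l, np.atleast_2d(p)[::3]) for l, p in labeled_points if len(p)]

    def assoc_residual(c):
        cur = surface.with_control_vertices(c)
        B, P, _ = associate_points(sub_pts, cur)
        X = np.asarray(B @ cur.vertices)
        return X, P, float(np.mean(np.sum((X - P) ** 2, axis=1)))

    _, _, r0 = assoc_residual(c0)
    best_c, best_r = c0, r0
    cand = c0
    if len(src) < 3:  # under-determined: stabilize with the centroid pair
        src.append(np.asarray(cur.vertices.mean(axis=0)))
        dst.append(allpts.mean(axis=0))
    if len(src) >= 3:
        R, t = _kabsch(np.asarray(src), np.asarray(dst))
        cand = c0 @ R.T + t
    prev_r = np.inf
    for _ in range(30):
        X, P, r = assoc_residual(cand)
        if r < best_r:
            best_c, best_r = cand, r
        if r > prev_r * 0.998:  # stalled
            break
        prev_r = r
        R, t = _kabsch(X, P)
        cand = cand @ R.T + t
    return best_c


def linear_fit(surface: SubdividedSurface, labeled_points, config: FitConfig | None = None,
               lambda_smooth=None, outer_iterations=None, initial_displacement=None,
               rigid_init=True):
    """Regularized linear least-squares fit of a template surface to
    labeled points, alternating closest-point association with the solve.

    The template is first rigidly registered to the points (a few
    closest-point Kabsch iterations), which keeps the deformation penalty
    from fighting the subject's pose, then
    ``mean ||surface(assoc) - point||^2 + lambda * mean_edges
    ||d_i - d_j||^2`` is minimized over control-vertex displacements ``d``
    (a small ridge term fixes the per-component translation gauge).
    Returns ``(fitted_surface, info)`` with the objective history
    (non-increasing across outer iterations), the registered control
    points and the final displacement field.
    """
    config = config or FitConfig()
    lam = config.lambda_smooth if lambda_smooth is None else lambda_smooth
    iters = config.outer_iterations if outer_iterations is None else outer_iterations
    ctrl = surface.control
    if ctrl is None:
        raise FitError("linear_fit requires a surface with its control mesh")
    if not labeled_points or all(len(p) == 0 for _, p in labeled_points):
        raise FitError("linear_fit: no contour points (singular system)")
    S = surface.operator
    c0 = ctrl.vertices  # the control points generating the input surface
    if rigid_init:
        c0 = _rigid_register(surface, labeled_points, c0)
    d = np.zeros_like(c0) if initial_displacement is None else initial_displacement.copy()
    K, n_e = _edge_laplacian(ctrl)
    history = []
    for _ in range(max(1, iters)):
        cur = surface.with_control_vertices(c0 + d)
        B, P, labs = associate_points(labeled_points, cur)
        M = (B @ S).tocsr()
        A = (M.T @ M) / len(P) + (lam / n_e) * K + config.ridge * sp.identity(K.shape[0])
        rhs = np.asarray(M.T @ (P - M @ c0)) / len(P)
        solve = spla.factorized(A.tocsc())
        d_new = np.column_stack([solve(rhs[:, k]) for k in range(3)])
        history.append(_objective(M, P, K, n_e, lam, config.ridge, c0, d_new))
        step = float(np.sqrt(np.mean((d_new - d) ** 2)))
        d = d_new
        if step < config.tol_mm:
            break
    fitted = surface.with_control_vertices(c0 + d)
    info = {
        "objective_history": history,
        "displacement": d,
        "c0": c0,
        "iterations": len(history),
    }
    return fitted, info


# ---------------------------------------------------------------------------
# constrained refinement


def constrained_refine(surface: SubdividedSurface, labeled_points, template,
                       config: FitConfig | None = None, info=None):
    """Nonlinear refinement with an epicardium-endocardium clearance hinge.

    Starts from the linear fit, re-associates once, and minimizes
    data + smoothness + ``clearance_weight * mean(max(0, d_min - c_i)^2)``
    where ``c_i`` is the signed LV-endocardium-to-epicardium clearance
    along the current wall direction.  Raises :class:`FitError` if any
    clearance is non-positive at convergence (the model is rejected).
    """
    config = config or FitConfig()
    ctrl = surface.control
    S = surface.operator
    c0 = info["c0"] if info else ctrl.vertices
    d0 = info["displacement"] if info else np.zeros_like(c0)
    K, n_e = _edge_laplacian(ctrl)
    lam = config.lambda_smooth

    cur = surface.with_control_vertices(c0 + d0)
    B, P, _ = associate_points(labeled_points, cur)
    M = (B @ S).tocsr()

    endo_ids, epi_ids = template.clearance_pairs()
    D = (S[epi_ids] - S[endo_ids]).tocsr()
    gap = cur.vertices[epi_ids] - cur.vertices[endo_ids]
    norms = np.linalg.norm(gap, axis=1)
    ref = template.surface("ed").vertices
    ref_gap = ref[epi_ids] - ref[endo_ids]
    bad = norms < 1e-6
    gap[bad] = ref_gap[bad]
    nhat = gap / np.maximum(np.linalg.norm(gap, axis=1), 1e-9)[:, None]
    dmin = config.clearance_min_mm
    mu = config.clearance_weight
    npairs = len(endo_ids)
    nP = len(P)

    def fun(x):
        d = x.reshape(-1, 3)
        res = M @ (c0 + d) - P
        data = float(np.sum(res**2)) / nP
        Kd = K @ d
        smooth = lam / n_e * float(np.sum(d * Kd))
        clr = np.einsum("ij,ij->i", (D @ (c0 + d)), nhat)
        h = np.maximum(0.0, dmin - clr)
        pen = mu * float(np.sum(h**2)) / npairs
        f = data + smooth + config.ridge * float(np.sum(d**2)) + pen
        g = (2.0 / nP) * (M.T @ res) + (2.0 * lam / n_e) * Kd + 2 * config.ridge * d
        if np.any(h > 0):
            g += (-2.0 * mu / npairs) * (D.T @ (h[:, None] * nhat))
        return f, g.ravel()

    out = minimize(
        fun,
        d0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.nonlinear_max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    d = out.x.reshape(-1, 3)
    refined = surface.with_control_vertices(c0 + d)
    clr = np.einsum("ij,ij->i", (D @ (c0 + d)), nhat)
    if np.any(clr <= 0):
        raise FitError(
            f"constrained_refine: {int(np.sum(clr <= 0))} epi-endo clearance "
            "violations at convergence; model rejected"
        )
    return refined, {
        "objective": float(out.fun),
        "iterations": int(out.nit),
        "converged": bool(out.success or out.nit >= 1),
        "min_clearance_mm": float(clr.min()),
        "displacement": d,
        "c0": c0,
    }


# ---------------------------------------------------------------------------
# full per-subject pipeline


def fit_subject(contour_set: ContourSet, template, config: FitConfig | None = None,
                correct=True) -> FittedModel:
    """correct_shifts -> linear_fit -> RV-epi offset -> constrained_refine,
    per frame; populates per-patch point-to-surface diagnostics."""
    from .slice_correction import correct_shifts

    config = config or FitConfig()
    for frame in ("ed", "es"):
        if frame not in contour_set.frames or not contour_set.frames[frame]:
            raise FitError(f"fit_subject: frame {frame!r} missing for "
                           f"{contour_set.subject_id}")
    if correct:
        try:
            contour_set, _ = correct_shifts(contour_set, template, config)
        except Exception as e:
            raise FitError(f"slice correction failed for {contour_set.subject_id}: {e}") from e

    surfaces = {}
    rv_epi = {}
    diagnostics = {}
    converged = True
    for frame in ("ed", "es"):
        pts = _gather_frame_points(contour_set, frame)
        base = template.surface(frame)
        try:
            lin, info = linear_fit(base, pts, config)
        except FitError as e:
            raise FitError(f"linear_fit[{frame}] failed for {contour_set.subject_id}: {e}") from e
        rv_surface = lin.subsurface(LABEL_PATCHES["rv_endo"])
        import warnings as _warnings

        with _warnings.catch_warnings():
            # the offset pinches at the sharp insertion creases; the RV
            # epicardium only completes the model and is never analyzed
            _warnings.simplefilter("ignore", UserWarning)
            rv_epi[frame] = offset_surface(rv_surface, config.rv_offset(frame))
        try:
            refined, rinfo = constrained_refine(base, pts, template, config, info)
        except FitError as e:
            raise FitError(
                f"constrained_refine[{frame}] failed for {contour_set.subject_id}: {e}"
            ) from e
        surfaces[frame] = refined
        converged &= rinfo["converged"]
        stats = {}
        for label in LABEL_PATCHES:
            p = np.vstack([p for l, p in pts if l == label]) if any(
                l == label for l, _ in pts
            ) else np.zeros((0, 3))
            if len(p):
                dd = point_to_surface(p, refined, LABEL_PATCHES[label])
                stats[label] = {
                    "mean_mm": float(dd.mean()),
                    "sd_mm": float(dd.std()),
                    "n": int(len(dd)),
                }
        diagnostics[frame] = {
            "patch_distances": stats,
            "linear_objective": info["objective_history"],
            "refine": {k: v for k, v in rinfo.items() if k not in ("displacement", "c0")},
        }
    return FittedModel(
        subject_id=contour_set.subject_id,
        surfaces=surfaces,
        rv_epi=rv_epi,
        diagnostics=diagnostics,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# slice-summation reference volumes


def _slice_label_area(s, label):
    import shapely.geometry as geo

    total = 0.0
    for lp in s.contours.get(label, []):
        if len(lp) >= 3:
            signed = abs(polygon_area(lp))
            poly = geo.Polygon(lp)
            if not poly.is_valid:
                # noise-level crossings are harmless (signed area ~ covered
                # area); a grossly self-intersecting polygon is an error
                covered = poly.buffer(0).area
                if covered <= 0 or signed < 0.9 * covered:
                    raise ValueError(
                        f"self-intersecting {label} polygon on slice {s.slice_index}"
                    )
            total += signed
    return total


def slice_summation_volume(contour_set: ContourSet, frame) -> dict:
    """Reference cavity volumes by the standard slice-summation method:
    sum of shoelace contour areas times slice spacing; LV mass from the
    epicardium-endocardium area difference times myocardial density."""
    sax = contour_set.slices(frame, "sax")
    spacing = float(contour_set.metadata.get("sax_spacing_mm", 8.0))
    out = {}
    for label, key in (("lv_endo", "lv_ml"), ("rv_endo", "rv_ml"), ("epi", "epi_ml")):
        n_with = sum(1 for s in sax if s.contours.get(label))
        if n_with < 3:
            raise ValueError(
                f"slice summation needs >=3 SAX slices with {label}, got {n_with}"
            )
        out[key] = sum(_slice_label_area(s, label) for s in sax) * spacing / 1000.0
    myo = 0.0
    for s in sax:
        a_epi = _slice_label_area(s, "epi")
        a_lv = _slice_label_area(s, "lv_endo")
        if a_epi > 0:
            myo += max(0.0, a_epi - a_lv)
    out["lv_mass_g"] = myo * spacing / 1000.0 * MYOCARDIAL_DENSITY
    return out


def fit_quality(model: FittedModel, contour_set: ContourSet) -> dict:
    """Per-patch distance statistics plus mesh-vs-slice-summation volume
    differences (Bland-Altman style entries for each frame)."""
    from .morphometrics import cavity_volumes

    report = {"patch_distances": {}, "volume_differences": {}}
    for frame in ("ed", "es"):
        pts = _gather_frame_points(contour_set, frame, labels=LABEL_PATCHES.keys())
        stats = {}
        for label in LABEL_PATCHES:
            p = [q for l, q in pts if l == label]
            if p:
                dd = point_to_surface(np.vstack(p), model.surface(frame), LABEL_PATCHES[label])
                stats[label] = {"mean_mm": float(dd.mean()), "sd_mm": float(dd.std())}
        report["patch_distances"][frame] = stats
        mesh_v = cavity_volumes(model.surface(frame))
        try:
            ref = slice_summation_volume(contour_set, frame)
        except ValueError:
            ref = None
        if ref is not None:
            report["volume_differences"][frame] = {
                "lv_ml": mesh_v["lv_ml"] - ref["lv_ml"],
                "rv_ml": mesh_v["rv_ml"] - ref["rv_ml"],
            }
    return report
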