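"""Population shape atlas: rigid alignment, ED+ES concatenation, PCA.

Fitted models share the template topology, so each subject is a vector of
corresponding vertex coordinates.  Following standard practice for
cardiac atlases:

* end-diastolic (ED) point sets are aligned by *generalized* Procrustes —
  translation and rotation only, never scaling, so size remains a mode of
  shape variation — and each subject's ED transform is applied verbatim
  to its end-systolic (ES) points, preserving the ED->ES motion;
* the aligned ED and ES coordinates are concatenated into one long vector
  per subject (length P = 6 x retained vertices);
* principal component analysis of the N x P matrix gives the mean shape,
  orthonormal modes ordered by variance, and per-mode variances.

Vertices with no contour support — the aortic and pulmonary ring vertices
and the basal valve-plane roof (and the synthesized RV free-wall
epicardium, which never enters a fitted surface) — are removed by a
retention mask stored inside the atlas, so projection of new subjects is
well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ShapeVector",
    "ShapeAtlas",
    "retention_mask",
    "procrustes_align",
    "build_atlas",
    "project",
    "reconstruct",
    "mode_shape",
    "embed_shape_vector",
    "save_atlas",
    "load_atlas",
]


@dataclass
class ShapeVector:
    """One subject's aligned, masked, concatenated ED+ES coordinates."""

    subject_id: str
    values: np.ndarray  # length P = 6 * retained vertices

    def __post_init__(self):
        self.values = np.asarray(self.values, float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite shape vector for {self.subject_id}")


@dataclass
class ShapeAtlas:
    """Mean shape, PCA basis and retention mask of the population model."""

    mean: np.ndarray  # (P,)
    components: np.ndarray  # (P, M), orthonormal columns
    variances: np.ndarray  # (M,), non-increasing
    total_variance: float
    mask: np.ndarray  # retained vertex indices into the template surface
    n_modes: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.components = np.asarray(self.components, float)
        self.variances = np.asarray(self.variances, float)
        self.mask = np.asarray(self.mask, int)

    @property
    def P(self):
        return len(self.mean)

    def variance_fractions(self):
        return self.variances / self.total_variance if self.total_variance > 0 else self.variances


def retention_mask(surface):
    """Indices of template-surface vertices entering the atlas: everything
    except aortic/pulmonary ring vertices and vertices used only by
    valve-plane roof faces."""
    drop = {
        v for v, t in surface.ring_label.items() if t in ("aortic", "pulmonary")
    }
    labels = surface.patch_label.astype(str)
    roof_verts = set(np.unique(surface.faces[labels == "valve_plane"]).tolist())
    nonroof_verts = set(np.unique(surface.faces[labels != "valve_plane"]).tolist())
    drop |= roof_verts - nonroof_verts
    keep = [v for v in range(len(surface.vertices)) if v not in drop]
    return np.asarray(keep, int)


# ---------------------------------------------------------------------------
# alignment


def _kabsch(X, Y):
    """Rotation R (det +1) and translation t minimizing ||R X + t - Y||."""
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    H = (X - cx).T @ (Y - cy)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    t = cy - R @ cx
    return R, t


def procrustes_align(models, mask=None, tol=1e-6, max_iter=100):
    """Generalized Procrustes alignment (translation + rotation, no
    scaling) of the ED point sets; each subject's ED transform is applied
    verbatim to its ES points.

    ``models`` is a list of :class:`~bivatlas.fitting.FittedModel` (or any
    object with ``surface(frame).vertices``).  Returns a list of
    :class:`ShapeVector` (ED coordinates then ES, x,y,z flattened per
    frame) over the retained vertices.
    """
    if len(models) < 2:
        raise ValueError("procrustes_align needs at least 2 models")
    n_verts = {len(m.surface("ed").vertices) for m in models} | {
        len(m.surface("es").vertices) for m in models
    }
    if len(n_verts) != 1:
        raise ValueError("models do not share a topology (vertex counts differ)")
    if mask is None:
        mask = retention_mask(models[0].surface("ed"))
    ED = np.stack([m.surface("ed").vertices[mask] for m in models])
    ES = np.stack([m.surface("es").vertices[mask] for m in models])

    # initialize: centre every ED shape
    aligned = ED - ED.mean(axis=1, keepdims=True)
    transforms = [( np.eye(3), -ED[i].mean(axis=0)) for i in range(len(models))]
    mean = aligned[0].copy()
    for _ in range(max_iter):
        new_aligned = []
        transforms = []
        for X in ED:
            R, t = _kabsch(X, mean)
            new_aligned.append(X @ R.T + t)
            transforms.append((R, t))
        new_aligned = np.stack(new_aligned)
        new_mean = new_aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        aligned = new_aligned
        mean = new_mean
        if shift < tol:
            break
    out = []
    for i, m in enumerate(models):
        R, t = transforms[i]
        es = ES[i] @ R.T + t
        vec = np.concatenate([aligned[i].ravel(), es.ravel()])
        out.append(ShapeVector(getattr(m, "subject_id", f"model{i}"), vec))
    return out


# ---------------------------------------------------------------------------
# PCA


def build_atlas(shapes, n_modes, mask=None):
    """Column-mean-centred PCA of the shape vectors.

    Components are ordered by variance with a deterministic sign
    convention (the largest-magnitude loading of each mode is positive).
    ``n_modes`` beyond the matrix rank is truncated with a warning.
    """
    import warnings

    X = np.stack([s.values if isinstance(s, ShapeVector) else np.asarray(s, float)
                  for s in shapes])
    n, P = X.shape
    if n < 2:
        raise ValueError("build_atlas needs at least 2 shapes")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    if n_modes > rank:
        warnings.warn(f"n_modes={n_modes} exceeds rank {rank}; truncating")
        n_modes = rank
    comps = Vt[:n_modes].T  # (P, M)
    # deterministic sign: largest-|loading| entry positive
    for j in range(comps.shape[1]):
        k = int(np.argmax(np.abs(comps[:, j])))
        if comps[k, j] < 0:
            comps[:, j] = -comps[:, j]
    variances = (s[:n_modes] ** 2) / (n - 1)
    total = float(np.sum(s**2) / (n - 1))
    if mask is None:
        mask = np.arange(P // 6)
    return ShapeAtlas(
        mean=mean,
        components=comps,
        variances=variances,
        total_variance=total,
        mask=np.asarray(mask, int),
        n_modes=int(n_modes),
    )


def project(shape, atlas: ShapeAtlas):
    """Mode scores of a shape vector: components^T (x - mean)."""
    x = shape.values if isinstance(shape, ShapeVector) else np.asarray(shape, float).ravel()
    if len(x) != atlas.P:
        raise ValueError(f"shape length {len(x)} != atlas P {atlas.P}")
    return atlas.components.T @ (x - atlas.mean)


def reconstruct(scores, atlas: ShapeAtlas):
    """Shape vector from mode scores: mean + components @ scores."""
    scores = np.asarray(scores, float).ravel()
    if len(scores) != atlas.n_modes:
        raise ValueError(f"score length {len(scores)} != atlas modes {atlas.n_modes}")
    return atlas.mean + atlas.components @ scores


def _split_frames(vec, n_retained):
    half = n_retained * 3
    return vec[:half].reshape(-1, 3), vec[half:].reshape(-1, 3)


def embed_shape_vector(vec, atlas: ShapeAtlas, template):
    """Lift a (masked) shape vector back onto full template surfaces.

    Retained vertices take the vector's coordinates; excluded vertices
    (valve-plane roof, aortic/pulmonary rings) follow a similarity
    transform estimated from the epicardial basal ring so capped volumes
    remain well defined.  Returns a FittedModel-like object.
    """
    from .fitting import FittedModel

    n_ret = len(atlas.mask)
    ed_pts, es_pts = _split_frames(np.asarray(vec, float), n_ret)
    out = {}
    for frame, pts in (("ed", ed_pts), ("es", es_pts)):
        surf = template.surface(frame)
        full = surf.vertices.copy()
        full[atlas.mask] = pts
        excluded = np.setdiff1d(np.arange(len(full)), atlas.mask)
        if len(excluded):
            # anchor on retained vertices near the excluded set's template
            # position (the basal rim): similarity (Umeyama) transform
            ring = _anchor_ids(surf, atlas.mask)
            sR, R, t = _umeyama(surf.vertices[ring], full[ring])
            full[excluded] = sR * (surf.vertices[excluded] @ R.T) + t
        out[frame] = surf.with_vertices(full)
    return FittedModel(subject_id="reconstruction", surfaces=out)


def _anchor_ids(surface, mask):
    labels = surface.patch_label.astype(str)
    epi_verts = np.unique(surface.faces[labels == "epi"])
    mask_set = set(mask.tolist())
    ids = [v for v in epi_verts if v in mask_set]
    z = surface.vertices[ids, 2]
    cut = np.quantile(z, 0.8)  # basal-most fifth of the epicardium
    return np.asarray([v for v, zz in zip(ids, z) if zz >= cut], int)


def _umeyama(src, dst):
    """Similarity transform (scale, rotation, translation) src -> dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    H = sc.T @ dc / len(src)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    var = np.mean(np.sum(sc**2, axis=1))
    scale = float(np.trace(np.diag(S) @ D) / var) if var > 0 else 1.0
    t = mu_d - scale * (R @ mu_s)
    return scale, R, t


def mode_shape(atlas: ShapeAtlas, mode, k_sd, template):
    """ED and ES surfaces of the mean shape displaced ``k_sd`` standard
    deviations along one mode (0-based)."""
    if mode >= atlas.n_modes:
        raise ValueError(f"mode {mode} >= retained modes {atlas.n_modes}")
    scores = np.zeros(atlas.n_modes)
    scores[mode] = k_sd * np.sqrt(atlas.variances[mode])
    vec = reconstruct(scores, atlas)
    model = embed_shape_vector(vec, atlas, template)
    return model.surface("ed"), model.surface("es")


# ---------------------------------------------------------------------------
# serialization: JSON metadata + raw little-endian float64 matrices


def save_atlas(atlas: ShapeAtlas, directory):
    """Documented archive: ``atlas.json`` (P, M, mask, variances) plus
    ``mean.f64`` and ``components.f64`` (row-major little-endian)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "P": int(atlas.P),
        "M": int(atlas.n_modes),
        "total_variance": atlas.total_variance,
        "variances": atlas.variances.tolist(),
        "mask": atlas.mask.tolist(),
        "layout": "row-major little-endian float64; components shape (P, M)",
    }
    (d / "atlas.json").write_text(json.dumps(meta, indent=1))
    atlas.mean.astype("<f8").tofile(d / "mean.f64")
    np.ascontiguousarray(atlas.components).astype("<f8").tofile(d / "components.f64")


def load_atlas(directory) -> ShapeAtlas:
    d = Path(directory)
    meta = json.loads((d / "atlas.json").read_text())
    mean = np.fromfile(d / "mean.f64", dtype="<f8")
    comps = np.fromfile(d / "components.f64", dtype="<f8").reshape(meta["P"], meta["M"])
    return ShapeAtlas(
        mean=mean,
        components=comps,
        variances=np.asarray(meta["variances"], float),
        total_variance=float(meta["total_variance"]),
        mask=np.asarray(meta["mask"], int),
        n_modes=int(meta["M"]),
    )
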