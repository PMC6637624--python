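"""Labeled contour stacks: the pipeline's raw input.

A ``ContourSet`` holds, per cardiac frame (end-diastole ``ed`` and
end-systole ``es``), a list of imaging planes.  Each plane carries its 3D
geometry (origin, in-plane unit axes, thickness) and per-label lists of
ordered 2D point loops/polylines in plane coordinates (u, v), in mm —
mirroring how short-axis (SAX) and long-axis (LAX) cine CMR contours are
delivered by manual analysis.  Serialized as a small versioned JSON
dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

SCHEMA_VERSION = "bivatlas-contours-1"

#: contour labels drawn on image planes
SURFACE_LABELS = ("lv_endo", "epi", "rv_endo")
#: point landmarks (valve points, RV apex)
LANDMARK_LABELS = ("mitral", "tricuspid", "rv_apex")


@dataclass
class SlicePlane:
    """One imaging plane with its contours.

    ``contours`` maps label -> list of (n, 2) uv arrays; closed loops are
    stored without a repeated endpoint.  ``kind`` is ``sax``, ``lax_2ch``
    or ``lax_4ch``.  ``applied_shift`` records an in-plane breath-hold
    shift that was added to every SAX point (ground truth bookkeeping) or
    a correction applied later.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    thickness_mm: float
    kind: str
    slice_index: int
    contours: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    applied_shift: np.ndarray | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axis_u = np.asarray(self.axis_u, float)
        self.axis_v = np.asarray(self.axis_v, float)

    @property
    def normal(self):
        return np.cross(self.axis_u, self.axis_v)

    def to_3d(self, uv):
        uv = np.atleast_2d(np.asarray(uv, float))
        return self.origin + uv[:, :1] * self.axis_u + uv[:, 1:2] * self.axis_v

    def to_uv(self, pts):
        pts = np.atleast_2d(np.asarray(pts, float)) - self.origin
        return np.stack([pts @ self.axis_u, pts @ self.axis_v], axis=1)

    def points3d(self, label):
        """All 3D points of a label on this plane (empty (0,3) if absent)."""
        loops = self.contours.get(label, [])
        if not loops:
            return np.zeros((0, 3))
        return np.vstack([self.to_3d(lp) for lp in loops])

    def translate_inplane(self, duv):
        """Shift every contour of this slice by (du, dv) mm, in place."""
        duv = np.asarray(duv, float)
        self.contours = {
            lab: [lp + duv for lp in loops] for lab, loops in self.contours.items()
        }


@dataclass
class ContourSet:
    """Per-subject contours at ED and ES with plane geometry metadata."""

    subject_id: str
    frames: dict  # 'ed' / 'es' -> list[SlicePlane]
    metadata: dict = field(default_factory=dict)
    schema: str = SCHEMA_VERSION

    def slices(self, frame, kind=None):
        out = self.frames[frame]
        if kind is not None:
            kinds = (kind,) if isinstance(kind, str) else tuple(kind)
            out = [s for s in out if s.kind in kinds]
        return out

    def all_points3d(self, frame, label):
        pts = [s.points3d(label) for s in self.frames[frame]]
        pts = [p for p in pts if len(p)]
        return np.vstack(pts) if pts else np.zeros((0, 3))

    def copy(self):
        return from_dict(to_dict(self))

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None, indent=None):
        d = json.dumps(to_dict(self), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(d)
        return d


def to_dict(cs: ContourSet) -> dict:
    def slice_d(s):
        return {
            "origin": s.origin.tolist(),
            "axis_u": s.axis_u.tolist(),
            "axis_v": s.axis_v.tolist(),
            "thickness_mm": s.thickness_mm,
            "kind": s.kind,
            "slice_index": s.slice_index,
            "contours": {
                lab: [np.asarray(lp).tolist() for lp in loops]
                for lab, loops in s.contours.items()
            },
            "flags": list(s.flags),
            "applied_shift": None
            if s.applied_shift is None
            else np.asarray(s.applied_shift).tolist(),
        }

    return {
        "schema": cs.schema,
        "subject_id": cs.subject_id,
        "metadata": cs.metadata,
        "frames": {f: [slice_d(s) for s in sl] for f, sl in cs.frames.items()},
    }


def from_dict(d: dict) -> ContourSet:
    if d.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unknown contour schema {d.get('schema')!r}")

    def slice_f(sd):
        return SlicePlane(
            origin=np.asarray(sd["origin"], float),
            axis_u=np.asarray(sd["axis_u"], float),
            axis_v=np.asarray(sd["axis_v"], float),
            thickness_mm=float(sd["thickness_mm"]),
            kind=sd["kind"],
            slice_index=int(sd["slice_index"]),
            contours={
                lab: [np.asarray(lp, float) for lp in loops]
                for lab, loops in sd["contours"].items()
            },
            flags=list(sd["flags"]),
            applied_shift=None
            if sd.get("applied_shift") is None
            else np.asarray(sd["applied_shift"], float),
        )

    return ContourSet(
        subject_id=d["subject_id"],
        frames={f: [slice_f(sd) for sd in sl] for f, sl in d["frames"].items()},
        metadata=d.get("metadata", {}),
    )


def from_json(src) -> ContourSet:
    if hasattr(src, "read"):
        return from_dict(json.load(src))
    s = str(src)
    if s.lstrip().startswith("{"):
        return from_dict(json.loads(s))
    with open(s) as fh:
        return from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# small polygon helpers (shoelace in plane coordinates)


def polygon_area(uv):
    """Signed shoelace area of an ordered closed polygon (no repeated
    endpoint), mm^2."""
    uv = np.asarray(uv, float)
    x, y = uv[:, 0], uv[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def polygon_centroid(uv):
    """Area centroid of an ordered closed polygon (shoelace formula)."""
    uv = np.asarray(uv, float)
    x, y = uv[:, 0], uv[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:
        return uv.mean(axis=0)
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6 * a)
    return np.array([cx, cy])
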