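"""Breath-hold slice-shift correction for short-axis contour stacks.

Each short-axis (SAX) slice of a cine CMR study is acquired in its own
breath-hold, so slices can be translated in-plane relative to one
another.  Correction proceeds as in LV atlas pipelines:

1. A *stiff* LV fit — the template LV deformed to the long-axis (LAX)
   contours only, with a heavily weighted smoothing term — provides a
   shift-free estimate of where the LV should be, since LAX views are not
   affected by the SAX misregistration being corrected.
2. The stiff surface is intersected with every SAX plane; each slice's
   model-side centre is the area-weighted barycentre of the intersection
   polygons.  A straight 3D longitudinal axis is fit to these centres by
   total least squares.
3. Every SAX slice's contours are translated in-plane so the observed
   contour barycentre lands on the axis-plane intersection point.  LAX
   contours are untouched; all labels on a slice move together.

The observed barycentre uses the LV endocardial contour when present,
falling back to the RV endocardium and then to the epicardium (apical
slices of the synthetic geometry may show the epicardium only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import ContourSet, polygon_area, polygon_centroid
from .fitting import FitConfig, FitError, linear_fit
from .synthetic import LABEL_PATCHES, Template

__all__ = [
    "SliceShiftReport",
    "stiff_lv_fit",
    "slice_barycentres",
    "correct_shifts",
]

#: barycentre label preference per slice
_BARYCENTRE_FALLBACK = ("lv_endo", "rv_endo", "epi")


@dataclass
class SliceShiftReport:
    """Per-slice corrections.  ``rows`` hold dicts with frame, slice
    index, the applied in-plane correction (du, dv) — the negative of the
    estimated breath-hold displacement — and the contour barycentre before
    and after correction."""

    rows: list = field(default_factory=list)

    def add(self, frame, slice_index, correction, bary_before, bary_after):
        self.rows.append(
            {
                "frame": frame,
                "slice_index": int(slice_index),
                "du_mm": float(correction[0]),
                "dv_mm": float(correction[1]),
                "magnitude_mm": float(np.hypot(*correction)),
                "bary_before_u": float(bary_before[0]),
                "bary_before_v": float(bary_before[1]),
                "bary_after_u": float(bary_after[0]),
                "bary_after_v": float(bary_after[1]),
            }
        )

    def estimated_shift(self, frame, slice_index):
        """Estimated breath-hold displacement of a slice (the negative of
        the applied correction)."""
        for r in self.rows:
            if r["frame"] == frame and r["slice_index"] == slice_index:
                return -np.array([r["du_mm"], r["dv_mm"]])
        return None

    @property
    def mean_shift_magnitude_mm(self):
        if not self.rows:
            return 0.0
        return float(np.mean([r["magnitude_mm"] for r in self.rows]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------


def stiff_lv_fit(contour_set: ContourSet, template: Template, frame,
                 config: FitConfig | None = None):
    """Stiff linear LV fit to the long-axis contours only.

    Smoothing weight is ``stiff_multiplier`` times the standard fit, so
    the result stays close to a similarity-registered template; SAX points
    are excluded.  Requires LV endocardial points on at least one LAX
    plane (two are prescribed; running with one is flagged).
    """
    config = config or FitConfig()
    lax = contour_set.slices(frame, ("lax_2ch", "lax_4ch"))
    pts = []
    n_planes = 0
    for s in lax:
        if s.contours.get("lv_endo"):
            n_planes += 1
            pts.append(("lv_endo", s.points3d("lv_endo")))
        if s.contours.get("mitral"):
            pts.append(("mitral", s.points3d("mitral")))
    if n_planes == 0:
        raise FitError("stiff_lv_fit: no LAX planes with LV endocardial points")
    flags = [] if n_planes >= 2 else ["single_lax_plane"]
    fitted, info = linear_fit(
        template.surface(frame),
        pts,
        config,
        lambda_smooth=config.lambda_smooth * config.stiff_multiplier,
        outer_iterations=3,
    )
    info["flags"] = flags
    return fitted, info


def slice_barycentres(surface, contour_set: ContourSet, frame):
    """Model-side and observed barycentres for every SAX slice.

    The model centre is the area-weighted barycentre of the LV-endocardium
    surface-plane intersection polygons; the observed centre is the
    area-weighted shoelace barycentre of the slice's contours (LV endo,
    falling back to RV endo then epi).  Slices the surface misses are
    flagged and excluded from the axis fit.
    """
    from .synthetic import _section_loops

    out = []
    for s in contour_set.slices(frame, "sax"):
        rec = {"slice_index": s.slice_index, "plane": s, "model_uv": None,
               "observed_uv": None, "observed_label": None, "flagged": False}
        loops = _section_loops(surface, LABEL_PATCHES["lv_endo"], s.origin, s.normal)
        polys = [s.to_uv(p) for closed, p in loops if closed and len(p) >= 3]
        if polys:
            areas = np.array([abs(polygon_area(p)) for p in polys])
            cents = np.array([polygon_centroid(p) for p in polys])
            rec["model_uv"] = (areas[:, None] * cents).sum(axis=0) / areas.sum()
        else:
            rec["flagged"] = True
        for label in _BARYCENTRE_FALLBACK:
            loops_o = [lp for lp in s.contours.get(label, []) if len(lp) >= 3]
            if loops_o:
                areas = np.array([abs(polygon_area(p)) for p in loops_o])
                cents = np.array([polygon_centroid(p) for p in loops_o])
                rec["observed_uv"] = (areas[:, None] * cents).sum(axis=0) / areas.sum()
                rec["observed_label"] = label
                break
        out.append(rec)
    return out


def _tls_line(points):
    """Total-least-squares 3D line through points: (centroid, unit dir)."""
    P = np.asarray(points, float)
    c = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - c, full_matrices=False)
    return c, vt[0]


def correct_shifts(contour_set: ContourSet, template: Template,
                   config: FitConfig | None = None):
    """Estimate and undo per-slice in-plane breath-hold shifts.

    Returns ``(corrected_contours, SliceShiftReport)``.  Corrections are
    estimated per frame by default (``config.correct_shifts_per_frame``);
    when disabled the ED and ES corrections of each slice are averaged and
    applied to both frames.  Raises :class:`FitError` with fewer than
    three usable slices for the axis fit.
    """
    config = config or FitConfig()
    corrected = contour_set.copy()
    report = SliceShiftReport()
    proposals = {}  # (frame, slice_index) -> (correction, before)
    for frame in ("ed", "es"):
        if frame not in corrected.frames:
            continue
        stiff, _ = stiff_lv_fit(corrected, template, frame, config)
        recs = slice_barycentres(stiff, corrected, frame)
        usable = [r for r in recs if r["model_uv"] is not None]
        if len(usable) < 3:
            raise FitError(
                f"correct_shifts[{frame}]: only {len(usable)} usable slices for the axis"
            )
        centres3d = [
            r["plane"].to_3d(r["model_uv"][None, :])[0] for r in usable
        ]
        c, u = _tls_line(centres3d)
        for r in recs:
            s = r["plane"]
            if r["observed_uv"] is None:
                continue
            n = s.normal
            denom = float(u @ n)
            if abs(denom) < 1e-9:
                continue
            t = float((s.origin - c) @ n) / denom
            target_uv = s.to_uv((c + t * u)[None, :])[0]
            corr = target_uv - r["observed_uv"]
            proposals[(frame, s.slice_index)] = (corr, r["observed_uv"])

    if not config.correct_shifts_per_frame:
        merged = {}
        idxs = {k[1] for k in proposals}
        for i in idxs:
            cs = [proposals[(f, i)][0] for f in ("ed", "es") if (f, i) in proposals]
            merged[i] = np.mean(cs, axis=0)
        proposals = {
            (f, i): (merged[i], proposals[(f, i)][1])
            for (f, i) in proposals
        }

    for frame in ("ed", "es"):
        if frame not in corrected.frames:
            continue
        for s in corrected.slices(frame, "sax"):
            key = (frame, s.slice_index)
            if key not in proposals:
                continue
            corr, before = proposals[key]
            s.translate_inplane(corr)
            report.add(frame, s.slice_index, corr, before, before + corr)
    return corrected, report
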