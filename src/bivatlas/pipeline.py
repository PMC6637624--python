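"""End-to-end cohort workflows tying the stages together.

Two entry paths produce fitted models:

* ``fit_cohort`` — the full imaging pipeline: render contour stacks,
  correct breath-hold shifts, run the two-stage mesh fit per frame.
* ``models_from_truth`` — bypass the imaging/fitting stages and build
  fitted models directly from the ground-truth surfaces (with optional
  control-vertex jitter emulating residual fitting error).  Used for
  atlas- and association-level analyses at cohort sizes where refitting
  every synthetic subject would add nothing but runtime.

``build_cohort_table`` assembles the per-subject analysis table: atlas
mode scores, traditional mass/volume features, factor indicators,
covariates and the reference-group flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import build_atlas, procrustes_align, project, retention_mask
from .fitting import FitConfig, FittedModel, fit_subject
from .morphometrics import compute_volumes
from .synthetic import (
    ImagingSpec,
    PopulationSpec,
    Template,
    render_contours,
    sample_population,
)

__all__ = [
    "models_from_truth",
    "fit_cohort",
    "build_cohort_table",
    "atlas_and_scores",
    "simulate_cohort_table",
]


def models_from_truth(subjects, template: Template, jitter_sd_mm=0.0, seed=0):
    """FittedModel per subject from the true surfaces.

    ``jitter_sd_mm`` adds iid Gaussian noise to the control vertices
    (smoothed by subdivision), emulating residual fit error without
    running the fitting stage.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in subjects:
        ed, es = s.control_ed, s.control_es
        if jitter_sd_mm > 0:
            ed = ed + rng.normal(0.0, jitter_sd_mm, ed.shape)
            es = es + rng.normal(0.0, jitter_sd_mm, es.shape)
        out.append(
            FittedModel(
                subject_id=s.id,
                surfaces={
                    "ed": template.surface_ed.with_control_vertices(ed),
                    "es": template.surface_es.with_control_vertices(es),
                },
            )
        )
    return out


def fit_cohort(subjects, template: Template, imaging: ImagingSpec | None = None,
               config: FitConfig | None = None, progress=False):
    """Render, correct and fit every subject.  Returns
    (models, contour_sets, per-subject shift reports)."""
    from .slice_correction import correct_shifts

    imaging = imaging or ImagingSpec()
    config = config or FitConfig()
    models, contour_sets, reports = [], [], []
    it = subjects
    if progress:
        from tqdm import tqdm

        it = tqdm(subjects, desc="fitting")
    for s in it:
        cs = render_contours(s, imaging)
        corrected, report = correct_shifts(cs, template, config)
        model = fit_subject(corrected, template, config, correct=False)
        models.append(model)
        contour_sets.append(cs)
        reports.append(report)
    return models, contour_sets, reports


def atlas_and_scores(models, n_modes, template: Template):
    """Procrustes -> PCA -> per-subject mode scores."""
    mask = retention_mask(template.surface_ed)
    shapes = procrustes_align(models, mask=mask)
    atlas = build_atlas(shapes, n_modes, mask=mask)
    scores = np.stack([project(s, atlas) for s in shapes])
    return atlas, shapes, scores


def build_cohort_table(models, subjects, scores) -> pd.DataFrame:
    """Per-subject analysis table: ``score_*`` columns, baseline
    mass/volume features, factor indicators, covariates, reference flag
    (no factor positive)."""
    rows = []
    for m, s, sc in zip(models, subjects, scores):
        v = compute_volumes(m)
        row = {
            "subject_id": s.id,
            "lv_edv": v["lv_edv"],
            "rv_edv": v["rv_edv"],
            "lv_esv": v["lv_esv"],
            "rv_esv": v["rv_esv"],
            "lv_mass": v["lv_mass"],
            **{f"score_{j}": float(x) for j, x in enumerate(sc)},
            **{k: int(vv) for k, vv in s.factors.items()},
            **s.covariates,
        }
        row["reference"] = int(all(vv == 0 for vv in s.factors.values()))
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort_table(template: Template, pop_spec: PopulationSpec,
                          n_modes=20, jitter_sd_mm=0.5, seed=None):
    """Truth-based cohort: sample, build models (with jitter), atlas,
    scores and the analysis table.  Returns (table, atlas, models,
    subjects)."""
    subjects = sample_population(template, pop_spec)
    models = models_from_truth(
        subjects, template, jitter_sd_mm=jitter_sd_mm,
        seed=pop_spec.seed + 1 if seed is None else seed,
    )
    atlas, shapes, scores = atlas_and_scores(models, n_modes, template)
    table = build_cohort_table(models, subjects, scores)
    return table, atlas, models, subjects
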