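# bivatlas

Biventricular cardiac shape atlases from cine CMR contours: subdivision-
surface mesh fitting, breath-hold slice correction, Procrustes + PCA
statistical shape modelling, derived morphometrics, and risk-factor
association models — with a synthetic-data generator so the whole
pipeline is testable end to end without any real imaging data.

## Who this is for

Researchers building statistical shape models of the heart from
segmented short-axis/long-axis contour stacks, and anyone who needs a
fully specified, reproducible reference implementation of the standard
atlas pipeline: contours → fitted 3D biventricular surfaces → population
shape modes → per-subject scores relating geometry to clinical factors.

## The model

A coarse labeled quad mesh (LV endocardium, RV endocardium, epicardium;
crease edges at the four valve rings and the RV insertions) is refined
by Catmull-Clark subdivision, `x_surface = S x_control`, with `S` a
sparse linear operator.  Fitting a subject minimizes

```
(1/N) Σ_i ‖ B_i S (c0 + d) − p_i ‖²  +  (λ/|E|) Σ_(jk)∈E ‖ d_j − d_k ‖²
```

over control-vertex displacements `d` (closest-point association rows
`B_i`, graph-Laplacian smoothing over control edges `E`), after rigid
pre-registration and slice-shift correction, followed by a nonlinear
refinement with a hinge penalty keeping the epicardium clear of the
endocardium.  Aligned end-diastolic and end-systolic coordinates are
concatenated into shape vectors (`P = 6 ×` retained vertices) and
decomposed by PCA; mode scores feed elastic-net classifiers (vs. a
mass/volume baseline, DeLong-tested) and covariate-adjusted
morphometric modes whose standardized projections are per-subject
z-scores.

## Worked example

```python
import numpy as np
from bivatlas import (
    PopulationSpec, make_template_pair, sample_population, render_contours,
    fit_subject, compute_measures,
)
from bivatlas.synthetic import septal_shift_factor
from bivatlas.pipeline import simulate_cohort_table
from bivatlas.risk import (
    BASELINE_FEATURES, assemble_cases, delong_test, fit_elasticnet_cv,
)

template = make_template_pair()

# fit one synthetic subject through the full imaging pipeline
spec = PopulationSpec(n_subjects=1, seed=42, noise_sd_mm=1.0, shift_sd_mm=2.5)
subject = sample_population(template, spec)[0]
contours = render_contours(subject)
model = fit_subject(contours, template)
for frame in ("ed", "es"):
    stats = model.diagnostics[frame]["patch_distances"]
    print(frame.upper(), {k: round(v["mean_mm"], 2) for k, v in stats.items()})
m = compute_measures(model)
print(f"LV EDV {m.lv_edv:.1f} mL  LV EF {m.lv_ef:.2f}  "
      f"RV EDV {m.rv_edv:.1f} mL  RV EF {m.rv_ef:.2f}")

# atlas + classification of a volume-preserving shape factor
spec = PopulationSpec(
    n_subjects=200, seed=7,
    factor_defs=(septal_shift_factor(prevalence=0.3, magnitude_mm=3.0),),
)
table, atlas, models, subjects = simulate_cohort_table(template, spec, n_modes=20)
cases = assemble_cases(table, "septal_shift")
scores = cases[[c for c in cases.columns if c.startswith("score_")]].to_numpy()
y = cases["label"].to_numpy()
r_pca = fit_elasticnet_cv(scores, y, seed=0)
r_mv = fit_elasticnet_cv(cases[list(BASELINE_FEATURES)].to_numpy(), y, seed=0)
yp, sp = r_pca.pooled(); _, sm = r_mv.pooled()
diff, p = delong_test(sp, sm, yp)
print(f"PCA-score AUC {r_pca.auc:.3f} vs MassVol AUC {r_mv.auc:.3f} "
      f"(DeLong p = {p:.1e})")
```

prints

```
ED {'lv_endo': 0.78, 'epi': 0.78, 'rv_endo': 0.74}
ES {'lv_endo': 0.78, 'epi': 0.76, 'rv_endo': 0.74}
LV EDV 118.7 mL  LV EF 0.58  RV EDV 124.9 mL  RV EF 0.45
PCA-score AUC 1.000 vs MassVol AUC 0.379 (DeLong p = 9.9e-31)
```

Reading the output: at contour noise of 1 mm and breath-hold shifts of
2.5 mm SD, the fitted surfaces sit ~0.8 mm from the contour points on
every patch, and the recovered volumes/EF are physiological.  The
`septal_shift` factor deforms the septum while keeping both cavity
volumes fixed, so the mass/volume baseline cannot see it (AUC near
chance) while the atlas shape scores separate positives essentially
perfectly — shape features carry information that traditional mass and
volume measures do not.

A CLI mirrors the pipeline stages
(`bivatlas simulate|correct|fit|atlas|measure|classify|score|all`); each
run writes a manifest with the config hash and seeds.  See
`docs/methods.md` for the model, conventions and limitations.

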