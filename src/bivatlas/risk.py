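"""Shape-factor association models.

Two complementary analyses mirror how shape atlases are related to risk
factors:

* **Classification strength** — for each binary factor, a penalised
  logistic regression with elastic-net regularization on the PCA mode
  scores, evaluated by stratified ten-fold cross-validation with
  fold-averaged ROC and precision-recall curves, operating points at the
  Youden cutoff, and DeLong's test against a baseline model built from
  traditional mass and volume measures (LVEDV, RVEDV, LVESV, RVESV, LV
  mass).  Covariates are deliberately excluded here so the comparison
  reflects geometric information alone.
* **Morphometric modes** — a multivariate linear regression of the mode
  scores on age, sex, height and all factor indicators partitions each
  factor's contribution to shape.  A factor's morphometric mode is its
  vector of regression coefficients across components; projections onto
  the unit mode direction, standardized against the reference (healthy)
  group, give per-subject z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "BASELINE_FEATURES",
    "ClassifierResult",
    "MorphometricMode",
    "assemble_cases",
    "fit_elasticnet_cv",
    "youden_cutoff",
    "delong_test",
    "fit_morphometric_modes",
    "morphometric_zscore",
    "mode_displacement_map",
    "measures_percent_difference",
]

#: traditional mass/volume baseline feature columns
BASELINE_FEATURES = ("lv_edv", "rv_edv", "lv_esv", "rv_esv", "lv_mass")


# ---------------------------------------------------------------------------
# case assembly


def assemble_cases(cohort: pd.DataFrame, factor: str):
    """Positives/negatives for one factor.

    Positives are factor-positive subjects minus those with previous
    myocardial infarction (MI) or angina — except: for the angina factor
    only MI-positives are removed, and for previous MI nobody is removed.
    Negatives are the reference (healthy) group.  Returns a DataFrame with
    a ``label`` column.
    """
    if factor not in cohort.columns:
        raise KeyError(f"unknown factor {factor!r}")
    pos = cohort[cohort[factor] == 1]
    if factor == "previous_mi":
        pass
    elif factor == "angina":
        if "previous_mi" in cohort.columns:
            pos = pos[pos["previous_mi"] != 1]
    else:
        for other in ("previous_mi", "angina"):
            if other in cohort.columns:
                pos = pos[pos[other] != 1]
    neg = cohort[cohort["reference"] == 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            f"factor {factor!r}: empty class (positives={len(pos)}, negatives={len(neg)})"
        )
    pos = pos.assign(label=1)
    neg = neg.assign(label=0)
    return pd.concat([pos, neg], axis=0)


# ---------------------------------------------------------------------------
# cross-validated elastic-net logistic regression


@dataclass
class ClassifierResult:
    """Fold-averaged ROC/PR curves, operating-point metrics at the Youden
    cutoff, and the raw per-fold predictions everything is recomputable
    from."""

    auc: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    npv: float
    cutoff: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    recall_grid: np.ndarray
    mean_precision: np.ndarray
    fold_aucs: list
    fold_predictions: list  # (y_true, y_score) per fold
    n_nonzero_coef: list
    pooled_auc: float

    def pooled(self):
        y = np.concatenate([t for t, _ in self.fold_predictions])
        s = np.concatenate([p for _, p in self.fold_predictions])
        return y, s


def _youden_from_scores(y, s):
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    best = int(np.argmax(j))
    # ties broken toward higher specificity (lower fpr)
    ties = np.where(np.isclose(j, j[best]))[0]
    best = int(ties[np.argmin(fpr[ties])])
    return float(thr[best])


def youden_cutoff(y_true, scores):
    """Threshold maximizing sensitivity + specificity - 1 over the
    observed scores (ties toward higher specificity)."""
    return _youden_from_scores(np.asarray(y_true), np.asarray(scores))


def _metrics_at(y, s, cutoff):
    pred = (s >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    prec = tp / max(tp + fp, 1)
    npv = tn / max(tn + fn, 1)
    f1 = 2 * prec * sens / max(prec + sens, 1e-12)
    return sens, spec, prec, f1, npv


def fit_elasticnet_cv(features, labels, n_folds=10, seed=0, l1_ratio=0.5,
                      c_grid=None, inner_folds=5) -> ClassifierResult:
    """Stratified k-fold CV of an elastic-net logistic regression.

    Features are standardized within each training fold; the penalty
    strength is chosen per fold by inner CV over a logarithmic grid.  The
    averaged ROC is the vertical (fixed-FPR-grid, 1001 points) mean of the
    per-fold test ROCs; operating metrics are averaged across folds at
    each fold's Youden cutoff.  With fewer minority-class members than
    folds, the fold count is reduced with a warning.
    """
    import warnings

    X = np.asarray(features, float)
    y = np.asarray(labels, int)
    if c_grid is None:
        c_grid = np.logspace(-2, 2, 7)
    n_min = min(int(np.sum(y == 1)), int(np.sum(y == 0)))
    if n_min < n_folds:
        warnings.warn(f"minority class has {n_min} members; using {n_min} folds")
        n_folds = max(2, n_min)
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fpr_grid = np.linspace(0.0, 1.0, 1001)
    recall_grid = np.linspace(0.0, 1.0, 1001)
    tprs, precs = [], []
    fold_aucs, fold_preds, nnz = [], [], []
    sens_l, spec_l, prec_l, f1_l, npv_l, cut_l = [], [], [], [], [], []
    for tr, te in outer.split(X, y):
        Xtr, ytr = X[tr], y[tr]
        best_c, best_score = None, -np.inf
        inner = StratifiedKFold(
            n_splits=min(inner_folds, max(2, int(np.sum(ytr == 1)))),
            shuffle=True,
            random_state=seed + 1,
        )
        for C in c_grid:
            scores = []
            for itr, ite in inner.split(Xtr, ytr):
                mdl = _enet(C, l1_ratio, seed)
                mdl.fit(Xtr[itr], ytr[itr])
                s = mdl.predict_proba(Xtr[ite])[:, 1]
                if len(np.unique(ytr[ite])) == 2:
                    scores.append(roc_auc_score(ytr[ite], s))
            score = float(np.mean(scores)) if scores else -np.inf
            if score > best_score:
                best_score, best_c = score, C
        mdl = _enet(best_c, l1_ratio, seed)
        mdl.fit(Xtr, ytr)
        coefs = mdl.named_steps["logisticregression"].coef_.ravel()
        nnz.append(int(np.sum(np.abs(coefs) > 1e-8)))
        s_te = mdl.predict_proba(X[te])[:, 1]
        y_te = y[te]
        fold_preds.append((y_te, s_te))
        fold_aucs.append(roc_auc_score(y_te, s_te))
        fpr, tpr, _ = roc_curve(y_te, s_te)
        # empirical ROC is a right-continuous step function: at each grid
        # FPR take the highest TPR attained at FPR <= grid value
        idx = np.searchsorted(fpr, fpr_grid, side="right") - 1
        tprs.append(tpr[np.clip(idx, 0, len(tpr) - 1)])
        from sklearn.metrics import precision_recall_curve

        pr, rc, _ = precision_recall_curve(y_te, s_te)
        order = np.argsort(rc)
        precs.append(np.interp(recall_grid, rc[order], pr[order]))
        cut = _youden_from_scores(y_te, s_te)
        se, sp, pr_, f1, npv = _metrics_at(y_te, s_te, cut)
        sens_l.append(se)
        spec_l.append(sp)
        prec_l.append(pr_)
        f1_l.append(f1)
        npv_l.append(npv)
        cut_l.append(cut)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    auc = float(np.trapezoid(mean_tpr, fpr_grid))
    yp, sp_all = np.concatenate([t for t, _ in fold_preds]), np.concatenate(
        [p for _, p in fold_preds]
    )
    return ClassifierResult(
        auc=auc,
        sensitivity=float(np.mean(sens_l)),
        specificity=float(np.mean(spec_l)),
        precision=float(np.mean(prec_l)),
        f1=float(np.mean(f1_l)),
        npv=float(np.mean(npv_l)),
        cutoff=float(np.mean(cut_l)),
        fpr_grid=fpr_grid,
        mean_tpr=mean_tpr,
        recall_grid=recall_grid,
        mean_precision=np.mean(precs, axis=0),
        fold_aucs=[float(a) for a in fold_aucs],
        fold_predictions=fold_preds,
        n_nonzero_coef=nnz,
        pooled_auc=float(roc_auc_score(yp, sp_all)),
    )


def _enet(C, l1_ratio, seed):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(
            solver="saga",  # l1_ratio in (0, 1) selects the elastic net
            l1_ratio=l1_ratio,
            C=C,
            max_iter=5000,
            random_state=seed,
        ),
    )


# ---------------------------------------------------------------------------
# DeLong's test


def _placements(pos, neg):
    """Mid-rank placement values V10 (per positive) and V01 (per
    negative) of the Mann-Whitney AUC estimator."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    m, n = len(pos), len(neg)
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0), cmp.mean()


def delong_test(scores_a, scores_b, labels):
    """DeLong comparison of two correlated AUCs on the same subjects.

    Returns ``(auc_a - auc_b, p_value)`` (two-sided).  Comparing a model
    with itself gives difference 0 and p = 1.
    """
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("delong_test requires both classes present")
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    pos, neg = y == 1, y == 0
    v10a, v01a, auc_a = _placements(a[pos], a[neg])
    v10b, v01b, auc_b = _placements(b[pos], b[neg])
    m, n = int(pos.sum()), int(neg.sum())
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 1e-15:
        return float(diff), 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(diff), float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# morphometric modes


@dataclass
class MorphometricMode:
    """A factor's direction in PCA-score space with reference
    standardization statistics."""

    factor: str
    direction: np.ndarray  # (M,) regression coefficients
    ref_mean: float
    ref_sd: float
    pos_mean_scores: np.ndarray
    neg_mean_scores: np.ndarray
    coef_se: np.ndarray = None

    @property
    def unit_direction(self):
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError(f"zero morphometric mode for {self.factor!r}")
        return self.direction / n


def fit_morphometric_modes(cohort: pd.DataFrame, factors, score_columns=None,
                           covariates=("age_yr", "sex", "height_cm")):
    """Per-component OLS of mode scores on covariates + factor indicators.

    Each of the M score components is regressed on [intercept, age, sex,
    height, all factor indicators]; factor f's morphometric mode is its
    coefficient vector across components.  Positive/negative mean score
    vectors push the cohort-mean covariate row with the factor set to 1/0
    through the fitted models; reference statistics are the
    reference-group projections onto the unit direction.
    """
    import statsmodels.api as sm

    if score_columns is None:
        score_columns = [c for c in cohort.columns if c.startswith("score_")]
    S = cohort[list(score_columns)].to_numpy(float)
    cols = list(covariates) + list(factors)
    X = cohort[cols].to_numpy(float)
    X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"design matrix rank deficient; most collinear columns: "
            f"{cols[i]!r} and {cols[j]!r}"
        )
    betas = np.zeros((X.shape[1], S.shape[1]))
    ses = np.zeros_like(betas)
    for k in range(S.shape[1]):
        fit = sm.OLS(S[:, k], X).fit()
        betas[:, k] = fit.params
        ses[:, k] = fit.bse
    xbar = X.mean(axis=0)
    ref = cohort["reference"] == 1
    if not ref.any():
        raise ValueError("no reference-group subjects to standardize against")
    modes = []
    for f in factors:
        row = 1 + len(covariates) + list(factors).index(f)
        direction = betas[row].copy()
        x_pos, x_neg = xbar.copy(), xbar.copy()
        x_pos[row], x_neg[row] = 1.0, 0.0
        mode = MorphometricMode(
            factor=f,
            direction=direction,
            ref_mean=0.0,
            ref_sd=1.0,
            pos_mean_scores=x_pos @ betas,
            neg_mean_scores=x_neg @ betas,
            coef_se=ses[row].copy(),
        )
        u = mode.unit_direction
        proj = S[ref.to_numpy()] @ u
        mode.ref_mean = float(proj.mean())
        sd = float(proj.std(ddof=0))
        if sd <= 0:
            raise ValueError(f"zero reference SD for factor {f!r}")
        mode.ref_sd = sd
        modes.append(mode)
    return modes


def morphometric_zscore(subject_scores, mode: MorphometricMode):
    """Standardized projection of score vectors onto the mode direction:
    z = (s . u - ref_mean) / ref_sd."""
    s = np.atleast_2d(np.asarray(subject_scores, float))
    z = (s @ mode.unit_direction - mode.ref_mean) / mode.ref_sd
    return z if z.size > 1 else float(z[0])


# ---------------------------------------------------------------------------
# mode visualization / percent differences


def _mode_models(mode: MorphometricMode, atlas, template):
    from .atlas import embed_shape_vector, reconstruct

    pos = embed_shape_vector(reconstruct(mode.pos_mean_scores, atlas), atlas, template)
    neg = embed_shape_vector(reconstruct(mode.neg_mean_scores, atlas), atlas, template)
    return pos, neg


def mode_displacement_map(mode: MorphometricMode, atlas, template):
    """Per-vertex signed displacement (mm) between the positive and
    negative mean shapes, projected on the negative shape's outward
    normal.  Sign convention: positive = outward for the free walls and,
    on the septum, outward from the LV (toward the RV).  Returns
    {'ed': values, 'es': values} over all template surface vertices."""
    from .mesh import vertex_normals

    pos, neg = _mode_models(mode, atlas, template)
    out = {}
    for frame in ("ed", "es"):
        sp_ = pos.surface(frame)
        sn = neg.surface(frame)
        normals = vertex_normals(sn)
        disp = np.einsum("ij,ij->i", sp_.vertices - sn.vertices, normals)
        # septal patch: outward-of-RV normals point toward the LV; flip so
        # positive means displacement toward the RV (outward from the LV)
        sept = np.unique(sn.faces[sn.patch_label.astype(str) == "rv_septum"])
        disp[sept] = -disp[sept]
        out[frame] = disp
    return out


def measures_percent_difference(mode: MorphometricMode, atlas, template) -> pd.Series:
    """Percent change of each derived measure between the positive-mean
    and negative-mean reconstructed shapes: 100 * (pos - neg) / neg."""
    from .morphometrics import compute_measures

    pos, neg = _mode_models(mode, atlas, template)
    mp = compute_measures(pos).as_dict()
    mn = compute_measures(neg).as_dict()
    return pd.Series(
        {k: 100.0 * (mp[k] - mn[k]) / mn[k] if mn[k] != 0 else np.nan for k in mp},
        name=mode.factor,
    )


# ---------------------------------------------------------------------------
# figures


def plot_roc_pr(results: dict, path=None):
    """ROC and PR panels for {model_name: ClassifierResult}."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for name, r in results.items():
        ax1.plot(r.fpr_grid, r.mean_tpr, label=f"{name} (AUC {r.auc:.3f})")
        ax2.plot(r.recall_grid, r.mean_precision, label=name)
    ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax1.set_xlabel("false positive rate")
    ax1.set_ylabel("true positive rate")
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax1.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
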