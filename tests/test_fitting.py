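"""Mesh-to-contour fitting: association, linear solve, refinement,
slice-summation volumes."""

import math

import numpy as np
import pytest

from bivatlas.contours import ContourSet, SlicePlane
from bivatlas.fitting import (
    FitConfig,
    FitError,
    associate_points,
    constrained_refine,
    fit_quality,
    fit_subject,
    linear_fit,
    slice_summation_volume,
    _gather_frame_points,
)
from bivatlas.mesh import point_to_surface, surface_triangles
from bivatlas.synthetic import (
    LABEL_PATCHES,
    PopulationSpec,
    render_contours,
    sample_population,
)


@pytest.fixture(scope="module")
def noiseless_subject(template):
    spec = PopulationSpec(
        n_subjects=1, seed=33, noise_sd_mm=0.0, shift_sd_mm=0.0
    )
    sub = sample_population(template, spec)[0]
    return sub, render_contours(sub)


class TestAssociate:
    def test_on_surface_points_zero_residual(self, template):
        s = template.surface_ed
        verts, tris, _ = surface_triangles(s, ("lv_endo",))
        pts = verts[tris].mean(axis=1)[:50]
        B, P, labs = associate_points([("lv_endo", pts)], s)
        res = np.linalg.norm(B @ s.vertices - P, axis=1)
        assert res.max() < 1e-9

    def test_label_gating(self, template):
        # an LV endo point right on the RV free wall must still pair with
        # the LV endo patch, never the RV patch
        s = template.surface_ed
        rv_ids = np.unique(s.faces[s.patch_label.astype(str) == "rv_freewall"])
        pt = s.vertices[rv_ids[40]][None, :]
        B, P, _ = associate_points([("lv_endo", pt)], s)
        touched = B.tocoo().col
        lv_ids = set(np.unique(s.faces[s.patch_label.astype(str) == "lv_endo"]).tolist())
        assert set(touched.tolist()) <= lv_ids

    def test_nearest_face_matches_brute_force(self, template):
        from bivatlas.mesh import _closest_on_tri_pairs

        s = template.surface_ed
        rng = np.random.default_rng(4)
        pts = s.vertices[::301] + rng.normal(0, 2, (len(s.vertices[::301]), 3))
        for label in ("lv_endo", "epi"):
            d = point_to_surface(pts, s, LABEL_PATCHES[label])
            verts, tris, _ = surface_triangles(s, LABEL_PATCHES[label])
            coords = verts[tris]
            for p, dd in zip(pts, d):
                cp = _closest_on_tri_pairs(
                    np.broadcast_to(p, (len(tris), 3)).copy(), coords
                )
                assert dd == pytest.approx(
                    np.linalg.norm(cp - p, axis=1).min(), abs=1e-9
                )

    def test_unknown_label_raises(self, template):
        with pytest.raises(KeyError, match="lv_wall"):
            associate_points([("lv_wall", np.zeros((1, 3)))], template.surface_ed)

    def test_valve_points_pair_to_ring(self, template):
        s = template.surface_ed
        ring = s.ring_vertices("mitral")
        pt = s.vertices[ring[3]][None, :] + [0.0, 0.0, 2.0]
        B, P, _ = associate_points([("mitral", pt)], s)
        assert set(B.tocoo().col.tolist()) <= set(ring)


class TestLinearFit:
    def test_self_fit_rms_below_point_one_mm(self, template):
        # contours sampled exactly from the template itself
        spec = PopulationSpec(n_subjects=1, seed=2, mode_sds=(0, 0, 0),
                              covariate_shape_coupling=False,
                              noise_sd_mm=0.0, shift_sd_mm=0.0)
        sub = sample_population(template, spec)[0]
        cs = render_contours(sub)
        pts = _gather_frame_points(cs, "ed")
        fitted, info = linear_fit(template.surface_ed, pts)
        res = []
        for label, p in pts:
            if label in LABEL_PATCHES:
                res.append(point_to_surface(p, fitted, LABEL_PATCHES[label]))
        rms = np.sqrt(np.mean(np.concatenate(res) ** 2))
        assert rms < 0.1

    def test_objective_non_increasing(self, template):
        spec = PopulationSpec(n_subjects=1, seed=41, noise_sd_mm=1.0, shift_sd_mm=0.0)
        sub = sample_population(template, spec)[0]
        cs = render_contours(sub)
        pts = _gather_frame_points(cs, "ed")
        _, info = linear_fit(template.surface_ed, pts)
        h = info["objective_history"]
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))

    def test_infinite_smoothing_gives_constant_displacement(self, template,
                                                           noiseless_subject):
        sub, cs = noiseless_subject
        pts = _gather_frame_points(cs, "ed", labels=("lv_endo",))
        _, info = linear_fit(template.surface_ed, pts, lambda_smooth=1e8,
                             outer_iterations=1)
        lo, hi = template.meta["lv_vertex_range"]
        d = info["displacement"][lo:hi]
        assert np.std(d, axis=0).max() < 1e-3

    def test_empty_contours_error(self, template):
        with pytest.raises(FitError, match="no contour points"):
            linear_fit(template.surface_ed, [])


class TestConstrainedRefine:
    def test_clear_input_unchanged_within_tolerance(self, template, noiseless_subject):
        sub, cs = noiseless_subject
        pts = _gather_frame_points(cs, "ed")
        lin, info = linear_fit(template.surface_ed, pts)
        refined, rinfo = constrained_refine(
            template.surface_ed, pts, template, info=info
        )
        assert rinfo["min_clearance_mm"] > 0
        # the hinge is inactive: refinement only polishes the same optimum
        assert np.abs(refined.vertices - lin.vertices).max() < 0.5

    def test_descent_contract(self, template):
        spec = PopulationSpec(n_subjects=1, seed=43, noise_sd_mm=1.0, shift_sd_mm=0.0)
        sub = sample_population(template, spec)[0]
        cs = render_contours(sub)
        pts = _gather_frame_points(cs, "ed")
        lin, info = linear_fit(template.surface_ed, pts)
        _, rinfo = constrained_refine(template.surface_ed, pts, template, info=info)
        assert rinfo["objective"] <= info["objective_history"][-1] + 1e-6

    def test_squeezed_wall_restored(self, template):
        # collapse the epicardium onto the endocardium; with no data term
        # the penalty must push the wall back to positive clearance
        ctrl = template.control_ed
        lo, hi = ctrl.meta["epi_vertex_range"]
        lv_lo, lv_hi = ctrl.meta["lv_vertex_range"]
        squeezed = ctrl.vertices.copy()
        # epi tube/cap vertices moved onto (slightly inside) the LV endo
        n_pair = min(hi - lo, lv_hi - lv_lo)
        squeezed[lo:lo + n_pair] = ctrl.vertices[lv_lo:lv_lo + n_pair] * 0.98
        d0 = squeezed - ctrl.vertices
        cfg = FitConfig(clearance_weight=50.0, nonlinear_max_iter=200)
        # a token data term far from the clearance pairs (tricuspid ring)
        s = template.surface_ed
        ring_pts = s.vertices[s.ring_vertices("tricuspid")]
        refined, rinfo = constrained_refine(
            s, [("tricuspid", ring_pts)], template, cfg,
            info={"c0": ctrl.vertices, "displacement": d0},
        )
        assert rinfo["min_clearance_mm"] > 0


class TestFitSubject:
    def test_noiseless_subject_under_half_mm(self, template, noiseless_subject):
        sub, cs = noiseless_subject
        model = fit_subject(cs, template)
        for frame in ("ed", "es"):
            for label, st in model.diagnostics[frame]["patch_distances"].items():
                assert st["mean_mm"] < 0.5, (frame, label)

    def test_topology_shared_with_template(self, template, noiseless_subject):
        sub, cs = noiseless_subject
        model = fit_subject(cs, template, correct=False)
        for frame in ("ed", "es"):
            np.testing.assert_array_equal(
                model.surface(frame).faces, template.surface(frame).faces
            )

    def test_missing_frame_propagates_stage_name(self, template, noiseless_subject):
        sub, cs = noiseless_subject
        broken = cs.copy()
        del broken.frames["es"]
        with pytest.raises(FitError, match="es"):
            fit_subject(broken, template)

    def test_rigid_equivariance(self, template, noiseless_subject):
        from scipy.spatial.transform import Rotation

        sub, cs = noiseless_subject
        R = Rotation.from_euler("zx", [14.0, -8.0], degrees=True).as_matrix()
        t = np.array([12.0, -5.0, 8.0])
        moved = cs.copy()
        for frame in ("ed", "es"):
            for s in moved.frames[frame]:
                s.origin = R @ s.origin + t
                s.axis_u = R @ s.axis_u
                s.axis_v = R @ s.axis_v
        base = fit_subject(cs, template, correct=False)
        rot = fit_subject(moved, template, correct=False)
        for frame in ("ed", "es"):
            mapped = base.surface(frame).vertices @ R.T + t
            rms = np.sqrt(np.mean((rot.surface(frame).vertices - mapped) ** 2))
            assert rms < 0.1


def test_noise_robustness_sublinear(template):
    # mean point-to-surface error grows sub-linearly with contour noise
    def mean_err(noise_sd, seed):
        spec = PopulationSpec(n_subjects=3, seed=seed, noise_sd_mm=noise_sd,
                              shift_sd_mm=0.0)
        errs = []
        for sub in sample_population(template, spec):
            cs = render_contours(sub)
            model = fit_subject(cs, template, correct=False)
            for frame in ("ed", "es"):
                for st in model.diagnostics[frame]["patch_distances"].values():
                    errs.append(st["mean_mm"])
        return float(np.mean(errs))

    lo = mean_err(0.5, 61)
    hi = mean_err(2.0, 61)
    assert hi / lo < 4.0  # noise quadrupled, error grew less


class TestSliceSummation:
    def _circle_stack(self, r=20.0, n_slices=10, spacing=8.0, label="lv_endo"):
        th = 2 * np.pi * np.arange(48) / 48
        circle = np.c_[r * np.cos(th), r * np.sin(th)]
        slices = []
        for k in range(n_slices):
            slices.append(
                SlicePlane(
                    origin=[0, 0, k * spacing], axis_u=[1, 0, 0], axis_v=[0, 1, 0],
                    thickness_mm=spacing, kind="sax", slice_index=k,
                    contours={label: [circle.copy()]},
                )
            )
        return ContourSet("toy", {"ed": slices}, {"sax_spacing_mm": spacing})

    def test_cylinder_volume(self):
        cs = self._circle_stack()
        cs2 = self._circle_stack(r=25.0)
        for s, s2 in zip(cs.frames["ed"], cs2.frames["ed"]):
            s.contours["epi"] = s2.contours["lv_endo"]
            s.contours["rv_endo"] = [s.contours["lv_endo"][0] + [60, 0]]
        out = slice_summation_volume(cs, "ed")
        # inscribed 48-gon area
        a48 = 0.5 * 48 * 20**2 * math.sin(2 * math.pi / 48)
        assert out["lv_ml"] == pytest.approx(a48 * 80 / 1000.0, rel=1e-9)
        assert out["lv_ml"] == pytest.approx(math.pi * 400 * 80 / 1000.0, rel=0.01)

    def test_synthetic_ellipsoid_within_five_percent(self, noiseless_subject):
        from bivatlas.morphometrics import cavity_volumes

        sub, cs = noiseless_subject
        out = slice_summation_volume(cs, "ed")
        # slice summation vs closed-surface integration of the same
        # (ellipsoidal) cavity: discretization differences only
        mesh_v = cavity_volumes(sub.true_surface_ed)
        assert out["lv_ml"] == pytest.approx(mesh_v["lv_ml"], rel=0.05)
        assert out["rv_ml"] == pytest.approx(mesh_v["rv_ml"], rel=0.12)

    def test_empty_slice_contributes_zero(self):
        cs = self._circle_stack(n_slices=10)
        for s in cs.frames["ed"]:
            s.contours["epi"] = [s.contours["lv_endo"][0] * 1.2]
            s.contours["rv_endo"] = [s.contours["lv_endo"][0] + [60, 0]]
        base = slice_summation_volume(cs, "ed")["lv_ml"]
        del cs.frames["ed"][4].contours["lv_endo"]
        less = slice_summation_volume(cs, "ed")["lv_ml"]
        assert less == pytest.approx(base * 9 / 10, rel=1e-9)

    def test_too_few_slices_error(self):
        cs = self._circle_stack(n_slices=2)
        with pytest.raises(ValueError, match=">=3"):
            slice_summation_volume(cs, "ed")

    def test_self_intersecting_polygon_error(self):
        bow = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], float)
        cs = self._circle_stack(n_slices=3)
        cs.frames["ed"][1].contours["lv_endo"] = [bow]
        with pytest.raises(ValueError, match="self-intersecting"):
            slice_summation_volume(cs, "ed")


class TestFitQuality:
    def test_distances_delegate_to_point_to_surface(self, template, noiseless_subject):
        sub, cs = noiseless_subject
        model = fit_subject(cs, template, correct=False)
        rep = fit_quality(model, cs)
        for frame in ("ed", "es"):
            for label, st in rep["patch_distances"][frame].items():
                pts = cs.all_points3d(frame, label)
                d = point_to_surface(pts, model.surface(frame), LABEL_PATCHES[label])
                assert st["mean_mm"] == pytest.approx(float(d.mean()))

    def test_volume_bias_small_on_noiseless_fit(self, template, noiseless_subject):
        sub, cs = noiseless_subject
        model = fit_subject(cs, template, correct=False)
        rep = fit_quality(model, cs)
        assert abs(rep["volume_differences"]["ed"]["lv_ml"]) < 8.0
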