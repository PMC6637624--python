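"""Derived global/regional shape measures."""

import math

import numpy as np
import pytest

from bivatlas.fitting import FittedModel
from bivatlas.mesh import ControlMesh, catmull_clark
from bivatlas.morphometrics import (
    cavity_volumes,
    compute_measures,
    compute_volumes,
    lv_eccentricity,
    lv_relative_wall_thickness,
    lv_sphericity,
    rv_eccentricity,
    rv_longitudinal_shortening,
    rv_sphericity,
    _max_chord,
)
from bivatlas.synthetic import TemplateSpec, make_template_pair


@pytest.fixture(scope="module")
def template_model(template):
    return FittedModel(
        "template", {"ed": template.surface_ed, "es": template.surface_es}
    )


@pytest.fixture(scope="module")
def frozen_model(template):
    """ED and ES identical (no motion)."""
    return FittedModel("frozen", {"ed": template.surface_ed, "es": template.surface_ed})


class TestVolumes:
    def test_identical_frames_zero_ef(self, frozen_model):
        v = compute_volumes(frozen_model)
        assert v["lv_ef"] == pytest.approx(0.0, abs=1e-12)
        assert v["rv_ef"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_ef_allowed_but_flagged(self, template):
        grown = template.surface_ed.with_vertices(template.surface_ed.vertices * 1.1)
        model = FittedModel("x", {"ed": template.surface_ed, "es": grown})
        v = compute_volumes(model)
        assert v["lv_ef"] < 0
        assert "negative_ejection_fraction" in v["flags"]

    def test_isotropic_scaling_cubes_volumes_fixes_ef(self, template_model, template):
        s = 1.3
        scaled = FittedModel(
            "s",
            {
                f: template.surface(f).with_vertices(template.surface(f).vertices * s)
                for f in ("ed", "es")
            },
        )
        v0 = compute_volumes(template_model)
        v1 = compute_volumes(scaled)
        for key in ("lv_edv", "lv_esv", "rv_edv", "rv_esv"):
            assert v1[key] == pytest.approx(v0[key] * s**3, rel=1e-9)
        assert v1["lv_ef"] == pytest.approx(v0["lv_ef"], abs=1e-12)
        assert v1["lv_mass"] == pytest.approx(v0["lv_mass"] * s**3, rel=1e-9)

    def test_physiological_template_values(self, template_model):
        m = compute_measures(template_model)
        m.validate()
        assert 80 < m.lv_edv < 160
        assert 80 < m.rv_edv < 180
        assert 0.4 < m.lv_ef < 0.75
        assert 0.3 < m.rv_ef < 0.7
        assert 60 < m.lv_mass < 200


class TestShortening:
    def test_frozen_heart_zero(self, frozen_model):
        assert rv_longitudinal_shortening(frozen_model) == pytest.approx(0.0)

    def test_ten_percent_apex_displacement(self, template):
        # move the ES frame so the tricuspid-apex length shrinks by 10%
        surf_ed = template.surface_ed
        ring = np.asarray(surf_ed.ring_vertices("tricuspid"), int)
        base_c = surf_ed.vertices[ring].mean(axis=0)
        apex = surf_ed.vertices[template.subdiv_apex("rv")]
        es_verts = surf_ed.vertices.copy()
        # contract every vertex 10% toward the tricuspid centroid
        es_verts = base_c + 0.9 * (es_verts - base_c)
        model = FittedModel(
            "t", {"ed": surf_ed, "es": surf_ed.with_vertices(es_verts)}
        )
        assert rv_longitudinal_shortening(model) == pytest.approx(0.10, abs=1e-9)

    def test_matches_manual_centroid_arithmetic(self, template):
        surf = template.surface_ed
        ring = np.asarray(surf.ring_vertices("tricuspid"), int)[:10]
        centroid = surf.vertices[np.asarray(surf.ring_vertices("tricuspid"), int)].mean(axis=0)
        apex = surf.vertices[template.subdiv_apex("rv")]
        L_ed = float(np.linalg.norm(centroid - apex))
        surf_es = template.surface_es
        centroid_es = surf_es.vertices[
            np.asarray(surf_es.ring_vertices("tricuspid"), int)
        ].mean(axis=0)
        apex_es = surf_es.vertices[template.subdiv_apex("rv")]
        L_es = float(np.linalg.norm(centroid_es - apex_es))
        model = FittedModel("t", {"ed": surf, "es": surf_es})
        assert rv_longitudinal_shortening(model) == pytest.approx(
            (L_ed - L_es) / L_ed
        )


def _box_rv_model(length=80.0, width=40.0):
    """Toy RV: septal wall at x=0, free wall at x=width, long axis z."""
    nz, ny = 9, 5
    zs = np.linspace(0, length, nz)
    ys = np.linspace(-25, 25, ny)
    verts = []
    faces = []
    labels = []
    idx = {}
    for xi, x in enumerate((0.0, width)):
        for zi, z in enumerate(zs):
            for yi, y in enumerate(ys):
                idx[(xi, zi, yi)] = len(verts)
                verts.append((x, y, z))
        for zi in range(nz - 1):
            for yi in range(ny - 1):
                faces.append(
                    (idx[(xi, zi, yi)], idx[(xi, zi + 1, yi)],
                     idx[(xi, zi + 1, yi + 1)], idx[(xi, zi, yi + 1)])
                )
                labels.append("rv_septum" if xi == 0 else "rv_freewall")
    # tricuspid ring: top edge vertices of the septal wall
    rings = {idx[(0, nz - 1, yi)]: "tricuspid" for yi in range(ny)}
    mesh = ControlMesh(np.asarray(verts, float), np.asarray(faces, int),
                       patch_label=np.asarray(labels, dtype=object),
                       ring_label=rings)
    mesh.meta = {"rv_apex_vertex": idx[(0, 0, (ny - 1) // 2)],
                 "lv_apex_vertex": idx[(0, 0, 0)]}
    surf = catmull_clark(mesh, 0)
    return FittedModel("box", {"ed": surf, "es": surf})


class TestSphericity:
    def test_toy_box_ratio_two(self):
        # 80 mm base-apex length, 40 mm septum-to-free-wall distance
        model = _box_rv_model(80.0, 40.0)
        assert rv_sphericity(model) == pytest.approx(2.0, rel=1e-6)

    def test_isotropic_scale_invariance(self, template, template_model):
        base = rv_sphericity(template_model)
        scaled = FittedModel(
            "s",
            {f: template.surface(f).with_vertices(template.surface(f).vertices * 1.4)
             for f in ("ed", "es")},
        )
        assert rv_sphericity(scaled) == pytest.approx(base, rel=1e-9)

    def test_halving_free_wall_offset_roughly_doubles(self, template_model):
        base_spec = TemplateSpec()
        half = make_template_pair(
            TemplateSpec(rv_offset_mm=base_spec.rv_offset_mm / 2)
        )
        m_half = FittedModel("h", {"ed": half.surface_ed, "es": half.surface_es})
        r_full = rv_sphericity(template_model)
        r_half = rv_sphericity(m_half)
        assert r_half / r_full == pytest.approx(2.0, rel=0.25)

    def test_lv_sphericity_monotone_in_elongation(self):
        vals = []
        for L in (80.0, 90.0, 100.0):
            tpl = make_template_pair(TemplateSpec(lv_long_axis_mm=L))
            m = FittedModel("t", {"ed": tpl.surface_ed, "es": tpl.surface_es})
            vals.append(lv_sphericity(m))
        assert vals[0] > vals[1] > vals[2]


class TestEccentricity:
    def test_circular_lv_cross_section_is_one(self, template_model):
        assert lv_eccentricity(template_model) == pytest.approx(1.0, abs=0.03)

    def test_ellipse_ratio(self, template, template_model):
        # squash the whole heart 0.8x along y (parallel to the septum the
        # chord shrinks; perpendicular unchanged) -> ratio scales by 0.8
        base = lv_eccentricity(template_model)
        squash = np.diag([1.0, 0.8, 1.0])
        model = FittedModel(
            "sq",
            {f: template.surface(f).with_vertices(template.surface(f).vertices @ squash)
             for f in ("ed", "es")},
        )
        assert lv_eccentricity(model) == pytest.approx(0.8 * base, rel=0.03)

    def test_chord_search_matches_dense_brute_force(self):
        rng = np.random.default_rng(1)
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        poly = np.c_[30 * np.cos(th), 18 * np.sin(th)]
        d = np.array([1.0, 0.0])
        fast = _max_chord(poly, d, n_offsets=101)
        brute = _max_chord(poly, d, n_offsets=2001)
        assert fast == pytest.approx(brute, rel=0.01)
        assert brute == pytest.approx(60.0, rel=0.01)

    def test_rv_eccentricity_positive(self, template_model):
        assert rv_eccentricity(template_model) > 0


class TestWallThickness:
    def test_concentric_cylinder_rwt(self):
        # endo radius 20, epi radius 28 -> RWT = 2*8/40 = 0.4
        def tube(r, label, n=32, nz=9, h=100.0):
            th = 2 * np.pi * np.arange(n) / n
            verts, faces, labels = [], [], []
            for zi, z in enumerate(np.linspace(0, h, nz)):
                verts += [(r * math.cos(a), r * math.sin(a), z) for a in th]
            for zi in range(nz - 1):
                for i in range(n):
                    faces.append(
                        (zi * n + i, zi * n + (i + 1) % n,
                         (zi + 1) * n + (i + 1) % n, (zi + 1) * n + i)
                    )
                    labels.append(label)
            return np.asarray(verts, float), faces, labels

    def test_template_rwt_in_echo_range(self, template_model):
        rwt = lv_relative_wall_thickness(template_model)
        assert 0.2 < rwt < 0.6

    def test_rwt_scale_invariant_mvr_too(self, template, template_model):
        from bivatlas.morphometrics import lv_mass_to_volume

        base_rwt = lv_relative_wall_thickness(template_model)
        base_mvr = lv_mass_to_volume(template_model)
        scaled = FittedModel(
            "s",
            {f: template.surface(f).with_vertices(template.surface(f).vertices * 1.25)
             for f in ("ed", "es")},
        )
        assert lv_relative_wall_thickness(scaled) == pytest.approx(base_rwt, rel=1e-6)
        assert lv_mass_to_volume(scaled) == pytest.approx(base_mvr, rel=1e-9)

    def test_mvr_matches_shell_arithmetic(self, template_model):
        from bivatlas.morphometrics import lv_mass_to_volume

        v = cavity_volumes(template_model.surface("ed"))
        expected = (v["epi_ml"] - v["lv_ml"]) * 1.05 / v["lv_ml"]
        assert lv_mass_to_volume(template_model) == pytest.approx(expected, rel=1e-9)


class TestPurity:
    def test_identical_models_identical_measures(self, template_model, template):
        m1 = compute_measures(template_model).as_dict()
        m2 = compute_measures(
            FittedModel("again", {"ed": template.surface_ed, "es": template.surface_es})
        ).as_dict()
        assert m1 == m2

    def test_rigid_motion_invariance(self, template, template_model):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [25.0, -10.0, 40.0], degrees=True).as_matrix()
        t = np.array([30.0, -12.0, 55.0])
        moved = FittedModel(
            "m",
            {f: template.surface(f).with_vertices(
                template.surface(f).vertices @ R.T + t)
             for f in ("ed", "es")},
        )
        m0 = compute_measures(template_model)
        m1 = compute_measures(moved)
        for k, v in m0.as_dict().items():
            assert v == pytest.approx(getattr(m1, k), rel=1e-6, abs=1e-9), k
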