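"""Geometry and nodal-area bookkeeping."""

import numpy as np
import pytest

from wiop.geometry import (EyeGeometryConfig, anterior_nodal_areas,
                           build_eye_mesh, write_vtk)


def cap_area(radius, half_chord):
    theta = np.arcsin(half_chord / radius)
    return 2.0 * np.pi * radius ** 2 * (1.0 - np.cos(theta))


class TestConfigValidation:
    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            EyeGeometryConfig(cct_um=9000.0, override_cct_limits=True)

    def test_rejects_out_of_band_cct_without_override(self):
        with pytest.raises(ValueError):
            EyeGeometryConfig(cct_um=250.0)
        cfg = EyeGeometryConfig(cct_um=250.0, override_cct_limits=True)
        assert cfg.cct_mm == pytest.approx(0.25)

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            EyeGeometryConfig(limbus_width=-1.0)


class TestBuildMesh:
    def test_anterior_area_matches_spherical_cap(self):
        cfg = EyeGeometryConfig()
        mesh = build_eye_mesh(cfg)
        expected = cap_area(cfg.anterior_corneal_radius, cfg.corneal_diameter / 2)
        assert mesh.anterior_surface_area() == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("cct", [484.0, 558.0, 600.0])
    def test_cct_realized_at_apex(self, cct):
        mesh = build_eye_mesh(EyeGeometryConfig(cct_um=cct))
        assert mesh.node_thickness[mesh.apex_node] == pytest.approx(
            cct * 1e-3, rel=0.01)

    def test_cct_changes_thickness_not_topology(self):
        m1 = build_eye_mesh(EyeGeometryConfig(cct_um=484.0))
        m2 = build_eye_mesh(EyeGeometryConfig(cct_um=600.0))
        assert m1.n_nodes == m2.n_nodes
        np.testing.assert_allclose(m1.nodes, m2.nodes)
        assert not np.allclose(m1.node_thickness, m2.node_thickness)

    def test_refinement_converges_and_preserves_area(self):
        a1 = build_eye_mesh(EyeGeometryConfig(mesh_resolution=1)).anterior_surface_area()
        a2 = build_eye_mesh(EyeGeometryConfig(mesh_resolution=2)).anterior_surface_area()
        assert abs(a2 - a1) / a1 < 0.005

    def test_refinement_halves_nodal_areas_sum_invariant(self):
        m1 = build_eye_mesh(EyeGeometryConfig(mesh_resolution=1))
        m2 = build_eye_mesh(EyeGeometryConfig(mesh_resolution=2))
        a1 = m1.anterior_nodal_area_array()
        a2 = m2.anterior_nodal_area_array()
        assert a1.sum() == pytest.approx(a2.sum(), rel=1e-3)
        # interior nodes of the refined mesh carry about half the area
        mid1 = a1[m1.anterior_nodes[5]]
        mid2 = a2[m2.anterior_nodes[10]]   # same meridional position
        assert mid2 == pytest.approx(mid1 / 2, rel=0.05)

    def test_apex_on_axis_and_fibres_orthonormal(self):
        mesh = build_eye_mesh(EyeGeometryConfig())
        assert mesh.nodes[mesh.apex_node, 0] == 0.0
        for arr in (mesh.fibre_meridional, mesh.fibre_circumferential):
            np.testing.assert_allclose(np.linalg.norm(arr, axis=1), 1.0,
                                       atol=1e-12)
        dots = (mesh.fibre_meridional * mesh.fibre_circumferential).sum(axis=1)
        assert np.max(np.abs(dots)) < 1e-8


class TestNodalAreas:
    def test_anterior_map_keys_and_positivity(self):
        mesh = build_eye_mesh(EyeGeometryConfig())
        areas = anterior_nodal_areas(mesh)
        assert set(areas) == set(int(i) for i in mesh.anterior_nodes)
        assert all(a >= 0 for a in areas.values())

    def test_deformed_areas_match_fine_discretization_oracle(self):
        """Areas recomputed on a radially stretched configuration agree with
        a 50x finer discretization of the same deformed surface."""
        mesh = build_eye_mesh(EyeGeometryConfig())

        def deform(coords):
            out = coords.copy()
            out[:, 0] *= 1.0 + 0.15 * np.exp(-coords[:, 0] ** 2 / 8.0)
            out[:, 1] += 0.8 * np.exp(-coords[:, 0] ** 2 / 2.0)
            return out

        coarse = mesh.anterior_nodal_area_array(deform(mesh.nodes)).sum()
        fine_mesh = build_eye_mesh(EyeGeometryConfig(mesh_resolution=50))
        fine = fine_mesh.anterior_nodal_area_array(deform(fine_mesh.nodes)).sum()
        assert coarse == pytest.approx(fine, rel=0.005)
        assert coarse != pytest.approx(mesh.anterior_surface_area(), rel=0.01)

    def test_area_continuity_under_tiny_perturbation(self, rng):
        mesh = build_eye_mesh(EyeGeometryConfig())
        base = mesh.nodal_areas()
        pert = mesh.nodes + 1e-9 * rng.standard_normal(mesh.nodes.shape)
        assert np.max(np.abs(mesh.nodal_areas(pert) - base)) < 1e-6

    def test_projected_areas_sum_to_projected_disc(self):
        cfg = EyeGeometryConfig()
        mesh = build_eye_mesh(cfg)
        proj = mesh.anterior_nodal_area_array(projected=True)
        r_rim = cfg.corneal_diameter / 2
        assert proj[mesh.anterior_nodes].sum() == pytest.approx(
            np.pi * r_rim ** 2, rel=1e-10)


def test_enclosed_volume_of_hemisphere_limit():
    """With the corneal sphere degenerate to the scleral one, the enclosed
    volume approaches the hemisphere closed form."""
    cfg = EyeGeometryConfig(anterior_corneal_radius=12.0, corneal_diameter=11.5,
                            scleral_radius=12.0, mesh_resolution=4)
    mesh = build_eye_mesh(cfg)
    hemi = 2.0 / 3.0 * np.pi * 12.0 ** 3
    assert mesh.enclosed_volume() == pytest.approx(hemi, rel=0.002)


def test_vtk_export_roundtrip(tmp_path):
    mesh = build_eye_mesh(EyeGeometryConfig())
    path = tmp_path / "eye.vtk"
    write_vtk(mesh, path)
    text = path.read_text()
    assert text.startswith("# vtk DataFile")
    assert f"POINTS {mesh.n_nodes} float" in text
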