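"""Geometry: mesh measures, OBJ interchange, scene building, descriptors."""

import math

import numpy as np
import pytest
import trimesh
from scipy.stats import chisquare

from gluclear import geometry as G


def _cube(edge=1.0, role="world"):
    box = trimesh.creation.box(extents=(edge,) * 3)
    return G.TriMesh(np.asarray(box.vertices), np.asarray(box.faces), role=role)


def _icosphere(radius, subdivisions=4, role="astrocyte"):
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return G.TriMesh(np.asarray(s.vertices), np.asarray(s.faces), role=role)


class TestMeshMeasures:
    def test_unit_cube_area_and_volume(self):
        cube = _cube()
        assert G.mesh_surface_area(cube) == pytest.approx(6.0)
        assert G.mesh_volume(cube) == pytest.approx(1.0)

    def test_icosphere_matches_closed_forms(self):
        r = 0.27
        sph = _icosphere(r)
        assert G.mesh_surface_area(sph) == pytest.approx(4 * math.pi * r**2,
                                                         rel=0.01)
        assert G.mesh_volume(sph) == pytest.approx(4 / 3 * math.pi * r**3,
                                                   rel=0.01)

    def test_area_additive_over_submeshes(self):
        cube = _cube()
        half_a = G.TriMesh(cube.vertices, cube.faces[:6], role="world")
        half_b = G.TriMesh(cube.vertices, cube.faces[6:], role="world")
        assert (G.mesh_surface_area(half_a) + G.mesh_surface_area(half_b)
                == pytest.approx(6.0))

    def test_inward_oriented_cube_volume_with_warning(self):
        cube = _cube()
        flipped = G.TriMesh(cube.vertices, cube.faces[:, ::-1], role="world")
        with pytest.warns(UserWarning, match="inward"):
            assert G.mesh_volume(flipped) == pytest.approx(1.0)

    def test_open_mesh_rejected_with_boundary_edges(self):
        cube = _cube()
        open_mesh = G.TriMesh(cube.vertices, cube.faces[:-2], role="world")
        with pytest.raises(G.GeometryError, match="boundary edges"):
            G.mesh_volume(open_mesh)


class TestObjRoundTrip:
    def test_cube_obj_read(self, tmp_path):
        path = tmp_path / "cube.obj"
        G.write_mesh_obj(_cube(), path)
        mesh = G.load_mesh_obj(path)
        assert len(mesh.vertices) == 8
        assert len(mesh.faces) == 12

    def test_round_trip_bit_identical(self, tmp_path):
        sph = _icosphere(0.27, subdivisions=2)
        p1, p2 = tmp_path / "a.obj", tmp_path / "b.obj"
        G.write_mesh_obj(sph, p1)
        loaded = G.load_mesh_obj(p1)
        G.write_mesh_obj(loaded, p2)
        assert p1.read_text() == p2.read_text()
        assert np.array_equal(loaded.vertices, sph.vertices)
        assert np.array_equal(loaded.faces, sph.faces)

    def test_quad_face_rejected_with_index(self, tmp_path):
        path = tmp_path / "quad.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        with pytest.raises(G.GeometryError, match="face 0"):
            G.load_mesh_obj(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            G.load_mesh_obj(tmp_path / "nope.obj")


class TestNearestDistance:
    def test_parallel_squares(self):
        v0 = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        f = np.array([[0, 1, 2], [0, 2, 3]])
        a = G.TriMesh(v0, f, role="psd")
        b = G.TriMesh(v0 + [0, 0, 0.1], f, role="astrocyte")
        assert G.nearest_surface_distance(a, b) == pytest.approx(100.0)

    def test_two_spheres(self):
        a = _icosphere(0.2, subdivisions=3)
        b = _icosphere(0.3, subdivisions=3)
        b = G.TriMesh(b.vertices + [1.0, 0, 0], b.faces, role="astrocyte")
        # centers 1 um apart, radii 0.2 + 0.3 -> 0.5 um gap
        assert G.nearest_surface_distance(a, b) == pytest.approx(500.0, rel=0.01)

    def test_symmetry(self):
        a = _icosphere(0.2, subdivisions=2)
        b = G.TriMesh(a.vertices + [0.9, 0, 0], a.faces, role="astrocyte")
        assert (G.nearest_surface_distance(a, b)
                == pytest.approx(G.nearest_surface_distance(b, a)))


class TestSurfacePlacement:
    def test_count_is_rounded_density_times_area(self):
        sph = _icosphere(0.27)
        area = G.mesh_surface_area(sph)
        pop = G.place_surface_molecules(sph, 10800.0, "transporter", seed=1)
        assert pop.count == round(10800.0 * area)

    def test_zero_density_empty(self):
        pop = G.place_surface_molecules(_icosphere(0.2), 0.0, "x", seed=0)
        assert pop.count == 0

    def test_deterministic_for_seed(self):
        sph = _icosphere(0.2)
        a = G.place_surface_molecules(sph, 5000.0, "t", seed=7)
        b = G.place_surface_molecules(sph, 5000.0, "t", seed=7)
        assert np.array_equal(a.positions, b.positions)

    def test_uniformity_chi_square_on_sphere(self):
        sph = _icosphere(0.5, subdivisions=3)
        areas = sph.triangle_areas()
        n = 100_000
        density = n / areas.sum()
        pop = G.place_surface_molecules(sph, density, "t", seed=3)
        counts = np.bincount(pop.tri_index, minlength=len(areas))
        expected = pop.count * areas / areas.sum()
        _, p = chisquare(counts, expected)
        assert p > 0.01

    def test_positions_lie_on_host_triangles(self):
        sph = _icosphere(0.5, subdivisions=2)
        pop = G.place_surface_molecules(sph, 2000.0, "t", seed=0)
        tri = sph.triangles[pop.tri_index]
        recon = np.einsum("nk,nkj->nj", pop.barycentric, tri)
        assert np.allclose(recon, pop.positions)


class TestSceneBuilder:
    def test_control_scene_astro_area(self, control_scene):
        assert control_scene.total_astro_area() == pytest.approx(1.38, rel=0.01)
        assert len(control_scene.meshes["astrocyte"]) == 2

    def test_control_scene_psd_astro_distance(self, control_scene):
        d = G.nearest_surface_distance(control_scene.meshes["psd"][0],
                                       control_scene.meshes["astrocyte"][0])
        assert d == pytest.approx(116.0, abs=2.0)

    def test_tfllr_scene(self, tfllr_scene):
        assert len(tfllr_scene.meshes["astrocyte"]) == 4
        d = G.nearest_surface_distance(tfllr_scene.meshes["psd"][0],
                                       tfllr_scene.meshes["astrocyte"][0])
        assert d == pytest.approx(190.0, abs=2.0)

    def test_terminal_volumes_match_spec(self, control_scene):
        spec = control_scene.spec
        assert (G.mesh_volume(control_scene.meshes["presynaptic"][0])
                == pytest.approx(spec.pre_volume, rel=0.01))
        assert (G.mesh_volume(control_scene.meshes["postsynaptic"][0])
                == pytest.approx(spec.post_volume, rel=0.01))

    def test_zero_astro_degenerate_scene(self):
        spec = G.SceneSpec(n_astro=0)
        scene = G.build_simplified_scene(spec)
        assert scene.meshes["astrocyte"] == []
        assert scene.transporter_count() == 0

    def test_infeasible_distance_raises(self):
        spec = G.SceneSpec(psd_astro_distance_nm=400.0)
        with pytest.raises(G.FeasibilityError):
            G.build_simplified_scene(spec)

    def test_transporter_population_matches_density(self, control_scene):
        per_process = round(10800.0 * 0.69)
        assert control_scene.transporter_count() == pytest.approx(
            2 * per_process, abs=2)

    def test_deterministic_build(self):
        a = G.build_simplified_scene(G.CONTROL_SPEC, seed=5)
        b = G.build_simplified_scene(G.CONTROL_SPEC, seed=5)
        pa = [p.positions for p in a.populations]
        pb = [p.positions for p in b.populations]
        assert all(np.array_equal(x, y) for x, y in zip(pa, pb))

    def test_compartments_inside_world(self, control_scene):
        for mesh in control_scene.compartment_meshes():
            assert np.all(np.abs(mesh.vertices) <= 0.5 + 1e-9)


class TestNeuropilDescriptors:
    def test_occupied_fraction_of_table_volumes(self, control_scene):
        # compartments with the per-simulation table volumes: 0.07 + 0.04
        # + 0.10 in a 1 um^3 world
        meshes = {r: [] for r in G.ROLES}
        for role, vol in (("presynaptic", 0.07), ("postsynaptic", 0.04),
                          ("astrocyte", 0.10)):
            edge = vol ** (1 / 3)
            box = trimesh.creation.box(extents=(edge,) * 3)
            meshes[role].append(
                G.TriMesh(np.asarray(box.vertices), np.asarray(box.faces),
                          role=role))
        scene = G.Scene(spec=G.CONTROL_SPEC, solids=control_scene.solids,
                        meshes=meshes, populations=[])
        assert G.occupied_volume_fraction(scene) == pytest.approx(0.21, rel=1e-6)

    def test_occupied_fraction_bounds_and_build(self, control_scene):
        frac = G.occupied_volume_fraction(control_scene)
        assert 0.0 < frac < 1.0

    def test_full_world(self, control_scene):
        meshes = {r: [] for r in G.ROLES}
        box = trimesh.creation.box(extents=(1.0,) * 3)
        meshes["presynaptic"].append(
            G.TriMesh(np.asarray(box.vertices), np.asarray(box.faces),
                      role="presynaptic"))
        scene = G.Scene(spec=G.CONTROL_SPEC, solids=control_scene.solids,
                        meshes=meshes, populations=[])
        assert G.occupied_volume_fraction(scene) == pytest.approx(1.0)

    def test_local_uptake_capacity(self):
        assert G.local_uptake_capacity(10800.0, 1.79) == pytest.approx(19332.0)

    def test_capacity_ratio_identity_and_error(self):
        assert G.capacity_ratio(5.0, 5.0) == 0.0
        with pytest.raises(G.GeometryError):
            G.capacity_ratio(0.0, 5.0)


class TestSpecValidation:
    def test_cleft_taller_than_radius_rejected(self):
        spec = G.SceneSpec(cleft_height_nm=300.0, pre_radius=0.27)
        with pytest.raises(G.GeometryError, match="cleft height"):
            spec.validate()

    def test_negative_density_rejected(self):
        with pytest.raises(G.GeometryError):
            G.SceneSpec(transporter_density=-1.0).validate()
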