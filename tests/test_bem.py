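import numpy as np
import pytest

from conftest import sphere_head, square_grid
from needlefield.bem import (
    assemble_system,
    interface_net_flux,
    solid_angle_block,
    solid_angle_gradient_block,
    solve,
    surface_fields,
)
from needlefield.head import icosphere
from needlefield.surfaces import TriSurface

Z = np.array([0.0, 0.0, 1.0])


def antipodal_sources(depth=0.8, R=10.0, current=30.0):
    pos = np.array([Z * R * depth, -Z * R * depth])
    return pos, np.array([current, -current])


class TestSolidAngleKernels:
    def test_closed_surface_sums_to_4pi_inside_zero_outside(self):
        s = icosphere(2, 5.0)
        pts = np.array([[0.0, 0, 0], [1, 1, 1], [10, 0, 0], [0, -8, 0]])
        total = solid_angle_block(s.vertices[s.triangles], pts).sum(axis=0)
        assert np.allclose(total[:2], 4 * np.pi, atol=1e-10)
        assert np.allclose(total[2:], 0.0, atol=1e-10)

    def test_gradient_matches_finite_differences(self):
        s = icosphere(1, 3.0)
        tri = s.vertices[s.triangles[:4]]
        pts = np.array([[0.5, -1.0, 2.0], [4.0, 1.0, -2.0]])
        grad = solid_angle_gradient_block(tri, pts)
        h = 1e-6
        for d in range(3):
            e = np.zeros(3)
            e[d] = h
            fd = (solid_angle_block(tri, pts + e) - solid_angle_block(tri, pts - e)) / (
                2 * h
            )
            assert np.allclose(grad[:, :, d], fd, atol=1e-7)


class TestAssembly:
    def test_direct_operator_size_is_total_vertex_count(self):
        head = sphere_head([10.0, 9.3, 8.6], [0.465, 0.3, 0.3], 3)
        system = assemble_system(head, validate=False, mode="direct")
        assert system.matrix.shape == (1926, 1926)
        assert system.n_total == 3 * 642

    def test_equal_conductivity_interface_has_zero_jump(self):
        head = sphere_head([10.0, 9.0], [0.3, 0.3], 2)
        system = assemble_system(head, validate=False, mode="direct")
        assert np.all(system.sigma_jump[system.surface_slice(1)] == 0.0)

    def test_open_surface_rejected(self):
        s = icosphere(2, 10.0)
        from needlefield.head import BregmaFrame, HeadModel

        broken = HeadModel(
            [(TriSurface(s.vertices, s.triangles[:-1]), 0.3)],
            BregmaFrame(origin=np.array([0.0, 0, 10.0])),
        )
        with pytest.raises(ValueError, match="invalid surface"):
            assemble_system(broken)

    def test_vertex_budget_enforced(self):
        head = sphere_head([10.0], [0.3], 3)
        with pytest.raises(ResourceWarning):
            assemble_system(head, validate=False, vertex_budget=100)

    def test_auto_mode_selects_multidomain_for_skull_contrast(self):
        high = sphere_head([10.0, 9.3, 8.6], [0.465, 0.015, 0.3], 2)
        low = sphere_head([10.0, 9.3, 8.6], [0.465, 0.3, 0.3], 2)
        assert assemble_system(high, validate=False).mode == "multidomain"
        assert assemble_system(low, validate=False).mode == "direct"


class TestSolutionProperties:
    @pytest.fixture(scope="class", params=["direct", "multidomain"])
    def solved(self, request):
        sigmas = [0.465, 0.1, 0.3] if request.param == "direct" else [0.465, 0.015, 0.3]
        head = sphere_head([10.0, 9.3, 8.6], sigmas, 2)
        system = assemble_system(head, validate=False, mode=request.param)
        sources = antipodal_sources(depth=0.97)
        return system, sources, solve(system, sources)

    def test_zero_sources_give_zero_fields(self, solved):
        system, _, _ = solved
        sol = solve(system, (np.zeros((0, 3)), np.zeros(0)))
        assert np.all(sol.potentials == 0.0)
        assert np.all(sol.brain_J_mag == 0.0)

    def test_nonzero_net_current_rejected(self, solved):
        system, _, _ = solved
        with pytest.raises(ValueError, match="net impressed current"):
            solve(system, (np.array([[0.0, 0, 9.7]]), np.array([10.0])))

    def test_solution_is_linear_in_source_amplitude(self, solved):
        system, (pos, cur), sol = solved
        scaled = solve(system, (pos, 3.0 * cur))
        assert np.allclose(scaled.potentials, 3.0 * sol.potentials, atol=1e-12)
        assert np.allclose(scaled.brain_J_mag, 3.0 * sol.brain_J_mag, atol=1e-12)

    def test_anode_cathode_swap_negates_potentials(self, solved):
        system, (pos, cur), sol = solved
        swapped = solve(system, (pos, -cur))
        assert np.allclose(swapped.potentials, -sol.potentials, atol=1e-14)

    def test_three_electrode_montage_superposes_pairwise(self, solved):
        system, _, _ = solved
        a = np.array([0.0, 0, 9.7])
        b = np.array([0.0, 9.7, 0])
        c = np.array([9.7, 0, 0])
        full = solve(system, (np.array([a, b, c]), np.array([20.0, -8.0, -12.0])))
        pair_ab = solve(system, (np.array([a, b]), np.array([8.0, -8.0])))
        pair_ac = solve(system, (np.array([a, c]), np.array([12.0, -12.0])))
        combined = pair_ab.potentials + pair_ac.potentials
        combined -= combined.mean()
        assert np.allclose(
            full.potentials, combined, atol=1e-9 * np.abs(full.potentials).max()
        )

    def test_interior_interface_net_flux_vanishes(self, solved):
        system, _, sol = solved
        _, cur = sol.sources
        injected = np.abs(cur).max()
        for l in (1, 2):
            assert abs(interface_net_flux(system, sol, l)) < 0.02 * injected

    def test_mirror_symmetric_sources_give_mirror_potentials(self, solved):
        system, _, _ = solved
        # source pair mirrored in the x=0 plane -> V(x,y,z) = -V(-x,y,z)
        pos = np.array([[3.0, 0.0, 9.0], [-3.0, 0.0, 9.0]])
        sol = solve(system, (pos, np.array([10.0, -10.0])))
        pts = system.head.scalp.vertices
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        # icosphere vertex sets are symmetric under x -> -x
        from scipy.spatial import cKDTree

        idx = cKDTree(pts).query(mirrored)[1]
        Vs = sol.surface_potential(0)
        assert np.allclose(Vs, -Vs[idx], atol=1e-6 * np.abs(Vs).max())


class TestSurfaceFields:
    def test_constant_potential_has_zero_field(self, ico3):
        E, J = surface_fields(ico3, np.ones(ico3.n_vertices), 0.3)
        assert np.allclose(E, 0.0, atol=1e-12)
        assert np.allclose(J, 0.0, atol=1e-12)

    def test_linear_potential_on_flat_patch_recovers_uniform_gradient(self):
        sq = square_grid(n=15)
        # rotate the patch into the x-z plane so V = z is tangential
        verts = sq.vertices[:, [0, 2, 1]]  # (x, 0, y)
        patch = TriSurface(verts, sq.triangles)
        V = patch.vertices[:, 2].copy()  # volts, coordinates in mm
        E, _ = surface_fields(patch, V, 0.3)
        # E = -grad V = (0, 0, -1) V/mm = (0, 0, -1000) V/m
        assert np.allclose(E / 1000.0, [0.0, 0.0, -1.0], atol=1e-6)

    def test_current_density_is_conductivity_times_field(self, ico3):
        rng = np.random.default_rng(0)
        V = rng.normal(size=ico3.n_vertices) * 1e-3
        E, J = surface_fields(ico3, V, 0.3)
        assert np.allclose(J, 0.3 * np.linalg.norm(E, axis=1), atol=1e-15)

    def test_length_mismatch_rejected(self, ico3):
        with pytest.raises(ValueError):
            surface_fields(ico3, np.ones(5), 0.3)
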