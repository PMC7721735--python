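import numpy as np
import pytest

from neureit.forward import (
    CEMSystem,
    ConductivityField,
    ElectrodeLayout,
    ProtocolError,
    build_protocol,
    compute_jacobian,
    project_to_voxels,
    solve_forward,
)
from neureit.mesh import REGION_NERVE, build_mesh


class TestProtocol:
    def test_ring_of_14_gives_196_measurements(self):
        p = build_protocol(n_electrodes=14, offset=4)
        assert p.n_injections == 14
        assert p.n_measurements == 196
        assert p.pairs == [(i, (i + 4) % 14) for i in range(14)]

    def test_adjacent_pad_spacing(self):
        assert ElectrodeLayout(n_electrodes=14).spacing_deg == pytest.approx(
            25.714, abs=1e-3
        )

    def test_eight_electrode_offset_three(self):
        p = build_protocol(n_electrodes=8, offset=3)
        assert p.pairs == [(0, 3), (1, 4), (2, 5), (3, 6), (4, 7), (5, 0), (6, 1), (7, 2)]
        assert p.n_measurements == 64

    @pytest.mark.parametrize("offset", [0, 14, 28])
    def test_coincident_drive_pair_rejected(self, offset):
        with pytest.raises(ProtocolError):
            build_protocol(n_electrodes=14, offset=offset)

    def test_row_order_injection_major(self):
        p = build_protocol(n_electrodes=4, offset=1)
        assert p.measurement_index()[:5] == [(0, 0), (0, 1), (0, 2), (0, 3), (1, 0)]


class TestForwardSolve:
    def test_current_conservation_machine_precision(self, forward_solution, protocol):
        inj = np.zeros_like(forward_solution.electrode_currents)
        for k, (a, b) in enumerate(protocol.pairs):
            inj[k, a] = protocol.current_a
            inj[k, b] = -protocol.current_a
        assert np.abs(forward_solution.electrode_currents - inj).max() < 1e-12
        assert np.abs(forward_solution.electrode_currents.sum(axis=1)).max() < 1e-15

    def test_mean_terminal_reference(self, forward_solution):
        assert np.abs(forward_solution.electrode_voltages.mean(axis=1)).max() < 1e-12

    def test_reciprocity(self, system):
        cem = system.cem
        L = system.layout.n_electrodes

        def transfer(src, snk, ma, mb):
            c = np.zeros(L)
            c[src], c[snk] = 1e-3, -1e-3
            _, U = cem.solve_currents(c)
            return U[0, ma] - U[0, mb]

        for (a, b), (c_, d) in [((0, 4), (7, 11)), ((2, 6), (9, 13)), ((1, 5), (3, 10))]:
            fwd = transfer(a, b, c_, d)
            rev = transfer(c_, d, a, b)
            assert abs(fwd - rev) / abs(fwd) < 1e-3

    def test_conductivity_scaling(self, mesh, layout, protocol, baseline_sigma):
        """Scaling σ by c scales tissue voltages by 1/c; exactly so when the
        contact impedance (the σ-independent terminal drop) scales along."""
        sol1 = solve_forward(mesh, baseline_sigma, layout, protocol)
        sol2 = solve_forward(
            mesh, ConductivityField(2.0 * baseline_sigma.values), layout, protocol
        )
        nondrive = np.ones((protocol.n_injections, layout.n_electrodes), bool)
        for k, (a, b) in enumerate(protocol.pairs):
            nondrive[k, a] = nondrive[k, b] = False
        v1, v2 = sol1.electrode_voltages[nondrive], sol2.electrode_voltages[nondrive]
        # non-drive terminals shunt a little σ-dependent current through the
        # contact impedance, so 1/c scaling is near-exact, not exact
        assert np.abs(2.0 * v2 - v1).max() / np.abs(v1).max() < 0.02

        half_z = ElectrodeLayout(contact_impedance_ohm=500.0)
        sol3 = solve_forward(
            mesh, ConductivityField(2.0 * baseline_sigma.values), half_z, protocol
        )
        assert np.allclose(2.0 * sol3.electrode_voltages, sol1.electrode_voltages,
                           rtol=1e-10, atol=1e-15)

    def test_homogeneous_disk_analytic_solution(self, bath_mesh):
        """Against the closed-form potential of a boundary source/sink pair
        on a uniform disk, away from the pads."""
        layout = ElectrodeLayout(pad_width_deg=2.0)
        sigma = ConductivityField(np.ones(bath_mesh.n_elements))
        cem = CEMSystem(bath_mesh, sigma, layout, thickness=1.0)
        I = 1e-3
        c = np.zeros(14)
        c[0], c[7] = I, -I
        u, _ = cem.solve_currents(c)
        u = u[0]
        R = bath_mesh.external_radius
        ang = np.radians(layout.center_angles_deg)
        pa = R * np.array([np.sin(ang[0]), np.cos(ang[0])])
        pb = R * np.array([np.sin(ang[7]), np.cos(ang[7])])
        pts = bath_mesh.nodes
        r = np.hypot(pts[:, 0], pts[:, 1])
        da = np.hypot(*(pts - pa).T)
        db = np.hypot(*(pts - pb).T)
        sel = (r < 0.8 * R) & (da > 0.3 * R) & (db > 0.3 * R)
        exact = (I / np.pi) * (np.log(db) - np.log(da))
        diff = (u[sel] - exact[sel]) - (u[sel] - exact[sel]).mean()
        scale = np.abs(exact[sel] - exact[sel].mean()).max()
        assert np.abs(diff).max() / scale < 0.01

    def test_mesh_convergence_of_boundary_voltages(self, layout, protocol):
        """Boundary voltages change <1% when the target element size halves."""
        vs = []
        for h in (30e-6, 15e-6):
            m = build_mesh(target_element_size=h)
            sol = solve_forward(m, ConductivityField.baseline(m), layout, protocol)
            vs.append(sol.electrode_voltages)
        denom = np.abs(vs[1]).max()
        assert np.abs(vs[0] - vs[1]).max() / denom < 0.01

    def test_zero_like_conductivity_rejected(self, mesh):
        with pytest.raises(ValueError):
            ConductivityField(np.zeros(mesh.n_elements))


class TestJacobian:
    def test_adjoint_matches_finite_difference(self):
        """Brute-force oracle: perturb single elements by 1% of baseline and
        re-solve; compare against adjoint columns (entries above 1e-3 of the
        column max), on a coarse sub-2000-element mesh."""
        from neureit.pipeline import NerveSystem

        coarse = NerveSystem.build(target_element_size=60e-6)
        mesh, layout, protocol = coarse.mesh, coarse.layout, coarse.protocol
        assert mesh.n_elements <= 2000
        sigma = coarse.sigma
        J = coarse.jacobian
        sol0 = solve_forward(mesh, sigma, layout, protocol)
        rng = np.random.default_rng(7)
        nerve = np.nonzero(mesh.region == REGION_NERVE)[0]
        for e in rng.choice(nerve, 8, replace=False):
            d = np.zeros(mesh.n_elements)
            d[e] = 0.01 * sigma.values[e]
            sol1 = solve_forward(mesh, ConductivityField(sigma.values + d), layout, protocol)
            fd = (sol1.electrode_voltages - sol0.electrode_voltages).ravel() / d[e]
            col = J.matrix[:, e]
            big = np.abs(col) > 1e-3 * np.abs(col).max()
            assert np.abs(fd[big] - col[big]).max() / np.abs(col[big]).max() < 0.01

    def test_uniform_step_matches_first_order(self, system):
        """J·(uniform δσ) equals the voltage change of a global conductivity
        step, to first order."""
        mesh, layout, protocol = system.mesh, system.layout, system.protocol
        eps = 1e-4  # relative step keeps the linearization error tiny
        d = eps * system.sigma.values
        sol0 = solve_forward(mesh, system.sigma, layout, protocol)
        sol1 = solve_forward(mesh, ConductivityField(system.sigma.values + d), layout, protocol)
        dv_fd = (sol1.electrode_voltages - sol0.electrode_voltages).ravel()
        dv_j = system.jacobian.matrix @ d
        assert np.abs(dv_j - dv_fd).max() / np.abs(dv_fd).max() < 0.01

    def test_injection_permutation_permutes_rows(self, system):
        """Relabeling symmetry: reordering the drive pairs reorders Jacobian
        rows identically."""
        from neureit.forward import InjectionProtocol

        p = system.protocol
        perm = [5, 0, 9, 3]
        p2 = InjectionProtocol(
            pairs=[p.pairs[i] for i in perm],
            current_a=p.current_a,
            carrier_hz=p.carrier_hz,
            n_electrodes=p.n_electrodes,
        )
        J2 = compute_jacobian(system.mesh, system.sigma, system.layout, p2,
                              system=system.cem)
        L = p.n_electrodes
        for new_i, old_i in enumerate(perm):
            assert np.allclose(
                J2.matrix[new_i * L : (new_i + 1) * L],
                system.jacobian.matrix[old_i * L : (old_i + 1) * L],
            )


class TestVoxelProjection:
    def test_masked_voxel_count(self, system):
        n = system.jacobian_voxel.matrix.shape[1]
        assert n == pytest.approx(np.pi * 17.5**2, rel=0.02)

    def test_total_sensitivity_preserved(self, system):
        nerve_cols = system.jacobian.matrix[:, system.mesh.region == REGION_NERVE]
        row_sums_el = nerve_cols.sum(axis=1)
        row_sums_vox = system.jacobian_voxel.matrix.sum(axis=1)
        denom = np.abs(row_sums_el).max()
        assert np.abs(row_sums_el - row_sums_vox).max() / denom < 0.005

    def test_contained_element_maps_to_single_voxel(self, system):
        """With voxels larger than elements, an element strictly inside one
        voxel contributes only to it."""
        Jv = project_to_voxels(system.jacobian, system.mesh, voxel_size=0.2e-3)
        n = Jv.grid_shape[0]
        cent = system.mesh.element_centroids()
        tri = system.mesh.nodes[system.mesh.elements]
        ix = np.round(tri[..., 0] / Jv.voxel_size + (n - 1) / 2.0).astype(int)
        iy = np.round(tri[..., 1] / Jv.voxel_size + (n - 1) / 2.0).astype(int)
        same = (np.ptp(ix, axis=1) == 0) & (np.ptp(iy, axis=1) == 0)
        inner = same & (system.mesh.region == REGION_NERVE) & (
            np.hypot(cent[:, 0], cent[:, 1]) < 0.5e-3
        )
        e = int(np.nonzero(inner)[0][0])
        vox = np.nonzero(
            (Jv.grid_index[:, 1] == ix[e, 0]) & (Jv.grid_index[:, 0] == iy[e, 0])
        )[0][0]
        # project a Jacobian whose only nonzero column is element e
        Jsingle = system.jacobian.matrix.copy()
        keep = np.zeros(Jsingle.shape[1], bool)
        keep[e] = True
        Jsingle[:, ~keep] = 0.0
        from neureit.forward import JacobianMatrix

        Jv1 = project_to_voxels(
            JacobianMatrix(matrix=Jsingle, row_index=system.jacobian.row_index,
                           kind="element"),
            system.mesh,
            voxel_size=0.2e-3,
        )
        col_mass = np.abs(Jv1.matrix).sum(axis=0)
        assert col_mass[vox] == pytest.approx(np.abs(Jsingle[:, e]).sum(), rel=1e-12)
        assert col_mass.sum() == pytest.approx(col_mass[vox], rel=1e-12)

    def test_voxel_size_exceeding_nerve_rejected(self, system):
        with pytest.raises(ValueError):
            project_to_voxels(system.jacobian, system.mesh, voxel_size=1e-3)
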