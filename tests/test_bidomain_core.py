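"""Assembly, linear-solver contract, splitting-scheme and field properties."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from epibidomain import bidomain_core as bc
from epibidomain import cell_models as cm
from epibidomain import geometry as geo


def two_triangle_mesh():
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    cells = np.array([[0, 1, 2], [0, 2, 3]])
    return geo.LabeledMesh(verts, cells, np.array([geo.GM_STABLE] * 2))


def hand_p1_matrices(verts, cells):
    """Classical closed-form P1 stiffness/mass assembly: for a triangle with
    vertices (x_i, y_i), grad(phi_i) = (b_i, c_i)/(2A) with b_i = y_j - y_k,
    c_i = x_k - x_j; K_ij = (b_i b_j + c_i c_j)/(4A); M_ij = A(1+delta)/12."""
    n = len(verts)
    K = np.zeros((n, n))
    M = np.zeros((n, n))
    for tri in cells:
        x = verts[tri, 0]
        y = verts[tri, 1]
        A = 0.5 * abs(
            (x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0])
        )
        b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
        c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
        for a in range(3):
            for d in range(3):
                K[tri[a], tri[d]] += (b[a] * b[d] + c[a] * c[d]) / (4.0 * A)
                M[tri[a], tri[d]] += A * (2.0 if a == d else 1.0) / 12.0
    return K, M


class TestAssembly:
    def test_matches_hand_assembled_matrices(self):
        mesh = two_triangle_mesh()
        table = {geo.GM_STABLE: (1.0, 1.0)}
        cond = geo.build_conductivity_map(mesh, table)
        ops = bc.assemble_operators(mesh, cond, bc.PhysicalParams(chi=1.0, Cm=1.0))
        K_ref, M_ref = hand_p1_matrices(mesh.vertices, mesh.cells)
        np.testing.assert_allclose(ops.K_i.toarray(), K_ref, atol=1e-14)
        np.testing.assert_allclose(ops.K_ie.toarray(), 2.0 * K_ref, atol=1e-14)
        np.testing.assert_allclose(ops.M.toarray(), M_ref, atol=1e-14)

    def test_stiffness_annihilates_linear_functions(self, slice_mesh):
        """With uniform identity tensors, the stiffness applied to nodal
        values of a linear function vanishes at interior nodes."""
        table = {lab: (1.0, 1.0) for lab in geo.ALL_LABELS}
        cond = geo.build_conductivity_map(slice_mesh, table)
        ops = bc.assemble_operators(slice_mesh, cond, bc.PhysicalParams())
        f = 2.0 * slice_mesh.vertices[:, 0] - 3.0 * slice_mesh.vertices[:, 1] + 1.0
        r = ops.K_i @ f
        x, y = slice_mesh.vertices.T
        interior = (
            (x > x.min() + 1e-9) & (x < x.max() - 1e-9)
            & (y > y.min() + 1e-9) & (y < y.max() - 1e-9)
        )
        assert np.max(np.abs(r[interior])) < 1e-12

    def test_neumann_compatibility(self, slice_mesh):
        cond = geo.build_conductivity_map(slice_mesh,
                                          wm_spec=geo.AnisotropySpec())
        ops = bc.assemble_operators(slice_mesh, cond, bc.PhysicalParams())
        ones = np.ones(ops.n)
        assert np.max(np.abs(ops.K_ie @ ones)) < 1e-12
        assert np.max(np.abs(ops.K_i @ ones)) < 1e-12

    def test_null_space_consistency(self, slice_mesh):
        """The pure-Neumann two-field operator annihilates (v=0, u=const)."""
        cond = geo.build_conductivity_map(slice_mesh,
                                          wm_spec=geo.AnisotropySpec())
        ops = bc.assemble_operators(slice_mesh, cond, bc.PhysicalParams())
        A = ops.pure_neumann_operator()
        z = np.concatenate([np.zeros(ops.n), np.full(ops.n, 3.7)])
        assert np.max(np.abs(A @ z)) < 1e-10

    def test_operators_symmetric(self, slice_mesh):
        cond = geo.build_conductivity_map(slice_mesh,
                                          wm_spec=geo.AnisotropySpec())
        ops = bc.assemble_operators(slice_mesh, cond, bc.PhysicalParams())
        for K in (ops.K_i, ops.K_ie, ops.M):
            d = (K - K.T).tocoo()
            asym = np.max(np.abs(d.data)) if d.nnz else 0.0
            assert asym < 1e-12

    def test_nonpositive_tensor_rejected(self):
        mesh = two_triangle_mesh()
        Mi = np.broadcast_to(np.eye(2), (2, 2, 2)).copy()
        Me = Mi.copy()
        cond = geo.ConductivityMap(Mi, Me)
        cond.Me[1] = [[1.0, 0.0], [0.0, -1.0]]  # mutate past validation
        with pytest.raises(bc.SolverError, match="cell 1"):
            bc.assemble_operators(mesh, cond, bc.PhysicalParams())

    def test_3d_tet_assembly(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        cells = np.array([[0, 1, 2, 3]])
        mesh = geo.LabeledMesh(verts, cells, np.array([geo.GM_STABLE]))
        cond = geo.build_conductivity_map(mesh, {geo.GM_STABLE: (1.0, 1.0)})
        ops = bc.assemble_operators(mesh, cond, bc.PhysicalParams())
        # reference tetrahedron: K = sum over faces; known closed form gives
        # row sums zero and K[0,0] = 3 * (1/6) * |grad(phi_0)|^2 with
        # grad(phi_0) = (-1,-1,-1), volume 1/6
        K = ops.K_i.toarray()
        assert np.max(np.abs(K.sum(axis=1))) < 1e-14
        assert K[0, 0] == pytest.approx(0.5)
        assert ops.M.toarray().sum() == pytest.approx(1.0 / 6.0)


class TestLinearSolve:
    def _system(self):
        mesh = geo.build_idealized_slice(cells_across_gm=1,
                                         horizontal_coarsening=4.0)
        cond = geo.build_conductivity_map(mesh)
        ops = bc.assemble_operators(mesh, cond, bc.PhysicalParams())
        return ops.coupled_matrix(0.025, 0.5)

    def test_zero_rhs_gives_zero(self):
        A = self._system()
        cfg = bc.SolverConfig()
        x = bc.solve_linear_system(A, np.zeros(A.shape[0]), cfg)
        assert not np.any(x)

    def test_matches_dense_direct_solve(self):
        A = self._system()
        assert A.shape[0] <= 400
        rng = np.random.default_rng(5)
        rhs = rng.standard_normal(A.shape[0])
        cfg = bc.SolverConfig(linear_solver="gmres", krylov_rtol=1e-12)
        x = bc.solve_linear_system(A, rhs, cfg)
        x_ref = np.linalg.solve(A.toarray(), rhs)
        assert np.linalg.norm(x - x_ref) / np.linalg.norm(x_ref) < 1e-8

    def test_residual_contract(self):
        A = self._system()
        rng = np.random.default_rng(6)
        rhs = rng.standard_normal(A.shape[0])
        cfg = bc.SolverConfig(linear_solver="gmres")
        x = bc.solve_linear_system(A, rhs, cfg)
        resid = np.linalg.norm(A @ x - rhs)
        assert resid <= 10 * max(cfg.krylov_rtol * np.linalg.norm(rhs),
                                 cfg.krylov_atol)

    def test_lu_path(self):
        A = self._system()
        rng = np.random.default_rng(7)
        rhs = rng.standard_normal(A.shape[0])
        x = bc.solve_linear_system(A, rhs, bc.SolverConfig(linear_solver="lu"))
        assert np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs) < 1e-10


def small_passive_sim(theta=0.5, linear_solver="lu"):
    mesh = geo.build_idealized_slice(cells_across_gm=2,
                                     horizontal_coarsening=2.0)
    cond = geo.build_conductivity_map(mesh, wm_spec=geo.AnisotropySpec())
    cfg = bc.SolverConfig(theta=theta, linear_solver=linear_solver)
    return bc.BidomainSimulation(mesh, cond, bc.PhysicalParams(), {}, cfg)


class TestSplitting:
    def test_zero_data_stays_zero(self):
        sim = small_passive_sim()
        for _ in range(20):
            sim.step()
        assert not np.any(sim.fields.v)
        assert not np.any(sim.fields.u_e)

    def test_one_step_identity_with_no_sources(self):
        sim = small_passive_sim()
        res = sim.run(0.025)
        assert res.times[-1] == pytest.approx(0.025)
        assert not np.any(sim.fields.v)

    def test_gauge_invariance(self):
        """Adding a constant to u_e before a step leaves v unchanged."""
        rng = np.random.default_rng(8)
        sims = [small_passive_sim(), small_passive_sim()]
        v0 = rng.standard_normal(sims[0].ops.n)
        for s in sims:
            s.fields.v = v0.copy()
        sims[1].fields.u_e = sims[1].fields.u_e + 42.0
        for s in sims:
            s.step()
        assert np.max(np.abs(sims[0].fields.v - sims[1].fields.v)) < 1e-10
        assert np.max(np.abs(sims[0].fields.u_e - sims[1].fields.u_e)) < 1e-10

    def test_regauged_zero_mean(self):
        sim = small_passive_sim()
        rng = np.random.default_rng(9)
        sim.fields.v = rng.standard_normal(sim.ops.n)
        sim.step()
        w = sim.ops.mean_vec
        assert abs(w @ sim.fields.u_e) / w.sum() < 1e-10

    @pytest.mark.parametrize("theta", [0.5, 1.0])
    def test_energy_decay_without_sources(self, theta):
        """The discrete energy (chi Cm / 2) v^T M v never grows when no
        ionic current drives the system and theta >= 1/2."""
        sim = small_passive_sim(theta=theta)
        rng = np.random.default_rng(10)
        sim.fields.v = rng.standard_normal(sim.ops.n)
        energy = [float(sim.fields.v @ (sim.ops.M @ sim.fields.v))]
        for _ in range(30):
            sim.step()
            energy.append(float(sim.fields.v @ (sim.ops.M @ sim.fields.v)))
        diffs = np.diff(energy)
        assert np.all(diffs <= 1e-12 * energy[0])

    def test_splitting_second_order_in_dt(self):
        """Manufactured-solution study: with a second-order reaction substep
        the Strang/theta(1/2) scheme converges at order >= 2 in dt."""
        mesh = geo.build_idealized_slice(10, 10, 2.5, 3, 0,
                                         passive_coarsening=1.0)
        table = {lab: (1.0, 1.0) for lab in geo.ALL_LABELS}
        cond = geo.build_conductivity_map(mesh, table)
        phys = bc.PhysicalParams(chi=1.0, Cm=1.0)
        k = np.pi
        lam = 2 * k ** 2

        def phi(x):
            return np.cos(k * x[:, 0]) * np.cos(k * x[:, 1])

        def f_v(x, t):
            return phi(x) * (np.cos(t) + lam * (np.sin(t) + np.cos(t)))

        def f_u(x, t):
            return phi(x) * lam * (np.sin(t) + 2.0 * np.cos(t))

        def run(dt):
            cfg = bc.SolverConfig(dt=dt, theta=0.5, ode_scheme="rk2")
            sim = bc.BidomainSimulation(mesh, cond, phys, {}, cfg,
                                        forcing=(f_v, f_u))
            sim.fields.v = np.zeros(mesh.n_vertices)
            sim.fields.u_e = phi(mesh.vertices)
            for _ in range(int(round(1.0 / dt))):
                sim.step()
            return sim.fields.v.copy()

        ref = run(0.003125)
        errs = [np.max(np.abs(run(dt) - ref)) for dt in (0.1, 0.05, 0.025)]
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) >= 1.9

    def test_mixed_regime_coefficients_rejected(self):
        mesh = geo.build_idealized_slice(cells_across_gm=2,
                                         horizontal_coarsening=2.0)
        cond = geo.build_conductivity_map(mesh, wm_spec=geo.AnisotropySpec())
        regimes = {
            geo.GM_STABLE: cm.CressmanParams(k_o_inf=4.0, g_k=30.0),
            geo.GM_UNSTABLE: cm.CressmanParams(k_o_inf=8.0),
        }
        with pytest.raises(ValueError, match="k_o_inf"):
            bc.BidomainSimulation(mesh, cond, bc.PhysicalParams(), regimes,
                                  bc.SolverConfig())


def test_wavefront_count_stable_under_refinement(slice_mesh, model_c_result):
    """The number of wavefronts passing a stable-GM probe in the first
    second is identical on the resolved mesh and its uniform refinement."""
    from epibidomain.spectral_analysis import count_spikes
    from conftest import _run_model_c

    j = model_c_result.probe_names.index("gm_stable_R")
    base_count = len(count_spikes(model_c_result.trace(j, "v")))
    refined = geo.refine_uniform(slice_mesh)
    res = _run_model_c(refined, 1000.0)
    ref_count = len(count_spikes(res.trace(j, "v")))
    assert ref_count == base_count


class TestTissue3D:
    """Interface validation of the solver on a tiny synthetic labeled
    tetrahedral mesh (a cube split into tetrahedra)."""

    def cube_mesh(self):
        from itertools import product
        pts = np.array(list(product([0.0, 1.0], repeat=3)))
        # 6-tet Kuhn subdivision of the unit cube
        tets = np.array([
            [0, 1, 3, 7], [0, 1, 5, 7], [0, 2, 3, 7],
            [0, 2, 6, 7], [0, 4, 5, 7], [0, 4, 6, 7],
        ])
        labels = np.array([geo.GM_STABLE] * 3 + [geo.CSF] * 3)
        return geo.LabeledMesh(pts, tets, labels)

    def test_volume_and_conformity(self):
        mesh = self.cube_mesh()
        mesh.validate_conforming()
        assert geo.cell_volumes(mesh).sum() == pytest.approx(1.0)

    def test_passive_run_stays_zero(self):
        mesh = self.cube_mesh()
        cond = geo.build_conductivity_map(mesh)
        sim = bc.BidomainSimulation(mesh, cond, bc.PhysicalParams(), {},
                                    bc.SolverConfig())
        res = sim.run(0.25)
        assert not res.incomplete
        assert not np.any(sim.fields.v) and not np.any(sim.fields.u_e)

    def test_active_run_produces_fields(self):
        mesh = self.cube_mesh()
        cond = geo.build_conductivity_map(mesh)
        regimes = {geo.GM_STABLE: cm.CressmanParams(k_o_inf=8.0)}
        probes = np.array([[0.4, 0.4, 0.4]])
        sim = bc.BidomainSimulation(mesh, cond, bc.PhysicalParams(), regimes,
                                    bc.SolverConfig(), probes=probes)
        res = sim.run(5.0)
        assert not res.incomplete
        assert np.all(np.isfinite(res.v))
        assert np.any(res.u_e != 0.0)

    def test_3d_gauge_invariance(self):
        mesh = self.cube_mesh()
        cond = geo.build_conductivity_map(mesh)
        sims = [
            bc.BidomainSimulation(mesh, cond, bc.PhysicalParams(), {},
                                  bc.SolverConfig())
            for _ in range(2)
        ]
        rng = np.random.default_rng(12)
        v0 = rng.standard_normal(8)
        for s in sims:
            s.fields.v = v0.copy()
        sims[1].fields.u_e += 11.0
        for s in sims:
            s.step()
        assert np.max(np.abs(sims[0].fields.v - sims[1].fields.v)) < 1e-10
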