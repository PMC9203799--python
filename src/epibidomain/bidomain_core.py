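"""Finite-element bidomain solver with operator splitting against cell ODEs.

The bidomain system couples the transmembrane potential v and extracellular
potential u_e through per-cell intracellular/extracellular conductivity
tensors M_i, M_e:

    div(M_i grad v) + div(M_i grad u_e) = chi*Cm dv/dt + chi*I_ion
    div(M_i grad v) + div((M_i+M_e) grad u_e) = 0

with homogeneous Neumann conditions on both fluxes, which leaves u_e defined
only up to a constant; the gauge is fixed by a mass-weighted zero-mean
constraint enforced through a Lagrange multiplier, keeping the linear system
nonsingular and mesh-independent.

Space: first-order continuous Lagrange elements on triangles/tetrahedra.
Time: Strang splitting — half a step of the cell ODEs (forward Euler by
default), one theta-scheme step (Crank-Nicolson by default) of the linear
PDE block, half a step of the ODEs.  The cell model runs only at nodes of
active tissue; elsewhere I_ion = 0 and v diffuses passively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from epibidomain import cell_models as cm
from epibidomain import geometry as geo
from epibidomain.spectral_analysis import ProbeTrace

__all__ = [
    "PhysicalParams",
    "BidomainFields",
    "SolverConfig",
    "SimulationResult",
    "BidomainOperators",
    "assemble_operators",
    "solve_linear_system",
    "BidomainSimulation",
    "splitting_step",
    "run_simulation",
    "SolverError",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhysicalParams:
    """chi: membrane area per tissue volume [1/cm]; Cm: capacitance [uF/cm^2]."""

    chi: float = 1.26e3
    Cm: float = 1.0

    def __post_init__(self) -> None:
        if self.chi <= 0 or self.Cm <= 0:
            raise ValueError("chi and Cm must be positive")


@dataclass
class BidomainFields:
    """Nodal fields at one instant: v, u_e in mV, time in ms."""

    v: np.ndarray
    u_e: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, float)
        self.u_e = np.asarray(self.u_e, float)
        if self.v.shape != self.u_e.shape:
            raise ValueError("v and u_e must be conformable")


@dataclass
class SolverConfig:
    dt: float = 0.025  # ms
    theta: float = 0.5  # PDE time weight; 1/2 keeps the splitting second order
    krylov_rtol: float = 1e-5
    krylov_atol: float = 1e-50
    max_iterations: int = 1000
    active_labels: frozenset = frozenset(geo.GM_LABELS)
    linear_solver: str = "lu"  # "lu" (prefactorized) or "gmres" (+ILU)
    lumped_mass: bool = False
    ode_scheme: str = "fe"  # "fe" | "rk2"
    ode_substeps: int = 1
    sample_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.krylov_rtol <= 0 or self.krylov_atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.linear_solver not in ("lu", "gmres"):
            raise ValueError("linear_solver must be 'lu' or 'gmres'")
        if self.ode_scheme not in ("fe", "rk2"):
            raise ValueError("ode_scheme must be 'fe' or 'rk2'")


@dataclass
class SimulationResult:
    """Probe time series plus solver bookkeeping.

    times: ms, shared by all traces; v/u_e arrays are (n_samples, n_probes).
    """

    times: np.ndarray
    v: np.ndarray
    u_e: np.ndarray
    probe_names: list[str]
    event_log: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)
    incomplete: bool = False

    def trace(self, probe: int | str, which: str = "u_e") -> ProbeTrace:
        j = probe if isinstance(probe, int) else self.probe_names.index(probe)
        data = self.u_e if which == "u_e" else self.v
        name = self.probe_names[j] if self.probe_names else str(j)
        return ProbeTrace(self.times, data[:, j], label=f"{name}:{which}")


# ---------------------------------------------------------------------------
# assembly


def _p1_gradients(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric basis gradients and volumes for all cells.

    pts: (m, d+1, d) vertex coordinates; returns (grads (m, d+1, d), vol (m,)).
    """
    d = pts.shape[2]
    T = pts[:, 1:, :] - pts[:, :1, :]  # (m, d, d) rows are edge vectors
    det = np.linalg.det(T)
    vol = np.abs(det) / (2.0 if d == 2 else 6.0)
    Tinv = np.linalg.inv(T)  # columns map to barycentric grads
    grads = np.empty((pts.shape[0], d + 1, d))
    grads[:, 1:, :] = np.swapaxes(Tinv, 1, 2)
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vol


def _stiffness(mesh: geo.LabeledMesh, tensors: np.ndarray) -> sp.csr_matrix:
    grads, vol = _p1_gradients(mesh.vertices[mesh.cells])
    flux = np.einsum("mab,mib->mia", tensors, grads)  # M . grad(phi_i)
    local = np.einsum("mia,mja,m->mij", flux, grads, vol)
    k = mesh.cells.shape[1]
    rows = np.repeat(mesh.cells, k, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, k)).ravel()
    A = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_vertices,) * 2
    )
    return A.tocsr()


def _mass(mesh: geo.LabeledMesh, lumped: bool = False) -> sp.csr_matrix:
    vol = geo.cell_volumes(mesh)
    k = mesh.cells.shape[1]
    d = k - 1
    scale = vol / ((d + 1) * (d + 2))
    local = np.ones((len(vol), k, k)) + np.eye(k)
    local *= scale[:, None, None]
    rows = np.repeat(mesh.cells, k, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, k)).ravel()
    M = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_vertices,) * 2
    ).tocsr()
    if lumped:
        M = sp.diags(np.asarray(M.sum(axis=1)).ravel()).tocsr()
    return M


@dataclass
class BidomainOperators:
    """Discrete operator set: stiffness for M_i and M_i+M_e, scaled mass, and
    the mean-constraint vector fixing the u_e gauge."""

    K_i: sp.csr_matrix
    K_ie: sp.csr_matrix
    M: sp.csr_matrix  # plain mass matrix
    chi_cm: float  # chi * Cm scaling of the time-derivative term
    mean_vec: np.ndarray  # M @ 1; <u_e> = mean_vec . u_e / sum(mean_vec)
    n: int

    def coupled_matrix(self, dt: float, theta: float) -> sp.csc_matrix:
        """The (v, u_e, multiplier) block matrix of one theta-scheme step.

        v is theta-averaged; the algebraic variable u_e appears once, at the
        theta point, so that eliminating it reproduces the theta scheme on
        the Schur-reduced parabolic operator (second order at theta = 1/2).
        """
        a = (self.chi_cm / dt) * self.M + theta * self.K_i
        m = self.mean_vec[:, None]
        top = sp.hstack([a, self.K_i, sp.csr_matrix((self.n, 1))])
        mid = sp.hstack([theta * self.K_i, self.K_ie, sp.csr_matrix(m)])
        bot = sp.hstack([sp.csr_matrix((1, self.n)), sp.csr_matrix(m.T),
                         sp.csr_matrix((1, 1))])
        return sp.vstack([top, mid, bot]).tocsc()

    def pure_neumann_operator(self) -> sp.csr_matrix:
        """The unaugmented 2n x 2n two-field operator; its null space is
        spanned by (v = 0, u_e = constant)."""
        top = sp.hstack([self.K_i, self.K_i])
        mid = sp.hstack([self.K_i, self.K_ie])
        return sp.vstack([top, mid]).tocsr()


def assemble_operators(
    mesh: geo.LabeledMesh,
    cond: geo.ConductivityMap,
    phys: PhysicalParams,
    lumped_mass: bool = False,
) -> BidomainOperators:
    """Assemble P1 stiffness/mass operators for the bidomain system."""
    eigs = np.linalg.eigvalsh(cond.Me)
    if np.any(eigs <= 0):
        bad = int(np.argmax(np.any(eigs <= 0, axis=1)))
        raise SolverError(f"non-positive-definite Me tensor at cell {bad}")
    K_i = _stiffness(mesh, cond.Mi)
    K_e = _stiffness(mesh, cond.Me)
    M = _mass(mesh, lumped=lumped_mass)
    mean_vec = np.asarray(M @ np.ones(mesh.n_vertices))
    return BidomainOperators(
        K_i=K_i, K_ie=(K_i + K_e).tocsr(), M=M,
        chi_cm=phys.chi * phys.Cm, mean_vec=mean_vec, n=mesh.n_vertices,
    )


# ---------------------------------------------------------------------------
# linear solves


def solve_linear_system(
    matrix: sp.spmatrix,
    rhs: np.ndarray,
    cfg: SolverConfig,
    factorization=None,
) -> np.ndarray:
    """Solve the coupled step system to the configured tolerance.

    "lu" uses a (pre)factorized sparse LU; "gmres" uses restarted GMRES with
    an incomplete-LU preconditioner and the configured relative/absolute
    tolerances.  Raises SolverError on non-convergence, with the residual.
    """
    rhs = np.asarray(rhs, float)
    if not np.any(rhs):
        return np.zeros_like(rhs)
    if cfg.linear_solver == "lu":
        lu = factorization if factorization is not None else spla.splu(matrix.tocsc())
        x = lu.solve(rhs)
    else:
        ilu = factorization if factorization is not None else spla.spilu(
            matrix.tocsc(), drop_tol=1e-6, fill_factor=20.0
        )
        prec = spla.LinearOperator(matrix.shape, ilu.solve)
        x, info = spla.gmres(
            matrix, rhs, rtol=cfg.krylov_rtol, atol=cfg.krylov_atol,
            restart=50, maxiter=cfg.max_iterations, M=prec,
        )
        if info != 0:
            res = float(np.linalg.norm(matrix @ x - rhs))
            raise SolverError(
                f"GMRES failed to converge (info={info}, residual={res:.3e})"
            )
    resid = float(np.linalg.norm(matrix @ x - rhs))
    bound = max(cfg.krylov_rtol * float(np.linalg.norm(rhs)), cfg.krylov_atol)
    if cfg.linear_solver == "gmres" and resid > 10.0 * bound:
        raise SolverError(f"residual {resid:.3e} above tolerance {bound:.3e}")
    return x


# ---------------------------------------------------------------------------
# the coupled simulation


class BidomainSimulation:
    """Holds the assembled system and marches the coupled model in time.

    `cell_regimes` maps tissue labels to CressmanParams for the labels where
    the cell ODEs run (the config's active_labels); all other tissue is
    passive (I_ion = 0).  `forcing` optionally supplies (f_v(x, t), f_u(x, t))
    volumetric source terms for verification studies.
    """

    def __init__(
        self,
        mesh: geo.LabeledMesh,
        cond: geo.ConductivityMap,
        phys: PhysicalParams,
        cell_regimes: dict[str, cm.CressmanParams] | None,
        cfg: SolverConfig,
        probes: np.ndarray | None = None,
        probe_names: list[str] | None = None,
        forcing=None,
        initial_states: dict[str, cm.CressmanState] | None = None,
    ) -> None:
        self.mesh = mesh
        self.phys = phys
        self.cfg = cfg
        self.forcing = forcing
        self.ops = assemble_operators(mesh, cond, phys, lumped_mass=cfg.lumped_mass)
        self.A = self.ops.coupled_matrix(cfg.dt, cfg.theta)
        if cfg.linear_solver == "lu":
            self._fact = spla.splu(self.A)
        else:
            self._fact = spla.spilu(self.A.tocsc(), drop_tol=1e-6, fill_factor=20.0)

        # node -> cell regime; a node is active if any adjacent cell is
        self.cell_regimes = dict(cell_regimes or {})
        n = mesh.n_vertices
        self.node_label = np.full(n, "", dtype="U12")
        order = [geo.SCALP, geo.SKULL, geo.CSF, geo.WM, geo.WM_LEFT,
                 geo.WM_RIGHT, geo.GM_STABLE, geo.GM_UNSTABLE]
        for label in order:  # later entries take precedence at interfaces
            m = mesh.cell_labels == label
            if np.any(m):
                self.node_label[np.unique(mesh.cells[m])] = label
        self.active_nodes = np.flatnonzero(
            np.isin(self.node_label, list(self.cell_regimes))
            & np.isin(self.node_label, list(cfg.active_labels))
        )
        regimes = sorted({str(self.node_label[i]) for i in self.active_nodes})
        self._params_by_regime = {r: self.cell_regimes[r] for r in regimes}
        # per-active-node bath potassium (the only regime-dependent coefficient
        # allowed to vary node-wise); remaining coefficients must agree
        base = None
        k_arr = np.empty(len(self.active_nodes))
        for r, p in self._params_by_regime.items():
            if base is None:
                base = p
            elif p.with_(k_o_inf=base.k_o_inf) != base:
                raise ValueError(
                    "cell regimes may differ only in k_o_inf in one tissue run"
                )
            k_arr[self.node_label[self.active_nodes] == r] = p.k_o_inf
        self._base_params = base
        self._k_arr = k_arr

        self.probes = probes
        self.probe_names = probe_names or (
            [f"p{i}" for i in range(len(probes))] if probes is not None else []
        )
        if probes is not None and len(probes):
            ci, w = geo.locate_points(mesh, probes)
            rows = np.repeat(np.arange(len(probes)), mesh.cells.shape[1])
            cols = mesh.cells[ci].ravel()
            self._P = sp.coo_matrix(
                (w.ravel(), (rows, cols)), shape=(len(probes), n)
            ).tocsr()
        else:
            self._P = None

        # initial data
        self.fields = BidomainFields(v=np.zeros(n), u_e=np.zeros(n), t=0.0)
        self.states = np.zeros((len(self.active_nodes), 6))
        if base is not None:
            # every neuron starts from the same documented seed state unless
            # overridden; regimes differ only through their bath potassium
            init = dict(initial_states or {})
            for r in self._params_by_regime:
                s = init.get(r, cm.SEED_STATE)
                sel = self.node_label[self.active_nodes] == r
                self.states[sel] = s.as_array()
            # passive tissue starts at the same membrane potential as the
            # active tissue to avoid an artificial initial jump
            rest_v = float(self.states[0, 0]) if len(self.states) else 0.0
            self.fields.v[:] = rest_v
            self.fields.v[self.active_nodes] = self.states[:, 0]
        self.event_log: dict = {"steps": 0, "linear_solver": cfg.linear_solver}

    # -- pieces -------------------------------------------------------------

    def _ode_half_step(self, half_dt: float, t0: float) -> None:
        if len(self.active_nodes) == 0:
            return
        sub = max(1, self.cfg.ode_substeps)
        dt = half_dt / sub
        y = self.states
        p = list(self._base_params.as_tuple())
        p[0] = self._k_arr  # node-wise bath potassium
        p = tuple(p)
        for _ in range(sub):
            d1 = cm._rhs_arrays(*(y[:, i] for i in range(6)), p)[1:]
            if self.cfg.ode_scheme == "fe":
                y = y + dt * np.column_stack(d1)
            else:  # midpoint
                ymid = y + 0.5 * dt * np.column_stack(d1)
                d2 = cm._rhs_arrays(*(ymid[:, i] for i in range(6)), p)[1:]
                y = y + dt * np.column_stack(d2)
        if not np.all(np.isfinite(y)):
            raise SolverError(f"cell states non-finite after ODE step dt={dt}")
        np.clip(y[:, 1:3], 0.0, 1.0, out=y[:, 1:3])
        self.states = y

    def _reaction_forcing_step(self, half_dt: float, t0: float) -> None:
        """Verification hook: advance v by the reaction forcing f_v."""
        f_v = self.forcing[0]
        x = self.mesh.vertices
        if self.cfg.ode_scheme == "fe":
            self.fields.v += half_dt * f_v(x, t0) / self.ops.chi_cm
        else:
            mid = f_v(x, t0 + 0.5 * half_dt)
            self.fields.v += half_dt * mid / self.ops.chi_cm

    def _pde_step(self) -> None:
        f = self.fields
        cfg = self.cfg
        ops = self.ops
        th = cfg.theta
        rhs_top = (ops.chi_cm / cfg.dt) * (ops.M @ f.v) - (1.0 - th) * (
            ops.K_i @ f.v
        )
        rhs_mid = -(1.0 - th) * (ops.K_i @ f.v)
        if self.forcing is not None:
            f_u = self.forcing[1]
            rhs_mid = rhs_mid + ops.M @ f_u(
                self.mesh.vertices, f.t + th * cfg.dt
            )
        rhs = np.concatenate([rhs_top, rhs_mid, [0.0]])
        x = solve_linear_system(self.A, rhs, cfg, factorization=self._fact)
        n = ops.n
        f.v = x[:n]
        f.u_e = x[n:2 * n]
        # the multiplier enforces the gauge; re-project for safety
        mean = float(ops.mean_vec @ f.u_e / ops.mean_vec.sum())
        f.u_e -= mean

    # -- public stepping ----------------------------------------------------

    def step(self) -> None:
        """One Strang-split step: half ODE, theta-scheme PDE, half ODE."""
        dt = self.cfg.dt
        t0 = self.fields.t
        if self.forcing is not None:
            self._reaction_forcing_step(dt / 2.0, t0)
            self._pde_step()
            self._reaction_forcing_step(dt / 2.0, t0 + dt / 2.0)
        else:
            self._ode_half_step(dt / 2.0, t0)
            self.fields.v[self.active_nodes] = self.states[:, 0]
            self._pde_step()
            self.states[:, 0] = self.fields.v[self.active_nodes]
            self._ode_half_step(dt / 2.0, t0 + dt / 2.0)
            self.fields.v[self.active_nodes] = self.states[:, 0]
        self.fields.t = t0 + dt
        self.event_log["steps"] += 1

    def run(self, duration_ms: float) -> SimulationResult:
        """March to `duration_ms`, sampling probes every `sample_stride` steps."""
        if duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        n_steps = int(round(duration_ms / self.cfg.dt))
        stride = max(1, self.cfg.sample_stride)
        n_samples = n_steps // stride + 1
        n_probes = self._P.shape[0] if self._P is not None else 0
        times = np.empty(n_samples)
        V = np.empty((n_samples, n_probes))
        U = np.empty((n_samples, n_probes))

        def sample(j):
            times[j] = self.fields.t
            if self._P is not None:
                V[j] = self._P @ self.fields.v
                U[j] = self._P @ self.fields.u_e

        sample(0)
        j = 1
        try:
            for k in range(1, n_steps + 1):
                self.step()
                if k % stride == 0:
                    sample(j)
                    j += 1
        except (SolverError, FloatingPointError) as exc:
            self.event_log["error"] = str(exc)
            return SimulationResult(
                times[:j], V[:j], U[:j], self.probe_names,
                event_log=dict(self.event_log), incomplete=True,
            )
        return SimulationResult(
            times, V, U, self.probe_names, event_log=dict(self.event_log)
        )


def splitting_step(sim: BidomainSimulation) -> BidomainFields:
    """Advance one split step and return the updated fields (functional view
    of BidomainSimulation.step)."""
    sim.step()
    return sim.fields


def run_simulation(
    mesh: geo.LabeledMesh,
    cond: geo.ConductivityMap,
    phys: PhysicalParams,
    cell_regimes: dict[str, cm.CressmanParams],
    cfg: SolverConfig,
    duration_ms: float,
    probes: np.ndarray | None = None,
    probe_names: list[str] | None = None,
) -> SimulationResult:
    """Set up and run a coupled simulation (see BidomainSimulation)."""
    sim = BidomainSimulation(
        mesh, cond, phys, cell_regimes, cfg, probes=probes,
        probe_names=probe_names,
    )
    return sim.run(duration_ms)
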