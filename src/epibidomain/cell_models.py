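"""Cressman-type conductance-based point-neuron model with slow ion dynamics.

The model couples a Hodgkin--Huxley-style membrane (sodium, potassium and
chloride leak currents, instantaneous sodium activation) to slow dynamics of
the extracellular potassium concentration ``K_o`` and intracellular sodium
``Na_i``.  Potassium is cleared by a Na/K pump, glial buffering and lateral
diffusion toward a bath concentration ``k_o_inf``; that single parameter
switches the neuron between a stable resting regime (4 mM) and a seizure-like
bursting regime (8 mM).

Units follow the usual membrane convention: mV, ms, mS/cm^2, uF/cm^2,
uA/cm^2 and mM.  The slow ion equations are written per second in the source
formulation and are divided by ``tau_slow`` (1000 ms/s) here so the whole
system advances in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
import math

import numpy as np

try:  # numba accelerates the long point-model trajectories; optional
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not args or not callable(args[0]) else args[0]


__all__ = [
    "CressmanParams",
    "CressmanState",
    "IonicCurrentOutput",
    "cressman_rhs",
    "cressman_rest_state",
    "forward_euler_step",
    "integrate_point_model",
    "SEED_STATE",
]


@dataclass(frozen=True)
class CressmanParams:
    """Coefficients of the Cressman single-neuron model.

    Defaults are the published values of the source model (with its
    corrected ion-rate constants); ``k_o_inf`` is the bath potassium
    concentration that selects the regime: 4 mM stable, 8 mM seizure-like.
    """

    k_o_inf: float = 4.0  # bath / steady-state extracellular K+ [mM]
    Cm: float = 1.0  # membrane capacitance [uF/cm^2]
    g_na: float = 100.0  # max Na conductance [mS/cm^2]
    g_na_leak: float = 0.0175  # Na leak conductance [mS/cm^2]
    g_k: float = 40.0  # max K conductance [mS/cm^2]
    g_k_leak: float = 0.05  # K leak conductance [mS/cm^2]
    g_ahp: float = 0.01  # Ca-gated afterhyperpolarisation conductance [mS/cm^2]
    g_cl_leak: float = 0.05  # Cl leak conductance [mS/cm^2]
    phi: float = 3.0  # gating rate scale [dimensionless]
    cl_i: float = 6.0  # intracellular chloride [mM]
    cl_o: float = 130.0  # extracellular chloride [mM]
    na_i0: float = 18.0  # reference intracellular Na [mM]
    na_o0: float = 144.0  # reference extracellular Na [mM]
    k_i0: float = 140.0  # reference intracellular K [mM]
    beta_vol: float = 7.0  # intra/extracellular volume ratio
    rho_pump: float = 1.25  # Na/K pump rate [mM/s]
    g_glia: float = 200.0 / 3.0  # glial K uptake strength [mM/s]
    eps_diffusion: float = 4.0 / 3.0  # lateral K diffusion rate [1/s]
    tau_slow: float = 1000.0  # ms per unit of slow (per-second) time
    g_ca: float = 0.1  # Ca channel conductance feeding the AHP [mS/cm^2]
    e_ca: float = 120.0  # Ca reversal potential [mV]
    gamma_conv: float = 0.0445  # current->concentration factor [mM cm^2 / uC]
    nernst_coef: float = 26.64  # RT/F at ~310 K [mV]

    def __post_init__(self) -> None:
        if not self.k_o_inf > 0:
            raise ValueError(f"k_o_inf must be positive, got {self.k_o_inf}")
        for name in ("Cm", "g_na", "g_k", "phi", "tau_slow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_na_leak", "g_k_leak", "g_ahp", "g_cl_leak",
                     "rho_pump", "g_glia", "eps_diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_(self, **kw) -> "CressmanParams":
        return replace(self, **kw)

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, f.name) for f in fields(self))


@dataclass
class CressmanState:
    """Instantaneous state of one Cressman neuron.

    ``ca_i`` is the dimensionless intracellular calcium variable gating the
    afterhyperpolarisation current; it rides along with the five principal
    variables (v, n, h, K_o, Na_i).
    """

    v: float  # membrane potential [mV]
    gate_n: float  # K activation, in [0, 1]
    gate_h: float  # Na inactivation, in [0, 1]
    K_o: float  # extracellular potassium [mM]
    Na_i: float  # intracellular sodium [mM]
    ca_i: float = 0.0  # intracellular calcium (dimensionless scaled)
    stationary: bool = True  # False when the state is a phase reference only

    def validate(self) -> None:
        for name in ("v", "gate_n", "gate_h", "K_o", "Na_i", "ca_i"):
            if not math.isfinite(getattr(self, name)):
                raise FloatingPointError(f"non-finite state field {name!r}")
        if not (0.0 <= self.gate_n <= 1.0 and 0.0 <= self.gate_h <= 1.0):
            raise ValueError("gating variables must lie in [0, 1]")
        if self.K_o <= 0 or self.Na_i <= 0:
            raise ValueError("ion concentrations must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.v, self.gate_n, self.gate_h, self.K_o, self.Na_i, self.ca_i]
        )

    @classmethod
    def from_array(cls, y, stationary: bool = True) -> "CressmanState":
        return cls(*(float(x) for x in y), stationary=stationary)


@dataclass(frozen=True)
class IonicCurrentOutput:
    """Transmembrane current and the state time-derivatives at one instant."""

    I_ion: float  # net outward ionic current [uA/cm^2]
    dv: float  # [mV/ms]
    dn: float
    dh: float
    dK_o: float  # [mM/ms]
    dNa_i: float  # [mM/ms]
    dca_i: float

    @property
    def state_derivatives(self) -> np.ndarray:
        return np.array([self.dv, self.dn, self.dh, self.dK_o, self.dNa_i, self.dca_i])


# Seed state used for reproducible initialisation: a depolarised rest-like
# point from which the stable regime relaxes (after a handful of spikes) and
# the unstable regime enters its first burst.
SEED_STATE = CressmanState(
    v=-50.0, gate_n=0.08553, gate_h=0.96859, K_o=7.8, Na_i=15.5, ca_i=0.0
)


def _rhs_arrays(v, n, h, ko, nai, ca, p):
    """Vectorised right-hand side; `p` is CressmanParams.as_tuple()."""
    (k_o_inf, Cm, g_na, g_nal, g_k, g_kl, g_ahp, g_cll, phi,
     cl_i, cl_o, na_i0, na_o0, k_i0, beta, rho, g_glia, eps, tau,
     g_ca, e_ca, gamma, rtf) = p

    # conservation closures for the unmodelled pools
    k_i = k_i0 + (na_i0 - nai)
    na_o = na_o0 - beta * (nai - na_i0)

    e_na = rtf * np.log(na_o / nai)
    e_k = rtf * np.log(ko / k_i)
    e_cl = rtf * np.log(cl_i / cl_o)

    a_m = 0.1 * (v + 30.0) / (1.0 - np.exp(-0.1 * (v + 30.0)))
    b_m = 4.0 * np.exp(-(v + 55.0) / 18.0)
    m_inf = a_m / (a_m + b_m)
    a_n = 0.01 * (v + 34.0) / (1.0 - np.exp(-0.1 * (v + 34.0)))
    b_n = 0.125 * np.exp(-(v + 44.0) / 80.0)
    a_h = 0.07 * np.exp(-(v + 44.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-0.1 * (v + 14.0)))

    i_na = (g_na * m_inf ** 3 * h + g_nal) * (v - e_na)
    i_k = (g_k * n ** 4 + g_ahp * ca / (1.0 + ca) + g_kl) * (v - e_k)
    i_cl = g_cll * (v - e_cl)
    i_ion = i_na + i_k + i_cl

    dv = -i_ion / Cm
    dn = phi * (a_n * (1.0 - n) - b_n * n)
    dh = phi * (a_h * (1.0 - h) - b_h * h)

    # slow ion dynamics (written per second, converted to per ms by tau)
    i_pump = rho / ((1.0 + np.exp((25.0 - nai) / 3.0)) * (1.0 + np.exp(5.5 - ko)))
    i_glia = g_glia / (1.0 + np.exp((18.0 - ko) / 2.5))
    i_diff = eps * (ko - k_o_inf)
    dko = (gamma * beta * i_k - 2.0 * beta * i_pump - i_glia - i_diff) / tau
    dnai = (-gamma * i_na - 3.0 * i_pump) / tau

    dca = -0.002 * g_ca * (v - e_ca) / (1.0 + np.exp(-(v + 25.0) / 2.5)) - ca / 80.0

    return i_ion, dv, dn, dh, dko, dnai, dca


def cressman_rhs(state: CressmanState, params: CressmanParams) -> IonicCurrentOutput:
    """Evaluate the ionic current and all state derivatives at `state`."""
    state.validate()
    out = _rhs_arrays(
        state.v, state.gate_n, state.gate_h, state.K_o, state.Na_i, state.ca_i,
        params.as_tuple(),
    )
    return IonicCurrentOutput(*(float(x) for x in out))


_GATE_EPS = 1e-6  # tolerated overshoot of gating variables per explicit step


def forward_euler_step(
    states: np.ndarray,
    params: CressmanParams,
    dt: float,
    coupling_current: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Advance a batch of neuron states one explicit Euler step.

    `states` has shape (n_neurons, 6) with columns (v, n, h, K_o, Na_i, ca).
    `coupling_current` (uA/cm^2, outward-positive) is added to the membrane
    balance; it is how the tissue solver feeds back into the point models.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    states = np.atleast_2d(np.asarray(states, dtype=float))
    v, n, h, ko, nai, ca = (states[:, i] for i in range(6))
    _, dv, dn, dh, dko, dnai, dca = _rhs_arrays(v, n, h, ko, nai, ca, params.as_tuple())
    dv = dv - np.asarray(coupling_current) / params.Cm

    out = np.empty_like(states)
    out[:, 0] = v + dt * dv
    out[:, 1] = n + dt * dn
    out[:, 2] = h + dt * dh
    out[:, 3] = ko + dt * dko
    out[:, 4] = nai + dt * dnai
    out[:, 5] = ca + dt * dca

    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite state after Euler step with dt={dt}")
    gates = out[:, 1:3]
    if np.any(gates < -_GATE_EPS) or np.any(gates > 1.0 + _GATE_EPS):
        raise FloatingPointError(
            f"gating variable left [0,1] by more than {_GATE_EPS} at dt={dt}"
        )
    np.clip(gates, 0.0, 1.0, out=gates)
    return out


@_njit(cache=True)
def _trajectory_numba(y0, p, dt, n_steps, stride):  # pragma: no cover - jit
    (k_o_inf, Cm, g_na, g_nal, g_k, g_kl, g_ahp, g_cll, phi,
     cl_i, cl_o, na_i0, na_o0, k_i0, beta, rho, g_glia, eps, tau,
     g_ca, e_ca, gamma, rtf) = p
    n_out = n_steps // stride + 1
    out = np.empty((n_out, 6))
    v, n, h, ko, nai, ca = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5]
    out[0, 0], out[0, 1], out[0, 2] = v, n, h
    out[0, 3], out[0, 4], out[0, 5] = ko, nai, ca
    j = 1
    for step in range(1, n_steps + 1):
        k_i = k_i0 + (na_i0 - nai)
        na_o = na_o0 - beta * (nai - na_i0)
        e_na = rtf * math.log(na_o / nai)
        e_k = rtf * math.log(ko / k_i)
        e_cl = rtf * math.log(cl_i / cl_o)
        a_m = 0.1 * (v + 30.0) / (1.0 - math.exp(-0.1 * (v + 30.0)))
        b_m = 4.0 * math.exp(-(v + 55.0) / 18.0)
        m_inf = a_m / (a_m + b_m)
        a_n = 0.01 * (v + 34.0) / (1.0 - math.exp(-0.1 * (v + 34.0)))
        b_n = 0.125 * math.exp(-(v + 44.0) / 80.0)
        a_h = 0.07 * math.exp(-(v + 44.0) / 20.0)
        b_h = 1.0 / (1.0 + math.exp(-0.1 * (v + 14.0)))
        i_na = (g_na * m_inf ** 3 * h + g_nal) * (v - e_na)
        i_k = (g_k * n ** 4 + g_ahp * ca / (1.0 + ca) + g_kl) * (v - e_k)
        i_cl = g_cll * (v - e_cl)
        i_pump = rho / ((1.0 + math.exp((25.0 - nai) / 3.0))
                        * (1.0 + math.exp(5.5 - ko)))
        i_glia = g_glia / (1.0 + math.exp((18.0 - ko) / 2.5))
        i_diff = eps * (ko - k_o_inf)
        v = v + dt * (-(i_na + i_k + i_cl) / Cm)
        n = n + dt * phi * (a_n * (1.0 - n) - b_n * n)
        h = h + dt * phi * (a_h * (1.0 - h) - b_h * h)
        ko = ko + dt * (gamma * beta * i_k - 2.0 * beta * i_pump
                        - i_glia - i_diff) / tau
        nai = nai + dt * (-gamma * i_na - 3.0 * i_pump) / tau
        ca = ca + dt * (-0.002 * g_ca * (v - e_ca)
                        / (1.0 + math.exp(-(v + 25.0) / 2.5)) - ca / 80.0)
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        if step % stride == 0:
            out[j, 0], out[j, 1], out[j, 2] = v, n, h
            out[j, 3], out[j, 4], out[j, 5] = ko, nai, ca
            j += 1
    return out


def integrate_point_model(
    state: CressmanState,
    params: CressmanParams,
    duration_ms: float,
    dt: float = 0.025,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler trajectory of one neuron.

    Returns ``(times_ms, states)`` where states has shape (n_samples, 6) and
    samples every `stride`-th step (the initial state included).
    """
    state.validate()
    if duration_ms <= 0 or dt <= 0:
        raise ValueError("duration_ms and dt must be positive")
    n_steps = int(round(duration_ms / dt))
    y0 = state.as_array()
    p = np.array(params.as_tuple())
    if _HAVE_NUMBA:
        traj = _trajectory_numba(y0, p, dt, n_steps, stride)
    else:
        traj = np.empty((n_steps // stride + 1, 6))
        traj[0] = y0
        y = y0[None, :].copy()
        j = 1
        for step in range(1, n_steps + 1):
            y = forward_euler_step(y, params, dt)
            if step % stride == 0:
                traj[j] = y[0]
                j += 1
    if not np.all(np.isfinite(traj)):
        raise FloatingPointError("trajectory diverged (non-finite values)")
    times = np.arange(traj.shape[0]) * (dt * stride)
    return times, traj


_V_DIVERGE = 500.0  # |v| beyond this is treated as divergence [mV]


def cressman_rest_state(
    params: CressmanParams,
    settle_time_ms: float = 10_000.0,
    seed_state: CressmanState = SEED_STATE,
    derivative_tol: float = 1e-8,
) -> CressmanState:
    """Relax the model from the documented seed state for `settle_time_ms`.

    Uses a high-accuracy adaptive integrator (LSODA, rtol 1e-10).  For stable
    parameterisations the returned state is a fixed point (derivative norm
    below `derivative_tol` of the per-field scales); for unstable ones the
    state at `settle_time_ms` is returned flagged ``stationary=False`` as a
    reproducible phase reference.
    """
    from scipy.integrate import solve_ivp

    if settle_time_ms <= 0:
        raise ValueError("settle_time_ms must be positive")
    p = params.as_tuple()

    def f(t, y):
        if abs(y[0]) > _V_DIVERGE:
            raise FloatingPointError("membrane potential diverged during settling")
        return _rhs_arrays(*y, p)[1:]

    sol = solve_ivp(
        f, (0.0, settle_time_ms), seed_state.as_array(),
        method="LSODA", rtol=1e-10, atol=1e-12,
    )
    y = sol.y[:, -1]
    scales = np.array([100.0, 1.0, 1.0, 10.0, 10.0, 1.0])  # typical field sizes

    def scaled_residual(z):
        return float(np.linalg.norm(np.asarray(_rhs_arrays(*z, p)[1:]) / scales))

    # the sodium pool relaxes over minutes; if settling has brought the
    # trajectory close to an equilibrium, polish it with a root solve
    if scaled_residual(y) < 1e-3:
        from scipy.optimize import fsolve

        root, _, ok, _ = fsolve(
            lambda z: np.asarray(_rhs_arrays(*z, p)[1:]) / scales, y,
            full_output=True, xtol=1e-13,
        )
        if ok and scaled_residual(root) < scaled_residual(y):
            y = root
    return CressmanState.from_array(y, stationary=scaled_residual(y) < derivative_tol)
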