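"""Shared fixtures: long point-model trajectories and the scaled 2D tissue
runs are computed once per session and reused across tests."""

import numpy as np
import pytest

from epibidomain import bidomain_core as bc
from epibidomain import cell_models as cm
from epibidomain import geometry as geo
from epibidomain.spectral_analysis import ProbeTrace

DT = 0.025  # ms, the reference time step used throughout


@pytest.fixture(scope="session")
def stable_trajectory():
    """10 s forward-Euler run of the stable (4 mM bath K) point model."""
    params = cm.CressmanParams(k_o_inf=4.0)
    times, traj = cm.integrate_point_model(cm.SEED_STATE, params, 10_000.0, dt=DT)
    return times, traj


@pytest.fixture(scope="session")
def unstable_trajectory():
    """10 s forward-Euler run of the seizure-like (8 mM bath K) point model."""
    params = cm.CressmanParams(k_o_inf=8.0)
    times, traj = cm.integrate_point_model(cm.SEED_STATE, params, 10_000.0, dt=DT)
    return times, traj


@pytest.fixture(scope="session")
def unstable_v_trace(unstable_trajectory):
    times, traj = unstable_trajectory
    return ProbeTrace(times, traj[:, 0], label="modelB:v")


def _model_c_probes(mesh):
    """Stable-GM probes, layer probes, and left/right WM depth columns."""
    probes = [geo.gm_probe_at(mesh, 45.0), geo.gm_probe_at(mesh, 15.0)]
    names = ["gm_stable_R", "gm_stable_L"]
    depths = [23, 22, 20, 18, 14, 10, 6, 2]  # mm above the bottom; GM/WM at 24
    for side, x in (("L", 15.0), ("R", 45.0)):
        for d in depths:
            probes.append(np.array([x, d]) / geo.MM_PER_CM)
            names.append(f"wm{side}_{d}")
    for p, nm in zip(mesh.probe_points,
                     ["wm_mid", "gm_mid", "csf", "skull", "scalp", "unstable"]):
        probes.append(p)
        names.append(nm)
    return np.vstack(probes), names, depths


def _run_model_c(mesh, duration_ms):
    cond = geo.build_conductivity_map(mesh, wm_spec=geo.AnisotropySpec())
    regimes = {
        geo.GM_STABLE: cm.CressmanParams(k_o_inf=4.0),
        geo.GM_UNSTABLE: cm.CressmanParams(k_o_inf=8.0),
    }
    probes, names, depths = _model_c_probes(mesh)
    sim = bc.BidomainSimulation(
        mesh, cond, bc.PhysicalParams(), regimes, bc.SolverConfig(),
        probes=probes, probe_names=names,
    )
    res = sim.run(duration_ms)
    res.event_log["depths_mm"] = depths
    return res


@pytest.fixture(scope="session")
def slice_mesh():
    return geo.build_idealized_slice()


@pytest.fixture(scope="session")
def model_c_result(slice_mesh):
    """1 s of the anisotropic 2D slice with a seizure-like central region,
    on the resolved (5 element rows across the GM) mesh."""
    return _run_model_c(slice_mesh, 1000.0)


@pytest.fixture(scope="session")
def model_c_coarse_result():
    """Same experiment on an under-resolved mesh (2 rows across the GM)."""
    mesh = geo.build_idealized_slice(cells_across_gm=2)
    return _run_model_c(mesh, 1000.0)
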