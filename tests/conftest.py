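"""Shared fixtures.

The expensive network simulations are session-scoped and shared across the
statistical tests: a gamma sweep at full network size (the regime-boundary
grid), one long run in the transient-UP showcase condition, and a
weight-variance sweep at reduced size (costs scale with N^2, and the
critical coupling scales as 1/N_E, so the reduced networks use
proportionally larger gamma).
"""

from __future__ import annotations

import numpy as np
import pytest

from slowwave import (
    DetectionParams,
    NetworkConfig,
    NeuronParams,
    build_network,
    cycle_statistics,
    find_rheobase,
    fit_response_function,
    measure_fi_curve,
    run_simulation,
    segment_updown,
)

MASTER_SEED = 20260926


def _cell_seed(idx: int) -> int:
    return int(np.random.SeedSequence([MASTER_SEED, idx]).generate_state(1)[0]
               % (2**31 - 1))


def run_condition(idx, analysis_s=5.0, **overrides):
    """One simulation plus its UP/DOWN segmentation and cycle stats."""
    kwargs = dict(
        N_E=1000, family="lognormal", sigma_E2=1.0,
        T_total=2000.0 + analysis_s * 1000.0, T_transient=2000.0,
        seed=_cell_seed(idx),
    )
    kwargs.update(overrides)
    cfg = NetworkConfig(**kwargs)
    res = run_simulation(build_network(cfg))
    tt, V = res.excitatory_traces()
    seg = segment_updown(V, cfg.trace_dt, DetectionParams(), t_start=tt[0])
    return {"config": cfg, "result": res, "seg": seg,
            "stats": cycle_statistics(seg)}


@pytest.fixture(scope="session")
def nosfa_fit():
    """Rheobase and quartic response fit of the no-adaptation neuron."""
    p = NeuronParams().without_sfa()
    theta = find_rheobase(p, sim_time=3000.0)
    grid = np.arange(theta + 20.0, theta + 1840.0, 20.0)
    points = measure_fi_curve(p, grid, sim_time=3000.0)
    fit = fit_response_function(points, theta_f=theta)
    return {"params": p, "theta": theta, "points": points, "fit": fit}


@pytest.fixture(scope="session")
def gamma_sweep():
    """Full-size sweep over the tied coupling factor (sigma_E^2 = 1)."""
    gammas = [0.08, 0.10, 0.12, 0.14]
    return {
        g: run_condition(i, analysis_s=5.0, gamma_E=g, gamma_I=g)
        for i, g in enumerate(gammas)
    }


@pytest.fixture(scope="session")
def transient_up_run():
    """Showcase transient-UP condition: gamma = 0.1, sigma_E = 10."""
    return run_condition(100, analysis_s=8.0, gamma_E=0.1, gamma_I=0.1,
                         sigma_E2=100.0)


@pytest.fixture(scope="session")
def sigma_sweep():
    """Weight-variance sweep at reduced size (N_E = 400, gamma scaled x2.5)."""
    sigmas = [2.0, 5.0, 8.0, 12.0]
    return {
        s: run_condition(200 + i, analysis_s=8.0, N_E=400,
                         gamma_E=0.25, gamma_I=0.25, sigma_E2=s * s)
        for i, s in enumerate(sigmas)
    }
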