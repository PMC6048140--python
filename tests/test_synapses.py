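"""Second-order synaptic gating and current assembly."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from slowwave import (
    GatingState,
    RECEPTORS,
    mean_gating,
    step_gating,
    synaptic_current,
)
from slowwave.synapses import receptor_table


def test_receptor_table_contract():
    """Five receptors, correct carriers, GABA-A conductance shared."""
    assert set(RECEPTORS) == {"AMPA", "NMDA", "GABA_A_fast", "GABA_A_slow",
                              "GABA_B"}
    assert RECEPTORS["AMPA"].carrier == "excitatory"
    assert RECEPTORS["NMDA"].carrier == "excitatory"
    for n in ("GABA_A_fast", "GABA_A_slow", "GABA_B"):
        assert RECEPTORS[n].carrier == "inhibitory"
    assert RECEPTORS["GABA_A_fast"].g == RECEPTORS["GABA_A_slow"].g
    assert all(s.tau_up < s.tau_dn for s in RECEPTORS.values())


def test_receptor_overrides_and_rejection():
    t = receptor_table({"AMPA": {"g": 2.0}})
    assert t["AMPA"].g == 2.0 and t["NMDA"].g == RECEPTORS["NMDA"].g
    with pytest.raises(KeyError):
        receptor_table({"AMPAR": {"g": 2.0}})
    with pytest.raises(KeyError):
        receptor_table({"AMPA": {"gain": 2.0}})


def test_rest_state_is_absorbing():
    """No presynaptic spikes and s = 0 stays exactly at 0."""
    st = GatingState.zeros(3)
    for _ in range(100):
        st = step_gating(st, RECEPTORS["AMPA"], 0.0, 0.05)
    assert np.all(st.s == 0.0) and np.all(st.x == 0.0)


@pytest.mark.parametrize("name", list(RECEPTORS))
def test_single_spike_rises_then_decays_with_tau_dn(name):
    """One spike: s rises, then decays ~exponentially with tau_dn."""
    spec = RECEPTORS[name]
    dt = 0.05
    st = step_gating(GatingState.zeros(1), spec, np.array([1.0]), dt)
    trace = []
    n = int((spec.tau_up * 8 + spec.tau_dn * 3) / dt)
    for _ in range(n):
        st = step_gating(st, spec, 0.0, dt)
        trace.append(st.s[0])
    trace = np.array(trace)
    peak = trace.argmax()
    assert 0.2 < trace[peak] < 1.0
    tail = trace[peak + int(spec.tau_dn / dt):]          # past the rise
    assert np.all(np.diff(tail) <= 1e-12)                # monotone decay
    # log-slope of the tail estimates tau_dn
    t = np.arange(tail.size) * dt
    slope = np.polyfit(t, np.log(tail), 1)[0]
    assert -1.0 / slope == pytest.approx(spec.tau_dn, rel=0.15)


def test_gating_stays_in_unit_interval_under_strong_drive():
    spec = RECEPTORS["AMPA"]
    rng = np.random.default_rng(0)
    st = GatingState.zeros(4)
    for _ in range(20000):
        st = step_gating(st, spec, rng.poisson(0.05, 4).astype(float), 0.05)
        assert np.all(st.s >= 0.0) and np.all(st.s <= 1.0)
        assert np.all(st.x >= 0.0)


def test_gating_matches_exact_integration():
    """RK2 trace agrees with an adaptive high-precision oracle."""
    spec = RECEPTORS["AMPA"]
    spikes = [2.013, 6.027, 6.533, 20.011]  # off-grid times
    dt = 0.05
    T = 40.0
    # package integrator
    st = GatingState.zeros(1)
    ours = []
    for i in range(int(T / dt)):
        t = i * dt
        n = sum(1 for ts in spikes if t <= ts < t + dt)
        st = step_gating(st, spec, np.array([float(n)]), dt)
        ours.append(st.s[0])
    # oracle: exact piecewise integration between spike jumps
    def rhs(t, y):
        return [-y[0] / spec.tau_up, y[0] * (1 - y[1]) - y[1] / spec.tau_dn]
    y = [0.0, 0.0]
    t_knots = [0.0] + [dt * np.floor(ts / dt) for ts in spikes] + [T]
    exact_t, exact_s = [], []
    for a, b in zip(t_knots[:-1], t_knots[1:]):
        y[0] += sum(1.0 / spec.tau_up for ts in spikes if abs(dt * np.floor(ts / dt) - a) < 1e-12 and a > 0)
        sol = solve_ivp(rhs, (a, b), y, rtol=1e-10, atol=1e-12, dense_output=True)
        tt = np.arange(np.ceil(a / dt), np.floor(b / dt) + 1) * dt
        tt = tt[(tt > a) & (tt <= b)]
        exact_t.extend(tt)
        exact_s.extend(sol.sol(tt)[1])
        y = [sol.y[0, -1], sol.y[1, -1]]
    exact = dict(zip(np.round(exact_t, 6), exact_s))
    ours_t = np.round((np.arange(int(T / dt)) + 1) * dt, 6)
    diffs = [abs(o - exact[t]) for o, t in zip(ours, ours_t) if t in exact]
    assert max(diffs) < 1e-3


def test_gating_blows_up_detection():
    spec = RECEPTORS["AMPA"]
    st = GatingState(x=np.array([1e6]), s=np.array([0.5]))
    with pytest.raises(FloatingPointError):
        step_gating(st, spec, 0.0, 5.0)  # absurd dt


def test_mean_gating_values():
    assert mean_gating(0.0, RECEPTORS["GABA_B"]) == 0.0
    assert mean_gating(1e9, RECEPTORS["AMPA"]) > 0.999
    # tau_dn = 4 ms at 50 Hz: 0.2/1.2
    assert mean_gating(50.0, RECEPTORS["AMPA"]) == pytest.approx(0.2 / 1.2)
    # tau_dn = 500 ms at 10 Hz: 5/6
    assert mean_gating(10.0, RECEPTORS["GABA_B"]) == pytest.approx(5.0 / 6.0)
    with pytest.raises(ValueError):
        mean_gating(-1.0, RECEPTORS["AMPA"])


def _frozen_gating(rng, n_e=4, n_i=3):
    gating = {
        "AMPA": rng.random(n_e), "NMDA": rng.random(n_e),
        "GABA_A_fast": rng.random(n_i), "GABA_A_slow": rng.random(n_i),
        "GABA_B": rng.random(n_i),
    }
    weights = {"E": rng.random(n_e) + 0.1, "I": rng.random(n_i) + 0.1}
    return gating, weights


def test_current_zero_when_gates_closed():
    gating = {k: np.zeros(3) for k in RECEPTORS}
    w = {"E": np.ones(3), "I": np.ones(3)}
    assert synaptic_current(-60.0, "E", gating, w, (0.1, 0.1)) == 0.0


def test_current_driving_force_nulls():
    """V_post = 0 kills AMPA/NMDA; V_post = -70 kills GABA-A but GABA-B
    still hyperpolarises."""
    rng = np.random.default_rng(1)
    gating, w = _frozen_gating(rng)
    at0 = synaptic_current(0.0, "E", gating, w, (1.0, 0.0))
    assert at0 == pytest.approx(0.0, abs=1e-12)
    at70 = synaptic_current(-70.0, "E", gating, w, (0.0, 1.0))
    only_b = synaptic_current(
        -70.0, "E",
        {"GABA_B": gating["GABA_B"]}, w, (0.0, 1.0),
        receptors={"GABA_B": RECEPTORS["GABA_B"]},
    )
    assert at70 == pytest.approx(only_b)
    assert at70 < 0  # -80 mV reversal still pulls down


def test_current_linear_in_gammas():
    """Superposition: the current is separately linear in gamma_E and
    gamma_I on frozen gating."""
    rng = np.random.default_rng(2)
    gating, w = _frozen_gating(rng)
    V = -58.0
    e = synaptic_current(V, "E", gating, w, (1.0, 0.0))
    i = synaptic_current(V, "E", gating, w, (0.0, 1.0))
    both = synaptic_current(V, "E", gating, w, (0.3, 0.7))
    assert both == pytest.approx(0.3 * e + 0.7 * i, rel=1e-12)


def test_current_shape_mismatch():
    gating = {"AMPA": np.zeros(3)}
    w = {"E": np.ones(4), "I": np.ones(2)}
    with pytest.raises(ValueError):
        synaptic_current(-60.0, "E", gating, w, (0.1, 0.1))
    with pytest.raises(ValueError):
        synaptic_current(-60.0, "X", gating, w, (0.1, 0.1))
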