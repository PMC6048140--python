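"""Adaptive exponential integrate-and-fire (AdEx) point neuron.

The membrane potential V obeys a leaky integrator with an exponential
spike-initiation term and a spike-frequency-adaptation (SFA) current u::

    C dV/dt = -g_L (V - V_L) + g_L Delta_T exp((V - V_T)/Delta_T) * R(t)
              - u + I(t)
    tau_u du/dt = -u + a_u (V - V_L)

where ``R(t) = 1 - exp(-([t - t_sp]_+ / t_ref)^20)`` suppresses spike
generation for ~``t_ref`` after the most recent spike ``t_sp``.  When V
reaches ``V_peak`` a spike is recorded, V is reset to ``V_reset`` and the
adaptation current jumps by ``b_u``.

Units throughout: pF, nS, mV, pA, ms (so nS*mV = pA and pA/pF = mV/ms).

Besides the single-neuron integrator this module measures the steady-state
f-I curve, locates the rheobase by bisection, and fits the origin-constrained
quartic response function used by the mean-field analysis of the recurrent
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "FIFit",
    "step_neuron",
    "simulate_constant_current",
    "measure_fi_curve",
    "find_rheobase",
    "fit_response_function",
]

#: hard cap on V inside right-hand-side evaluations; the exponential term
#: diverges during spike generation and must not leak into RK stages.
_V_RHS_CAP_IS_VPEAK = True


@dataclass
class NeuronParams:
    """AdEx membrane and adaptation constants.

    Defaults are the values used for every neuron in the network model
    (excitatory and inhibitory neurons are identical).
    """

    C: float = 150.0          # membrane capacitance, pF
    g_L: float = 10.005       # leak conductance, nS
    V_L: float = -70.0        # leak reversal, mV
    Delta_T: float = 2.0      # spike slope factor, mV
    V_T: float = -55.0        # effective threshold, mV
    V_reset: float = -55.0    # post-spike reset, mV
    V_peak: float = 20.0      # spike detection ceiling, mV
    tau_u: float = 200.0      # adaptation time constant, ms
    a_u: float = 4.0          # subthreshold adaptation, nS
    b_u: float = 50.0         # spike-triggered adaptation increment, pA
    t_ref: float = 2.0        # refractory shaping constant, ms

    def __post_init__(self) -> None:
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be positive")
        if self.tau_u <= 0:
            raise ValueError("tau_u must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")

    def without_sfa(self) -> "NeuronParams":
        """Copy with spike-frequency adaptation disabled (a_u = b_u = 0)."""
        return replace(self, a_u=0.0, b_u=0.0)


@dataclass
class NeuronState:
    """Dynamical state of one neuron.

    ``t_last_spike`` is ``-inf`` before the first spike, which makes the
    refractory factor exactly 1 (no suppression).
    """

    V: float = -70.0
    u: float = 0.0
    t_last_spike: float = -np.inf


def refractory_factor(elapsed, t_ref: float = 2.0):
    """Suppression of the exponential spike term after a spike.

    ``1 - exp(-(elapsed/t_ref)^20)``: ~0 for elapsed < t_ref, ~1 above.
    Accepts scalars or arrays; the exponent is clipped to avoid overflow.
    """
    z = np.minimum(np.asarray(elapsed, dtype=float) / t_ref, 6.0)
    z = np.maximum(z, 0.0)
    return -np.expm1(-(z**20))


def _rhs(V, u, I, elapsed, p: NeuronParams):
    """Time derivatives (dV/dt, du/dt); V is capped at V_peak inside."""
    Vc = np.minimum(V, p.V_peak)
    ref = refractory_factor(elapsed, p.t_ref)
    exp_term = p.g_L * p.Delta_T * np.exp((Vc - p.V_T) / p.Delta_T) * ref
    dV = (-p.g_L * (Vc - p.V_L) + exp_term - u + I) / p.C
    du = (-u + p.a_u * (Vc - p.V_L)) / p.tau_u
    return dV, du


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    I_total: float,
    t: float,
    dt: float,
):
    """Advance one neuron by a single second-order Runge-Kutta (Heun) step.

    Returns ``(new_state, spiked)``.  If V crosses ``V_peak`` within the
    step, the spike time is linearly interpolated, V is reset, and the
    adaptation current receives the ``b_u`` increment.  A spike cannot be
    emitted within ``t_ref`` of the previous one.

    Raises ``FloatingPointError`` if the state becomes non-finite
    (integration failure; usually dt too large).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(I_total):
        raise ValueError("I_total must be finite")

    V0, u0 = state.V, state.u
    k1V, k1u = _rhs(V0, u0, I_total, t - state.t_last_spike, params)
    V1 = V0 + dt * k1V
    u1 = u0 + dt * k1u
    k2V, k2u = _rhs(V1, u1, I_total, t + dt - state.t_last_spike, params)
    V = V0 + 0.5 * dt * (k1V + k2V)
    u = u0 + 0.5 * dt * (k1u + k2u)

    if not (np.isfinite(u) and not np.isnan(V)):
        raise FloatingPointError(
            f"non-finite neuron state at t={t:.3f} ms (dt too large?)"
        )

    spiked = False
    t_spike = None
    if V >= params.V_peak:
        # interpolate the crossing within the step, reset at step end
        denom = V - V0
        frac = (params.V_peak - V0) / denom if denom > 0 else 1.0
        t_spike = t + dt * min(max(frac, 0.0), 1.0)
        if t_spike - state.t_last_spike >= params.t_ref:
            V = params.V_reset
            u = u + params.b_u
            spiked = True
        else:
            t_spike = None
            V = params.V_peak  # still refractory: hold at ceiling

    new = NeuronState(V=V, u=u, t_last_spike=t_spike if spiked else state.t_last_spike)
    return new, spiked


def simulate_constant_current(
    params: NeuronParams,
    currents,
    sim_time: float,
    dt: float = 0.05,
    discard: float = 1000.0,
    return_spike_times: bool = False,
):
    """Simulate a batch of independent neurons, one per constant current.

    Vectorised across the current grid.  Returns an array of steady firing
    rates (Hz) computed from spike counts after ``discard`` ms, or the full
    per-current spike-time lists if ``return_spike_times``.
    """
    if sim_time <= 0:
        raise ValueError("sim_time must be positive")
    if sim_time <= discard:
        raise ValueError("sim_time must exceed the discard window")
    I = np.atleast_1d(np.asarray(currents, dtype=float))
    n = I.size
    V = np.full(n, params.V_L)
    u = np.zeros(n)
    t_last = np.full(n, -np.inf)
    n_steps = int(round(sim_time / dt))
    counts = np.zeros(n, dtype=int)
    spike_times: list[list[float]] = [[] for _ in range(n)]

    for i in range(n_steps):
        t = i * dt
        k1V, k1u = _rhs(V, u, I, t - t_last, params)
        V1 = V + dt * k1V
        u1 = u + dt * k1u
        k2V, k2u = _rhs(V1, u1, I, t + dt - t_last, params)
        Vn = V + 0.5 * dt * (k1V + k2V)
        un = u + 0.5 * dt * (k1u + k2u)
        crossed = Vn >= params.V_peak
        if crossed.any():
            idx = np.flatnonzero(crossed)
            denom = Vn[idx] - V[idx]
            frac = np.where(denom > 0, (params.V_peak - V[idx]) / denom, 1.0)
            ts = t + dt * np.clip(frac, 0.0, 1.0)
            ok = ts - t_last[idx] >= params.t_ref
            idx, ts = idx[ok], ts[ok]
            t_last[idx] = ts
            Vn[idx] = params.V_reset
            un[idx] += params.b_u
            after = ts >= discard
            counts[idx[after]] += 1
            if return_spike_times:
                for j, tv in zip(idx, ts):
                    spike_times[j].append(float(tv))
        np.minimum(Vn, params.V_peak, out=Vn)
        V, u = Vn, un

    rates = counts / ((sim_time - discard) / 1000.0)
    if return_spike_times:
        return rates, spike_times
    return rates


def measure_fi_curve(
    params: NeuronParams,
    currents: Sequence[float],
    sim_time: float = 3000.0,
    dt: float = 0.05,
    discard: float = 1000.0,
):
    """Steady firing rate versus constant input current.

    Returns a list of ``(current_pA, rate_Hz)`` pairs.  The rate is the
    spike count after the ``discard`` transient divided by the remaining
    time, so with SFA enabled it is the adapted steady rate.
    """
    rates = simulate_constant_current(params, currents, sim_time, dt, discard)
    return list(zip(np.atleast_1d(np.asarray(currents, float)), rates))


def find_rheobase(
    params: NeuronParams,
    lo: float = 50.0,
    hi: float = 300.0,
    tol: float = 0.05,
    sim_time: float = 3000.0,
    dt: float = 0.05,
    discard: float = 1000.0,
) -> float:
    """Minimal constant current producing sustained repetitive firing.

    Batched bisection on "steady rate > 0": each round evaluates a grid of
    currents across the bracket simultaneously and narrows to the first
    firing grid cell, until the bracket is below ``tol`` (pA).
    """
    lo, hi = float(lo), float(hi)
    r = simulate_constant_current(params, [lo, hi], sim_time, dt, discard)
    if r[0] > 0:
        raise ValueError("lower bracket already fires; decrease lo")
    if r[1] == 0:
        raise ValueError("upper bracket does not fire; increase hi")
    while hi - lo > tol:
        grid = np.linspace(lo, hi, 10)
        rates = simulate_constant_current(params, grid, sim_time, dt, discard)
        firing = np.flatnonzero(rates > 0)
        k = firing[0]
        lo, hi = grid[k - 1], grid[k]
    return 0.5 * (lo + hi)


@dataclass
class FIFit:
    """Origin-constrained quartic fit of the f-I curve.

    ``rate(I) = Theta(I - theta_f) * [A x + B x^2 + C x^3 + D x^4]`` with
    ``x = I - theta_f``, valid for ``x < valid_range_max``.  Beyond the
    validity range the response is held at its value at the range edge
    (the neuron is nearly saturated there).
    """

    theta_f: float            # rheobase, pA
    A: float                  # Hz/pA
    B: float                  # Hz/pA^2
    Ccoef: float              # Hz/pA^3
    D: float                  # Hz/pA^4
    valid_range_max: float = 1840.0  # pA above theta_f
    rms_residual: float = field(default=np.nan)

    def __call__(self, I):
        x = np.asarray(I, dtype=float) - self.theta_f
        x = np.clip(x, 0.0, self.valid_range_max)
        val = x * (self.A + x * (self.B + x * (self.Ccoef + x * self.D)))
        return np.maximum(val, 0.0)


def fit_response_function(
    fi_points: Sequence[tuple[float, float]],
    theta_f: float | None = None,
    valid_range_max: float = 1840.0,
) -> FIFit:
    """Least-squares quartic through the origin on the shifted current axis.

    ``theta_f`` defaults to the largest sampled current with zero steady
    rate (the caller may pass a bisection-refined value instead).  Only
    points with ``0 <= I - theta_f < valid_range_max`` enter the fit.
    """
    pts = np.asarray(fi_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("fi_points must be (current, rate) pairs")
    I, r = pts[:, 0], pts[:, 1]
    if np.all(r == 0):
        raise ValueError("all rates are zero: no rheobase in the sampled range")
    if theta_f is None:
        silent = I[r == 0]
        if silent.size == 0:
            raise ValueError("no subthreshold point sampled; pass theta_f")
        theta_f = float(silent.max())
    x = I - theta_f
    sel = (x >= 0) & (x < valid_range_max) & (r > 0)
    xs, rs = x[sel], r[sel]
    if xs.size < 4:
        raise ValueError("need at least 4 suprathreshold points for a quartic")
    X = np.column_stack([xs, xs**2, xs**3, xs**4])
    coef, *_ = np.linalg.lstsq(X, rs, rcond=None)
    resid = X @ coef - rs
    rms = float(np.sqrt(np.mean(resid**2)))
    return FIFit(
        theta_f=float(theta_f),
        A=float(coef[0]),
        B=float(coef[1]),
        Ccoef=float(coef[2]),
        D=float(coef[3]),
        valid_range_max=valid_range_max,
        rms_residual=rms,
    )
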