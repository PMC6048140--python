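"""Conductance-based synapses with second-order gating kinetics.

Five receptor classes mediate the recurrent connections: AMPA and NMDA on
excitatory connections, fast GABA-A, slow GABA-A and (post-synaptic) GABA-B
on inhibitory connections.  For each (presynaptic neuron, receptor) pair a
gating pair (x, s) evolves as::

    dx/dt = (1/tau_up) * sum_spikes delta(t - tau_axon - t_sp) - x/tau_up
    ds/dt = x (1 - s) - s/tau_dn

so each delayed presynaptic spike increments x by 1/tau_up; s is the
fraction of open channels and stays in [0, 1].  The synaptic current onto a
postsynaptic cell is a weight- and conductance-scaled sum of driving-force
terms ``g_psi * s_psi_j * (V_R_psi - V_post)`` over presynaptic gates, with
separate global scaling factors gamma_E / gamma_I for excitatory and
inhibitory connections.

Under stationary Poisson presynaptic firing at rate f0 the time-averaged
gate is ``tau_dn f0 / (1 + tau_dn f0)``, which the mean-field analysis of
the network uses as its synaptic drive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ReceptorSpec",
    "GatingState",
    "RECEPTORS",
    "EXCITATORY_RECEPTORS",
    "INHIBITORY_RECEPTORS",
    "TAU_AXON",
    "step_gating",
    "mean_gating",
    "simulate_gating_poisson",
    "synaptic_current",
]

#: axonal conduction delay applied to every recurrent spike, ms
TAU_AXON = 1.0


@dataclass(frozen=True)
class ReceptorSpec:
    """Kinetic and conductance constants of one receptor class."""

    name: str
    tau_up: float     # rise time constant, ms
    tau_dn: float     # decay time constant, ms
    V_R: float        # reversal potential, mV
    g: float          # conductance, nS
    carrier: str      # "excitatory" or "inhibitory"

    def __post_init__(self):
        if self.tau_up <= 0 or self.tau_dn <= 0:
            raise ValueError(f"{self.name}: time constants must be positive")
        if self.carrier not in ("excitatory", "inhibitory"):
            raise ValueError(f"{self.name}: bad carrier {self.carrier!r}")


# Default receptor table.  GABA-A fast and slow share the single
# GABA-A conductance of 4.0 nS.
RECEPTORS: dict[str, ReceptorSpec] = {
    "AMPA": ReceptorSpec("AMPA", 0.5, 4.0, 0.0, 1.05, "excitatory"),
    "NMDA": ReceptorSpec("NMDA", 5.8, 87.5, 0.0, 1.05, "excitatory"),
    "GABA_A_fast": ReceptorSpec("GABA_A_fast", 1.8, 12.0, -70.0, 4.0, "inhibitory"),
    "GABA_A_slow": ReceptorSpec("GABA_A_slow", 1.8, 47.0, -70.0, 4.0, "inhibitory"),
    "GABA_B": ReceptorSpec("GABA_B", 100.0, 500.0, -80.0, 2.0, "inhibitory"),
}

EXCITATORY_RECEPTORS = ("AMPA", "NMDA")
INHIBITORY_RECEPTORS = ("GABA_A_fast", "GABA_A_slow", "GABA_B")


@dataclass
class GatingState:
    """Gating pair (x, s) per presynaptic source for one receptor class.

    ``x`` has units 1/ms; ``s`` is the dimensionless open fraction.
    """

    x: np.ndarray
    s: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "GatingState":
        return cls(x=np.zeros(n), s=np.zeros(n))


def gating_derivatives(x, s, spec: ReceptorSpec):
    """Smooth part of the kinetics (spike impulses handled separately)."""
    dx = -x / spec.tau_up
    ds = x * (1.0 - s) - s / spec.tau_dn
    return dx, ds


def step_gating(
    state: GatingState,
    spec: ReceptorSpec,
    n_delayed_spikes,
    dt: float,
    s_tol: float = 1e-6,
) -> GatingState:
    """Advance the gating pair by one RK2 step.

    ``n_delayed_spikes`` is the per-source count of presynaptic spikes whose
    (axonal-delay-shifted) arrival falls in this step; each adds 1/tau_up
    to x at the step start.  Raises ``FloatingPointError`` if s leaves
    [0, 1] beyond tolerance.
    """
    x = state.x + np.asarray(n_delayed_spikes, dtype=float) / spec.tau_up
    s = state.s
    dx1, ds1 = gating_derivatives(x, s, spec)
    dx2, ds2 = gating_derivatives(x + dt * dx1, s + dt * ds1, spec)
    x_new = x + 0.5 * dt * (dx1 + dx2)
    s_new = s + 0.5 * dt * (ds1 + ds2)
    if np.any(s_new < -s_tol) or np.any(s_new > 1.0 + s_tol):
        raise FloatingPointError(
            f"{spec.name}: gating fraction left [0,1] (dt too large?)"
        )
    np.clip(s_new, 0.0, 1.0, out=s_new)
    np.maximum(x_new, 0.0, out=x_new)
    return GatingState(x=x_new, s=s_new)


def mean_gating(f0: float, spec: ReceptorSpec) -> float:
    """Stationary mean of s under Poisson presynaptic firing at f0 (Hz).

    ``tau_dn f0 / (1 + tau_dn f0)`` with tau_dn converted to seconds.
    """
    if f0 < 0:
        raise ValueError("presynaptic rate must be non-negative")
    tf = spec.tau_dn / 1000.0 * f0
    return tf / (1.0 + tf)


def simulate_gating_poisson(
    spec: ReceptorSpec,
    rate: float,
    duration: float,
    dt: float = 0.05,
    seed: int | None = 0,
    discard: float | None = None,
):
    """Drive one gate with a Poisson spike train; return (times, s trace).

    Used to verify the stationary-mean formula (and by the acceptance
    checks).  ``discard`` (ms) removes the equilibration transient from the
    returned trace; default is 5 decay time constants.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    p = rate * dt / 1000.0
    spikes = rng.random(n_steps) < p
    state = GatingState.zeros(1)
    trace = np.empty(n_steps)
    for i in range(n_steps):
        state = step_gating(state, spec, np.array([1.0]) if spikes[i] else 0.0, dt)
        trace[i] = state.s[0]
    times = (np.arange(n_steps) + 1) * dt
    if discard is None:
        discard = 5.0 * spec.tau_dn
    keep = times >= discard
    return times[keep], trace[keep]


def poisson_gating_means(
    pairs: Sequence[tuple[ReceptorSpec, float]],
    duration: float = 60000.0,
    dt: float = 0.1,
    seed: int | None = 0,
    block_ms: float = 5000.0,
):
    """Time-averaged s under Poisson drive for many (receptor, rate) pairs.

    Vectorised across the batch; returns ``(means, standard_errors)`` where
    the SE comes from treating non-overlapping blocks of ``block_ms`` as
    independent samples (block length should exceed the slowest tau_dn).
    Used to verify the stationary-mean formula against direct simulation.
    """
    rng = np.random.default_rng(seed)
    n = len(pairs)
    tup = np.array([s.tau_up for s, _ in pairs])
    tdn = np.array([s.tau_dn for s, _ in pairs])
    p_spk = np.array([r for _, r in pairs]) * dt / 1000.0
    x = np.zeros(n)
    s = np.zeros(n)
    n_steps = int(round(duration / dt))
    block_steps = max(int(round(block_ms / dt)), 1)
    n_blocks = n_steps // block_steps
    block_sums = np.zeros((n_blocks, n))
    for i in range(n_steps):
        k = rng.poisson(p_spk)
        if k.any():
            x = x + k / tup
        dx1 = -x / tup
        ds1 = x * (1.0 - s) - s / tdn
        x1 = x + dt * dx1
        s1 = s + dt * ds1
        ds2 = x1 * (1.0 - s1) - s1 / tdn
        x = x + 0.5 * dt * (dx1 - x1 / tup)
        s = s + 0.5 * dt * (ds1 + ds2)
        b = i // block_steps
        if b < n_blocks:
            block_sums[b] += s
    block_means = block_sums / block_steps
    means = block_means.mean(axis=0)
    ses = block_means.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return means, ses


def synaptic_current(
    postsyn_V: float,
    post_type: str,
    gating: Mapping[str, np.ndarray],
    weights: Mapping[str, np.ndarray],
    gammas: tuple[float, float],
    receptors: Mapping[str, ReceptorSpec] = RECEPTORS,
) -> float:
    """Total synaptic current (pA) onto one postsynaptic neuron.

    ``gating`` maps receptor name -> per-presynaptic-source s values;
    ``weights`` maps "E"/"I" -> the postsynaptic neuron's weight row onto
    excitatory / inhibitory sources (J^{XE} / J^{XI}); ``gammas`` is
    (gamma_E, gamma_I).  The driving force uses the postsynaptic cell's own
    membrane potential regardless of its type.

    This is the reference implementation of the current assembly; the
    network integrator computes the same sums in a vectorised form.
    """
    if post_type not in ("E", "I"):
        raise ValueError("post_type must be 'E' or 'I'")
    gamma_E, gamma_I = gammas
    total = 0.0
    for name, spec in receptors.items():
        if name not in gating:
            continue
        s = np.asarray(gating[name], dtype=float)
        J = np.asarray(weights["E" if spec.carrier == "excitatory" else "I"], float)
        if J.shape != s.shape:
            raise ValueError(
                f"{name}: weight row shape {J.shape} != gating shape {s.shape}"
            )
        gamma = gamma_E if spec.carrier == "excitatory" else gamma_I
        total += gamma * spec.g * (spec.V_R - postsyn_V) * float(J @ s)
    return total


def receptor_table(overrides: Mapping[str, Mapping] | None = None) -> dict[str, ReceptorSpec]:
    """Default receptor table with optional per-field overrides.

    ``overrides`` maps receptor name -> {field: value}; unknown receptor
    names or fields raise.
    """
    table = dict(RECEPTORS)
    if overrides:
        for name, fields in overrides.items():
            if name not in table:
                raise KeyError(f"unknown receptor {name!r}")
            base = table[name]
            valid = {"tau_up", "tau_dn", "V_R", "g", "carrier"}
            bad = set(fields) - valid
            if bad:
                raise KeyError(f"unknown receptor fields {sorted(bad)}")
            kwargs = {f: getattr(base, f) for f in valid}
            kwargs.update(fields)
            table[name] = ReceptorSpec(name=name, **kwargs)
    return table
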