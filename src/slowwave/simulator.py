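"""Recurrent E/I network simulator.

Assembles N_E excitatory and N_I (= N_E/4 by default) inhibitory AdEx
neurons, all-to-all randomly weighted through the five receptor classes,
drives each excitatory neuron with an independent stationary Poisson
afferent train filtered through a second-order gate, and integrates every
state variable with a shared second-order Runge-Kutta step.  Recurrent
spikes are delivered after a 1 ms axonal delay, binned to the integration
grid.

Gating is tracked per (presynaptic neuron, receptor), so the storage is
(N_E + N_I) x 5 pairs and the per-step cost is dominated by two
matrix-vector products with the stacked weight blocks (held in float32).

The afferent current follows the gated-Poisson form
``I_input = gamma_input * J_input * s_input`` scaled by a single gain
constant in pA (``input_gain``); the bare dimensionless form is far
below rheobase, so the gain sets the physical scale of one afferent
synapse.  The default (2000 pA) makes one afferent spike through a
unit-weight synapse at gamma = 0.1 reach the rheobase scale, which
produces a quiescent DOWN state punctuated by input-triggered UP
ignitions.  Inhibitory neurons receive no afferent input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .neuron import NeuronParams
from .synapses import (
    RECEPTORS,
    TAU_AXON,
    EXCITATORY_RECEPTORS,
    INHIBITORY_RECEPTORS,
    ReceptorSpec,
)
from .weights import WeightMatrix, WeightEnsemble, sample_weights, sample_weight_matrix

__all__ = [
    "NetworkConfig",
    "Network",
    "SimulationResult",
    "build_network",
    "generate_afferent",
    "run_simulation",
    "simulate",
]


@dataclass
class NetworkConfig:
    """Full parameterisation of one network simulation."""

    N_E: int = 1000
    N_I: int | None = None          # default round(N_E / 4)
    gamma_E: float = 0.1
    gamma_I: float = 0.1
    sigma_E2: float = 1.0           # variance of E->E and E->I weights
    family: str = "lognormal"
    input_rate: float = 10.0        # Hz, per excitatory neuron
    input_gain: float = 2000.0      # pA scale of the afferent synapse
    tau_input_up: float = 1.0       # ms
    tau_input_dn: float = 20.0      # ms
    dt: float = 0.05                # ms
    T_total: float = 10000.0        # ms
    T_transient: float = 2000.0     # ms discarded from analyses
    seed: int = 0
    noise_sd: float = 0.0           # pA; optional white membrane noise
    trace_dt: float = 1.0           # ms between recorded membrane samples
    record: str = "E"               # "all", "E", or "none"
    neuron: NeuronParams = field(default_factory=NeuronParams)
    receptors: dict = field(default_factory=lambda: dict(RECEPTORS))

    def __post_init__(self):
        if self.N_I is None:
            self.N_I = int(round(self.N_E / 4))
        if self.gamma_E <= 0 or self.gamma_I <= 0:
            raise ValueError("gamma_E and gamma_I must be positive")
        if self.T_total <= self.T_transient:
            raise ValueError("T_total must exceed T_transient")
        if self.input_rate < 0:
            raise ValueError("input_rate must be non-negative")
        if self.record not in ("all", "E", "none"):
            raise ValueError("record must be 'all', 'E' or 'none'")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I


@dataclass
class Network:
    """A built network: weights, afferent weights, receptor grouping."""

    config: NetworkConfig
    weight_matrix: WeightMatrix
    J_exc: np.ndarray         # (N, N_E) float32, [EE; IE]
    J_inh: np.ndarray         # (N, N_I) float32, [EI; II]
    J_input: np.ndarray       # (N_E,) afferent weights, sigma^2 = 1
    seed_seq: np.random.SeedSequence


@dataclass
class SimulationResult:
    """Spike raster plus sampled membrane traces.

    Spike times are interpolated within the integration step; neuron ids
    0..N_E-1 are excitatory, N_E..N-1 inhibitory.  The raster includes the
    initial transient (flagged by ``T_transient``); analyses should drop
    ``t < T_transient``.
    """

    spike_ids: np.ndarray      # int32
    spike_times: np.ndarray    # float64, ms
    trace_times: np.ndarray    # float64, ms
    traces: np.ndarray         # (n_samples, n_recorded) float32, mV
    trace_neurons: np.ndarray  # int32 ids of recorded neurons
    config: NetworkConfig
    wall_time: float = 0.0

    @property
    def N_E(self) -> int:
        return self.config.N_E

    @property
    def T_transient(self) -> float:
        return self.config.T_transient

    def spike_types(self) -> np.ndarray:
        return np.where(self.spike_ids < self.config.N_E, "E", "I")

    def spikes_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"neuron_id": self.spike_ids, "type": self.spike_types(),
             "t_ms": self.spike_times}
        )

    def excitatory_spikes(self, discard_transient: bool = True):
        """(ids, times) of excitatory spikes, optionally post-transient."""
        m = self.spike_ids < self.config.N_E
        if discard_transient:
            m &= self.spike_times >= self.config.T_transient
        return self.spike_ids[m], self.spike_times[m]

    def excitatory_traces(self, discard_transient: bool = True):
        """(times, V) for recorded excitatory neurons."""
        cols = self.trace_neurons < self.config.N_E
        m = np.ones(self.trace_times.size, bool)
        if discard_transient:
            m = self.trace_times >= self.config.T_transient
        return self.trace_times[m], self.traces[np.ix_(m, cols)]


def build_network(config: NetworkConfig) -> Network:
    """Sample weights and assemble the stacked float32 blocks.

    The master seed spawns independent child streams for the recurrent
    weights, the afferent weights, the afferent spike trains and the
    membrane noise, so e.g. changing the input realisation never perturbs
    the connectivity.
    """
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(4)  # weights, input-weights, input-events, noise
    wm = sample_weight_matrix(
        config.N_E, config.N_I, config.family, config.sigma_E2, kids[0]
    )
    J_exc = np.vstack([wm.EE, wm.IE]).astype(np.float32)
    J_inh = np.vstack([wm.EI, wm.II]).astype(np.float32)
    ens_in = WeightEnsemble(config.family, 1.0)
    J_input = sample_weights(ens_in, (config.N_E,), np.random.default_rng(kids[1]))
    return Network(
        config=config, weight_matrix=wm, J_exc=J_exc, J_inh=J_inh,
        J_input=J_input, seed_seq=ss,
    )


def generate_afferent(
    config: NetworkConfig, duration: float, seed
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains, one per E neuron.

    Returns per-neuron sorted spike-time arrays in ms over [0, duration).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if config.input_rate < 0:
        raise ValueError("input_rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trains: list[np.ndarray] = []
    if config.input_rate == 0:
        return [np.empty(0) for _ in range(config.N_E)]
    mean_gap = 1000.0 / config.input_rate  # ms
    n_guess = int(duration / mean_gap * 1.5 + 20)
    for _ in range(config.N_E):
        gaps = rng.exponential(mean_gap, size=n_guess)
        t = np.cumsum(gaps)
        while t[-1] < duration:
            extra = rng.exponential(mean_gap, size=n_guess)
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
        trains.append(t[t < duration])
    return trains


def _receptor_groups(receptors: dict[str, ReceptorSpec]):
    """Group receptors by (carrier, reversal potential).

    Receptors sharing a carrier and V_R contribute through the same
    matrix-vector product; with the default table this yields one
    excitatory group (AMPA+NMDA at 0 mV) and two inhibitory groups
    (GABA-A at -70 mV, GABA-B at -80 mV).
    """
    exc = [receptors[n] for n in EXCITATORY_RECEPTORS if n in receptors]
    inh = [receptors[n] for n in INHIBITORY_RECEPTORS if n in receptors]
    def groups(specs):
        out: dict[float, list[ReceptorSpec]] = {}
        for s in specs:
            out.setdefault(s.V_R, []).append(s)
        return [(VR, lst) for VR, lst in out.items()]
    return exc, inh, groups(exc), groups(inh)


def run_simulation(
    network: Network,
    config: NetworkConfig | None = None,
    engine: str = "numba",
) -> SimulationResult:
    """Integrate the full network and record spikes and membrane traces.

    Deterministic for a fixed config + seed (per engine).  Two engines
    produce the same dynamics: ``"numba"`` (compiled, default) and
    ``"numpy"`` (pure-numpy reference used to cross-validate the compiled
    loop).  Raises ``FloatingPointError`` on numerical blow-up, reporting
    the time.
    """
    import time as _time

    if engine not in ("numba", "numpy"):
        raise ValueError("engine must be 'numba' or 'numpy'")
    cfg = config or network.config
    p = cfg.neuron
    NE, NI, N = cfg.N_E, cfg.N_I, cfg.N
    dt = cfg.dt
    n_steps = int(round(cfg.T_total / dt))
    delay_steps = max(int(round(TAU_AXON / dt)), 1)

    exc_specs, inh_specs, exc_groups, inh_groups = _receptor_groups(cfg.receptors)
    n_exc_r, n_inh_r = len(exc_specs), len(inh_specs)
    inv_tup_E = np.array([1.0 / s.tau_up for s in exc_specs])[:, None]
    inv_tdn_E = np.array([1.0 / s.tau_dn for s in exc_specs])[:, None]
    inv_tup_I = np.array([1.0 / s.tau_up for s in inh_specs])[:, None]
    inv_tdn_I = np.array([1.0 / s.tau_dn for s in inh_specs])[:, None]

    # per-group conductance-weighted selection of gating rows
    exc_g = [(VR, np.array([s.g for s in lst]),
              np.array([exc_specs.index(s) for s in lst])) for VR, lst in exc_groups]
    inh_g = [(VR, np.array([s.g for s in lst]),
              np.array([inh_specs.index(s) for s in lst])) for VR, lst in inh_groups]
    nge, ngi = len(exc_g), len(inh_g)

    # state
    V = np.full(N, p.V_L)
    u = np.zeros(N)
    t_last = np.full(N, -np.inf)
    xE = np.zeros((n_exc_r, NE)); sE = np.zeros((n_exc_r, NE))
    xI = np.zeros((n_inh_r, NI)); sI = np.zeros((n_inh_r, NI))
    xin = np.zeros(NE); sin = np.zeros(NE)

    # afferent events -> per-step pointers (delayed by tau_axon).
    # Children are re-derived from the config seed (not by re-spawning the
    # stateful network sequence) so repeated runs are identical: streams
    # 0/1 feed the weights in build_network, 2/3 the input events / noise.
    kids = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_in = np.random.default_rng(kids[2])
    rng_noise = np.random.default_rng(kids[3])
    trains = generate_afferent(cfg, cfg.T_total, rng_in)
    ev_step = np.concatenate(
        [np.floor((t + TAU_AXON) / dt).astype(np.int64) for t in trains]
    ) if NE else np.empty(0, np.int64)
    ev_nid = np.concatenate(
        [np.full(t.size, j, np.int64) for j, t in enumerate(trains)]
    ) if NE else np.empty(0, np.int64)
    order = np.argsort(ev_step, kind="stable")
    ev_step, ev_nid = ev_step[order], ev_nid[order]
    ev_ptr = 0
    n_ev = ev_step.size

    # recurrent delivery ring buffer: per-slot spiking neuron ids
    ring: list[np.ndarray | None] = [None] * delay_steps

    # recording
    rec_every = max(int(round(cfg.trace_dt / dt)), 1)
    if cfg.record == "all":
        rec_ids = np.arange(N, dtype=np.int32)
    elif cfg.record == "E":
        rec_ids = np.arange(NE, dtype=np.int32)
    else:
        rec_ids = np.empty(0, np.int32)
    n_rec_samples = n_steps // rec_every
    traces = np.zeros((n_rec_samples, rec_ids.size), dtype=np.float32)
    trace_times = (np.arange(n_rec_samples) + 1) * rec_every * dt

    # preallocated drive matrices (stage 1 | stage 2 columns)
    D_exc = np.zeros((NE, 2 * nge), dtype=np.float32)
    D_inh = np.zeros((NI, 2 * ngi), dtype=np.float32)
    VR_exc = np.array([VR for VR, _, _ in exc_g])
    VR_inh = np.array([VR for VR, _, _ in inh_g])

    gamma_input = cfg.gamma_E
    Jin_scaled = gamma_input * cfg.input_gain * network.J_input
    noise_scale = cfg.noise_sd / np.sqrt(dt) if cfg.noise_sd > 0 else 0.0

    t0 = _time.time()
    if engine == "numba":
        from ._core import integrate

        n_exc_r = len(exc_specs)
        n_inh_r = len(inh_specs)
        g_exc_mat = np.zeros((len(exc_g), n_exc_r))
        for c, (VR, gv, rows) in enumerate(exc_g):
            g_exc_mat[c, rows] = gv
        g_inh_mat = np.zeros((len(inh_g), n_inh_r))
        for c, (VR, gv, rows) in enumerate(inh_g):
            g_inh_mat[c, rows] = gv
        noise_seed = int(np.random.default_rng(kids[3]).integers(2**31 - 1))
        sp_ids, sp_ts, blow_up = integrate(
            network.J_exc, network.J_inh,
            g_exc_mat, g_inh_mat, VR_exc, VR_inh,
            np.array([1.0 / s.tau_up for s in exc_specs]),
            np.array([1.0 / s.tau_dn for s in exc_specs]),
            np.array([1.0 / s.tau_up for s in inh_specs]),
            np.array([1.0 / s.tau_dn for s in inh_specs]),
            Jin_scaled, ev_step, ev_nid,
            n_steps, dt, delay_steps, NE, NI,
            p.C, p.g_L, p.V_L, p.Delta_T, p.V_T, p.V_reset, p.V_peak,
            p.tau_u, p.a_u, p.b_u, p.t_ref,
            cfg.gamma_E, cfg.gamma_I, cfg.tau_input_up, cfg.tau_input_dn,
            noise_scale, noise_seed,
            rec_every, rec_ids, traces,
        )
        if blow_up >= 0:
            raise FloatingPointError(
                f"membrane potential blew up at t={blow_up:.2f} ms"
            )
        order = np.argsort(sp_ts, kind="stable")
        return SimulationResult(
            spike_ids=sp_ids[order], spike_times=sp_ts[order],
            trace_times=trace_times, traces=traces, trace_neurons=rec_ids,
            config=cfg, wall_time=_time.time() - t0,
        )

    spike_id_chunks: list[np.ndarray] = []
    spike_t_chunks: list[np.ndarray] = []

    for i in range(n_steps):
        t = i * dt
        slot = i % delay_steps
        # deliver recurrent spikes emitted delay_steps ago
        ids = ring[slot]
        if ids is not None and ids.size:
            e_ids = ids[ids < NE]
            i_ids = ids[ids >= NE] - NE
            if e_ids.size:
                np.add.at(xE, (slice(None), e_ids), inv_tup_E)
            if i_ids.size:
                np.add.at(xI, (slice(None), i_ids), inv_tup_I)
        ring[slot] = None
        # deliver afferent events binned to this step
        if ev_ptr < n_ev and ev_step[ev_ptr] <= i:
            j = ev_ptr
            while j < n_ev and ev_step[j] == i:
                j += 1
            np.add.at(xin, ev_nid[ev_ptr:j], 1.0 / cfg.tau_input_up)
            ev_ptr = j

        # ---- gating RK2; keep start-of-step s for the first V stage ----
        for col, (VR, gv, rows) in enumerate(exc_g):
            D_exc[:, col] = gv @ sE[rows]
        for col, (VR, gv, rows) in enumerate(inh_g):
            D_inh[:, col] = gv @ sI[rows]
        for x, s, itup, itdn in ((xE, sE, inv_tup_E, inv_tdn_E),
                                 (xI, sI, inv_tup_I, inv_tdn_I)):
            dx1 = -x * itup
            ds1 = x * (1.0 - s) - s * itdn
            x1 = x + dt * dx1
            s1 = s + dt * ds1
            dx2 = -x1 * itup
            ds2 = x1 * (1.0 - s1) - s1 * itdn
            x += 0.5 * dt * (dx1 + dx2)
            s += 0.5 * dt * (ds1 + ds2)
        sin0 = sin.copy()
        dx1 = -xin / cfg.tau_input_up
        ds1 = xin * (1.0 - sin) - sin / cfg.tau_input_dn
        x1 = xin + dt * dx1
        s1 = sin + dt * ds1
        dx2 = -x1 / cfg.tau_input_up
        ds2 = x1 * (1.0 - s1) - s1 / cfg.tau_input_dn
        xin += 0.5 * dt * (dx1 + dx2)
        sin += 0.5 * dt * (ds1 + ds2)
        for col, (VR, gv, rows) in enumerate(exc_g):
            D_exc[:, nge + col] = gv @ sE[rows]
        for col, (VR, gv, rows) in enumerate(inh_g):
            D_inh[:, ngi + col] = gv @ sI[rows]

        # two matrix products cover both RK stages of every neuron
        P = network.J_exc @ D_exc   # (N, 2*nge)
        Q = network.J_inh @ D_inh   # (N, 2*ngi)

        I_in1 = np.zeros(N); I_in2 = np.zeros(N)
        I_in1[:NE] = Jin_scaled * sin0
        I_in2[:NE] = Jin_scaled * sin
        if noise_scale:
            eta = rng_noise.normal(0.0, noise_scale, N)
            I_in1 += eta
            I_in2 += eta

        # ---- membrane RK2 ----
        def rhs(Vv, uu, elapsed, stage):
            Vc = np.minimum(Vv, p.V_peak)
            z = np.minimum(elapsed / p.t_ref, 6.0)
            ref = -np.expm1(-(z**20))
            exp_term = p.g_L * p.Delta_T * np.exp((Vc - p.V_T) / p.Delta_T) * ref
            off_e = 0 if stage == 1 else nge
            off_i = 0 if stage == 1 else ngi
            Isyn = np.zeros(N)
            for c in range(nge):
                Isyn += cfg.gamma_E * P[:, off_e + c] * (VR_exc[c] - Vc)
            for c in range(ngi):
                Isyn += cfg.gamma_I * Q[:, off_i + c] * (VR_inh[c] - Vc)
            Iin = I_in1 if stage == 1 else I_in2
            dV = (-p.g_L * (Vc - p.V_L) + exp_term - uu + Isyn + Iin) / p.C
            du = (-uu + p.a_u * (Vc - p.V_L)) / p.tau_u
            return dV, du

        k1V, k1u = rhs(V, u, t - t_last, 1)
        V1 = V + dt * k1V
        u1 = u + dt * k1u
        k2V, k2u = rhs(V1, u1, t + dt - t_last, 2)
        Vn = V + 0.5 * dt * (k1V + k2V)
        un = u + 0.5 * dt * (k1u + k2u)

        crossed = Vn >= p.V_peak
        if crossed.any():
            idx = np.flatnonzero(crossed)
            denom = Vn[idx] - V[idx]
            frac = np.where(denom > 0, (p.V_peak - V[idx]) / denom, 1.0)
            ts = t + dt * np.clip(frac, 0.0, 1.0)
            ok = ts - t_last[idx] >= p.t_ref  # interpolated-time gap check
            idx, ts = idx[ok], ts[ok]
            if idx.size:
                t_last[idx] = ts
                Vn[idx] = p.V_reset
                un[idx] += p.b_u
                spike_id_chunks.append(idx.astype(np.int32))
                spike_t_chunks.append(ts)
                ring[(i + delay_steps) % delay_steps] = idx
        np.minimum(Vn, p.V_peak, out=Vn)
        V, u = Vn, un

        if not np.isfinite(V).all():
            raise FloatingPointError(
                f"membrane potential blew up at t={t + dt:.2f} ms"
            )
        if rec_ids.size and (i + 1) % rec_every == 0:
            traces[(i + 1) // rec_every - 1] = V[rec_ids]

    if spike_id_chunks:
        spike_ids = np.concatenate(spike_id_chunks)
        spike_times = np.concatenate(spike_t_chunks)
        order = np.argsort(spike_times, kind="stable")
        spike_ids, spike_times = spike_ids[order], spike_times[order]
    else:
        spike_ids = np.empty(0, np.int32)
        spike_times = np.empty(0)

    return SimulationResult(
        spike_ids=spike_ids, spike_times=spike_times,
        trace_times=trace_times, traces=traces, trace_neurons=rec_ids,
        config=cfg, wall_time=_time.time() - t0,
    )


def simulate(config: NetworkConfig) -> SimulationResult:
    """Build the network for ``config`` and run it (convenience wrapper)."""
    return run_simulation(build_network(config))
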