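"""Mean-field fixed-point analysis of UP-state existence and stability.

The analysis assumes a homogeneous network in which every neuron fires at a
common stationary rate f during an UP state and the mean membrane potential
is pinned at ``V_mean`` (default -55 mV).  Under Poisson firing the mean
gate of receptor psi is ``m_psi(f) = tau_dn_psi f / (1 + tau_dn_psi f)``,
giving the mean synaptic drive::

    I_syn(f) = gamma_E N_E <J> sum_{psi in exc} g_psi (V_R_psi - V_mean) m_psi(f)
             + gamma_I N_I <J> sum_{psi in inh} g_psi (V_R_psi - V_mean) m_psi(f)

with <J> = 1, and the mean adaptation current::

    u(f) = a_u (V_mean - V_L) + b_u tau_u f.

UP states correspond to solutions of the self-consistency map
``f = F'(f) = F[I_syn(f) - u(f)]`` where F is the quartic single-neuron
response function.  A crossing is classified stable iff the iteration-map
slope dF'/df is below 1 there.  Regimes:

- ``no_up``: only the trivial f = 0 solution;
- ``transient_up``: a non-trivial but unstable crossing exists;
- ``self_sustained_up``: a stable non-trivial crossing exists.

Because I_syn scales linearly with the network size, the critical coupling
gamma scales as 1/N_E.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .neuron import FIFit, NeuronParams
from .synapses import (
    RECEPTORS,
    EXCITATORY_RECEPTORS,
    INHIBITORY_RECEPTORS,
    ReceptorSpec,
    mean_gating,
)

__all__ = [
    "MeanFieldConfig",
    "FixedPointReport",
    "drive_at_rate",
    "adaptation_at_rate",
    "response_map",
    "solve_fixed_points",
    "critical_gamma_E",
]

REGIMES = ("no_up", "transient_up", "self_sustained_up")


@dataclass
class MeanFieldConfig:
    """Inputs of the fixed-point analysis."""

    fifit: FIFit
    gamma_E: float = 0.1
    gamma_I: float = 0.1
    N_E: int = 1000
    N_I: int | None = None
    V_mean: float = -55.0            # assumed UP-state mean voltage, mV
    b_u: float = 50.0                # pA
    a_u: float = 4.0                 # nS
    V_L: float = -70.0               # mV
    tau_u: float = 200.0             # ms
    mean_J: float = 1.0
    receptors: dict = field(default_factory=lambda: dict(RECEPTORS))

    def __post_init__(self):
        if self.N_I is None:
            self.N_I = int(round(self.N_E / 4))
        lows = [s.V_R for s in self.receptors.values()
                if s.carrier == "inhibitory"]
        lower = min(lows) if lows else -np.inf
        if not (lower < self.V_mean < 20.0):
            raise ValueError("V_mean must lie between the lowest inhibitory "
                             "reversal potential and V_peak")


@dataclass
class FixedPointReport:
    """Non-trivial crossings of f = F'(f) and the resulting regime."""

    fixed_points: list[tuple[float, bool]]   # (f* in Hz, stable?)
    regime: str
    f_grid: np.ndarray
    map_values: np.ndarray                   # F'(f) on the grid

    @property
    def stable_points(self) -> list[float]:
        return [f for f, s in self.fixed_points if s]


def drive_at_rate(f, cfg: MeanFieldConfig):
    """Mean synaptic current (pA) when every neuron fires at f (Hz)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("rate must be non-negative")
    total = np.zeros_like(f)
    for name, spec in cfg.receptors.items():
        m = (spec.tau_dn / 1000.0 * f) / (1.0 + spec.tau_dn / 1000.0 * f)
        df = spec.V_R - cfg.V_mean
        if spec.carrier == "excitatory":
            total = total + cfg.gamma_E * cfg.N_E * cfg.mean_J * spec.g * df * m
        else:
            total = total + cfg.gamma_I * cfg.N_I * cfg.mean_J * spec.g * df * m
    return total if total.ndim else float(total)


def adaptation_at_rate(f, cfg: MeanFieldConfig):
    """Mean adaptation current (pA) at postsynaptic rate f (Hz).

    ``a_u (V_mean - V_L) + b_u tau_u f`` with tau_u in seconds so that
    Hz * s * pA reconciles to pA.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("rate must be non-negative")
    out = cfg.a_u * (cfg.V_mean - cfg.V_L) + cfg.b_u * (cfg.tau_u / 1000.0) * f
    return out if out.ndim else float(out)


def response_map(f, cfg: MeanFieldConfig):
    """The iteration map F'(f) = F[I_syn(f) - u(f)]."""
    return cfg.fifit(drive_at_rate(f, cfg) - adaptation_at_rate(f, cfg))


def _saturation_rate(cfg: MeanFieldConfig) -> float:
    """Upper end of the f search range: the response function's ceiling."""
    return float(cfg.fifit(cfg.fifit.theta_f + cfg.fifit.valid_range_max)) + 50.0


def solve_fixed_points(
    cfg: MeanFieldConfig,
    f_grid: np.ndarray | None = None,
) -> FixedPointReport:
    """Locate all non-trivial crossings of f = F'(f) and classify them.

    Crossings are bracketed by sign changes of ``F'(f) - f`` on the grid
    and refined by bisection; stability uses the numerical slope of the
    map at the crossing (< 1 is stable).  The f = 0 neighbourhood is
    always examined: the grid starts at 0 and the trivial solution is not
    reported as a fixed point.
    """
    if f_grid is None:
        f_grid = np.linspace(0.0, _saturation_rate(cfg), 4001)
    g = np.asarray(f_grid, dtype=float)
    vals = response_map(g, cfg)
    if not np.all(np.isfinite(vals)):
        raise ValueError("response map non-finite on the grid")
    resid = vals - g
    points: list[tuple[float, bool]] = []
    fun = lambda f: float(response_map(f, cfg)) - f
    for k in range(len(g) - 1):
        if g[k] == 0.0 and resid[k] <= 0.0:
            continue  # trivial DOWN solution
        a, b = resid[k], resid[k + 1]
        if a == 0.0:
            root = g[k]
        elif a * b < 0:
            root = brentq(fun, g[k], g[k + 1], xtol=1e-6)
        else:
            continue
        h = max(1e-4, 1e-6 * max(root, 1.0))
        lo = max(root - h, 0.0)
        slope = (float(response_map(root + h, cfg))
                 - float(response_map(lo, cfg))) / (root + h - lo)
        if root > 1e-9:
            points.append((float(root), bool(slope < 1.0)))
    if not points:
        regime = "no_up"
    elif any(s for _, s in points):
        regime = "self_sustained_up"
    else:
        regime = "transient_up"
    return FixedPointReport(
        fixed_points=points, regime=regime, f_grid=g, map_values=vals
    )


def _regime_reached(cfg: MeanFieldConfig, target: str) -> bool:
    rep = solve_fixed_points(cfg)
    if target == "self_sustained_up":
        return rep.regime == "self_sustained_up"
    if target == "transient_up":
        return rep.regime in ("transient_up", "self_sustained_up")
    raise ValueError(f"unknown regime target {target!r}")


def critical_gamma_E(
    gamma_I: float | None,
    cfg: MeanFieldConfig,
    regime_target: str = "self_sustained_up",
    bracket: tuple[float, float] = (1e-3, 1.0),
    tol: float = 1e-4,
) -> float:
    """Bisect gamma_E to the onset of the target regime.

    With ``gamma_I=None`` the two factors are tied (gamma_E = gamma_I),
    which is the constraint used for the boundary quoted on the phase
    diagram's diagonal.  Raises if the bracket does not straddle the
    boundary.
    """
    lo, hi = bracket

    def reached(gE: float) -> bool:
        c = replace(cfg, gamma_E=gE, gamma_I=gE if gamma_I is None else gamma_I)
        return _regime_reached(c, regime_target)

    if reached(lo):
        raise ValueError("regime already present at the lower bracket")
    if not reached(hi):
        raise ValueError("regime absent at the upper bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if reached(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
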