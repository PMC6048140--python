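"""UP/DOWN segmentation of membrane traces and slow-oscillation statistics.

A neuron is in the UP state while its boxcar-smoothed membrane potential
exceeds a threshold placed midway between the DOWN (~ -70 mV) and UP
(~ -55 mV) plateaus.  Brief DOWN gaps are merged and brief UP episodes
discarded, so the segmentation is robust to spike transients.  From the
per-neuron intervals the module derives UP/DOWN-cycle statistics (an
UP-DOWN cycle is one UP state plus the consecutive DOWN state), the
population UP state (>= half of the excitatory neurons simultaneously UP)
whose onset rate measures the slow-oscillation frequency, Fano factors of
spike counts across repeated UP episodes, and phase-diagram sweeps over
the coupling factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "DetectionParams",
    "UpDownSegmentation",
    "CycleStats",
    "segment_updown",
    "up_mask",
    "cycle_statistics",
    "population_up_intervals",
    "oscillation_frequency",
    "fano_factor",
    "updown_phase_diagram",
]


@dataclass(frozen=True)
class DetectionParams:
    """UP-state detector constants (all configurable; ms and mV)."""

    threshold: float = -62.0     # mV, midpoint between the two plateaus
    smooth_ms: float = 10.0      # boxcar width
    min_duration: float = 50.0   # shortest UP episode kept
    merge_gap: float = 50.0      # DOWN gaps shorter than this are merged


@dataclass
class UpDownSegmentation:
    """Per-neuron UP intervals [(onset, offset), ...] in ms."""

    intervals: list[np.ndarray]     # each (n_k, 2), disjoint, ordered
    params: DetectionParams
    t_start: float                  # analysed window, ms
    t_stop: float

    def __post_init__(self):
        for iv in self.intervals:
            if iv.size and (np.any(iv[:, 1] <= iv[:, 0])
                            or np.any(np.diff(iv[:, 0]) <= 0)):
                raise ValueError("intervals must be ordered and non-empty")

    @property
    def n_neurons(self) -> int:
        return len(self.intervals)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def up_durations(self) -> np.ndarray:
        """Pooled UP-state durations over all neurons (ms)."""
        d = [iv[:, 1] - iv[:, 0] for iv in self.intervals if iv.size]
        return np.concatenate(d) if d else np.empty(0)

    def mean_up_duration(self) -> float:
        d = self.up_durations()
        return float(d.mean()) if d.size else np.nan


def _mask_to_intervals(mask: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Contiguous True runs of ``mask`` as (onset, offset) time pairs."""
    if not mask.any():
        return np.empty((0, 2))
    m = np.asarray(mask, dtype=np.int8)
    d = np.diff(m)
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    out = np.empty((len(starts), 2))
    dt = times[1] - times[0] if times.size > 1 else 1.0
    for k, (a, b) in enumerate(zip(starts, stops)):
        out[k, 0] = times[a]
        out[k, 1] = times[b - 1] + dt
    return out


def _clean_intervals(iv: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Merge short DOWN gaps, then drop short UP episodes."""
    if iv.shape[0] == 0:
        return iv
    merged = [iv[0].copy()]
    for a, b in iv[1:]:
        if a - merged[-1][1] < params.merge_gap:
            merged[-1][1] = b
        else:
            merged.append(np.array([a, b]))
    out = np.array(merged)
    keep = (out[:, 1] - out[:, 0]) >= params.min_duration
    return out[keep]


def up_mask(
    traces: np.ndarray,
    trace_dt: float,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Boolean (n_samples, n_neurons) mask of smoothed-V > threshold."""
    V = np.atleast_2d(np.asarray(traces, dtype=float))
    if V.shape[0] == 1 and traces.ndim == 1:
        V = V.T
    w = max(int(round(params.smooth_ms / trace_dt)), 1)
    if V.shape[0] < w:
        raise ValueError("trace shorter than the smoothing window")
    sm = uniform_filter1d(V, size=w, axis=0, mode="nearest")
    return sm > params.threshold


def segment_updown(
    traces: np.ndarray,
    trace_dt: float,
    params: DetectionParams = DetectionParams(),
    t_start: float = 0.0,
) -> UpDownSegmentation:
    """Segment membrane traces into per-neuron UP intervals.

    ``traces`` is (n_samples, n_neurons) (a 1-D array is treated as one
    neuron) sampled every ``trace_dt`` ms, starting at ``t_start``.
    """
    mask = up_mask(traces, trace_dt, params)
    n_samples, n_neurons = mask.shape
    times = t_start + np.arange(n_samples) * trace_dt
    intervals = []
    for j in range(n_neurons):
        iv = _mask_to_intervals(mask[:, j], times)
        intervals.append(_clean_intervals(iv, params))
    return UpDownSegmentation(
        intervals=intervals, params=params,
        t_start=t_start, t_stop=t_start + n_samples * trace_dt,
    )


@dataclass
class CycleStats:
    """Pooled UP-DOWN-cycle statistics for one condition.

    ``normalized`` are cycle durations divided by the pooled mean cycle
    duration, so their sample mean is 1 by construction.  ``empty`` marks
    conditions without a single complete cycle.
    """

    mean_up: float
    mean_cycle: float
    normalized: np.ndarray
    n_cycles: int

    @property
    def empty(self) -> bool:
        return self.n_cycles == 0

    def density(self, bins=40, range=(0.0, 4.0)):
        """Histogram estimate of the normalized-cycle-duration density."""
        if self.normalized.size == 0:
            edges = np.linspace(range[0], range[1], bins + 1)
            return 0.5 * (edges[:-1] + edges[1:]), np.zeros(bins)
        hist, edges = np.histogram(self.normalized, bins=bins, range=range,
                                   density=True)
        return 0.5 * (edges[:-1] + edges[1:]), hist


def cycle_statistics(seg: UpDownSegmentation) -> CycleStats:
    """UP-DOWN-cycle durations pooled over all neurons.

    A cycle is the time from one UP onset to the next UP onset of the same
    neuron (UP duration plus the consecutive DOWN duration); neurons with
    fewer than two UP episodes contribute none.
    """
    cycles = []
    for iv in seg.intervals:
        if iv.shape[0] >= 2:
            cycles.append(np.diff(iv[:, 0]))
    ups = seg.up_durations()
    mean_up = float(ups.mean()) if ups.size else np.nan
    if not cycles:
        return CycleStats(mean_up=mean_up, mean_cycle=np.nan,
                          normalized=np.empty(0), n_cycles=0)
    c = np.concatenate(cycles)
    mean_cycle = float(c.mean())
    return CycleStats(
        mean_up=mean_up, mean_cycle=mean_cycle,
        normalized=c / mean_cycle, n_cycles=int(c.size),
    )


def population_up_intervals(
    traces: np.ndarray,
    trace_dt: float,
    params: DetectionParams = DetectionParams(),
    fraction: float = 0.5,
    t_start: float = 0.0,
) -> np.ndarray:
    """Intervals during which >= ``fraction`` of the neurons are UP."""
    mask = up_mask(traces, trace_dt, params)
    pop = mask.mean(axis=1) >= fraction
    times = t_start + np.arange(mask.shape[0]) * trace_dt
    iv = _mask_to_intervals(pop, times)
    return _clean_intervals(iv, params)


def oscillation_frequency(
    traces: np.ndarray,
    trace_dt: float,
    params: DetectionParams = DetectionParams(),
    fraction: float = 0.5,
) -> float:
    """Population UP-onset rate in Hz (slow-oscillation frequency)."""
    iv = population_up_intervals(traces, trace_dt, params, fraction)
    duration_s = traces.shape[0] * trace_dt / 1000.0
    return iv.shape[0] / duration_s


def fano_factor(
    spike_ids: np.ndarray,
    spike_times: np.ndarray,
    seg: UpDownSegmentation,
    neuron_ids: Sequence[int] | None = None,
    window: float | None = None,
    max_window: float | None = None,
    min_episodes: int = 5,
):
    """Fano factor of spike counts across repeated UP episodes.

    For each neuron, fixed-length windows are aligned at its UP onsets
    (length = the minimum episode duration, optionally capped by
    ``max_window``, or an explicit ``window``), so counts are comparable
    across episodes of unequal length; spikes outside UP states never
    enter a count.  F = var(count)/mean(count) (unbiased variance);
    neurons with fewer than ``min_episodes`` episodes or zero mean count
    get NaN.  Returns (per-neuron array, mean over defined neurons).
    """
    if neuron_ids is None:
        neuron_ids = range(seg.n_neurons)
    neuron_ids = list(neuron_ids)
    out = np.full(len(neuron_ids), np.nan)
    for k, nid in enumerate(neuron_ids):
        iv = seg.intervals[nid]
        if iv.shape[0] < min_episodes:
            continue
        durs = iv[:, 1] - iv[:, 0]
        w = window if window is not None else float(durs.min())
        if max_window is not None:
            w = min(w, max_window)
        st = spike_times[spike_ids == nid]
        counts = np.array([
            np.count_nonzero((st >= a) & (st < a + w)) for a, _ in iv
        ], dtype=float)
        m = counts.mean()
        if m > 0:
            out[k] = counts.var(ddof=1) / m
    defined = out[np.isfinite(out)]
    return out, (float(defined.mean()) if defined.size else np.nan)


def updown_phase_diagram(
    cells: Sequence[dict],
    base_config,
    detection: DetectionParams = DetectionParams(),
    engine: str = "numba",
):
    """Mean UP duration over a grid of simulation conditions.

    ``cells`` is a sequence of config-override dicts (e.g.
    ``{"gamma_E": 0.1, "gamma_I": 0.1}``); each cell runs one simulation
    with a seed derived stably from the base seed and the cell index.
    Per-cell failures are recorded as flagged rows, not raised.  Returns a
    pandas DataFrame with one row per cell.
    """
    import pandas as pd

    from .simulator import build_network, run_simulation

    rows = []
    for idx, cell in enumerate(cells):
        cfg = replace(base_config, **cell)
        cfg.seed = int(np.random.SeedSequence([base_config.seed, idx])
                       .generate_state(1)[0] % (2**31 - 1))
        row = dict(cell)
        row["seed"] = cfg.seed
        try:
            res = run_simulation(build_network(cfg), engine=engine)
            tt, V = res.excitatory_traces()
            seg = segment_updown(V, cfg.trace_dt, detection, t_start=tt[0])
            stats = cycle_statistics(seg)
            analysis = seg.duration
            row.update(
                mean_up_ms=stats.mean_up,
                mean_cycle_ms=stats.mean_cycle,
                n_cycles=stats.n_cycles,
                near_continuous=bool(
                    np.isfinite(stats.mean_up) and stats.mean_up >= 0.8 * analysis
                ),
                failed=False, error="",
            )
        except (FloatingPointError, ValueError) as exc:  # flagged, not fatal
            row.update(mean_up_ms=np.nan, mean_cycle_ms=np.nan, n_cycles=0,
                       near_continuous=False, failed=True, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
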