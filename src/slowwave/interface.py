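"""Configuration schema, run containers and fixture generators.

Configuration lives in a YAML file with nested sections (``neuron``,
``receptors``, ``weights``, ``network``, ``detection``, ``nmf``); every
field defaults to the model's standard constants, an empty file is a
complete valid configuration, and unknown keys are rejected with the
offending name.  One master seed drives independent child streams for
weights, afferent input, noise and NMF restarts, so e.g. changing the
number of NMF restarts never perturbs the simulated dynamics.

Run containers are HDF5 files holding the spike table, the membrane-trace
table and a verbatim YAML echo of the resolved configuration; a
write-then-read round trip reproduces the spike tables exactly.

``make_fixture_raster`` builds UP/DOWN square-wave-modulated Poisson
rasters with planted co-active assemblies and returns the ground truth, so
the segmentation and NMF analyses are testable without the simulator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .neuron import NeuronParams
from .synapses import receptor_table
from .simulator import NetworkConfig, SimulationResult
from .updown import DetectionParams

__all__ = [
    "RunConfig",
    "NMFSettings",
    "load_config",
    "config_to_dict",
    "save_result",
    "load_result",
    "FixtureSpec",
    "FixtureRaster",
    "make_fixture_raster",
]

SCHEMA_VERSION = 1

_NETWORK_KEYS = {
    "N_E", "N_I", "gamma_E", "gamma_I", "input_rate", "input_gain",
    "tau_input_up", "tau_input_dn", "dt", "T_total", "T_transient",
    "seed", "noise_sd", "trace_dt", "record",
}
_WEIGHT_KEYS = {"family", "sigma_E2"}


@dataclass
class NMFSettings:
    k_max: int = 15
    restarts: int = 3
    window: float = 200.0   # ms
    step: float = 50.0      # ms; == window gives non-overlapping binning

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("nmf.restarts must be >= 1")
        if self.k_max < 1:
            raise ValueError("nmf.k_max must be >= 1")


@dataclass
class RunConfig:
    """Fully resolved configuration of a simulation + analysis run."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    nmf: NMFSettings = field(default_factory=NMFSettings)
    schema_version: int = SCHEMA_VERSION

    @property
    def seed(self) -> int:
        return self.network.seed


def _check_keys(section: str, given: Mapping, allowed: set):
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )


def _from_dict(data: Mapping) -> RunConfig:
    allowed_sections = {"neuron", "receptors", "weights", "network",
                        "detection", "nmf", "schema_version"}
    _check_keys("<root>", data, allowed_sections)

    neuron_fields = {f.name for f in dataclasses.fields(NeuronParams)}
    neuron_cfg = dict(data.get("neuron") or {})
    _check_keys("neuron", neuron_cfg, neuron_fields)
    neuron = NeuronParams(**neuron_cfg)

    receptors = receptor_table(data.get("receptors") or None)

    weights_cfg = dict(data.get("weights") or {})
    _check_keys("weights", weights_cfg, _WEIGHT_KEYS)

    network_cfg = dict(data.get("network") or {})
    _check_keys("network", network_cfg, _NETWORK_KEYS)
    network = NetworkConfig(
        neuron=neuron, receptors=receptors, **weights_cfg, **network_cfg
    )
    # validate the weight family/variance combination up front so config
    # errors surface at load time, not mid-run
    from .weights import WeightEnsemble

    WeightEnsemble(network.family, network.sigma_E2)

    det_fields = {f.name for f in dataclasses.fields(DetectionParams)}
    det_cfg = dict(data.get("detection") or {})
    _check_keys("detection", det_cfg, det_fields)
    detection = DetectionParams(**det_cfg)

    nmf_cfg = dict(data.get("nmf") or {})
    _check_keys("nmf", nmf_cfg, {f.name for f in dataclasses.fields(NMFSettings)})
    nmf = NMFSettings(**nmf_cfg)

    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    return RunConfig(network=network, detection=detection, nmf=nmf)


def load_config(path) -> RunConfig:
    """Parse a YAML config file; missing sections take their defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    """Resolved configuration as a plain nested dict (YAML-serialisable)."""
    net = cfg.network
    return {
        "schema_version": cfg.schema_version,
        "neuron": dataclasses.asdict(net.neuron),
        "receptors": {
            name: {"tau_up": s.tau_up, "tau_dn": s.tau_dn, "V_R": s.V_R,
                   "g": s.g, "carrier": s.carrier}
            for name, s in net.receptors.items()
        },
        "weights": {"family": net.family, "sigma_E2": net.sigma_E2},
        "network": {k: getattr(net, k) for k in sorted(_NETWORK_KEYS)},
        "detection": dataclasses.asdict(cfg.detection),
        "nmf": dataclasses.asdict(cfg.nmf),
    }


# ---------------------------------------------------------------------------
# run containers

def save_result(result: SimulationResult, path, run_config: RunConfig | None = None):
    """Write a simulation result to an HDF5 container."""
    import h5py

    if run_config is None:
        run_config = RunConfig(network=result.config)
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("neuron_id", data=result.spike_ids)
        g.create_dataset("t_ms", data=result.spike_times)
        g = f.create_group("traces")
        g.create_dataset("t_ms", data=result.trace_times)
        g.create_dataset("V_mV", data=result.traces)
        g.create_dataset("neuron_id", data=result.trace_neurons)
        f.attrs["config_yaml"] = yaml.safe_dump(config_to_dict(run_config))
        f.attrs["wall_time_s"] = result.wall_time


def load_result(path) -> tuple[SimulationResult, RunConfig]:
    """Read a run container back; spike tables round-trip exactly."""
    import h5py

    with h5py.File(path, "r") as f:
        cfg = _from_dict(yaml.safe_load(f.attrs["config_yaml"]))
        res = SimulationResult(
            spike_ids=f["spikes/neuron_id"][...],
            spike_times=f["spikes/t_ms"][...],
            trace_times=f["traces/t_ms"][...],
            traces=f["traces/V_mV"][...],
            trace_neurons=f["traces/neuron_id"][...],
            config=cfg.network,
            wall_time=float(f.attrs.get("wall_time_s", 0.0)),
        )
    return res, cfg


# ---------------------------------------------------------------------------
# fixtures

@dataclass
class FixtureSpec:
    """Planted-assembly raster specification.

    ``assemblies`` lists the member neurons of each ground-truth assembly;
    ``up_windows`` are (start, stop) ms intervals during which the
    population is UP.  Within each UP window exactly one assembly (cycled
    in order) is active: its members fire at ``rate_assembly`` while every
    neuron fires at ``rate_up``; between windows all neurons fire at
    ``rate_down``.  Overlapping assemblies are allowed.
    """

    n_neurons: int = 60
    assemblies: Sequence[Sequence[int]] = ()
    up_windows: Sequence[tuple[float, float]] = ()
    rate_up: float = 2.0          # Hz, every neuron during UP
    rate_down: float = 0.2        # Hz, between UP windows
    rate_assembly: float = 25.0   # Hz, active-assembly members during UP
    T: float = 10000.0            # ms
    seed: int = 0

    def __post_init__(self):
        for r in (self.rate_up, self.rate_down, self.rate_assembly):
            if r < 0:
                raise ValueError("rates must be non-negative")
        for members in self.assemblies:
            for m in members:
                if not 0 <= m < self.n_neurons:
                    raise ValueError(f"assembly member {m} out of range")
        for a, b in self.up_windows:
            if not 0 <= a < b <= self.T:
                raise ValueError(f"bad UP window ({a}, {b})")


@dataclass
class FixtureRaster:
    """Generated raster plus its ground truth."""

    spike_ids: np.ndarray
    spike_times: np.ndarray
    spec: FixtureSpec
    up_intervals: np.ndarray          # (n_windows, 2), same for every neuron
    membership: np.ndarray            # (n_assemblies, n_neurons) bool
    window_assembly: np.ndarray       # assembly index active in each window


def _poisson_times(rng, rate_hz: float, a: float, b: float) -> np.ndarray:
    if rate_hz <= 0 or b <= a:
        return np.empty(0)
    n = rng.poisson(rate_hz * (b - a) / 1000.0)
    return np.sort(rng.uniform(a, b, size=n))


def make_fixture_raster(spec: FixtureSpec) -> FixtureRaster:
    """Generate an UP/DOWN-modulated Poisson raster with planted assemblies."""
    rng = np.random.default_rng(spec.seed)
    n_asm = len(spec.assemblies)
    windows = np.asarray(spec.up_windows, dtype=float).reshape(-1, 2)
    window_assembly = (np.arange(windows.shape[0]) % n_asm
                       if n_asm else np.full(windows.shape[0], -1))
    membership = np.zeros((n_asm, spec.n_neurons), dtype=bool)
    for k, members in enumerate(spec.assemblies):
        membership[k, list(members)] = True

    ids, times = [], []
    # DOWN-state background over the complement of the UP windows
    edges = [0.0]
    for a, b in windows:
        edges += [a, b]
    edges.append(spec.T)
    for j in range(spec.n_neurons):
        for lo, hi in zip(edges[0::2], edges[1::2]):
            t = _poisson_times(rng, spec.rate_down, lo, hi)
            times.append(t)
            ids.append(np.full(t.size, j, np.int32))
    # UP-state firing
    for w, (a, b) in enumerate(windows):
        active = (membership[window_assembly[w]]
                  if n_asm else np.zeros(spec.n_neurons, bool))
        for j in range(spec.n_neurons):
            rate = spec.rate_assembly if active[j] else spec.rate_up
            t = _poisson_times(rng, rate, a, b)
            times.append(t)
            ids.append(np.full(t.size, j, np.int32))

    all_t = np.concatenate(times) if times else np.empty(0)
    all_i = np.concatenate(ids) if ids else np.empty(0, np.int32)
    order = np.argsort(all_t, kind="stable")
    return FixtureRaster(
        spike_ids=all_i[order], spike_times=all_t[order], spec=spec,
        up_intervals=windows, membership=membership,
        window_assembly=window_assembly,
    )
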