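# slowwave

A spiking-network model and analysis toolkit for cortical UP/DOWN
dynamics during slow-wave activity, for computational neuroscientists
studying how the statistics of random synaptic connectivity shape the
slow (~1 Hz) alternation between depolarized UP states and quiescent
DOWN states — and what that alternation implies for the repetition of
cell assemblies.

The model is a recurrent network of N_E excitatory and N_I = N_E/4
inhibitory adaptive exponential integrate-and-fire (AdEx) neurons,

    C dV/dt   = -g_L (V - V_L) + g_L Δ_T e^{(V - V_T)/Δ_T} R(t) - u
                + I_syn + I_input,
    τ_u du/dt = -u + a_u (V - V_L),   u ← u + b_u at each spike,

coupled all-to-all through AMPA/NMDA and GABA-A(fast, slow)/GABA-B
conductance synapses with second-order gating kinetics and random
weights drawn from a lognormal, sparse-Gaussian, or sparse-lognormal
ensemble with mean 1 and variance σ² (σ_E² on excitatory axons, 1 on
inhibitory ones), scaled by factors γ_E and γ_I.  Each excitatory neuron
receives an independent 10 Hz Poisson afferent train.

On top of the simulator the package provides:

- **mean-field analysis** — existence and stability of UP-state fixed
  points of f = F[I_syn(f) - u(f)], regime classification, and the
  critical coupling γ_c (which scales as 1/N_E);
- **UP/DOWN statistics** — threshold segmentation of membrane traces,
  UP-DOWN-cycle distributions, population-UP oscillation frequency,
  phase-diagram sweeps, and Fano factors of spike counts across repeated
  UP episodes;
- **cell-assembly extraction** — NMF of the neurons × time firing-rate
  matrix, D ≈ BC, with the order selected by small-sample-corrected
  AIC (AICc), plus order-vs-duration and activation-correlation
  statistics;
- **fixture generators** — planted-assembly UP/DOWN rasters with ground
  truth, so every analysis stage is testable without the simulator.

See `docs/methods.md` for the model equations, parameter tables, and
numerical choices, including the one free scale the model leaves open
(the afferent input gain) and the known bias of the stationary gating
approximation used by the mean-field layer.

## Worked example

Single-neuron response and the mean-field UP-state boundary:

```python
import numpy as np
from slowwave import (NeuronParams, find_rheobase, measure_fi_curve,
                      fit_response_function, MeanFieldConfig,
                      critical_gamma_E, solve_fixed_points)

p = NeuronParams().without_sfa()          # disable adaptation
theta = find_rheobase(p)                  # pA
fit = fit_response_function(
    measure_fi_curve(p, np.arange(theta + 20, theta + 1840, 20)),
    theta_f=theta)
print(f"rheobase {theta:.1f} pA, fit A = {fit.A:.3f} Hz/pA")

cfg = MeanFieldConfig(fifit=fit, N_E=1000, b_u=50.0)
gc = critical_gamma_E(None, cfg)          # tied gamma_E = gamma_I
rep = solve_fixed_points(cfg)             # at gamma = 0.1
print(f"critical gamma = {gc:.4f}; regime at gamma=0.1: {rep.regime}")
for f, stable in rep.fixed_points:
    print(f"  fixed point {f:7.2f} Hz, {'stable' if stable else 'unstable'}")
```

prints

```
rheobase 130.1 pA, fit A = 1.301 Hz/pA
critical gamma = 0.0208; regime at gamma=0.1: self_sustained_up
  fixed point    2.62 Hz, unstable
  fixed point  454.09 Hz, stable
```

i.e. the neuron starts firing at ~130 pA with a near-linear response of
~1.3 Hz per pA above rheobase; at network coupling γ = 0.1 the
mean-field map has an ignition threshold at ~2.6 Hz and a stable
high-rate UP fixed point, and stable UP solutions first appear at
γ_c ≈ 0.021 for N_E = 1000 (halving to ≈ 0.010 at N_E = 2000 — the
1/N_E law).

Simulating the network and segmenting its UP states:

```python
from slowwave import (NetworkConfig, simulate, segment_updown,
                      cycle_statistics, oscillation_frequency)

cfg = NetworkConfig(N_E=1000, gamma_E=0.1, gamma_I=0.1, sigma_E2=100.0,
                    T_total=10_000.0, seed=7)   # 2 s transient included
res = simulate(cfg)
tt, V = res.excitatory_traces()                 # post-transient traces
seg = segment_updown(V, cfg.trace_dt, t_start=tt[0])
st = cycle_statistics(seg)
print(f"mean UP {st.mean_up:.0f} ms, mean cycle {st.mean_cycle:.0f} ms, "
      f"oscillation {oscillation_frequency(V, cfg.trace_dt):.2f} Hz")
```

prints

```
mean UP 253 ms, mean cycle 1169 ms, oscillation 0.87 Hz
```

— synchronous UP episodes of a couple hundred milliseconds recurring at
just under 1 Hz, the slow-oscillation regime.

The same operations are available from the shell:

```sh
slowwave simulate --config run.yaml --out run.h5
slowwave updown --run run.h5 --report report/
slowwave assemblies --run run.h5 --kmax 12 --out nmf.h5
slowwave meanfield --gamma-i 0.1 --bu 50 --ne 1000
slowwave phase-diagram --sweep "gamma=0.08:0.14:4" --out grid.tsv
```

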