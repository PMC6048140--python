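# Methods

`slowwave` simulates a randomly connected cortical network of adaptive
exponential integrate-and-fire (AdEx) neurons whose population dynamics
alternate between a depolarized, spiking UP state and a quiescent DOWN
state, as in slow-wave sleep, and analyses those dynamics: a mean-field
account of when UP states can self-sustain, UP/DOWN segmentation and
cycle statistics, spike-count variability (Fano factors), and
non-negative matrix factorization (NMF) of the population rate to extract
recurring cell assemblies.

## Neuron model

Every neuron (excitatory and inhibitory alike) follows

    C dV/dt   = -g_L (V - V_L) + g_L Δ_T exp[(V - V_T)/Δ_T] · R(t)
                - u + I_syn + I_input + η
    τ_u du/dt = -u + a_u (V - V_L)

with a spike registered when V reaches V_peak = 20 mV, after which
V ← V_reset = -55 mV and u ← u + b_u.  The factor
R(t) = 1 - exp{-[(t - t_sp)/2 ms]^20} silences the exponential term for
about 2 ms after the latest spike t_sp, giving an effective refractory
period; we additionally refuse to register a second spike within 2 ms, so
the raster satisfies a hard 2 ms minimum inter-spike interval.  Defaults:
C = 150 pF, g_L = 10.005 nS, V_L = -70 mV, Δ_T = 2 mV, V_T = -55 mV,
τ_u = 200 ms, a_u = 4 nS, b_u = 50 pA.  Units are (pF, nS, mV, pA, ms)
throughout, so nS·mV = pA and pA/pF = mV/ms.

Two conventions deserve note.  First, writing the spike-triggered
adaptation as b_u δ(t - t_sp) inside τ_u du/dt would literally produce a
jump of b_u/τ_u = 0.25 pA, which is negligible; since b_u is given in
current units and adaptation is described as visibly suppressing firing,
we adopt the standard AdEx convention u ← u + b_u.  Second, the noise
term η is unspecified in magnitude; it is implemented as optional
zero-mean Gaussian white current (`noise_sd`, default 0).

The deterministic single neuron has rheobase θ_f ≈ 130.1 pA (the analytic
value is -g_L(V_T - V_L) + g_L Δ_T = 130.06 pA) and type-I (continuous)
rate onset.  The steady f-I curve without adaptation, measured on a
uniform 20 pA grid up to θ_f + 1840 pA (3 s per current, first second
discarded), is fitted by an origin-constrained quartic
f(x) = A x + B x² + C x³ + D x⁴ on x = I - θ_f, giving A ≈ 1.30 Hz/pA
with B < 0, C > 0, D < 0; beyond the fitting range the response is
treated as saturated.  The leading coefficient varies by under 1% for
grid spacings between 20 and 100 pA.

## Synapses

Five receptor classes mediate recurrent connections — AMPA and NMDA on
excitatory axons; fast GABA-A, slow GABA-A, and GABA-B on inhibitory
axons — each with second-order kinetics per (presynaptic neuron,
receptor) pair:

    dx/dt = (1/τ_up) Σ δ(t - τ_axon - t_sp) - x/τ_up
    ds/dt = x (1 - s) - s/τ_dn

with τ_axon = 1 ms axonal delay.  Time constants (τ_up, τ_dn) in ms:
AMPA (0.5, 4), NMDA (5.8, 87.5), GABA-A fast (1.8, 12), GABA-A slow
(1.8, 47), GABA-B (100, 500).  Reversal potentials: 0 mV (AMPA, NMDA),
-70 mV (both GABA-A), -80 mV (GABA-B); conductances 1.05, 1.05, 4.0,
4.0, 2.0 nS (the single GABA-A value applies to both fast and slow
components).  The synaptic current onto cell i of type X is

    I_syn = γ_E Σ_ψ∈exc Σ_j J^{XE}_ij g_ψ s_ψj (V_Rψ - V_i)
          + γ_I Σ_ψ∈inh Σ_k J^{XI}_ik g_ψ s_ψk (V_Rψ - V_i),

always using the postsynaptic cell's own membrane potential in the
driving force.  Each excitatory connection carries both AMPA and NMDA
with the same weight; each inhibitory connection carries all three GABA
components.  No NMDA magnesium block is modelled.

Under stationary Poisson presynaptic firing at rate f the mean gate is
commonly approximated as m(f) = τ_dn f/(1 + τ_dn f).  This is exact only
in the limit of small per-spike increments.  Here each spike injects an
x-impulse of unit integral, driving s up by ≈ 0.63·(1 - s), so x and s
are positively correlated and the true time average lies systematically
below m(f): by ~30% for AMPA, ~20% for NMDA, and a few percent for
GABA-B at high rates (verified against exact event-driven integration).
The mean-field analysis uses m(f) as its drive model regardless — it is
the closed form consistent with the averaged kinetics — but this bias is
one reason the mean-field boundary and the simulated network disagree
quantitatively (below).

## Weight ensembles

Connection weights are non-negative i.i.d. draws with mean fixed at 1 and
variance σ² from one of three families: lognormal (fully connected),
sparse-Gaussian, and sparse-lognormal (both with a point mass 1 - a at
zero, a = (π/2)/(σ² + 1), so they require σ² ≥ π/2 - 1).  E→E and E→I
blocks use variance σ_E² (the main experimental dial); I→E and I→I
blocks and the afferent weights use variance 1.  For the
sparse-lognormal family, matching the mean to 1 requires
μ = ln(1/a) - ln[a(σ² + 1)]/2; the algebraically inconsistent variant
μ = ln(1/a) - ln(σ² + 1)/2 (whose mean is √a) is available behind a
flag for comparison.  Self-connections are permitted (an O(1/N) effect).

## Network and integration

N_E excitatory and N_I = N_E/4 inhibitory neurons are all-to-all
connected through the sampled weight blocks.  Each excitatory neuron
receives an independent 10 Hz Poisson afferent train filtered through a
second-order gate (τ_up = 1 ms, τ_dn = 20 ms) and scaled by
γ_input J_input with γ_input = γ_E; inhibitory neurons receive no
afferent input.  The gated-Poisson expression
γ_input J_input s_input is dimensionless: with order-one weights and
gates it evaluates to well under 1 pA, five hundred times less than
rheobase, so without a current scale the network could never leave the
DOWN state.  A single gain constant in pA (`input_gain`) supplies that
scale.  Its default, 2000 pA, is chosen so that at the reference
coupling γ = 0.1 one afferent spike through a unit-weight synapse
transiently reaches the rheobase scale (gain ≈ θ_f/(γ·s_peak) =
130/(0.1·0.63)); this yields a quiescent DOWN state punctuated by
input-triggered UP ignitions at the ~1/s slow-oscillation rate.

All state variables advance with a shared second-order Runge-Kutta
(Heun) step, dt = 0.05 ms by default.  Spikes are delivered after the
1 ms delay, binned to the integration grid; spike times are linearly
interpolated within the step.  Because the exponential term diverges
during spike generation, every right-hand-side evaluation clamps V at
V_peak; without this, intermediate RK stages inject unphysical
mega-ampere transients into the adaptation variable.  Gating variables
evolve independently of the membrane within a step, so both RK stages of
every neuron's synaptic drive are obtained from two batched float32
matrix products with the stacked weight blocks — the computational
bottleneck.  The production integrator is a numba-compiled kernel; a
pure-numpy reference engine implements the identical scheme and the test
suite checks that the two produce the same raster over horizons short
enough that float-ordering differences have not been amplified by the
network's chaotic dynamics.  One master seed spawns independent child
streams (weights, afferent weights, afferent events, noise), so runs are
exactly reproducible and changing one stream never perturbs the others.

## Mean-field analysis of UP states

Assuming a homogeneous population firing at rate f with mean UP-state
voltage pinned at V_mean = -55 mV, the mean drive is

    I_syn(f) = γ_E N_E Σ_ψ∈exc g_ψ (V_Rψ - V_mean) m_ψ(f)
             + γ_I N_I Σ_ψ∈inh g_ψ (V_Rψ - V_mean) m_ψ(f)

(with the mean weight 1) and the mean adaptation current is
u(f) = a_u (V_mean - V_L) + b_u τ_u f.  UP states correspond to
solutions of f = F'(f) ≡ F[I_syn(f) - u(f)], with F the fitted quartic
response.  Crossings are bracketed on a grid spanning [0, the response
ceiling] and refined by bisection; a crossing is classified stable when
the iteration-map slope is below 1.  Regimes: only the trivial solution
(no UP), an unstable non-trivial crossing (transient UP), or a stable
non-trivial crossing (self-sustainable UP).  Because I_syn is linear in
network size, the critical coupling scales exactly as 1/N_E; the package
verifies γ_c·N_E constant over N_E ∈ {500, 1000, 2000, 4000}.

With the default constants this recipe places the self-sustainability
boundary (γ_E = γ_I tied, b_u = 50 pA) at γ_c ≈ 0.021 for N_E = 1000,
with the stable fixed point at several hundred Hz.  The direct
simulations are consistent with this strong-drive picture: UP episodes
are violent population bursts rather than moderate-rate plateaus, and
near-continuous UP states appear only around γ ≈ 0.2.  The recipe and
the simulations therefore agree qualitatively but not quantitatively:
the rate description, which ignores synchrony, overstates how easily the
UP state persists.  The analysis also deliberately keeps
V_mean fixed (no self-consistent voltage loop) and ignores conductance
shunting — F was measured under current injection, while the network's
synapses add tens of nS of conductance — both of which push the analytic
boundary below the simulated one.

## UP/DOWN segmentation and statistics

A neuron is UP while its 10 ms boxcar-smoothed membrane potential exceeds
-62 mV (midway between the ~-70 mV DOWN and ~-55 mV UP plateaus); DOWN
gaps shorter than 50 ms are merged and UP episodes shorter than 50 ms
discarded.  All four constants are configuration, since the detector is
an analysis choice rather than part of the dynamical model; square-wave
fixtures segment exactly (to one sample) under the defaults, and
segmentation is invariant to integer upsampling of the trace.

An UP-DOWN cycle is one UP state plus the consecutive DOWN state
(onset-to-onset); cycle durations are pooled over all excitatory neurons
and normalized by the pooled mean, so the normalized sample mean is 1 by
construction.  The population UP state holds while at least half the
excitatory neurons are individually UP; its onset rate is the
slow-oscillation frequency.  Fano factors use fixed-length count windows
aligned at each neuron's UP onsets (window = the neuron's minimum episode
duration, cappable), so counts are comparable across episodes of unequal
length and spikes outside UP states never enter; neurons need at least
five episodes and a nonzero mean count.

## Cell assemblies

The excitatory raster is binned into a rate matrix D (neurons × windows;
200 ms windows at 50 ms steps by default, i.e. rate vectors sampled at
20 Hz — an alternative non-overlapping binning is available as
step = window and the two cannot both hold at once).  NMF factorizes
D ≈ B C by multiplicative updates (Frobenius objective, provably
non-increasing per iteration) from a deterministic double-SVD
initialisation plus seeded random restarts; the order k minimises
AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n-K-1) with n the number of matrix
entries and K = k(rows + cols), a Gaussian residual model with every
factor entry counted as a parameter.  Ties break toward smaller k.  One
practical finding: with overlapping windows the Poisson counting noise is
correlated across neighbouring columns, which the independent-entry AICc
penalty under-counts, inflating the selected order; planted-assembly
recovery (order and membership, g ∈ {2, 3, 5}) is exact with
non-overlapping windows, and analyses that feed AICc use that variant.
Downstream statistics are the Pearson correlation of the selected order
(raw and normalized by total UP time) with the log mean UP duration
across conditions, and the mean pairwise Pearson correlation of the
activation time courses (rows of C).

## Synthetic fixtures

`make_fixture_raster` generates UP/DOWN square-wave-modulated Poisson
rasters with planted co-active assemblies (one assembly active per UP
window, cycling): background 0.2 Hz between windows, 2 Hz during UP, and
25 Hz for the active assembly's members by default, which puts the
assembly signal well above counting noise in 200 ms windows.  These
fixtures exercise the segmentation, Fano and NMF layers without the
simulator; they emulate rate co-activation only — no membrane dynamics,
no refractoriness, no spike-timing structure — so passing them validates
the analysis pipeline, not the network model.

## Problem sizes and tolerances

Default analyses use N_E = 1000 (N_I = 250).  The test suite and the
acceptance script use 5 s of analysed activity per sweep cell after the
2 s transient, 8-20 s for frequency and distribution measurements, and a
reduced N_E = 400 (with coupling scaled by the 1/N_E law, γ = 0.25) for
the weight-variance sweep; planted-model checks use tens of neurons.
Moment checks use standard-error bands (5 SE); Monte-Carlo gating
comparisons use 3 SE with block-resampled errors; the mean-field
bisection tolerance is 1e-4 in γ and the rheobase bisection 0.05 pA.

## Known limitations

- The afferent gain is a modelling completion (see above); only its
  scale, not its existence, is adjustable downstream.
- The stationary gating formula used by the mean-field drive is biased
  high relative to the true kinetics (up to ~30% per receptor).
- The mean-field layer has no fluctuation corrections, no finite-size
  theory, and a fixed V_mean; it is a rate description that cannot see
  the synchronous, adaptation-terminated bursts the simulation produces.
- With the default conductances the simulated UP states fire near the
  refractory ceiling; regime *structure* (silent → transient UP-DOWN at
  ~1 Hz → continuous UP) reproduces, but boundary locations and in-UP
  rates do not match a moderate-rate plateau picture.
- No thalamocortical loop, no synaptic plasticity, no clustered
  connectivity.
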