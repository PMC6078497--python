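# Methods

`gridperturb` simulates recurrent grid-cell circuit models under global
perturbations and analyzes the outcome through the distribution of relative
phase shifts (DRPS). This note records the models, the measurement
procedures, the synthetic-data conditions, and the numerical and design
choices, so that every number the tests and the acceptance script produce
can be traced to a definition.

## Network models

Three 1D architectures share the same two-excitatory-population (EL, ER) +
inhibitory (I) structure, with N_EL = N_ER = 400 and N_I = 160 by default
(inhibitory cells are one fifth of the excitatory count, as in cortex):

* **aperiodic** — local connectivity with hard boundaries; activity and
  weights are tapered by a smooth envelope `A_i` (flat within a fraction
  `kappa = 0.3` of the half-width, Gaussian taper with steepness `a0 = 30`
  outside). The population pattern period is free to change smoothly.
* **partially periodic** — the same local connectivity wrapped on a ring
  (periodicity scale `rho = 1`). The ring must accommodate an integer
  number of bumps, so the period can change only in discrete jumps.
* **fully periodic** — ring connectivity dilated by `rho = 11`: coupling
  wraps many times around the ring, the wiring itself fixes the pattern
  period, and gain or time-constant perturbations cannot move it.

Weight blocks are Gaussians in the offset coordinate `x_ij = i - gamma*j`
(`gamma` the population-size ratio), with block-specific strength `eta`,
shift `Delta`, width `sigma`, a central diagonal cut of half-width `delta`
for I→E and I→I, and one-sided Heaviside windows (direction `mu`) for I→E.
Default tables: E→I `(eta 11.5, Delta ∓2, sigma 4)`, I→E `(4, ±8, 10,
mu ∓1, delta 3)`, I→I `(12, 4, 6, delta 3)`; an E–E variant adds direct
excitatory coupling with its own tables. The Heaviside convention is
`Theta(0) = 1`. Inhibitory-source blocks are stored as non-negative
magnitudes and enter the rate-model input sum negatively; this sign
convention is required for lateral-inhibition pattern formation and makes
the inhibitory gain knob `gamma_inh` an inhibition strength in the literal
sense. Perturbations (`gamma_inh`, `tau_syn` rescaling) multiply; applying a
perturbation and its reciprocal restores the original weights exactly.

## LNP dynamics

Rates are threshold-linear in the summed input
`G = [alpha_vel (G_rec + G0) + G0'] * A` (multiplicative velocity gain
`alpha_vel = 1 + beta_vel * v·e_P`, with `e_P` rightward for ER, leftward
for EL, zero for I; an additive mode with `W_vel = 200` is available).
Biases: `G0 = 50`, `G0'_E = 15`, `G0'_I = 0`; `beta_vel = 1` (s/m);
`tau_syn = 30 ms`; Euler step `dt = 0.5 ms`.

Spiking is a sub-Poisson renewal process built by time rescaling: the
integrated rate is compared against thresholds drawn from Gamma(4, 1/4),
giving ISI CV = 1/2 at constant rate while preserving the mean rate. Spikes
increment synaptic activations `s` by 1; `s` decays with `tau_syn`. The
integration loop is numba-compiled; a run is bit-reproducible given (config,
weights, trajectory, seed).

**Trajectories.** The 1D track is 400 cm long. (200 cm was tried first; the
emergent spatial tuning period of roughly 60–100 cm then leaves barely two
periods per tuning curve and relative-phase estimates are dominated by
spectral quantization. 400 cm keeps four to six periods per curve with the
same simulation cost.) The quasi-random generator runs full-track sweeps at
per-sweep speeds drawn from U(0.15, 0.45) m/s with Ornstein–Uhlenbeck
jitter, clipped to [0.1, 0.5] m/s; sweep structure makes occupancy uniform
by construction (max/min 1 cm-bin occupancy ratio below 3 in 60 s, the
normative contract). A constant-velocity mode (position wrapping, velocity
never changing sign) supports velocity-response measurements.

## Conductance-based (CHH) dynamics

The cortical regular-spiking Hodgkin–Huxley neuron: leak, fast K (n⁴),
slow M-type K (q), and Na (m³h) currents, with the conductances and
reversals `g_L 0.1, g_K 5, g_M 0.07, g_Na 50 mS/cm²; V_L −70, V_K −90,
V_Na +50 mV`, `Cm = 1 µF/cm²`, `dt = 0.025 ms`, `tau_syn = 15 ms`,
`beta_vel = 0.8`. Gate kinetics live in one swappable module
(`chh_kinetics.py`): Traub/Miles-style Na–K rates shifted by
`V_T = −56.2 mV` and an M-current with `tau_max = 608 ms`,
`tau_x = 1/(alpha_x + beta_x)`. Synapses are conductances: the LNP weight
magnitudes scaled by 0.0015 drive currents toward 0 mV (excitatory sources)
or −80 mV (inhibitory sources). Spikes are upward 0 mV crossings.

**Bias sign.** The constant bias `I0 = 3 µA/cm²` is implemented as a
depolarizing current (it enters the synaptic current negatively under the
membrane equation's overall minus sign). Read with the opposite sign the
bias hyperpolarizes every cell and the network, which has no noise source,
stays silent forever; the depolarizing reading is the one under which the
network forms the multi-bump pattern the model is built to study, and
mirrors the role of `G0` in the rate model.

**Temperature.** Q10 factors scale conductance amplitudes by
`1.3^((T−36)/10)` and divide time constants by `3^((T−36)/10)`. The scaling
can be restricted to the ionic group (g-bars and gate taus) or the synaptic
group (weights and `tau_syn`) to dissociate their effects. In simulation the
two groups move the population period in opposite directions (ionic-only
cooling expands it, synaptic-only cooling contracts it) and full cooling
yields a net expansion. CHH rate snapshots are 10 ms spike-count bins
smoothed with a 50 ms boxcar (the snapshot construction is a measurement
choice, shared with no other component).

## Measurements

* **Tuning curves**: occupancy-normalized spike histograms, 1 cm bins,
  5-bin boxcar; unvisited bins are linearly interpolated and flagged.
* **Tuning period**: wavelength of the dominant nonzero-frequency peak of
  the curve's power spectrum (unpadded DFT; the peak frequency is refined by
  parabolic interpolation of log-power, the peak power is not).
  **Amplitude**: mean rate density over bins.
* **Population period / gridness**: each activity snapshot is restricted to
  the middle half of the population vector, normalized (mean-subtracted,
  SD-divided), and Fourier-analyzed with the spectrum rescaled by `2/L²`
  so a pure sinusoid scores exactly 1; period and peak power are averaged
  over the last 10000 snapshots. For periodic rings a separate bump-count
  measure takes the modal integer frequency over the full (unshortened)
  ring. Analysis includes all cells in periodic networks and the central
  3/4 in aperiodic ones. (With the middle-half rule, L = 200 for a
  400-cell population; both this and an L = 100 decimated variant are
  reachable through the configuration.)
* **Velocity response**: pattern translation speed under fixed velocity,
  from frame-to-frame circular cross-correlation with subpixel peak
  refinement, displacement smoothed by a 4 s moving average, mean speed over
  the middle half of the trace.
* **Relative phase (1D)**: offset of the cross-correlation peak closest to
  zero lag between two tuning curves, divided by the shared tuning period,
  wrapped to [−1/2, 1/2). Sign convention: positive means the second curve
  is shifted rightward. When a cell sample is analyzed together the shared
  period is estimated once from the aggregate power spectrum of the sample
  (cells of a module share a period); each curve must still agree with it
  within 10%. **(2D)**: the displacement of the correlogram peak closest to
  the origin is obliquely projected onto the lattice vectors and wrapped
  componentwise.
* **DRPS**: histogram (200 bins over [−1/2, 1/2]) of magnitude shifts
  `|delta_pre| − |delta_post|` (Lee-distance magnitudes; a signed-shift mode
  exists for display conventions). Smoothing is a 2-bin Gaussian applied
  circularly, which makes the periodicity score of a pure sinusoid exactly
  1. `sigma_DRPS` is the standard deviation of the shift sample. Peak
  counting uses smoothed local maxima with prominence ≥ 5% of the maximal
  bin, excluding maxima within 2 bins of zero shift; the count estimates 2M
  per dimension when `M·Delta < 1/2` (`Delta = alpha/(1+alpha)`).
* **Periodicity score**: smooth (circular 2-bin Gaussian), normalize,
  rescale the power spectrum by `2/L²`, report the maximal nonzero-frequency
  power; a zero-variance histogram scores 0 by convention.
* **Stretch-factor inference**: the branchwise transform that subtracts
  `(1+alpha)·phi_post` collapses idealized shifts onto exactly M clusters
  spaced `alpha`; candidate alphas on a 0.005-step grid are scored by
  Pearson correlation between the transformed histogram and an indicator
  comb with teeth at multiples of alpha (both lightly smoothed). An argmax
  at the grid's lower edge, or a flat correlation profile, is flagged
  inconclusive (unperturbed data degenerate to the trivial solution).
* **Bootstrap phase uncertainty**: spike positions resampled with
  replacement (100 resamples; resample size 90% of the smaller map),
  spatial maps smoothed with a 2-bin Gaussian (a smooth correlation peak
  keeps the subpixel offset well behaved at low counts), relative phase per
  resample, and the Rayleigh maximum-likelihood scale (= the fitted mode) of
  the deviation magnitudes reported. Estimates from maps with under 50
  spikes, or with many failed resamples, are flagged unreliable.

## The perturbation protocol and classifier

`run_protocol` settles the unperturbed network for 5 s and applies every
condition — baseline included — to that ongoing state. The warm start is
deliberate: the partially periodic ring is multistable in bump count, and
fresh runs can settle into different configurations at identical parameters,
which would confound pre/post phase comparisons; an experimental
perturbation likewise acts on the running circuit. Each condition is
measured over three 60 s quasi-random trajectories and the tuning curves
averaged (as for a longer recording); single-trajectory width estimates
proved erratic. Default strengths are `gamma_inh` in {1, 1.165, 1.33,
1.66}: at the default bump count (M ≈ 10) the DRPS already saturates by
1.33, so an intermediate strength is needed to see the smooth rise that
separates aperiodic from stepped behavior.

The classifier follows the experimental decision tree. An amplitude change
(> 2%) certifies the perturbation is in effect. A tuning-period change
(> 2%) separates recurrent from feedforward. Among recurrent outcomes, each
strength's DRPS is judged *narrow at zero* by its central mass (fraction of
shifts within 0.025 of zero, threshold 0.75) — the standard deviation alone
is outlier-dominated for near-delta distributions measured from finite
data. Narrow everywhere → fully periodic; narrow at weak strengths then
broad → partially periodic (step); broad everywhere with a steadily rising
width (relative rise ≥ 15%, monotone) → aperiodic. Broad-everywhere-flat is
reported inconclusive: the step may lie below the weakest tested strength.
All thresholds are keyword arguments.

## Grid-to-place reset model

Grid cells have sinusoidal spatial tuning with fixed within-module phases
and a random module-wide phase per environment; place-cell weights sum
Hebbian increments over L = 2 familiar environments; subthreshold place
activation is the linear weight-sum. Defaults (the source supplement prints
none): 4 modules with periods {30, 42, 59, 83} cm, 100 cells/module, 200
place cells, 200 cm environments. The familiar/novel comparison contrasts
each cell's field-peak activation in familiar environments against its
maximal activation across novel environments (fresh module phases, no
learning). Under these equations typical novel activation levels sit far
below familiar field peaks and interference decreases with module count,
but extreme novel maxima (maximized over position and environments) can
reach the familiar-peak range: with sinusoidal (rather than concentrated)
tuning, familiar peaks grow like M while novel maxima grow like sqrt(M)
times an extreme-value factor, so a strict quantile gap between the two
distributions would require far more modules than is realistic. The module
suite tests the properties the model does exhibit; the acceptance suite
states the strict quantile property and records its failure.

## What the synthetic data do and do not show

Idealized phase patterns (uniform stretches of a perfect lattice) isolate
the combinatorial content of the DRPS — quanta, 2M peaks, aliasing beyond
`M·Delta = 1/2` — without estimation noise; network simulations add
realistic spiking noise, drift, and boundary effects but remain 1D, with
topographically ordered cells and a noiseless velocity signal. Synthetic
periodic-Poisson spike maps for the bootstrap obey the idealized
`T^(−1/2)` information scaling; real recordings add behavioral
nonstationarity the generator does not model. Passing tests therefore
certify the method's internal logic and its robustness to sampling and
spiking noise, not performance on raw experimental data.

## Problem sizes

Module tests use reduced networks (100+100 excitatory, 40 inhibitory) where
pattern formation, not velocity integration, is at stake; velocity-response
and discrimination tests use the full 400+400+160 network. Zero-velocity
period measurements run 12 s of simulated time; protocol conditions 3 × 60 s;
CHH thermal runs use a half-size network (200+200+80) for 3 s per condition,
with directions spot-checked at full size. These sizes are the package's
defaults for its own test suite; all are parameters.
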