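# Methods

## Model definition

One neuron is advanced in fixed 1-ms steps. Per step, in this order:

1. **Decay.** Every dynamic variable is multiplied by its exact per-step
   factor 2^(−dt/λ), where λ is its half-life in ms (τ = λ/ln 2). Calcium
   decays toward its resting level `C_rest`; all other variables decay
   toward 0. Exact multipliers (rather than forward-Euler decay) make the
   half-life law hold to machine precision and keep runs bit-stable.
2. **Synaptic input.** EPSP and IPSP counts for the step are Poisson draws
   with means `I_re/1000` and `I_ratio·I_re/1000`; the voltage increment
   `e_n·e_h + i_n·i_h` is added to `V_syn`. Counts (not Bernoulli events)
   are used, so several PSPs may land in one step at high rates.
3. **Membrane potential.**
   `V = V_rest + V_syn + HAP + DAP + AHP + V_L`, with the leak
   `L = 1 − tanh((C − C_rest − D)/k_L)` and `V_L = −g_L·L`. HAP and AHP are
   stored with negative (hyperpolarising) sign, so the sum is literal.
4. **Threshold.** A spike fires if `V > V_thresh` and at least
   `refractory_ms` (3 ms) has passed since the last spike. Forced
   (antidromic) spikes bypass both tests — axonal invasion does not depend
   on somatic depolarisation — but reset the refractory clock. Membrane
   state keeps evolving during the refractory period; only emission is
   suppressed. The spike waveform itself is not modelled.
5. **Spike increments**, effective from the next step: `HAP −= k_HAP`,
   `DAP += k_DAP`, `C += k_C`, `D += k_D`, and
   `AHP −= k_AHP·max(0, C − C_AHP)` with the calcium increment applied
   first, so only fast spiking (calcium accumulated above `C_AHP`)
   substantially activates the AHP.

### The leak normalisation

`L` is the activation of the hyperpolarising K⁺ leak current. It spans the
sigmoid's range (0, 2) and is half-maximal at zero argument, i.e. at rest
(`C = C_rest`, `D = 0`) the leak contributes `−g_L` (−8.5 mV for the m1
fit) and in a deep dynorphin-dominated silence approaches `−2·g_L`. This
normalisation was fixed by validating candidate scalings against the
fitted-cell burst statistics and the matched-rate population baselines:
the halved variant (rest at `−g_L/2`, depth `g_L`) produces bursts roughly
six times too long and silences half as long, and is rejected. Note the
parameter table glosses `g_L` as the leak "maximum voltage"; under the
validated normalisation it is the resting (half-activation) magnitude,
with the full range twice that.

Mechanism: calcium (τ ≈ 3.6 s) rises with firing and suppresses the leak —
a slow depolarising afterpotential creating positive feedback that sustains
a burst plateau. Dynorphin (τ ≈ 10–15 s, small increment per spike) creeps
toward the calcium level without quite reaching equilibrium; as the margin
shrinks, ordinary rate fluctuations suffice to collapse the plateau. In the
silence, calcium decays quickly while dynorphin lingers, holding the leak
fully active until dynorphin has decayed enough for spike clusters to
restart the feedback. Bistability is emergent: there is no explicit
two-state variable.

### The AHP reading

`C_AHP` is the minimum calcium to activate the AHP. The increment is
proportional to the excess `C − C_AHP` (units of `k_AHP`: mV/nM), with the
spike's own calcium increment counted. This reading keeps the dynamics
invariant to removing the calcium unit offset (`C_rest → 0` with `C_AHP`
shifted accordingly) and recovers the fitted-cell burst statistics; the
alternative reading `k_AHP·C` gated at `C > C_AHP` halves burst durations
and is rejected.

## Parameters

Units: rates Hz, potentials mV, half-lives ms, calcium nM, dynorphin a.u.
The m1 (cell v1) defaults: `I_re` 600, `I_ratio` 1, `e_h` 2, `i_h` −2,
`λ_syn` 7.5, `k_HAP` 60, `λ_HAP` 8, `k_DAP` 0, `λ_DAP` 150, `k_AHP`
0.00012, `λ_AHP` 10000, `C_AHP` 200, `C_rest` 113, `k_C` 10, `λ_C` 2500,
`k_D` 1.68, `λ_D` 10000, `k_L` 36, `g_L` 8.5, `V_rest` −56, `V_thresh` −50.
Sets m2–m5 override the eight fitting parameters (`I_re`, `λ_HAP`,
`k_DAP`, `k_AHP`, `k_C`, `k_D`, `λ_D`, `g_L`); the same subset carries the
published heterogeneity means/SDs used for population sampling (normal
draws, invalid values resampled, fixed `I_re` and `λ_D`).

The parameters that matter most: `k_D` dominates burst duration (smaller →
much longer bursts, eventually continuous firing — the burst-duration map
is strongly convex in `k_D`); `λ_D` and `g_L` set silence duration;
`k_AHP` sets the intra-burst rate and the size of the rate peak at the
burst head; `I_re` moves the cell along the irregular → phasic →
continuous continuum.

### Dynorphin-store extension

Optional, off by default, and with release permanently available it
reduces exactly to the base model (regression-tested bit-identical). A
slow activity signal `T` (`k_T` = 1e-5 per spike, λ 500 s) sets the
replenishment rate (`k_Dstore` = 0.02/ms per unit `T`) of a releasable
store capped at `D_storecap` = 10; a spike releases one quantum and
depletes the store by `D_spike` = 0.1 only while the store exceeds the
quantum. After a simulated hypertonic injection (osmotic pressure 295 →
315 mOsmol/l with τ_O = 200 s, i.e. input 300 → 700 Hz), the store cannot
keep up with the abrupt firing increase, dynorphin accumulation stalls,
and the cell fires continuously until `T` (τ ≈ 12 min) catches up — then
phasic firing begins. The run is preceded by a ≥10-min burn-in at the
pre-injection rate so `T` and the store start at that regime's
equilibrium, since no analytic initial condition is stated. At the
pre-injection rate the m1 cell is nearly silent, so `T` starts from ~0 and
the simulated transition (first silence ~20–25 min post-injection) is
longer than the ~10-min transition seen in vivo; the qualitative contrast
with the base model (silences within ~30 s) is unambiguous.

## Spike-train analysis

A burst is a maximal run of **more than 25 spikes** with **no ISI over
1500 ms**; burst duration runs first to last spike; the intra-burst rate
of a burst with n spikes and duration d is (n−1)/d (intervals per second),
averaged across bursts. Silences are gaps between successive detected
bursts; the censored partial gaps before the first and after the last
burst are excluded. ISI histograms and hazards default to 10-ms bins over
0–500 ms; the hazard is deaths/at-risk per bin and is NaN where no
intervals survive. The exponential tail fit is ordinary least squares on
log counts (zero bins dropped, ≥3 bins required) beyond 150 ms, with r²
reported on the log scale. Burst profiles average 1-s-binned rates over
the first and last 50 s of every burst at least that long, with half-open
bins anchored at the burst's first/last spike.

## Seeding and reproducibility

All randomness flows from `numpy.random.SeedSequence`. A simulation seed
spawns two child streams (EPSP, IPSP); a population master seed expands to
per-cell integer seeds via `generate_state`. Paired intervention runs
(antidromic stimulation, the k_D-reduction experiment) reuse the same
per-cell entropy, so control and intervention see bit-identical synaptic
input — the in-silico analogue of replaying the same noise. Identical
(parameters, protocol, seed) triples give bit-identical spike trains.

## Numerical and scale choices

The stepper is a numba-compiled loop; Poisson count arrays are
pre-generated per cell. A 3000-s cell costs ~0.5 s after JIT warm-up.
State traces (V, components, C, D, L, V_L) sample every 100 ms by default.
Non-finite membrane potentials abort with the step index. Test and
acceptance problem sizes: fitted-cell statistics use 3000-s runs (three
seeds in the test suite, six in the acceptance script — the published
burst-duration SDs are ~60% of their means, so single runs of ~20–40
bursts carry ~8% sampling error on the mean); population baselines use
100 cells × 2000 s; the antagonist experiment 100 cells × 3000 s × 2; the
linearity comparison 20 cells × 500 s per input level, which already
bounds the population-rate error well below the effects asserted.

## What the synthetic experiments do and do not show

All inputs are synthetic Poisson PSP streams at fixed amplitudes; there is
no synaptic conductance model, no PSP-size variability, no correlated
input across cells, no voltage-dependent channel kinetics, and no
secretion model. Passing tests therefore demonstrate that the mechanism —
calcium-suppressed, dynorphin-restored leak under stochastic drive —
reproduces the in-vivo firing statistics and intervention responses; they
do not validate biophysical parameter values beyond that statistical
match, and real cells' responses to inputs outside the fitted range
(e.g. strongly correlated afferent volleys) are out of scope.

## Known limitations

- The m3 fit reproduces the intra-burst rate and silence duration to
  within a few percent, but its burst durations run ~50% long; the m2 and
  m4 burst means run ~10–15% long. The burst-termination rate is the
  statistic most sensitive to the leak sigmoid's exact shape, and no
  further principled constraint was available to refine it.
- Burst-count totals in the heterogeneous antagonist experiment inherit
  that sensitivity through the convex k_D → burst-duration map and vary
  strongly across heterogeneity draws (the reduced-k_D total spans roughly
  1250–1750 across seeds); the control total is stable within ~10%.
- Single-compartment, point-event spikes: the HAP's large initial
  magnitude (60 mV) is a stand-in for the unmodelled spike waveform and is
  only meaningful during the refractory window.
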