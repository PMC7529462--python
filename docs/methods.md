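# Methods

`thalburst` models how the kinetics of GABA_B-receptor-mediated inhibition
control post-inhibitory rebound bursting in thalamocortical (TC) relay
neurons and seizure-like oscillations in reticular-thalamocortical (RT-TC)
circuits. This note documents the models, the numerical choices, the
synthetic-data generators and their limits, and the design decisions taken
where the design was genuinely open.

## GABA_B IPSC waveforms

The inhibitory conductance evoked by an RT burst is

    g(t) = A (1 - e^{-t/tau_rise})^8 (w e^{-t/tau_ff} + (1-w) e^{-t/tau_fs}),

with one parameter row per pharmacological condition (control, GAT1
blockade, GAT3 blockade, dual blockade). GAT1 blockade scales the amplitude
(A 16 -> 24 nS); GAT3 and dual blockade also reshape the decay, dual
blockade slowing the dominant component to tau_fs = 2.6 s. The reversal
potential is -115 mV. A Q10 of 2.1 scales all time constants away from the
33 °C measurement temperature (identity at 33 °C, where all simulations
run). "The time constant" in the kinetics-manipulation experiments is
implemented as a single multiplicative factor applied to all three time
constants, preserving waveform shape while sweeping overall speed; the
charge-preserving variant rescales A so the trapezoidal area (0.1 ms grid
over ten slow time constants) is unchanged to 0.1 %.

Note that, because of the eighth-power rise against a fast decay, the
*effective* peak conductance is much smaller than A (control at 200 %
amplitude peaks near 4 nS, not 32 nS).

## Membrane mechanisms

Channel kinetics are frozen in `src/thalburst/data/channel_kinetics.yaml`
and transcribed from the canonical mechanism definitions the field uses for
these cells: the relay-cell T current (GHK flux, open probability m^2 h,
+2 mV screening shift, Q10 3.6/2.8 referenced to 24 °C) with a first-order
submembranal calcium shell (0.1 µm depth, 5 ms extrusion, 240 nM rest); the
resting-conductance set Ih (E = -43 mV), the fast transient K current IA
(two activation components, dual inactivation), the inward rectifier IKir
(instantaneous), and a persistent Na current INaP implemented with
instantaneous, non-inactivating activation (its slow inactivation is
negligible at the seeded density of 5.5e-6 S/cm^2); and Traub-style fast
Na/K spiking currents with the threshold parameter shifted to -65 mV for TC
somata (-55 mV for RT cells). Ionic conditions: E_K = -100 mV, E_Na =
+88 mV, [Ca]_o = 2 mM, [Ca]_i(0) = 240 nM, 33 °C. The GHK flux handles the
V = 0 singularity with a second-order series for small arguments.

At physiological potentials the T-current inactivation time constant is
roughly ten-fold slower than activation — the asymmetry that generates the
open-probability discrepancy analyzed below.

## Three-compartment TC neuron and integrator

Geometry: a cylindrical soma (length = diameter) in series with two
cylindrical dendritic compartments of equal diameter, each carrying half the
dendritic length; C_m = 0.88 µF/cm^2 and R_a = 173 Ω·cm are fixed; leak
density is uniform with reversal -70 mV. Axial coupling uses the standard
half-cylinder series-resistance formula.

The engine advances gates with analytic exponential updates toward their
steady states at the present voltage, then solves a linearized implicit
(backward-Euler) voltage update: ohmic currents contribute their exact
conductances, the GHK current its numerical slope (1 mV secant), and the
per-cell tridiagonal system is solved directly. The default step is 0.1 ms;
halving it changes rebound-peak voltage and latency by well under 1 mV/1 ms
on the reference parameter set. The scheme is first-order; an analytic
eigen-decomposition of the passive RC network (`passive.analytic_pulse_response`)
serves as an exact oracle for passive behaviour (agreement ~0.02 mV).

Protocols mirror the dynamic-clamp experiments: a 2 s somatic voltage clamp
at the holding potential (from -70 mV initial conditions) yields the holding
current; current clamp follows with that holding current, a -50 pA/10 ms
test pulse at 2.1 s, and the IPSC conductance at the soma from 3 s. A
simulation is aborted if |V| exceeds 150 mV.

## Passive-parameter estimation

Current-pulse responses are bridge-corrected (instantaneous onset jumps
detected against an Otsu split of the across-sweep initial-slope histogram,
the offset measured by extrapolating the early in-pulse charging back to the
pre-onset sample), averaged, and fitted with the two-exponential first-order
response equation (amplitudes seeded with the steady deflection, time
constants with 10 and 1 ms; amplitudes and time constants bounded to
physiological ranges so baseline wander or fast noise cannot hijack a
component). The ball-and-stick relations then give input resistance
(C0+C1)/I_p, membrane time constant tau0, the electrotonic length L from
the transcendental cot relation (bracketed bisection around pi/alpha1,
opened slightly below pi/2 to cover the compact-cell limit), the
dendritic-to-somatic conductance ratio rho, and the printed sphere-surface /
3/2-power conversions to (diam_soma, diam_dend, L_dend, g_pas). The printed
diameter formulas contain typographic ambiguity; they are resolved against
the standard textbook forms and validated by the round-trip oracle, which is
the binding contract.

Because the continuous-cable inversion is only approximate for a
three-compartment target, `PassiveModel.fit` finishes with a bounded
least-squares polish of the four parameters against the forward-simulated
response (same engine as the data, so no integrator bias). Noiseless round
trips recover the generating parameters to numerical precision across
electrotonic lengths 0.1–1.5. With realistic noise (0.3 mV OU) the somatic
response constrains *functional* quantities (total membrane conductance,
somatic diameter, leak density) well, but dendritic geometry becomes
unidentifiable for electrotonically compact cells (L below roughly 0.5);
the noisy-recovery tests therefore assert tight recovery of the functional
quantities and are run at cohort-typical lengths (the experimental cohort
mean is 0.71 space constants). Estimates for compact cells should be
treated as optimization seeds only.

## LTS and burst detection

A sweep is median-filtered (30 ms) to strip action potentials and
moving-average-filtered (30 ms; reflective padding avoids onset artifacts).
The LTS candidate is the local maximum of the doubly filtered trace with the
most negative second derivative (first differences; the first-derivative
series is smoothed 30 ms before the second difference) between the IPSC peak
(within 300 ms of onset) and 7 s after onset; ties take the earliest peak.
A population threshold can be fitted as the pdf minimum between the two
lowest-mean components of a three-Gaussian mixture of candidate second
derivatives (degenerate fits fall back to the fixed default, -2.3 V/s^2).
An accepted LTS must satisfy: prominence above the SD of the filtered
pre-IPSC baseline; second derivative below threshold; and, when spikes ride
on it, a peak after the first spike. The feature window is bounded by the
first filtered-trace local minima flanking the peak; the maximum slope is
recomputed on a re-filtered trace whose moving-average window (1–30 ms) is
chosen so the maximum within-window voltage range on the rising phase is
closest to 3 mV; riding spikes are raw-trace peaks 10 mV above the LTS
amplitude; a burst is an LTS with at least one riding spike.

## Open-probability discrepancy

d(t) = mT^2 hT - mT,inf^2 hT,inf is computed pointwise on the distal
dendritic compartment (the other compartments behave similarly), resampled
to 1 ms. Slope and concavity of log10 d use ~3 ms smoothing and central
differences. The decision point is the concavity's first rising zero
crossing; a trajectory that only saturates contributes the falling crossing
nearest the slope maximum (the inflection of log d), and a strictly concave
curve its point of maximal concavity — this tie-break keeps the point stable
under resampling while matching the closed-form sigmoid and pure-decay
cases. LTS prediction thresholds the maximum of d over the whole post-IPSC
epoch at the empirical constant 1e-2 (exposed in config, not derived).

## Nelder-Mead fitting

The total error is the weighted average of the LTS-match penalty (18 for a
missed LTS, 6 for a false one), the voltage RMSE over 0–1.8 s after IPSC
onset (targets median-filtered, candidates simulated without fast Na/K), and
relative LTS amplitude/latency/slope errors over LTS-matching traces
(components without matching traces are dropped and the weights
renormalized; unequal sweep weights switch the trace average to a weighted
root-mean-square). Feature errors are expressed as dimensionless fractions
(the source defers normalization to its implementation); the match penalty
dominates early phases by design.

The simplex operates in an unconstrained space: each parameter maps linearly
to [-1, 1], then through tan(pi u/2) to the real line (the inverse-tangent
direction stated in prose maps the wrong way; the tangent pair is the only
self-consistent reading). Densities are fitted in log10 space (they span
orders of magnitude across the cohort), geometry linearly; default bounds
are two orders of magnitude around density seeds and [0.5x, 2x] around
passive estimates. Coefficients: reflection 1, expansion 2, contraction
0.75, shrinkage 0.8; initial vertices displace one parameter by 2/3 of its
range away from the nearer bound; stopping uses the stated relative error
and parameter tolerances (0.1) with 2000-iteration/4000-evaluation caps.
Non-finite objectives (divergent simulations) are penalized, not fatal. The
published 21-iteration weight schedule is not printed; the default schedule
runs three phases emphasizing LTS match, then timing, then full trace shape,
with warm restarts from the best parameters. A cohort is ranked by total
error and members more than two standard deviations above the mean are
excluded; the rest are well-fitted.

## Networks

The RT cell is a single compartment (L = diam = 70 µm, C_m = 1 µF/cm^2)
with Traub Na/K (0.1 / 0.08 S/cm^2), the reticular T current, and leak.
Its exact densities are not reprinted in the source chain, so the package
freezes its own calibration: pbar_T = 3e-4 cm/s scaled to 2e-4 with leak
reversal -85 mV, chosen so the cell rests quiescently near -83 mV and a
0.2 nA/40 ms pulse evokes a ~12-spike burst (matching the published example
cycle). GABA_B synapses expand the IPSC waveform into 18 pure exponentials
(binomial expansion of the eighth-power rise crossed with the two decays) so
overlapping events sum linearly as state-variable increments; each event
carries 1/12 of the dynamic-clamp amplitude, restoring the template under a
typical burst. AMPA synapses are biexponential (0.5 ms rise, 5.6 ms decay,
7 nS, 0 mV). Spikes are -30 mV upward crossings with a 1 ms delay and
release probability 1.

Ring networks pair equal RT and TC layers; RT cell i inhibits TC cells
i-4..i+4 and TC cell i excites RT cells i-2..i+2 (wrapped; the only
symmetric reading of nine/five "nearest" on aligned rings); the stimulus
targets the centered fifth of the RT layer (cells 40–59 at n = 100).
Protocols sweep the TC leak reversal (-73..-60 mV, also the initial
potential), redraw RT leak from U(45, 55) µS/cm^2 and jitter TC leak ±10 %
per trial, stimulate at 3 s, and run 30 s at 0.1 ms (analyses here use
10–15 s totals; oscillation period ~0.3–0.6 s makes the three-burst
criterion insensitive to the shorter horizon).

Oscillation metrics on pooled post-stimulus spikes reuse the multiunit
algorithms with 100 ms bins and a secondary-peak-relative prominence of 0.5;
an oscillation needs at least three bursts; probabilities are taken over the
reversal x trial grid; period/OI/half-activation means are over oscillating
trials. In the synthetic cohorts, per-network summaries are computed over
*all* networks (the quiescence flag is reported alongside): restricting to
fully quiescent networks, as the slice-modelling study did for its cohort,
leaves the synthetic cohort too small for stable condition contrasts.

## Oscillation analysis of multiunit sweeps

Raw sweeps are bandpass-filtered 100–1000 Hz; per-sweep baseline slope noise
(RMS before the stimulus) and maximum slope (≥ 25 ms after it) combine into
the slice SNR r = 1 + 0.1(beta/alpha - 1) and sweep thresholds r·alpha_i;
spikes are slope local maxima above threshold outside the 25 ms artifact
window. Bursts join 10 ms histogram bins at ≥ 100 Hz (one spike per bin, the
only consistent discretization), require 60 ms minimum length, a 2 s maximum
post-stimulus start, and 2 s maximum gaps; duration runs to the last chained
burst's end. The period minimizes f(delta) = sum |p_j - q_j(delta)| over
fACF peak lags (100 ms moving average of the mean-removed binned-spike
autocorrelation, primary peak normalized to 1; peaks need 2 % prominence,
positive fACF value, and lags below the duration), scanned densely on
[2/3, 3/2] of the first peak spacing. OI = (A2 - At)/(A1 - At) with the
secondary peak the largest non-primary peak and At the minimum between.
End-of-phase values average the five of the last ten sweeps within 40 % of
the group mean, found by greedily dropping the farthest outlier (fewer than
five qualifying values fall back, flagged, to the plain mean of the last
five).

## Synthetic data: what it emulates, and what it does not

* Multiunit sweeps place stereotyped band-limited spikes (a Gaussian-windowed
  500 Hz cycle — band-limited so the detection filter does not ring) in
  bursts of 15 spikes at 6 ms spacing, recurring at the programmed period
  with 20 ms onset jitter and slow amplitude decay, on white noise; the
  drug-experiment generator applies the reported transporter-blockade effect
  sizes (duration x1.36/x1.99/x0.52, period x1.13/x1.32) with 5 % log-normal
  slice scatter, baselines drawn from 2–6 s so a doubled drug-phase duration
  stays inside the 13 s experimental ceiling. Sidecars carry the *realized*
  durations (last placed spike), since burst placement quantizes the
  programmed value by up to one period.
* Passive sweeps are forward simulations of known geometries with optional
  OU noise and bridge offsets on alternate repetitions (so the slope
  histogram contains both classes).
* Dynamic-clamp datasets run the IPSC protocol over the
  condition x scale x hold grid (defaults match the experimental 24
  waveforms x 3 holds x 5 repetitions) and add OU voltage noise
  (tau = 5 ms); LTS truth labels come from the noiseless runs.
* The model-neuron cohort jitters the reference parameter set log-uniformly
  with the cohort orderings enforced (dendritic T density above somatic;
  somatic A-type density high). Ranges were chosen so the cohort reproduces
  the qualitative study conditions — near-zero dual-blockade LTS
  probability, rising LTS probability with amplitude scale, an LTS/no-LTS
  discrepancy separation of a few orders of magnitude — while spreading
  LTS probabilities across members.

None of the generators reproduce electrode artifacts beyond bridge offsets,
spatially correlated network noise, or biological channel diversity beyond
the five modelled conductances; passing tests demonstrate algorithmic
correctness and qualitative mechanism reproduction, not quantitative
agreement with any particular slice.

## The reference neuron

`reference_neuron()` is a synthetic representative well-fitted TC cell
(32 µm soma, 6.5 µm x 500 µm dendrite, g_pas 1.5e-4 S/cm^2, dendritic
pbar_T 5e-4 cm/s, somatic gbar_A 4e-2 S/cm^2, gbar_Kir 2e-4 S/cm^2). It was
calibrated once so that, at 200 % amplitude and -70 mV hold, the GAT1- and
GAT3-blockade waveforms evoke an LTS while the dual-blockade waveform does
not (control sits near its threshold, consistent with the ~50–60 % control
LTS probability of the recorded cohort); halving the T-channel inactivation
time constant abolishes the GAT3-blockade LTS and doubling it restores the
dual-blockade LTS. Two design constraints shaped it: the steady-state
current-voltage relation must be monotone (so the slow dual-blockade decay
releases the cell quasi-statically without igniting an LTS, and the cell
does not latch into delta-like bursting under its holding current), while
the relation with inactivation frozen at a recovered value must fold (so a
fast release ignites). These constraints — not any single density — are what
make rebound selectivity possible.

## Known limitations

* The voltage integrator is first-order; quantitative spike shapes at
  0.1 ms carry percent-level error (all acceptance quantities are
  insensitive to halving the step).
* TC cells with hyperpolarized leak reversals (≤ about -70 mV) can
  delta-oscillate spontaneously in network protocols, making some synthetic
  networks non-quiescent at baseline; the per-trial quiescence flag exposes
  this, and the cohort-level analyses report it.
* Real-cohort quantities that depend on the deposited recordings (exact
  per-neuron parameter tables, the 24-of-31 quiescence count, the
  percentage effect sizes of the real slice experiments) are emulated by the
  seeded generators, not reproduced from data.
* Problem sizes in the tests and the acceptance script are scaled down
  (cohorts of 6–10 neurons, 20-cell rings, 10–15 s simulations, reduced
  trial grids) — chosen as the smallest sizes at which the condition
  contrasts are stable.
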