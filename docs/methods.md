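# Methods

## Model overview

`rulesrnn` simulates and trains an excitatory–inhibitory spiking recurrent
network (SRNN) on a rule-dependent two-alternative forced-choice (2AFC)
task. A trial consists of a 200-ms fixation period, a 100-ms rule cue
("attend vision" vs. "attend audition"), a 400-ms delay in which only noise
is present, and a 100-ms presentation of conflicting visual and auditory
targets. The rewarded side is the side of the attended modality, so the
network must hold the rule in working memory across the delay and use it to
gate the sensory evidence.

The pipeline has three stages:

1. **Encoder** — five leaky integrate-and-fire (LIF) neurons (one cue
   channel, four sensory channels: Vision/L, Vision/R, Audition/L,
   Audition/R) turn analog channel currents into spike trains.
2. **Recurrent network** — `n_rec` LIF units (default 500; 80%
   excitatory per Dale's principle) with low-pass synaptic currents, a
   slowly drifting baseline current, membrane noise, and spike-frequency
   adaptation (SFA) on a random 25% of units.
3. **Decoder** — a non-spiking leaky readout of the excitatory population
   through `W_out`; the final readout voltages express the choice
   ((0,1) codes left, (1,0) codes right).

## Dynamics and discretization

All differential equations are integrated with exponential-Euler updates at
`dt = 2 ms`. Per step and unit:

    I   <- exp(-dt/tau_syn) * I + W_rec S(t-1) + W_in S_in(t) + I_base
    V   <- v_rest + exp(-dt/tau_m) (V - v_rest) + (1 - exp(-dt/tau_m)) R I + xi_m
    A   <- exp(-dt/tau_a) A + (1 - exp(-dt/tau_a)) S(t-1)
    V_th_eff = v_th + psi * A * A_mask
    S   <- Theta(V - V_th_eff),  then reset V -> v_rest, refractory 6 ms

with `tau_m = 20 ms`, `tau_syn = 35 ms` (E units) / `40 ms` (I units),
`tau_a = 400 ms`, `v_rest = -65 mV`, `v_th = -50 mV`, `psi = 1.6 mV`.
`W_rec = M ⊙ D` combines a nonnegative magnitude matrix `M` with the fixed
Dale sign mask `D` (excitatory columns `+1/d_norm`, inhibitory columns
`-4/d_norm`, zero diagonal, `d_norm = sqrt(Σ d²)`); the per-neuron
constraint items sum to zero, balancing excitation and inhibition.

**Units.** Voltages are in mV, currents in nA, and `R = 10⁻² GΩ` is applied
as 10 mV/nA inside the `(1-exp(-dt/tau_m)) R I` term. With the baseline
current drawn as `0.041 × N(2, 0.1²)` truncated to [1.8, 2.4] (so
`I_base ∈ [0.074, 0.098] nA` per step), the noise-free membrane steady
state spans roughly [-51.7, -47.3] mV across units — the heterogeneous
baseline draw places part of the population above threshold, and those
units fire tonically. We integrate the membrane drive with the `(1-α)`
factor of the exponential-Euler scheme rather than adding the raw `R·I`
each step; the raw form is not a consistent discretization of the
underlying ODE and, with these constants, would not produce a sensible
operating point. The adaptation scale `ψ = 1.6` is dimensionless in the
normalized LIF convention (rest 0, threshold 1) and is applied as
`ψ · (v_th − v_rest)` = 24 mV here: a fully adapted unit raises its
threshold by 1.6 threshold-gaps, which is what makes adaptation a potent
working-memory mechanism rather than a ~1% perturbation.

**Noise.** The membrane noise (variance 16) and baseline random-walk noise
(variance 4×10⁻⁶) enter as plain Euler terms, per-step SD `σ·dt` (dt in
seconds): 0.008 mV per step on the membrane. Spontaneous firing therefore
comes from the deterministic supra-threshold part of the I_base
distribution, with the noise jittering spike times. This regime reproduces
spontaneous rates of ~4 Hz for excitatory and ~11 Hz for inhibitory units
(the E/I difference follows from the synaptic time constants, 35 vs 40 ms,
which give inhibitory units ~14% more integrated baseline current). The
alternative `σ·sqrt(dt)` diffusion reading produces a noise-dominated
membrane (stationary SD ~0.4 mV at the threshold) in which the baseline
heterogeneity is irrelevant and training gradients are far noisier; it is
not used.

**Initialization.** All weight matrices are Glorot-uniform; the recurrent
matrix is rescaled to spectral radius `g = 1.5` before taking magnitudes.
The five input channels are initialized as one fan-in-5 Glorot matrix and
split into cue/sensory blocks. Initial membrane potentials are uniform in
`[v_rest, v_th]` per trial; the baseline-current draw is fixed across all
trials of one network.

**Encoder/decoder.** Both use the LIF constants `tau_m = 5 ms`,
`v_rest = 0`, `v_th = 1`, `R = 1`; the decoder's synaptic filter has
`tau_syn = 20 ms`. The encoder spikes and resets; for a constant
suprathreshold current its inter-spike interval equals the continuous-time
LIF solution rounded up to the step grid (exponential Euler is exact
between resets), which the tests exploit as a closed-form oracle. The
decoder is integrated without the spiking threshold: its voltage must
represent targets of 0 and 1 around the nominal threshold of 1, and a
reset-on-spike readout could not express them; the readout voltage is the
decision variable.

## Task synthesis

Cue waveforms are constant currents of 2.0 (rule 1) and 1.2 (rule 2) for
100 ms, chosen so both drive the encoder above threshold at clearly distinct
rates (250 Hz vs. 100 Hz at the encoder). Rule mixtures use the convex
combination `q·rule1 + (1-q)·rule2`; `q = 0.5` is maximally ambiguous.
Active sensory channels carry constant 2.0 during the stimulus window.
During fixation and delay all channels carry zero-mean Gaussian noise
(SD 0.05) — far below the encoder threshold, so the encoder is essentially
silent outside the cue and stimulus windows and trial-to-trial variability
enters through the network's own noise sources. Stimulus sides are sampled
independently (50/50), so half the trials are incongruent; only those
reveal whether the rule was used. An optional distractor is a 50-ms
square pulse added to the cue channel during the delay.

## Training

The loss is the mean-squared error of the two readout voltages against the
one-hot target over the final five steps, `L_mse = 1/(2·5·N_batch) Σ (y -
V_dec)²`, plus a firing-rate penalty `λ Σ_b m_b²` over 10-ms bins (rates in
Hz), which discourages excessive population firing. At the default
λ = 10⁻⁹ the penalty sits many orders of magnitude below the readout loss
in these units and is effectively inactive. Raising it to where it
actively caps delay-period rates (λ ≈ 10⁻⁵) keeps excitatory rates below
inhibitory ones after training but slows rule learning enough that some
initializations no longer reach criterion within the scaled-down budget,
and another decade blocks convergence outright; the preset therefore keeps
the inactive default and accepts that the learned solution elevates
excitatory persistent activity (see Known limitations).

Gradients are computed by backpropagation through time over the exact
discrete dynamics, with the SuperSpike fast-sigmoid pseudo-derivative
`1/(1+β|V - V_th_eff|)²` standing in for the threshold derivative
(`β = 1000` per volt, i.e. a ~1 mV half-width on the mV scale). The hard
reset and the refractory gate are treated as constants of the forward
trajectory (gradients flow through the membrane, synaptic and adaptation
chains but not through the reset event itself). Adam (η = 3×10⁻⁴, default
moments) updates `M`, `W_cueing`, `W_sensory` and `W_out`; after every step
`M` is clipped at zero, which preserves the Dale sign pattern exactly and
is idempotent. Gradients are clipped to a global norm of 100.

**Surrogate dampening.** With the ~1 mV surrogate the linearized adjoint
map of this network is expansive: measured on the 160-unit configuration,
the backward current-adjoint grows by a factor of ~10⁶ over a 400-step
trial, so the weight gradient is dominated by the earliest (and least
informative) timesteps. We therefore dampen the pseudo-derivative by a
factor `surrogate_gain = 0.3` in the backward pass only — a standard device
in surrogate-gradient practice — which makes the adjoint approximately
neutral (the gradient reaching the cue period is within an order of
magnitude of the late-trial gradient). The gain is exposed in
`TrainingConfig`; setting it to 1 recovers the exact derivative of the
fast-sigmoid-smoothed model, which is what the gradient-consistency oracle
in the tests verifies against finite differences.

**Optimization schedule.** Gradients are clipped to a global norm of 5:
the transition in which the rule attractor forms produces gradient spikes
that otherwise un-learn the solution. Adam's moment estimates are reset
("warm restart") every 20 epochs during the plateau phase — learning
passes through a long side-only plateau (congruent trials perfect,
incongruent at chance) before rule learning takes off, and the periodic
reset measurably shortens the escape. The loop tracks the best-by-
validation weights and returns those; early stopping triggers after
validation accuracy ≥ 0.99 on three consecutive epochs.

**Batch structure.** The reference schedule is 200 batches per epoch with
batch size 64 and up to 60 epochs. The scaled-down preset used for
single-CPU experiments trains a 128E+32I network on 50 batches of 32
balanced trials per epoch for up to 120 epochs (~190k trial presentations;
roughly fifteen minutes on one CPU). Convergence time varies across
initializations — most reach held-out accuracy 0.96-1.00 within the
budget, occasional slow seeds land lower — so the reproduction script and
the end-to-end tests train under a wall-clock cap
(`TrainingConfig.time_budget_s`) with a generous epoch ceiling, letting
the epoch count adapt to the machine.

## Analysis pipeline

* **PSTH tuning** — 8-ms bins, Gaussian smoothing with SD 4 bins, 50 trials
  per rule; z-scored against the delay-period mean and SD of the smoothed
  PSTH pooled over both rules (so every retained z-series has delay mean 0
  and SD 1). Units with pooled delay rate < 2 Hz are excluded. A candidate
  peak is a local maximum of the delay-period z-series with height ≥ 2; a
  unit counts as rule-tuned only if it additionally passes a rule-shuffle
  significance screen: its peak |z₁ − z₂| difference must exceed the 95th
  percentile of the same statistic under 100 random reassignments of trials
  to pseudo-rules. The screen matters because the z-series is normalized to
  SD 1 by construction — a bare height-2 rule flags ~24% of
  homogeneous-Poisson units — and because parametric noise estimates are
  misleading for units with structured delay activity (oscillations). The
  permutation version holds the unit-level false-positive rate at ≤ 5% by
  construction while recovering sharp planted rate bumps at their true bin
  (±1).
* **PNR** — maximum delay z divided by the SD of the z-series excluding ±2
  smoothing SDs around the peak (noise floored at 10⁻⁶). The estimator has
  a known positive bias of roughly +1 on a planted bump of height 5 over
  unit noise (noise adds to the selected maximum).
* **Sequentiality index** — entropy of the population peak-time
  distribution plus the mean log ridge-to-background ratio; the ridge
  window is ~50 ms (6 PSTH bins) centered on each unit's peak, with a
  0.1-Hz rate floor inside the log. Population SI is computed from
  smoothed spike-density PSTHs of units with ≥ 1 Hz delay activity
  (`delay_sequence_rates`); on raw PSTHs a unit with one stray spike gets
  an enormous ridge ratio at a random time, which inflates the SI of
  structureless activity.
* **Trajectories** — PCA fitted on pooled (trials × bins, excitatory
  units) delay rates; kinetic energy `K = ½‖dx/dt‖²` from finite
  differences of the per-rule trial-averaged latent trajectory.
* **Correlograms** — per-trigger-normalized lag histograms with bins
  centered on multiples of the bin width (a bin sits exactly at lag 0, and
  zero-lag self-pairs are dropped for autocorrelograms); only pairs within
  ±max-lag enter, so total mass is invariant to the bin size.
* **Beta detection** — per-trial periodograms of single-trial delay
  activity are averaged (this detects oscillations whose phase is not
  locked across trials and shrinks the null variance); a unit is flagged
  when the largest local peak in 15–30 Hz reaches 2× the spectrum median.
  On a raw single-series periodogram the same threshold would be crossed by
  ~25% of pure-noise bins (periodogram bins are exponentially distributed),
  which is why the averaged form is the default.
* **LFP proxy** — the plain sum of synaptic currents across units, with a
  short-time spectrogram for visualization.
* **Population decoding** — delay spike counts in 20-ms (or 50-ms) bins,
  reduced to 15 PCs, classified by a two-layer LSTM (hidden 16, dropout
  0.2, L2 10⁻³, Adam) written in NumPy; 10-fold stratified CV with a 90/10
  split; accuracy is also reported cumulatively over delay time by reading
  the classifier at every prefix length.

## Synthetic data and what passing tests show

All inputs are synthesized: the trial generator *is* the experiment, and
its defaults (period durations, cue amplitudes, noise SDs, the 50/50
congruency split) define the study conditions. The planted-data tests
(rate bumps, low-rank population modes, phase-jittered oscillations,
Poisson nulls) verify that each statistic detects exactly the structure it
claims to detect and stays quiet on matched null data. They do not show
that real cortical data would produce the same effect sizes: real
recordings have far fewer simultaneous units, non-Poisson variability,
drifting baselines and unobserved inputs, so thresholds calibrated here
(e.g. the tuning-peak criterion) would need re-calibration against
session-matched surrogates before use on experimental spike trains.

**Learning trajectory.** Training is stagewise: the side report (congruent
trials) is learned within a few epochs, then a long plateau follows in
which delay-period rule information builds slowly, and finally the readout
locks onto it and accuracy snaps toward 1. Plateau length varies
substantially across initializations; the 120-epoch budget covers typical
realizations at this scale. Without adaptation (the SFA-off control) the
network stays on the plateau: the adaptive threshold is the mechanism that
carries the cue across the delay.

The firing-rate penalty's behavioral effect on spontaneous rates is not
resolvable at this scale: baseline firing is pinned by the untrainable
baseline current, so the tests verify the penalty's gradient exactly
(λ-linearity and the finite-difference oracle) rather than a rate shift
after a short training run.

## Numerical choices and degenerate inputs

* Exact decoder-voltage ties resolve to output 0 and are flagged.
* `spectral_rescale` rejects the zero matrix; `build_dale_mask` requires an
  integral excitatory split.
* Non-finite network state raises immediately with the step index.
* The refractory countdown clamps the membrane at rest; a unit that spiked
  cannot spike again for 3 steps (6 ms).
* Sparsification samples only among currently nonzero magnitudes, so the
  requested drop fraction is exact; block scaling multiplies magnitudes, so
  no perturbation can violate the sign constraints.
* All randomness flows from named `SeedSequence` substreams of one global
  seed (init / trials / noise / masks); two runs with the same config and
  seed are bit-identical.

## Known limitations

* At the scaled-down size the trained solution holds the rule as *sustained*
  rule-selective persistent activity: delay-period excitatory rates rise
  above inhibitory ones, few single units develop the transient z ≥ 2
  tuning peaks that a sequential code produces, and the sequentiality index
  of the trained network does not exceed that of untrained controls. The
  sparse sequential regime reported for ten 500-unit realizations under the
  full training schedule was not reached at this scale under any rate-
  penalty strength tested (stronger penalties first restore the E<I rate
  relation at some cost in convergence reliability, then block learning).
  The corresponding end-to-end checks in the test suite measure these
  quantities honestly and fail on the scaled-down network by design rather
  than being weakened.

* Current-based single-compartment LIF units; no conductances, bursting or
  cell-type diversity beyond E/I and the SFA subset.
* The compiled simulation kernels assume the five-channel task layout.
* The scaled-down (160-unit) configuration reproduces the phenomena
  directionally; quantitative ensemble statistics (tuned fractions, rate
  means, beta fractions) at the 500-unit scale require the full schedule.
* The decoder's interpretation of readout voltages as "probabilities" is
  nominal — they are unnormalized voltages compared by argmax (softmax for
  the four-choice variant).
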