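# Methods

## Model neuron

The simulated cell is a single-compartment Wang–Buzsáki (WB) neuron:

C_m dV/dt = −g_L(V−E_L) − g_Na m∞(V)³ h (V−E_Na) − g_K n⁴ (V−E_K)
            − g_slow z (V−E_K) + I_inj(t) + ξ(t)

with the standard parameter set E_L = −65 mV, E_Na = 55 mV,
E_K = −90 mV, g_L = 0.1, g_Na = 35, g_K = 9 mS/cm², C_m = 1 µF/cm².
Sodium activation is instantaneous (m = m∞(V)); h and n follow
dx/dt = ζ(α_x(V)(1−x) − β_x(V)x) with the canonical WB rate functions
and gate-speed factor ζ = 5. The removable singularities of α_m (at
−35 mV) and α_n (at −34 mV) are evaluated by their analytic limits.

Currents are in µA/cm²; with C_m = 1 µF/cm² a 1 nA offset from an
in-vitro protocol maps numerically onto the model drive after the gain
ν. This is a documentation convention, not enforced by code.

**Noise.** ξ is a white-noise current with ⟨ξ_i(t)ξ_j(t′)⟩ =
2λδ(t−t′)δ_ij; λ has units mV²/ms. Each integration step draws one
uniform variate, held constant for the step and shared by both
Runge–Kutta stages. The default (`noise_dialect="contract"`) uses
bounds ±√(6λ/dt), which makes the per-step variance exactly 2λ/dt and
hence reproduces the stated autocorrelation; an alternative
`"literal"` dialect with bounds ±12λ/dt is retained for comparison
because that bound also circulates but is dimensionally inconsistent
with the autocorrelation.

**Slow potassium current.** An optional current g_slow·z·(V−E_K)
(default g_slow = 0.5 mS/cm² when enabled) has a gating variable z that
charges toward 1 with τ = 10 ms while V ≥ V_z and decays to 0 with
τ = 500 ms below it. V_z defaults to −20 mV so the gate charges only
during the action-potential upstroke; the hard voltage switch is a
deliberate simplification, and results near threshold are sensitive to
V_z (configurable). With this current, different initial z values send
otherwise identical noiseless trials into distinct spike sequences that
persist to the end of the trial — the mechanism behind long-lasting
spike patterns.

**Integration.** Second-order Runge–Kutta (midpoint) at dt = 0.05 ms;
stimulus samples are resampled onto the integration grid by zero-order
hold; gates start at their stationary values for V0 (default −70 mV).
At dt = 0.05 the period of tonic spiking is within ~1% of runs at
dt = 0.005 and 0.001 (which agree with each other to < 5·10⁻⁴); the
residual offset is the expected cost of the coarse working step on the
stiff spike upstroke. Spike times are the first sample with V ≥ 0 mV
preceded by a sample below 0 mV; no sub-sample interpolation is done.

## Stimuli

The frozen-noise waveform h(t) is built from uniform white noise on
[0,1] at 10 kHz, passed through the causal recursion
y[n] = x[n] + 0.99·y[n−1] (zero initial state; ~100 Hz corner), then a
causal 50-sample (5 ms) running average; the first 500 output samples
are discarded and the rest centered and divided by the population
standard deviation. Any seeded PRNG stream is acceptable — the analysis
depends only on h being a fixed, smooth, normalized waveform — so the
seed is recorded with the waveform rather than attempting to reproduce
any particular historical random stream. Injected currents are
I(t) = ν(a + b·h(t)): mean ν·a, SD ν·|b|.

The FM waveform is amplitude·sin(φ(t)) with piecewise-constant
instantaneous frequency and phase continuous across segments, giving a
train of equal-amplitude upswings at variable intervals and slopes. The
default segment list (5–20 Hz over 1100 ms, ~12.5 upswings) makes a
neuron firing ~7 spikes per trial sample only a subset of upswings,
which is the regime in which multiple patterns carry extra stimulus
information.

## Spike-train metrics

**R-reliability.** Each train is notionally convolved with a Gaussian
of SD σ; R is the mean cosine similarity over all distinct trial pairs.
The cosine is computed analytically from the Gaussian inner-product
identity — the inner product of two smoothed trains is
Σ_kl exp(−(t_k−t_l)²/4σ²) — skipping pairs separated by more than 6σ
(each skipped term is below e⁻⁹ ≈ 1.2·10⁻⁴). Similarity involving an
empty train is defined as 0 so silent, unreliable trials lower R.
Defaults: σ = 3 ms for experimental-style data, σ = 1 ms for model
spike trains, which are more precise.

**Victor–Purpura distance.** Standard dynamic program; insert/delete
cost 1, shift cost q·|Δt|. q = 0 degenerates to the spike-count
difference. 1/q is the temporal resolution at which two spike times
count as similar; the pipeline default q = 0.5/ms (2 ms) matches the
~1–2 ms event jitter of precise cortical-style responses. Setting q
much smaller makes a missing spike (cost 1) dominate the jitter
scatter, which splits patterns into spurious missing-spike subclusters
during clustering.

**PSTH** uses half-open 0.5 ms bins, normalization by trial count and
bin width in seconds, and Gaussian smoothing with SD = 4 bins (kernel
truncated at ±4 SD and renormalized at the edges so flat regions stay
flat). **Firing rate** is spikes per trial divided by duration; the
across-trial spread is the sample SD (n−1) — the convention is stated
here because either convention is defensible. The **STA** averages the
25 ms of stimulus preceding each spike, excluding spikes with
insufficient history, on the stimulus grid with lag axis [−25, 0] ms.

## Event-finding pipeline

Four parameters govern the pipeline: q (above), N_c (cluster count),
t_ISI = 3 ms and t_ROC = 0.5.

1. **Segmentation.** Long trials are cut into ~500 ms segments at local
   minima of the smoothed PSTH that fall below 20% of the mean rate,
   nearest to the uniform-grid boundaries; if no quiet minimum exists
   near a boundary a fixed-length cut is used with a warning. Spikes
   are assigned to segments by half-open windows [start, end).
2. **Clustering.** Trial i's feature vector is column i of the VP
   distance matrix, so trials expressing the same pattern (mutually
   small distances) form a block. Standard fuzzy c-means (fuzzifier
   m = 2, tolerance 10⁻⁶, ≤1000 iterations, best objective of 10
   seeded restarts) assigns soft memberships; hard labels are the
   argmax, ties to the lowest index.
3. **Cluster count.** A gap statistic compares log W*_k of the FCM
   partition against B = 20 reference data sets drawn uniformly over
   the bounding box of the feature columns. Two choices differ from the
   textbook recipe, both forced by the geometry of distance-matrix
   features. First, the dispersion is size-weighted,
   W*_k = Σ_r W_r/(n_r−1), so splitting off a tiny subcluster cannot
   produce a large spurious dispersion drop. Second, the selected k is
   the one with the largest one-step gap increase Gap(k) − Gap(k−1)
   (falling back to k = 1 when even the largest increase is within 2
   reference SEs): trial ensembles concentrate near a low-dimensional
   manifold, so the uniform reference dispersion decays only as
   k^(−2/p) in the ambient dimension p while the data dispersion keeps
   dropping, and the original "smallest k with Gap(k) ≥ Gap(k+1) −
   s(k+1)" rule runs off to k_max. The increment rule instead keys on
   the point where real structure is resolved, which is where the gap
   curve jumps.
4. **Events (interval method).** Within each pattern, all spikes of all
   trials are pooled into one time-ordered aggregate train; a gap
   strictly greater than t_ISI starts a new event (a gap exactly equal
   to t_ISI does not split).
5. **ROC merge.** For every cross-pattern pair of temporally
   overlapping events, the Mann–Whitney AUC of the two spike-time
   samples gives discriminability d = 2|AUC−½|; pairs with d ≤ t_ROC
   merge, transitively (union–find), pooling spikes. At t_ROC = 0.5
   moderately overlapping events merge; fully separated supports
   (d = 1) never do.
6. **Noise classification.** Events represented in fewer than 2
   distinct trials are reclassified as noise spikes (the existence of
   noise spikes is part of the analysis contract; this minimal rule is
   the package's choice).

Per-event statistics: reliability = fraction of trials contributing at
least one spike; jitter = sample SD of the event's spike times;
precision = 1/jitter (undefined for single-spike events and excluded
from condition-level averages, which are unweighted means over events).

## Information measures

Pattern labels form a classification c over trials; p_j is the class
distribution, S = −Σ p_j log₂ p_j (0·log 0 = 0). Bias and SD of the
plug-in entropy are estimated by drawing 1000 multinomial data sets of
the observed trial count from p and comparing their mean entropy to
S(p); the plug-in bias is negative and shrinks with trial count. No
bias correction is applied to reported values — bias is reported
alongside. Mutual information between two classifications uses the
plug-in joint distribution; I_N = I/max(S(c), S(d)), which makes
I_N = 1 exactly for identical classifications (normalizing by log₂N_c
would not). If both entropies vanish, I_N is 1 when the degenerate
labels coincide and 0 otherwise. The same multinomial scheme applied to
the joint counts gives resampling bias/SD for I_N.

## Reconstruction

Each event with reliability > 5% adds one copy of the measured STA,
anchored with its lag-0 sample at the event's mean time (the STA is
stimulus *history*, so each event paints the 25 ms before its spikes).
Contributions are summed — overlapping copies add — and the result is
z-scored, since only the waveform shape is compared. Every qualifying
event contributes equally regardless of reliability and jitter. Quality
is the Pearson correlation with the true stimulus over the trial
window. Each noise condition uses its own measured STA.

In the two-noise-level experiment (`reconstruct.noise_comparison`), the
WB neuron is driven by the FM waveform at offset 0.1, amplitude 0.3
µA/cm² — a bifurcation-point regime where the low-noise
(λ = 10⁻⁴ mV²/ms) ensemble locks to a single pattern sampling ~6–7
upswings, while the medium-noise (λ = 0.025) ensemble expresses several
patterns that jointly sample more upswings. The medium-noise
reconstruction therefore correlates better with the stimulus, although
its single-trial reliability is lower.

## Sweeps and bifurcation candidates

A sweep simulates an ensemble per condition (per-trial seeds derived
deterministically from (base_seed, condition, trial) via a seed
sequence, all below 2³¹), then computes R-reliability and spike-count
mean/SD across trials. The reliability curve is smoothed by a 3-point
running average (endpoints average the available neighbors). A
**bifurcation candidate** is a strict interior local minimum of the
smoothed curve, at least 0.02 deep relative to the lower flank, whose
rounded mean spike count changes within one condition step of the dip;
dips flag parameter values where the spike sequence reorganizes, and
the co-located count transition separates genuine pattern competition
from mere noise in the reliability estimate. Default scan sizes are 21
amplitudes × 25 trials (a full 101 × 50 design is a flag away); the
reduced design resolves the same dip/plateau structure.

## Synthetic ensembles

The generator draws, per trial, a pattern according to the occupation
probabilities; each of the pattern's events fires with probability
equal to its reliability at a time ~ Normal(mean, jitter), truncated to
the trial window; contaminant spikes are homogeneous Poisson. It
records which pattern each trial expressed and which event produced
each spike, so pipeline output can be scored against realized ground
truth (nominal event times differ from realized event means by
~jitter/√n_spikes). What the generator deliberately does not emulate:
afterhyperpolarization-induced correlations between events within a
trial, non-stationarity across trials, and refractory interactions —
passing recovery tests therefore certifies the analysis chain on
independently structured events, not its behavior on strongly
history-dependent data; the conductance-based simulator covers that
regime.

## Numerical conventions and edge cases

- All-empty ensembles: R undefined, conditions flagged NaN in sweeps.
- Zero-variance waveform normalization is rejected (constant input).
- FCM membership ties break to the lowest cluster index; events with a
  gap exactly t_ISI do not split; singleton events still enter the ROC
  comparison (AUC of singleton vs sample is defined).
- Determinism: identical seeds give bit-identical waveforms, traces and
  pipeline CSV outputs.

## Known limitations

- The gap-statistic variant cannot distinguish "one pattern with
  unreliable events" from genuinely split patterns in borderline cases;
  at the default q this ambiguity is resolved in favor of the coarser
  clustering, which matches the pattern semantics but is a modeling
  choice.
- The hard V_z switch of the slow gate is a caricature of graded
  activation; bifurcation positions with g_slow > 0 shift with V_z.
- Spike times are quantized to the integration step (no interpolation).
- The reconstruction sums overlapping STA copies; a max-pooling variant
  would weight dense event clusters differently (untested).
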