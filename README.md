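# spikebifurc

Tools for studying **spike-time bifurcations**: how the spike trains of a
neuron driven by a repeated ("frozen") fluctuating current reorganize
discretely as the stimulus amplitude or DC offset is varied, and what
that reorganization means for how an ensemble of similar neurons encodes
the stimulus.

The package is aimed at computational neuroscientists analyzing
trial-ensemble spike data (repeated somatic current injection in vitro,
or simulated conductance-based neurons). It provides:

- a **Wang–Buzsáki model neuron** (fast Na⁺ with instantaneous
  activation m = m∞(V), delayed-rectifier K⁺, leak; optional slow
  spike-activated K⁺ current) integrated with second-order Runge–Kutta
  at dt = 0.05 ms, with a per-trial white-noise current of intensity λ
  (⟨ξ(t)ξ(t′)⟩ = 2λδ(t−t′));
- **frozen-noise and FM stimulus generators**, scaled as
  I(t) = ν(a + b·h(t)) with h normalized to zero mean and unit variance;
- **spike-train metrics**: the Schreiber R-reliability (mean pairwise
  cosine similarity of Gaussian-smoothed trains at timescale σ,
  evaluated analytically via Σ exp(−Δt²/4σ²)), the Victor–Purpura (VP)
  edit distance (insert/delete cost 1, shift cost q·|Δt|), PSTH, firing
  rate and spike-triggered average (STA);
- the **event-finding pipeline**: fuzzy c-means clustering of trials
  into spike patterns on the columns of the VP distance matrix, cluster
  count chosen by a weighted gap statistic, per-pattern event detection
  with the interval method (aggregate inter-spike gap > t_ISI starts a
  new event), and ROC-based merging of events common to several
  patterns (Mann–Whitney discriminability d = 2|AUC−½| ≤ t_ROC);
- **pattern statistics**: per-event reliability/jitter/precision,
  pattern occupations, entropy S = −Σ pⱼ log₂ pⱼ with multinomial
  resampling bias/SD, and normalized mutual information
  I_N = I(c,d)/max(S(c), S(d)) between classifications;
- **event-based stimulus reconstruction**: each event with reliability
  above 5% paints one copy of the STA at its mean time;
- **amplitude/offset sweeps** that compute reliability and spike-count
  curves and flag bifurcation candidates — reliability dips that
  co-locate with transitions between spike-count plateaus;
- a **synthetic ensemble generator** with known pattern/event ground
  truth for validating every analysis stage.

## Worked example

Generate a two-pattern synthetic ensemble (events at 50/150/250 ms and
80/180/280 ms, 1 ms jitter, reliability 0.9, 40 trials), then recover
its structure:

```
$ spikebifurc synth --spec patterns.yaml --out synth.csv
wrote synth.csv
$ spikebifurc analyze --spikes synth.csv --duration 400 --out-dir ana
2 patterns, 6 events -> ana
$ spikebifurc info --labels ana/labels.csv
S = 0.9982 bits over 40 trials
$ head -4 ana/events.csv
event_id,mean_time,n_spikes,reliability,jitter,precision
0,49.92531056598843,20,0.5,1.0771739725723515,0.9283551454663765
1,80.04200139126658,18,0.45,0.951726792611532,1.0507217068629608
2,149.57008977802508,17,0.425,0.5265101963162692,1.8992984504317376
```

The pipeline finds the two designed patterns (entropy ≈ 1 bit: the two
patterns occur about equally often) and six events whose mean times,
reliabilities (≈ 0.9 × the 0.5 occupation of each pattern) and jitters
(≈ 1 ms) match the generator's ground truth.

The same `analyze` command works on simulated ensembles
(`spikebifurc simulate`) or on any CSV of (trial, condition_id, t_ms)
rows. `spikebifurc scan` sweeps the stimulus amplitude of the model
neuron and reports bifurcation candidates; `spikebifurc run` executes a
configured end-to-end pipeline with a manifest.

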