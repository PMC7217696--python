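# Methods

## Network construction

Neurons occupy a `side × side` open grid (default 50, i.e. 2500 neurons),
75% excitatory. Inhibitory neurons are placed with Mitchell's best-candidate
algorithm (k = 10 uniform candidates per point; the candidate farthest from
all placed points wins), which yields a blue-noise spatial distribution and
avoids chance clusters of one type; the remaining cells are excitatory.
Neuron ids enumerate the grid row-major, coordinates are 0-based (row, col).

Connectivity is local and distance-dependent: within Euclidean distance
≤ 4 (the neuron itself excluded, no toroidal wrap), each ordered
(pre, post) pair is connected independently with probability
`min(α e^(−r), 1)`. α is solved per presynaptic neuron so that the expected
connected fraction of its own neighbourhood equals CE (excitatory pre) or
CI (inhibitory pre), in percent. Border neurons have smaller neighbourhoods
and get their own α. The solve uses Nelder–Mead on the absolute residual,
initialized at the unsaturated closed form `target·|J| / Σ e^(−r_j)` with
tolerance 1e-6, polished with the exact root of the active linear piece
(the residual is piecewise linear in α). Solutions are cached by the
(distance multiset, target) key — interior neurons share one neighbourhood
shape, so a 2500-neuron build performs only a few dozen solves. When no
root exists (very high targets on saturated border neighbourhoods) the
minimizing α is accepted and the residual recorded per neuron.

Edge weights depend only on the (pre, post) type pair:
W_EE = W_IE = 0.0085, W_EI = −0.569, W_II = −2 (first index = post,
second = pre). Connections are made to neighbours of both types.

## Dynamics

Probabilistic integrate-and-fire with dt = 1 ms, updated synchronously in
the order: input integration → activation → spike draw → reset. Spikes take
effect on their targets at the next step. Constants: τ_I = 9 ms shared;
excitatory τ_P = 6 ms, A_0 = 10⁻⁶, A_r = −2; inhibitory τ_P = 12 ms,
A_0 = 0, A_r = −20. The spike probability is the activation clamped to
[0, 1]; the activation itself is not clamped in state. A_0 gives excitatory
neurons a ~10⁻⁶/ms spontaneous rate that seeds recurrent activity.

Stimulation injects `w_input × input_multiplier` (default 0.0085 × 1, the
excitatory-excitatory weight) into the synaptic input of a fixed random
subset of n excitatory neurons for exactly one step, before that step's
input decay. The subset is drawn once per run; stimulus times recur at
intervals drawn uniformly (integer ms) from 500–1500 ms. Dynamics noise and
stimulus bookkeeping use two independent child streams of the run seed, so
the stimulus placement is reproducible independently of the spiking draws.
Runs are bitwise reproducible given (network, protocol, seed).

Each run starts from a silent state (I = A = 0). The network takes tens of
seconds to reach stationary activity, so unstimulated analyses discard a
50 s startup transient by default; at the production scale of 2000 s runs
this is negligible, at the 100–200 s runs used throughout the tests it is
material.

## Network signal and spectra

The analysis signal is the per-millisecond total spike count plus Gaussian
white noise (σ = 3 spikes) — the noise guarantees a defined, time-varying
phase during silent periods. The raw, noise-free count series is kept for
avalanche analysis. Spectra use Welch's method (Hamming window, 2¹¹-point
segments, 50% overlap; overlap is our choice, a standard default).

Two peak-frequency estimators are provided. `peak_frequency` is the raw PSD
argmax within a stated band. Near criticality the signal carries scale-free
slow fluctuations whose low-frequency power exceeds the 8–16 Hz oscillation
bump, so the raw argmax within 1–30 Hz lands on the lowest bins regardless
of the oscillation. `oscillation_peak_frequency` therefore separates the
aperiodic background first — a quadratic fit in log-log coordinates over
1–45 Hz with the 6–18 Hz region (oscillation band plus shoulders) excluded,
which captures both the steep low-frequency slope and the flat noise
floor — and returns the frequency of the largest positive residual: the
standard periodic/aperiodic decomposition used for oscillation peaks on
1/f backgrounds. At CE = 60/CI = 75 this yields 9–11 Hz across seeds; for
strongly oscillating supercritical networks both estimators agree.

## Phase and amplitude

Band-pass 8–16 Hz with a one-way causal linear-phase FIR filter (windowed
sinc, Hamming, order 250): output at time t never depends on samples after
t, so pre-stimulus phase and amplitude are uncontaminated by the response.
The cost is a constant group delay of 125 samples (125 ms at 1 kHz), which
is deliberately not compensated — post-stimulus latencies (e.g. the 150 ms
analysis point) are quoted on the delayed timeline, and the −5 ms
pre-stimulus phase is read off the filtered signal literally. Instantaneous
phase ((−π, π], cosine convention) and amplitude come from the Hilbert
transform computed over the full run and then epoched, avoiding per-trial
edge artifacts; the analytic stage is global, the causality contract
applies to the filter stage.

## Criticality metrics

**Avalanches.** Threshold = half the median of the raw count series over
all time steps; an avalanche is a maximal run of steps strictly above
threshold; size = summed counts, duration = run length. The same rule is
used for sizes and durations; edge-truncated runs are kept.

**κ index.** κ = 1 + mean(P − A) over 10 log-spaced points between the
observed minimum and maximum, where P is the CDF of a continuous truncated
power law (exponent −1.5 for sizes, −2.0 for durations) normalized over the
observed support and A the empirical CDF. κ < 1 subcritical, > 1
supercritical. κ is invariant under rescaling all sizes (the evaluation
grid shifts with the support).

**DFA.** Cumulative sum of the mean-removed envelope; windows of 20
log-spaced sizes spanning 0.1–55 s (clipped to half the signal), 50%
overlap; least-squares linear detrend per window; F(t) = pooled RMS
residual; exponent = slope of log₁₀F vs log₁₀t over the fit range. The
full-scale fit range is 2–50 s (appropriate for 2000 s runs, respecting the
rule that the largest window stay within 10% of the signal); the scaled
default for the 100–200 s runs used here is 1–10 s, and a warning is issued
whenever the fit range exceeds 10% of the duration. Calibration: white
noise → 0.50 (±0.02 over seeds at 2×10⁵ samples with 0.1–10 s fits);
spectrally synthesized long-memory signals with planted exponents 0.5–0.9
are recovered within ±0.05.

**Fitness.** 1 / (|1−DFA| + |1−κ_size| + |1−κ_dur|), capped at 10⁹ when the
denominator vanishes; a scalar summary of distance from criticality.

## Response metrics

**PLF** = norm of the mean unit phase vector across trials at a latency
(default 150 ms post-stimulus, where the delayed response peaks).

**Dynamic range.** A 4-parameter logistic in x = log₁₀(stimulus size) is
fit by least squares to PLF(150 ms) vs size; free asymptotes, because
strongly oscillating networks do not saturate at PLF = 1. Dynamic range
= x₉₀ − x₁₀ = 2 ln 9 / |k| in decades. Non-convergent fits are flagged,
not raised.

**Reg_amp.** Trials ranked by mean 8–16 Hz amplitude over −150…−50 ms,
split into 10 equal-count percentile bins; Reg_amp = Spearman ρ between bin
index and bin PLF at 150 ms. Ties get average ranks; constant bin PLFs
define Reg_amp = 0 with a flag.

**Reg_phase.** Trials are assigned by their phase at −5 ms to 32
overlapping bins: centers at 2πk/32, each covering center ± π/16 (width
π/8, adjacent bins overlap by half — the only reading consistent with 32
evenly spaced overlapping bins of that width). Every bin is subsampled with
a seeded draw to the smallest bin's count so bin PLFs are comparable;
Reg_phase = ‖Σ PLF_i z_i‖ / Σ PLF_i over bin-center unit vectors z_i: 1
when one bin carries all locking, 0 when locking is uniform.

**Bootstrap baseline.** Each iteration simulates 10 runs of 2000 uniform
(pre, post) phase pairs, computes Reg_phase per run and averages; the
threshold is the 95th percentile over 10000 iterations (defaults; tests use
400 trials and a few hundred iterations). The threshold applies to the
10-run average, matching its use on replicate networks. Note that the
threshold is approximately invariant to the trial count: the null scale of
the normalized PLF-weighted resultant is governed by the coefficient of
variation of the per-bin PLF, which is constant (~0.52, Rayleigh) in the
per-bin trial count.

## Criticality-function association

Per-network function metrics are binned by the networks' DFA exponents
(half-open bins of width 0.02 covering 0.5–0.9; empty bins dropped), and
the association is the Spearman ρ between bin-mean DFA and bin-mean metric
(two-sided p by the large-sample t approximation). Across post-stimulus
latencies, multiple comparisons use cluster-based permutation: clusters are
maximal runs of latencies with p ≤ α; cluster size = summed |ρ|; the null
shuffles metric values across bins independently per latency; threshold =
(1−α)·100 percentile of the permutation distribution of the maximum cluster
size. Full-scale parameters α = 0.001, 10000 permutations; the test profile
uses α = 0.01 and a few hundred permutations. Family-wise error on
pure-noise data is verified at the nominal level.

## Synthetic ground-truth generators

* Truncated power-law avalanche sizes by inverse-CDF sampling (oracle for
  κ: exponent −1.5 draws give κ = 1 ± 0.02 at 10⁵ samples).
* Long-memory envelopes by spectral synthesis (1/f^(β/2) amplitude shaping
  with β = 2·exponent − 1, then a shift to non-negativity, which leaves DFA
  unchanged) — oracle for the DFA estimator.
* Coupled trial sets: each trial is a 12 Hz oscillation with random onset
  phase and a log-normal per-trial amplitude. At stimulus onset the phase
  resets to a fixed angle with per-trial probability p; non-reset trials
  continue from a fresh random phase, emulating ongoing dynamics whose
  phase has decorrelated by the analysis latency. The planted couplings act
  on p only (amplitude coupling: p decreases with amplitude percentile,
  perfectly monotone at strength 1; phase coupling: p follows the positive
  cosine of the distance from the favoured rising-phase angle; null:
  constant p), so the PLF is the sole readout. The generators emulate the
  statistical structure the regulation metrics consume — they are not
  surrogate network simulations: passing recovery tests validates the
  estimators, not the network model.

## Scale choices

Production scale (256 connectivity combinations × 10 networks × 2000 s) is
cluster-level. The package's test profile uses what one CPU sustains in
minutes: 100–200 s runs, 3 replicate networks, the three example cells
(45/90 subcritical, 60/75 critical, 75/60 supercritical), DFA fits over
1–10 s, bootstrap thresholds from a few hundred iterations, and reduced
permutation counts. At that scale the implementation reproduces the
qualitative structure: DFA ordering critical > sub/supercritical, κ
straddling 1 across the three cells, a 9–11 Hz oscillation at the critical
cell, and planted regulation separating from null at the bootstrap
threshold.

## Known limitations

* The critical line's exact position in (CE, CI) is sensitive to
  implementation details and run length; at 100–200 s the 60/75 cell sits
  marginally on the subcritical side of κ = 1 while showing strong LRTC.
* Desk-scale runs make per-network DFA and κ noisy; phase-space maps at
  5% connectivity resolution need the production scale.
* The stimulated-run regulation analyses need thousands of trials for
  stable per-bin PLFs; at a few hundred trials the bin subsampling noise
  dominates weak couplings.
* No synaptic delays, conductances, plasticity, or external noise currents;
  the grid is open, so border neurons are systematically less connected.
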