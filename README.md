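# crosnet

A Python implementation of the CROS ("CRitical OScillations") spiking
network — a probabilistic integrate-and-fire model on a 50×50 grid whose
excitatory/inhibitory connectivity balance (CE, CI) moves it between
subcritical, critical and supercritical oscillatory regimes — together with
the complete time-series analysis suite needed to measure criticality and
stimulus-response function at desk scale.

It is aimed at computational neuroscientists studying how near-critical
network dynamics shape the processing of incoming stimuli: the central
quantity is the phase-locking factor (PLF) of the 8–16 Hz network
oscillation, and the package measures how strongly pre-stimulus oscillation
amplitude and phase regulate the post-stimulus phase-locked response, and
how that regulation depends on the network's distance from criticality.

## Model

Neurons sit on an open (non-periodic) grid, 75% excitatory. Within a local
circle of radius 4, a presynaptic neuron connects to a neighbour at distance
*r* with probability

    P(r) = min(α e^(−r), 1),

with α solved per neuron (Nelder–Mead) so the expected connected fraction of
its neighbourhood equals CE (excitatory) or CI (inhibitory). Each 1 ms step
updates synaptic input *I*, activation *A*, and spiking:

    I_i ← (I_i + Σ_j W_ij S_j) (1 − dt/τ_I)
    A_i ← (A_i + I_i) (1 − dt/τ_P) + A_0 dt/τ_P
    P(spike) = clamp(A_i, 0, 1);  on spike: A_i ← A_r

with W_EE = W_IE = 0.0085, W_EI = −0.569, W_II = −2, τ_I = 9 ms,
τ_P = 6/12 ms, A_0 = 10⁻⁶/0, A_r = −2/−20 (excitatory/inhibitory).

The analysis side provides: neuronal avalanches and the κ index (empirical
avalanche CDF vs a −1.5/−2.0 power-law reference; κ = 1 at criticality),
detrended fluctuation analysis (DFA) of the 8–16 Hz amplitude envelope
(long-range temporal correlations; 0.5 = uncorrelated), Welch spectra,
causal FIR band-pass phase/amplitude, PLF, dynamic range of the PLF
stimulus-response sigmoid, pre-stimulus amplitude regulation (Reg_amp,
Spearman over 10 amplitude percentile bins), pre-stimulus phase regulation
(Reg_phase, PLF-weighted circular resultant over 32 phase bins), a bootstrap
significance baseline for Reg_phase, and a cluster-based permutation test
for the DFA-function association across post-stimulus latencies. Synthetic
generators with planted ground truth (power-law avalanches, long-memory
envelopes, coupled trial sets) back every metric's tests.

## Worked example

Build a critical-line network (CE = 60%, CI = 75%), run it unstimulated for
150 s, and measure its criticality:

```python
from crosnet import (GridSpec, ConnectivityParams, SynapticWeights,
                     build_connections, run_simulation)
from crosnet.experiment import analyze_run

net = build_connections(GridSpec(seed=1), ConnectivityParams(CE=60, CI=75),
                        SynapticWeights(), seed=1)
print(f"network: {net.n_neurons} neurons "
      f"({len(net.excitatory_ids)} excitatory), {len(net.pre)} synapses")

raster = run_simulation(net, n_steps=150_000, seed=1, record_spikes=False)
metrics = analyze_run(raster, fit_range=(1.0, 10.0), noise_seed=1,
                      burn_in_ms=50_000)
for k, v in metrics.items():
    print(f"{k:>16s} = {v:.3f}")
```

prints

```
network: 2500 neurons (1875 excitatory), 71424 synapses
       peak_freq = 1.465
   osc_peak_freq = 9.277
             dfa = 0.968
      kappa_size = 0.903
  kappa_duration = 0.948
         fitness = 5.531
```

The network oscillates at ~9 Hz (`osc_peak_freq`, the spectral peak above
the aperiodic 1/f background; `peak_freq` is the raw band argmax, which the
scale-free slow fluctuations of a near-critical signal dominate). The DFA
exponent of 0.97 indicates strong long-range temporal correlations, and
κ ≈ 0.9–0.95 places this realization just on the subcritical side of the
avalanche criterion; the fitness scalar summarizes the distance of all
three from their critical values. A subcritical network (CE = 45, CI = 90)
gives DFA ≈ 0.5 and κ ≈ 0.78; a supercritical one (CE = 75, CI = 60) gives
κ > 1 with a strong 12.7 Hz rhythm.

A CLI mirrors the library:

```sh
crosnet simulate --ce 60 --ci 75 --steps 200000 --stim-n 5 --seed 7 --out run.npz
crosnet analyze run.npz
crosnet sweep --ce 45,60,75 --ci 90,75,60 --seeds 0,1,2 --out results/
crosnet figures results/metrics_<hash>.csv --out figs/
```

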