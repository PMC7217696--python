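"""Experiment orchestration: E/I sweeps, analysis, storage and figures.

An experiment runs, for every (CE, CI, seed) cell of a connectivity grid:
one unstimulated run (criticality metrics: DFA exponent, kappa of avalanche
sizes and durations, oscillation peak frequency) and optionally stimulated
runs of the SAME network (function metrics: PLF at the analysis latency,
pre-stimulus amplitude and phase regulation; dynamic range when several
stimulus sizes are swept). Results accumulate in a tidy metrics table
(CSV) keyed by a hash of the configuration; reruns skip rows already
present, which makes interrupted sweeps resumable and reruns idempotent.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import criticality, response, signals
from .dynamics import (
    NeuronParams,
    StimulusProtocol,
    SynapticWeights,
    run_simulation,
)
from .topology import ConnectivityParams, GridSpec, build_connections

__all__ = ["ExperimentConfig", "run_experiment", "make_figures", "analyze_run"]

METRIC_COLUMNS = ["CE", "CI", "seed", "stim_n", "input_multiplier", "metric", "value"]


@dataclass
class ExperimentConfig:
    """Declarative sweep configuration.

    ``profile`` selects analysis defaults: "test" uses the scaled-down DFA
    fit range (1-10 s) suited to runs of a few hundred seconds; "full" the
    2-50 s range of production-length (2000 s) runs.
    """

    ce_values: tuple = (45.0, 60.0, 75.0)
    ci_values: tuple = (90.0, 75.0, 60.0)
    pair_grid: bool = False          # True: full CE x CI grid; False: zip pairs
    seeds: tuple = (0, 1, 2)
    n_steps: int = 200_000
    stim_sizes: tuple = ()           # e.g. STIMULUS_SIZES for a response sweep
    input_multipliers: tuple = (1.0,)
    side_length: int = 50
    noise_sigma: float = 3.0
    profile: str = "test"            # "test" | "full"
    wee_factor: float = 1.0          # scale W_EE (robustness variants)

    def __post_init__(self) -> None:
        if self.profile not in ("test", "full"):
            raise ValueError("profile must be 'test' or 'full'")
        for v in self.ce_values + self.ci_values:
            if not 0 <= v <= 100:
                raise ValueError("connectivity percentages must be in [0, 100]")
        if not self.pair_grid and len(self.ce_values) != len(self.ci_values):
            raise ValueError("paired sweep needs equal-length CE/CI lists")
        for n in self.stim_sizes:
            if n < 0:
                raise ValueError("stimulus sizes must be >= 0")

    @property
    def dfa_fit_range(self) -> tuple[float, float]:
        return (criticality.DFA_FIT_RANGE_TEST if self.profile == "test"
                else criticality.DFA_FIT_RANGE_FULL)

    def cells(self):
        if self.pair_grid:
            return [(ce, ci) for ce in self.ce_values for ci in self.ci_values]
        return list(zip(self.ce_values, self.ci_values))

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: startup transient discarded before analysing an unstimulated run (ms);
#: the network starts silent and takes tens of seconds to become stationary
DEFAULT_BURN_IN_MS = 50_000


def analyze_run(raster, fit_range=(1.0, 10.0), noise_sigma: float = 3.0,
                noise_seed: int = 0, burn_in_ms: int = 0) -> dict:
    """Criticality metrics of one unstimulated run.

    ``burn_in_ms`` drops the leading samples (startup transient) before any
    analysis; use :data:`DEFAULT_BURN_IN_MS` for runs started from silence.
    """
    counts = raster.counts_total if hasattr(raster, "counts_total") else np.asarray(raster)
    if burn_in_ms:
        if burn_in_ms >= len(counts):
            raise ValueError("burn-in longer than the run")
        counts = counts[burn_in_ms:]
    sig = signals.make_network_signal(counts, noise_sigma=noise_sigma,
                                      seed=noise_seed)
    out: dict[str, float] = {}
    freqs, power = signals.welch_psd(sig)
    out["peak_freq"] = signals.peak_frequency(freqs, power, (1.0, 30.0))
    out["osc_peak_freq"] = signals.oscillation_peak_frequency(freqs, power)
    analytic = signals.bandpass_phase_amplitude(sig)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["dfa"] = criticality.dfa(analytic.amplitude, fit_range=fit_range).exponent
    catalog = criticality.detect_avalanches(sig.raw)
    for name, vals, exp in (
        ("kappa_size", catalog.sizes, criticality.KAPPA_EXPONENT_SIZE),
        ("kappa_duration", catalog.durations, criticality.KAPPA_EXPONENT_DURATION),
    ):
        try:
            out[name] = criticality.kappa_index(vals, exp).kappa
        except ValueError:
            out[name] = float("nan")
    if np.isfinite(out["kappa_size"]) and np.isfinite(out["kappa_duration"]):
        out["fitness"] = criticality.compute_fitness(
            out["dfa"], out["kappa_size"], out["kappa_duration"])
    return out


def _analyze_stimulated(raster, noise_sigma: float, noise_seed: int,
                        latency_ms: float = 150.0) -> dict:
    sig = signals.make_network_signal(raster, noise_sigma=noise_sigma,
                                      seed=noise_seed)
    analytic = signals.bandpass_phase_amplitude(sig)
    trials = signals.epoch_trials(analytic, raster.stim_times,
                                  window=(-200, 500))
    out = {"n_trials": float(trials.n_trials)}
    out["plf"] = response.plf(trials.phase_at(latency_ms))
    try:
        out["reg_amp"] = response.reg_amp(trials, latency_ms=latency_ms).value
    except ValueError:
        out["reg_amp"] = float("nan")
    try:
        out["reg_phase"] = response.reg_phase(trials, latency_ms=latency_ms,
                                              seed=noise_seed).value
    except ValueError:
        out["reg_phase"] = float("nan")
    return out


def run_experiment(config: ExperimentConfig, out_dir: str | Path,
                   record_spikes: bool = False, verbose: bool = False) -> pd.DataFrame:
    """Run (or resume) a sweep; returns the tidy metrics table.

    For each (CE, CI, seed): the network is built once and reused for the
    unstimulated and every stimulated run. Rows already present in the
    stored table (matched on the sweep keys) are skipped, so an interrupted
    sweep resumed with the same config converges to the same store. Cell
    failures are logged as warnings and skipped, not fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    table_path = out_dir / f"metrics_{chash}.csv"
    if table_path.exists():
        table = pd.read_csv(table_path)
    else:
        table = pd.DataFrame(columns=METRIC_COLUMNS)

    def have(ce, ci, seed, stim_n, mult) -> bool:
        if table.empty:
            return False
        m = ((table.CE == ce) & (table.CI == ci) & (table.seed == seed)
             & (table.stim_n == stim_n) & (table.input_multiplier == mult))
        return bool(m.any())

    new_rows = []
    weights_kw = {}
    spec_base = GridSpec(side_length=config.side_length)

    for ce, ci in config.cells():
        for seed in config.seeds:
            w = SynapticWeights(W_EE=0.0085 * config.wee_factor,
                                **weights_kw)
            net = None
            try:
                if not have(ce, ci, seed, 0, 1.0):
                    spec = GridSpec(side_length=config.side_length, seed=seed)
                    net = build_connections(
                        spec, ConnectivityParams(CE=ce, CI=ci), w, seed=seed)
                    raster = run_simulation(
                        net, NeuronParams(), None, config.n_steps,
                        seed=seed, weights=w, record_spikes=record_spikes)
                    metrics = analyze_run(
                        raster, fit_range=config.dfa_fit_range,
                        noise_sigma=config.noise_sigma, noise_seed=seed,
                        burn_in_ms=min(DEFAULT_BURN_IN_MS, config.n_steps // 4))
                    for k, v in metrics.items():
                        new_rows.append([ce, ci, seed, 0, 1.0, k, v])
                for mult in config.input_multipliers:
                    for stim_n in config.stim_sizes:
                        if stim_n == 0 or have(ce, ci, seed, stim_n, mult):
                            continue
                        if net is None:
                            spec = GridSpec(side_length=config.side_length,
                                            seed=seed)
                            net = build_connections(
                                spec, ConnectivityParams(CE=ce, CI=ci), w,
                                seed=seed)
                        wm = SynapticWeights(W_EE=0.0085 * config.wee_factor,
                                             input_multiplier=mult)
                        proto = StimulusProtocol(n_stimulated=stim_n, seed=seed)
                        raster = run_simulation(
                            net, NeuronParams(), proto, config.n_steps,
                            seed=seed + 1000, weights=wm,
                            record_spikes=record_spikes)
                        metrics = _analyze_stimulated(
                            raster, config.noise_sigma, noise_seed=seed)
                        for k, v in metrics.items():
                            new_rows.append([ce, ci, seed, stim_n, mult, k, v])
            except Exception as e:  # pragma: no cover - defensive
                warnings.warn(f"cell (CE={ce}, CI={ci}, seed={seed}) failed: {e}",
                              stacklevel=2)
                continue
            if verbose:
                print(f"done CE={ce} CI={ci} seed={seed}")

    if new_rows:
        fresh = pd.DataFrame(new_rows, columns=METRIC_COLUMNS)
        table = fresh if table.empty else pd.concat([table, fresh],
                                                    ignore_index=True)
        table = table.sort_values(METRIC_COLUMNS[:6]).reset_index(drop=True)
        table.to_csv(table_path, index=False)
    (out_dir / f"config_{chash}.json").write_text(
        json.dumps(config.__dict__, indent=2, default=list))
    # round-trip through the store so dtypes are identical across reruns
    return pd.read_csv(table_path) if table_path.exists() else table


def phase_space_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(CE, CI, stim_n, metric) means over seeds, tidy."""
    g = (table.groupby(["CE", "CI", "stim_n", "input_multiplier", "metric"])
         ["value"].agg(["mean", "count"]).reset_index())
    return g


def make_figures(table: pd.DataFrame, out_dir: str | Path,
                 metrics: tuple = ("dfa", "kappa_size", "plf",
                                   "reg_amp", "reg_phase")) -> list[Path]:
    """Heatmaps over (CE, CI) for each available metric; panels for metrics
    missing from the store are skipped with a warning. The kappa map gets a
    contour at kappa = 1 (the critical line) when the grid allows one."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ps = phase_space_table(table)
    for metric in metrics:
        sub = ps[ps.metric == metric]
        if sub.empty:
            warnings.warn(f"metric {metric!r} missing from store; panel skipped",
                          stacklevel=2)
            continue
        sub = sub.groupby(["CE", "CI"])["mean"].mean().reset_index()
        pivot = sub.pivot(index="CI", columns="CE", values="mean")
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values,
                           shading="nearest")
        fig.colorbar(im, ax=ax, label=metric)
        if metric.startswith("kappa") and pivot.shape[0] > 1 and pivot.shape[1] > 1:
            filled = np.ma.masked_invalid(pivot.values)
            if filled.count() == pivot.size:
                ax.contour(pivot.columns, pivot.index, pivot.values,
                           levels=[1.0], colors="black")
        ax.set_xlabel("CE (%)")
        ax.set_ylabel("CI (%)")
        ax.set_title(metric)
        path = out_dir / f"phase_space_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
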