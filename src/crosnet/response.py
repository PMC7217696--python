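"""Stimulus-response metrics built on the phase-locking factor (PLF).

PLF at a post-stimulus latency is the length of the mean unit phase vector
across trials: 1 when every trial has the same phase, 0 for uniformly
spread phases. From it derive:

* dynamic range — orders of magnitude of stimulus size spanning the
  10%-90% points of a sigmoid fit to PLF vs log10(stimulus size);
* pre-stimulus amplitude regulation (Reg_amp) — Spearman correlation
  between pre-stimulus amplitude percentile-bin index (10 equal-count bins,
  amplitude averaged over -150..-50 ms) and the bin's PLF at +150 ms;
* pre-stimulus phase regulation (Reg_phase) — the PLF-weighted circular
  resultant over 32 overlapping pre-stimulus phase bins (phase at -5 ms,
  bin width pi/8), normalized by the summed PLFs: 1 if a single bin carries
  all the locking, 0 if all bins lock equally;
* a bootstrap significance baseline for Reg_phase from uniformly random
  pre/post phase pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .signals import TrialEpochs

__all__ = [
    "PLFSeries",
    "DynamicRangeResult",
    "RegulationResult",
    "plf",
    "plf_series",
    "dynamic_range",
    "reg_amp",
    "reg_phase",
    "phase_regulation_from_bin_plfs",
    "bootstrap_phase_threshold",
]

DEFAULT_LATENCY_MS = 150.0
AMP_WINDOW_MS = (-150.0, -50.0)
PHASE_LATENCY_MS = -5.0
N_AMP_BINS = 10
N_PHASE_BINS = 32
PHASE_BIN_HALFWIDTH = np.pi / 16  # bins of width pi/8, centers 2*pi*k/32


@dataclass
class PLFSeries:
    """PLF at each latency relative to stimulus onset."""

    latencies: np.ndarray
    plf: np.ndarray
    n_trials: int


@dataclass
class DynamicRangeResult:
    """Orders of magnitude of stimulus size between the sigmoid's 10% and
    90% points; ``params`` = (lower, upper, midpoint in log10 n, slope)."""

    dynamic_range: float
    params: tuple[float, float, float, float]
    latency_ms: float = DEFAULT_LATENCY_MS
    converged: bool = True
    message: str = ""


@dataclass
class RegulationResult:
    value: float                     # Reg_amp in [-1,1] or Reg_phase in [0,1]
    kind: str                        # "amplitude" | "phase"
    bin_plf: np.ndarray              # per-bin PLF at the analysis latency
    bin_centers: np.ndarray          # bin index (amplitude) or radians (phase)
    latency_ms: float = DEFAULT_LATENCY_MS
    flags: dict = field(default_factory=dict)


def plf(phases) -> float:
    """Phase-locking factor: norm of the mean unit vector of the phases."""
    ph = np.asarray(phases, float)
    if ph.size == 0:
        raise ValueError("plf of empty phase set")
    return float(np.abs(np.mean(np.exp(1j * ph))))


def plf_series(trials: TrialEpochs) -> PLFSeries:
    """PLF at every latency of the epoch window."""
    z = np.exp(1j * trials.phase)
    return PLFSeries(
        latencies=trials.times.astype(float),
        plf=np.abs(z.mean(axis=0)),
        n_trials=trials.n_trials,
    )


def _logistic(x, lower, upper, x0, k):
    return lower + (upper - lower) / (1.0 + np.exp(-k * (x - x0)))


def dynamic_range(
    plf_by_stimsize: dict[int, float],
    latency_ms: float = DEFAULT_LATENCY_MS,
) -> DynamicRangeResult:
    """Fit a 4-parameter logistic to PLF vs log10(stimulus size) and return
    the width x90 - x10 between the fitted curve's own 10% and 90% points
    (closed form 2*ln(9)/k for slope k).

    The asymptotes are free because strongly oscillating (supercritical)
    networks do not saturate at PLF = 1.
    """
    if len(plf_by_stimsize) < 4:
        raise ValueError("need at least 4 stimulus sizes")
    n = np.array(sorted(plf_by_stimsize), dtype=float)
    if np.log10(n.max() / n.min()) < 1.0:
        raise ValueError("stimulus sizes must span at least one decade")
    y = np.array([plf_by_stimsize[int(v)] for v in n], float)
    x = np.log10(n)

    span = max(y.max() - y.min(), 1e-6)
    p0 = [y.min(), y.max(), float(x[np.argmin(np.abs(y - y.mean()))]), 4.0 / span]
    try:
        popt, _ = curve_fit(
            _logistic, x, y, p0=p0,
            bounds=([-0.5, -0.5, x.min() - 2, 1e-3], [1.5, 1.5, x.max() + 2, 1e3]),
            maxfev=20000,
        )
    except RuntimeError as e:
        return DynamicRangeResult(
            dynamic_range=float("nan"), params=tuple(p0),
            latency_ms=latency_ms, converged=False, message=str(e),
        )
    lower, upper, x0, k = (float(v) for v in popt)
    dr = 2.0 * np.log(9.0) / abs(k)
    return DynamicRangeResult(
        dynamic_range=float(dr),
        params=(lower, upper, x0, k),
        latency_ms=latency_ms,
    )


def reg_amp(
    trials: TrialEpochs,
    latency_ms: float = DEFAULT_LATENCY_MS,
    amp_window: tuple[float, float] = AMP_WINDOW_MS,
    n_bins: int = N_AMP_BINS,
) -> RegulationResult:
    """Pre-stimulus amplitude regulation of the phase-locked response.

    Trials are ranked by mean band amplitude over ``amp_window`` and split
    into ``n_bins`` equal-count percentile bins; Reg_amp is the Spearman
    correlation between bin index and the bin's PLF at ``latency_ms``.
    """
    if trials.n_trials < n_bins:
        raise ValueError(f"need at least {n_bins} trials")
    amp = trials.amplitude_mean(*amp_window)
    post_phase = trials.phase_at(latency_ms)
    order = np.argsort(amp, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_plf = np.array([plf(post_phase[b]) for b in bins])
    flags = {}
    if np.allclose(bin_plf, bin_plf[0]):
        rho = 0.0
        flags["constant_plf"] = True
    else:
        rho = float(spearmanr(np.arange(n_bins), bin_plf).statistic)
    return RegulationResult(
        value=rho,
        kind="amplitude",
        bin_plf=bin_plf,
        bin_centers=np.arange(n_bins, dtype=float),
        latency_ms=latency_ms,
        flags=flags,
    )


def phase_regulation_from_bin_plfs(bin_plfs, bin_centers) -> float:
    """Reg_phase kernel: PLF-weighted circular resultant over bin centers,
    normalized by the summed PLFs.

    Returns ||sum_i PLF_i z_i|| / sum_i PLF_i with z_i the unit vector at
    bin center i — 1 when one bin carries all locking, 0 when locking is
    identical across bins.
    """
    w = np.asarray(bin_plfs, float)
    c = np.asarray(bin_centers, float)
    total = w.sum()
    if total <= 0:
        return 0.0
    return float(np.abs(np.sum(w * np.exp(1j * c))) / total)


def _phase_bin_members(pre_phase: np.ndarray, centers: np.ndarray,
                       halfwidth: float) -> list[np.ndarray]:
    # circular distance of every trial to every bin center
    d = np.angle(np.exp(1j * (pre_phase[None, :] - centers[:, None])))
    return [np.flatnonzero(np.abs(row) <= halfwidth) for row in d]


def reg_phase(
    trials: TrialEpochs,
    latency_ms: float = DEFAULT_LATENCY_MS,
    phase_latency_ms: float = PHASE_LATENCY_MS,
    n_bins: int = N_PHASE_BINS,
    seed: int = 0,
) -> RegulationResult:
    """Pre-stimulus phase regulation of the phase-locked response.

    Trials are assigned to ``n_bins`` overlapping phase bins (centers evenly
    spaced on the circle, half-width pi/16) by their phase at
    ``phase_latency_ms``; every bin is subsampled (seeded) to the smallest
    bin's count so the per-bin PLFs are comparable; Reg_phase is the
    PLF-weighted circular resultant over bin centers.
    """
    pre = trials.phase_at(phase_latency_ms)
    post = trials.phase_at(latency_ms)
    centers = 2.0 * np.pi * np.arange(n_bins) / n_bins
    centers = np.angle(np.exp(1j * centers))  # wrap to (-pi, pi]
    members = _phase_bin_members(pre, centers, PHASE_BIN_HALFWIDTH)
    occupancy = np.array([len(m) for m in members])
    if (occupancy == 0).any():
        raise ValueError(
            "empty pre-stimulus phase bin; occupancy: " + str(occupancy.tolist())
        )
    x = int(occupancy.min())
    rng = np.random.default_rng(seed)
    bin_plf = np.empty(n_bins)
    for i, m in enumerate(members):
        pick = m if len(m) == x else rng.choice(m, size=x, replace=False)
        bin_plf[i] = plf(post[pick])
    return RegulationResult(
        value=phase_regulation_from_bin_plfs(bin_plf, centers),
        kind="phase",
        bin_plf=bin_plf,
        bin_centers=centers,
        latency_ms=latency_ms,
        flags={"bin_count": x},
    )


def _reg_phase_from_pairs(pre: np.ndarray, post: np.ndarray,
                          rng: np.random.Generator,
                          n_bins: int = N_PHASE_BINS) -> float:
    """Reg_phase of raw (pre, post) phase pairs; used by the bootstrap."""
    centers = np.angle(np.exp(1j * (2.0 * np.pi * np.arange(n_bins) / n_bins)))
    members = _phase_bin_members(pre, centers, PHASE_BIN_HALFWIDTH)
    occupancy = np.array([len(m) for m in members])
    if (occupancy == 0).any():
        # uniform draws with few trials can leave a bin empty; treat the
        # iteration's regulation as undefined -> resample caller-side
        return float("nan")
    x = int(occupancy.min())
    w = np.empty(n_bins)
    for i, m in enumerate(members):
        pick = m if len(m) == x else rng.choice(m, size=x, replace=False)
        w[i] = np.abs(np.mean(np.exp(1j * post[pick])))
    return phase_regulation_from_bin_plfs(w, centers)


def bootstrap_phase_threshold(
    n_runs: int = 10,
    trials_per_run: int = 2000,
    n_boot: int = 10000,
    seed: int = 0,
    percentile: float = 95.0,
) -> float:
    """Significance baseline for Reg_phase under the null of no regulation.

    Each bootstrap iteration simulates ``n_runs`` runs of
    ``trials_per_run`` uniformly random (pre, post) phase pairs, computes
    Reg_phase per run and averages across runs; the threshold is the
    ``percentile`` of those averages over ``n_boot`` iterations.
    """
    if min(n_runs, trials_per_run, n_boot) < 1:
        raise ValueError("bootstrap parameters must be positive")
    rng = np.random.default_rng(seed)
    means = np.empty(n_boot)
    for b in range(n_boot):
        vals = np.empty(n_runs)
        for r in range(n_runs):
            v = float("nan")
            while not np.isfinite(v):
                pre = rng.uniform(-np.pi, np.pi, trials_per_run)
                post = rng.uniform(-np.pi, np.pi, trials_per_run)
                v = _reg_phase_from_pairs(pre, post, rng)
            vals[r] = v
        means[b] = vals.mean()
    return float(np.percentile(means, percentile))
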