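"""Criticality metrics: neuronal avalanches, the kappa index, and DFA.

An avalanche is a maximal run of consecutive time steps where the raw
(noise-free) population spike count exceeds half the median activity; its
size is the summed count, its duration the run length. The kappa index
compares the empirical avalanche CDF with a reference power-law CDF
(exponent -1.5 for sizes, -2.0 for durations) at 10 log-spaced points:
kappa = 1 at criticality, < 1 subcritical, > 1 supercritical. Long-range
temporal correlations of the oscillation amplitude envelope are quantified
with detrended fluctuation analysis (DFA): the scaling exponent of the RMS
fluctuation of the integrated, per-window linearly detrended signal; 0.5
means an uncorrelated signal, 0.5-1.0 persistent scale-free correlations.
A scalar fitness summarizes distance from criticality: the reciprocal of
the summed deviations of DFA, kappa_size and kappa_duration from 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AvalancheCatalog",
    "KappaResult",
    "DFAResult",
    "detect_avalanches",
    "kappa_index",
    "kappa_from_cdfs",
    "reference_powerlaw_cdf",
    "dfa",
    "compute_fitness",
]

KAPPA_EXPONENT_SIZE = -1.5
KAPPA_EXPONENT_DURATION = -2.0
KAPPA_N_POINTS = 10
FITNESS_CAP = 1e9

#: scaled-down DFA fit range for >=100 s signals (seconds); the full-scale
#: range used on long (2000 s) runs is (2, 50)
DFA_FIT_RANGE_TEST = (1.0, 10.0)
DFA_FIT_RANGE_FULL = (2.0, 50.0)


@dataclass
class AvalancheCatalog:
    sizes: np.ndarray       # summed spikes per avalanche
    durations: np.ndarray   # run length, ms
    threshold: float        # spikes; half the median activity

    @property
    def n_avalanches(self) -> int:
        return len(self.sizes)


@dataclass
class KappaResult:
    kappa: float
    reference_exponent: float
    beta_points: np.ndarray


@dataclass
class DFAResult:
    exponent: float
    window_sizes: np.ndarray   # seconds
    fluctuations: np.ndarray   # F(t)
    fit_range: tuple[float, float]


def detect_avalanches(raw_counts) -> AvalancheCatalog:
    """Find avalanches in the raw population spike-count series.

    Threshold = 0.5 x median over all time steps; an avalanche is a maximal
    run of steps with count strictly above threshold. Edge-truncated runs
    are kept.
    """
    x = np.asarray(raw_counts)
    if x.ndim != 1:
        raise ValueError("raw_counts must be 1-D")
    threshold = 0.5 * float(np.median(x))
    above = x > threshold
    if not above.any():
        return AvalancheCatalog(
            sizes=np.empty(0, dtype=np.int64),
            durations=np.empty(0, dtype=np.int64),
            threshold=threshold,
        )
    # run boundaries of the boolean mask
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x)]
    csum = np.r_[0, np.cumsum(x)]
    sizes = csum[ends] - csum[starts]
    return AvalancheCatalog(
        sizes=sizes.astype(np.int64),
        durations=(ends - starts).astype(np.int64),
        threshold=threshold,
    )


def reference_powerlaw_cdf(beta, exponent: float, xmin: float, xmax: float) -> np.ndarray:
    """CDF of a continuous truncated power law with density ~ x**exponent
    on [xmin, xmax] (exponent < -1)."""
    beta = np.asarray(beta, float)
    a1 = exponent + 1.0
    return (beta**a1 - xmin**a1) / (xmax**a1 - xmin**a1)


def kappa_from_cdfs(reference: np.ndarray, empirical: np.ndarray) -> float:
    """kappa = 1 + mean(P - A) over the evaluation points, where P is the
    reference power-law CDF and A the empirical CDF."""
    reference = np.asarray(reference, float)
    empirical = np.asarray(empirical, float)
    if reference.shape != empirical.shape:
        raise ValueError("CDF arrays must have the same shape")
    return float(1.0 + np.mean(reference - empirical))


def kappa_index(
    values,
    reference_exponent: float = KAPPA_EXPONENT_SIZE,
    n_points: int = KAPPA_N_POINTS,
) -> KappaResult:
    """Kappa index of a sample of avalanche sizes (or durations).

    Evaluates the reference power-law CDF and the empirical CDF at
    ``n_points`` log-spaced points between the observed min and max, and
    returns 1 plus their mean difference.
    """
    x = np.asarray(values, float)
    if x.size < 2 or np.min(x) == np.max(x):
        raise ValueError("kappa needs at least 2 distinct values")
    if np.min(x) <= 0:
        raise ValueError("values must be positive")
    xmin, xmax = float(np.min(x)), float(np.max(x))
    beta = np.logspace(np.log10(xmin), np.log10(xmax), n_points)
    ref = reference_powerlaw_cdf(beta, reference_exponent, xmin, xmax)
    xs = np.sort(x)
    emp = np.searchsorted(xs, beta, side="right") / x.size
    return KappaResult(
        kappa=kappa_from_cdfs(ref, emp),
        reference_exponent=reference_exponent,
        beta_points=beta,
    )


def _dfa_window_sizes(n: int, fs: float, n_sizes: int = 20,
                      t_min_s: float = 0.1, t_max_s: float = 55.0) -> np.ndarray:
    """Log-spaced window sizes in samples, clipped to the signal length."""
    t_max_s = min(t_max_s, n / fs / 2.0)
    sizes = np.unique(
        np.round(np.logspace(np.log10(t_min_s * fs), np.log10(t_max_s * fs),
                             n_sizes)).astype(int)
    )
    return sizes[(sizes >= 4) & (sizes <= n // 2)]


def dfa(
    envelope,
    fit_range: tuple[float, float] = DFA_FIT_RANGE_TEST,
    fs: float = 1000.0,
    n_sizes: int = 20,
    overlap: float = 0.5,
) -> DFAResult:
    """Detrended fluctuation analysis of a signal (typically the 8-16 Hz
    amplitude envelope).

    Steps: cumulative sum of the mean-removed signal; split into windows of
    size t with ``overlap`` fraction overlap; remove a least-squares line
    per window; F(t) = RMS of the residuals pooled over windows. The
    exponent is the slope of log10 F vs log10 t over window sizes within
    ``fit_range`` (seconds).
    """
    x = np.asarray(envelope, float)
    if fit_range[1] > 0.10 * len(x) / fs + 1e-9:
        warnings.warn(
            "DFA fit range exceeds 10% of the signal duration; the largest "
            "windows are unreliable",
            stacklevel=2,
        )
    sizes = _dfa_window_sizes(len(x), fs, n_sizes=n_sizes)
    if len(sizes) < 2:
        raise ValueError("signal too short for DFA")
    y = np.cumsum(x - x.mean())
    F = np.empty(len(sizes))
    for k, t in enumerate(sizes):
        step_len = max(1, int(round(t * (1.0 - overlap))))
        starts = np.arange(0, len(y) - t + 1, step_len)
        seg = y[starts[:, None] + np.arange(t)[None, :]]
        # closed-form linear detrend per window
        u = np.arange(t, dtype=float)
        u -= u.mean()
        denom = (u**2).sum()
        seg_c = seg - seg.mean(axis=1, keepdims=True)
        slope = (seg_c @ u) / denom
        resid = seg_c - slope[:, None] * u[None, :]
        F[k] = np.sqrt(np.mean(resid**2))
    t_s = sizes / fs
    sel = (t_s >= fit_range[0]) & (t_s <= fit_range[1])
    if sel.sum() < 2:
        raise ValueError("fewer than 2 window sizes inside fit_range")
    with np.errstate(divide="ignore"):
        slope, _ = np.polyfit(np.log10(t_s[sel]), np.log10(F[sel]), 1)
    return DFAResult(
        exponent=float(slope),
        window_sizes=t_s,
        fluctuations=F,
        fit_range=fit_range,
    )


def compute_fitness(dfa_exp: float, kappa_size: float, kappa_duration: float,
                    cap: float = FITNESS_CAP) -> float:
    """fitness = 1 / (|1-DFA| + |1-kappa_size| + |1-kappa_duration|),
    capped at ``cap`` when the denominator vanishes."""
    for v in (dfa_exp, kappa_size, kappa_duration):
        if not np.isfinite(v):
            raise ValueError("fitness inputs must be finite")
    denom = abs(1.0 - dfa_exp) + abs(1.0 - kappa_size) + abs(1.0 - kappa_duration)
    if denom < 1e-9:
        return cap
    return min(1.0 / denom, cap)
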