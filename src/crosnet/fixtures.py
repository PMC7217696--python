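"""Synthetic ground-truth generators for every analysis metric.

These give each metric an input with a known answer without running the
full network simulator: truncated power-law avalanche sizes (oracle for the
kappa index), long-memory envelope signals with a planted DFA exponent
(spectral synthesis), and trial sets with a planted coupling between
pre-stimulus amplitude/phase and the post-stimulus phase-locked response
(oracle for Reg_amp / Reg_phase). All generators are deterministic under
their seed.
"""

from __future__ import annotations

import numpy as np

from .signals import TrialEpochs

__all__ = [
    "gen_powerlaw_avalanches",
    "gen_scaling_envelope",
    "gen_coupled_trials",
]

FIXTURE_BAND_FREQ_HZ = 12.0  # centre of the 8-16 Hz band
FIXTURE_WINDOW_MS = (-200, 300)


def gen_powerlaw_avalanches(
    exponent: float,
    n: int,
    xmin: float = 1.0,
    xmax: float = 1e4,
    seed: int = 0,
) -> np.ndarray:
    """Inverse-CDF draws from a continuous truncated power law with density
    proportional to x**exponent on [xmin, xmax] (exponent < -1)."""
    if exponent >= -1:
        raise ValueError("exponent must be < -1")
    if xmax <= xmin or xmin <= 0:
        raise ValueError("invalid support")
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    a1 = exponent + 1.0
    return (xmin**a1 + u * (xmax**a1 - xmin**a1)) ** (1.0 / a1)


def gen_scaling_envelope(
    target_exponent: float,
    n_samples: int,
    seed: int = 0,
) -> np.ndarray:
    """Non-negative long-memory series with a planted DFA exponent.

    Spectral synthesis: shape white Gaussian noise by 1/f^(beta/2) in
    amplitude with beta = 2*target_exponent - 1 (so DFA of the series is
    the target), then shift so the minimum is zero — an additive constant
    leaves DFA unchanged, so the planted scaling is preserved exactly.
    """
    if not 0.5 <= target_exponent <= 1.0:
        raise ValueError("target_exponent must be within [0.5, 1.0]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    beta = 2.0 * target_exponent - 1.0
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-beta / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n_samples)
    return x - x.min()


def gen_coupled_trials(
    coupling: str,
    strength: float,
    n_trials: int,
    seed: int = 0,
    window: tuple[int, int] = FIXTURE_WINDOW_MS,
    reset_angle: float = 0.3,
) -> TrialEpochs:
    """Trial sets with a planted pre-stimulus -> response coupling.

    Each trial carries an 8-16 Hz band oscillation: pre-stimulus phase
    advances linearly at 12 Hz from a random start, the amplitude is a
    random per-trial constant. At stimulus onset the oscillation's phase
    resets to ``reset_angle`` with a per-trial probability p; non-reset
    trials continue from a fresh random phase, emulating ongoing dynamics
    whose phase has decorrelated from the pre-stimulus phase by the
    analysis latency — so the post-stimulus PLF of a trial group equals
    the group's reset fraction (up to sampling noise). The planted
    couplings act on p only:

    * ``"amplitude"``: p = strength * (1 - amplitude percentile rank) —
      high pre-stimulus amplitude suppresses phase-locking (negative
      regulation), perfectly monotone at strength 1.
    * ``"phase"``: p = strength * max(0, cos(phase(-5 ms) - reset_angle))
      — trials on the rising side of the cycle lock, others do not.
    * ``"none"``: p = strength/2 for every trial (no regulation).
    """
    if coupling not in ("none", "amplitude", "phase"):
        raise ValueError(f"unknown coupling {coupling!r}")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t0, t1 = window
    times = np.arange(t0, t1 + 1)
    omega = 2.0 * np.pi * FIXTURE_BAND_FREQ_HZ / 1000.0  # rad per ms

    phi0 = rng.uniform(-np.pi, np.pi, n_trials)          # phase at onset
    amp = rng.lognormal(mean=0.0, sigma=0.5, size=n_trials)

    # phase before onset (and in non-reset trials after onset): free-running
    phase = np.angle(np.exp(1j * (phi0[:, None] + omega * times[None, :])))
    amplitude = np.repeat(amp[:, None], len(times), axis=1)

    pre_phase = np.angle(np.exp(1j * (phi0 - omega * 5.0)))  # at -5 ms
    if coupling == "amplitude":
        rank = np.argsort(np.argsort(amp)) / max(n_trials - 1, 1)
        p_reset = strength * (1.0 - rank)
    elif coupling == "phase":
        p_reset = strength * np.maximum(0.0, np.cos(pre_phase - reset_angle))
    else:
        p_reset = np.full(n_trials, strength / 2.0)

    reset = rng.random(n_trials) < p_reset
    post = times >= 0
    # post-stimulus phase restarts at onset: from reset_angle for reset
    # trials, from a fresh random angle (decorrelated from phi0) otherwise
    start = np.where(reset, reset_angle, rng.uniform(-np.pi, np.pi, n_trials))
    phase[:, post] = np.angle(
        np.exp(1j * (start[:, None] + omega * times[post][None, :]))
    )
    return TrialEpochs(times=times, phase=phase, amplitude=amplitude)
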