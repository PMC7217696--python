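"""From spike rasters to the analysis signal and its phase/amplitude.

The network signal is the per-millisecond total spike count plus Gaussian
white noise (sigma = 3 spikes) — the model's analogue of a single M/EEG
channel; the noise guarantees a time-varying phase during silent periods.
Oscillation power uses Welch's method (Hamming window, 2^11 FFT points).
Phase and amplitude come from a one-way causal FIR band-pass (order 250,
8-16 Hz) followed by the Hilbert transform; the causal filter keeps the
pre-stimulus estimates uncontaminated by the response at the cost of a
constant 125 ms group delay, which is deliberately NOT compensated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import firwin, hilbert, lfilter, welch

__all__ = [
    "NetworkSignal",
    "AnalyticSignal",
    "TrialEpochs",
    "make_network_signal",
    "welch_psd",
    "peak_frequency",
    "oscillation_peak_frequency",
    "bandpass_filter",
    "bandpass_phase_amplitude",
    "epoch_trials",
]

FS_HZ = 1000.0
DEFAULT_NOISE_SIGMA = 3.0
DEFAULT_BAND = (8.0, 16.0)
FIR_ORDER = 250
WELCH_NFFT = 2**11


@dataclass
class NetworkSignal:
    """1 kHz scalar analysis signal with its noise-free companion.

    ``values`` = summed spikes + Gaussian noise; ``raw`` keeps the integer
    counts for avalanche analysis.
    """

    values: np.ndarray
    raw: np.ndarray
    fs: float = FS_HZ
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.values) != len(self.raw):
            raise ValueError("values and raw must have equal length")


@dataclass
class AnalyticSignal:
    """Instantaneous phase/amplitude of the band-passed signal.

    Timestamps follow the causal filter's convention: the constant group
    delay ``filter_delay`` ms is included, not compensated.
    """

    phase: np.ndarray      # radians, wrapped to (-pi, pi]
    amplitude: np.ndarray  # envelope, >= 0
    filtered: np.ndarray   # band-passed signal
    band: tuple[float, float] = DEFAULT_BAND
    fs: float = FS_HZ
    filter_delay: float = FIR_ORDER / 2.0  # ms at 1 kHz


@dataclass
class TrialEpochs:
    """Per-trial phase/amplitude aligned to stimulus onset.

    ``times`` are ms relative to onset; ``phase`` and ``amplitude`` are
    (n_trials, len(times)) arrays.
    """

    times: np.ndarray
    phase: np.ndarray
    amplitude: np.ndarray
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    def _col(self, latency_ms: float) -> int:
        idx = int(np.argmin(np.abs(self.times - latency_ms)))
        if abs(self.times[idx] - latency_ms) > 0.5:
            raise ValueError(f"latency {latency_ms} ms outside epoch window")
        return idx

    def phase_at(self, latency_ms: float) -> np.ndarray:
        """Per-trial phase at a latency (ms relative to onset)."""
        return self.phase[:, self._col(latency_ms)]

    def amplitude_mean(self, t_from: float, t_to: float) -> np.ndarray:
        """Per-trial mean amplitude over [t_from, t_to] ms."""
        sel = (self.times >= t_from) & (self.times <= t_to)
        if not sel.any():
            raise ValueError("window outside epoch times")
        return self.amplitude[:, sel].mean(axis=1)


def make_network_signal(
    raster,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> NetworkSignal:
    """Build the analysis signal from a raster: total spikes per step plus
    zero-mean Gaussian noise of standard deviation ``noise_sigma``."""
    raw = np.asarray(raster.counts_total if hasattr(raster, "counts_total") else raster)
    if len(raw) == 0:
        raise ValueError("empty raster")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=len(raw)) if noise_sigma > 0 else 0.0
    return NetworkSignal(
        values=raw.astype(float) + noise,
        raw=raw.astype(np.int64),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def welch_psd(signal, fs: float = FS_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with a Hamming window, 2^11 FFT points
    per segment and 50% overlap."""
    x = signal.values if isinstance(signal, NetworkSignal) else np.asarray(signal, float)
    if len(x) < WELCH_NFFT:
        raise ValueError(f"signal shorter than one {WELCH_NFFT}-point segment")
    return welch(x, fs=fs, window="hamming", nperseg=WELCH_NFFT,
                 noverlap=WELCH_NFFT // 2)


def peak_frequency(
    freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]
) -> float:
    """Frequency of the largest PSD value within ``band`` (Hz)."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("band contains no frequency bins")
    return float(freqs[sel][np.argmax(power[sel])])


def oscillation_peak_frequency(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = (1.0, 30.0),
    trend_band: tuple[float, float] = (1.0, 45.0),
    exclude_band: tuple[float, float] = (6.0, 18.0),
) -> float:
    """Peak frequency of the oscillatory component within ``band`` (Hz).

    Critical network signals carry scale-free (1/f-like) slow fluctuations
    on which the band-limited oscillation rides; the raw PSD argmax then
    lands on the lowest frequency bin regardless of the oscillation. This
    estimator separates the aperiodic background first — a quadratic in
    log-log coordinates fitted over ``trend_band`` with ``exclude_band``
    (the oscillation band plus shoulders) left out, which captures both the
    steep low-frequency 1/f and the flat noise floor — and returns the
    frequency of the largest positive residual within ``band``: the
    spectral peak standing out above the background.
    """
    sel_t = ((freqs >= trend_band[0]) & (freqs <= trend_band[1]) & (power > 0)
             & ~((freqs >= exclude_band[0]) & (freqs <= exclude_band[1])))
    if sel_t.sum() < 4:
        raise ValueError("too few bins to fit the aperiodic trend")
    coef = np.polyfit(np.log10(freqs[sel_t]), np.log10(power[sel_t]), 2)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (power > 0)
    if not sel.any():
        raise ValueError("band contains no frequency bins")
    resid = np.log10(power[sel]) - np.polyval(coef, np.log10(freqs[sel]))
    return float(freqs[sel][np.argmax(resid)])


def design_fir(band: tuple[float, float] = DEFAULT_BAND,
               order: int = FIR_ORDER, fs: float = FS_HZ) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) band-pass FIR taps, length
    order+1; group delay = order/2 samples."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError("band must lie inside (0, fs/2)")
    return firwin(order + 1, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_filter(x: np.ndarray, band: tuple[float, float] = DEFAULT_BAND,
                    order: int = FIR_ORDER, fs: float = FS_HZ) -> np.ndarray:
    """One-way (causal) FIR band-pass: output at time t depends only on
    samples at times <= t."""
    x = np.asarray(x, float)
    if len(x) <= order:
        raise ValueError("signal must be longer than the filter order")
    return lfilter(design_fir(band, order, fs), [1.0], x)


def bandpass_phase_amplitude(
    signal,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = FIR_ORDER,
    fs: float = FS_HZ,
) -> AnalyticSignal:
    """Causal band-pass then Hilbert transform over the whole run.

    The filter stage is strictly causal; the analytic (Hilbert) stage is
    computed over the full filtered signal — phase/amplitude are then
    epoched, which avoids per-trial edge artifacts.
    """
    x = signal.values if isinstance(signal, NetworkSignal) else np.asarray(signal, float)
    filt = bandpass_filter(x, band, order, fs)
    analytic = hilbert(filt)
    return AnalyticSignal(
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        filtered=filt,
        band=band,
        fs=fs,
        filter_delay=order / 2.0 * (1000.0 / fs),
    )


def epoch_trials(
    analytic: AnalyticSignal,
    stim_times: np.ndarray,
    window: tuple[int, int] = (-200, 500),
) -> TrialEpochs:
    """Cut per-trial phase/amplitude epochs aligned to stimulus onsets.

    ``window`` is (start, end) in ms relative to onset, inclusive. Trials
    whose window falls outside the signal are dropped (counted in
    ``n_dropped``).
    """
    stim_times = np.asarray(stim_times, dtype=np.int64)
    if np.any(np.diff(stim_times) < 0):
        raise ValueError("stim_times must be sorted")
    t0, t1 = window
    times = np.arange(t0, t1 + 1)
    n = len(analytic.phase)
    keep = (stim_times + t0 >= 0) & (stim_times + t1 < n)
    kept = stim_times[keep]
    if len(kept) == 0:
        raise ValueError("no trial fits inside the signal")
    idx = kept[:, None] + times[None, :]
    return TrialEpochs(
        times=times,
        phase=analytic.phase[idx],
        amplitude=analytic.amplitude[idx],
        n_dropped=int(len(stim_times) - len(kept)),
    )
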