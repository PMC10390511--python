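"""Phase-amplitude coupling.

Two routes are provided: (a) the modulation index — normalized KL
divergence between the phase-binned amplitude distribution and uniform —
computed from band-passed/Hilbert phase and amplitude series, and (b) a
qualitative route based on generalized-Morse-wavelet time-frequency
representations averaged after phase synchronization and folded into a
one-period amplitude-vs-phase curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import fft, ifft, next_fast_len

from .preprocessing import EpochedData, _fir_zero_phase

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 18
DEFAULT_AMP_BAND = (31.0, 90.0)
DEFAULT_SWEEP = (1.0, 20.0, 0.1)
PHASE_HALF_BANDWIDTH = 1.0  # Hz each side of the sweep frequency
MIN_PHASE_EDGE = 0.5  # Hz floor for the phase band's low edge


# ---------------------------------------------------------------------------
# Modulation index (distribution route)
# ---------------------------------------------------------------------------

@dataclass
class PhaseAmplitudeDistribution:
    """Mean high-band amplitude per low-band phase bin on [-pi, pi)."""

    mean_amplitude: np.ndarray  # (n_bins,)
    phase_band: tuple = (np.nan, np.nan)
    amp_band: tuple = DEFAULT_AMP_BAND

    def __post_init__(self) -> None:
        self.mean_amplitude = np.asarray(self.mean_amplitude, dtype=np.float64)
        if self.mean_amplitude.ndim != 1 or self.n_bins < 2:
            raise ValueError("need a 1-D distribution with at least 2 bins")
        if np.any(self.mean_amplitude < 0):
            raise ValueError("mean amplitudes must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.mean_amplitude)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(-np.pi, np.pi, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def p(self) -> np.ndarray:
        """Normalized distribution P(j); uniform if all amplitudes are 0."""
        total = self.mean_amplitude.sum()
        if total == 0:
            return np.full(self.n_bins, 1.0 / self.n_bins)
        return self.mean_amplitude / total

    @property
    def preferred_phase(self) -> float:
        """Circular mean phase weighted by the binned amplitudes."""
        return float(np.angle(np.sum(self.p * np.exp(1j * self.bin_centers))))


@dataclass
class MIResult:
    mi: float
    phase_freq: float
    distribution: PhaseAmplitudeDistribution


def modulation_index_from_distribution(
    dist: PhaseAmplitudeDistribution, phase_freq: float = np.nan
) -> MIResult:
    """MI = (log N - H(P)) / log N with H the Shannon entropy, 0*log0 := 0."""
    p = dist.p
    n = dist.n_bins
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    mi = float((np.log(n) - h) / np.log(n))
    if abs(mi) < 1e-15:  # exact-uniform input leaves only log round-off
        mi = 0.0
    return MIResult(mi=min(max(mi, 0.0), 1.0), phase_freq=phase_freq, distribution=dist)


def bin_amplitude_by_phase(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> PhaseAmplitudeDistribution:
    """Mean amplitude per equal-width phase bin; bins left-closed on [-pi, pi)."""
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # phase == pi lands in the last bin
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return PhaseAmplitudeDistribution(mean_amplitude=means)


# ---------------------------------------------------------------------------
# Band-pass + Hilbert (signal route)
# ---------------------------------------------------------------------------

def _bandpass_taps(lo: float, hi: float, fs: float) -> np.ndarray:
    """Zero-phase FIR band-pass; tap count = 3 cycles of the low edge."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band ({lo}, {hi}) invalid at fs={fs}")
    n = int(round(3 * fs / lo))
    n += 1 - n % 2  # odd
    return sps.firwin(n, [lo, hi], fs=fs, pass_zero=False, window="hamming")


def _phase_and_amplitude(
    x: np.ndarray, fs: float, phase_band: tuple, amp_band: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Hilbert phase of the low band and envelope of the high band,
    with one filter length discarded at each end."""
    tp = _bandpass_taps(*phase_band, fs)
    ta = _bandpass_taps(*amp_band, fs)
    xp = _fir_zero_phase(x, tp)
    xa = _fir_zero_phase(x, ta)
    nfast = next_fast_len(len(x))
    phase = np.angle(sps.hilbert(xp, N=nfast)[: len(x)])
    amp = np.abs(sps.hilbert(xa, N=nfast)[: len(x)])
    trim = max(len(tp), len(ta))
    if 2 * trim >= len(x):
        raise ValueError("signal too short after discarding filter transients")
    return phase[trim:-trim], amp[trim:-trim]


def phase_band_for(freq: float) -> tuple[float, float]:
    """Default sweep phase band: [f-1, f+1] Hz, low edge floored at 0.5 Hz."""
    return (max(freq - PHASE_HALF_BANDWIDTH, MIN_PHASE_EDGE), freq + PHASE_HALF_BANDWIDTH)


def modulation_index_from_signal(
    x: np.ndarray,
    fs: float,
    phase_band: tuple,
    amp_band: tuple = DEFAULT_AMP_BAND,
    n_bins: int = DEFAULT_N_BINS,
) -> MIResult:
    """MI of a single-channel signal via band-pass + Hilbert + phase binning."""
    x = np.asarray(x, dtype=np.float64)
    f_center = 0.5 * (phase_band[0] + phase_band[1])
    if len(x) / fs * phase_band[0] < 10:
        raise ValueError("signal shorter than 10 cycles of the phase band's low edge")
    if phase_band[1] > amp_band[0]:
        logger.warning("phase band %s not below amplitude band %s", phase_band, amp_band)
    phase, amp = _phase_and_amplitude(x, fs, phase_band, amp_band)
    dist = bin_amplitude_by_phase(phase, amp, n_bins)
    dist.phase_band = tuple(phase_band)
    dist.amp_band = tuple(amp_band)
    return modulation_index_from_distribution(dist, phase_freq=f_center)


def mi_phase_sweep(
    x: np.ndarray,
    fs: float,
    sweep: tuple = DEFAULT_SWEEP,
    amp_band: tuple = DEFAULT_AMP_BAND,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """MI over a grid of phase frequencies (default 1-20 Hz, step 0.1).

    The gamma envelope is computed once; each sweep point band-passes the
    phase band [f-1, f+1] Hz (low edge floored at 0.5 Hz).  Returns
    (frequencies, mi values).
    """
    x = np.asarray(x, dtype=np.float64)
    start, stop, step = sweep
    freqs = np.round(np.arange(start, stop + step / 2, step), 10)
    if len(x) / fs * phase_band_for(freqs[0])[0] < 10:
        raise ValueError("signal shorter than 10 cycles of the lowest phase band edge")
    ta = _bandpass_taps(*amp_band, fs)
    nfast = next_fast_len(len(x))
    amp_full = np.abs(sps.hilbert(_fir_zero_phase(x, ta), N=nfast)[: len(x)])
    mis = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        band = phase_band_for(f)
        tp = _bandpass_taps(*band, fs)
        phase_full = np.angle(sps.hilbert(_fir_zero_phase(x, tp), N=nfast)[: len(x)])
        trim = max(len(tp), len(ta))
        dist = bin_amplitude_by_phase(phase_full[trim:-trim], amp_full[trim:-trim], n_bins)
        mis[i] = modulation_index_from_distribution(dist, phase_freq=f).mi
    return freqs, mis


# ---------------------------------------------------------------------------
# Generalized Morse wavelet TFR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TFRParams:
    gamma: float = 3.0
    time_bandwidth: float = 60.0  # P^2 = gamma * beta
    freqs: tuple = tuple(range(1, 101))

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.time_bandwidth <= self.gamma:
            raise ValueError("time-bandwidth product must exceed gamma")

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma

    @property
    def peak_omega(self) -> float:
        return (self.beta / self.gamma) ** (1.0 / self.gamma)


def _morse_filters(n: int, fs: float, params: TFRParams) -> np.ndarray:
    """Frequency-domain analytic Morse wavelets, peak-normalized to 2."""
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    wp = params.peak_omega
    filters = np.zeros((len(params.freqs), n))
    for i, f in enumerate(params.freqs):
        if f >= fs / 2:
            raise ValueError(f"TFR frequency {f} Hz at/above Nyquist ({fs / 2} Hz)")
        scale = wp / (2 * np.pi * f)
        w = omega * scale
        pos = w > 0
        # log-domain evaluation: 2 * (w/wp)^beta * exp(wp^gamma - w^gamma)
        filters[i, pos] = 2.0 * np.exp(
            params.beta * np.log(w[pos] / wp) + (wp**params.gamma - w[pos] ** params.gamma)
        )
    return filters


def tfr_morse(
    x: np.ndarray, fs: float, params: TFRParams = TFRParams(), complex_output: bool = False
) -> np.ndarray:
    """Morse-wavelet transform: (n_freqs, n_samples) moduli (or complex).

    Peak-normalized so a unit real sinusoid at a grid frequency has
    modulus 1.0 on its own row.
    """
    x = np.asarray(x, dtype=np.float64)
    X = fft(x)
    W = ifft(X[np.newaxis, :] * _morse_filters(len(x), fs, params), axis=1)
    return W if complex_output else np.abs(W)


def phase_synchronized_average(
    ep: EpochedData,
    f_low: float,
    params: TFRParams = TFRParams(),
    channel: int = 0,
    return_shifts: bool = False,
):
    """Average single-channel epoch TFRs after aligning their f_low phase.

    The f_low phase is read from the complex wavelet coefficient at the
    epoch midpoint; each epoch's TFR is circularly shifted rightward by
    phase/(2*pi*f_low) seconds (epochs whose oscillation started earlier,
    i.e. with larger midpoint phase, move further right), so all epochs
    share zero midpoint phase before averaging.
    """
    if ep.n_epochs < 1:
        raise ValueError("need at least one epoch")
    freqs = np.asarray(params.freqs, dtype=float)
    row = int(np.argmin(np.abs(freqs - f_low)))
    n = ep.data.shape[2]
    mid = n // 2
    acc = np.zeros((len(freqs), n))
    shifts = np.empty(ep.n_epochs, dtype=int)
    for e in range(ep.n_epochs):
        W = tfr_morse(ep.data[e, channel], ep.fs, params, complex_output=True)
        phi = np.angle(W[row, mid])
        k = int(round(phi / (2 * np.pi * f_low) * ep.fs))
        shifts[e] = k
        acc += np.abs(np.roll(W, k, axis=1))
    avg = acc / ep.n_epochs
    return (avg, shifts) if return_shifts else avg


def fold_tfr(
    avg_tfr: np.ndarray,
    f_low: float,
    fs: float,
    freqs=None,
    amp_band: tuple = DEFAULT_AMP_BAND,
) -> np.ndarray:
    """Fold an averaged TFR into a one-period amplitude-vs-phase curve.

    The time axis is cut into f_low-periods (trimmed to an integer number
    of periods), the periods are averaged, and the rows within amp_band
    are averaged, yielding a curve of round(fs / f_low) samples.
    """
    avg_tfr = np.atleast_2d(np.asarray(avg_tfr, dtype=np.float64))
    n_freqs, n_samples = avg_tfr.shape
    if freqs is None:
        freqs = np.arange(1, n_freqs + 1, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    period = fs / f_low
    n_periods = int(np.floor(n_samples / period))
    if n_periods < 1:
        raise ValueError("TFR shorter than one period of f_low")
    keep = int(round(n_periods * period))
    rows = (freqs >= amp_band[0]) & (freqs <= amp_band[1])
    if not rows.any():
        raise ValueError("no TFR rows inside the amplitude band")
    trace = avg_tfr[rows, :keep].mean(axis=0)
    curve_len = int(round(period))
    t = np.arange(keep)
    bins = np.floor((t % period) / period * curve_len).astype(int)
    bins = np.clip(bins, 0, curve_len - 1)
    sums = np.bincount(bins, weights=trace, minlength=curve_len)
    counts = np.bincount(bins, minlength=curve_len)
    return sums / counts
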