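"""Bartlett-averaged amplitude spectra and canonical band amplitudes.

Amplitude convention: one-sided 2/L scaling, so a unit-amplitude sinusoid
at an integer frequency reads 1.0 at its bin.  Spectra are tabulated at
1-Hz spacing over 1-100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import EpochedData

FREQ_LO, FREQ_HI = 1, 100


@dataclass
class Spectrum:
    """channels x frequency-bin amplitude table."""

    amplitude: np.ndarray
    freqs: np.ndarray
    kind: str = "raw"
    channel_labels: tuple = ()

    def __post_init__(self) -> None:
        self.amplitude = np.atleast_2d(np.asarray(self.amplitude, dtype=np.float64))
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.amplitude.shape[1] != len(self.freqs):
            raise ValueError("amplitude columns must match freqs")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite")
        if self.kind not in ("raw", "aperiodic_removed"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "raw" and np.any(self.amplitude < 0):
            raise ValueError("raw amplitudes must be non-negative")

    def bin_index(self, f: float) -> int:
        idx = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[idx] - f) > 1e-9:
            raise ValueError(f"frequency {f} Hz not on the spectrum grid")
        return idx

    def copy_with(self, **kw) -> "Spectrum":
        return replace(self, **kw)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (FREQ_LO <= self.lo <= self.hi <= FREQ_HI):
            raise ValueError(f"band {self.name}: need 1 <= lo <= hi <= 100")

    @property
    def n_bins(self) -> int:
        return self.hi - self.lo + 1


#: band edges used for all statistics (default preset)
BANDS_STATS = {
    "theta": BandDefinition("theta", 4, 7),
    "alpha": BandDefinition("alpha", 8, 12),
    "beta": BandDefinition("beta", 13, 30),
    "gamma": BandDefinition("gamma", 31, 90),
}

#: alternative preset with the wider theta / narrower alpha edges
BANDS_ALT = {
    "theta": BandDefinition("theta", 4, 8),
    "alpha": BandDefinition("alpha", 9, 12),
    "beta": BandDefinition("beta", 13, 30),
    "gamma": BandDefinition("gamma", 31, 90),
}

BAND_PRESETS = {"stats": BANDS_STATS, "alt": BANDS_ALT}


def bartlett_spectrum(ep: EpochedData, f_lo: int = FREQ_LO, f_hi: int = FREQ_HI) -> Spectrum:
    """Average one-sided amplitude spectrum over non-overlapping epochs.

    Each epoch's DFT magnitude is scaled by 2/L (unit sinusoid -> 1.0);
    the mean over epochs is returned on the integer-Hz grid f_lo..f_hi.
    Epochs must span an integer number of seconds so integer frequencies
    fall exactly on DFT bins.
    """
    if ep.n_epochs == 0:
        raise ValueError("no epochs")
    if abs(ep.epoch_length - round(ep.epoch_length)) > 1e-9:
        raise ValueError("epoch length must be an integer number of seconds")
    L = ep.data.shape[2]
    amp = 2.0 / L * np.abs(np.fft.rfft(ep.data, axis=2))  # (epochs, ch, bins)
    mean_amp = amp.mean(axis=0)
    bin_freqs = np.fft.rfftfreq(L, d=1.0 / ep.fs)
    freqs = np.arange(f_lo, f_hi + 1, dtype=float)
    # integer frequencies sit exactly on bins: bin index = f * epoch_length
    idx = np.array([int(round(f * ep.epoch_length)) for f in freqs])
    if idx[-1] >= len(bin_freqs) or np.any(np.abs(bin_freqs[idx] - freqs) > 1e-9):
        raise ValueError("requested frequencies not resolvable at this fs/epoch length")
    return Spectrum(
        amplitude=mean_amp[:, idx], freqs=freqs, kind="raw",
        channel_labels=ep.channel_labels,
    )


def notch_interpolate(spec: Spectrum, f0: float = 50.0) -> Spectrum:
    """Replace amp(f0) by the mean of amp(f0-1) and amp(f0+1), exactly."""
    i0 = spec.bin_index(f0)
    ilo, ihi = spec.bin_index(f0 - 1), spec.bin_index(f0 + 1)
    amp = spec.amplitude.copy()
    amp[:, i0] = 0.5 * (amp[:, ilo] + amp[:, ihi])
    return spec.copy_with(amplitude=amp)


def band_amplitude(spec: Spectrum, band: BandDefinition) -> np.ndarray:
    """Unweighted mean amplitude over the band's bins (lo..hi inclusive)."""
    ilo, ihi = spec.bin_index(band.lo), spec.bin_index(band.hi)
    return spec.amplitude[:, ilo : ihi + 1].mean(axis=1)


def band_table(spec: Spectrum, bands: dict | None = None) -> dict:
    """Per-band per-channel amplitudes, default band preset = 'stats'."""
    bands = bands or BANDS_STATS
    return {name: band_amplitude(spec, b) for name, b in bands.items()}
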