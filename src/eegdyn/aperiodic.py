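"""Split-band parameterization of amplitude spectra.

Each band segment (low 1-25 Hz, high 26-90 Hz by default) is modeled in
log10-amplitude as a line over log10-frequency (the aperiodic component,
"fixed" form: offset - exponent * log10 f) plus up to ``max_peaks``
Gaussian humps over linear frequency.  The two segments are fitted
independently; the split frequency is a plain parameter so robustness
checks (e.g. a 30-Hz split) are one call away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .preprocessing import EpochedData
from .spectral import Spectrum, bartlett_spectrum

SEGMENT_LOW = (1, 25)
SEGMENT_HIGH = (26, 90)
MAX_PEAKS_LOW = 2
MAX_PEAKS_HIGH = 0

PEAK_WIDTH_BOUNDS = (1.0, 12.0)  # Hz
MIN_PEAK_HEIGHT = 0.05  # log10 units


@dataclass
class AperiodicFit:
    """Aperiodic line plus peaks for one channel on one band segment."""

    segment: tuple
    offset: float
    exponent: float
    peaks: list = field(default_factory=list)  # (center Hz, height log10, width Hz)
    r_squared: float = np.nan

    def aperiodic_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def aperiodic_linear(self, freqs: np.ndarray) -> np.ndarray:
        return 10.0 ** self.aperiodic_log10(freqs)

    def model_log10(self, freqs: np.ndarray) -> np.ndarray:
        y = self.aperiodic_log10(freqs)
        for c, h, w in self.peaks:
            y = y + h * np.exp(-0.5 * ((freqs - c) / w) ** 2)
        return y


def _ols_line(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares y = offset - exponent * logf."""
    slope, intercept = np.polyfit(logf, y, 1)
    return float(intercept), float(-slope)


def _decile_line(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Deterministic initial line through the first/last decile means."""
    k = max(1, len(y) // 10)
    x0, y0 = logf[:k].mean(), y[:k].mean()
    x1, y1 = logf[-k:].mean(), y[-k:].mean()
    if x1 == x0:
        return float(y.mean()), 0.0
    slope = (y1 - y0) / (x1 - x0)
    return float(y0 - slope * x0), float(-slope)


def _seed_peaks(freqs: np.ndarray, resid: np.ndarray, max_peaks: int) -> list:
    """Greedy peak seeding on positive residuals (largest first)."""
    resid = resid.copy()
    peaks = []
    for _ in range(max_peaks):
        i = int(np.argmax(resid))
        h = resid[i]
        if h < MIN_PEAK_HEIGHT:
            break
        c = freqs[i]
        # half-height extent on each side -> sigma estimate
        half = h / 2.0
        li = i
        while li > 0 and resid[li] > half:
            li -= 1
        ri = i
        while ri < len(resid) - 1 and resid[ri] > half:
            ri += 1
        fwhm = max(freqs[ri] - freqs[li], 1.0)
        w = float(np.clip(fwhm / 2.355, *PEAK_WIDTH_BOUNDS))
        peaks.append((float(c), float(h), w))
        resid -= h * np.exp(-0.5 * ((freqs - c) / w) ** 2)
    return peaks


def _fit_channel(freqs: np.ndarray, amp: np.ndarray, segment: tuple, max_peaks: int) -> AperiodicFit:
    logf = np.log10(freqs)
    y = np.log10(amp)

    off, expo = _decile_line(logf, y)
    if max_peaks == 0:
        off, expo = _ols_line(logf, y)
        peaks: list = []
    else:
        peaks = _seed_peaks(freqs, y - (off - expo * logf), max_peaks)
        # re-estimate the line on peak-subtracted data
        y_flat = y.copy()
        for c, h, w in peaks:
            y_flat -= h * np.exp(-0.5 * ((freqs - c) / w) ** 2)
        off, expo = _ols_line(logf, y_flat)

        # joint nonlinear refinement of line + Gaussians
        p0, lb, ub = [off, expo], [-np.inf, -np.inf], [np.inf, np.inf]
        for c, h, w in peaks:
            p0 += [c, h, w]
            lb += [segment[0], 0.0, PEAK_WIDTH_BOUNDS[0]]
            ub += [segment[1], np.inf, PEAK_WIDTH_BOUNDS[1]]

        npk = len(peaks)

        def residual(p):
            model = p[0] - p[1] * logf
            for k in range(npk):
                c, h, w = p[2 + 3 * k : 5 + 3 * k]
                model = model + h * np.exp(-0.5 * ((freqs - c) / w) ** 2)
            return model - y

        if npk:
            sol = least_squares(
                residual, np.clip(p0, lb, ub), bounds=(lb, ub),
                xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=500,
            )
            off, expo = float(sol.x[0]), float(sol.x[1])
            peaks = [
                (float(sol.x[2 + 3 * k]), float(sol.x[3 + 3 * k]), float(sol.x[4 + 3 * k]))
                for k in range(npk)
                if sol.x[3 + 3 * k] >= MIN_PEAK_HEIGHT
            ]

    fit = AperiodicFit(segment=tuple(segment), offset=off, exponent=expo, peaks=peaks)
    resid = fit.model_log10(freqs) - y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    fit.r_squared = min(max(r2, 0.0), 1.0)
    return fit


def fit_segment(spec: Spectrum, segment: tuple = SEGMENT_LOW, max_peaks: int = MAX_PEAKS_LOW,
                as_power: bool = False) -> list:
    """Fit the aperiodic + peaks model per channel on one band segment.

    Set ``as_power=True`` to fit squared (power) spectra; the exponent
    then doubles relative to the amplitude convention.
    """
    lo, hi = segment
    ilo, ihi = spec.bin_index(lo), spec.bin_index(hi)
    freqs = spec.freqs[ilo : ihi + 1]
    amps = spec.amplitude[:, ilo : ihi + 1]
    if np.any(amps <= 0):
        raise ValueError(
            "spectrum has non-positive amplitudes on the segment; "
            "fit raw spectra (not 1/f-removed ones)"
        )
    if as_power:
        amps = amps**2
    return [_fit_channel(freqs, a, (lo, hi), max_peaks) for a in amps]


def subtract_aperiodic(spec: Spectrum, low_fits: list, high_fits: list) -> Spectrum:
    """Subtract the fitted aperiodic curves (linear units) per segment.

    Bins inside the low fits' segment use the low curve, bins inside the
    high fits' segment the high curve; bins beyond both (e.g. 91-100 Hz)
    pass through unchanged.  Negative residuals are permitted.
    """
    if len(low_fits) != spec.amplitude.shape[0] or len(high_fits) != spec.amplitude.shape[0]:
        raise ValueError("need one fit per channel for each segment")
    amp = spec.amplitude.copy()
    for fits in (low_fits, high_fits):
        lo, hi = fits[0].segment
        ilo, ihi = spec.bin_index(lo), spec.bin_index(hi)
        f = spec.freqs[ilo : ihi + 1]
        for ch, fit in enumerate(fits):
            amp[ch, ilo : ihi + 1] -= fit.aperiodic_linear(f)
    return spec.copy_with(amplitude=amp, kind="aperiodic_removed")


def split_half_reliability(
    eps: list,
    segment: tuple = SEGMENT_LOW,
    max_peaks: int = MAX_PEAKS_LOW,
) -> dict:
    """Split-half reliability of the 1/f parameters across a cohort.

    For each participant's EpochedData the epochs are split into first
    and second halves, each half is fitted, and the across-participant
    Pearson r between half estimates is returned per channel for both
    the exponent and the offset.
    """
    if len(eps) < 3:
        raise ValueError("split-half reliability needs at least 3 participants")
    halves: dict[str, list] = {"first": [], "second": []}
    for ep in eps:
        n = ep.n_epochs
        if n < 4:
            raise ValueError("need at least 2 epochs per half")
        for name, sl in (("first", slice(0, n // 2)), ("second", slice(n // 2, 2 * (n // 2)))):
            half = EpochedData(
                data=ep.data[sl], fs=ep.fs, epoch_length=ep.epoch_length,
                channel_labels=ep.channel_labels,
            )
            fits = fit_segment(bartlett_spectrum(half), segment, max_peaks)
            halves[name].append(fits)
    n_ch = len(halves["first"][0])
    out = {}
    for param in ("exponent", "offset"):
        a = np.array([[getattr(f, param) for f in fits] for fits in halves["first"]])
        b = np.array([[getattr(f, param) for f in fits] for fits in halves["second"]])
        out[param] = np.array([pearsonr(a[:, c], b[:, c])[0] for c in range(n_ch)])
    return out
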