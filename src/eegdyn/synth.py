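"""Synthetic multi-channel EEG with known ground truth.

Recordings are built by spectral shaping: the target one-sided amplitude
profile — a two-segment power law joined (without smoothing) at the split
frequency, plus Gaussian oscillation humps — is imposed on random-phase
Fourier coefficients, giving exact control of the band-wise log-log
slopes.  A phase-amplitude-coupled component adds a low-frequency
sinusoid and band-limited carrier noise whose envelope follows
baseline * (1 + depth * cos(phase - preferred_phase)).

All randomness flows from one cohort seed through numpy SeedSequence
spawn keys (participant index, condition index), so any recording is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Recording
from .montage import MONTAGE_32_LABELS, montage_positions

SPLIT_HZ = 25.0  # low band ends here; high band starts just above
PROFILE_FLOOR_HZ = 0.5  # no aperiodic energy injected below this


@dataclass(frozen=True)
class CohortSpec:
    n_participants: int
    n_channels: int = 32
    fs: float = 250.0
    duration: float = 60.0
    seed: int = 0
    montage_name: str = "standard-32"

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.fs < 200:
            raise ValueError("fs must be >= 200 Hz so the 90-Hz band is below Nyquist")
        if self.duration < 2:
            raise ValueError("duration must be >= 2 s (at least 2 one-second epochs)")

    @property
    def channel_labels(self) -> tuple:
        return MONTAGE_32_LABELS[: self.n_channels]


@dataclass(frozen=True)
class Oscillation:
    """Gaussian spectral hump: center (Hz), amplitude, bandwidth (Hz sd)."""

    center: float
    amplitude: float
    bandwidth: float
    gain: tuple  # per-channel, entries >= 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.bandwidth <= 0:
            raise ValueError("amplitude must be >= 0 and bandwidth > 0")
        if any(g < 0 for g in self.gain):
            raise ValueError("gain entries must be >= 0")


@dataclass(frozen=True)
class PACParams:
    """Low-frequency phase driver modulating a band-limited carrier."""

    phase_freq: float
    depth: float  # m in [0, 1]
    gain: tuple
    carrier_band: tuple = (31.0, 90.0)
    preferred_phase: float = 0.0
    phase_amp: float = 1.0
    carrier_amp: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")
        if any(g < 0 for g in self.gain):
            raise ValueError("gain entries must be >= 0")


@dataclass(frozen=True)
class ConditionParams:
    aperiodic_low: tuple = (0.0, 1.0)  # (offset log10, exponent) for 1-25 Hz
    aperiodic_high: tuple = (0.0, 1.0)  # for 26-90 Hz (extended to Nyquist)
    oscillations: tuple = ()
    pac: PACParams | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for _, expo in (self.aperiodic_low, self.aperiodic_high):
            if expo < 0:
                raise ValueError("exponents must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """Between-condition shifts: parameter key -> (mean shift, between-
    participant SD).  Keys: low_offset, low_exponent, high_offset,
    high_exponent, pac_depth, noise_sd, osc_<name>_amplitude."""

    shifts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (_, sd) in self.shifts.items():
            if sd < 0:
                raise ValueError(f"shift SD for {key!r} must be >= 0")

    def draw(self, rng: np.random.Generator) -> dict:
        return {k: m + sd * rng.standard_normal() for k, (m, sd) in self.shifts.items()}


def apply_shifts(params: ConditionParams, values: dict) -> ConditionParams:
    """Return a copy of *params* with generative parameters shifted."""
    low = list(params.aperiodic_low)
    high = list(params.aperiodic_high)
    oscs = list(params.oscillations)
    pac = params.pac
    noise_sd = params.noise_sd
    for key, dv in values.items():
        if key == "low_offset":
            low[0] += dv
        elif key == "low_exponent":
            low[1] = max(low[1] + dv, 0.0)
        elif key == "high_offset":
            high[0] += dv
        elif key == "high_exponent":
            high[1] = max(high[1] + dv, 0.0)
        elif key == "pac_depth":
            if pac is None:
                raise ValueError("pac_depth shift without a PAC component")
            pac = replace(pac, depth=float(np.clip(pac.depth + dv, 0.0, 1.0)))
        elif key == "noise_sd":
            noise_sd = max(noise_sd + dv, 0.0)
        elif key.startswith("osc_") and key.endswith("_amplitude"):
            name = key[4:-10]
            hit = [i for i, o in enumerate(oscs) if o.name == name]
            if not hit:
                raise ValueError(f"no oscillation named {name!r}")
            for i in hit:
                oscs[i] = replace(oscs[i], amplitude=max(oscs[i].amplitude + dv, 0.0))
        else:
            raise ValueError(f"unknown effect key {key!r}")
    return ConditionParams(
        aperiodic_low=tuple(low), aperiodic_high=tuple(high),
        oscillations=tuple(oscs), pac=pac, noise_sd=noise_sd,
    )


def template_gains(kind: str, montage_name: str = "standard-32", width: float = 0.45) -> tuple:
    """Fixed spatial gain templates (Gaussian falloff from a scalp focus)."""
    foci = {
        "frontal": (0.0, 0.70),
        "posterior": (0.0, -0.75),
        "occipital": (0.0, -0.90),
        "uniform": None,
    }
    if kind not in foci:
        raise ValueError(f"unknown template {kind!r}; choose from {sorted(foci)}")
    pos = montage_positions(montage_name)
    if foci[kind] is None:
        return tuple(1.0 for _ in pos)
    fx, fy = foci[kind]
    return tuple(
        float(np.exp(-((x - fx) ** 2 + (y - fy) ** 2) / (2 * width**2)))
        for x, y in pos.values()
    )


def _aperiodic_profile(freqs: np.ndarray, params: ConditionParams, split_hz: float) -> np.ndarray:
    """Target one-sided amplitude (unit-sinusoid convention) per frequency."""
    prof = np.zeros_like(freqs)
    lo_off, lo_exp = params.aperiodic_low
    hi_off, hi_exp = params.aperiodic_high
    low = (freqs >= PROFILE_FLOOR_HZ) & (freqs <= split_hz)
    high = freqs > split_hz
    with np.errstate(over="ignore"):
        prof[low] = 10.0**lo_off * freqs[low] ** (-lo_exp)
        prof[high] = 10.0**hi_off * freqs[high] ** (-hi_exp)
    return prof


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, band: tuple) -> np.ndarray:
    """Unit-RMS noise with flat amplitude inside *band*, random phases."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(len(freqs), dtype=complex)
    spec[mask] = np.exp(2j * np.pi * rng.random(mask.sum()))
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(
    spec: CohortSpec,
    params: ConditionParams,
    participant_seed,
    state: str = "other",
    participant_id: str = "",
    split_hz: float = SPLIT_HZ,
) -> Recording:
    """One synthetic recording; deterministic given *participant_seed*."""
    n = int(round(spec.duration * spec.fs))
    if n < 2 * spec.fs:
        raise ValueError("duration/fs give fewer than 2 one-second epochs")
    rng = np.random.default_rng(participant_seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    n_ch = spec.n_channels

    base_prof = _aperiodic_profile(freqs, params, split_hz)
    # Calibration: with random-phase shaping, the expected 1-s-epoch
    # Bartlett amplitude of the synthesized signal is the target profile
    # times sqrt(duration) (bins aggregated per 1-Hz bin) times the
    # Rayleigh mean factor sqrt(pi/4); divide both out so the analysis
    # convention (unit sinusoid -> 1.0) recovers the profile directly.
    scale = (n / 2.0) / (np.sqrt(spec.duration) * np.sqrt(np.pi / 4.0))
    data = np.empty((n_ch, n))
    for ch in range(n_ch):
        prof = base_prof.copy()
        for osc in params.oscillations:
            g = osc.gain[ch] if len(osc.gain) > ch else 0.0
            prof += osc.amplitude * g * np.exp(
                -0.5 * ((freqs - osc.center) / osc.bandwidth) ** 2
            )
        phases = np.exp(2j * np.pi * rng.random(len(freqs)))
        coeffs = prof * scale * phases
        coeffs[0] = 0.0
        data[ch] = np.fft.irfft(coeffs, n=n)

    if params.pac is not None:
        p = params.pac
        t = np.arange(n) / spec.fs
        theta0 = 2 * np.pi * rng.random()
        phase = 2 * np.pi * p.phase_freq * t + theta0
        carrier = _bandlimited_noise(rng, n, spec.fs, p.carrier_band)
        comp = p.phase_amp * np.cos(phase) + p.carrier_amp * carrier * (
            1.0 + p.depth * np.cos(phase - p.preferred_phase)
        )
        for ch in range(n_ch):
            g = p.gain[ch] if len(p.gain) > ch else 0.0
            data[ch] += g * comp

    if params.noise_sd > 0:
        data += params.noise_sd * rng.standard_normal((n_ch, n))

    return Recording(
        data=data, fs=spec.fs, channel_labels=spec.channel_labels,
        state=state, participant_id=participant_id,
        meta={"seed_repr": str(participant_seed)},
    )


def participant_seed(cohort_seed: int, participant: int, condition: int) -> np.random.SeedSequence:
    """Splittable counter scheme: one stream per (participant, condition)."""
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(participant, condition))


def generate_cohort(
    spec: CohortSpec,
    base: ConditionParams,
    effect: EffectSpec,
    states: tuple = ("count_easy", "count_hard"),
) -> list:
    """Two-condition cohort: list of (Recording_A, Recording_B) pairs.

    Each participant draws a personal parameter shift from *effect*
    (applied to condition B), and condition order is counterbalanced and
    stored in each recording's meta.
    """
    pairs = []
    for i in range(spec.n_participants):
        shift_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(i, 2))
        )
        params_b = apply_shifts(base, effect.draw(shift_rng))
        pid = f"P{i:03d}"
        order = ("A", "B") if i % 2 == 0 else ("B", "A")
        rec_a = generate_recording(
            spec, base, participant_seed(spec.seed, i, 0), states[0], pid
        )
        rec_b = generate_recording(
            spec, params_b, participant_seed(spec.seed, i, 1), states[1], pid
        )
        rec_a.meta["order"] = rec_b.meta["order"] = "-".join(order)
        pairs.append((rec_a, rec_b))
    return pairs


def write_cohort(pairs, outdir) -> str:
    """Write cohort recordings as HDF5 plus a TSV manifest; returns manifest path."""
    from pathlib import Path

    from .io import write_hdf5

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "cohort_manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("participant\tcondition\tstate\torder\tpath\n")
        for rec_a, rec_b in pairs:
            for cond, rec in (("A", rec_a), ("B", rec_b)):
                fname = f"{rec.participant_id}_{cond}_{rec.state}.h5"
                write_hdf5(rec, outdir / fname)
                fh.write(
                    f"{rec.participant_id}\t{cond}\t{rec.state}\t"
                    f"{rec.meta.get('order', '')}\t{fname}\n"
                )
    return str(manifest)
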