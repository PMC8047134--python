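"""Synthetic EEG generators emulating motor-imagery and SSVEP recordings,
plus the shared preprocessing (zero-phase band-pass, Welch spectra).

The generators are first-class study material, not test scaffolding: they
produce class-balanced epoch sets with the biomarkers the real paradigms
carry.

Motor imagery (two channels, C3/C4, 3 s at 250 Hz): a 10 Hz mu rhythm with
a slowly varying random envelope and random phase per trial, superimposed
on 1/f plus white noise.  Imagining the left hand desynchronizes the
contralateral (right) motor cortex, attenuating the C4 mu amplitude by the
ERD depth; right-hand imagery attenuates C3.

SSVEP (one channel, Oz, 2 s at 250 Hz): a stimulus-locked sinusoid at the
class frequency (fixed phase across trials — the response is phase-locked
to the flicker, which is what makes trial averaging a valid template
extractor) plus a weaker first harmonic over 1/f and white noise.

All output is band-limited 0.5-20 Hz.  Amplitudes are in microvolts at
magnitudes typical of scalp EEG (mu and SSVEP oscillations of a few uV over
a comparable noise floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .augmentation import EpochSet

__all__ = [
    "FixtureSpec",
    "make_mi_fixture",
    "make_ssvep_fixture",
    "bandpass",
    "power_spectrum",
    "pink_noise",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic EEG generators.

    ``mu_amp`` / ``ssvep_amp`` are oscillation amplitudes in uV;
    ``erd_depth`` in [0, 1] is the fractional mu attenuation on the
    contralateral channel; ``pink_sigma``/``white_sigma`` set the noise
    floor (uV RMS); ``pink_exponent`` is the 1/f^a slope.
    """

    modality: str  # "MI" | "SSVEP"
    fs: float = 250.0
    duration_s: float = 3.0
    n_trials_per_class: int = 40
    seed: int = 0
    band: tuple[float, float] = (0.5, 20.0)
    # MI parameters
    mu_hz: float = 10.0
    mu_amp: float = 6.0
    erd_depth: float = 0.8
    # SSVEP parameters
    ssvep_freqs: tuple[float, ...] = (10.0, 11.0)
    ssvep_amp: float = 4.0
    harmonic_ratio: float = 0.25
    # noise
    pink_exponent: float = 1.0
    pink_sigma: float = 1.5
    white_sigma: float = 0.75

    def __post_init__(self) -> None:
        if self.modality not in ("MI", "SSVEP"):
            raise ValueError("modality must be 'MI' or 'SSVEP'")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integral sample count")
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must lie in [0, 1]")
        top = self.mu_hz if self.modality == "MI" else 2 * max(self.ssvep_freqs)
        if self.fs <= 2 * top:
            raise ValueError("fs must exceed twice the highest signal frequency")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.duration_s)

    @classmethod
    def mi(cls, **overrides) -> "FixtureSpec":
        base = cls(modality="MI", duration_s=3.0, pink_sigma=2.0, white_sigma=1.0)
        return replace(base, **overrides) if overrides else base

    @classmethod
    def ssvep(cls, **overrides) -> "FixtureSpec":
        base = cls(modality="SSVEP", duration_s=2.0, n_trials_per_class=20)
        return replace(base, **overrides) if overrides else base


def pink_noise(
    rng: np.random.Generator, n: int, exponent: float, sigma: float
) -> np.ndarray:
    """1/f^exponent noise with the requested RMS, zero mean."""
    if sigma == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec[0] = 0.0
    spec[1:] = spec[1:] / f[1:] ** (exponent / 2.0)
    out = np.fft.irfft(spec, n)
    return sigma * out / out.std()


def _noise(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    return pink_noise(
        rng, spec.n_samples, spec.pink_exponent, spec.pink_sigma
    ) + spec.white_sigma * rng.standard_normal(spec.n_samples)


def _mu_envelope(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    """Slow random amplitude modulation so no two trials are identical."""
    n = spec.n_samples
    slow = pink_noise(rng, n, 2.0, 1.0)
    env = 1.0 + 0.3 * slow
    return np.clip(env, 0.2, None)


def make_mi_fixture(spec: FixtureSpec) -> EpochSet:
    """Two-class motor-imagery set over C3/C4 with lateralized mu attenuation."""
    if spec.modality != "MI":
        raise ValueError("spec.modality must be 'MI'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    class_names = ["LH-MI", "RH-MI"]
    channel_names = ["C3", "C4"]
    data = np.empty((2 * spec.n_trials_per_class, 2, n))
    labels = np.empty(2 * spec.n_trials_per_class, dtype=np.int64)
    row = 0
    for k, _ in enumerate(class_names):
        # LH imagery attenuates the contralateral C4; RH imagery attenuates C3
        atten = np.array([1.0, 1.0 - spec.erd_depth] if k == 0 else [1.0 - spec.erd_depth, 1.0])
        for _trial in range(spec.n_trials_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            env = _mu_envelope(rng, spec)
            mu = env * np.sin(2 * np.pi * spec.mu_hz * t + phase)
            gain = spec.mu_amp * rng.lognormal(0.0, 0.1)
            for c in range(2):
                data[row, c] = gain * atten[c] * mu + _noise(rng, spec)
            labels[row] = k
            row += 1
    epochs = EpochSet(data, labels, spec.fs, channel_names, class_names)
    return bandpass(epochs, *spec.band)


def make_ssvep_fixture(spec: FixtureSpec) -> EpochSet:
    """Single-channel (Oz) SSVEP set, one class per stimulus frequency."""
    if spec.modality != "SSVEP":
        raise ValueError("spec.modality must be 'SSVEP'")
    freqs = spec.ssvep_freqs
    if len(freqs) >= 2:
        resolvable = 2.0 / spec.duration_s
        gaps = np.diff(sorted(freqs))
        if (gaps < resolvable).any():
            import warnings

            warnings.warn(
                f"class frequencies closer than {resolvable:g} Hz are not "
                "spectrally resolvable at this epoch length",
                stacklevel=2,
            )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    class_names = [f"{f:g}Hz" for f in freqs]
    data = np.empty((len(freqs) * spec.n_trials_per_class, 1, n))
    labels = np.empty(len(freqs) * spec.n_trials_per_class, dtype=np.int64)
    phases = rng.uniform(0, 2 * np.pi, size=(len(freqs), 2))  # fixed per class
    row = 0
    for k, f in enumerate(freqs):
        locked = spec.ssvep_amp * (
            np.sin(2 * np.pi * f * t + phases[k, 0])
            + spec.harmonic_ratio * np.sin(2 * np.pi * 2 * f * t + phases[k, 1])
        )
        for _trial in range(spec.n_trials_per_class):
            data[row, 0] = locked + _noise(rng, spec)
            labels[row] = k
            row += 1
    epochs = EpochSet(data, labels, spec.fs, ["Oz"], class_names)
    return bandpass(epochs, *spec.band)


def bandpass(epochs: EpochSet, low_hz: float, high_hz: float) -> EpochSet:
    """Zero-phase 4th-order Butterworth band-pass applied per trial/channel."""
    if not 0 < low_hz < high_hz < epochs.fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    sos = scipy.signal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=epochs.fs, output="sos"
    )
    data = scipy.signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(
        data, epochs.labels.copy(), epochs.fs,
        list(epochs.channel_names), list(epochs.class_names),
    )


def power_spectrum(
    signal: np.ndarray, fs: float, nperseg: int | None = None, window: str = "hann"
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectrum along the last axis.

    The default segment length is min(n, 2 * fs) samples, giving at least
    0.5 Hz bin spacing on epochs of 2 s or longer (enough to separate the
    10 and 11 Hz SSVEP classes by peak location).  Tones separated by
    exactly the bin spacing only resolve into two distinct maxima with the
    rectangular window (``window='boxcar'``); the Hann default trades that
    edge case for sidelobe suppression.
    """
    signal = np.asarray(signal, dtype=np.float64)
    n = signal.shape[-1]
    if nperseg is None:
        nperseg = min(n, round(2 * fs))
    return scipy.signal.welch(signal, fs=fs, nperseg=nperseg, window=window, axis=-1)


def spectral_peak_hz(signal_1d: np.ndarray, fs: float) -> float:
    """Frequency of the Welch power maximum of a single-channel signal."""
    f, p = power_spectrum(signal_1d, fs)
    return float(f[int(np.argmax(p))])
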