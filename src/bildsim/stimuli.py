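"""Acoustic stimulus construction for the binaural word-in-noise task.

The task presents monosyllabic target words over headphones, either diotically
(in phase at the two ears, ``T0``) or antiphasically (the target inverted in
one ear, ``Tpi``); the masker, when present, is a noise shaped to the
long-term average spectrum (LTAS) of the target corpus and is always diotic
(``M0``).  This module estimates the corpus LTAS, synthesizes spectrally
shaped masking noise, and assembles stereo trial waveforms at a commanded
signal-to-noise ratio (SNR).

Levels follow the conventions of the remote protocol: digital full scale maps
to a configurable "comfortable" playback reference (nominally ~60 dB SPL at a
50% system-volume setting), masked stimuli are specified in dB SNR re the
masker RMS, and quiet stimuli in dB re the comfortable reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.io import wavfile as _wavfile

__all__ = [
    "Condition",
    "Spectrum",
    "TrialStimulus",
    "third_octave_centers",
    "compute_ltas",
    "shape_noise",
    "assemble_trial",
    "synthesize_corpus",
    "read_wav_mono",
    "write_wav",
]

#: digital-full-scale RMS that corresponds to the comfortable reference level
COMFORTABLE_REFERENCE_DB = 60.0


class Condition(enum.Enum):
    """Stimulus condition of a threshold-estimation run.

    ``M0T0``: diotic masker, diotic target.  ``M0TPI``: diotic masker, target
    inverted in the right channel.  ``QUIET``: diotic target, masker amplitude
    zero (levels then expressed re the comfortable reference).
    """

    QUIET = "quiet"
    M0T0 = "m0t0"
    M0TPI = "m0tpi"

    @property
    def is_masked(self) -> bool:
        return self is not Condition.QUIET


def third_octave_centers(fmin: float = 100.0, fmax: float = 10_000.0) -> np.ndarray:
    """Base-2 one-third-octave band center frequencies covering [fmin, fmax]."""
    n_lo = int(np.ceil(3 * np.log2(fmin / 1000.0)))
    n_hi = int(np.floor(3 * np.log2(fmax / 1000.0)))
    return 1000.0 * 2.0 ** (np.arange(n_lo, n_hi + 1) / 3.0)


@dataclass
class Spectrum:
    """Band-averaged power-density spectrum (the LTAS shaping target).

    ``magnitude_db`` holds the mean power spectral density within each band in
    dB re the corpus mean-square-per-Hz, so a unit-RMS white input yields a
    flat spectrum near 0 dB.  Frequencies are strictly increasing, magnitudes
    finite, and at least 10 bands are required.
    """

    center_frequencies: np.ndarray
    magnitude_db: np.ndarray
    band_resolution: str = "one-third octave"

    def __post_init__(self) -> None:
        self.center_frequencies = np.asarray(self.center_frequencies, dtype=float)
        self.magnitude_db = np.asarray(self.magnitude_db, dtype=float)
        if self.center_frequencies.ndim != 1 or self.center_frequencies.size < 10:
            raise ValueError("a Spectrum needs at least 10 bands")
        if self.center_frequencies.size != self.magnitude_db.size:
            raise ValueError("frequency and magnitude arrays must align")
        if not np.all(np.diff(self.center_frequencies) > 0):
            raise ValueError("center frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.magnitude_db)):
            raise ValueError("band magnitudes must be finite")

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.center_frequencies, self.magnitude_db])
        np.savetxt(
            path, arr, delimiter=",", header="frequency_hz,magnitude_db", comments=""
        )

    @classmethod
    def from_csv(cls, path, band_resolution: str = "one-third octave") -> "Spectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1], band_resolution)


@dataclass
class TrialStimulus:
    """Stereo waveform for one trial plus its level bookkeeping.

    The masker component is identical in both channels (diotic, M0); in the
    antiphasic condition the target component in the right channel is the
    sample-wise negation of the left-channel target.
    """

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    condition: Condition
    snr_db: float
    masker_level_db: float = COMFORTABLE_REFERENCE_DB

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")

    @property
    def stereo(self) -> np.ndarray:
        return np.column_stack([self.left, self.right])


def _band_edges(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    half = 2.0 ** (1.0 / 6.0)
    return centers / half, centers * half


def compute_ltas(
    waveforms: list[np.ndarray],
    sample_rate: float,
    band_resolution: str = "one-third octave",
    fmin: float = 100.0,
    fmax: float = 10_000.0,
) -> Spectrum:
    """Estimate the long-term average spectrum of a corpus of mono waveforms.

    The corpus is concatenated, its power spectral density estimated by
    Welch's method, and the PSD averaged within one-third-octave bands.  The
    result is normalized so the overall level is 0 dB re the corpus RMS (band
    values are density levels re corpus mean-square-per-Hz, so white noise
    reads flat at ~0 dB).

    Raises ``ValueError`` for an empty or silent corpus.
    """
    if band_resolution != "one-third octave":
        raise ValueError(f"unsupported band resolution: {band_resolution!r}")
    if not waveforms:
        raise ValueError("corpus is empty")
    parts = [np.asarray(w, dtype=float).ravel() for w in waveforms]
    if any(p.size == 0 for p in parts):
        raise ValueError("corpus contains an empty waveform")
    x = np.concatenate(parts)
    mean_square = float(np.mean(x**2))
    if mean_square <= 0.0:
        raise ValueError("corpus is silent (all-zero)")

    nperseg = min(4096, x.size)
    freqs, psd = _signal.welch(x, fs=sample_rate, nperseg=nperseg)

    nyquist = sample_rate / 2.0
    centers = third_octave_centers(fmin, min(fmax, nyquist / 2.0 ** (1.0 / 6.0)))
    lo, hi = _band_edges(centers)
    mags = np.empty_like(centers)
    for i, (f_lo, f_hi) in enumerate(zip(lo, hi)):
        sel = (freqs >= f_lo) & (freqs < f_hi)
        if not np.any(sel):
            # band narrower than the frequency resolution: take nearest bin
            sel = np.array([np.argmin(np.abs(freqs - centers[i]))])
        band_psd = float(np.mean(psd[sel]))
        # floor keeps empty bands finite (e.g. a pure-tone corpus)
        mags[i] = 10.0 * np.log10(max(band_psd, 1e-30))
    # normalize: 0 dB == corpus mean-square spread evenly over the full band
    mags -= 10.0 * np.log10(mean_square / nyquist)
    return Spectrum(centers, mags, band_resolution)


def shape_noise(
    target: Spectrum,
    duration: float,
    sample_rate: float,
    rng_seed: int,
) -> np.ndarray:
    """Generate unit-RMS Gaussian noise shaped to a target LTAS.

    White Gaussian noise is generated from ``rng_seed``, its FFT magnitudes
    multiplied by the interpolated target envelope (linear in dB over log
    frequency, edge values held beyond the band range), and the result
    renormalized to unit RMS.  The same seed reproduces the waveform exactly.
    """
    if duration < 0.5:
        raise ValueError("duration must be at least 0.5 s to estimate bands")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)

    # piecewise-constant band envelope: bins take their band's magnitude
    # exactly (one-third-octave edges are contiguous), edge values held
    # outside the band range, so the shaped band spectrum reproduces the
    # target by construction
    lo, _ = _band_edges(target.center_frequencies)
    idx = np.clip(
        np.searchsorted(lo, freqs, side="right") - 1,
        0,
        target.center_frequencies.size - 1,
    )
    env_db = target.magnitude_db[idx]
    spec *= 10.0 ** (env_db / 20.0)
    spec[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec, n=n)
    return shaped / np.sqrt(np.mean(shaped**2))


def _fit_masker_to(target_len: int, masker: np.ndarray, pad: int) -> np.ndarray:
    """Trim or loop the masker to target length plus padding."""
    need = target_len + pad
    if masker.size >= need:
        return masker[:need]
    reps = int(np.ceil(need / masker.size))
    return np.tile(masker, reps)[:need]


def assemble_trial(
    target_word: np.ndarray,
    masker: np.ndarray | None,
    condition: Condition,
    snr_db: float,
    sample_rate: float,
    masker_level_db: float = COMFORTABLE_REFERENCE_DB,
    padding_s: float = 0.0,
) -> TrialStimulus:
    """Assemble the stereo waveform for one trial.

    In the masked conditions the masker is presented identically in both
    channels at its reference level and the target is scaled so that
    ``20*log10(rms_target / rms_masker) = snr_db``; in ``M0TPI`` the target
    component is inverted in the right channel.  In ``QUIET`` the masker is
    absent and ``snr_db`` is interpreted as the target level in dB re the
    comfortable (unit-RMS full-scale) reference.
    """
    target = np.asarray(target_word, dtype=float).ravel()
    if target.size == 0:
        raise ValueError("target waveform is empty")
    rms_t = float(np.sqrt(np.mean(target**2)))
    if rms_t <= 0:
        raise ValueError("target waveform is silent")

    if condition is Condition.QUIET:
        if not np.isfinite(snr_db):
            raise ValueError("level must be finite")
        scaled = target * (10.0 ** (snr_db / 20.0) / rms_t)
        return TrialStimulus(
            left=scaled,
            right=scaled.copy(),
            sample_rate=sample_rate,
            condition=condition,
            snr_db=snr_db,
            masker_level_db=masker_level_db,
        )

    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite in masked conditions")
    if masker is None:
        raise ValueError("masked conditions require a masker waveform")
    masker = np.asarray(masker, dtype=float).ravel()
    pad = int(round(padding_s * sample_rate))
    if masker.size < target.size:
        raise ValueError("masker must be at least as long as the target")
    m = _fit_masker_to(target.size, masker, pad)
    rms_m = float(np.sqrt(np.mean(m**2)))
    if rms_m <= 0:
        raise ValueError("masker waveform is silent")

    t = np.zeros_like(m)
    t[: target.size] = target * (rms_m * 10.0 ** (snr_db / 20.0) / rms_t)
    sign = -1.0 if condition is Condition.M0TPI else 1.0
    return TrialStimulus(
        left=m + t,
        right=m + sign * t,
        sample_rate=sample_rate,
        condition=condition,
        snr_db=snr_db,
        masker_level_db=masker_level_db,
    )


def synthesize_corpus(
    sample_rate: float = 32_000.0,
    n_sets: int = 25,
    words_per_set: int = 3,
    duration: float = 0.5,
    seed: int = 20210
) -> list[list[np.ndarray]]:
    """Synthesize a stand-in target corpus of formant-like tone complexes.

    The recorded monosyllabic words of the remote protocol (25 sets of 3
    vowel-contrasted words from a female talker) are not distributable, so
    this SYNTHETIC corpus emulates their gross spectro-temporal shape: each
    "word" is a harmonic complex (f0 jittered around 220 Hz) filtered through
    two formant resonances that differ across the words of a set, plus a weak
    aspiration-noise floor, under a rise/fall envelope.  It is a testing
    stand-in, not a reproduction of the recordings.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    tt = np.arange(n) / sample_rate
    # vowel-ish formant pairs to rotate through within a set
    formant_menu = [(300, 2300), (650, 1100), (500, 1700), (750, 1300), (400, 2000)]
    corpus: list[list[np.ndarray]] = []
    for _ in range(n_sets):
        base = rng.integers(0, len(formant_menu))
        words = []
        for w in range(words_per_set):
            f0 = rng.uniform(150.0, 300.0)
            f1, f2 = formant_menu[(base + w) % len(formant_menu)]
            f1 *= rng.uniform(0.9, 1.1)
            f2 *= rng.uniform(0.9, 1.1)
            x = np.zeros(n)
            k = 1
            while k * f0 < 5000.0:
                fk = k * f0
                amp = (
                    1.0 / (1.0 + ((fk - f1) / 120.0) ** 2)
                    + 0.5 / (1.0 + ((fk - f2) / 180.0) ** 2)
                    + 0.01
                )
                x += amp * np.sin(2 * np.pi * fk * tt + rng.uniform(0, 2 * np.pi))
                k += 1
            # aspiration-like floor keeps the corpus LTAS smooth, as for
            # real speech, rather than a sparse line spectrum
            x += 10.0 ** (-18.0 / 20.0) * rng.standard_normal(n) * np.std(x)
            ramp = min(int(0.05 * sample_rate), n // 4)
            env = np.ones(n)
            env[:ramp] = np.sin(np.linspace(0, np.pi / 2, ramp)) ** 2
            env[-ramp:] = env[:ramp][::-1]
            x *= env
            words.append(x / np.sqrt(np.mean(x**2)))
        corpus.append(words)
    return corpus


def read_wav_mono(path) -> tuple[np.ndarray, float]:
    """Read a WAV file as a float mono waveform in [-1, 1]; returns (x, fs)."""
    fs, data = _wavfile.read(path)
    x = np.asarray(data, dtype=float)
    if np.issubdtype(data.dtype, np.integer):
        x /= float(np.iinfo(data.dtype).max)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return x, float(fs)


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a mono or stereo float waveform as 32-bit-float WAV."""
    _wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))
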