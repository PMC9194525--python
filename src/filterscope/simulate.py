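"""Class-conditioned synthetic electrophysiology generator.

Each class is described by a :class:`ClassRecipe`: band-limited oscillations
(narrowband Gaussian processes with random phase), optional transient
waveforms (K-complex-like biphasic deflections, spindle-like modulated
bursts) dropped at Poisson-distributed counts, all riding on 1/f colored
noise.  The generator emulates the statistical shape of preprocessed
single-channel sleep EEG — per-subject recordings, fixed-length windows,
class imbalance — while keeping the discriminative feature of every class
known exactly, which is what makes planted-feature validation of the
explainability engines possible.

Amplitudes are in units of the noise standard deviation: the colored-noise
floor is normalised to sd 1 per window, and a band component of amplitude
``a`` has rms ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SignalDataset
from .errors import ConfigurationError

__all__ = [
    "BandComponent",
    "TransientComponent",
    "ClassRecipe",
    "generate_dataset",
]


@dataclass(frozen=True)
class BandComponent:
    """A band-limited oscillation: center frequency, bandwidth, rms amplitude."""

    center_hz: float
    bandwidth_hz: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("band amplitude must be >= 0")
        if self.center_hz < 0 or self.bandwidth_hz < 0:
            raise ConfigurationError("band frequencies must be >= 0")


@dataclass(frozen=True)
class TransientComponent:
    """A transient waveform dropped into windows at a Poisson rate.

    ``kind`` is one of:

    - ``"biphasic_lowfreq"``: one negative-then-positive half-sine pair
      (K-complex-like), ``duration_s`` typically 0.5–1 s;
    - ``"modulated_burst"``: a Hann-windowed sinusoid at ``carrier_hz``
      (spindle-like).

    ``rate`` is the expected number of events per window; ``amplitude`` is
    the peak amplitude in noise-sd units.
    """

    kind: str
    rate: float
    amplitude: float
    duration_s: float
    carrier_hz: float = 13.0

    def __post_init__(self) -> None:
        if self.kind not in ("biphasic_lowfreq", "modulated_burst"):
            raise ConfigurationError(f"unknown transient kind {self.kind!r}")
        if self.rate < 0 or self.amplitude < 0 or self.duration_s <= 0:
            raise ConfigurationError("transient rate/amplitude/duration invalid")


@dataclass(frozen=True)
class ClassRecipe:
    """Generative description of one class."""

    name: str
    band_components: tuple[BandComponent, ...] = ()
    transient_components: tuple[TransientComponent, ...] = ()
    noise_exponent: float = 1.0
    class_prior: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "band_components", tuple(self.band_components))
        object.__setattr__(
            self, "transient_components", tuple(self.transient_components)
        )
        if self.class_prior < 0:
            raise ConfigurationError("class prior must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "ClassRecipe":
        return cls(
            name=d["name"],
            band_components=tuple(
                BandComponent(**b) for b in d.get("band_components", [])
            ),
            transient_components=tuple(
                TransientComponent(**t) for t in d.get("transient_components", [])
            ),
            noise_exponent=d.get("noise_exponent", 1.0),
            class_prior=d.get("class_prior", 1.0),
        )


# ------------------------------------------------------------------ pieces
def _colored_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-sd noise with power spectral density ~ 1/f**exponent.

    White-noise rFFT coefficients are shaped by f**(-exponent/2); the DC bin
    keeps zero weight so the trace stays mean-free before normalisation.
    """
    white = rng.standard_normal(n)
    if exponent == 0.0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    if sd == 0.0:  # pragma: no cover - only for pathological n
        return shaped
    return shaped / sd


def _band_oscillation(
    rng: np.random.Generator, n: int, fs: float, comp: BandComponent
) -> np.ndarray:
    """Random-phase oscillation confined to ``center ± bandwidth/2`` with rms
    equal to ``comp.amplitude``.

    A zero-bandwidth (or single-bin) component degenerates to a pure sinusoid
    with uniform random phase.
    """
    if comp.amplitude == 0.0:
        return np.zeros(n)
    half = comp.bandwidth_hz / 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= comp.center_hz - half) & (freqs <= comp.center_hz + half)
    mask &= freqs > 0
    if not mask.any():
        # narrower than one bin: pure sinusoid at the nearest nonzero bin,
        # peak amplitude sqrt(2)*rms so the rms convention is preserved
        k = int(np.argmin(np.abs(freqs[1:] - comp.center_hz))) + 1
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / fs
        return comp.amplitude * np.sqrt(2.0) * np.cos(
            2.0 * np.pi * freqs[k] * t + phase
        )
    spec = np.zeros(len(freqs), dtype=complex)
    k = np.flatnonzero(mask)
    spec[k] = rng.standard_normal(len(k)) + 1j * rng.standard_normal(len(k))
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0:  # pragma: no cover
        return x
    return comp.amplitude * x / rms


def _transient_waveform(comp: TransientComponent, fs: float) -> np.ndarray:
    m = max(2, int(round(comp.duration_s * fs)))
    t = np.arange(m) / m
    if comp.kind == "biphasic_lowfreq":
        # one full period of -sin: negative half-wave then positive half-wave
        w = -np.sin(2.0 * np.pi * t)
    else:  # modulated_burst
        hann = 0.5 - 0.5 * np.cos(2.0 * np.pi * t)
        w = hann * np.sin(2.0 * np.pi * comp.carrier_hz * np.arange(m) / fs)
    peak = np.max(np.abs(w))
    return comp.amplitude * w / peak


def _add_transients(
    rng: np.random.Generator,
    window: np.ndarray,
    comp: TransientComponent,
    fs: float,
) -> None:
    n = len(window)
    count = rng.poisson(comp.rate)
    if count == 0:
        return
    shape = _transient_waveform(comp, fs)
    m = len(shape)
    for _ in range(count):
        start = int(rng.integers(0, n))  # truncate at the right edge
        seg = min(m, n - start)
        window[start : start + seg] += shape[:seg]


# ------------------------------------------------------------------ generator
def generate_dataset(
    recipes: list[ClassRecipe],
    n_subjects: int,
    windows_per_subject: int,
    fs: float,
    window_seconds: float,
    seed: int,
) -> SignalDataset:
    """Generate a subject-structured, class-conditioned dataset.

    Per window: a class is drawn from the (normalised) class priors, then the
    window is synthesised as colored noise + the class's band oscillations
    (random phase per window) + Poisson-placed transients.  Bit-identical for
    identical inputs and seed.

    Raises
    ------
    ConfigurationError
        For empty recipes, non-positive sizes, or a non-integer window length
        ``fs * window_seconds``.
    """
    if not recipes:
        raise ConfigurationError("at least one ClassRecipe is required")
    if n_subjects < 1 or windows_per_subject < 1:
        raise ConfigurationError("n_subjects and windows_per_subject must be >= 1")
    n_t = fs * window_seconds
    if abs(n_t - round(n_t)) > 1e-9:
        raise ConfigurationError(
            f"fs * window_seconds = {n_t} is not an integer number of samples"
        )
    n_t = int(round(n_t))
    priors = np.array([r.class_prior for r in recipes], dtype=float)
    if priors.sum() <= 0:
        raise ConfigurationError("class priors must sum to a positive value")
    priors = priors / priors.sum()

    rng = np.random.default_rng(seed)
    n_total = n_subjects * windows_per_subject
    windows = np.empty((n_total, n_t))
    labels = np.empty(n_total, dtype=np.int64)
    subjects = np.empty(n_total, dtype=np.int64)

    i = 0
    for s in range(n_subjects):
        for _ in range(windows_per_subject):
            c = int(rng.choice(len(recipes), p=priors))
            recipe = recipes[c]
            x = _colored_noise(rng, n_t, recipe.noise_exponent)
            for band in recipe.band_components:
                x = x + _band_oscillation(rng, n_t, fs, band)
            for trans in recipe.transient_components:
                _add_transients(rng, x, trans, fs)
            windows[i] = x
            labels[i] = c
            subjects[i] = s
            i += 1

    return SignalDataset(
        windows=windows,
        labels=labels,
        subjects=subjects,
        fs=float(fs),
        class_names=[r.name for r in recipes],
    )
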