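"""First-layer filter spectra and spectral clustering.

Long first-layer kernels are short signals in their own right: an FFT turns
each one into a power spectrum on a grid of ``fs / filter_len`` Hz bins,
restricted to 0–50 Hz (the physiologically meaningful range; capped at
Nyquist).  Spectrally distinct groups of filters are then found by two
rounds of Euclidean k-means on the raw power rows: a first round scanning a
k range and scoring each k by mean silhouette width, and a second round at
the selected k with more initialisations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError, ShapeError
from .model import FilterBank

__all__ = [
    "SpectraMatrix",
    "ClusterAssignment",
    "filter_power_spectra",
    "select_k",
    "cluster_filters",
]

MAX_FREQ_HZ = 50.0


@dataclass(frozen=True)
class SpectraMatrix:
    """Per-filter power on a non-negative frequency grid up to 50 Hz."""

    power: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=np.float64)
        f = np.asarray(self.freqs, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != f.shape[0]:
            raise ShapeError(
                f"power {p.shape} incompatible with freqs {f.shape}"
            )
        if (p < 0).any():
            raise ShapeError("spectral power must be non-negative")
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "freqs", f)

    @property
    def n_filters(self) -> int:
        return self.power.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.power, columns=[f"{f:g}Hz" for f in self.freqs])
        df.insert(0, "filter", np.arange(self.n_filters))
        return df


@dataclass(frozen=True)
class ClusterAssignment:
    """Filter -> cluster map with the cluster spectra centers."""

    labels: np.ndarray
    k: int
    centers: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.min() < 0 or lab.max() >= self.k:
            raise ShapeError("cluster labels outside [0, k)")
        if self.centers.shape[0] != self.k:
            raise ShapeError("one center per cluster required")
        object.__setattr__(self, "labels", lab)

    @property
    def n_filters(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"filter": np.arange(self.n_filters), "cluster": self.labels}
        )


def filter_power_spectra(bank: FilterBank) -> SpectraMatrix:
    """Squared-magnitude DFT of each filter at non-negative frequencies up
    to ``min(50, fs/2)`` Hz (both endpoints included)."""
    if bank.fs <= 0:
        raise ConfigurationError("sampling rate must be positive")
    if bank.filter_len < 2:
        raise ConfigurationError("filters must have length >= 2 to admit an FFT")
    spec = np.fft.rfft(bank.weights, axis=1)
    freqs = np.fft.rfftfreq(bank.filter_len, d=1.0 / bank.fs)
    keep = freqs <= min(MAX_FREQ_HZ, bank.fs / 2.0) + 1e-12
    return SpectraMatrix(power=np.abs(spec[:, keep]) ** 2, freqs=freqs[keep])


def _features(spectra: SpectraMatrix, preprocess: str) -> np.ndarray:
    """Clustering feature rows.

    ``"power"`` clusters the raw power values (groups kernels extracting
    similar rhythms at similar strength); ``"shape"`` divides each row by
    its total so clustering sees only the spectral profile — useful when
    overall kernel magnitudes vary more than their spectral identities,
    as in small trained banks.
    """
    if preprocess == "power":
        return spectra.power
    if preprocess == "shape":
        totals = spectra.power.sum(axis=1, keepdims=True)
        safe = np.where(totals > 0, totals, 1.0)
        return spectra.power / safe
    raise ConfigurationError(f"unknown spectra preprocess {preprocess!r}")


def _kmeans(x: np.ndarray, k: int, n_init: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)


def select_k(
    spectra: SpectraMatrix,
    k_range: range | list[int] | None = None,
    n_init: int = 50,
    seed: int = 0,
    preprocess: str = "power",
) -> int:
    """First clustering round: the k in ``k_range`` (default 2..10, clipped
    to n_filters - 1) with the highest mean silhouette width; ties go to the
    smallest k."""
    n = spectra.n_filters
    if n < 3:
        raise ConfigurationError("silhouette selection needs at least 3 filters")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ConfigurationError(
            f"k_range must lie within [2, {n - 1}], got {ks}"
        )
    x = _features(spectra, preprocess)
    best_k, best_score = None, -np.inf
    for k in ks:
        km = _kmeans(x, k, n_init, seed)
        score = silhouette_score(x, km.labels_)
        if score > best_score:  # strict: first (smallest) k wins ties
            best_k, best_score = k, score
    return int(best_k)


def cluster_filters(
    spectra: SpectraMatrix,
    k: int,
    n_init: int = 100,
    seed: int = 0,
    preprocess: str = "power",
) -> ClusterAssignment:
    """Second clustering round: best-inertia k-means assignment at ``k``.

    Centers are reported in raw-power units (per-cluster means of the
    spectra rows) regardless of the clustering feature space.
    """
    n = spectra.n_filters
    if not 2 <= k < n:
        raise ConfigurationError(f"k must be in [2, {n - 1}], got {k}")
    km = _kmeans(_features(spectra, preprocess), k, n_init, seed)
    labels = km.labels_
    centers = np.vstack([
        spectra.power[labels == j].mean(axis=0) for j in range(k)
    ])
    return ClusterAssignment(
        labels=labels, k=k, centers=centers, freqs=spectra.freqs
    )
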