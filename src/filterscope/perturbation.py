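"""Cluster ablation, band zeroing, and sliding-window temporal ablation.

All three engines follow the same contract: perturb first-layer kernel
weights only (never biases), re-predict the held-out test set, report the
percent change in per-class and weighted F1 relative to a cached baseline,
and restore the original weights bit-exactly — verified by comparing a
post-run prediction against the pre-run prediction, with a hard error on
any mismatch.

Frequency bands use the canonical EEG partition δ(0–4), θ(4–8), α(8–12),
β(12–25), γ(25–50) Hz.  Bands are half-open ``[lo, hi)`` so shared edges are
zeroed exactly once; the DC bin falls to δ and the Nyquist bin (when
``hi == fs/2``) to the top band, which makes "zero every band" equivalent
to ablating the filter outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .datasets import SignalDataset
from .errors import ConfigurationError, RestorationError, ShapeError
from .metrics import ClassMetrics, class_metrics, percent_change
from .model import TrainedModel, predict
from .spectra import ClusterAssignment

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "PerturbationResult",
    "ImportanceMap",
    "ablate_cluster",
    "perturb_band",
    "temporal_ablation",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A half-open frequency interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo < self.hi:
            raise ConfigurationError(
                f"band {self.name!r}: need 0 <= lo < hi, got [{self.lo}, {self.hi})"
            )


CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 0.0, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("alpha", 8.0, 12.0),
    FrequencyBand("beta", 12.0, 25.0),
    FrequencyBand("gamma", 25.0, 50.0),
)


@dataclass(frozen=True)
class PerturbationResult:
    """Outcome of one perturbation: descriptor, per-class and weighted F1
    percent change, and the baseline it was measured against."""

    kind: str
    descriptor: dict
    per_class_change: np.ndarray
    weighted_change: float
    baseline: ClassMetrics
    perturbed: ClassMetrics

    def to_frame(self) -> pd.DataFrame:
        names = self.baseline.class_names or tuple(
            str(i) for i in range(self.baseline.n_classes)
        )
        rows = [
            {"engine": self.kind, **self.descriptor, "class": name,
             "percent_change": self.per_class_change[i]}
            for i, name in enumerate(names)
        ]
        rows.append(
            {"engine": self.kind, **self.descriptor, "class": "weighted",
             "percent_change": self.weighted_change}
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImportanceMap:
    """Percent-change importance per first-layer weight position.

    ``importance`` has shape (n_filters, filter_len, n_classes + 1); the
    last slice of the final axis is the weighted-F1 change, preceded by the
    per-class changes.
    """

    importance: np.ndarray
    window_len: int
    step: int
    class_names: tuple[str, ...] = ()

    @property
    def n_filters(self) -> int:
        return self.importance.shape[0]

    @property
    def filter_len(self) -> int:
        return self.importance.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n_classes = self.importance.shape[2] - 1
        names = list(self.class_names) or [str(i) for i in range(n_classes)]
        names = names + ["weighted"]
        f, p, c = np.meshgrid(
            np.arange(self.n_filters), np.arange(self.filter_len),
            np.arange(n_classes + 1), indexing="ij",
        )
        return pd.DataFrame(
            {
                "filter": f.ravel(),
                "position": p.ravel(),
                "class": [names[i] for i in c.ravel()],
                "percent_change": self.importance.ravel(),
            }
        )

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("importance", data=self.importance)
            fh.attrs["window_len"] = self.window_len
            fh.attrs["step"] = self.step
            fh.attrs["class_names"] = list(self.class_names)


# ------------------------------------------------------------------ shared
def _evaluate(model: TrainedModel, test: SignalDataset) -> ClassMetrics:
    labels, _ = predict(model, test)
    return class_metrics(
        test.labels, labels, model.config.n_classes,
        tuple(test.class_names) or tuple(
            str(i) for i in range(model.config.n_classes)
        ),
    )


def _conv1(model: TrainedModel):
    return model.layers_by_name["conv1d"]


def _check_restored(
    model: TrainedModel, test: SignalDataset, pre_proba: np.ndarray, engine: str
) -> None:
    _, post = predict(model, test)
    if not np.array_equal(post, pre_proba):
        raise RestorationError(
            f"{engine}: post-run predictions differ from pre-run predictions; "
            "weight restoration failed"
        )


def _result(
    kind: str, descriptor: dict, baseline: ClassMetrics, perturbed: ClassMetrics
) -> PerturbationResult:
    per_class, weighted = percent_change(baseline, perturbed)
    return PerturbationResult(
        kind=kind, descriptor=descriptor, per_class_change=per_class,
        weighted_change=weighted, baseline=baseline, perturbed=perturbed,
    )


# ----------------------------------------------------------------- engines
def ablate_cluster(
    model: TrainedModel,
    assignment: ClusterAssignment,
    cluster_id: int,
    test: SignalDataset,
    baseline: ClassMetrics,
) -> PerturbationResult:
    """Zero every filter of one cluster, measure F1 percent change, restore."""
    if not 0 <= cluster_id < assignment.k:
        raise ConfigurationError(
            f"cluster_id {cluster_id} outside [0, {assignment.k})"
        )
    conv1 = _conv1(model)
    if assignment.n_filters != conv1.params["W"].shape[0]:
        raise ShapeError(
            "cluster assignment covers a different number of filters than the model"
        )
    _, pre_proba = predict(model, test)
    w0 = conv1.params["W"].copy()
    members = assignment.members(cluster_id)
    try:
        w = w0.copy()
        w[members] = 0.0
        conv1.params["W"] = w
        perturbed = _evaluate(model, test)
    finally:
        conv1.params["W"] = w0
    _check_restored(model, test, pre_proba, "ablate_cluster")
    return _result(
        "ablation",
        {"cluster": cluster_id, "n_filters_ablated": int(len(members))},
        baseline, perturbed,
    )


def band_bin_mask(freqs: np.ndarray, band: FrequencyBand, fs: float) -> np.ndarray:
    """Boolean mask over (signed) DFT frequencies covered by ``band``.

    Half-open [lo, hi); the Nyquist bin is included when ``hi == fs/2`` so
    the canonical five bands together cover every bin except none.
    """
    a = np.abs(freqs)
    mask = (a >= band.lo - 1e-12) & (a < band.hi - 1e-12)
    if np.isclose(band.hi, fs / 2.0):
        mask |= np.isclose(a, fs / 2.0)
    return mask


def perturb_band(
    model: TrainedModel,
    assignment: ClusterAssignment,
    cluster_id: int,
    band: FrequencyBand,
    test: SignalDataset,
    baseline: ClassMetrics,
) -> PerturbationResult:
    """Zero one frequency band inside every filter of one cluster.

    Each member filter goes through forward FFT -> zero the band's complex
    coefficients (conjugate-symmetric bins together, so the inverse
    transform is real) -> inverse FFT -> install; the test set is
    re-predicted and the weights restored.
    """
    if not 0 <= cluster_id < assignment.k:
        raise ConfigurationError(
            f"cluster_id {cluster_id} outside [0, {assignment.k})"
        )
    fs = model.config.fs
    if band.hi > fs / 2.0 + 1e-9:
        raise ConfigurationError(
            f"band {band.name!r} upper edge {band.hi} Hz exceeds Nyquist {fs / 2}"
        )
    conv1 = _conv1(model)
    _, pre_proba = predict(model, test)
    w0 = conv1.params["W"].copy()
    filter_len = w0.shape[1]
    freqs = np.fft.fftfreq(filter_len, d=1.0 / fs)
    mask = band_bin_mask(freqs, band, fs)
    members = assignment.members(cluster_id)
    try:
        w = w0.copy()
        if len(members) and mask.any():
            coeffs = np.fft.fft(w[members], axis=1)
            coeffs[:, mask] = 0.0
            back = np.fft.ifft(coeffs, axis=1)
            residue = np.abs(back.imag).max()
            if residue > 1e-9:
                raise ConfigurationError(
                    f"imaginary residue {residue:.3g} after band zeroing; "
                    "conjugate symmetry violated"
                )
            w[members] = back.real
        conv1.params["W"] = w
        perturbed = _evaluate(model, test)
    finally:
        conv1.params["W"] = w0
    _check_restored(model, test, pre_proba, "perturb_band")
    return _result(
        "spectral",
        {"cluster": cluster_id, "band": band.name,
         "lo_hz": band.lo, "hi_hz": band.hi},
        baseline, perturbed,
    )


def temporal_ablation(
    model: TrainedModel,
    test: SignalDataset,
    baseline: ClassMetrics,
    window_len: int = 25,
    step: int = 1,
) -> ImportanceMap:
    """Sliding-window weight ablation over every first-layer filter.

    Filters are conceptually zero-padded by ``window_len // 2`` on each side
    so the window's center sweeps every true weight position.  At each
    center the covered true weights are zeroed, the test set re-predicted,
    and the F1 percent changes recorded as the importance of the center
    position; windows covering only padding (or only already-zero weights)
    record exactly 0 without a model evaluation.  With ``step > 1``,
    unevaluated positions inherit the nearest evaluated center's value.
    """
    if window_len < 1 or step < 1:
        raise ConfigurationError("window_len and step must be >= 1")
    conv1 = _conv1(model)
    _, pre_proba = predict(model, test)
    w0 = conv1.params["W"].copy()
    n_filters, filter_len = w0.shape
    n_classes = baseline.n_classes
    center = window_len // 2
    importance = np.zeros((n_filters, filter_len, n_classes + 1))
    evaluated = np.arange(0, filter_len, step)
    try:
        for f in range(n_filters):
            for p in evaluated:
                a = max(0, p - center)
                b = min(filter_len, p - center + window_len)
                if a >= b or not np.any(w0[f, a:b]):
                    continue  # padding-only or already-zero: null perturbation
                w = w0.copy()
                w[f, a:b] = 0.0
                conv1.params["W"] = w
                perturbed = _evaluate(model, test)
                per_class, weighted = percent_change(baseline, perturbed)
                importance[f, p, :n_classes] = per_class
                importance[f, p, n_classes] = weighted
            if step > 1:
                nearest = evaluated[
                    np.argmin(
                        np.abs(np.arange(filter_len)[:, None] - evaluated[None, :]),
                        axis=1,
                    )
                ]
                importance[f] = importance[f, nearest]
    finally:
        conv1.params["W"] = w0
    _check_restored(model, test, pre_proba, "temporal_ablation")
    return ImportanceMap(
        importance=importance, window_len=window_len, step=step,
        class_names=tuple(test.class_names),
    )
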