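"""Windowed single-channel signal datasets.

The :class:`SignalDataset` is the unit every stage of the toolkit consumes: a
matrix of fixed-length windows cut from per-subject recordings, with integer
class labels, a subject identifier per window, and the sampling rate.  For
sleep staging this corresponds to 30-s single-electrode EEG epochs, but
nothing here is specific to sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ShapeError, ZeroVarianceError

__all__ = ["SignalDataset", "zscore_per_subject", "subject_split"]


@dataclass(frozen=True)
class SignalDataset:
    """Windows x timepoints matrix plus per-window label and subject.

    Parameters
    ----------
    windows : ndarray, shape (n_windows, n_timepoints)
        Fixed-length signal windows, float64.
    labels : ndarray of int, shape (n_windows,)
        Class index per window, in ``[0, n_classes)``.
    subjects : ndarray, shape (n_windows,)
        Subject identifier per window (any hashable scalar; stored as given).
    fs : float
        Sampling rate in Hz.
    class_names : list of str
        Display name per class index.
    """

    windows: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs: float
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=np.float64)
        lab = np.asarray(self.labels)
        sub = np.asarray(self.subjects)
        if w.ndim != 2:
            raise ShapeError(f"windows must be 2-D, got shape {w.shape}")
        if lab.shape != (w.shape[0],) or sub.shape != (w.shape[0],):
            raise ShapeError(
                "labels and subjects must have one entry per window: "
                f"windows {w.shape[0]}, labels {lab.shape}, subjects {sub.shape}"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "labels", lab.astype(np.int64))
        object.__setattr__(self, "subjects", sub)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.windows.shape[1]

    @property
    def n_classes(self) -> int:
        if self.class_names:
            return len(self.class_names)
        return int(self.labels.max()) + 1 if self.n_windows else 0

    @property
    def window_seconds(self) -> float:
        return self.n_timepoints / self.fs

    def subject_ids(self) -> np.ndarray:
        """Unique subjects in order of first appearance."""
        _, idx = np.unique(self.subjects, return_index=True)
        return self.subjects[np.sort(idx)]

    def select(self, mask: np.ndarray) -> "SignalDataset":
        """Row-subset by boolean mask or index array."""
        return replace(
            self,
            windows=self.windows[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
        )

    def manifest(self) -> pd.DataFrame:
        """Tidy (window_id, subject_id, label) manifest."""
        return pd.DataFrame(
            {
                "window_id": np.arange(self.n_windows),
                "subject_id": self.subjects,
                "label": self.labels,
            }
        )

    # ------------------------------------------------------------------ io
    def to_hdf5(self, path: str) -> None:
        """Persist as HDF5 with datasets /windows, /labels, /subjects."""
        with h5py.File(path, "w") as f:
            f.create_dataset("windows", data=self.windows)
            f.create_dataset("labels", data=self.labels)
            subs = np.asarray(self.subjects)
            if subs.dtype.kind in "UO":
                subs = subs.astype(h5py.string_dtype())
            f.create_dataset("subjects", data=subs)
            f.attrs["fs"] = self.fs
            f.attrs["class_names"] = list(self.class_names)

    @classmethod
    def from_hdf5(cls, path: str) -> "SignalDataset":
        with h5py.File(path, "r") as f:
            subs = f["subjects"][()]
            if subs.dtype.kind in "SO":
                subs = np.asarray([s.decode() for s in subs])
            return cls(
                windows=f["windows"][()],
                labels=f["labels"][()],
                subjects=subs,
                fs=float(f.attrs["fs"]),
                class_names=[str(c) for c in f.attrs.get("class_names", [])],
            )


def zscore_per_subject(dataset: SignalDataset) -> SignalDataset:
    """Z-score each subject's concatenated signal to mean 0, sd 1.

    Mirrors per-recording standardisation of raw EEG: all of one subject's
    windows are concatenated, a single mean/sd is estimated, and every window
    of that subject is rescaled with it.  Window boundaries are unchanged.

    Raises
    ------
    ZeroVarianceError
        If any subject's concatenated signal is constant (names the subject).
    """
    out = dataset.windows.copy()
    for sid in dataset.subject_ids():
        mask = dataset.subjects == sid
        block = dataset.windows[mask]
        mu = block.mean()
        sd = block.std()
        if sd == 0.0 or not np.isfinite(sd):
            raise ZeroVarianceError(f"subject {sid!r} has zero-variance signal")
        out[mask] = (block - mu) / sd
    return replace(dataset, windows=out)


def subject_split(
    dataset: SignalDataset,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int,
) -> tuple[SignalDataset, SignalDataset, SignalDataset]:
    """Randomly assign whole subjects to disjoint train/val/test groups.

    Splitting at the subject level (rather than the window level) keeps the
    evaluation honest: every window of a held-out subject is unseen during
    training.

    Raises
    ------
    ConfigurationError
        If the dataset has fewer subjects than ``n_train + n_val + n_test``.
    """
    ids = dataset.subject_ids()
    need = n_train + n_val + n_test
    if need > len(ids):
        raise ConfigurationError(
            f"need {need} subjects for a {n_train}/{n_val}/{n_test} split, "
            f"dataset has {len(ids)}"
        )
    if min(n_train, n_val, n_test) < 0:
        raise ConfigurationError("split sizes must be non-negative")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    train_ids = set(ids[order[:n_train]].tolist())
    val_ids = set(ids[order[n_train : n_train + n_val]].tolist())
    test_ids = set(ids[order[n_train + n_val : need]].tolist())

    def pick(group: set) -> SignalDataset:
        mask = np.array([s in group for s in dataset.subjects])
        return dataset.select(mask)

    return pick(train_ids), pick(val_ids), pick(test_ids)
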