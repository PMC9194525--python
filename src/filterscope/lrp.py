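"""Layer-wise relevance propagation (αβ rule) to first-layer activations.

Relevance starts at the predicted class's pre-softmax score and is pushed
backward through dense, flatten/reshape, max-pooling, and 2-D convolution
layers by the αβ rule

    R_j = Σ_k [ α (a_j w_jk)+ / Σ_{0,j} (a_j w_jk)+
              − β (a_j w_jk)− / Σ_{0,j} (a_j w_jk)− ] R_k,

where the ``0`` index in the denominators is the bias term: biases widen
the denominators but receive no relevance themselves.  α − β = 1 is
required; with α = 1, β = 0 only positive evidence propagates and all
relevance values are non-negative.  Max pooling routes relevance
winner-take-all to the argmax input.  Propagation stops at the first
convolution's ReLU activations, giving a per-window, per-position,
per-filter relevance tensor.

``cluster_relevance`` aggregates that tensor into the normalized per-class,
per-cluster score: per subject and predicted class, the fraction of total
first-layer relevance landing on each cluster's filter channels, summed
over subjects and scaled by (F − F_C)/F where F is the total filter count
and F_C the cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .datasets import SignalDataset
from .errors import ConfigurationError, PropagationError
from .model import TrainedModel
from .spectra import ClusterAssignment

__all__ = [
    "RelevanceTensor",
    "ClusterRelevance",
    "propagate",
    "propagate_network",
    "cluster_relevance",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class RelevanceTensor:
    """First-layer relevance per window: (n_windows, positions, n_filters)."""

    relevance: np.ndarray
    predicted_class: np.ndarray
    subjects: np.ndarray


@dataclass(frozen=True)
class ClusterRelevance:
    """Normalized relevance per (class, cluster), plus the per-subject
    shares it was aggregated from."""

    nr: np.ndarray  # (n_classes, k)
    shares: pd.DataFrame  # columns: subject, predicted_class, cluster, share
    scaling: str

    def to_frame(self, class_names: tuple[str, ...] = ()) -> pd.DataFrame:
        n_classes, k = self.nr.shape
        names = list(class_names) or [str(i) for i in range(n_classes)]
        rows = [
            {"class": names[c], "cluster": j, "nr": self.nr[c, j]}
            for c in range(n_classes)
            for j in range(k)
        ]
        return pd.DataFrame(rows)


def _stabilized(x: np.ndarray) -> np.ndarray:
    """Add ε with the sign of x (sign 0 treated as +) to avoid division by 0."""
    return x + np.where(x >= 0.0, _EPS, -_EPS)


# ------------------------------------------------------------- layer rules
def _dense_rule(layer: nn.Dense, rel: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    a = layer.cache["x"]  # (n, J)
    W = layer.params["W"]  # (J, K)
    b = layer.params["b"]
    if (a >= 0.0).all():
        # fast path: (a w)+ = a w+ elementwise when a >= 0
        wp, wn = np.maximum(W, 0.0), np.minimum(W, 0.0)
        sp = _stabilized(a @ wp + np.maximum(b, 0.0))
        out = alpha * a * ((rel / sp) @ wp.T)
        if beta != 0.0:
            sn = _stabilized(a @ wn + np.minimum(b, 0.0))
            out -= beta * a * ((rel / sn) @ wn.T)
        return out
    # general path: explicit sign split of z_jk = a_j w_jk
    z = a[:, :, None] * W[None, :, :]  # (n, J, K)
    zp, zn = np.maximum(z, 0.0), np.minimum(z, 0.0)
    sp = _stabilized(zp.sum(axis=1) + np.maximum(b, 0.0))
    out = alpha * np.einsum("njk,nk->nj", zp, rel / sp)
    if beta != 0.0:
        sn = _stabilized(zn.sum(axis=1) + np.minimum(b, 0.0))
        out -= beta * np.einsum("njk,nk->nj", zn, rel / sn)
    return out


def _conv2d_rule(layer: nn.Conv2D, rel: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    cols = layer.cache["cols"]  # (n, OH, OW, K)
    if cols.min() < 0.0:
        raise PropagationError(
            f"layer {layer.name!r}: relevance rule assumes non-negative "
            "(post-ReLU) inputs"
        )
    x = layer.cache["x"]
    n, oh, ow, f = rel.shape
    kh, kw = layer.kh, layer.kw
    c = x.shape[-1]
    wmat = layer.params["W"].reshape(-1, f)
    b = layer.params["b"]

    def half(wpart: np.ndarray, bpart: np.ndarray) -> np.ndarray:
        s = _stabilized(cols @ wpart + bpart)
        return cols * ((rel / s) @ wpart.T)  # (n, OH, OW, K)

    rcols = alpha * half(np.maximum(wmat, 0.0), np.maximum(b, 0.0))
    if beta != 0.0:
        rcols -= beta * half(np.minimum(wmat, 0.0), np.minimum(b, 0.0))
    rcols = rcols.reshape(n, oh, ow, kh, kw, c)
    rin = np.zeros_like(x)
    for i in range(kh):
        for j in range(kw):
            rin[:, i : i + oh, j : j + ow, :] += rcols[:, :, :, i, j]
    return rin


def _pool2d_rule(layer: nn.MaxPool2D, rel: np.ndarray) -> np.ndarray:
    rin = np.zeros(layer.cache["x_shape"])
    hi, wi = layer._abs_positions()
    n, _, _, c = rel.shape
    ni = np.arange(n)[:, None, None, None]
    ci = np.arange(c)[None, None, None, :]
    np.add.at(rin, (ni, hi, wi, ci), rel)
    return rin


def _pool1d_rule(layer: nn.MaxPool1D, rel: np.ndarray) -> np.ndarray:
    rin = np.zeros(layer.cache["x_shape"])
    pos = layer.winner_positions()
    n, q, f = rel.shape
    ni, qi, fi = np.ogrid[:n, :q, :f]
    np.add.at(rin, (ni, pos, fi), rel)
    return rin


def _propagate_one(layer: nn.Layer, rel: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    if isinstance(layer, nn.Dense):
        return _dense_rule(layer, rel, alpha, beta)
    if isinstance(layer, nn.Conv2D):
        return _conv2d_rule(layer, rel, alpha, beta)
    if isinstance(layer, nn.MaxPool2D):
        return _pool2d_rule(layer, rel)
    if isinstance(layer, nn.MaxPool1D):
        return _pool1d_rule(layer, rel)
    if isinstance(layer, nn.Flatten):
        return rel.reshape(layer.cache["x_shape"])
    if isinstance(layer, nn.ToImage):
        return rel[..., 0]
    raise PropagationError(
        f"no relevance rule registered for layer {layer.name!r} "
        f"({type(layer).__name__})"
    )


def propagate_network(
    net: nn.Sequential,
    x: np.ndarray,
    alpha: float = 1.0,
    beta: float = 0.0,
    stop_before: int = 0,
    seed_relevance: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate relevance backward through ``net`` on batch ``x``.

    ``stop_before`` is the index of the first layer NOT propagated through:
    the returned tensor is the relevance of that layer's outputs (index 0
    returns relevance at the network input).  ``seed_relevance`` overrides
    the default output seeding (predicted class's pre-softmax score).
    """
    if abs((alpha - beta) - 1.0) > 1e-12:
        raise ConfigurationError(
            f"alpha - beta must equal 1, got alpha={alpha}, beta={beta}"
        )
    scores = net.forward(x)
    rel = _seed(scores, seed_relevance)
    rel = _backward_from(net, rel, alpha, beta, stop_before)
    net.clear_caches()
    return rel


def _seed(scores: np.ndarray, seed_relevance: np.ndarray | None) -> np.ndarray:
    if seed_relevance is None:
        rel = np.zeros_like(scores)
        pred = scores.argmax(axis=1)
        rows = np.arange(len(scores))
        rel[rows, pred] = scores[rows, pred]
        return rel
    rel = np.asarray(seed_relevance, dtype=np.float64)
    if rel.shape != scores.shape:
        raise ConfigurationError(
            f"seed relevance shape {rel.shape} != output shape {scores.shape}"
        )
    return rel


def _backward_from(
    net: nn.Sequential, rel: np.ndarray, alpha: float, beta: float,
    stop_before: int,
) -> np.ndarray:
    for layer in reversed(net.layers[stop_before:]):
        rel = _propagate_one(layer, rel, alpha, beta)
    return rel


def propagate(
    model: TrainedModel,
    dataset: SignalDataset,
    alpha: float = 1.0,
    beta: float = 0.0,
    batch_size: int = 64,
) -> RelevanceTensor:
    """First-layer activation relevance for every window of ``dataset``.

    Relevance is seeded at each window's predicted output node with its
    pre-softmax score and propagated down to the first convolution's ReLU
    activations (shape n_windows x positions x n_filters1).
    """
    if abs((alpha - beta) - 1.0) > 1e-12:
        raise ConfigurationError(
            f"alpha - beta must equal 1, got alpha={alpha}, beta={beta}"
        )
    conv_index = next(
        i for i, layer in enumerate(model.net.layers)
        if isinstance(layer, nn.Conv1D)
    )
    rels, preds = [], []
    x = dataset.windows
    for start in range(0, len(x), batch_size):
        batch = x[start : start + batch_size]
        scores = model.net.forward(batch)
        preds.append(scores.argmax(axis=1))
        rel = _seed(scores, None)
        rels.append(
            _backward_from(model.net, rel, alpha, beta, conv_index + 1)
        )
        model.net.clear_caches()
    return RelevanceTensor(
        relevance=np.concatenate(rels, axis=0),
        predicted_class=np.concatenate(preds, axis=0),
        subjects=dataset.subjects.copy(),
    )


def cluster_relevance(
    rel: RelevanceTensor,
    assignment: ClusterAssignment,
    n_classes: int,
    scaling: str = "as_printed",
) -> ClusterRelevance:
    """Normalized per-class, per-cluster relevance.

    For each subject and predicted class, the share of total first-layer
    relevance on each cluster's filters is computed; shares are summed over
    subjects within the class and scaled per cluster.  ``scaling``:

    - ``"as_printed"``: (F − F_C) / F — down-weights larger clusters;
    - ``"reciprocal"``: F / (F − F_C).

    Subjects with zero total relevance for a class are excluded with a
    logged warning.
    """
    if scaling not in ("as_printed", "reciprocal"):
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    if rel.relevance.shape[2] != assignment.n_filters:
        raise ConfigurationError(
            "relevance tensor and cluster assignment disagree on filter count"
        )
    f_total = assignment.n_filters
    per_filter = rel.relevance.sum(axis=1)  # (n_windows, F)
    k = assignment.k
    nr = np.zeros((n_classes, k))
    share_rows = []
    for c in range(n_classes):
        cmask = rel.predicted_class == c
        for sid in pd.unique(rel.subjects):
            mask = cmask & (rel.subjects == sid)
            if not mask.any():
                continue
            total = per_filter[mask].sum()
            if total <= 0.0:
                logger.warning(
                    "subject %r has zero total relevance for predicted class "
                    "%d; excluded from cluster relevance", sid, c,
                )
                continue
            for j in range(k):
                share = per_filter[np.ix_(mask, assignment.members(j))].sum() / total
                nr[c, j] += share
                share_rows.append(
                    {"subject": sid, "predicted_class": c, "cluster": j,
                     "share": share}
                )
    f_c = assignment.sizes.astype(float)
    if scaling == "as_printed":
        scale = (f_total - f_c) / f_total
    else:
        with np.errstate(divide="ignore"):
            scale = np.where(f_c < f_total, f_total / (f_total - f_c), np.inf)
    nr = nr * scale[None, :]
    return ClusterRelevance(
        nr=nr,
        shares=pd.DataFrame(
            share_rows, columns=["subject", "predicted_class", "cluster", "share"]
        ),
        scaling=scaling,
    )
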