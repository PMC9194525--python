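"""αβ-rule relevance propagation against literal brute-force evaluation,
plus the normalized cluster-relevance aggregation."""

import logging

import numpy as np
import pytest

from filterscope import build_model, cluster_relevance, propagate
from filterscope.errors import ConfigurationError, PropagationError
from filterscope.lrp import RelevanceTensor, propagate_network
from filterscope import nn
from filterscope.spectra import ClusterAssignment


# ------------------------------------------------------------------ oracle
def brute_force_alpha_beta(layers, x, rel_out, alpha, beta, eps=1e-9):
    """Literal term-by-term evaluation of the αβ rule on a dense chain.

    ``layers`` is a list of (W, b, relu) triples.  Relevance is pushed from
    the output back to the input activations with explicit loops over the
    shallow index j and deep index k; the bias enters each denominator as
    the '0' term but receives no relevance.
    """
    acts = [x]
    a = x
    for W, b, relu in layers:
        z = a @ W + b
        a = np.maximum(z, 0.0) if relu else z
        acts.append(a)
    rel = rel_out
    for (W, b, _), a in zip(reversed(layers), reversed(acts[:-1])):
        n, J = a.shape
        K = W.shape[1]
        new = np.zeros((n, J))
        for s in range(n):
            for k in range(K):
                zp_sum = max(b[k], 0.0)
                zn_sum = min(b[k], 0.0)
                for j in range(J):
                    z = a[s, j] * W[j, k]
                    zp_sum += max(z, 0.0)
                    zn_sum += min(z, 0.0)
                dp = zp_sum + (eps if zp_sum >= 0 else -eps)
                dn = zn_sum + (eps if zn_sum >= 0 else -eps)
                for j in range(J):
                    z = a[s, j] * W[j, k]
                    new[s, j] += (
                        alpha * max(z, 0.0) / dp - beta * min(z, 0.0) / dn
                    ) * rel[s, k]
        rel = new
    return rel


def _dense_chain(sizes, seed, relu=True, bias=True, positive=False):
    """Build a matching (Sequential, oracle-layers) pair."""
    rng = np.random.default_rng(seed)
    layers, oracle = [], []
    for i, (d_in, d_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        last = i == len(sizes) - 2
        lay = nn.Dense(d_out, relu=relu and not last, name=f"d{i}")
        layers.append(lay)
    net = nn.Sequential(layers, input_shape=(sizes[0],), seed=seed)
    for lay in layers:
        if positive:
            lay.params["W"] = np.abs(lay.params["W"])
        if bias:
            lay.params["b"] = rng.standard_normal(lay.params["b"].shape) * 0.1
        oracle.append((lay.params["W"], lay.params["b"], lay.relu))
    return net, oracle


class TestAlphaBetaRule:
    def test_single_linear_layer_closed_form(self):
        """Positive weights, positive input, one-hot output relevance:
        R_j = a_j w_j / sum(a w) * R_out and the total is conserved."""
        net, _ = _dense_chain([4, 2], seed=0, relu=False, bias=False,
                              positive=True)
        x = np.array([[1.0, 2.0, 0.5, 3.0]])
        seed_rel = np.array([[5.0, 0.0]])
        rel = propagate_network(net, x, 1.0, 0.0, seed_relevance=seed_rel)
        W = net.layers[0].params["W"]
        expected = x[0] * W[:, 0] / (x[0] @ W[:, 0]) * 5.0
        assert np.allclose(rel[0], expected, rtol=1e-9)
        assert rel.sum() == pytest.approx(5.0)

    @pytest.mark.parametrize("alpha, beta", [(1.0, 0.0), (2.0, 1.0)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_toy_networks(self, alpha, beta, seed):
        """Three-layer ReLU chains (<= 50 units), raw possibly-negative
        inputs: vectorized propagation equals the printed formula evaluated
        term by term."""
        sizes = [7, 5, 4, 3]
        net, oracle = _dense_chain(sizes, seed=seed, bias=True)
        rng = np.random.default_rng(100 + seed)
        x = rng.standard_normal((4, sizes[0]))
        scores = net.forward(x)
        rel_out = np.zeros_like(scores)
        pred = scores.argmax(axis=1)
        rel_out[np.arange(len(x)), pred] = scores[np.arange(len(x)), pred]
        net.clear_caches()
        expected = brute_force_alpha_beta(oracle, x, rel_out, alpha, beta)
        got = propagate_network(net, x, alpha, beta)
        assert np.allclose(got, expected, rtol=1e-6, atol=1e-12)

    def test_non_negative_under_alpha1_beta0(self):
        net, _ = _dense_chain([6, 5, 3], seed=3, bias=True)
        x = np.abs(np.random.default_rng(5).standard_normal((8, 6)))
        seed_rel = np.zeros((8, 3))
        seed_rel[:, 1] = 2.0
        rel = propagate_network(net, x, 1.0, 0.0, seed_relevance=seed_rel)
        assert rel.min() >= 0.0

    def test_conservation_on_bias_free_net(self):
        """α=1, β=0, no biases, positive weights: every propagation step
        conserves total relevance within 1e-5 relative."""
        net, _ = _dense_chain([10, 8, 4], seed=7, bias=False, positive=True)
        x = np.abs(np.random.default_rng(2).standard_normal((5, 10))) + 0.1
        scores = net.forward(x)
        rel_out = np.zeros_like(scores)
        pred = scores.argmax(axis=1)
        rel_out[np.arange(5), pred] = scores[np.arange(5), pred]
        net.clear_caches()
        rel_in = propagate_network(net, x, 1.0, 0.0, seed_relevance=rel_out)
        assert np.allclose(rel_in.sum(axis=1), rel_out.sum(axis=1), rtol=1e-5)

    def test_alpha_beta_constraint_enforced(self):
        net, _ = _dense_chain([3, 2], seed=0)
        with pytest.raises(ConfigurationError, match="alpha"):
            propagate_network(net, np.ones((1, 3)), alpha=1.0, beta=0.5)

    def test_unknown_layer_type_named(self):
        class Odd(nn.Layer):
            name = "odd"

            def forward(self, x):
                self.cache = {"x_shape": x.shape}
                return x

        net = nn.Sequential([Odd()], input_shape=(4,), seed=0)
        net.forward(np.ones((1, 4)))
        from filterscope.lrp import _propagate_one

        with pytest.raises(PropagationError, match="odd"):
            _propagate_one(net.layers[0], np.ones((1, 4)), 1.0, 0.0)


class TestFullModelPropagation:
    def test_relevance_lands_on_first_layer_activations(self, micro_model,
                                                        micro_dataset):
        rel = propagate(micro_model, micro_dataset, alpha=1.0, beta=0.0)
        n = micro_dataset.n_windows
        assert rel.relevance.shape == (n, 53, 2)
        assert rel.predicted_class.shape == (n,)
        assert np.array_equal(rel.subjects, micro_dataset.subjects)

    def test_conservation_through_conv_and_pool_layers(self, micro_model,
                                                       micro_dataset):
        """The untrained model has all-zero biases, so total relevance at
        the first-layer activations equals the seeded output score."""
        rel = propagate(micro_model, micro_dataset, alpha=1.0, beta=0.0)
        scores = micro_model.net.forward(micro_dataset.windows)
        micro_model.net.clear_caches()
        pred = scores.argmax(axis=1)
        seeded = scores[np.arange(len(pred)), pred]
        totals = rel.relevance.sum(axis=(1, 2))
        assert np.allclose(totals, seeded, rtol=1e-5, atol=1e-9)


# --------------------------------------------------------- cluster scores
def _assignment(labels, k, n_bins=4):
    labels = np.asarray(labels)
    centers = np.zeros((k, n_bins))
    return ClusterAssignment(labels=labels, k=k, centers=centers,
                             freqs=np.arange(n_bins, dtype=float))


class TestClusterRelevance:
    def test_all_relevance_in_one_cluster(self):
        # 4 filters, cluster 1 = filters {2, 3}; everything lands there
        rel = np.zeros((3, 5, 4))
        rel[:, :, 2:] = 1.0
        tensor = RelevanceTensor(
            relevance=rel, predicted_class=np.zeros(3, dtype=int),
            subjects=np.array([0, 0, 0]),
        )
        asn = _assignment([0, 0, 1, 1], k=2)
        out = cluster_relevance(tensor, asn, n_classes=1)
        assert out.nr[0, 1] == pytest.approx(1.0 * (4 - 2) / 4)
        assert out.nr[0, 0] == pytest.approx(0.0)

    def test_uniform_relevance_gives_size_scaled_shares(self):
        """Uniform relevance: pre-scaling share F_C/F, post-scaling
        F_C (F - F_C) / F^2."""
        f = 5
        rel = np.ones((2, 3, f))
        tensor = RelevanceTensor(
            relevance=rel, predicted_class=np.zeros(2, dtype=int),
            subjects=np.zeros(2),
        )
        asn = _assignment([0, 0, 0, 1, 1], k=2)
        out = cluster_relevance(tensor, asn, n_classes=1)
        for c, fc in [(0, 3), (1, 2)]:
            assert out.nr[0, c] == pytest.approx(fc * (f - fc) / f**2)
            share = out.shares.query(f"cluster == {c}")["share"].iloc[0]
            assert share == pytest.approx(fc / f)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        n, pos, f, k, n_classes = 12, 6, 7, 3, 2
        rel = np.abs(rng.standard_normal((n, pos, f)))
        pred = rng.integers(0, n_classes, size=n)
        subs = rng.integers(0, 4, size=n)
        labels = rng.integers(0, k, size=f)
        tensor = RelevanceTensor(relevance=rel, predicted_class=pred,
                                 subjects=subs)
        asn = _assignment(labels, k=k)
        out = cluster_relevance(tensor, asn, n_classes=n_classes)

        expected = np.zeros((n_classes, k))
        for cls in range(n_classes):
            for c in range(k):
                for s in np.unique(subs):
                    mask = (pred == cls) & (subs == s)
                    if not mask.any():
                        continue
                    total = rel[mask].sum()
                    num = 0.0
                    for filt in range(f):
                        if labels[filt] == c:
                            num += rel[mask][:, :, filt].sum()
                    fc = int((labels == c).sum())
                    expected[cls, c] += (num / total) * (f - fc) / f
        assert np.allclose(out.nr, expected, rtol=1e-10)

    def test_zero_relevance_subject_excluded_with_warning(self, caplog):
        rel = np.ones((2, 3, 4))
        rel[1] = 0.0  # subject 9 contributes nothing
        tensor = RelevanceTensor(
            relevance=rel, predicted_class=np.zeros(2, dtype=int),
            subjects=np.array([1, 9]),
        )
        asn = _assignment([0, 0, 1, 1], k=2)
        with caplog.at_level(logging.WARNING, logger="filterscope.lrp"):
            out = cluster_relevance(tensor, asn, n_classes=1)
        assert "9" in caplog.text
        assert out.nr[0, 0] == pytest.approx(0.5 * 2 / 4)

    def test_reciprocal_scaling_switch(self):
        rel = np.ones((1, 2, 4))
        tensor = RelevanceTensor(relevance=rel,
                                 predicted_class=np.zeros(1, dtype=int),
                                 subjects=np.zeros(1))
        asn = _assignment([0, 0, 0, 1], k=2)
        printed = cluster_relevance(tensor, asn, n_classes=1,
                                    scaling="as_printed")
        recip = cluster_relevance(tensor, asn, n_classes=1,
                                  scaling="reciprocal")
        assert printed.nr[0, 0] == pytest.approx(0.75 * 1 / 4)
        assert recip.nr[0, 0] == pytest.approx(0.75 * 4 / 1)
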