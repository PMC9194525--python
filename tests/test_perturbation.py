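"""Perturbation engines: band partition, ablation, temporal sliding window,
and the weight-restoration guarantee."""

import numpy as np
import pytest

from filterscope import (
    CANONICAL_BANDS,
    FrequencyBand,
    ModelConfig,
    ablate_cluster,
    build_model,
    class_metrics,
    perturb_band,
    predict,
    temporal_ablation,
)
from filterscope.datasets import SignalDataset
from filterscope.errors import ConfigurationError, RestorationError
from filterscope.perturbation import band_bin_mask
from filterscope.spectra import ClusterAssignment, filter_power_spectra
from filterscope.model import get_first_layer_filters


def _dataset(n, n_t, fs=100.0, seed=0, n_classes=2):
    rng = np.random.default_rng(seed)
    return SignalDataset(
        windows=rng.standard_normal((n, n_t)),
        labels=rng.integers(0, n_classes, size=n),
        subjects=rng.integers(0, 3, size=n),
        fs=fs,
    )


@pytest.fixture
def band_model():
    """Tiny two-filter model at 100 Hz so the canonical bands apply."""
    cfg = ModelConfig(
        input_len=60, fs=100.0, n_filters1=2, filter_len1=8,
        pool1_size=5, pool1_stride=5, n_filters2=4, filter2_shape=(3, 2),
        pool2_size=(2, 1), pool2_stride=(1, 1), dense_sizes=(8,), n_classes=2,
    )
    return build_model(cfg, seed=5)


def _assignment(model, k=None):
    bank = get_first_layer_filters(model)
    spec = filter_power_spectra(bank)
    n = bank.n_filters
    labels = np.arange(n) % (k or n)
    kk = k or n
    centers = np.vstack([
        spec.power[labels == j].mean(axis=0) if (labels == j).any()
        else np.zeros(spec.power.shape[1])
        for j in range(kk)
    ])
    return ClusterAssignment(labels=labels, k=kk, centers=centers,
                             freqs=spec.freqs)


def _baseline(model, ds):
    labels, _ = predict(model, ds)
    return class_metrics(ds.labels, labels, model.config.n_classes)


class TestBandPartition:
    def test_canonical_bands_partition_the_dft_grid(self):
        """The five bands tile every DFT bin of a 100 Hz, 2-s filter exactly
        once: DC goes to delta, shared edges to the upper band, Nyquist to
        gamma."""
        freqs = np.fft.fftfreq(200, d=0.01)
        masks = [band_bin_mask(freqs, b, 100.0) for b in CANONICAL_BANDS]
        total = np.sum(masks, axis=0)
        assert np.array_equal(total, np.ones(200, dtype=int))
        delta, theta, alpha, beta, gamma = masks
        assert delta[0]  # DC
        assert theta[np.isclose(np.abs(freqs), 4.0)].all()  # edge upward
        assert gamma[np.isclose(np.abs(freqs), 50.0)].all()  # Nyquist

    def test_band_validation(self):
        with pytest.raises(ConfigurationError):
            FrequencyBand("bad", 8.0, 8.0)
        with pytest.raises(ConfigurationError):
            FrequencyBand("bad", -1.0, 4.0)


class TestAblateCluster:
    def test_empty_cluster_is_a_null_perturbation(self, band_model):
        ds = _dataset(20, 60)
        asn = _assignment(band_model, k=3)  # cluster 2 has no members
        baseline = _baseline(band_model, ds)
        res = ablate_cluster(band_model, asn, 2, ds, baseline)
        assert np.allclose(res.per_class_change, 0.0)
        assert res.weighted_change == 0.0

    def test_ablating_every_cluster_equals_zero_filter_model(self, band_model):
        """Sequentially measured: a model whose filters are all zero is the
        oracle for 'everything ablated'."""
        ds = _dataset(30, 60)
        asn = _assignment(band_model, k=2)
        conv1 = band_model.layers_by_name["conv1d"]
        w0 = conv1.params["W"].copy()
        conv1.params["W"] = np.zeros_like(w0)
        zero_labels, _ = predict(band_model, ds)
        conv1.params["W"] = w0

        w = w0.copy()
        for c in range(asn.k):
            w[asn.members(c)] = 0.0
        conv1.params["W"] = w
        all_ablated_labels, _ = predict(band_model, ds)
        conv1.params["W"] = w0
        assert np.array_equal(all_ablated_labels, zero_labels)

    def test_weights_restored_bit_exactly(self, band_model):
        ds = _dataset(20, 60)
        asn = _assignment(band_model, k=2)
        baseline = _baseline(band_model, ds)
        w0 = band_model.layers_by_name["conv1d"].params["W"].copy()
        _, p0 = predict(band_model, ds)
        ablate_cluster(band_model, asn, 0, ds, baseline)
        assert np.array_equal(band_model.layers_by_name["conv1d"].params["W"], w0)
        _, p1 = predict(band_model, ds)
        assert np.array_equal(p0, p1)

    def test_restoration_failure_is_a_hard_error(self, band_model, monkeypatch):
        """If anything (here: a sneaky bias shift) changes predictions
        between the pre- and post-run checks, the engine must raise."""
        from filterscope import perturbation as pert

        ds = _dataset(20, 60)
        asn = _assignment(band_model, k=2)
        baseline = _baseline(band_model, ds)
        real_evaluate = pert._evaluate

        def corrupting_evaluate(model, test):
            model.layers_by_name["conv1d"].params["b"] = (
                model.layers_by_name["conv1d"].params["b"] + 5.0
            )
            return real_evaluate(model, test)

        monkeypatch.setattr(pert, "_evaluate", corrupting_evaluate)
        with pytest.raises(RestorationError):
            ablate_cluster(band_model, asn, 0, ds, baseline)

    def test_invalid_cluster_id(self, band_model):
        ds = _dataset(10, 60)
        asn = _assignment(band_model, k=2)
        with pytest.raises(ConfigurationError):
            ablate_cluster(band_model, asn, 5, ds, _baseline(band_model, ds))


class TestPerturbBand:
    def test_band_without_filter_power_changes_nothing(self, band_model):
        """Filters restricted to the delta bins are untouched by a theta
        perturbation."""
        conv1 = band_model.layers_by_name["conv1d"]
        w = conv1.params["W"]
        freqs = np.fft.fftfreq(w.shape[1], d=0.01)
        keep = band_bin_mask(freqs, CANONICAL_BANDS[0], 100.0)  # delta only
        coeffs = np.fft.fft(w, axis=1)
        coeffs[:, ~keep] = 0.0
        conv1.params["W"] = np.fft.ifft(coeffs, axis=1).real
        ds = _dataset(20, 60)
        asn = _assignment(band_model, k=2)
        baseline = _baseline(band_model, ds)
        res = perturb_band(band_model, asn, 0, CANONICAL_BANDS[1], ds, baseline)
        assert np.allclose(res.per_class_change, 0.0)
        assert res.weighted_change == pytest.approx(0.0)

    def test_zeroing_all_bands_everywhere_equals_full_ablation(self, band_model):
        """Applying every canonical band to every cluster one after another
        (without restoring in between) empties the filters completely —
        checked against the directly zeroed model."""
        ds = _dataset(30, 60)
        conv1 = band_model.layers_by_name["conv1d"]
        w0 = conv1.params["W"].copy()
        freqs = np.fft.fftfreq(w0.shape[1], d=0.01)
        w = w0.copy()
        coeffs = np.fft.fft(w, axis=1)
        for band in CANONICAL_BANDS:
            coeffs[:, band_bin_mask(freqs, band, 100.0)] = 0.0
        w = np.fft.ifft(coeffs, axis=1).real
        assert np.allclose(w, 0.0, atol=1e-12)  # bands tile the whole grid
        conv1.params["W"] = w
        banded_labels, _ = predict(band_model, ds)
        conv1.params["W"] = np.zeros_like(w0)
        zeroed_labels, _ = predict(band_model, ds)
        conv1.params["W"] = w0
        assert np.array_equal(banded_labels, zeroed_labels)

    def test_restores_weights(self, band_model):
        ds = _dataset(15, 60)
        asn = _assignment(band_model, k=2)
        baseline = _baseline(band_model, ds)
        w0 = band_model.layers_by_name["conv1d"].params["W"].copy()
        perturb_band(band_model, asn, 1, CANONICAL_BANDS[3], ds, baseline)
        assert np.array_equal(
            band_model.layers_by_name["conv1d"].params["W"], w0
        )

    def test_band_above_nyquist_rejected(self, micro_model, micro_dataset):
        # micro model runs at 20 Hz: gamma (25-50) is out of range
        asn = _assignment(micro_model, k=2)
        baseline = _baseline(micro_model, micro_dataset)
        with pytest.raises(ConfigurationError, match="Nyquist"):
            perturb_band(micro_model, asn, 0, CANONICAL_BANDS[4],
                         micro_dataset, baseline)


class TestTemporalAblation:
    @pytest.fixture
    def spike_model(self):
        """One-filter model whose kernel is a single nonzero weight."""
        cfg = ModelConfig(
            input_len=60, fs=100.0, n_filters1=1, filter_len1=8,
            pool1_size=5, pool1_stride=5, n_filters2=4, filter2_shape=(3, 1),
            pool2_size=(2, 1), pool2_stride=(1, 1), dense_sizes=(8,),
            n_classes=2,
        )
        model = build_model(cfg, seed=2)
        w = np.zeros((1, 8))
        w[0, 5] = 1.5
        model.layers_by_name["conv1d"].params["W"] = w
        return model

    def test_single_spike_profile_matches_exhaustive_enumeration(self, spike_model):
        """Window length 3: only centers 4, 5, 6 cover the spike; their
        changes equal direct zeroing of the spike, all others are 0."""
        ds = _dataset(25, 60, seed=3)
        baseline = _baseline(spike_model, ds)
        imap = temporal_ablation(spike_model, ds, baseline, window_len=3, step=1)

        conv1 = spike_model.layers_by_name["conv1d"]
        w0 = conv1.params["W"].copy()
        expected = np.zeros((8, 3))
        for p in range(8):
            a, b = max(0, p - 1), min(8, p + 2)
            if not np.any(w0[0, a:b]):
                continue
            w = w0.copy()
            w[0, a:b] = 0.0
            conv1.params["W"] = w
            labels, _ = predict(spike_model, ds)
            m = class_metrics(ds.labels, labels, 2)
            conv1.params["W"] = w0
            with np.errstate(invalid="ignore", divide="ignore"):
                expected[p, :2] = np.where(
                    baseline.f1 > 0,
                    100.0 * (m.f1 - baseline.f1) / baseline.f1,
                    np.nan,
                )
            expected[p, 2] = (
                100.0 * (m.weighted_f1 - baseline.weighted_f1)
                / baseline.weighted_f1
            )
        assert np.allclose(imap.importance[0], expected, equal_nan=True)
        covering = np.zeros(8, dtype=bool)
        covering[4:7] = True
        assert not imap.importance[0, ~covering].any()

    def test_all_zero_filter_has_zero_importance_row(self, band_model):
        conv1 = band_model.layers_by_name["conv1d"]
        w = conv1.params["W"].copy()
        w[1] = 0.0
        conv1.params["W"] = w
        ds = _dataset(20, 60, seed=1)
        baseline = _baseline(band_model, ds)
        imap = temporal_ablation(band_model, ds, baseline, window_len=3)
        assert not imap.importance[1].any()

    def test_every_position_receives_a_value(self, band_model):
        ds = _dataset(15, 60, seed=2)
        baseline = _baseline(band_model, ds)
        imap = temporal_ablation(band_model, ds, baseline, window_len=5, step=3)
        assert imap.importance.shape == (2, 8, 3)
        assert np.isfinite(
            np.nan_to_num(imap.importance, nan=0.0)
        ).all()
        # step > 1: unevaluated centers inherit the nearest evaluated value
        assert np.array_equal(imap.importance[:, 1], imap.importance[:, 0])

    def test_predictions_identical_after_full_run(self, band_model):
        ds = _dataset(15, 60, seed=4)
        baseline = _baseline(band_model, ds)
        _, before = predict(band_model, ds)
        temporal_ablation(band_model, ds, baseline, window_len=3)
        _, after = predict(band_model, ds)
        assert np.array_equal(before, after)
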