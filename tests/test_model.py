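"""Architecture contracts: shapes, determinism, positions, gating, gradients."""

import numpy as np
import pytest

from pulsedet import nn
from pulsedet import model as mdl
from pulsedet.dataset import Window
from pulsedet.simulate import Segment, Trace


@pytest.fixture(scope="module")
def tiny_config():
    return mdl.ModelConfig(hidden_dim=32, n_queries=5, encoder_layers=1,
                           decoder_layers=1, attention_heads=4, ffn_dim=64,
                           backbone_base_width=4, backbone_blocks=(1, 1, 1, 1))


@pytest.fixture(scope="module")
def tiny_model(tiny_config):
    return mdl.PulseDetector(tiny_config)


def make_window(n=2000, seed=0, targets=()):
    rng = np.random.default_rng(seed)
    return Window(rng.normal(size=n), 0.0, 10_000.0,
                  targets=np.array(targets).reshape(-1, 2))


class TestPositionalEncoding:
    def test_position_zero(self):
        enc = mdl.encode_positions(4, 8)
        np.testing.assert_allclose(enc[0, 0::2], 0.0)
        np.testing.assert_allclose(enc[0, 1::2], 1.0)

    def test_rows_injective(self):
        enc = mdl.encode_positions(500, 16)
        distinct = {tuple(np.round(row, 12)) for row in enc}
        assert len(distinct) == 500

    def test_row_norm(self):
        enc = mdl.encode_positions(64, 32)
        np.testing.assert_allclose(np.linalg.norm(enc, axis=1),
                                   np.sqrt(32 / 2), atol=1e-6)

    def test_range_and_parity(self):
        enc = mdl.encode_positions(100, 12)
        assert enc.min() >= -1.0 and enc.max() <= 1.0
        with pytest.raises(ValueError):
            mdl.encode_positions(10, 7)


class TestBackbone:
    def test_output_length_matches_prediction(self, tiny_model):
        for n in (2000, 5000):
            x = nn.Tensor(np.random.default_rng(0).normal(size=(1, 1, n)))
            feats = tiny_model.backbone_forward(x)
            assert feats.shape == (1, tiny_model.backbone.output_length(n),
                                   tiny_model.config.hidden_dim)

    def test_deterministic(self, tiny_model):
        x = np.random.default_rng(1).normal(size=(2, 1, 2000))
        a = tiny_model.backbone_forward(nn.Tensor(x)).data
        b = tiny_model.backbone_forward(nn.Tensor(x)).data
        np.testing.assert_array_equal(a, b)

    def test_translation_equivariance(self, tiny_model):
        """Shifting a smooth input by one cumulative stride shifts features."""
        rng = np.random.default_rng(2)
        n = 4096
        stride = 32  # cumulative stride of the default topology
        base = np.cumsum(rng.normal(size=n + stride))
        base = base / base.std()
        a = tiny_model.backbone_forward(nn.Tensor(base[None, None, :n].copy())).data[0]
        b = tiny_model.backbone_forward(nn.Tensor(base[None, None, stride:n + stride].copy())).data[0]
        # compare overlapping part, one feature position apart
        va, vb = a[1:-1].ravel(), b[:-2].ravel()
        corr = np.corrcoef(va, vb)[0, 1]
        assert corr > 0.9


class TestTransformer:
    def test_fixed_output_count(self, tiny_model, tiny_config):
        """N embeddings come out regardless of the input sequence length."""
        for n in (2000, 5000):
            x = nn.Tensor(np.random.default_rng(3).normal(size=(2, 1, n)))
            out = tiny_model.transformer_forward(tiny_model.backbone_forward(x))
            assert out.shape == (2, tiny_config.n_queries, tiny_config.hidden_dim)

    def test_zero_layer_identity(self):
        cfg = mdl.ModelConfig(hidden_dim=16, n_queries=3, encoder_layers=0,
                              decoder_layers=0, attention_heads=2, ffn_dim=32,
                              backbone_base_width=4, backbone_blocks=(1, 1, 1, 1))
        model = mdl.PulseDetector(cfg)
        x = nn.Tensor(np.random.default_rng(4).normal(size=(2, 1, 1000)))
        out = model.transformer_forward(model.backbone_forward(x))
        np.testing.assert_allclose(out.data[0], model.queries.data, atol=1e-6)
        np.testing.assert_allclose(out.data[1], model.queries.data, atol=1e-6)

    def test_permutation_of_positioned_sequence(self, monkeypatch):
        """Permuting encoder inputs together with their positional encodings
        leaves decoder outputs unchanged (set property of attention)."""
        monkeypatch.setattr(nn, "DEFAULT_DTYPE", np.float64)
        cfg = mdl.ModelConfig(hidden_dim=16, n_queries=3, encoder_layers=1,
                              decoder_layers=1, attention_heads=2, ffn_dim=32,
                              backbone_base_width=4, backbone_blocks=(1, 1, 1, 1))
        model = mdl.PulseDetector(cfg)
        rng = np.random.default_rng(5)
        L = 20
        feats = rng.normal(size=(1, L, 16))
        positioned = feats + mdl.encode_positions(L, 16)

        def run(seq):
            memory = nn.Tensor(seq)
            for layer in model.encoder:
                memory = layer(memory)
            q = nn.reshape(model.queries, (1, cfg.n_queries, 16))
            for layer in model.decoder:
                q = layer(q, memory)
            return q.data

        base = run(positioned)
        perm = rng.permutation(L)
        permuted = run(positioned[:, perm, :])
        np.testing.assert_allclose(permuted, base, atol=1e-5)


class TestHeads:
    def test_outputs_in_open_unit_interval(self, tiny_model, tiny_config):
        x = nn.Tensor(np.random.default_rng(6).normal(size=(3, 1, 2000)))
        logits, segments = tiny_model(x)
        assert logits.shape == (3, tiny_config.n_queries, 2)
        assert (segments.data > 0).all() and (segments.data < 1).all()

    def test_full_set_emitted_with_surplus_no_pulse(self, tiny_model):
        """All N candidates are emitted; thresholding marks surplus no-pulse."""
        window = make_window(2000, seed=7)
        dets = tiny_model.predict_window(window, class_threshold=0.0)
        assert len(dets) <= tiny_model.config.n_queries
        all_probs = 1 / (1 + np.exp(-np.diff(
            -tiny_model(nn.Tensor(window.samples[None, None, :]))[0].data[0]).ravel()))
        assert all_probs.shape == (tiny_model.config.n_queries,)

    def test_deterministic(self, tiny_model):
        w = make_window(2000, seed=8)
        a = tiny_model.predict_window(w, class_threshold=0.0)
        b = tiny_model.predict_window(w, class_threshold=0.0)
        assert [(d.segment.start_ms, d.segment.end_ms, d.score) for d in a] \
            == [(d.segment.start_ms, d.segment.end_ms, d.score) for d in b]


class TestGradientFlow:
    def test_all_parameters_receive_gradient(self, tiny_config):
        """End-to-end differentiability: every parameter gets a finite, not
        identically zero gradient from the set loss."""
        from pulsedet import matching
        model = mdl.PulseDetector(tiny_config)
        x = nn.Tensor(np.random.default_rng(9).normal(size=(2, 1, 2000)))
        logits, segments = model(x)
        truth = np.array([[0.4, 0.1]])
        total = None
        for b in range(2):
            probs = 1 / (1 + np.exp(-(logits.data[b, :, 0] - logits.data[b, :, 1])))
            assign = matching.match_hungarian(probs, segments.data[b], truth)
            loss, _ = matching.hungarian_loss(logits[b], segments[b], truth, assign)
            total = loss if total is None else nn.add(total, loss)
        model.zero_grad()
        total.backward()
        zero_grads = 0
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            if np.abs(p.grad).max() == 0:
                zero_grads += 1
        assert zero_grads <= 2  # at most isolated dead units at init


class TestCounterAndGate:
    def test_untrained_counter_unavailable(self):
        counter = mdl.PulseCounter(base_width=4)
        with pytest.raises(mdl.CounterUnavailableError):
            counter.count(make_window(1000))

    def test_count_nonnegative_integer(self):
        counter = mdl.PulseCounter(base_width=4)
        counter.trained = True
        c = counter.count(make_window(1000, seed=11))
        assert isinstance(c, int) and c >= 0

    def test_gate_closed_everywhere_gives_no_detections(self, tiny_model):
        class ZeroCounter:
            def count(self, window):
                return 0

        trace = Trace(np.random.default_rng(12).normal(size=10_000), 10_000.0,
                      ground_truth=[Segment(100.0, 105.0)])
        assert mdl.detect(trace, tiny_model, ZeroCounter()) == []

    def test_detections_stay_inside_windows_and_sorted(self, tiny_model):
        trace = Trace(np.random.default_rng(13).normal(size=10_000), 10_000.0)
        dets = mdl.detect(trace, tiny_model, counter=None, window_seconds=0.2,
                          class_threshold=0.0)
        starts = [d.segment.start_ms for d in dets]
        assert starts == sorted(starts)
        for d in dets:
            assert 0.0 <= d.segment.start_ms < d.segment.end_ms <= 1000.0
            # never crosses a window boundary
            w = int(d.segment.start_ms // 200.0)
            assert d.segment.end_ms <= (w + 1) * 200.0 + 1e-9

    def test_no_autoregressive_loop(self, tiny_model):
        """Structural parallelism: candidate count is set by the query bank,
        not by the pulse content of the window."""
        empty = make_window(2000, seed=14)
        logits_a, _ = tiny_model(nn.Tensor(empty.samples[None, None, :]))
        busy = make_window(2000, seed=15)
        busy.samples[300:400] -= 25.0
        logits_b, _ = tiny_model(nn.Tensor(busy.samples[None, None, :]))
        assert logits_a.shape == logits_b.shape


class TestCheckpoints:
    def test_detector_roundtrip(self, tiny_model, tmp_path):
        path = tmp_path / "det.npz"
        mdl.save_detector(path, tiny_model)
        loaded = mdl.load_detector(path)
        assert loaded.config == tiny_model.config
        w = make_window(2000, seed=16)
        a = tiny_model.predict_window(w, class_threshold=0.0)
        b = loaded.predict_window(w, class_threshold=0.0)
        assert [(d.segment.start_ms, d.score) for d in a] \
            == [(d.segment.start_ms, d.score) for d in b]

    def test_counter_roundtrip(self, tmp_path):
        counter = mdl.PulseCounter(base_width=4, init_seed=3)
        counter.trained = True
        path = tmp_path / "cnt.npz"
        mdl.save_counter(path, counter)
        loaded = mdl.load_counter(path)
        assert loaded.trained
        w = make_window(1000, seed=17)
        assert loaded.count(w) == counter.count(w)

    def test_kind_mismatch_rejected(self, tiny_model, tmp_path):
        path = tmp_path / "det.npz"
        mdl.save_detector(path, tiny_model)
        with pytest.raises(ValueError):
            mdl.load_counter(path)
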