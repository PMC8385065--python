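"""Memory traces, softmax-signature comparison, embeddings, rendering."""

import numpy as np
import pytest

from chirpnet import _nn
from chirpnet import interpret_viz as iv
from chirpnet import legendre_memory as lm
from chirpnet import model_zoo as mz
from chirpnet import recurrent_cells as rc
from chirpnet import synthetic_audio as sa

rng = np.random.default_rng(0)


def lmu_model(n_classes=3, theta=8, seed=0):
    return mz.assemble_hybrid(mz.HybridSpec(
        representation="CNN1", temporal="LMU", size="S", rnn_layers=1,
        n_classes=n_classes, memory_size=16, theta=theta), seed=seed)


class _EnergyRep(_nn.Layer):
    """Test instrument: per-slide feature = mean level above the dB floor
    (exactly zero for silent slides), so the LMU drive mirrors signal energy."""

    def forward(self, x, train=False):  # x: (B*T, 1, H, W) normalized dB
        return (x.mean(axis=(1, 2, 3)) + 1.0)[:, None]  # silence -> 0

    def backward(self, dout):
        raise NotImplementedError


def passthrough_lmu_model(n_steps, d=16):
    """Hybrid whose drive equals the per-slide energy feature exactly."""
    model = lmu_model(theta=n_steps)
    model.representation = _EnergyRep()
    cell = model.rnn_layers[0].cell
    cell.input_size = 1
    cell.system = lm.default_system(d, n_steps=n_steps)
    cell.weights["e_x"] = np.ones(1, np.float32)
    cell.weights["e_h"][...] = 0
    cell.weights["e_m"][...] = 0
    cell.weights["W_x"] = np.zeros((cell.hidden_size, 1), np.float32)
    cell.memory_size = d
    cell.weights["W_m"] = np.zeros((cell.hidden_size, d), np.float32)
    return model


def pulse_stack(n_steps=12, onset_step=4):
    """Slide stack whose slices are silent before ``onset_step`` (dB floor)
    and active after."""
    slices = np.full((n_steps, 16, 8), -80.0, np.float32)
    slices[onset_step:, 4:8, :] = -10.0
    return slices


class TestMemoryTrace:
    def test_zero_encoders_zero_trace(self):
        model = lmu_model(theta=6)
        cell = model.rnn_layers[0].cell
        for k in ("e_x", "e_h", "e_m"):
            cell.weights[k][...] = 0
        trace = iv.memory_trace(model, rng.uniform(-80, 0, (6, 64, 16)))
        assert np.all(trace.values == 0.0)

    def test_channels_silent_before_onset_active_after(self):
        model = passthrough_lmu_model(n_steps=12)
        trace = iv.memory_trace(model, pulse_stack(12, onset_step=4))
        assert np.abs(trace.values[:, :4]).max() < 1e-6
        assert np.abs(trace.values[:, 4:]).max() > 1e-3

    def test_trace_equals_run_recursive_on_the_drive(self):
        """Frozen pass-through LMU: the recorded memory equals the standalone
        recursion driven by the per-slide energies (module cross-oracle)."""
        n = 10
        model = passthrough_lmu_model(n_steps=n)
        stack = pulse_stack(n, onset_step=3)
        trace = iv.memory_trace(model, stack)
        drive = (stack * model.input_norm.scale
                 + model.input_norm.shift).mean(axis=(1, 2)) + 1.0
        ref = lm.run_recursive(lm.default_system(16, n_steps=n),
                               drive).coeffs
        np.testing.assert_allclose(trace.values, ref, atol=1e-5)

    def test_causality_of_traces(self):
        model = lmu_model(theta=8)
        stack = rng.uniform(-80, 0, (8, 64, 16)).astype(np.float32)
        a = iv.memory_trace(model, stack).values
        tampered = stack.copy()
        tampered[5:] = -80.0
        b = iv.memory_trace(model, tampered).values
        np.testing.assert_allclose(a[:, :5], b[:, :5], atol=1e-6)

    def test_model_without_lmu_rejected(self):
        model = mz.assemble_hybrid(mz.HybridSpec(
            representation="CNN1", temporal="GRU", size="S", rnn_layers=1,
            n_classes=3), seed=0)
        with pytest.raises(sa.ValidationError):
            iv.memory_trace(model, rng.uniform(-80, 0, (4, 64, 16)))


class TestSignatures:
    def test_references(self):
        y = np.array([0, 2, 1])
        true_sig, rand_sig = iv.reference_signatures(y, 3)
        np.testing.assert_array_equal(
            true_sig.blocks(), [[1, 0, 0], [0, 0, 1], [0, 1, 0]])
        blocks = rand_sig.blocks()
        np.testing.assert_allclose(blocks.sum(axis=1), 1.0)
        assert np.ptp(blocks) == 0.0  # all entries equal (maximum entropy)

    def test_perfect_hard_classifier_matches_true_anchor(self):
        y = np.array([1, 0, 1, 2])

        class Hard:
            def forward(self, X, train=False):
                out = np.zeros((len(X), 3))
                out[np.arange(len(X)), X[:, 0].astype(int)] = 1.0
                return out

        sig = iv.signature(Hard(), y[:, None].astype(float), "hard")
        true_sig, _ = iv.reference_signatures(y, 3)
        assert np.linalg.norm(sig.vector - true_sig.vector) == 0.0

    def test_signature_blocks_sum_to_one(self):
        model = lmu_model(theta=4)
        sig = iv.signature(model, rng.uniform(-80, 0, (5, 4, 64, 16)))
        np.testing.assert_allclose(sig.blocks().sum(axis=1), 1.0, atol=1e-6)

    def test_random_anchor_has_maximal_entropy(self):
        y = np.array([0, 1, 1, 0])
        model = lmu_model(theta=4)
        sig = iv.signature(model, rng.uniform(-80, 0, (4, 4, 64, 16)),
                           "m")
        _, rand_sig = iv.reference_signatures(y, 3)

        def entropy(s):
            b = np.clip(s.blocks(), 1e-12, 1)
            return -(b * np.log(b)).sum(axis=1)

        assert np.all(entropy(sig) <= np.log(3) + 1e-9)
        np.testing.assert_allclose(entropy(rand_sig), np.log(3), atol=1e-12)


class TestPCACompare:
    def _sig(self, vec, name):
        return iv.ModelSignature(np.asarray(vec, float), name, n_classes=2)

    def test_rank_two_distances_preserved(self):
        """Signatures in a 2-D affine subspace: the projection reproduces all
        pairwise distances exactly."""
        basis = rng.standard_normal((2, 40))
        weights = rng.standard_normal((5, 2))
        vecs = weights @ basis + rng.standard_normal(40)
        sigs = [self._sig(v, f"m{i}") for i, v in enumerate(vecs)]
        coords = iv.pca_compare(sigs)
        for i in range(5):
            for j in range(5):
                d2 = np.linalg.norm(coords[f"m{i}"] - coords[f"m{j}"])
                dfull = np.linalg.norm(vecs[i] - vecs[j])
                assert d2 == pytest.approx(dfull, abs=1e-8)

    def test_collinear_signatures_have_flat_second_axis(self):
        base = rng.standard_normal(20)
        direction = rng.standard_normal(20)
        sigs = [self._sig(base + t * direction, f"m{t}") for t in range(4)]
        coords = iv.pca_compare(sigs)
        assert max(abs(c[1]) for c in coords.values()) < 1e-8

    def test_duplicate_signatures_coincide(self):
        v = rng.standard_normal(12)
        sigs = [self._sig(v, "a"), self._sig(v, "b"),
                self._sig(rng.standard_normal(12), "c")]
        coords = iv.pca_compare(sigs)
        np.testing.assert_allclose(coords["a"], coords["b"], atol=1e-10)

    def test_too_few_or_mismatched_rejected(self):
        with pytest.raises(sa.ValidationError):
            iv.pca_compare([self._sig(np.ones(4), "a"),
                            self._sig(np.ones(4), "b")])
        with pytest.raises(sa.ValidationError):
            iv.pca_compare([self._sig(np.ones(4), "a"),
                            self._sig(np.ones(4), "b"),
                            self._sig(np.ones(6), "c")])


class TestEmbeddings:
    def _model_and_data(self):
        ds = sa.make_dataset(2, 12, clip_len=1.5, sample_rate=16_000, seed=4)
        from chirpnet import frontend as fe
        mel = fe.MelParams(sample_rate=16_000, n_mels=64, n_fft=1024,
                           hop_length=512)
        X = np.stack([fe.build_slide_stack(c, fe.SlideSpec(), mel).slices
                      for c in ds.clips]).astype(np.float32)
        y = np.array(ds.labels)
        model = mz.assemble_hybrid(mz.HybridSpec(
            representation="CNN1", temporal="GRU", size="S", rnn_layers=1,
            n_classes=2, theta=X.shape[1]), seed=0)
        return model, X, y

    def test_disjoint_bands_separate_in_embedding(self):
        """Two species with distinct frequency bands: mean inter-class
        distance in the seeded embedding exceeds mean intra-class distance."""
        model, X, y = self._model_and_data()
        emb = iv.embed_representations(model, X, y, top_k_species=2, seed=0)
        assert emb.points.shape == (len(y), 2)
        d = np.linalg.norm(emb.points[:, None] - emb.points[None], axis=-1)
        same = y[:, None] == y[None]
        np.fill_diagonal(same, False)
        inter = d[y[:, None] != y[None]].mean()
        intra = d[same].mean()
        assert inter > intra

    def test_top_k_filtering_and_bounds(self):
        model, X, y = self._model_and_data()
        emb = iv.embed_representations(model, X, y, top_k_species=1, seed=0)
        assert emb.points.shape[0] == np.sum(y == emb.labels[0])
        with pytest.raises(sa.ValidationError):
            iv.embed_representations(model, X, y, top_k_species=5)

    def test_embedding_deterministic_under_seed(self):
        model, X, y = self._model_and_data()
        a = iv.embed_representations(model, X, y, 2, seed=3)
        b = iv.embed_representations(model, X, y, 2, seed=3)
        np.testing.assert_array_equal(a.points, b.points)


class TestRender:
    def test_identical_inputs_identical_bytes(self, tmp_path):
        trace = iv.MemoryTrace(values=rng.standard_normal((8, 6)),
                               slide_times=np.arange(6) * 0.25)
        p1 = iv.render(trace, tmp_path / "a.png")
        p2 = iv.render(trace, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_trace_axes_follow_hop_mapping(self, tmp_path):
        times = np.arange(10) * 0.25  # k * Hs seconds
        trace = iv.MemoryTrace(values=rng.standard_normal((4, 10)),
                               slide_times=times)
        out = iv.render(trace, tmp_path / "t.png",
                        spectrogram=rng.uniform(-80, 0, (16, 40)))
        assert out.exists() and out.stat().st_size > 0
        assert times[-1] == pytest.approx(2.25)

    def test_empty_trace_still_renders(self, tmp_path):
        trace = iv.MemoryTrace(values=np.zeros((4, 0)),
                               slide_times=np.zeros(0))
        out = iv.render(trace, tmp_path / "empty.png")
        assert out.exists() and out.stat().st_size > 0
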