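"""AC-GAN model: loss identities, objective composition, head coupling and
gradient-direction sanity of the adversarial updates."""

import numpy as np
import pytest

from pdl1tps import nn
from pdl1tps.acgan import (ACGANSpec, Discriminator, Generator, class_loss,
                           discriminator_forward, generator_forward,
                           load_checkpoint, model_state, objectives,
                           save_checkpoint, set_model_state, source_loss)

SPEC = ACGANSpec(patch_size=16, n_classes=8, d_z=20, base_width=8)


def _onehot(labels, k):
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


class TestSourceLoss:
    def test_perfect_discrimination_is_zero_within_clipping(self):
        l_s = source_loss(np.ones(10), np.zeros(10))
        assert l_s <= 0.0
        assert abs(l_s) <= 3e-7  # 2 * eps

    def test_chance_level_is_two_log_half(self):
        l_s = source_loss(np.full(5, 0.5), np.full(5, 0.5))
        assert np.isclose(l_s, 2 * np.log(0.5), atol=1e-9)

    def test_monotone_in_real_probability(self):
        p_fake = np.full(4, 0.3)
        values = [source_loss(np.full(4, p), p_fake) for p in (0.2, 0.5, 0.8, 0.99)]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestClassLoss:
    def test_confident_correct_predictions_near_zero(self):
        probs = np.eye(8)[[0, 3, 5]]
        l_c = class_loss(probs, [0, 3, 5], probs, [0, 3, 5])
        assert abs(l_c) < 1e-5

    def test_uniform_predictions_give_two_log_one_over_k(self):
        probs = np.full((6, 8), 1.0 / 8)
        labels = np.arange(6)
        assert np.isclose(class_loss(probs, labels, probs, labels), 2 * np.log(1 / 8), atol=1e-6)

    def test_empty_labeled_real_subset_leaves_fake_term(self):
        probs_fake = np.full((4, 8), 1.0 / 8)
        l_c = class_loss(np.empty((0, 8)), np.empty(0, dtype=int), probs_fake, [0, 1, 2, 3])
        assert np.isclose(l_c, np.log(1 / 8), atol=1e-6)


class TestObjectives:
    @pytest.mark.parametrize(
        "l_s, l_c, expected",
        [(-1.0, -2.0, (-3.0, 1.0)), (0.0, 0.0, (0.0, 0.0)), (-0.5, -0.25, (-0.75, -0.25))],
    )
    def test_composition(self, l_s, l_c, expected):
        assert objectives(l_s, l_c) == expected

    def test_raising_class_loss_helps_both_players(self):
        d0, g0 = objectives(-1.0, -2.0)
        d1, g1 = objectives(-1.0, -1.0)  # L_C improved
        assert d1 > d0  # discriminator objective (maximized) rises
        assert g1 < g0  # generator objective (minimized) falls


class TestGenerator:
    def test_deterministic_given_z_c_params(self, rng):
        gen = Generator(SPEC, np.random.default_rng(0))
        z = rng.standard_normal((4, SPEC.d_z))
        c = _onehot([0, 1, 2, 3], SPEC.n_classes)
        a = generator_forward(gen, z, c)
        b = generator_forward(gen, z, c)
        assert np.array_equal(a, b)

    def test_output_shape_and_range(self, rng):
        gen = Generator(SPEC, np.random.default_rng(0))
        z = rng.standard_normal((5, SPEC.d_z))
        c = _onehot([0] * 5, SPEC.n_classes)
        img = generator_forward(gen, z, c)
        assert img.shape == (5, 3, SPEC.patch_size, SPEC.patch_size)
        assert img.min() >= -1.0 and img.max() <= 1.0

    def test_non_onehot_condition_rejected(self, rng):
        gen = Generator(SPEC, np.random.default_rng(0))
        z = rng.standard_normal((2, SPEC.d_z))
        bad = np.full((2, SPEC.n_classes), 0.5)
        with pytest.raises(ValueError, match="one-hot"):
            generator_forward(gen, z, bad)

    def test_dimension_mismatch_rejected(self, rng):
        gen = Generator(SPEC, np.random.default_rng(0))
        with pytest.raises(ValueError):
            gen.forward(rng.standard_normal((2, SPEC.d_z + 1)), _onehot([0, 1], SPEC.n_classes))


class TestDiscriminator:
    def test_class_posterior_sums_to_one(self, rng):
        disc = Discriminator(SPEC, np.random.default_rng(0))
        x = rng.standard_normal((6, 3, 16, 16)).astype(np.float32)
        out = discriminator_forward(disc, x)
        assert np.allclose(out.p_class.sum(axis=1), 1.0, atol=1e-6)
        assert ((out.p_source >= 0) & (out.p_source <= 1)).all()

    def test_fresh_model_near_uniform_class_entropy(self, rng):
        """At initialization the auxiliary head should be uninformative:
        mean posterior entropy close to log K over random inputs."""
        disc = Discriminator(SPEC, np.random.default_rng(3))
        x = rng.standard_normal((100, 3, 16, 16)).astype(np.float32)
        p = discriminator_forward(disc, x).p_class
        entropy = -(p * np.log(p)).sum(axis=1).mean()
        assert entropy > 0.95 * np.log(SPEC.n_classes)

    def test_batch_order_preserved(self, rng):
        # eval mode: a training-mode forward advances the spectral-norm
        # power iteration, which is stateful by design
        disc = Discriminator(SPEC, np.random.default_rng(0))
        disc.set_training(False)
        x = rng.standard_normal((4, 3, 16, 16)).astype(np.float32)
        batch = discriminator_forward(disc, x)
        for i in range(4):
            single = discriminator_forward(disc, x[i : i + 1])
            assert np.allclose(single.p_class[0], batch.p_class[i], atol=1e-5)

    def test_trunk_is_shared_between_heads(self, rng):
        """Perturbing one trunk weight moves both the source and the class
        output — the auxiliary classifier shares parameters with D."""
        disc = Discriminator(SPEC, np.random.default_rng(0))
        x = rng.standard_normal((3, 3, 16, 16)).astype(np.float32)
        before = discriminator_forward(disc, x)
        trunk_conv = disc.trunk.layers[0]
        trunk_conv.W.value[0, :] += 0.5
        after = discriminator_forward(disc, x)
        assert not np.allclose(before.p_source, after.p_source)
        assert not np.allclose(before.p_class, after.p_class)

    def test_discriminator_convs_spectrally_normalized(self):
        disc = Discriminator(SPEC, np.random.default_rng(0))
        convs = [l for l in disc.trunk.layers if isinstance(l, nn.Conv2d)]
        assert convs and all(c.spectral_norm for c in convs)


class TestAdversarialGradientSanity:
    """One optimizer step in each direction moves the corresponding
    objective the right way on a fixed toy batch."""

    def _setup(self):
        rng = np.random.default_rng(11)
        gen = Generator(SPEC, np.random.default_rng(1))
        disc = Discriminator(SPEC, np.random.default_rng(2))
        x_real = rng.standard_normal((8, 3, 16, 16)).astype(np.float32) * 0.5
        y_real = rng.integers(0, SPEC.n_classes, 8)
        z = rng.standard_normal((8, SPEC.d_z)).astype(np.float32)
        y_fake = rng.integers(0, SPEC.n_classes, 8)
        return gen, disc, x_real, y_real, z, y_fake

    def _d_objective(self, gen, disc, x_real, y_real, z, y_fake):
        x_fake = gen.forward(z, _onehot(y_fake, SPEC.n_classes))
        out_r = discriminator_forward(disc, x_real)
        out_f = discriminator_forward(disc, x_fake)
        l_s = source_loss(out_r.p_source, out_f.p_source)
        l_c = class_loss(out_r.p_class, y_real, out_f.p_class, y_fake)
        return objectives(l_s, l_c)

    def test_discriminator_step_raises_d_objective(self):
        gen, disc, x_real, y_real, z, y_fake = self._setup()
        gen.set_training(False)
        disc.set_training(False)  # freeze BN/SN state: compare a pure weight move
        d_before, _ = self._d_objective(gen, disc, x_real, y_real, z, y_fake)

        x_fake = gen.forward(z, _onehot(y_fake, SPEC.n_classes))
        x_all = np.concatenate([x_real, x_fake])
        s_logits, c_logits = disc.forward(x_all)
        p_s = nn.sigmoid(s_logits)
        p_c = nn.softmax(c_logits)
        n = len(x_real)
        ds = np.concatenate([-(1 - p_s[:n]) / n, p_s[n:] / n]).astype(np.float32)
        dc = np.zeros_like(c_logits)
        dc[:n] = (p_c[:n] - _onehot(y_real, SPEC.n_classes)) / n
        dc[n:] = (p_c[n:] - _onehot(y_fake, SPEC.n_classes)) / n
        opt = nn.Adam(disc.parameters(), lr=1e-4)
        opt.zero_grad()
        disc.backward(ds, dc.astype(np.float32))
        opt.step()

        d_after, _ = self._d_objective(gen, disc, x_real, y_real, z, y_fake)
        assert d_after > d_before

    def test_generator_step_lowers_g_objective(self):
        gen, disc, x_real, y_real, z, y_fake = self._setup()
        gen.set_training(False)
        disc.set_training(False)
        _, g_before = self._d_objective(gen, disc, x_real, y_real, z, y_fake)

        c = _onehot(y_fake, SPEC.n_classes)
        x_fake = gen.forward(z, c)
        s_logits, c_logits = disc.forward(x_fake)
        p_s = nn.sigmoid(s_logits)
        p_c = nn.softmax(c_logits)
        n = len(z)
        ds = (-p_s / n).astype(np.float32)
        dc = ((p_c - c) / n).astype(np.float32)
        opt = nn.Adam(gen.parameters(), lr=1e-4)
        opt.zero_grad()
        dx = disc.backward(ds, dc)
        gen.backward(dx)
        opt.step()

        _, g_after = self._d_objective(gen, disc, x_real, y_real, z, y_fake)
        assert g_after < g_before


class TestCheckpointRoundTrip:
    def test_save_load_preserves_outputs(self, tmp_path, rng):
        disc = Discriminator(SPEC, np.random.default_rng(0))
        x = rng.standard_normal((3, 3, 16, 16)).astype(np.float32)
        before = disc.predict_proba(x)
        save_checkpoint(tmp_path / "model.npz", disc, extra={"note": "test"})
        loaded = load_checkpoint(tmp_path / "model.npz")
        assert np.allclose(loaded.predict_proba(x), before)

    def test_state_roundtrip_in_memory(self, rng):
        gen = Generator(SPEC, np.random.default_rng(0))
        state = model_state(gen)
        gen2 = Generator(SPEC, np.random.default_rng(99))
        set_model_state(gen2, state)
        z = rng.standard_normal((2, SPEC.d_z))
        c = _onehot([0, 1], SPEC.n_classes)
        gen.set_training(False)
        gen2.set_training(False)
        assert np.allclose(gen.forward(z, c), gen2.forward(z, c))
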