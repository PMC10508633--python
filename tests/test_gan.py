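"""Network shape contracts, loss algebra, and training-loop behaviour."""

import numpy as np
import pytest

from occlugen.gan import (
    Checkpoint,
    DiscriminatorSpec,
    GanConfig,
    GeneratorSpec,
    adversarial_terms,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generate,
    generator_loss,
    l1_term,
    patch_mean_prob,
    perceptual_deviation,
    train,
)
from occlugen.gan.nn import Adam
from occlugen.gan.training import load_triplet_arrays


class TestGeneratorContracts:
    @pytest.mark.parametrize("res", [64, 32])
    def test_output_matches_input_spatial_shape(self, res):
        gen = build_generator(GeneratorSpec.for_resolution(res, base_channels=16), seed=1)
        out, _ = gen.forward(np.zeros((2, res, res), dtype=np.float32))
        assert out.shape == (1, res, res)
        assert (-1 <= out).all() and (out <= 1).all()

    def test_seeded_initialization_deterministic(self):
        spec = GeneratorSpec.for_resolution(32, base_channels=8)
        g1 = build_generator(spec, seed=3)
        g2 = build_generator(spec, seed=3)
        x = np.random.default_rng(0).normal(size=(2, 32, 32)).astype(np.float32)
        o1, _ = g1.forward(x)
        o2, _ = g2.forward(x)
        assert np.array_equal(o1, o2)

    def test_invalid_resolution_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec.for_resolution(100)

    def test_asymmetric_spec_rejected(self):
        spec = GeneratorSpec(resolution=64, encoder_channels=(8, 16))
        with pytest.raises(ValueError, match="asymmetric"):
            spec.validate()


class TestDiscriminatorContracts:
    def test_patch_matrix_size_arithmetic(self):
        # strides 2,2,2,1 then the final stride-1 conv: 256 -> 30
        assert DiscriminatorSpec.for_resolution(256).patch_size() == 30
        assert DiscriminatorSpec.for_resolution(64).patch_size() == 6

    def test_outputs_are_probabilities(self):
        dis = build_discriminator(DiscriminatorSpec.for_resolution(64, base_channels=16), seed=2)
        x = np.random.default_rng(1).normal(size=(3, 64, 64)).astype(np.float32)
        patch, acts, _ = dis.forward(x)
        assert patch.shape == (6, 6)
        assert ((patch > 0) & (patch < 1)).all()

    def test_exposed_layers_returned(self):
        dis = build_discriminator(DiscriminatorSpec.for_resolution(64, base_channels=16), seed=2)
        _, acts, _ = dis.forward(np.zeros((3, 64, 64), dtype=np.float32))
        assert set(acts) == {2, 3, 4}


class TestLossAlgebra:
    def test_constant_half_discriminator(self):
        class Stub:
            def forward(self, x):
                return np.full((4, 4), 0.5), {}, None

        x = np.zeros((1, 8, 8))
        t_real, t_fake = adversarial_terms(Stub(), x, x, x, x)
        assert t_real == pytest.approx(np.log(0.5), abs=1e-12)
        assert t_fake == pytest.approx(np.log(0.5), abs=1e-12)

    def test_perfect_discriminator_terms_vanish(self):
        class Stub:
            def __init__(self):
                self.calls = 0

            def forward(self, x):
                self.calls += 1
                v = 1.0 if self.calls == 1 else 0.0
                return np.full((4, 4), v), {}, None

        x = np.zeros((1, 8, 8))
        t_real, t_fake = adversarial_terms(Stub(), x, x, x, x)
        # clamped at eps away from {0, 1}: both terms approach 0
        assert abs(t_real) < 1e-6 and abs(t_fake) < 1e-6

    def test_patch_mean_hand_matrix(self):
        patch = np.array([[0.2, 0.4], [0.6, 0.8]])
        assert patch_mean_prob(patch) == pytest.approx(0.5, abs=1e-12)
        assert np.log(patch_mean_prob(patch)) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_l1_closed_forms(self):
        a = np.zeros((2, 2))
        assert l1_term(a, a) == 0.0
        assert l1_term(a, a + 0.3) == pytest.approx(0.3, abs=1e-12)
        b = a.copy()
        b[0, 0] = 1.0
        assert l1_term(b, a) == pytest.approx(0.25, abs=1e-12)

    def test_perceptual_hand_values(self):
        acts_y = {2: np.array([[[3.0]]])}
        acts_g = {2: np.array([[[1.0]]])}
        s, total = perceptual_deviation(acts_y, acts_g, {2: 2.0})
        assert s[2] == pytest.approx(2.0, abs=1e-12)
        assert total == pytest.approx(4.0, abs=1e-12)

    def test_perceptual_identical_zero_and_weight_linearity(self):
        rng = np.random.default_rng(0)
        a = {2: rng.normal(size=(3, 4, 4)), 3: rng.normal(size=(6, 2, 2))}
        b = {k: v + rng.normal(size=v.shape) for k, v in a.items()}
        _, t0 = perceptual_deviation(a, a, {2: 1.0, 3: 2.0})
        assert t0 == 0.0
        _, t1 = perceptual_deviation(a, b, {2: 1.0, 3: 2.0})
        _, t2 = perceptual_deviation(a, b, {2: 2.0, 3: 4.0})
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_generator_loss_hand_value(self):
        cfg = GanConfig(group=3)
        assert generator_loss(cfg, 0.7, 0.1, 0.02) == pytest.approx(11.7, abs=1e-12)

    def test_generator_loss_group_reductions(self):
        adv, l1v, perc = 0.7, 0.1, 0.02
        g1 = generator_loss(GanConfig(group=1), adv, l1v, perc)
        assert g1 == pytest.approx(adv, abs=1e-15)
        zeroed = generator_loss(GanConfig(group=3, lambda_l1=0, lambda_pg=0), adv, l1v, perc)
        assert zeroed == pytest.approx(g1, abs=1e-15)

    def test_discriminator_hinge_values(self):
        cfg = GanConfig(group=3)  # m=0.35, lambda_pd=20
        base = discriminator_loss(cfg, (0.0, 0.0), perceptual_sum=0.5)
        assert base == pytest.approx(0.0, abs=1e-12)  # hinge inactive
        active = discriminator_loss(cfg, (0.0, 0.0), perceptual_sum=0.15)
        assert active == pytest.approx(4.0, abs=1e-12)
        no_margin_cfg = GanConfig(group=3, margin=1e-12)
        assert discriminator_loss(no_margin_cfg, (0.0, 0.0), 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            GanConfig(group=4)


class TestTrainingLoop:
    def test_history_length_one_sample_one_epoch(self, tiny_dataset):
        cfg = GanConfig(group=2, epochs=1, seed=0, base_channels=8)
        _, hist = train(tiny_dataset[:1], cfg)
        assert len(hist) == 1
        assert len(hist.loss_g) == 1 and len(hist.loss_d) == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], GanConfig())

    def test_single_generator_step_decreases_loss(self, tiny_dataset):
        """With the discriminator frozen, one small generator step lowers L(G)."""
        cfg = GanConfig(group=2, seed=4, base_channels=8)
        x, op, y = load_triplet_arrays(tiny_dataset[0])
        from occlugen.gan.networks import (
            DiscriminatorSpec,
            GeneratorSpec,
            build_discriminator,
            build_generator,
        )

        res = x.shape[-1]
        gen = build_generator(GeneratorSpec.for_resolution(res, 8), seed=10)
        dis = build_discriminator(DiscriminatorSpec.for_resolution(res, 8), seed=11)
        cond = np.concatenate([x, op], axis=0)

        def g_loss():
            out, cache = gen.forward(cond)
            patch, _, dcache = dis.forward(np.concatenate([x, op, out], axis=0))
            pf = patch_mean_prob(patch)
            return generator_loss(cfg, -np.log(pf), l1_term(out, y), 0.0), out, cache, dcache, patch

        before, out, cache, dcache, patch = g_loss()
        npatch = patch.size
        dpatch = np.full(patch.shape, -1.0 / (patch_mean_prob(patch) * npatch), dtype=np.float32)
        d_fake_in, _ = dis.backward(dcache, dpatch)
        d_gout = d_fake_in[2:] + (cfg.lambda_l1 / y.size) * np.sign(out - y).astype(np.float32)
        grads = gen.backward(cache, d_gout)
        Adam(gen.params, lr=1e-4, beta1=cfg.beta1, beta2=cfg.beta2).step(grads)
        after = g_loss()[0]
        assert after < before

    def test_generate_deterministic_and_in_range(self, tiny_dataset):
        cfg = GanConfig(group=1, epochs=1, seed=2, base_channels=8)
        ckpt, _ = train(tiny_dataset[:2], cfg)
        from PIL import Image

        x = np.asarray(Image.open(tiny_dataset[0]["x_path"]).convert("L"))
        op = np.asarray(Image.open(tiny_dataset[0]["op_path"]).convert("L"))
        a = generate(ckpt, x, op)
        b = generate(ckpt, x, op)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.dtype == np.uint8

    def test_untrained_generator_near_constant_on_zero_input(self):
        gen = build_generator(GeneratorSpec.for_resolution(64, base_channels=16), seed=7)
        out, _ = gen.forward(np.zeros((2, 64, 64), dtype=np.float32))
        grey = (out[0] + 1.0) * 127.5
        assert grey.std() < 10.0

    def test_checkpoint_round_trip_identical_output(self, tiny_dataset, tmp_path):
        cfg = GanConfig(group=2, epochs=1, seed=6, base_channels=8)
        ckpt, _ = train(tiny_dataset[:1], cfg)
        p = tmp_path / "ck.npz"
        ckpt.save(p)
        loaded = Checkpoint.load(p)
        from PIL import Image

        x = np.asarray(Image.open(tiny_dataset[0]["x_path"]).convert("L"))
        op = np.asarray(Image.open(tiny_dataset[0]["op_path"]).convert("L"))
        assert np.array_equal(generate(ckpt, x, op).pixels, generate(loaded, x, op).pixels)

    def test_resolution_mismatch_rejected(self, tiny_dataset):
        cfg = GanConfig(group=1, epochs=1, seed=2, base_channels=8)
        ckpt, _ = train(tiny_dataset[:1], cfg)
        with pytest.raises(ValueError, match="resolution"):
            generate(ckpt, np.zeros((32, 32), dtype=np.uint8), np.zeros((32, 32), dtype=np.uint8))
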