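"""GAN: architecture contracts, loss closed forms, R1 oracle, sampling,
scoring, determinism.  Training-quality checks at full desk scale live in
the acceptance suite; here training runs are short."""

import numpy as np
import pytest

from deepevo import nn
from deepevo import variant_generator as vg
from deepevo.nn import autograd as ag
from deepevo.seqio import AMINO_ACIDS, SequenceRecord
from deepevo.variant_generator import (GanConfig, GanPair, build_gan,
                                       discriminator_score, generate,
                                       ns_discriminator_loss,
                                       ns_generator_loss, r1_penalty,
                                       train_gan)

TINY = dict(l_max=32, channels=8, attention_heads=2, noise_dim=16,
            total_steps=8, attention_pool=4)


@pytest.fixture(scope="module")
def tiny_family():
    from deepevo.synthdata import FamilyConfig, make_family

    records, _ = make_family(FamilyConfig(
        n_sequences=80, length=32, seed=5,
        motif_positions=frozenset({5, 9}),
        trait_positions=frozenset({3, 16, 28})))
    return records


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(total_steps=0), dict(noise_dim=0),
        dict(lr_start=1e-5, lr_end=1e-3),
        dict(channels=10, attention_heads=4),
        dict(l_max=30, attention_pool=4),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GanConfig(**kwargs)

    def test_presets(self):
        desk = GanConfig.desk_preset()
        assert desk.l_max == 128 and desk.total_steps == 2000
        paper = GanConfig.paper_preset()
        assert paper.l_max == 512 and paper.total_steps == 200_000


class TestArchitecture:
    def test_untrained_generator_rows_sum_to_one(self):
        pair = build_gan(GanConfig(**TINY))
        z = np.random.default_rng(0).standard_normal((4, 16))
        out = pair.generator(ag.Tensor(z)).data
        assert out.shape == (4, 32, 21)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-6)

    def test_discriminator_returns_finite_scalar(self):
        pair = build_gan(GanConfig(**TINY))
        x = np.random.default_rng(0).uniform(size=(3, 32, 21))
        logits = pair.discriminator(ag.Tensor(x)).data
        assert logits.shape == (3, 1)
        assert np.isfinite(logits).all()

    def test_parameter_count_matches_hand_count(self):
        config = GanConfig(**TINY, n_resnet_blocks=2)
        pair = build_gan(config)
        c, l, k, nz, v = 8, 32, 3, 16, 21
        dense_stem = nz * (c * l) + c * l
        res_block = 3 * (c * k * c + c)
        attention = 4 * (c * c + c)
        g_head = c * k * v + v
        expected_g = dense_stem + 2 * res_block + attention + g_head
        assert pair.generator.n_parameters() == expected_g
        d_stem = v * k * c + c
        pos = c * l
        d_head = c * 1 + 1
        expected_d = d_stem + pos + 2 * res_block + attention + d_head
        assert pair.discriminator.n_parameters() == expected_d


class TestLosses:
    def test_generator_loss_at_zero_logit_is_log2(self):
        loss = ns_generator_loss(ag.Tensor(np.zeros((4, 1))))
        assert loss.item() == pytest.approx(np.log(2.0), abs=1e-12)

    def test_discriminator_loss_limit(self):
        loss = ns_discriminator_loss(ag.Tensor(np.full((4, 1), 50.0)),
                                     ag.Tensor(np.full((4, 1), -50.0)))
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_losses_match_direct_formula_evaluation(self, rng):
        """-log sigmoid identities at 100 random logits, 1e-8 agreement."""
        logits = rng.normal(scale=3.0, size=(100, 1))
        direct_g = float(np.mean(-np.log(1.0 / (1.0 + np.exp(-logits)))))
        assert ns_generator_loss(ag.Tensor(logits)).item() == \
            pytest.approx(direct_g, abs=1e-8)
        logits_fake = rng.normal(scale=3.0, size=(100, 1))
        sig = lambda x: 1.0 / (1.0 + np.exp(-x))
        direct_d = float(np.mean(-np.log(sig(logits)))
                         + np.mean(-np.log(1.0 - sig(logits_fake))))
        assert ns_discriminator_loss(ag.Tensor(logits),
                                     ag.Tensor(logits_fake)).item() == \
            pytest.approx(direct_d, abs=1e-8)


class TestR1Penalty:
    def test_constant_discriminator_zero_penalty(self):
        const = lambda x: ag.Tensor(np.zeros((x.shape[0], 1)))
        batch = np.random.default_rng(0).uniform(size=(4, 6, 21))
        # constant maps have no input dependence: penalty must be 0
        x = ag.Tensor(batch, requires_grad=True)
        out = (x * 0.0).sum()
        gx, = ag.grad(out, [x], create_graph=True)
        assert float(((gx ** 2).sum()).item()) == 0.0

    def test_linear_discriminator_closed_form(self, rng):
        """D(x) = <w, x> gives penalty (gamma/2) * ||w||^2 exactly."""
        w = rng.normal(size=(5, 21))

        class Linear:
            def __call__(self, x):
                return (x * ag.Tensor(w)).sum(axis=(1, 2)).reshape(
                    x.shape[0], 1)

        batch = rng.uniform(size=(3, 5, 21))
        gamma = 10.0
        penalty = r1_penalty(Linear(), batch, gamma)
        assert penalty.item() == pytest.approx(
            (gamma / 2.0) * float((w ** 2).sum()), rel=1e-10)

    def test_matches_finite_difference_on_tiny_network(self, rng):
        """Penalty value equals (gamma/2) * mean ||grad_x D||^2 with the
        gradient estimated by central differences (<= 1,000 parameters)."""
        net = nn.MLP([12, 6, 1], rng)

        class Wrap:
            def __call__(self, x):
                b = x.shape[0]
                return net(x.reshape(b, 12))

        batch = rng.uniform(size=(2, 4, 3))
        gamma = 10.0
        penalty = r1_penalty(Wrap(), batch, gamma).item()
        eps = 1e-5
        total = 0.0
        for b in range(2):
            sq = 0.0
            it = np.nditer(batch[b], flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                up, down = batch.copy(), batch.copy()
                up[b][i] += eps
                down[b][i] -= eps
                f_up = net(ag.Tensor(up[b].reshape(1, 12))).item()
                f_dn = net(ag.Tensor(down[b].reshape(1, 12))).item()
                sq += ((f_up - f_dn) / (2 * eps)) ** 2
            total += sq
        expected = (gamma / 2.0) * total / 2
        assert penalty == pytest.approx(expected, abs=1e-4)


class TestTraining:
    def test_one_step_run_records_finite_history(self, tiny_family):
        config = GanConfig(**{**TINY, "total_steps": 1})
        pair = train_gan(tiny_family, config)
        assert len(pair.history["generator_loss"]) == 1
        for series in pair.history.values():
            assert np.isfinite(series).all()

    def test_determinism_same_seed_identical_weights(self, tiny_family):
        config = GanConfig(**TINY)
        p1 = train_gan(tiny_family, config)
        p2 = train_gan(tiny_family, config)
        for a, b in zip(p1.generator.state_arrays(),
                        p2.generator.state_arrays()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(p1.discriminator.state_arrays(),
                        p2.discriminator.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_too_few_sequences_rejected(self, tiny_family):
        with pytest.raises(ValueError, match="at least"):
            train_gan(tiny_family[:10], GanConfig(**TINY))

    def test_overlength_sequences_rejected(self):
        long = [SequenceRecord(f"r{i}", "A" * 40) for i in range(80)]
        with pytest.raises(ValueError, match="l_max"):
            train_gan(long, GanConfig(**TINY))

    def test_sampling_weights_validated(self, tiny_family):
        with pytest.raises(ValueError, match="sampling_weights"):
            train_gan(tiny_family, GanConfig(**TINY),
                      sampling_weights=np.ones(3))

    def test_zero_extra_steps_leaves_weights_unchanged(self, tiny_family):
        config = GanConfig(**TINY)
        pair = train_gan(tiny_family, config)
        before = [a.copy() for a in pair.generator.state_arrays()]
        train_gan(tiny_family, config, pair=pair, steps=0)
        for a, b in zip(before, pair.generator.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_checkpoint_roundtrip(self, tiny_family, tmp_path):
        config = GanConfig(**TINY)
        pair = train_gan(tiny_family, config)
        path = tmp_path / "gan.npz"
        pair.save(path)
        loaded = GanPair.load(path)
        assert loaded.config == config
        for a, b in zip(pair.generator.state_arrays(),
                        loaded.generator.state_arrays()):
            np.testing.assert_array_equal(a, b)
        recs_a = generate(pair, 5, seed=3)
        recs_b = generate(loaded, 5, seed=3)
        assert [r.residues for r in recs_a] == [r.residues for r in recs_b]


class TestSampling:
    def test_generate_contracts(self, tiny_family):
        pair = train_gan(tiny_family, GanConfig(**TINY))
        records, n_invalid = generate(pair, 10, seed=2,
                                      return_invalid_count=True)
        assert len(records) + 0 <= 10
        assert len(records) + n_invalid == 10
        for rec in records:
            assert set(rec.residues) <= set(AMINO_ACIDS)
        with pytest.raises(ValueError):
            generate(pair, 0)

    def test_generate_fixed_seed_identical(self, tiny_family):
        pair = train_gan(tiny_family, GanConfig(**TINY))
        a = generate(pair, 8, seed=11)
        b = generate(pair, 8, seed=11)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_scores_deterministic_and_finite(self, tiny_family, rng):
        pair = train_gan(tiny_family, GanConfig(**TINY))
        randoms = [SequenceRecord(f"x{i}",
                                  "".join(rng.choice(list(AMINO_ACIDS), 32)))
                   for i in range(50)]
        s1 = discriminator_score(pair, randoms)
        s2 = discriminator_score(pair, randoms)
        assert s1 == s2
        assert all(np.isfinite(s) for _, s in s1)

    def test_overlength_scoring_rejected(self, tiny_family):
        pair = train_gan(tiny_family, GanConfig(**TINY))
        with pytest.raises(ValueError):
            discriminator_score(pair, [SequenceRecord("big", "A" * 50)])
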