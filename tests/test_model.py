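"""Transformer model: initialization, schedule, loss, causality, training
mechanics and decoding."""

import numpy as np
import pytest

from chemtrace import autodiff as ad
from chemtrace.corpus import Vocabulary, make_batches, make_pairs
from chemtrace.model import (ModelConfig, TrainState, TransformerSeq2Seq,
                             WarmupOptimizer, lr_at_step, train_step)

TINY = dict(d_model=16, d_ff=32, n_layers_enc=1, n_layers_dec=1, n_heads=2,
            dropout=0.0, warmup_steps=50, token_budget_per_step=2000,
            grad_accum_batches=1, max_steps=500)


def tiny_model(vocab, seed=0, **kw):
    cfg = ModelConfig(**{**TINY, **kw, "seed": seed})
    return TransformerSeq2Seq(cfg, len(vocab), pad_id=vocab.pad_id)


@pytest.fixture(scope="module")
def overfit_setup(small_corpus, small_vocab):
    """A tiny model trained 500 steps on one fixed 8-molecule batch."""
    records = small_corpus[:8]
    rng = np.random.default_rng(0)
    pairs = make_pairs(records, small_vocab, small_vocab, rng,
                       source_mode="canonical")
    batches = make_batches(pairs, 2000, False, rng, small_vocab.pad_id)
    assert len(batches) == 1
    model = tiny_model(small_vocab, d_model=32, d_ff=64)
    opt = WarmupOptimizer(model)
    state = TrainState()
    for _ in range(500):
        loss = train_step(model, opt, batches, state)
    return model, batches[0], loss


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=10, n_heads=3)
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            ModelConfig(norm_placement="mid_ln")
        with pytest.raises(ValueError):
            ModelConfig(max_steps=0)

    def test_paper_scale_defaults(self):
        cfg = ModelConfig()
        assert (cfg.d_model, cfg.d_ff, cfg.n_layers_enc, cfg.n_layers_dec) == \
            (512, 2048, 6, 6)
        assert cfg.warmup_steps == 4000
        assert cfg.token_budget_per_step == 25000


class TestSchedule:
    def test_knee_continuity(self):
        cfg = ModelConfig(warmup_steps=4000)
        w = cfg.warmup_steps
        assert lr_at_step(w, cfg) == pytest.approx(
            cfg.d_model ** -0.5 * w ** -0.5, rel=1e-12)

    def test_closed_form_at_warmup(self):
        cfg = ModelConfig(d_model=512, warmup_steps=4000)
        assert lr_at_step(4000, cfg) == pytest.approx(
            512 ** -0.5 * 4000 ** -0.5)

    def test_monotone_up_then_down(self):
        cfg = ModelConfig(d_model=64, warmup_steps=100)
        lrs = [lr_at_step(s, cfg) for s in range(1, 300)]
        knee = 99
        assert all(a < b for a, b in zip(lrs[:knee], lrs[1:knee + 1]))
        assert all(a > b for a, b in zip(lrs[knee:], lrs[knee + 1:]))

    def test_step_zero_rejected(self):
        with pytest.raises(ValueError):
            lr_at_step(0, ModelConfig())


class TestBuild:
    def test_same_seed_same_weights(self, small_vocab):
        a = tiny_model(small_vocab, seed=7)
        b = tiny_model(small_vocab, seed=7)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)
        c = tiny_model(small_vocab, seed=8)
        assert any(not np.array_equal(a.params[k].data, c.params[k].data)
                   for k in a.params)

    def test_pre_and_post_ln_have_equal_param_counts(self, small_vocab):
        post = tiny_model(small_vocab, norm_placement="post_ln")
        pre = tiny_model(small_vocab, norm_placement="pre_ln")
        assert post.num_params() == pre.num_params()

    def test_param_count_matches_closed_form(self):
        vocab_size, d, f, h = 10, 8, 16, 2
        cfg = ModelConfig(d_model=d, d_ff=f, n_layers_enc=1, n_layers_dec=1,
                          n_heads=h, dropout=0.0)
        model = TransformerSeq2Seq(cfg, vocab_size)
        attn = 4 * (d * d + d)
        ln = 2 * d
        ffn = d * f + f + f * d + d
        expected = (
            2 * vocab_size * d            # source + target embeddings
            + (attn + ffn + 2 * ln) + ln  # encoder layer + final norm
            + (2 * attn + ffn + 3 * ln) + ln  # decoder layer + final norm
            + d * vocab_size + vocab_size     # output projection
        )
        assert model.num_params() == expected

    def test_he_normal_init_zero_bias(self, small_vocab):
        m = tiny_model(small_vocab, init_scheme="he_normal")
        assert np.all(m.params["enc.0.ffn.b1"].data == 0)
        w = m.params["enc.0.ffn.w1"].data
        assert abs(w.std() - np.sqrt(2 / w.shape[0])) < 0.2 * np.sqrt(2 / w.shape[0])


class TestLoss:
    def test_padding_does_not_change_loss(self, small_corpus, small_vocab):
        model = tiny_model(small_vocab)
        rng = np.random.default_rng(1)
        pairs = make_pairs(small_corpus[:4], small_vocab, small_vocab, rng)
        batch = make_batches(pairs, 2000, False, rng, small_vocab.pad_id)[0]
        with ad.no_grad():
            model.train(False)
            base = float(model.loss_on_batch(batch).data)
            from chemtrace.corpus import Batch
            pad = small_vocab.pad_id
            wide = Batch(
                source=np.pad(batch.source, ((0, 0), (0, 7)),
                              constant_values=pad),
                target=np.pad(batch.target, ((0, 0), (0, 7)),
                              constant_values=pad),
                molecule_indices=batch.molecule_indices,
            )
            padded = float(model.loss_on_batch(wide).data)
        assert padded == pytest.approx(base, rel=1e-5)

    def test_loss_nonnegative(self, overfit_setup):
        _, _, loss = overfit_setup
        assert loss >= 0


class TestTraining:
    def test_overfits_single_batch(self, overfit_setup):
        _, _, loss = overfit_setup
        assert loss < 0.05

    def test_loss_history_reproducible(self, small_corpus, small_vocab):
        def run():
            rng = np.random.default_rng(3)
            pairs = make_pairs(small_corpus[:16], small_vocab, small_vocab, rng)
            batches = make_batches(pairs, 400, True, rng, small_vocab.pad_id)
            model = tiny_model(small_vocab, dropout=0.1, seed=5)
            opt = WarmupOptimizer(model)
            state = TrainState()
            for i in range(0, min(len(batches), 6)):
                train_step(model, opt, [batches[i]], state)
            return state.loss_history

        assert run() == run()


class TestTeacherForcing:
    def test_causality_under_future_perturbation(self, small_corpus, small_vocab):
        model = tiny_model(small_vocab)
        rng = np.random.default_rng(2)
        pairs = make_pairs(small_corpus[:3], small_vocab, small_vocab, rng)
        batch = make_batches(pairs, 2000, False, rng, small_vocab.pad_id)[0]
        preds = model.teacher_forced_predict(batch.source, batch.target)
        cut = 4
        perturbed = batch.target.copy()
        perturbed[:, cut:] = small_vocab.unk_id
        preds2 = model.teacher_forced_predict(batch.source, perturbed)
        # prediction at position i sees only target tokens < i+1
        assert np.array_equal(preds[:, :cut - 1], preds2[:, :cut - 1])

    def test_overfitted_predictions_match_targets(self, overfit_setup, small_vocab):
        model, batch, _ = overfit_setup
        preds = model.teacher_forced_predict(batch.source, batch.target)
        tgt_out = batch.target[:, 1:]
        mask = tgt_out != small_vocab.pad_id
        assert np.array_equal(preds[mask], tgt_out[mask])

    def test_output_shape(self, overfit_setup):
        model, batch, _ = overfit_setup
        preds = model.teacher_forced_predict(batch.source, batch.target)
        assert preds.shape == (batch.target.shape[0], batch.target.shape[1] - 1)


class TestGreedyDecode:
    def test_overfitted_decode_is_exact(self, overfit_setup, small_vocab):
        model, batch, _ = overfit_setup
        ids, truncated = model.greedy_decode(batch.source, 64,
                                             small_vocab.start_id,
                                             small_vocab.end_id)
        assert not truncated.any()
        for row in range(batch.source.shape[0]):
            assert small_vocab.decode(ids[row]) == \
                small_vocab.decode(batch.target[row])

    def test_decode_is_deterministic(self, overfit_setup, small_vocab):
        model, batch, _ = overfit_setup
        a, _ = model.greedy_decode(batch.source, 64, small_vocab.start_id,
                                   small_vocab.end_id)
        b, _ = model.greedy_decode(batch.source, 64, small_vocab.start_id,
                                   small_vocab.end_id)
        assert np.array_equal(a, b)

    def test_max_len_truncation(self, overfit_setup, small_vocab):
        model, batch, _ = overfit_setup
        ids, _ = model.greedy_decode(batch.source, 2, small_vocab.start_id,
                                     small_vocab.end_id)
        assert ids.shape[1] <= 2
        with pytest.raises(ValueError):
            model.greedy_decode(batch.source, 1, small_vocab.start_id,
                                small_vocab.end_id)


def test_checkpoint_round_trip(overfit_setup, small_vocab, tmp_path):
    model, batch, _ = overfit_setup
    model.save(tmp_path / "ck")
    loaded = TransformerSeq2Seq.load(tmp_path / "ck")
    with ad.no_grad():
        loaded.train(False)
        model.train(False)
        a = model.forward(batch.source, batch.target[:, :-1]).data
        b = loaded.forward(batch.source, batch.target[:, :-1]).data
    assert np.allclose(a, b)
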