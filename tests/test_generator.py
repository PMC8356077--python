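"""LSTM language model: learning, transfer, sampling and serialization."""

from dataclasses import replace

import numpy as np
import pytest

from denovotki import (
    GeneratorConfig,
    build_corpus,
    fine_tune,
    load_model,
    parse_and_canonicalize,
    pretrain,
    sample,
    save_model,
)
from denovotki.nn import CharLSTM

TINY = GeneratorConfig(hidden_units=32, embedding_dim=16, epochs=5,
                       batch_size=16, seed=0)


class TestPretrain:
    def test_loss_decreases(self, generator_study):
        log = generator_study["pretrained"].training_log
        assert log[-1] < log[0]

    def test_single_string_memorized_by_greedy_decode(self):
        corpus = build_corpus(["CCOc1ccccc1"], max_length=30)
        model = pretrain(corpus, replace(TINY, epochs=250))
        decoded = sample(model, 1, temperature=1e-6, seed=0)
        assert decoded == ["CCOc1ccccc1"]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            pretrain(build_corpus([], max_length=10), TINY)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(keep_probability=0.0)
        with pytest.raises(ValueError):
            GeneratorConfig(temperature=-1.0)


class TestFineTune:
    def test_shifts_samples_toward_family(self, generator_study):
        """Mean nearest-neighbour Tanimoto of valid samples to the fine-tune
        family strictly increases after transfer learning (fixed seeds)."""
        from rdkit.Chem import DataStructs

        from denovotki import morgan_fingerprint

        family_fps = [morgan_fingerprint(r).bits for r in generator_study["family"]]

        def mean_nn(samples):
            vals = []
            for s in samples:
                if not s:
                    continue
                rec = parse_and_canonicalize(s)
                if not rec.valid:
                    continue
                fp = morgan_fingerprint(rec).bits
                vals.append(max(DataStructs.BulkTanimotoSimilarity(fp, family_fps)))
            assert vals, "no valid samples"
            return float(np.mean(vals))

        assert mean_nn(generator_study["samples_post"]) > mean_nn(
            generator_study["samples_pre"])

    def test_input_model_unmodified(self, generator_study):
        before = sample(generator_study["pretrained"], 30, seed=55)
        ft = fine_tune(generator_study["pretrained"], generator_study["ft_corpus"],
                       replace(generator_study["config"], epochs=1))
        assert ft is not generator_study["pretrained"]
        assert sample(generator_study["pretrained"], 30, seed=55) == before

    def test_zero_epochs_is_noop(self, generator_study):
        ft = fine_tune(generator_study["pretrained"], generator_study["ft_corpus"],
                       replace(generator_study["config"], epochs=0))
        assert sample(ft, 50, seed=3) == sample(generator_study["pretrained"], 50, seed=3)

    def test_unseen_token_rejected(self):
        corpus = build_corpus(["CCO"], max_length=20)
        model = pretrain(corpus, replace(TINY, epochs=1))
        other = build_corpus(["CC[Se]C"], max_length=20)
        with pytest.raises(ValueError, match="vocabulary"):
            fine_tune(model, other, replace(TINY, epochs=1))

    def test_memorizes_ten_string_corpus(self, generator_study):
        samples = sample(generator_study["memorizer"], 100, temperature=0.5, seed=42)
        assert sum(s in set(generator_study["ten_strings"]) for s in samples) >= 1


class TestSample:
    def test_deterministic_under_seed(self, generator_study):
        m = generator_study["pretrained"]
        assert sample(m, 100, seed=9) == sample(m, 100, seed=9)

    def test_trained_beats_untrained_validity(self, generator_study):
        untrained = pretrain(generator_study["corpus"],
                             replace(generator_study["config"], epochs=0))
        def validity(model):
            out = sample(model, 100, seed=13)
            return sum(parse_and_canonicalize(s).valid for s in out if s)
        assert validity(generator_study["pretrained"]) > validity(untrained)

    def test_greedy_limit_collapses_to_one_string(self, generator_study):
        out = sample(generator_study["pretrained"], 20, temperature=1e-6, seed=1)
        assert len(set(out)) == 1

    def test_n_must_be_positive(self, generator_study):
        with pytest.raises(ValueError):
            sample(generator_study["pretrained"], 0)


class TestLossMasking:
    def test_extra_padding_leaves_loss_unchanged(self):
        corpus = build_corpus(["CCO", "c1ccccc1"], max_length=12)
        rng = np.random.default_rng(0)
        net = CharLSTM(len(corpus.vocabulary), 8, 12, 1, 1.0, rng)
        X = corpus.to_array()
        X_padded = np.concatenate(
            [X, np.full((len(X), 5), corpus.pad_id, dtype=X.dtype)], axis=1)
        loss_a, _ = net.loss_and_grads(X, corpus.pad_id, train=False, rng=None)
        loss_b, _ = net.loss_and_grads(X_padded, corpus.pad_id, train=False, rng=None)
        assert loss_a == pytest.approx(loss_b, rel=1e-6)


class TestSerialization:
    def test_round_trip_preserves_sampling(self, generator_study, tmp_path):
        m = generator_study["finetuned"]
        save_model(m, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        assert sample(loaded, 50, seed=21) == sample(m, 50, seed=21)
        assert loaded.training_log == m.training_log
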