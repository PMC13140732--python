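"""LSTM generator: encoding, forward math, training, generation."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from pepgen import PeptideRecord
from pepgen.lstm import (
    GeneratorConfig,
    PeptideLSTM,
    SequenceModel,
    TokenVocabulary,
    _batch_loss_and_grads,
    _init_params,
    encode_training_pairs,
    evaluate_accuracy,
    forward,
    generate,
    train,
)


@pytest.fixture(scope="module")
def vocab():
    return TokenVocabulary()


def _zero_model(embedding_dim=4, hidden_units=3):
    v = TokenVocabulary()
    return SequenceModel(
        vocabulary=v,
        embedding=np.zeros((23, embedding_dim)),
        Wx=np.zeros((embedding_dim, 4 * hidden_units)),
        Wh=np.zeros((hidden_units, 4 * hidden_units)),
        b=np.zeros(4 * hidden_units),
        Wy=np.zeros((hidden_units, 22)),
        by=np.zeros(22),
        config=GeneratorConfig(embedding_dim=embedding_dim,
                               hidden_units=hidden_units),
    )


class TestVocabulary:
    def test_bijection_of_22_tokens(self, vocab):
        assert vocab.size == 22
        assert len(vocab.residue_to_index) == 22
        for tok, idx in vocab.residue_to_index.items():
            assert vocab.index_to_residue[idx] == tok

    def test_encode_decode_roundtrip(self, vocab, qk):
        assert vocab.decode(vocab.encode(qk)) == qk

    def test_unknown_residue_raises(self, vocab):
        with pytest.raises(ValueError):
            vocab.encode("AXB")

    def test_special_tokens_never_decode(self, vocab):
        with pytest.raises(ValueError):
            vocab.decode([vocab.start_index])


class TestEncodeTrainingPairs:
    def test_two_residue_peptide_yields_three_pairs(self, vocab):
        pairs = encode_training_pairs([PeptideRecord(id="x", sequence="AR")],
                                      vocab)
        assert len(pairs) == 3
        s = vocab.start_index
        a, r = vocab.encode("AR")
        assert pairs[0] == ((s,), a)
        assert pairs[1] == ((s, a), r)
        assert pairs[2] == ((s, a, r), vocab.end_index)

    def test_published_sequence_pair_count(self, vocab, vmp3):
        pairs = encode_training_pairs(
            [PeptideRecord(id="VMP3", sequence=vmp3)], vocab
        )
        assert len(pairs) == len(vmp3) + 1  # 15

    def test_empty_record_list(self, vocab):
        assert encode_training_pairs([], vocab) == []


class TestForward:
    def test_zero_weights_give_uniform_distribution(self):
        p = forward(_zero_model(), "ARND")
        assert np.allclose(p, 1.0 / 22)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_softmax_normalised_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        cfg = GeneratorConfig(embedding_dim=5, hidden_units=4)
        model = SequenceModel(vocabulary=TokenVocabulary(),
                              config=cfg, **_init_params(rng, cfg))
        p = forward(model, "KLTWQ")
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_token_prefix_must_start_with_start(self):
        model = _zero_model()
        with pytest.raises(ValueError, match="START"):
            forward(model, [0, 1])

    def test_single_unit_model_matches_hand_computation(self):
        """1-unit LSTM, hand-set weights, pure-float gate equations."""
        v = TokenVocabulary()
        E, H = 1, 1
        emb = np.zeros((23, E))
        emb[v.start_index, 0] = 0.5
        emb[0, 0] = -0.3  # residue 'A'
        Wx = np.array([[0.1, -0.2, 0.3, 0.4]])       # gates i, f, o, g
        Wh = np.array([[0.05, 0.06, -0.07, 0.08]])
        b = np.array([0.01, 0.02, 0.03, 0.04])
        Wy = np.full((1, 22), 0.2)
        Wy[0, 3] = -0.6
        by = np.linspace(-0.1, 0.1, 22)
        model = SequenceModel(
            vocabulary=v, embedding=emb, Wx=Wx, Wh=Wh, b=b, Wy=Wy, by=by,
            config=GeneratorConfig(embedding_dim=E, hidden_units=H),
        )

        def sigmoid(x):
            return 1.0 / (1.0 + math.exp(-x))

        h = c = 0.0
        for x in (0.5, -0.3):  # START then 'A'
            i = sigmoid(0.1 * x + 0.05 * h + 0.01)
            f = sigmoid(-0.2 * x + 0.06 * h + 0.02)
            o = sigmoid(0.3 * x + -0.07 * h + 0.03)
            g = math.tanh(0.4 * x + 0.08 * h + 0.04)
            c = f * c + i * g
            h = o * math.tanh(c)
        logits = [0.2 * h + by[k] for k in range(22)]
        logits[3] = -0.6 * h + by[3]
        z = max(logits)
        exps = [math.exp(l - z) for l in logits]
        expected = np.array(exps) / sum(exps)

        assert np.allclose(forward(model, "A"), expected, atol=1e-10)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, vocab):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(embedding_dim=3, hidden_units=2)
        params = _init_params(rng, cfg)
        tokens = np.array([[22, 20, 0, 5], [20, 3, 7, 2]])  # row 0 padded
        targets = np.array([9, 21])
        _, grads = _batch_loss_and_grads(params, tokens, targets,
                                         vocab.pad_index)
        eps = 1e-6
        for name in params:
            it = np.nditer(params[name], flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = params[name][ix]
                params[name][ix] = orig + eps
                lp, _ = _batch_loss_and_grads(params, tokens, targets,
                                              vocab.pad_index)
                params[name][ix] = orig - eps
                lm, _ = _batch_loss_and_grads(params, tokens, targets,
                                              vocab.pad_index)
                params[name][ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, abs=1e-5), name


class TestTraining:
    def test_seeded_determinism(self, tiny_corpus):
        cfg = GeneratorConfig(embedding_dim=8, hidden_units=6, epochs=3,
                              seed=5)
        m1, t1 = train(tiny_corpus, cfg)
        m2, t2 = train(tiny_corpus, cfg)
        assert t1.train_loss == t2.train_loss
        assert t1.train_accuracy == t2.train_accuracy
        assert all(
            np.array_equal(m1._params()[k], m2._params()[k])
            for k in m1._params()
        )

    def test_different_seed_differs(self, tiny_corpus):
        cfg = GeneratorConfig(embedding_dim=8, hidden_units=6, epochs=3)
        _, t1 = train(tiny_corpus, GeneratorConfig(**{**cfg.__dict__,
                                                      "seed": 1}))
        _, t2 = train(tiny_corpus, GeneratorConfig(**{**cfg.__dict__,
                                                      "seed": 2}))
        assert t1.train_loss != t2.train_loss

    def test_corpus_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            train(["ARNDKWYA"], GeneratorConfig(epochs=1))

    def test_trace_lengths_and_ranges(self, tiny_corpus):
        cfg = GeneratorConfig(embedding_dim=8, hidden_units=6, epochs=4,
                              holdout_fraction=0.34, seed=0)
        _, trace = train(tiny_corpus, cfg)
        assert len(trace.train_loss) == 4
        assert len(trace.holdout_loss) == 4
        assert all(l >= 0 for l in trace.train_loss)
        assert all(0.0 <= a <= 1.0 for a in trace.train_accuracy)

    def test_memorization_reaches_perfect_accuracy(self, memorizing_estimator):
        trace = memorizing_estimator.trace_
        assert trace.train_accuracy[-1] == 1.0
        assert trace.train_loss[-1] < 0.05  # nats

    def test_loss_approaches_entropy_floor_on_memorizable_corpus(self):
        # with k distinct equiprobable peptides the irreducible mean
        # cross-entropy is ln(k) / (L + 1): the first residue carries
        # the full choice entropy, everything after is determined
        seqs = ["ARNDKW", "LLEQMK", "WFHCPG"]
        est = PeptideLSTM(epochs=200, holdout_fraction=0.0, seed=3)
        est.fit(seqs * 11)
        floor = math.log(3) / (len(seqs[0]) + 1)
        assert est.trace_.train_loss[-1] < floor + 0.05
        assert est.trace_.train_loss[-1] >= floor - 1e-6


class TestGeneration:
    def test_greedy_emits_memorized_peptide(self, memorizing_estimator):
        out = memorizing_estimator.sample(3, rng_seed=9, temperature=0.0)
        assert out == ["ARNDKWYA"] * 3

    def test_greedy_deterministic_across_calls(self, memorizing_estimator):
        a = memorizing_estimator.sample(2, rng_seed=1, temperature=0.0)
        b = memorizing_estimator.sample(2, rng_seed=2, temperature=0.0)
        assert a == b

    def test_greedy_equals_manual_argmax_decoding(self, memorizing_estimator):
        model = memorizing_estimator.model_
        vocab = model.vocabulary
        seq = ""
        for _ in range(model.config.max_generate_len):
            probs = forward(model, seq)
            probs = probs.copy()
            probs[vocab.start_index] = -1.0
            nxt = int(np.argmax(probs))
            if nxt == vocab.end_index:
                break
            seq += vocab.index_to_residue[nxt]
        assert memorizing_estimator.sample(1, temperature=0.0) == [seq]

    def test_sampled_sequences_stay_in_alphabet(self, memorizing_estimator):
        out = memorizing_estimator.sample(20, rng_seed=4, temperature=1.5)
        for s in out:
            assert set(s) <= set("ACDEFGHIKLMNPQRSTVWY")
            assert len(s) <= memorizing_estimator.max_generate_len

    def test_stochastic_sampling_reproducible_from_seed(
        self, memorizing_estimator
    ):
        a = memorizing_estimator.sample(5, rng_seed=7, temperature=1.0)
        b = memorizing_estimator.sample(5, rng_seed=7, temperature=1.0)
        assert a == b

    def test_seed_prefix_respected(self, memorizing_estimator):
        out = memorizing_estimator.sample(2, seed_prefix="ARN",
                                          rng_seed=0, temperature=0.0)
        assert all(s.startswith("ARN") for s in out)

    def test_negative_temperature_rejected(self, memorizing_estimator):
        with pytest.raises(ValueError):
            generate(memorizing_estimator.model_, "", 1,
                     GeneratorConfig(temperature=-1.0), rng_seed=0)


class TestEvaluateAccuracy:
    def test_zero_model_near_chance(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
                for _ in range(50)]
        acc = evaluate_accuracy(_zero_model(), seqs)
        assert acc <= 1.0 / 22 + 0.05

    def test_memorizing_model_perfect_on_own_corpus(self,
                                                    memorizing_estimator):
        assert memorizing_estimator.score(["ARNDKWYA"]) == 1.0

    def test_invariant_to_record_order(self, memorizing_estimator,
                                       tiny_corpus):
        model = memorizing_estimator.model_
        a = evaluate_accuracy(model, tiny_corpus)
        b = evaluate_accuracy(model, list(reversed(tiny_corpus)))
        assert a == pytest.approx(b)

    def test_empty_records_error(self, memorizing_estimator):
        with pytest.raises(ValueError):
            evaluate_accuracy(memorizing_estimator.model_, [])


class TestModelPersistence:
    def test_save_load_roundtrip(self, memorizing_estimator, tmp_path):
        path = tmp_path / "model.json"
        memorizing_estimator.model_.save(path)
        loaded = SequenceModel.load(path)
        assert np.allclose(forward(loaded, "ARN"),
                           forward(memorizing_estimator.model_, "ARN"))
        cfg = GeneratorConfig(**loaded.config.__dict__)
        assert generate(loaded, "", 2, cfg, rng_seed=0) == \
            memorizing_estimator.sample(2, rng_seed=0)


class TestEstimatorInterface:
    def test_get_set_params_and_clone(self):
        est = PeptideLSTM(epochs=7, hidden_units=12)
        assert est.get_params()["epochs"] == 7
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        est.set_params(epochs=9)
        assert est.epochs == 9

    def test_fitted_attributes(self, tiny_corpus):
        est = PeptideLSTM(embedding_dim=8, hidden_units=6, epochs=2, seed=0)
        est.fit(tiny_corpus)
        assert hasattr(est, "model_")
        assert hasattr(est, "trace_")
        assert len(est.train_records_) + len(est.holdout_records_) == len(
            tiny_corpus
        )
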