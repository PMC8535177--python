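"""Pretraining-instance construction and the tiny encoder's NSP behavior."""

import numpy as np
import pytest
from scipy import stats

from ctrscoder.adaptation import (
    CLS,
    MASK,
    SEP,
    AdaptationConfig,
    EncoderConfig,
    PretrainingInstance,
    TinyTransformerEncoder,
    Vocabulary,
    build_instances,
    continue_pretraining,
    nsp_accuracy,
    split_sessions,
    tiny_adaptation_config,
)
from ctrscoder.synthetic_data import generate_adjacency_corpus
from ctrscoder.transcript_io import SessionMetadata, SessionTranscript, Utterance


def two_utterance_session(texts=("alpha beta", "gamma delta"), sid="s0"):
    meta = SessionMetadata(clinic="c", level_of_care="l", population="p",
                           assessment_time="a")
    utts = [Utterance(role="therapist", text=t, start_s=3.0 * i, end_s=3.0 * i + 1)
            for i, t in enumerate(texts)]
    return SessionTranscript(session_id=sid, therapist_id="t0", utterances=utts,
                             metadata=meta)


@pytest.fixture(scope="module")
def adjacency_corpus():
    return generate_adjacency_corpus(n_sessions=30, seed=5)


@pytest.fixture(scope="module")
def adjacency_vocab(adjacency_corpus):
    return Vocabulary.build(adjacency_corpus)


class TestBuildInstances:
    def test_single_session_positives_come_from_its_adjacency(self):
        corpus = [two_utterance_session()]
        vocab = Vocabulary.build(corpus)
        cfg = AdaptationConfig(seed=0, short_seq_prob=0.0)
        instances = build_instances(corpus, cfg, vocab)
        assert len(instances) == 1
        inst = instances[0]
        assert inst.tokens_a == ["alpha", "beta"]
        if inst.is_next:
            assert inst.tokens_b == ["gamma", "delta"]

    def test_negative_fraction_within_binomial_ci(self, adjacency_corpus, adjacency_vocab):
        cfg = AdaptationConfig(seed=3)
        instances = build_instances(adjacency_corpus, cfg, adjacency_vocab)
        n = len(instances)
        assert n >= 500
        neg = sum(not i.is_next for i in instances)
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= neg <= hi

    def test_masked_fraction_close_to_rate(self, adjacency_corpus, adjacency_vocab):
        cfg = AdaptationConfig(seed=3, mask_rate=0.15)
        instances = build_instances(adjacency_corpus, cfg, adjacency_vocab)
        masked = sum(len(i.masked_positions) for i in instances)
        candidates = sum(len(i.tokens_a) + len(i.tokens_b) for i in instances)
        # per-instance rounding (and the >=1 floor) biases the realized rate
        # slightly; it must stay close to the nominal 15%
        assert abs(masked / candidates - 0.15) < 0.03

    def test_negatives_never_adjacency_consistent(self, adjacency_corpus, adjacency_vocab):
        cfg = AdaptationConfig(seed=4, short_seq_prob=0.0)
        utt_tokens = {}
        for s in adjacency_corpus:
            toks = [u.text.lower().split() for u in s.utterances]
            for i in range(len(toks) - 1):
                utt_tokens[tuple(toks[i])] = tuple(toks[i + 1])
        for inst in build_instances(adjacency_corpus, cfg, adjacency_vocab):
            if not inst.is_next:
                true_b = utt_tokens[tuple(inst.tokens_a)]
                assert tuple(inst.tokens_b) != true_b

    def test_masking_replacement_mix(self, adjacency_corpus, adjacency_vocab):
        cfg = AdaptationConfig(seed=5)
        instances = build_instances(adjacency_corpus, cfg, adjacency_vocab)
        n_masked = n_mask_symbol = n_changed = 0
        for inst in instances:
            clean = inst.unmasked_tokens()
            for pos, target in zip(inst.masked_positions, inst.masked_targets):
                assert clean[pos] == target
                n_masked += 1
                if inst.input_tokens[pos] == MASK:
                    n_mask_symbol += 1
                elif inst.input_tokens[pos] != target:
                    n_changed += 1
        assert 0.75 < n_mask_symbol / n_masked < 0.85
        assert 0.05 < n_changed / n_masked < 0.15

    def test_pair_respects_length_budget(self, adjacency_corpus, adjacency_vocab):
        cfg = AdaptationConfig(seed=6, max_len=16)
        for inst in build_instances(adjacency_corpus, cfg, adjacency_vocab):
            assert len(inst.tokens_a) + len(inst.tokens_b) <= 13
            assert len(inst.input_tokens) <= 16
            assert inst.input_tokens[0] == CLS
            assert inst.input_tokens.count(SEP) == 2

    def test_too_small_corpus_rejected(self):
        corpus = [two_utterance_session(texts=("only one",))]
        vocab = Vocabulary.build(corpus)
        with pytest.raises(ValueError):
            build_instances(corpus, AdaptationConfig(), vocab)


class TestSplitSessions:
    def test_session_level_disjoint(self, adjacency_corpus):
        train, ev = split_sessions(adjacency_corpus, 0.2, seed=1)
        train_ids = {s.session_id for s in train}
        eval_ids = {s.session_id for s in ev}
        assert not (train_ids & eval_ids)
        assert len(train_ids) + len(eval_ids) == len(adjacency_corpus)

    def test_seeded_split_reproducible(self, adjacency_corpus):
        a = split_sessions(adjacency_corpus, 0.2, seed=9)
        b = split_sessions(adjacency_corpus, 0.2, seed=9)
        assert [s.session_id for s in a[1]] == [s.session_id for s in b[1]]


class _StubEncoder:
    """Oracle/constant predictors for the accuracy bounds."""

    def __init__(self, mode):
        self.mode = mode

    def predict_is_next(self, instances):
        if self.mode == "oracle":
            return np.array([i.is_next for i in instances])
        return np.zeros(len(instances), dtype=bool)


class TestNSPAccuracy:
    def test_oracle_encoder_scores_one(self, adjacency_corpus, adjacency_vocab):
        inst = build_instances(adjacency_corpus[:5], AdaptationConfig(seed=0),
                               adjacency_vocab)
        assert nsp_accuracy(_StubEncoder("oracle"), inst) == 1.0

    def test_constant_encoder_near_half_on_balanced_pairs(self, adjacency_corpus,
                                                          adjacency_vocab):
        inst = build_instances(adjacency_corpus, AdaptationConfig(seed=1),
                               adjacency_vocab)
        acc = nsp_accuracy(_StubEncoder("constant"), inst)
        lo, hi = stats.binom.interval(0.999, len(inst), 0.5)
        assert lo / len(inst) <= acc <= hi / len(inst)

    def test_untrained_encoder_at_chance(self, adjacency_corpus, adjacency_vocab):
        inst = build_instances(adjacency_corpus, AdaptationConfig(seed=2),
                               adjacency_vocab)
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24, seed=0), adjacency_vocab)
        acc = nsp_accuracy(enc, inst)
        lo, hi = stats.binom.interval(0.999, len(inst), 0.5)
        assert lo / len(inst) <= acc <= hi / len(inst)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            nsp_accuracy(_StubEncoder("oracle"), [])


class TestContinuePretraining:
    def test_zero_steps_is_identity(self, adjacency_corpus, adjacency_vocab):
        cfg = tiny_adaptation_config(steps=0, seed=0)
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24, seed=1), adjacency_vocab)
        inst = build_instances(adjacency_corpus[:5], cfg, adjacency_vocab)
        adapted = continue_pretraining(enc, inst, cfg)
        for k in enc.params:
            np.testing.assert_array_equal(adapted.params[k].data, enc.params[k].data)

    def test_original_encoder_unmodified(self, adjacency_corpus, adjacency_vocab):
        cfg = tiny_adaptation_config(steps=5, seed=0)
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24, seed=1), adjacency_vocab)
        before = {k: v.data.copy() for k, v in enc.params.items()}
        inst = build_instances(adjacency_corpus[:10], cfg, adjacency_vocab)
        adapted = continue_pretraining(enc, inst, cfg)
        for k in before:
            np.testing.assert_array_equal(enc.params[k].data, before[k])
        assert any(not np.array_equal(adapted.params[k].data, before[k]) for k in before)

    def test_same_seed_reproduces_training(self, adjacency_corpus, adjacency_vocab):
        cfg = tiny_adaptation_config(steps=10, seed=3)
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24, seed=1), adjacency_vocab)
        inst = build_instances(adjacency_corpus[:10], cfg, adjacency_vocab)
        a = continue_pretraining(enc, inst, cfg)
        b = continue_pretraining(enc, inst, cfg)
        la = float(a.loss(inst[:50]).data)
        lb = float(b.loss(inst[:50]).data)
        assert la == lb

    def test_loss_decreases_on_structured_corpus(self, adjacency_corpus, adjacency_vocab):
        cfg = tiny_adaptation_config(steps=200, seed=2)
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24, seed=2), adjacency_vocab)
        inst = build_instances(adjacency_corpus, AdaptationConfig(seed=2, max_len=24),
                               adjacency_vocab)
        loss_before = float(enc.loss(inst[:200]).data)
        adapted = continue_pretraining(enc, inst, cfg)
        loss_after = float(adapted.loss(inst[:200]).data)
        assert loss_after < loss_before

    def test_empty_stream_rejected(self, adjacency_vocab):
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24), adjacency_vocab)
        with pytest.raises(ValueError):
            continue_pretraining(enc, [], tiny_adaptation_config())


class TestEncoderAsBackend:
    def test_embeds_tokens_excluding_specials(self, adjacency_vocab):
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24, seed=0), adjacency_vocab)
        vecs = enc.encode_tokens(["qlink00", "qlink01"])
        assert vecs.shape == (2, enc.dimension)
        with_special = enc.encode_tokens(["qlink00", "qlink01"], include_special=True)
        assert with_special.shape == (4, enc.dimension)

    def test_checkpoint_round_trip(self, tmp_path, adjacency_vocab):
        enc = TinyTransformerEncoder(EncoderConfig(max_len=24, seed=4), adjacency_vocab)
        enc.save(tmp_path / "enc")
        loaded = TinyTransformerEncoder.load(tmp_path / "enc")
        np.testing.assert_array_equal(
            enc.encode_tokens(["qlink02"]), loaded.encode_tokens(["qlink02"])
        )
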