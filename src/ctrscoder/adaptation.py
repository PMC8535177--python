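"""Domain-adaptive continued pretraining of a transformer utterance encoder.

A generic encoder is adapted to in-domain transcripts by continuing training
on two self-supervised objectives: masked-token prediction (a fraction of
tokens is hidden and must be recovered) and next-sentence prediction (NSP:
is segment B the true successor of segment A within a session?).  NSP is the
probe of interest for long dialogues: an encoder that models cross-utterance
structure should judge adjacency far above chance.

The encoder here is a compact trainable transformer (token + position +
segment embeddings, multi-head self-attention blocks, MLM and NSP heads)
running on the in-package autodiff engine.  The shipped profile is small
(2 layers, width 32) so adaptation experiments run in seconds; the same code
scales to larger settings via :class:`EncoderConfig`.  After adaptation the
encoder doubles as an utterance embedding backend (average-pooled final
layer, special tokens excluded).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .embeddings import whitespace_tokenize
from .transcript_io import SessionTranscript, filter_role

PAD, UNK, CLS, SEP, MASK = "[pad]", "[unk]", "[cls]", "[sep]", "[mask]"
SPECIALS = (PAD, UNK, CLS, SEP, MASK)


@dataclass(frozen=True)
class Vocabulary:
    token_to_id: Dict[str, int]

    @classmethod
    def build(cls, sessions: Sequence[SessionTranscript]) -> "Vocabulary":
        tokens = sorted({
            t for s in sessions for u in s.utterances for t in whitespace_tokenize(u.text)
        })
        mapping = {t: i for i, t in enumerate(SPECIALS)}
        for t in tokens:
            mapping[t] = len(mapping)
        return cls(token_to_id=mapping)

    def __len__(self) -> int:
        return len(self.token_to_id)

    def encode(self, tokens: Sequence[str]) -> List[int]:
        unk = self.token_to_id[UNK]
        return [self.token_to_id.get(t, unk) for t in tokens]

    @property
    def regular_tokens(self) -> List[str]:
        return [t for t in self.token_to_id if t not in SPECIALS]


@dataclass
class AdaptationConfig:
    """Continued-pretraining hyperparameters.

    The full-scale recipe (10,000 steps, lr 2e-5, batch 64, 64-token
    sequences, 15% masking, short-sequence probability 0.5) is the default;
    :func:`tiny_adaptation_config` gives the fast profile used for
    simulation studies and tests.
    """

    steps: int = 10000
    learning_rate: float = 2e-5
    batch_size: int = 64
    max_len: int = 64
    short_seq_prob: float = 0.5
    mask_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 0 or self.batch_size < 1:
            raise ValueError("steps must be >= 0 and batch_size positive")
        for p in (self.short_seq_prob, self.mask_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def tiny_adaptation_config(steps: int = 500, seed: int = 0, max_len: int = 24) -> AdaptationConfig:
    """Scaled-down profile: few steps on a small encoder need a larger
    learning rate than the full-scale recipe."""
    return AdaptationConfig(steps=steps, learning_rate=3e-3, batch_size=64,
                            max_len=max_len, seed=seed)


@dataclass
class PretrainingInstance:
    """One sentence-pair training example.

    ``masked_positions`` index into the assembled input sequence
    ``[cls] tokens_a [sep] tokens_b [sep]`` after masking;
    ``masked_targets`` are the original tokens at those positions.
    """

    tokens_a: List[str]
    tokens_b: List[str]
    is_next: bool
    masked_positions: List[int]
    masked_targets: List[str]
    input_tokens: List[str]  # full post-masking sequence incl. specials

    @property
    def segment_ids(self) -> List[int]:
        na = len(self.tokens_a) + 2  # [cls] a [sep]
        return [0] * na + [1] * (len(self.input_tokens) - na)

    def unmasked_tokens(self) -> List[str]:
        return [CLS, *self.tokens_a, SEP, *self.tokens_b, SEP]


# ---------------------------------------------------------------------------
# Instance construction
# ---------------------------------------------------------------------------

def _truncate_pair(a: List[str], b: List[str], max_tokens: int) -> Tuple[List[str], List[str]]:
    a, b = list(a), list(b)
    while len(a) + len(b) > max_tokens:
        longer = a if len(a) >= len(b) else b
        longer.pop()  # trim from the end of the longer segment
    return a, b


def build_instances(
    sessions: Sequence[SessionTranscript],
    config: AdaptationConfig,
    vocab: Vocabulary,
    role_filter: Optional[str] = None,
) -> List[PretrainingInstance]:
    """Build sentence-pair instances from a corpus.

    Positive pairs are consecutive utterances within a session (consecutive
    *after* optional role filtering, matching how a role-restricted encoder
    sees the corpus).  With probability 0.5 the second segment is replaced
    by one drawn uniformly from the whole corpus, re-drawn if it happens to
    be the true successor, giving a 50% negative rate.  Masking selects
    ``mask_rate`` of non-special tokens: 80% become the mask symbol, 10% a
    random vocabulary token, 10% stay unchanged.
    """
    rng = np.random.default_rng(config.seed)
    if role_filter is not None:
        sessions = [filter_role(s, role_filter) for s in sessions]
    utt_tokens: List[List[List[str]]] = [
        [whitespace_tokenize(u.text) for u in s.utterances] for s in sessions
    ]
    flat: List[List[str]] = [t for sess in utt_tokens for t in sess]
    if sum(len(sess) >= 2 for sess in utt_tokens) == 0:
        raise ValueError("no session has >= 2 utterances after filtering")
    regular = vocab.regular_tokens

    instances: List[PretrainingInstance] = []
    for sess in utt_tokens:
        for i in range(len(sess) - 1):
            a, true_b = sess[i], sess[i + 1]
            if not a or not true_b:
                continue
            is_next = bool(rng.random() < 0.5)
            if is_next:
                b = true_b
            else:
                while True:
                    b = flat[int(rng.integers(len(flat)))]
                    if b and b != true_b:  # never adjacency-consistent
                        break
            budget = config.max_len - 3
            if rng.random() < config.short_seq_prob:
                # shorter than max length, but never so short that the pair
                # degenerates to single tokens
                lo = max(4, budget // 4)
                budget = int(rng.integers(lo, max(lo + 1, budget)))
            a_t, b_t = _truncate_pair(a, b, budget)
            if not a_t or not b_t:
                continue
            tokens = [CLS, *a_t, SEP, *b_t, SEP]
            candidates = [j for j, t in enumerate(tokens) if t not in (CLS, SEP)]
            n_mask = max(1, int(round(config.mask_rate * len(candidates))))
            positions = sorted(rng.choice(candidates, size=n_mask, replace=False).tolist())
            targets = [tokens[j] for j in positions]
            masked = list(tokens)
            for j in positions:
                u = rng.random()
                if u < 0.8:
                    masked[j] = MASK
                elif u < 0.9:
                    masked[j] = regular[int(rng.integers(len(regular)))]
                # else: keep the original token
            instances.append(PretrainingInstance(
                tokens_a=a_t, tokens_b=b_t, is_next=is_next,
                masked_positions=positions, masked_targets=targets,
                input_tokens=masked,
            ))
    return instances


def split_sessions(
    sessions: Sequence[SessionTranscript], eval_fraction: float = 0.1, seed: int = 0,
) -> Tuple[List[SessionTranscript], List[SessionTranscript]]:
    """Random train/eval split at the session level, so no evaluation
    utterance can appear inside a training instance."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(sessions))
    n_eval = max(1, int(round(eval_fraction * len(sessions))))
    eval_ids = set(idx[:n_eval].tolist())
    train = [s for i, s in enumerate(sessions) if i not in eval_ids]
    ev = [s for i, s in enumerate(sessions) if i in eval_ids]
    return train, ev


# ---------------------------------------------------------------------------
# The encoder
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    dim: int = 32
    n_layers: int = 2
    n_heads: int = 2
    ffn_dim: int = 64
    max_len: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim % self.n_heads != 0:
            raise ValueError("dim must be divisible by n_heads")


class TinyTransformerEncoder:
    """Compact BERT-style encoder with MLM and NSP heads.

    Also satisfies the utterance-embedding backend protocol: per-token
    final-layer vectors with special boundary tokens excluded.
    """

    def __init__(self, config: EncoderConfig, vocab: Vocabulary):
        self.config = config
        self.vocab = vocab
        self.max_tokens = config.max_len - 2  # room for [cls]/[sep]
        self.dimension = config.dim
        self.name = f"tinybert-d{config.dim}-l{config.n_layers}"
        rng = np.random.default_rng(config.seed)
        d, V = config.dim, len(vocab)
        p: Dict[str, Tensor] = {
            "tok_emb": ad.parameter(0.02 * rng.standard_normal((V, d))),
            "pos_emb": ad.parameter(0.02 * rng.standard_normal((config.max_len, d))),
            "seg_emb": ad.parameter(0.02 * rng.standard_normal((2, d))),
            "W_nsp": ad.parameter(ad.glorot(rng, (d, 2))),
            "b_nsp": ad.parameter(np.zeros(2)),
            "W_mlm": ad.parameter(ad.glorot(rng, (d, V))),
            "b_mlm": ad.parameter(np.zeros(V)),
        }
        for i in range(config.n_layers):
            p[f"Wq{i}"] = ad.parameter(ad.glorot(rng, (d, d)))
            p[f"Wk{i}"] = ad.parameter(ad.glorot(rng, (d, d)))
            p[f"Wv{i}"] = ad.parameter(ad.glorot(rng, (d, d)))
            p[f"Wo{i}"] = ad.parameter(ad.glorot(rng, (d, d)))
            p[f"Wf1_{i}"] = ad.parameter(ad.glorot(rng, (d, config.ffn_dim)))
            p[f"bf1_{i}"] = ad.parameter(np.zeros(config.ffn_dim))
            p[f"Wf2_{i}"] = ad.parameter(ad.glorot(rng, (config.ffn_dim, d)))
            p[f"bf2_{i}"] = ad.parameter(np.zeros(d))
        self.params = p

    def clone(self) -> "TinyTransformerEncoder":
        other = TinyTransformerEncoder(self.config, self.vocab)
        for k in self.params:
            other.params[k].data = self.params[k].data.copy()
        return other

    # -- forward -------------------------------------------------------------

    def _hidden(self, ids: np.ndarray, segs: np.ndarray, mask: np.ndarray) -> Tensor:
        cfg = self.config
        p = self.params
        B, L = ids.shape
        d, h = cfg.dim, cfg.n_heads
        dh = d // h
        pos = np.broadcast_to(np.arange(L), (B, L))
        x = ad.gather_rows(p["tok_emb"], ids) + ad.gather_rows(p["pos_emb"], pos) \
            + ad.gather_rows(p["seg_emb"], segs)
        attn_mask = mask[:, None, None, :]  # keys mask
        for i in range(cfg.n_layers):
            def proj(W):
                y = ad.reshape(ad.matmul(ad.reshape(x, (B * L, d)), W), (B, L, h, dh))
                return ad.swapaxes(y, 1, 2)  # (B,h,L,dh)

            q, k, v = proj(p[f"Wq{i}"]), proj(p[f"Wk{i}"]), proj(p[f"Wv{i}"])
            scores = ad.matmul(q, ad.swapaxes(k, 2, 3)) * (1.0 / np.sqrt(dh))
            attn = ad.masked_softmax(scores, attn_mask, axis=-1)
            ctx = ad.swapaxes(ad.matmul(attn, v), 1, 2)  # (B,L,h,dh)
            ctx = ad.reshape(ctx, (B * L, d))
            out = ad.reshape(ad.matmul(ctx, p[f"Wo{i}"]), (B, L, d))
            x = ad.layer_norm(x + out)
            ff = ad.relu(ad.matmul(ad.reshape(x, (B * L, d)), p[f"Wf1_{i}"]) + p[f"bf1_{i}"])
            ff = ad.reshape(ad.matmul(ff, p[f"Wf2_{i}"]) + p[f"bf2_{i}"], (B, L, d))
            x = ad.layer_norm(x + ff)
        return x

    def _featurize(self, instances: Sequence[PretrainingInstance], masked: bool):
        seqs = [inst.input_tokens if masked else inst.unmasked_tokens() for inst in instances]
        L = min(max(len(s) for s in seqs), self.config.max_len)
        B = len(seqs)
        ids = np.zeros((B, L), dtype=int)
        segs = np.zeros((B, L), dtype=int)
        mask = np.zeros((B, L), dtype=bool)
        for i, (inst, s) in enumerate(zip(instances, seqs)):
            s = s[:L]
            ids[i, :len(s)] = self.vocab.encode(s)
            segs[i, :len(s)] = inst.segment_ids[:len(s)]
            mask[i, :len(s)] = True
        return ids, segs, mask

    def loss(self, instances: Sequence[PretrainingInstance]) -> Tensor:
        """Combined MLM + NSP cross-entropy on one minibatch."""
        ids, segs, mask = self._featurize(instances, masked=True)
        hidden = self._hidden(ids, segs, mask)
        B, L, d = hidden.shape
        flat = ad.reshape(hidden, (B * L, d))

        rows, targets = [], []
        for i, inst in enumerate(instances):
            for pos, tok in zip(inst.masked_positions, inst.masked_targets):
                if pos < L:
                    rows.append(i * L + pos)
                    targets.append(self.vocab.token_to_id[tok])
        cls = hidden[:, 0]
        nsp_logits = ad.matmul(cls, self.params["W_nsp"]) + self.params["b_nsp"]
        labels = np.array([int(inst.is_next) for inst in instances])
        nsp = ad.cross_entropy_logits(nsp_logits, labels)
        if not rows:  # every masked position was cropped away
            return nsp
        mlm_logits = ad.matmul(ad.getitem(flat, np.array(rows)), self.params["W_mlm"]) \
            + self.params["b_mlm"]
        mlm = ad.cross_entropy_logits(mlm_logits, np.array(targets))
        return mlm + nsp

    def predict_is_next(self, instances: Sequence[PretrainingInstance]) -> np.ndarray:
        """NSP decisions on unmasked inputs."""
        ids, segs, mask = self._featurize(instances, masked=False)
        hidden = self._hidden(ids, segs, mask)
        logits = (hidden.data[:, 0] @ self.params["W_nsp"].data) + self.params["b_nsp"].data
        return logits.argmax(axis=1).astype(bool)

    # -- embedding-backend protocol -------------------------------------------

    def tokenize(self, text: str) -> List[str]:
        return whitespace_tokenize(text)

    def encode_tokens(self, tokens: Sequence[str], include_special: bool = False) -> np.ndarray:
        tokens = list(tokens)[: self.max_tokens]
        seq = [CLS, *tokens, SEP]
        ids = np.array([self.vocab.encode(seq)])
        segs = np.zeros_like(ids)
        mask = np.ones_like(ids, dtype=bool)
        hidden = self._hidden(ids, segs, mask).data[0]
        return hidden if include_special else hidden[1:-1]

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        from pathlib import Path
        import json

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in self.params.items()})
        path.with_suffix(".json").write_text(json.dumps({
            "config": self.config.__dict__, "vocab": self.vocab.token_to_id,
        }))

    @classmethod
    def load(cls, path) -> "TinyTransformerEncoder":
        from pathlib import Path
        import json

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        enc = cls(EncoderConfig(**meta["config"]), Vocabulary(meta["vocab"]))
        arrays = np.load(path.with_suffix(".npz"))
        for k in enc.params:
            enc.params[k].data = arrays[k]
        return enc


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

def continue_pretraining(
    encoder: TinyTransformerEncoder,
    instances: Sequence[PretrainingInstance],
    config: AdaptationConfig,
) -> TinyTransformerEncoder:
    """Run exactly ``config.steps`` optimizer updates on the combined
    MLM + NSP objective.  The input encoder is left unmodified; the adapted
    copy is returned.  Fixed seed gives a reproducible instance order."""
    if not instances:
        raise ValueError("empty instance stream")
    adapted = encoder.clone()
    if config.steps == 0:
        return adapted
    optimizer = ad.Adam(adapted.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 17)
    order = rng.permutation(len(instances))
    cursor = 0
    for _ in range(config.steps):
        if cursor + config.batch_size > len(order):
            order = rng.permutation(len(instances))
            cursor = 0
        batch = [instances[i] for i in order[cursor:cursor + config.batch_size]]
        cursor += config.batch_size
        optimizer.zero_grad()
        loss = adapted.loss(batch)
        loss.backward()
        optimizer.step()
    return adapted


def nsp_accuracy(encoder, eval_pairs: Sequence[PretrainingInstance]) -> float:
    """Fraction of pairs whose predicted adjacency matches the label."""
    if not eval_pairs:
        raise ValueError("nsp_accuracy needs a nonempty evaluation set")
    pred = np.asarray(encoder.predict_is_next(eval_pairs), dtype=bool)
    truth = np.array([inst.is_next for inst in eval_pairs], dtype=bool)
    return float((pred == truth).mean())
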