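"""Session-scoring networks: single-task binary classifier and multi-task
11-code regressor.

Both architectures share the same trunk: the sequence of utterance embedding
vectors is fed to a bidirectional GRU layer; per-utterance hidden states are
the concatenation of the forward and backward outputs.  An additive
self-attention layer summarizes the session as a weighted average of hidden
states; the context vector, optionally concatenated with the one-hot session
metadata vector, passes through a small MLP.

* single-task: one attention head, sigmoid output = P(total CTRS >= 40),
  trained with class-weighted binary cross-entropy;
* multi-task: eleven attention heads over the shared hidden states, one per
  CTRS code, each with its own MLP and linear output, trained with the sum
  over codes of per-code mean squared error.  Outputs are clipped to [0, 6]
  at inference only; the total is their sum and the label its binarization.

Training uses Adam with early stopping on validation loss.  Everything runs
on the in-package autodiff engine; no GPU framework is involved.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .embeddings import EmbeddedSession
from .transcript_io import CTRS_CODES, HIGH, LOW, binarize_total

SINGLE = "single"
MULTI = "multi"


@dataclass
class ModelConfig:
    recurrent_units: int = 64
    attention_hidden: int = 10
    mlp_hidden: int = 20
    learning_rate: float = 0.001
    max_epochs: int = 200
    patience: int = 10
    seq_cap: int = 256  # 256 for therapist-only sequences, 512 for all utterances
    batch_size: int = 128  # 128 with cap 256; drop to 64 with cap 512
    use_metadata: bool = True
    arch: str = MULTI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in (SINGLE, MULTI):
            raise ValueError(f"arch must be '{SINGLE}' or '{MULTI}'")
        for f_ in ("recurrent_units", "attention_hidden", "mlp_hidden",
                   "max_epochs", "patience", "seq_cap", "batch_size"):
            if getattr(self, f_) < 1:
                raise ValueError(f"{f_} must be positive")


@dataclass
class EncoderOutput:
    """Per-utterance context vectors from the bidirectional recurrent layer."""

    hidden: np.ndarray  # (L, 2 * recurrent_units)
    mask: np.ndarray  # (L,) bool


@dataclass
class AttentionProfile:
    """Nonnegative per-utterance weights summing to 1 over valid positions."""

    weights: np.ndarray
    head_id: str


@dataclass
class Prediction:
    session_id: str
    label_pred: str
    prob_high: Optional[float] = None
    code_preds: Optional[np.ndarray] = None  # (11,), clipped to [0, 6]
    total_pred: Optional[float] = None
    attention: List[AttentionProfile] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Losses and class weights
# ---------------------------------------------------------------------------

BCE_EPS = 1e-7


def class_weights(labels: Sequence[int]) -> Dict[int, float]:
    """Per-class weights inversely proportional to class frequencies,
    normalized so the average sample weight is 1: w_c = n / (2 * n_c)."""
    y = np.asarray(labels, dtype=int)
    n = y.size
    counts = {c: int((y == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("class_weights requires both classes present")
    return {c: n / (2.0 * counts[c]) for c in (0, 1)}


def weighted_bce_loss(labels, probs, weights: Union[Dict[int, float], Sequence[float]]):
    """Mean over samples of w_{y_i} * [-y_i log p_i - (1-y_i) log(1-p_i)].

    Probabilities at exactly 0 or 1 are clamped by ``BCE_EPS``.  Accepts a
    numpy array (returns float) or an autodiff Tensor (returns a Tensor on
    the tape) for ``probs``.
    """
    y = np.asarray(labels, dtype=float)
    if isinstance(weights, dict):
        w = np.array([weights[int(v)] for v in y])
    else:
        w = np.array([np.asarray(weights)[int(v)] for v in y])
    if isinstance(probs, Tensor):
        p = ad.clamp(probs, BCE_EPS, 1.0 - BCE_EPS)
        loss = ad.mean(Tensor(w) * (Tensor(-y) * ad.log(p) + Tensor(y - 1.0) * ad.log(1.0 - p)))
        return loss
    p = np.clip(np.asarray(probs, dtype=float), BCE_EPS, 1.0 - BCE_EPS)
    if p.shape != y.shape:
        raise ValueError("labels and probs must have equal length")
    return float(np.mean(w * (-y * np.log(p) - (1.0 - y) * np.log(1.0 - p))))


def multitask_loss(true_codes, pred_codes):
    """Sum over the 11 codes of the per-code mean squared error.

    Predictions are used raw (not clipped) inside the loss.
    """
    t = np.asarray(true_codes, dtype=float)
    if isinstance(pred_codes, Tensor):
        if pred_codes.shape != t.shape:
            raise ValueError("true and predicted code arrays must match in shape")
        diff = pred_codes - Tensor(t)
        return ad.sum_(ad.mean(ad.square(diff), axis=0))
    p = np.asarray(pred_codes, dtype=float)
    if p.shape != t.shape:
        raise ValueError("true and predicted code arrays must match in shape")
    return float(((p - t) ** 2).mean(axis=0).sum())


# ---------------------------------------------------------------------------
# Stand-alone spec operations (single sequence, plain numpy)
# ---------------------------------------------------------------------------

def additive_attention(hidden: EncoderOutput, head_params: Dict[str, np.ndarray],
                       head_id: str = "total") -> Tuple[np.ndarray, AttentionProfile]:
    """Additive (Bahdanau-style) attention over one hidden sequence.

    score_t = v . tanh(W h_t + b); weights = softmax over valid positions;
    context = sum_t weight_t h_t.  Padded positions get weight exactly 0.
    """
    H, mask = hidden.hidden, np.asarray(hidden.mask, dtype=bool)
    if not mask.any():
        raise ValueError("additive_attention: all positions masked")
    scores = np.tanh(H @ head_params["W"] + head_params["b"]) @ head_params["v"]
    z = np.where(mask, scores, -np.inf)
    z -= z.max()
    e = np.where(mask, np.exp(z), 0.0)
    w = e / e.sum()
    return w @ H, AttentionProfile(weights=w, head_id=head_id)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class CTRSModel:
    """Bidirectional-GRU attention network over embedded sessions.

    Holds the parameter tensors for one architecture (single- or
    multi-task); :func:`train_model` is the fitting entry point.
    """

    def __init__(self, config: ModelConfig, embed_dim: int, meta_dim: int):
        self.config = config
        self.embed_dim = embed_dim
        self.meta_dim = meta_dim
        #: input feature scaling (1 / RMS norm of training utterance
        #: vectors); mean-pooled embeddings are short vectors, and without
        #: rescaling the recurrent layer starts deep in its linear regime
        self.input_scale = 1.0
        self.n_heads = len(CTRS_CODES) if config.arch == MULTI else 1
        self.head_ids = list(CTRS_CODES) if config.arch == MULTI else ["total"]
        rng = np.random.default_rng(config.seed)
        u, A, Hm = config.recurrent_units, config.attention_hidden, config.mlp_hidden
        K, E, M = self.n_heads, embed_dim, meta_dim
        D = 2 * u
        din = D + (M if config.use_metadata else 0)
        p: Dict[str, Tensor] = {}
        for d in ("f", "b"):
            p[f"W_in_{d}"] = ad.parameter(ad.glorot(rng, (E, 3 * u)))
            p[f"b_in_{d}"] = ad.parameter(np.zeros(3 * u))
            p[f"U_zr_{d}"] = ad.parameter(ad.glorot(rng, (u, 2 * u)))
            p[f"U_h_{d}"] = ad.parameter(ad.glorot(rng, (u, u)))
        p["Wa"] = ad.parameter(ad.glorot(rng, (D, K * A)))
        p["ba"] = ad.parameter(np.zeros(K * A))
        p["va"] = ad.parameter(ad.glorot(rng, (K, A)))
        p["W1"] = ad.parameter(ad.glorot(rng, (K, din, Hm)))
        p["b1"] = ad.parameter(np.zeros((K, 1, Hm)))
        p["W2"] = ad.parameter(ad.glorot(rng, (K, Hm, 1)))
        p["b2"] = ad.parameter(np.zeros((K, 1, 1)))
        self.params = p

    # -- forward pieces ------------------------------------------------------

    def _gru_direction(self, X: Tensor, mask: np.ndarray, direction: str) -> List[Tensor]:
        cfg = self.config
        u = cfg.recurrent_units
        B, T, E = X.shape
        p = self.params
        xproj = ad.reshape(
            ad.matmul(ad.reshape(X, (B * T, E)), p[f"W_in_{direction}"]) + p[f"b_in_{direction}"],
            (B, T, 3 * u),
        )
        order = range(T) if direction == "f" else range(T - 1, -1, -1)
        h = Tensor(np.zeros((B, u)))
        out: List[Optional[Tensor]] = [None] * T
        for t in order:
            h = ad.gru_step(h, xproj, t, p[f"U_zr_{direction}"],
                            p[f"U_h_{direction}"], mask[:, t][:, None].astype(float))
            out[t] = h
        return out  # type: ignore[return-value]

    def _forward(self, X: np.ndarray, mask: np.ndarray,
                 meta: Optional[np.ndarray]) -> Tuple[Tensor, Tensor]:
        """Returns (outputs (B, K), attention weights (B, K, T))."""
        cfg = self.config
        if X.shape[2] != self.embed_dim:
            raise ValueError(
                f"embedding dimension {X.shape[2]} does not match model ({self.embed_dim})"
            )
        p = self.params
        K, A = self.n_heads, cfg.attention_hidden
        B, T, _ = X.shape
        Xt = Tensor(X * self.input_scale)
        hf = self._gru_direction(Xt, mask, "f")
        hb = self._gru_direction(Xt, mask, "b")
        H = ad.concat([ad.stack(hf, axis=1), ad.stack(hb, axis=1)], axis=2)  # (B,T,2u)
        D = 2 * cfg.recurrent_units

        act = ad.tanh(ad.matmul(ad.reshape(H, (B * T, D)), p["Wa"]) + p["ba"])
        scores = ad.sum_(ad.reshape(act, (B, T, K, A)) * p["va"], axis=-1)  # (B,T,K)
        scores = ad.swapaxes(scores, 1, 2)  # (B,K,T)
        weights = ad.masked_softmax(scores, mask[:, None, :], axis=-1)
        context = ad.matmul(weights, H)  # (B,K,D)

        if cfg.use_metadata:
            if meta is None:
                raise ValueError("model was configured with use_metadata=True "
                                 "but no metadata vectors were provided")
            tiled = np.repeat(meta[:, None, :], K, axis=1)
            context = ad.concat([context, Tensor(tiled)], axis=2)
        x = ad.swapaxes(context, 0, 1)  # (K,B,din)
        h1 = ad.relu(ad.matmul(x, p["W1"]) + p["b1"])
        out = ad.matmul(h1, p["W2"]) + p["b2"]  # (K,B,1)
        out = ad.swapaxes(ad.reshape(out, (K, B)), 0, 1)  # (B,K)
        return out, weights

    # -- public surface ------------------------------------------------------

    def encode_sequence(self, session: EmbeddedSession) -> EncoderOutput:
        """Run only the bidirectional recurrent trunk on one session."""
        if session.length == 0:
            raise ValueError("cannot encode an empty session")
        X = session.vectors[None, :, :]
        mask = np.ones((1, session.length), dtype=bool)
        Xt = Tensor(X * self.input_scale)
        hf = self._gru_direction(Xt, mask, "f")
        hb = self._gru_direction(Xt, mask, "b")
        H = ad.concat([ad.stack(hf, axis=1), ad.stack(hb, axis=1)], axis=2)
        return EncoderOutput(hidden=H.data[0], mask=mask[0])

    def head_attention_params(self, head: int) -> Dict[str, np.ndarray]:
        """The additive-attention parameters of one head, in standalone form."""
        A = self.config.attention_hidden
        sl = slice(head * A, (head + 1) * A)
        return {
            "W": self.params["Wa"].data[:, sl],  # (2u, A): scores = tanh(H W + b) v
            "b": self.params["ba"].data[sl],
            "v": self.params["va"].data[head],
        }

    def predict(self, session: EmbeddedSession) -> Prediction:
        return self.predict_batch([session])[0]

    def predict_batch(self, sessions: Sequence[EmbeddedSession]) -> List[Prediction]:
        X, mask, meta, _ = assemble_batch(sessions, self.config.seq_cap)
        out, weights = self._forward(X, mask, meta if self.config.use_metadata else None)
        preds = []
        for i, s in enumerate(sessions):
            L = min(s.length, self.config.seq_cap)
            profiles = [
                AttentionProfile(weights=weights.data[i, k, :L].copy(), head_id=hid)
                for k, hid in enumerate(self.head_ids)
            ]
            if self.config.arch == SINGLE:
                prob = float(1.0 / (1.0 + np.exp(-out.data[i, 0])))
                preds.append(Prediction(
                    session_id=s.session_id,
                    label_pred=HIGH if prob >= 0.5 else LOW,
                    prob_high=prob, attention=profiles,
                ))
            else:
                codes = np.clip(out.data[i], 0.0, 6.0)
                total = float(codes.sum())
                preds.append(Prediction(
                    session_id=s.session_id,
                    label_pred=binarize_total(total),
                    code_preds=codes, total_pred=total, attention=profiles,
                ))
        return preds

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in self.params.items()})
        meta = {"config": self.config.__dict__, "embed_dim": self.embed_dim,
                "meta_dim": self.meta_dim, "input_scale": self.input_scale}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "CTRSModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]), meta["embed_dim"], meta["meta_dim"])
        model.input_scale = meta.get("input_scale", 1.0)
        arrays = np.load(path.with_suffix(".npz"))
        for k in model.params:
            model.params[k].data = arrays[k]
        return model


def encode_sequence(session: EmbeddedSession, model: CTRSModel) -> EncoderOutput:
    return model.encode_sequence(session)


def single_task_forward(session: EmbeddedSession, model: CTRSModel) -> Prediction:
    if model.config.arch != SINGLE:
        raise ValueError("model is not a single-task model")
    return model.predict(session)


def multi_task_forward(session: EmbeddedSession, model: CTRSModel) -> Prediction:
    if model.config.arch != MULTI:
        raise ValueError("model is not a multi-task model")
    return model.predict(session)


# ---------------------------------------------------------------------------
# Batching and training
# ---------------------------------------------------------------------------

def assemble_batch(sessions: Sequence[EmbeddedSession], cap: int):
    """Pad a group of sessions to a common length (the batch maximum).

    Returns (X (B,T,E), mask (B,T) bool, meta (B,M), lengths).
    """
    if not sessions:
        raise ValueError("empty batch")
    lengths = [min(s.length, cap) for s in sessions]
    T = max(lengths)
    E = sessions[0].vectors.shape[1]
    B = len(sessions)
    X = np.zeros((B, T, E))
    mask = np.zeros((B, T), dtype=bool)
    meta = np.stack([s.metadata_vec for s in sessions])
    for i, (s, L) in enumerate(zip(sessions, lengths)):
        X[i, :L] = s.vectors[:L]
        mask[i, :L] = True
    return X, mask, meta, lengths


def _targets(sessions: Sequence[EmbeddedSession], arch: str) -> np.ndarray:
    for s in sessions:
        if s.labels is None:
            raise ValueError(f"session {s.session_id} is unlabeled; training "
                             "requires all 11 CTRS codes")
    if arch == SINGLE:
        return np.array([1.0 if s.labels.label == HIGH else 0.0 for s in sessions])
    return np.stack([s.labels.as_vector() for s in sessions])


def _batch_loss(model: CTRSModel, batch: Sequence[EmbeddedSession],
                weights: Optional[Dict[int, float]]) -> Tensor:
    X, mask, meta, _ = assemble_batch(batch, model.config.seq_cap)
    out, _ = model._forward(X, mask, meta if model.config.use_metadata else None)
    if model.config.arch == SINGLE:
        y = _targets(batch, SINGLE)
        probs = ad.reshape(ad.sigmoid(out), (len(batch),))
        return weighted_bce_loss(y, probs, weights)
    y = _targets(batch, MULTI)
    return multitask_loss(y, out)


def train_model(
    config: ModelConfig,
    train: Sequence[EmbeddedSession],
    val: Sequence[EmbeddedSession],
) -> Tuple[CTRSModel, List[Dict[str, float]]]:
    """Fit a model with Adam and early stopping on validation loss.

    Stops when the validation loss has not improved for ``config.patience``
    consecutive epochs (or at ``config.max_epochs``) and returns the
    parameters of the best-validation-loss epoch.  ``val`` must be
    therapist-disjoint from ``train``.  History records per-epoch
    train/val loss.
    """
    if not train or not val:
        raise ValueError("train and val must both be nonempty")
    overlap = {s.therapist_id for s in train} & {s.therapist_id for s in val}
    if overlap:
        raise ValueError(f"therapist overlap between train and val: {sorted(overlap)[:5]}")
    _targets(train, config.arch)  # validate labels up front
    _targets(val, config.arch)

    embed_dim = train[0].vectors.shape[1]
    meta_dim = train[0].metadata_vec.shape[0]
    model = CTRSModel(config, embed_dim, meta_dim)
    # condition the inputs and the output head on the training data: scale
    # utterance vectors to unit RMS norm, and start the regression heads at
    # the per-code training means (the single-task head starts at logit 0)
    norms = np.concatenate([np.linalg.norm(s.vectors, axis=1) for s in train])
    rms = float(np.sqrt(np.mean(norms**2)))
    if rms > 0:
        model.input_scale = 1.0 / rms
    if config.arch == MULTI:
        code_means = np.stack([s.labels.as_vector() for s in train]).mean(axis=0)
        model.params["b2"].data = code_means.reshape(-1, 1, 1).copy()
    optimizer = ad.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    weights = None
    if config.arch == SINGLE:
        weights = class_weights([1 if s.labels.label == HIGH else 0 for s in train])

    # bucket by length so padded timesteps (pure overhead) are minimized
    order = sorted(range(len(train)), key=lambda i: train[i].length)
    batches = [
        [train[j] for j in order[i:i + config.batch_size]]
        for i in range(0, len(order), config.batch_size)
    ]
    val_batches = [
        list(val)[i:i + config.batch_size] for i in range(0, len(val), config.batch_size)
    ]

    history: List[Dict[str, float]] = []
    best_loss = np.inf
    best_epoch = 0
    best_params = None
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(batches))
        train_losses = []
        for bi in perm:
            batch = batches[bi]
            optimizer.zero_grad()
            loss = _batch_loss(model, batch, weights)
            loss.backward()
            optimizer.step()
            train_losses.append(float(loss.data) * len(batch))
        val_loss = sum(
            float(_batch_loss(model, vb, weights).data) * len(vb) for vb in val_batches
        ) / len(val)
        history.append({
            "epoch": epoch,
            "train_loss": sum(train_losses) / len(train),
            "val_loss": val_loss,
        })
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_params = {k: v.data.copy() for k, v in model.params.items()}
        if epoch - best_epoch >= config.patience:
            break
    assert best_params is not None
    for k, v in best_params.items():
        model.params[k].data = v
    return model, history


def history_to_csv(history: List[Dict[str, float]], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
        w.writeheader()
        w.writerows(history)
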