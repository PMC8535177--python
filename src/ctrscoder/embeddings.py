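"""Utterance embedding backends and session sequence assembly.

Each utterance is mapped to a fixed-dimension vector by average-pooling the
per-token representations of an encoder backend over at most ``max_tokens``
tokens.  A session becomes an ordered, length-capped sequence of such vectors
plus a one-hot metadata vector (:class:`EmbeddedSession`), the input unit for
the downstream scoring networks.

Two backends are provided:

* :class:`HashEmbeddingBackend` — every whitespace token maps to a fixed
  pseudo-random unit vector keyed by ``(token, seed)``.  Fully deterministic
  and download-free; the default for tests and simulation studies.
* a trainable transformer encoder (see :mod:`ctrscoder.adaptation`), which
  satisfies the same protocol after domain-adaptive pretraining.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .transcript_io import (
    CTRSScores,
    MetadataVocab,
    SessionTranscript,
    encode_metadata,
)

DEFAULT_MAX_TOKENS = 64


def whitespace_tokenize(text: str) -> List[str]:
    """Lowercased whitespace tokenization (the hash backend's tokenizer)."""
    return text.lower().split()


def tokenize_crop(text: str, max_tokens: int = DEFAULT_MAX_TOKENS,
                  tokenizer=whitespace_tokenize) -> List[str]:
    """Tokenize and keep only the first ``max_tokens`` tokens."""
    return tokenizer(text)[:max_tokens]


@runtime_checkable
class EmbeddingBackend(Protocol):
    """What an utterance encoder must provide."""

    name: str
    dimension: int
    max_tokens: int

    def tokenize(self, text: str) -> List[str]:
        ...

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        """Per-token final-layer vectors, shape (len(tokens), dimension)."""
        ...


@dataclass
class HashEmbeddingBackend:
    """Deterministic hash-based token embeddings.

    Each distinct token is assigned a fixed unit vector drawn from a
    generator seeded by a cryptographic hash of ``(token, seed)``, so the
    mapping is stable across processes and runs and distinct tokens get
    near-orthogonal directions in expectation.
    """

    dimension: int = 64
    seed: int = 0
    max_tokens: int = DEFAULT_MAX_TOKENS
    name: str = field(init=False)
    _cache: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.name = f"hash-d{self.dimension}-s{self.seed}"

    def tokenize(self, text: str) -> List[str]:
        return whitespace_tokenize(text)

    def token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}\x00{token}".encode("utf-8"), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dimension)
            vec /= np.linalg.norm(vec)
            self._cache[token] = vec
        return vec

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros((0, self.dimension))
        return np.stack([self.token_vector(t) for t in tokens])


def hash_embed_backend(dimension: int = 64, seed: int = 0,
                       max_tokens: int = DEFAULT_MAX_TOKENS) -> HashEmbeddingBackend:
    """Construct the deterministic hash embedding backend."""
    return HashEmbeddingBackend(dimension=dimension, seed=seed, max_tokens=max_tokens)


def embed_utterance(text: str, backend: EmbeddingBackend) -> np.ndarray:
    """Average-pool the backend's final-layer token vectors.

    Tokenization is cropped to the backend's ``max_tokens``.  Padding and
    special boundary tokens never enter the mean (backends return only real
    token vectors).  An utterance with no tokens maps to the zero vector so
    turn indexing against the transcript is preserved.
    """
    tokens = tokenize_crop(text, backend.max_tokens, backend.tokenize)
    if not tokens:
        return np.zeros(backend.dimension)
    return backend.encode_tokens(tokens).mean(axis=0)


@dataclass
class EmbeddedSession:
    """A session as the scoring networks see it: utterance vectors in order,
    a metadata one-hot vector, and the labels if known."""

    session_id: str
    therapist_id: str
    vectors: np.ndarray  # (L, dimension), L <= cap
    metadata_vec: np.ndarray
    labels: Optional[CTRSScores] = None

    @property
    def length(self) -> int:
        return self.vectors.shape[0]


def embed_session(
    session: SessionTranscript,
    backend: EmbeddingBackend,
    cap: int,
    vocab: MetadataVocab,
    truncation: str = "first",
) -> EmbeddedSession:
    """Embed at most ``cap`` utterances of a session, in order.

    ``truncation`` chooses which utterances survive when the session is
    longer than the cap: ``"first"`` keeps the earliest ``cap`` utterances
    (the simplest deterministic rule, the default); ``"edges"`` keeps the
    first ``ceil(cap/2)`` and last ``floor(cap/2)``, preserving session
    ends — several session-level skills (agenda setting, homework review
    and assignment) concentrate their evidence there.  Padding/masking to
    a common length happens at batch assembly time, not here.
    """
    if not session.utterances:
        raise ValueError(f"session {session.session_id}: no utterances to encode")
    if truncation not in ("first", "edges"):
        raise ValueError(f"unknown truncation policy {truncation!r}")
    if truncation == "edges" and len(session.utterances) > cap:
        head = (cap + 1) // 2
        utts = list(session.utterances[:head]) + list(session.utterances[-(cap - head):])
    else:
        utts = session.utterances[:cap]
    vectors = np.stack([embed_utterance(u.text, backend) for u in utts])
    if not np.isfinite(vectors).all():
        raise ValueError(f"session {session.session_id}: non-finite embedding")
    return EmbeddedSession(
        session_id=session.session_id,
        therapist_id=session.therapist_id,
        vectors=vectors,
        metadata_vec=encode_metadata(session.metadata, vocab),
        labels=session.labels,
    )


# ---------------------------------------------------------------------------
# Embedding cache
# ---------------------------------------------------------------------------

def _transcript_checksum(session: SessionTranscript) -> str:
    payload = json.dumps(
        [[u.role, u.text, u.start_s, u.end_s] for u in session.utterances],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def save_embedding_cache(path, session: SessionTranscript,
                         embedded: EmbeddedSession, backend: EmbeddingBackend,
                         cap: int) -> None:
    """Persist one session's vectors with a sidecar guarding against drift
    between the cache and the transcript it was computed from."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), vectors=embedded.vectors,
             metadata_vec=embedded.metadata_vec)
    sidecar = {
        "session_id": embedded.session_id,
        "backend": backend.name,
        "dimension": backend.dimension,
        "cap": cap,
        "checksum": _transcript_checksum(session),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_embedding_cache(path, session: SessionTranscript,
                         backend: EmbeddingBackend, cap: int) -> EmbeddedSession:
    """Load cached vectors; refuse silently stale caches."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar["backend"] != backend.name or sidecar["cap"] != cap:
        raise ValueError("embedding cache was built with a different configuration")
    if sidecar["checksum"] != _transcript_checksum(session):
        raise ValueError(
            f"embedding cache for {session.session_id} does not match the transcript"
        )
    arrays = np.load(path.with_suffix(".npz"))
    return EmbeddedSession(
        session_id=session.session_id,
        therapist_id=session.therapist_id,
        vectors=arrays["vectors"],
        metadata_vec=arrays["metadata_vec"],
        labels=session.labels,
    )
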