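"""Data model and file I/O for coded therapy session transcripts.

A session is an ordered list of role-tagged talk turns plus session-level
metadata and, optionally, the eleven CTRS quality codes.  The operations here
cover the deterministic preprocessing applied before any modeling: merging
same-speaker turns separated by short silences, restricting to one speaker
role, one-hot encoding the categorical metadata, and binarizing the total
CTRS score into the clinically used low/high competence label.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

THERAPIST = "therapist"
PATIENT = "patient"
ROLES = (THERAPIST, PATIENT)

#: The 11 CTRS code abbreviations, in canonical order:
#: agenda, feedback, understanding, interpersonal effectiveness,
#: collaboration, pacing, guided discovery, key cognitions & behaviors,
#: strategy for change, application of techniques, homework.
CTRS_CODES = ("ag", "fb", "un", "ip", "co", "pt", "gd", "cb", "sc", "at", "hw")

#: Total CTRS at or above this value indicates competent CBT delivery.
COMPETENCE_THRESHOLD = 40

METADATA_FIELDS = ("clinic", "level_of_care", "population", "assessment_time")

LOW = "low"
HIGH = "high"


class TranscriptError(ValueError):
    """Raised on malformed transcript data or schema violations."""


@dataclass(frozen=True)
class Utterance:
    """A talk turn: a maximal same-speaker segment of the session."""

    role: str
    text: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TranscriptError(f"unknown speaker role: {self.role!r}")
        if self.start_s < 0:
            raise TranscriptError(f"negative start time: {self.start_s}")
        if self.end_s < self.start_s:
            raise TranscriptError(
                f"utterance ends ({self.end_s}) before it starts ({self.start_s})"
            )


@dataclass(frozen=True)
class SessionMetadata:
    """Categorical session-level side information.

    Values are free strings; they are resolved against a vocabulary (with a
    reserved unknown slot per field) only at encoding time, so corpora with
    unseen categories always load.
    """

    clinic: str
    level_of_care: str
    population: str
    assessment_time: str

    def as_dict(self) -> Dict[str, str]:
        return {f: getattr(self, f) for f in METADATA_FIELDS}


@dataclass(frozen=True)
class CTRSScores:
    """The eleven 0-6 CTRS codes. The total is always recomputed from the
    individual codes, never trusted from file."""

    codes: Dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in CTRS_CODES if c not in self.codes]
        extra = [c for c in self.codes if c not in CTRS_CODES]
        if missing or extra:
            raise TranscriptError(
                f"CTRS codes must be exactly {CTRS_CODES}; "
                f"missing={missing}, unexpected={extra}"
            )
        for c, v in self.codes.items():
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 6):
                raise TranscriptError(f"code {c!r} must be an integer in [0, 6], got {v!r}")

    @property
    def total(self) -> int:
        return int(sum(self.codes[c] for c in CTRS_CODES))

    @property
    def label(self) -> str:
        return binarize_total(self.total)

    def as_vector(self) -> np.ndarray:
        return np.array([self.codes[c] for c in CTRS_CODES], dtype=float)


@dataclass
class SessionTranscript:
    """One coded session: the unit of prediction."""

    session_id: str
    therapist_id: str
    utterances: List[Utterance]
    metadata: SessionMetadata
    labels: Optional[CTRSScores] = None

    def __post_init__(self) -> None:
        starts = [u.start_s for u in self.utterances]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise TranscriptError(
                f"session {self.session_id}: utterances not sorted by start time"
            )


# ---------------------------------------------------------------------------
# JSONL corpus I/O
# ---------------------------------------------------------------------------

def _session_to_record(s: SessionTranscript) -> dict:
    return {
        "session_id": s.session_id,
        "therapist_id": s.therapist_id,
        "metadata": s.metadata.as_dict(),
        "utterances": [
            {"role": u.role, "text": u.text, "start_s": u.start_s, "end_s": u.end_s}
            for u in s.utterances
        ],
        "ctrs": dict(s.labels.codes) if s.labels is not None else None,
    }


def _record_to_session(rec: dict, lineno: int) -> SessionTranscript:
    try:
        meta = SessionMetadata(**{f: str(rec["metadata"][f]) for f in METADATA_FIELDS})
        utts = [
            Utterance(
                role=u["role"],
                text=str(u["text"]),
                start_s=float(u["start_s"]),
                end_s=float(u["end_s"]),
            )
            for u in rec["utterances"]
        ]
        ctrs = rec.get("ctrs")
        labels: Optional[CTRSScores] = None
        # Sessions missing any of the 11 codes load as unlabeled; filtering
        # them out (as done when only fully coded sessions are usable) is the
        # caller's decision.
        if ctrs is not None and all(c in ctrs for c in CTRS_CODES):
            labels = CTRSScores(codes={c: int(ctrs[c]) for c in CTRS_CODES})
        return SessionTranscript(
            session_id=str(rec["session_id"]),
            therapist_id=str(rec["therapist_id"]),
            utterances=utts,
            metadata=meta,
            labels=labels,
        )
    except (KeyError, TypeError) as exc:
        raise TranscriptError(f"line {lineno}: malformed session record: {exc}") from exc


def read_corpus(path) -> List[SessionTranscript]:
    """Read a JSONL transcript corpus, one session per line, order preserved.

    A session whose ``ctrs`` entry is null or incomplete is loaded with
    ``labels=None``.  Duplicate session ids raise :class:`TranscriptError`.
    """
    sessions: List[SessionTranscript] = []
    seen = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TranscriptError(f"line {lineno}: invalid JSON: {exc}") from exc
            s = _record_to_session(rec, lineno)
            if s.session_id in seen:
                raise TranscriptError(f"line {lineno}: duplicate session_id {s.session_id!r}")
            seen.add(s.session_id)
            sessions.append(s)
    return sessions


def write_corpus(sessions: Iterable[SessionTranscript], path) -> None:
    """Write sessions as JSONL (inverse of :func:`read_corpus`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sessions:
            fh.write(json.dumps(_session_to_record(s), sort_keys=True) + "\n")


def write_labels_csv(sessions: Iterable[SessionTranscript], path) -> None:
    """Export labels as CSV: session_id, the 11 code columns, and the total."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["session_id", *CTRS_CODES, "total"])
        for s in sessions:
            if s.labels is None:
                continue
            w.writerow([s.session_id, *(s.labels.codes[c] for c in CTRS_CODES), s.labels.total])


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def merge_turns(utterances: Sequence[Utterance], max_gap: float = 2.0) -> List[Utterance]:
    """Merge consecutive same-role utterances separated by short silences.

    Two adjacent utterances with the same role are merged when the silence
    gap between them is strictly shorter than ``max_gap`` seconds (a gap of
    exactly ``max_gap`` does not merge).  Texts are joined with a single
    space; the merged span runs from the first start to the last end.  The
    rule is applied transitively left-to-right.
    """
    starts = [u.start_s for u in utterances]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise TranscriptError("merge_turns requires utterances sorted by start time")
    merged: List[Utterance] = []
    for u in utterances:
        if merged:
            prev = merged[-1]
            if u.role == prev.role and (u.start_s - prev.end_s) < max_gap:
                joined = f"{prev.text} {u.text}".strip() if (prev.text and u.text) else (prev.text + u.text)
                merged[-1] = Utterance(
                    role=prev.role,
                    text=joined,
                    start_s=prev.start_s,
                    end_s=max(prev.end_s, u.end_s),
                )
                continue
        merged.append(u)
    return merged


def filter_role(session: SessionTranscript, role: str) -> SessionTranscript:
    """Keep only the utterances of one speaker role (metadata/labels intact)."""
    if role not in ROLES:
        raise TranscriptError(f"unknown speaker role: {role!r}")
    return replace(session, utterances=[u for u in session.utterances if u.role == role])


def binarize_total(total: int, threshold: int = COMPETENCE_THRESHOLD) -> str:
    """Binarize a total CTRS score: ``high`` iff total >= threshold."""
    if not 0 <= total <= 66:
        raise TranscriptError(f"total CTRS must be in [0, 66], got {total}")
    return HIGH if total >= threshold else LOW


# ---------------------------------------------------------------------------
# Metadata encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetadataVocab:
    """Per-field category lists, built from training sessions only.

    Each field encodes to a one-hot block of ``len(categories) + 1`` slots;
    the extra slot is reserved for categories unseen at fit time, so train
    and test vectors always share a dimension even when a fold excludes an
    entire clinic.
    """

    categories: Dict[str, List[str]]

    def __post_init__(self) -> None:
        missing = [f for f in METADATA_FIELDS if f not in self.categories]
        if missing:
            raise TranscriptError(f"vocab missing metadata fields: {missing}")

    @property
    def dimension(self) -> int:
        return sum(len(self.categories[f]) + 1 for f in METADATA_FIELDS)

    @classmethod
    def fit(cls, sessions: Iterable[SessionTranscript]) -> "MetadataVocab":
        cats: Dict[str, List[str]] = {f: [] for f in METADATA_FIELDS}
        for s in sessions:
            d = s.metadata.as_dict()
            for f in METADATA_FIELDS:
                if d[f] not in cats[f]:
                    cats[f].append(d[f])
        return cls(categories={f: sorted(v) for f, v in cats.items()})


def encode_metadata(metadata: SessionMetadata, vocab: MetadataVocab) -> np.ndarray:
    """One-hot encode metadata: one block per field, unknown slot last.

    Exactly one slot is active within each field's block.
    """
    blocks = []
    d = metadata.as_dict()
    for f in METADATA_FIELDS:
        cats = vocab.categories[f]
        block = np.zeros(len(cats) + 1)
        try:
            block[cats.index(d[f])] = 1.0
        except ValueError:
            block[-1] = 1.0  # unseen category -> reserved unknown slot
        blocks.append(block)
    return np.concatenate(blocks)
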