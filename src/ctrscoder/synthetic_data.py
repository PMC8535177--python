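"""Seeded generator of coded therapy corpora.

Real coded CBT corpora are not publicly distributable, so every pipeline
stage here is exercised on synthetic transcripts that reproduce the
*statistical* structure the method relies on:

* multi-turn therapist/patient dialogue, a few hundred talk turns per
  session, with timestamps whose silence gaps occasionally fall under the
  two-second merge rule;
* eleven session-level 0-6 codes whose sum binarizes at 40, with roughly a
  quarter of sessions on the competent (high) side;
* code-specific lexical marker tokens planted in therapist turns, localized
  early in the session, early+late, or uniformly, with a rate proportional
  to the latent code score — the lexical signal the attention networks are
  supposed to find;
* therapists with several sessions each and a per-therapist skill offset,
  so therapist-grouped evaluation is meaningful;
* four categorical metadata variables whose category-specific shifts move
  the scores, so metadata fusion has real signal.

The generative score model is deliberately simple and additive (Gaussian
latents, rounded and clamped), making parameter recovery well-posed: for
code ``c`` in session ``s`` of therapist ``t``,

    x_sc    = base_c + skill_t + lexical_noise          (drives the text)
    score_sc = clamp(round(x_sc + delta_s + noise), 0, 6)

where ``delta_s`` is the summed metadata shift.  Marker tokens for code
``c`` are planted at a rate proportional to ``x_sc`` (markers per 100
therapist turns), so the text carries ``x_sc`` but not ``delta_s`` — the
metadata variables carry information the language genuinely does not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .transcript_io import (
    CTRS_CODES,
    PATIENT,
    THERAPIST,
    CTRSScores,
    SessionMetadata,
    SessionTranscript,
    Utterance,
)

EARLY = "early"
EARLY_LATE = "early_late"
UNIFORM = "uniform"
LOCALIZATIONS = (EARLY, EARLY_LATE, UNIFORM)

#: Fraction of therapist turns counted as the "early" (and "late") window.
EDGE_FRACTION = 0.15

LEVEL_OF_CARE = (
    "inpatient", "outpatient", "intensive_outpatient", "residential",
    "school_based", "assertive_community_treatment",
)
POPULATIONS = (
    "child", "adolescent", "adult", "geriatric", "substance_use",
    "serious_mental_illness", "lgbtqi", "forensic", "homelessness",
)
ASSESSMENT_TIMES = (
    "pre_workshop", "post_workshop", "month_03", "month_06",
    "month_12", "month_18", "month_24",
)
CLINICS = tuple(f"clinic_{i:02d}" for i in range(1, 26))

# Invented filler vocabulary (pronounceable non-words, fixed and seed-free).
_CONS = ("n", "b", "t", "s", "m", "r", "l", "v")
_VOWELS = ("a", "e", "o", "u")
FILLER_VOCAB = tuple(
    c1 + v1 + c2 + v2
    for (c1, v1), (c2, v2) in itertools.islice(
        itertools.product(itertools.product(_CONS, _VOWELS), itertools.product(_CONS, _VOWELS)),
        64,
    )
)

#: Per-code marker token (invented non-words the hash embedder separates
#: cleanly from filler).
MARKER_TOKENS = {c: f"xq{c}ium" for c in CTRS_CODES}


def default_localizations() -> Dict[str, str]:
    """Where each code's lexical signal lives in the session.

    Agenda setting happens at the start; homework review/assignment at the
    start and end; every other skill is exhibited throughout.
    """
    loc = {c: UNIFORM for c in CTRS_CODES}
    loc["ag"] = EARLY
    loc["hw"] = EARLY_LATE
    return loc


def default_metadata_effects() -> Dict[str, Dict[str, float]]:
    """Per-category additive shifts on every code's latent score."""
    effects: Dict[str, Dict[str, float]] = {}
    effects["assessment_time"] = {
        c: s for c, s in zip(ASSESSMENT_TIMES, np.linspace(-0.45, 0.45, len(ASSESSMENT_TIMES)))
    }
    effects["level_of_care"] = {
        c: s for c, s in zip(LEVEL_OF_CARE, np.linspace(-0.25, 0.25, len(LEVEL_OF_CARE)))
    }
    effects["population"] = {
        c: s for c, s in zip(POPULATIONS, np.linspace(-0.2, 0.2, len(POPULATIONS)))
    }
    # small, non-monotone clinic effects
    effects["clinic"] = {
        c: 0.3 * (((7 * i) % 25) / 24.0 - 0.5) for i, c in enumerate(CLINICS)
    }
    return effects


@dataclass
class SimulationConfig:
    """Defaults target a corpus with the scale and structure of a real coded
    CBT archive: ~430 +/- 230 turns per session with roughly 47% of turns
    therapist-attributed, and 20-35% of sessions above the competence
    threshold."""

    n_therapists: int = 60
    sessions_per_therapist: int = 10
    turns_mean: float = 430.0
    turns_sd: float = 230.0
    min_turns: int = 60
    max_turns: int = 900
    words_per_turn_mean: float = 11.0
    code_base: float = 3.1
    skill_sd: float = 0.8
    lexical_noise_sd: float = 0.4
    noise_sd: float = 0.25
    marker_rate_per_score: float = 14.0  # markers per 100 therapist turns per score unit
    marker_rate_offset: float = 1.5  # latent-score floor below which no markers appear
    #: early_late codes split their lexical evidence into two half-signals
    #: (e.g., reviewing previous homework vs assigning new homework), each
    #: carrying independent noise of this size, so an accurate readout must
    #: attend to both session ends rather than either one alone
    edge_component_sd: float = 0.7
    localizations: Dict[str, str] = field(default_factory=default_localizations)
    metadata_effects: Dict[str, Dict[str, float]] = field(default_factory=default_metadata_effects)
    metadata_scale: float = 1.0
    leak_to_patient: bool = False  # plant markers in patient turns too
    asr_noise_rate: float = 0.0  # random token deletion/substitution rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_therapists < 1 or self.sessions_per_therapist < 1:
            raise ValueError("counts must be positive")
        if self.min_turns < 2:
            raise ValueError("sessions need at least two turns")
        for c, loc in self.localizations.items():
            if loc not in LOCALIZATIONS:
                raise ValueError(f"unknown localization {loc!r} for code {c!r}")


@dataclass
class GroundTruth:
    """Everything the generator decided, recorded exactly as generated."""

    therapist_skill: Dict[str, float]
    #: session_id -> code -> latent score x_sc (before metadata/noise/rounding)
    latent: Dict[str, Dict[str, float]]
    #: session_id -> summed metadata shift delta_s
    metadata_shift: Dict[str, float]
    #: session_id -> code -> list of (turn_index, word_index) marker plants
    marker_positions: Dict[str, Dict[str, List[Tuple[int, int]]]]

    def marker_count(self, session_id: str, code: str) -> int:
        return len(self.marker_positions[session_id][code])


def _role_sequence(n_turns: int, rng: np.random.Generator) -> List[str]:
    """Alternating therapist/patient turns; with probability ~0.13 the
    patient takes a second consecutive turn, bringing the therapist share
    of turns to roughly 47%."""
    roles: List[str] = []
    role = THERAPIST
    while len(roles) < n_turns:
        roles.append(role)
        if role == THERAPIST:
            role = PATIENT
        else:
            role = PATIENT if rng.random() < 0.128 else THERAPIST
    return roles[:n_turns]


def _edge_window_indices(idx: Sequence[int], localization: str) -> List[int]:
    """Subset of therapist-turn indices eligible for a code's markers."""
    n = len(idx)
    k = max(1, int(np.ceil(EDGE_FRACTION * n)))
    if localization == EARLY:
        return list(idx[:k])
    if localization == EARLY_LATE:
        return list(dict.fromkeys(list(idx[:k]) + list(idx[-k:])))
    return list(idx)


def generate_corpus(config: SimulationConfig) -> Tuple[List[SessionTranscript], GroundTruth]:
    """Generate a labeled synthetic corpus plus its ground truth.

    Fixed seed gives a byte-identical corpus (via ``write_corpus``).
    """
    # separate streams so text-generation draws do not perturb the score
    # model (and vice versa) when structural parameters change
    rng = np.random.default_rng([config.seed, 1])
    rng_text = np.random.default_rng([config.seed, 2])
    sessions: List[SessionTranscript] = []
    gt = GroundTruth({}, {}, {}, {})

    meta_effects = config.metadata_effects
    for t_i in range(config.n_therapists):
        tid = f"t{t_i:03d}"
        skill = rng.normal(0.0, config.skill_sd)
        gt.therapist_skill[tid] = skill
        clinic = CLINICS[rng.integers(len(CLINICS))]
        level = LEVEL_OF_CARE[rng.integers(len(LEVEL_OF_CARE))]
        population = POPULATIONS[rng.integers(len(POPULATIONS))]
        for s_i in range(config.sessions_per_therapist):
            sid = f"{tid}_s{s_i:02d}"
            atime = ASSESSMENT_TIMES[rng.integers(len(ASSESSMENT_TIMES))]
            metadata = SessionMetadata(
                clinic=clinic, level_of_care=level,
                population=population, assessment_time=atime,
            )
            delta = config.metadata_scale * sum(
                meta_effects[f][v] for f, v in metadata.as_dict().items()
            )

            n_turns = int(np.clip(round(rng_text.normal(config.turns_mean, config.turns_sd)),
                                  config.min_turns, config.max_turns))
            roles = _role_sequence(n_turns, rng_text)
            words: List[List[str]] = [
                list(rng_text.choice(FILLER_VOCAB,
                                     size=max(1, rng_text.poisson(config.words_per_turn_mean))))
                for _ in range(n_turns)
            ]
            target_idx = [
                i for i, r in enumerate(roles)
                if r == THERAPIST or (config.leak_to_patient and r == PATIENT)
            ]
            n_t_turns = sum(r == THERAPIST for r in roles)

            latent: Dict[str, float] = {}
            markers: Dict[str, List[Tuple[int, int]]] = {c: [] for c in CTRS_CODES}
            codes: Dict[str, int] = {}
            def marker_count(x_eff: float, scale: float = 1.0) -> int:
                return max(0, int(round(
                    config.marker_rate_per_score * scale
                    * max(x_eff - config.marker_rate_offset, 0.0)
                    * n_t_turns / 100.0)))

            def plant(window: Sequence[int], m: int, token: str) -> None:
                for _ in range(m):
                    turn = int(window[rng_text.integers(len(window))])
                    pos = int(rng_text.integers(len(words[turn]) + 1))
                    words[turn].insert(pos, token)

            for c in CTRS_CODES:
                x = config.code_base + skill + rng.normal(0.0, config.lexical_noise_sd)
                latent[c] = x
                loc = config.localizations[c]
                if loc == EARLY_LATE:
                    # two complementary half-signals: early and late windows
                    # each reflect x plus independent noise, so neither end
                    # alone suffices for an accurate readout
                    x_e = x + rng.normal(0.0, config.edge_component_sd)
                    x_l = x + rng.normal(0.0, config.edge_component_sd)
                    plant(_edge_window_indices(target_idx, EARLY),
                          marker_count(x_e), MARKER_TOKENS[c])
                    late = [i for i in _edge_window_indices(target_idx, EARLY_LATE)
                            if i not in set(_edge_window_indices(target_idx, EARLY))]
                    plant(late or target_idx, marker_count(x_l), MARKER_TOKENS[c])
                else:
                    plant(_edge_window_indices(target_idx, loc),
                          marker_count(x), MARKER_TOKENS[c])
                score = int(np.clip(round(x + delta + rng.normal(0.0, config.noise_sd)), 0, 6))
                codes[c] = score
            # recover exact word positions after all insertions
            for c in CTRS_CODES:
                tok = MARKER_TOKENS[c]
                markers[c] = [
                    (i, j) for i in target_idx for j, w in enumerate(words[i]) if w == tok
                ]

            if config.asr_noise_rate > 0:
                for w in words:
                    for j in range(len(w) - 1, -1, -1):
                        if rng_text.random() < config.asr_noise_rate:
                            if rng_text.random() < 0.5 and len(w) > 1:
                                del w[j]
                            else:
                                w[j] = str(rng_text.choice(FILLER_VOCAB))

            utterances: List[Utterance] = []
            t_cursor = 0.0
            for i, (r, w) in enumerate(zip(roles, words)):
                dur = 0.42 * len(w)
                utterances.append(Utterance(role=r, text=" ".join(w),
                                            start_s=round(t_cursor, 3),
                                            end_s=round(t_cursor + dur, 3)))
                t_cursor += dur + rng_text.exponential(1.2)

            sessions.append(SessionTranscript(
                session_id=sid, therapist_id=tid, utterances=utterances,
                metadata=metadata, labels=CTRSScores(codes=codes),
            ))
            gt.latent[sid] = latent
            gt.metadata_shift[sid] = delta
            gt.marker_positions[sid] = markers
    return sessions, gt


def make_splits(
    sessions: Sequence[SessionTranscript],
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Tuple[List[SessionTranscript], ...]:
    """Partition sessions into therapist-disjoint groups at given fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive and sum to 1")
    therapists = sorted({s.therapist_id for s in sessions})
    if len(therapists) < len(fractions):
        raise ValueError("not enough therapists for the requested partitions")
    rng = np.random.default_rng(seed)
    rng.shuffle(therapists)
    counts = [max(1, int(round(f * len(therapists)))) for f in fractions[1:]]
    counts = [len(therapists) - sum(counts)] + counts
    if counts[0] < 1:
        raise ValueError("fractions leave a partition without therapists")
    parts: List[List[SessionTranscript]] = []
    lo = 0
    for c in counts:
        group = set(therapists[lo:lo + c])
        parts.append([s for s in sessions if s.therapist_id in group])
        lo += c
    return tuple(parts)


# ---------------------------------------------------------------------------
# Adjacency-structured corpus for domain-adaptation experiments
# ---------------------------------------------------------------------------

CHAIN_VOCAB = tuple(f"qlink{i:02d}" for i in range(16))


def generate_adjacency_corpus(
    n_sessions: int = 120,
    turns_per_session: int = 30,
    copies: int = 5,
    seed: int = 0,
) -> List[SessionTranscript]:
    """Corpus whose utterance adjacency is lexically decidable.

    Codewords form one global cyclic topic sequence; a session enters the
    cycle at a random offset and each utterance carries several copies of
    its own topic codeword and of the next one, shuffled together.  True
    successors therefore share a codeword, and — because the successor
    relation is corpus-wide, not session-specific — an encoder that learns
    it on training sessions can decide adjacency on held-out sessions.
    Used to exercise continued pretraining: next-sentence prediction is at
    chance before adaptation and solvable after.
    """
    rng = np.random.default_rng(seed)
    V = len(CHAIN_VOCAB)
    meta = SessionMetadata(clinic="clinic_01", level_of_care="outpatient",
                           population="adult", assessment_time="pre_workshop")
    sessions = []
    for s_i in range(n_sessions):
        k0 = int(rng.integers(V))
        utterances = []
        t_cursor = 0.0
        for i in range(turns_per_session):
            toks = [CHAIN_VOCAB[(k0 + i) % V]] * copies \
                + [CHAIN_VOCAB[(k0 + i + 1) % V]] * copies
            rng.shuffle(toks)
            dur = 0.42 * len(toks)
            utterances.append(Utterance(
                role=THERAPIST if i % 2 == 0 else PATIENT,
                text=" ".join(toks),
                start_s=round(t_cursor, 3), end_s=round(t_cursor + dur, 3),
            ))
            t_cursor += dur + 2.5  # keep turns unmerged
        sessions.append(SessionTranscript(
            session_id=f"adj{s_i:03d}", therapist_id=f"t{s_i % 10:02d}",
            utterances=utterances, metadata=meta, labels=None,
        ))
    return sessions
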