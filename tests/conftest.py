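import numpy as np
import pytest

import ctrscoder as cc
from ctrscoder.transcript_io import (
    CTRS_CODES,
    CTRSScores,
    SessionMetadata,
    SessionTranscript,
    Utterance,
)


def make_utterance(role="therapist", text="hello there", start=0.0, end=1.0):
    return Utterance(role=role, text=text, start_s=start, end_s=end)


def make_session(session_id="s1", therapist_id="t1", n_turns=6, labels=True,
                 text="nova belu timo"):
    utts = []
    t = 0.0
    for i in range(n_turns):
        role = "therapist" if i % 2 == 0 else "patient"
        utts.append(Utterance(role=role, text=text, start_s=t, end_s=t + 2.0))
        t += 5.0
    scores = CTRSScores(codes={c: 3 for c in CTRS_CODES}) if labels else None
    return SessionTranscript(
        session_id=session_id,
        therapist_id=therapist_id,
        utterances=utts,
        metadata=SessionMetadata(clinic="clinic_01", level_of_care="outpatient",
                                 population="adult", assessment_time="pre_workshop"),
        labels=scores,
    )


@pytest.fixture
def tiny_corpus():
    """Small labeled synthetic corpus: 8 therapists x 3 sessions."""
    # code_base near the decision threshold so even 24 sessions reliably
    # contain both competence classes
    cfg = cc.SimulationConfig(n_therapists=8, sessions_per_therapist=3,
                              turns_mean=70, turns_sd=15, min_turns=40,
                              code_base=3.6, seed=7)
    sessions, gt = cc.generate_corpus(cfg)
    return sessions, gt


@pytest.fixture(scope="session")
def default_corpus():
    """The generator's default study corpus (600 sessions), shared across
    tests that check its statistical properties."""
    sessions, gt = cc.generate_corpus(cc.SimulationConfig(seed=202))
    return sessions, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
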