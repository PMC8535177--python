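"""The package's headline simulation study, runnable end to end.

One call generates the default synthetic coded corpus, embeds the
therapist-attributed turns with the hash backend, trains the multi-task
scoring network twice under a shared therapist-grouped split — once with
and once without metadata fusion — and evaluates held-out macro-F1,
attention-saliency localization, and the tf-idf/SVM reference system.

Problem sizes follow the generator defaults (60 therapists x 10 sessions);
the held-out set is 20% of therapists.  Training is capped at 70 epochs
with early stopping (patience 10), a budget at which validation loss has
plateaued on this corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .baseline import baseline_predictions
from .embeddings import EmbeddedSession, embed_session, hash_embed_backend
from .evaluation import assert_no_therapist_overlap, macro_f1, prepare_sessions
from .models import ModelConfig, Prediction, train_model
from .saliency import SaliencyCurve, aggregate_saliency, collect_profiles
from .synthetic_data import SimulationConfig, generate_corpus, make_splits
from .transcript_io import THERAPIST, MetadataVocab


@dataclass
class RecoveryStudyResult:
    f1_metadata: float
    f1_no_metadata: float
    f1_baseline: float
    high_share: float
    n_sessions: int
    n_test: int
    curves: Dict[str, SaliencyCurve]
    predictions_metadata: List[Prediction]
    epochs: Dict[str, int] = field(default_factory=dict)


def run_recovery_study(
    seed: int = 0,
    sim_config: Optional[SimulationConfig] = None,
    embed_dim: int = 64,
    max_epochs: int = 70,
    with_baseline: bool = True,
) -> RecoveryStudyResult:
    """Run the default end-to-end recovery experiment.

    Both model variants (with/without metadata) share the corpus, the
    therapist-grouped 70/10/20 train/validation/test split, the embeddings,
    and the training seed, so their difference isolates metadata fusion.
    Saliency curves aggregate only held-out (test) attention profiles.
    """
    sim = sim_config or SimulationConfig(seed=seed)
    sessions, _ = generate_corpus(sim)
    high_share = float(np.mean([s.labels.label == "high" for s in sessions]))

    prep = prepare_sessions(sessions, "therapist")
    train_s, val_s, test_s = make_splits(prep, (0.7, 0.1, 0.2), seed=seed)
    assert_no_therapist_overlap(train_s + val_s, test_s)
    vocab = MetadataVocab.fit(train_s + val_s)
    backend = hash_embed_backend(dimension=embed_dim, seed=seed)
    # edge-preserving truncation: late-session evidence (homework
    # assignment) must survive for sessions longer than the cap
    embedded: Dict[str, EmbeddedSession] = {
        s.session_id: embed_session(s, backend, 256, vocab, truncation="edges")
        for s in prep
    }
    emb_train = [embedded[s.session_id] for s in train_s]
    emb_val = [embedded[s.session_id] for s in val_s]
    emb_test = [embedded[s.session_id] for s in test_s]
    y_test = [s.labels.label for s in test_s]

    results: Dict[bool, float] = {}
    preds_meta: List[Prediction] = []
    epochs: Dict[str, int] = {}
    for use_meta in (True, False):
        cfg = ModelConfig(arch="multi", use_metadata=use_meta,
                          max_epochs=max_epochs, seed=seed)
        model, history = train_model(cfg, emb_train, emb_val)
        preds = model.predict_batch(emb_test)
        results[use_meta] = macro_f1(y_test, [p.label_pred for p in preds])
        epochs["metadata" if use_meta else "no_metadata"] = len(history)
        if use_meta:
            preds_meta = preds

    f1_base = float("nan")
    if with_baseline:
        raw_by_id = {s.session_id: s for s in sessions}
        raw_train = [raw_by_id[s.session_id] for s in train_s + val_s]
        raw_test = [raw_by_id[s.session_id] for s in test_s]
        base_pred = baseline_predictions(raw_train, raw_test,
                                         role_filter=THERAPIST, seed=seed)
        f1_base = macro_f1(y_test, base_pred)

    curves = {
        c.head_id: c
        for c in aggregate_saliency(collect_profiles(preds_meta))
    }
    return RecoveryStudyResult(
        f1_metadata=results[True],
        f1_no_metadata=results[False],
        f1_baseline=f1_base,
        high_share=high_share,
        n_sessions=len(sessions),
        n_test=len(test_s),
        curves=curves,
        predictions_metadata=preds_meta,
        epochs=epochs,
    )
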