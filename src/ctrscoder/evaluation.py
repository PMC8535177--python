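"""Therapist-grouped cross-validation, macro-F1 scoring, paired bootstrap
significance testing, and the experiment-grid orchestrator.

Sessions by the same therapist must never straddle a train/test boundary:
fold assignment operates on therapists, packing them into folds greedily
(largest session count first, into the currently smallest fold) so fold
sizes stay balanced.  Every train/test split is re-checked for therapist
overlap at run time.

The paired bootstrap resamples sessions with replacement and compares the
macro-F1 of a candidate system against a reference on each resample; the
one-sided p-value is the fraction of resamples on which the candidate fails
to improve.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import f1_score

from .embeddings import EmbeddingBackend, embed_session
from .models import (
    MULTI,
    SINGLE,
    CTRSModel,
    ModelConfig,
    Prediction,
    train_model,
)
from .transcript_io import (
    HIGH,
    THERAPIST,
    MetadataVocab,
    SessionTranscript,
    filter_role,
    merge_turns,
)


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """session_id -> fold index; all sessions of a therapist share a fold."""

    fold_of: Dict[str, int]
    k: int

    def fold_sessions(self, fold: int) -> List[str]:
        return [sid for sid, f in self.fold_of.items() if f == fold]

    def content_hash(self) -> str:
        payload = json.dumps(sorted(self.fold_of.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def grouped_kfold(sessions: Sequence[SessionTranscript], k: int = 10,
                  seed: int = 0) -> FoldAssignment:
    """Assign therapists to k folds, balancing session counts greedily.

    Therapists are shuffled by seed, ordered by descending session count
    (stable, so the shuffle breaks ties), and each is placed in the fold
    with the fewest sessions so far (lowest index on ties).
    """
    by_therapist: Dict[str, List[str]] = {}
    for s in sessions:
        by_therapist.setdefault(s.therapist_id, []).append(s.session_id)
    therapists = sorted(by_therapist)
    if len(therapists) < k:
        raise ValueError(f"{len(therapists)} therapists cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    rng.shuffle(therapists)
    therapists.sort(key=lambda t: -len(by_therapist[t]))  # stable: keeps shuffle order on ties
    fold_sizes = np.zeros(k, dtype=int)
    fold_of: Dict[str, int] = {}
    for t in therapists:
        f = int(np.argmin(fold_sizes))
        fold_sizes[f] += len(by_therapist[t])
        for sid in by_therapist[t]:
            fold_of[sid] = f
    return FoldAssignment(fold_of=fold_of, k=k)


def assert_no_therapist_overlap(train: Sequence[SessionTranscript],
                                test: Sequence[SessionTranscript]) -> None:
    overlap = {s.therapist_id for s in train} & {s.therapist_id for s in test}
    if overlap:
        raise AssertionError(f"therapist leakage across folds: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def macro_f1(y_true: Sequence, y_pred: Sequence) -> float:
    """Unweighted mean of per-class F1 over the observed label set.

    A class with zero predicted and zero true positives contributes 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("macro_f1 needs equal-length nonempty label vectors")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))


def _macro_f1_binary_counts(tp, pred_pos, true_pos, tn_pred, tn_true, tp_neg):
    """Vectorized binary macro-F1 from resampled counts (see paired_bootstrap)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f1_pos = np.where(pred_pos + true_pos > 0, 2 * tp / (pred_pos + true_pos), 0.0)
        f1_neg = np.where(tn_pred + tn_true > 0, 2 * tp_neg / (tn_pred + tn_true), 0.0)
    return 0.5 * (f1_pos + f1_neg)


def paired_bootstrap(
    y_true: Sequence,
    pred_a: Sequence,
    pred_b: Sequence,
    n_resamples: int = 100_000,
    seed: int = 0,
    chunk: int = 10_000,
) -> Dict[str, float]:
    """One-sided paired bootstrap: does system A improve over reference B?

    Sessions are resampled with replacement ``n_resamples`` times; each
    resample scores d = macro_f1(A) - macro_f1(B); the p-value is the
    fraction of resamples with d <= 0.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    y = np.asarray(y_true)
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("y_true, pred_a, pred_b must have equal length")
    n = y.size
    pos = np.unique(y)[-1]  # either class works; macro-F1 is symmetric

    # per-session indicator columns; a resample's counts are a weighted sum
    ind = np.column_stack([
        (a == pos) & (y == pos), (a == pos), (y == pos),
        (a != pos), (y != pos), (a != pos) & (y != pos),
        (b == pos) & (y == pos), (b == pos),
        (b != pos), (b != pos) & (y != pos),
    ]).astype(float)

    rng = np.random.default_rng(seed)
    n_le = 0
    diff_sum = 0.0
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        w = rng.multinomial(n, np.full(n, 1.0 / n), size=m).astype(float)
        c = w @ ind  # (m, 10)
        fa = _macro_f1_binary_counts(c[:, 0], c[:, 1], c[:, 2], c[:, 3], c[:, 4], c[:, 5])
        fb = _macro_f1_binary_counts(c[:, 6], c[:, 7], c[:, 2], c[:, 8], c[:, 4], c[:, 9])
        d = fa - fb
        n_le += int((d <= 0).sum())
        diff_sum += float(d.sum())
        done += m
    return {
        "p_value": n_le / n_resamples,
        "mean_diff": diff_sum / n_resamples,
        "n_resamples": n_resamples,
    }


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    config_tag: Dict[str, object]
    per_session: List[Dict[str, object]]
    macro_f1: float
    fold_hash: str
    bootstrap: Optional[Dict[str, float]] = None

    def labels(self) -> Tuple[np.ndarray, np.ndarray]:
        y_true = np.array([r["label_true"] for r in self.per_session])
        y_pred = np.array([r["label_pred"] for r in self.per_session])
        return y_true, y_pred


FitPredict = Callable[[List[SessionTranscript], List[SessionTranscript]], List[Prediction]]


def cross_validate(
    sessions: Sequence[SessionTranscript],
    folds: FoldAssignment,
    fit_predict: FitPredict,
    config_tag: Optional[Dict[str, object]] = None,
) -> EvaluationReport:
    """Run one system through every fold; collect per-session predictions.

    ``fit_predict(train, test)`` must train from scratch on ``train`` only
    and return one :class:`Prediction` per test session (in order).
    """
    by_id = {s.session_id: s for s in sessions}
    labeled = [s for s in sessions if s.labels is not None]
    per_session: List[Dict[str, object]] = []
    for f in range(folds.k):
        test_ids = set(folds.fold_sessions(f))
        test = [s for s in labeled if s.session_id in test_ids]
        train = [s for s in labeled if s.session_id not in test_ids]
        if not test:
            continue
        assert_no_therapist_overlap(train, test)
        preds = fit_predict(train, test)
        for s, p in zip(test, preds):
            per_session.append({
                "session_id": s.session_id,
                "fold": f,
                "label_true": s.labels.label,
                "label_pred": p.label_pred,
                "prediction": p,
            })
    y_true = [r["label_true"] for r in per_session]
    y_pred = [r["label_pred"] for r in per_session]
    return EvaluationReport(
        config_tag=config_tag or {},
        per_session=per_session,
        macro_f1=macro_f1(y_true, y_pred),
        fold_hash=folds.content_hash(),
    )


# ---------------------------------------------------------------------------
# Experiment grid (arch x metadata x utterance set x backend)
# ---------------------------------------------------------------------------

SEQ_CAPS = {"therapist": 256, "all": 512}
BATCH_SIZES = {"therapist": 128, "all": 64}


def prepare_sessions(sessions: Sequence[SessionTranscript],
                     utterance_set: str) -> List[SessionTranscript]:
    """Merge short-gap same-role turns, then optionally keep therapist turns."""
    out = []
    for s in sessions:
        merged = SessionTranscript(
            session_id=s.session_id, therapist_id=s.therapist_id,
            utterances=merge_turns(s.utterances), metadata=s.metadata,
            labels=s.labels,
        )
        if utterance_set == "therapist":
            merged = filter_role(merged, THERAPIST)
        out.append(merged)
    return out


def make_neural_runner(
    arch: str,
    use_metadata: bool,
    backend: EmbeddingBackend,
    utterance_set: str,
    model_config: Optional[ModelConfig] = None,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> FitPredict:
    """Build a fit/predict closure for one grid cell.

    Metadata vocabulary is fit on the training sessions of each call only;
    a therapist-grouped slice of the training data (about ``val_fraction``
    of therapists) is held out for early stopping.
    """
    from .synthetic_data import make_splits

    base = model_config or ModelConfig()
    cap = base.seq_cap if model_config is not None else SEQ_CAPS[utterance_set]
    batch = base.batch_size if model_config is not None else BATCH_SIZES[utterance_set]

    def fit_predict(train: List[SessionTranscript], test: List[SessionTranscript]):
        cfg = ModelConfig(**{**base.__dict__, "arch": arch, "use_metadata": use_metadata,
                             "seq_cap": cap, "batch_size": batch, "seed": seed})
        train_p = prepare_sessions(train, utterance_set)
        test_p = prepare_sessions(test, utterance_set)
        vocab = MetadataVocab.fit(train_p)
        tr, va = make_splits(train_p, (1.0 - val_fraction, val_fraction), seed=seed)
        emb_tr = [embed_session(s, backend, cfg.seq_cap, vocab) for s in tr]
        emb_va = [embed_session(s, backend, cfg.seq_cap, vocab) for s in va]
        model, _ = train_model(cfg, emb_tr, emb_va)
        emb_te = [embed_session(s, backend, cfg.seq_cap, vocab) for s in test_p]
        return model.predict_batch(emb_te)

    return fit_predict


def run_experiment_grid(
    sessions: Sequence[SessionTranscript],
    backends: Dict[str, EmbeddingBackend],
    k: int = 10,
    seed: int = 0,
    archs: Sequence[str] = (SINGLE, MULTI),
    metadata_options: Sequence[bool] = (False, True),
    utterance_sets: Sequence[str] = ("all", "therapist"),
    model_config: Optional[ModelConfig] = None,
    reference_cell: Optional[Dict[str, object]] = None,
    n_bootstrap: int = 0,
) -> List[EvaluationReport]:
    """Evaluate every grid cell under one shared fold assignment.

    Sharing folds makes the comparisons paired; each cell re-fits metadata
    vocabularies (and any other fold-local state) from its training folds.
    If ``reference_cell`` is given and ``n_bootstrap`` > 0, every other cell
    is bootstrap-compared against it.
    """
    labeled = [s for s in sessions if s.labels is not None]
    folds = grouped_kfold(labeled, k=k, seed=seed)
    reports: List[EvaluationReport] = []
    for backend_name, backend in backends.items():
        for utt in utterance_sets:
            for arch in archs:
                for use_meta in metadata_options:
                    tag = {"backend": backend_name, "utterance_set": utt,
                           "arch": arch, "metadata": use_meta}
                    runner = make_neural_runner(arch, use_meta, backend, utt,
                                                model_config=model_config, seed=seed)
                    reports.append(cross_validate(labeled, folds, runner, config_tag=tag))
    if reference_cell is not None and n_bootstrap > 0:
        ref = next(r for r in reports if r.config_tag == reference_cell)
        order = [r["session_id"] for r in ref.per_session]
        y_true = np.array([r["label_true"] for r in ref.per_session])
        ref_pred = np.array([r["label_pred"] for r in ref.per_session])
        for rep in reports:
            if rep is ref:
                continue
            pred_map = {r["session_id"]: r["label_pred"] for r in rep.per_session}
            pred = np.array([pred_map[sid] for sid in order])
            rep.bootstrap = paired_bootstrap(y_true, pred, ref_pred,
                                             n_resamples=n_bootstrap, seed=seed)
    return reports


def technique_marginals(reports: Sequence[EvaluationReport],
                        techniques: Dict[str, Callable[[Dict[str, object]], bool]]
                        ) -> Dict[str, Dict[str, float]]:
    """Mean F1 across grid cells with/without each technique, plus the
    relative improvement (yes - no) / no."""
    out: Dict[str, Dict[str, float]] = {}
    for name, is_on in techniques.items():
        yes = [r.macro_f1 for r in reports if is_on(r.config_tag)]
        no = [r.macro_f1 for r in reports if not is_on(r.config_tag)]
        if not yes or not no:
            raise ValueError(f"technique {name!r} does not split the grid")
        m_yes, m_no = float(np.mean(yes)), float(np.mean(no))
        out[name] = {"no": m_no, "yes": m_yes,
                     "relative_improvement": (m_yes - m_no) / m_no}
    return out
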