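"""Frequency-based reference system: unigram tf-idf features, univariate
F-test feature selection (default k = 32), linear support-vector classifier.

Each session is one document — the concatenation of its (optionally
role-filtered) utterance texts.  tf-idf uses the common smoothed convention
idf = ln((1+N)/(1+df)) + 1 with L2-normalized rows (recorded in
``TfidfModel.settings``).  Everything is fit on training folds only;
refitting per cross-validation fold is the evaluator's responsibility.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.feature_selection import f_classif
from sklearn.svm import LinearSVC

from .transcript_io import HIGH, LOW, SessionTranscript, filter_role


@dataclass
class TfidfModel:
    vectorizer: TfidfVectorizer
    settings: Dict[str, bool]

    @property
    def vocabulary(self) -> Dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def idf(self) -> np.ndarray:
        return self.vectorizer.idf_

    def transform(self, sessions: Sequence[SessionTranscript],
                  role_filter: Optional[str] = None) -> np.ndarray:
        docs = [session_document(s, role_filter) for s in sessions]
        return self.vectorizer.transform(docs).toarray()


def session_document(session: SessionTranscript, role_filter: Optional[str] = None) -> str:
    if role_filter is not None:
        session = filter_role(session, role_filter)
    return " ".join(u.text for u in session.utterances)


def fit_tfidf(sessions: Sequence[SessionTranscript],
              role_filter: Optional[str] = None) -> TfidfModel:
    """Fit session-level unigram tf-idf (smoothed idf, L2 rows)."""
    docs = [session_document(s, role_filter) for s in sessions]
    vec = TfidfVectorizer(
        lowercase=True, token_pattern=r"(?u)\S+", sublinear_tf=False,
        smooth_idf=True, norm="l2",
    )
    try:
        vec.fit(docs)
    except ValueError as exc:
        raise ValueError("empty vocabulary: no usable tokens in the corpus") from exc
    return TfidfModel(vectorizer=vec, settings={"lowercase": True, "sublinear_tf": False})


def select_k_best_ftest(X: np.ndarray, y: Sequence, k: int = 32) -> List[int]:
    """Indices of the k largest one-way ANOVA F statistics between the two
    label groups, ties broken by lower column index.

    Zero-variance features have undefined F; it is taken as 0, so they are
    never selected ahead of any feature with positive F.
    """
    X = np.asarray(X)
    y_arr = np.asarray(y)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the number of features {X.shape[1]}")
    if len(np.unique(y_arr)) != 2:
        raise ValueError("F-test selection requires exactly two classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stats, _ = f_classif(X, y_arr)
    f_stats = np.nan_to_num(f_stats, nan=0.0, posinf=np.inf)
    f_stats = np.where(np.isfinite(f_stats), f_stats, np.finfo(float).max)
    # stable sort on -F: equal statistics resolve to the lower column index
    return np.argsort(-f_stats, kind="stable")[:k].tolist()


def feature_report(model: TfidfModel, X: np.ndarray, y: Sequence,
                   selected: Sequence[int], path) -> None:
    """CSV of selected tokens with their F statistic and rank."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stats, _ = f_classif(np.asarray(X), np.asarray(y))
    f_stats = np.nan_to_num(f_stats, nan=0.0)
    inv_vocab = {i: t for t, i in model.vocabulary.items()}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["token", "f_statistic", "rank"])
        for rank, col in enumerate(selected, start=1):
            w.writerow([inv_vocab[col], f"{f_stats[col]:.6g}", rank])


def train_svm(X_selected: np.ndarray, y: Sequence,
              class_weighting: bool = True, seed: int = 0) -> LinearSVC:
    """Linear SVM on the selected features (class-weighted by default,
    mirroring the imbalance handling of the neural models)."""
    y_arr = np.asarray(y)
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training needs at least 2 samples in each class")
    clf = LinearSVC(
        class_weight="balanced" if class_weighting else None,
        random_state=seed, dual="auto",
    )
    clf.fit(np.asarray(X_selected), y_arr)
    return clf


def predict(classifier: LinearSVC, X_selected: np.ndarray) -> np.ndarray:
    return classifier.predict(np.asarray(X_selected))


def baseline_predictions(
    train_sessions: Sequence[SessionTranscript],
    test_sessions: Sequence[SessionTranscript],
    role_filter: Optional[str] = None,
    k: int = 32,
    seed: int = 0,
) -> np.ndarray:
    """Full baseline pipeline for one train/test split: fit tf-idf and
    feature selection on the training sessions only, then predict the
    binary competence label for the test sessions."""
    y_train = np.array([s.labels.label for s in train_sessions])
    model = fit_tfidf(train_sessions, role_filter)
    X_train = model.transform(train_sessions, role_filter)
    cols = select_k_best_ftest(X_train, y_train == HIGH, k=min(k, X_train.shape[1]))
    clf = train_svm(X_train[:, cols], y_train, seed=seed)
    X_test = model.transform(test_sessions, role_filter)
    return predict(clf, X_test[:, cols])
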