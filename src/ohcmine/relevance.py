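"""Relevance classification: patient-experience posts vs the rest.

Only posts relaying firsthand patient (or family/friend) experience
with the target drug carry off-label evidence; general-knowledge posts
and consumption-free questions are filtered out first.  Texts are
vectorized with bag-of-words schemes under a hard feature cap — 900
features for a single scheme, 450 + 450 for the concatenated
count+TF-IDF ensemble, 300 for the averaged-word-embedding scheme —
and fed to a classic classifier grid.  The selected configuration is
a gradient-boosted tree ensemble over the concatenated count+TF-IDF
vectors, chosen on held-out F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import (
    CountVectorizer,
    TfidfVectorizer,
    ENGLISH_STOP_WORDS,
)
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .corpus_io import Post
from .entities import EmbeddingTable, train_embeddings
from .evaluation import MetricsReport, confusion_matrix, metrics_from_cm
from .spellnorm import tokenize

SCHEMES = ("count", "tfidf", "count_plus_tfidf", "doc_embedding")
CLASSIFIERS = ("svm", "naive_bayes", "sgd_linear", "random_forest", "gradient_boosted_trees")

MODEL_FORMAT_VERSION = 1


class RelevanceError(ValueError):
    pass


@dataclass(frozen=True)
class VectorizerSpec:
    scheme: str = "count_plus_tfidf"
    max_features: int = 900
    remove_stopwords: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise RelevanceError(f"unknown scheme {self.scheme!r}")
        if self.max_features <= 0:
            raise RelevanceError("max_features must be positive")


@dataclass(frozen=True)
class TrainConfig:
    test_fraction: float = 0.2
    k_folds: int = 10
    classifier: str = "gradient_boosted_trees"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise RelevanceError("test_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise RelevanceError("k_folds must be >= 2")
        if self.classifier not in CLASSIFIERS:
            raise RelevanceError(f"unknown classifier {self.classifier!r}")


def _texts(posts: Sequence[Union[Post, str]]) -> list[str]:
    return [p.text if isinstance(p, Post) else p for p in posts]


class TextVectorizer:
    """Fit/transform wrapper over the supported vectorization schemes.

    Feature selection under the cap keeps the highest-corpus-frequency
    terms.  For ``count_plus_tfidf`` each half is capped at
    max_features // 2 and the halves are horizontally concatenated.
    ``doc_embedding`` averages corpus-trained word vectors
    (max_features doubles as the embedding dimension, 300 by default
    at the call sites).
    """

    def __init__(self, spec: VectorizerSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        self._count: Optional[CountVectorizer] = None
        self._tfidf: Optional[TfidfVectorizer] = None
        self._table: Optional[EmbeddingTable] = None
        self.fitted = False

    def _stopwords(self) -> Optional[list[str]]:
        return sorted(ENGLISH_STOP_WORDS) if self.spec.remove_stopwords else None

    def _make(self, cls, cap: int):
        return cls(
            tokenizer=tokenize,
            token_pattern=None,
            lowercase=False,  # tokenize() already lowercases
            stop_words=self._stopwords(),
            max_features=cap,
        )

    def fit_transform(self, texts: Sequence[str]):
        if not texts:
            raise RelevanceError("cannot fit a vectorizer on an empty corpus")
        scheme = self.spec.scheme
        cap = self.spec.max_features
        if scheme == "count":
            self._count = self._make(CountVectorizer, cap)
            X = self._count.fit_transform(texts)
        elif scheme == "tfidf":
            self._tfidf = self._make(TfidfVectorizer, cap)
            X = self._tfidf.fit_transform(texts)
        elif scheme == "count_plus_tfidf":
            half = cap // 2
            self._count = self._make(CountVectorizer, half)
            self._tfidf = self._make(TfidfVectorizer, half)
            X = sp.hstack(
                [self._count.fit_transform(texts), self._tfidf.fit_transform(texts)],
                format="csr",
            )
        else:  # doc_embedding
            stop = set(self._stopwords() or ())
            corpus = [[t for t in tokenize(x) if t not in stop] for x in texts]
            self._table = train_embeddings(
                corpus, d=cap, window=5, min_count=1, seed=self.seed
            )
            X = self._embed(corpus)
        self.fitted = True
        return X

    def transform(self, texts: Sequence[str]):
        if not self.fitted:
            raise RelevanceError("vectorizer not fitted")
        scheme = self.spec.scheme
        if scheme == "count":
            return self._count.transform(texts)
        if scheme == "tfidf":
            return self._tfidf.transform(texts)
        if scheme == "count_plus_tfidf":
            return sp.hstack(
                [self._count.transform(texts), self._tfidf.transform(texts)],
                format="csr",
            )
        stop = set(self._stopwords() or ())
        corpus = [[t for t in tokenize(x) if t not in stop] for x in texts]
        return self._embed(corpus)

    def _embed(self, corpus: list[list[str]]) -> np.ndarray:
        table = self._table
        out = np.zeros((len(corpus), table.dimension))
        for i, toks in enumerate(corpus):
            vecs = [table[t] for t in toks if t in table]
            if vecs:
                out[i] = np.mean(vecs, axis=0)
        return out

    @property
    def vocabulary_(self) -> dict[str, int]:
        vocab: dict[str, int] = {}
        if self._count is not None:
            vocab.update(self._count.vocabulary_)
        if self._tfidf is not None:
            offset = len(vocab)
            for term, idx in self._tfidf.vocabulary_.items():
                vocab.setdefault(term, offset + idx)
        if self._table is not None:
            vocab.update({t: i for i, t in enumerate(sorted(self._table.vectors))})
        return vocab


def vectorize(texts: Sequence[str], spec: VectorizerSpec, seed: int = 0):
    """Fit a vectorizer on ``texts`` and return (matrix, vectorizer)."""
    vec = TextVectorizer(spec, seed=seed)
    X = vec.fit_transform(texts)
    return X, vec


def _make_classifier(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="linear", random_state=seed)
    if name == "naive_bayes":
        return MultinomialNB()
    if name == "sgd_linear":
        return SGDClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if name == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.3,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    raise RelevanceError(f"unknown classifier {name!r}")


@dataclass
class RelevanceModel:
    """A fitted vectorizer + classifier with its training provenance."""

    vectorizer: TextVectorizer
    classifier: object
    spec: VectorizerSpec
    config: TrainConfig
    format_version: int = MODEL_FORMAT_VERSION

    def predict(self, texts: Sequence[str]) -> list[bool]:
        if not self.vectorizer.fitted:
            raise RelevanceError("model not fitted")
        if not texts:
            return []
        X = self.vectorizer.transform(texts)
        return [bool(v) for v in self.classifier.predict(X)]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": self.format_version,
                "vectorizer": self.vectorizer,
                "classifier": self.classifier,
                "spec": self.spec,
                "config": self.config,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RelevanceModel":
        bundle = joblib.load(path)
        if bundle.get("format_version") != MODEL_FORMAT_VERSION:
            raise RelevanceError(
                f"unsupported model bundle version {bundle.get('format_version')!r}"
            )
        return cls(
            vectorizer=bundle["vectorizer"],
            classifier=bundle["classifier"],
            spec=bundle["spec"],
            config=bundle["config"],
        )


def train_relevance_classifier(
    posts: Sequence[Union[Post, str]],
    labels: Sequence[bool],
    spec: VectorizerSpec | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[RelevanceModel, MetricsReport]:
    """Train on an 80/20 split (stratified) and report held-out metrics.

    The vectorizer is fitted on the training split only; metrics come
    from the evaluation module on the held-out fraction.
    """
    spec = spec or VectorizerSpec()
    cfg = cfg or TrainConfig()
    texts = _texts(posts)
    if len(texts) != len(labels):
        raise RelevanceError("posts and labels must align")
    if not texts:
        raise RelevanceError("empty training input")
    y = np.asarray([bool(v) for v in labels])
    if len(set(y.tolist())) < 2:
        raise RelevanceError("training labels contain a single class")
    idx_train, idx_test = train_test_split(
        np.arange(len(texts)),
        test_size=cfg.test_fraction,
        random_state=cfg.seed,
        stratify=y,
    )
    vec = TextVectorizer(spec, seed=cfg.seed)
    X_train = vec.fit_transform([texts[i] for i in idx_train])
    clf = _make_classifier(cfg.classifier, cfg.seed)
    clf.fit(X_train, y[idx_train])
    model = RelevanceModel(vectorizer=vec, classifier=clf, spec=spec, config=cfg)
    predictions = model.predict([texts[i] for i in idx_test])
    cm = confusion_matrix(predictions, y[idx_test].tolist())
    return model, metrics_from_cm(cm)


def classify_relevance(
    model: RelevanceModel, posts: Sequence[Union[Post, str]]
) -> list[bool]:
    """One relevance flag per post; pure function of (model, text)."""
    return model.predict(_texts(posts))


def kfold_cv(
    posts: Sequence[Union[Post, str]],
    labels: Sequence[bool],
    spec: VectorizerSpec | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[list[MetricsReport], dict[str, dict[str, float]]]:
    """Seeded stratified k-fold cross-validation.

    Folds partition the data (each sample validates exactly once); each
    fold refits the vectorizer and classifier from scratch.  Returns
    per-fold reports and a mean/sd summary per metric.
    """
    spec = spec or VectorizerSpec()
    cfg = cfg or TrainConfig()
    texts = _texts(posts)
    y = np.asarray([bool(v) for v in labels])
    if cfg.k_folds > len(texts):
        raise RelevanceError(f"k_folds={cfg.k_folds} exceeds n={len(texts)}")
    splitter = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
    reports: list[MetricsReport] = []
    for train_idx, val_idx in splitter.split(np.zeros(len(texts)), y):
        vec = TextVectorizer(spec, seed=cfg.seed)
        X_train = vec.fit_transform([texts[i] for i in train_idx])
        clf = _make_classifier(cfg.classifier, cfg.seed)
        clf.fit(X_train, y[train_idx])
        fold_model = RelevanceModel(vectorizer=vec, classifier=clf, spec=spec, config=cfg)
        predictions = fold_model.predict([texts[i] for i in val_idx])
        reports.append(metrics_from_cm(confusion_matrix(predictions, y[val_idx].tolist())))
    summary: dict[str, dict[str, float]] = {}
    for metric in ("accuracy", "precision", "recall", "f1"):
        vals = [getattr(r, metric) for r in reports if getattr(r, metric) is not None]
        if vals:
            summary[metric] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
    return reports, summary
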