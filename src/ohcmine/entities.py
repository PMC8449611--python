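"""Medical entity recognition and the embedding-based nonmedical filter.

Drug and indication mentions are recognized by greedy longest match of
lowercase token n-grams against the lexicon — a dictionary NER that
replaces a full clinical NER system while keeping its output contract
(mentions with sentence index, token span, category and concept id).

Spurious "indication" matches are filtered with a distributional test:
word vectors are trained on the corpus and any mention whose vector has
a *negative* cosine similarity with the target drug's vector is removed
as nonmedical.  Mentions with no vector are retained.

The embedding trainer is skip-gram with negative sampling (word2vec),
fitted as full-batch logistic matrix factorization of the within-window
co-occurrence matrix: observed pairs are pushed toward positive inner
products and expected negative samples toward negative ones, so words
sharing no context with the drug end up with negative cosine — the sign
behaviour the nonmedical filter relies on.  Full-batch gradient descent
with a seeded initialization makes training exactly reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .spellnorm import Lexicon, tokenize

# ---------------------------------------------------------------------------
# Sentence splitting

_SENT_BOUNDARY = re.compile(r"[.!?]+(?=\s+[A-Z]|\s*$)")


def split_sentences(text: str) -> list[str]:
    """Deterministic splitter: ``.``/``!``/``?`` followed by whitespace
    plus an uppercase letter, or end of text."""
    sentences: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        chunk = text[start : m.end()].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# Dictionary NER


@dataclass(frozen=True)
class EntityMention:
    """A recognized drug or indication span.

    ``token_span`` is a half-open [start, end) interval of token indices
    within the sentence given by ``sentence_index``.
    """

    post_id: str
    sentence_index: int
    token_span: tuple[int, int]
    surface: str
    category: str
    concept_id: str

    def __post_init__(self) -> None:
        start, end = self.token_span
        if not (0 <= start < end):
            raise ValueError(f"invalid token span {self.token_span}")
        if self.category not in ("drug", "indication"):
            raise ValueError(f"unknown category {self.category!r}")


def recognize_entities(text: str, lexicon: Lexicon, post_id: str = "") -> list[EntityMention]:
    """Greedy longest-match dictionary NER over spell-normalized text.

    Scans each sentence left to right; at each token the longest lexicon
    surface starting there wins, so retained spans never overlap.
    """
    mentions: list[EntityMention] = []
    for s_idx, sentence in enumerate(split_sentences(text)):
        tokens = tokenize(sentence)
        i = 0
        n = len(tokens)
        while i < n:
            matched = None
            for width in range(min(lexicon.max_surface_tokens, n - i), 0, -1):
                entry = lexicon.lookup_tokens(tuple(tokens[i : i + width]))
                if entry is not None:
                    matched = (width, entry)
                    break
            if matched is None:
                i += 1
                continue
            width, entry = matched
            mentions.append(
                EntityMention(
                    post_id=post_id,
                    sentence_index=s_idx,
                    token_span=(i, i + width),
                    surface=" ".join(tokens[i : i + width]),
                    category=entry.category,
                    concept_id=entry.concept_id,
                )
            )
            i += width
    return mentions


def write_mentions(mentions: Sequence[EntityMention], path: str | Path) -> None:
    """Mentions as JSONL (post_id, sentence_index, start, end, surface,
    category, concept_id)."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "post_id": m.post_id,
                        "sentence_index": m.sentence_index,
                        "start": m.token_span[0],
                        "end": m.token_span[1],
                        "surface": m.surface,
                        "category": m.category,
                        "concept_id": m.concept_id,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_mentions(path: str | Path) -> list[EntityMention]:
    import json

    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                EntityMention(
                    post_id=rec["post_id"],
                    sentence_index=rec["sentence_index"],
                    token_span=(rec["start"], rec["end"]),
                    surface=rec["surface"],
                    category=rec["category"],
                    concept_id=rec["concept_id"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Word embeddings (skip-gram with negative sampling)


@dataclass
class EmbeddingTable:
    vectors: dict[str, np.ndarray]
    dimension: int
    window: int
    min_count: int
    seed: int
    epochs: int = 0

    def __post_init__(self) -> None:
        for tok, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(f"vector for {tok!r} has wrong dimension")
            if not np.any(v):
                raise ValueError(f"zero-norm vector stored for {tok!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def save(self, path: str | Path) -> None:
        """word2vec-style text format: header, then token + floats."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for tok in sorted(self.vectors):
                vals = " ".join(f"{x:.6f}" for x in self.vectors[tok])
                fh.write(f"{tok} {vals}\n")

    @classmethod
    def load(cls, path: str | Path, window: int = 5, min_count: int = 2, seed: int = 0) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]], dtype=float)
        if len(vectors) != n:
            raise ValueError("embedding file header disagrees with row count")
        return cls(vectors=vectors, dimension=d, window=window, min_count=min_count, seed=seed)


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    d: int = 100,
    window: int = 5,
    min_count: int = 2,
    seed: int = 0,
    negative: int = 5,
    epochs: int = 200,
    learning_rate: float = 0.05,
) -> EmbeddingTable:
    """Train skip-gram word vectors with negative sampling.

    Builds the symmetric within-``window`` co-occurrence matrix over
    tokens with frequency >= ``min_count`` and fits the SGNS objective
    by full-batch gradient descent: for word/context matrices W, C the
    loss is sum_ij [ X_ij log s(w_i.c_j) + k_ij log s(-w_i.c_j) ] where
    X is the co-occurrence count and k_ij = ``negative`` expected
    samples from the 0.75-power unigram distribution.  One ``epoch`` is
    one full-batch gradient step.  Word vectors (W) are returned.

    Deterministic for a fixed corpus and seed.  Dense in the vocabulary
    (O(V^2) memory), intended for desk-scale corpora.
    """
    if not corpus:
        raise ValueError("empty corpus")
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError(f"no token reaches min_count={min_count}")
    index = {t: i for i, t in enumerate(vocab)}
    n = len(vocab)
    cooc = np.zeros((n, n), dtype=float)
    for sent in corpus:
        ids = [index.get(t, -1) for t in sent]
        for i, a in enumerate(ids):
            if a < 0:
                continue
            for j in range(max(0, i - window), i):
                b = ids[j]
                if b >= 0:
                    cooc[a, b] += 1.0
                    cooc[b, a] += 1.0
    total = cooc.sum()
    if total == 0:
        raise ValueError("no co-occurrences within window")
    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    unigram = freq / freq.sum()
    neg_weight = negative * total * np.outer(unigram, unigram)
    rng = np.random.default_rng(seed)
    W = rng.normal(scale=0.1, size=(n, d))
    C = rng.normal(scale=0.1, size=(n, d))
    for _ in range(epochs):
        scores = np.clip(W @ C.T, -30.0, 30.0)
        sig = 1.0 / (1.0 + np.exp(-scores))
        grad = (cooc * (1.0 - sig) - neg_weight * sig) / total
        dW = grad @ C
        dC = grad.T @ W
        W += learning_rate * n * dW
        C += learning_rate * n * dC
    vectors = {tok: W[i].copy() for tok, i in index.items() if np.any(W[i])}
    return EmbeddingTable(
        vectors=vectors, dimension=d, window=window, min_count=min_count,
        seed=seed, epochs=epochs,
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


@dataclass
class EntityFilterConfig:
    """Sign test on cosine similarity: mentions scoring below the
    threshold (default 0, i.e. strictly negative cosine) are removed."""

    similarity_threshold: float = 0.0


def _mention_vector(table: EmbeddingTable, mention: EntityMention) -> Optional[np.ndarray]:
    toks = [t for t in tokenize(mention.surface) if t in table]
    if not toks:
        return None
    return np.mean([table[t] for t in toks], axis=0)


def filter_nonmedical(
    drug_concept: str,
    mentions: Sequence[EntityMention],
    table: EmbeddingTable,
    cfg: EntityFilterConfig | None = None,
) -> list[EntityMention]:
    """Drop mentions whose cosine similarity with the drug is negative.

    A mention is removed iff a vector exists for it and
    cosine(drug, mention) < threshold; out-of-vocabulary mentions are
    retained.  Output preserves input order and is a subset of it.
    """
    cfg = cfg or EntityFilterConfig()
    if drug_concept not in table:
        raise KeyError(f"drug concept {drug_concept!r} absent from embedding table")
    drug_vec = table[drug_concept]
    kept: list[EntityMention] = []
    for m in mentions:
        vec = _mention_vector(table, m)
        if vec is None or not np.any(vec):
            kept.append(m)
            continue
        if cosine_similarity(drug_vec, vec) >= cfg.similarity_threshold:
            kept.append(m)
    return kept
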