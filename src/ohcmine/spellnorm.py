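"""Consumer-language spelling normalization.

Posts on patient forums are written by laypersons and commonly contain
misspelled drug and condition names ("gabapentn", "insomia").  Before
entity recognition the text is normalized by an edit-distance corrector
over a combined vocabulary: the medical lexicon surfaces plus a general
English word list.  The corrector is deliberately conservative:

* in-vocabulary tokens are never touched;
* tokens shorter than 4 characters are never touched (protects "it",
  "rx", dosage tokens);
* tokens containing digits are never touched;
* a correction is applied only when a unique nearest candidate exists
  within Levenshtein distance 2 (ties broken in favour of medical
  surfaces, then lexicographically).

The stage is a contract-compatible stand-in for an external consumer
spell checker; any callable with the same signature can replace it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import edlib

MAX_EDIT_DISTANCE = 2
MIN_CORRECTABLE_LENGTH = 4

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z]+)?")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens (alphanumeric runs, apostrophes kept)."""
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Tokens with their character offsets, case preserved."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class LexiconError(ValueError):
    """Malformed lexicon input."""


@dataclass(frozen=True)
class LexiconEntry:
    surface: str  # lowercase, possibly multi-word
    concept_id: str
    category: str  # "drug" | "indication"

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise LexiconError(f"empty concept_id for surface {self.surface!r}")
        if self.category not in ("drug", "indication"):
            raise LexiconError(f"unknown category {self.category!r}")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(tokenize(self.surface))


@dataclass
class Lexicon:
    """Surface-form dictionary mapping consumer terms to concepts.

    Stands in for a full medical metathesaurus: each entry maps a
    lowercase surface form to a concept id under one of two categories
    (drug, indication).  ``general_vocabulary`` is a plain English word
    list used only by the spell corrector.
    """

    entries: list[LexiconEntry]
    general_vocabulary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.surface, e.category)
            if key in seen:
                raise LexiconError(f"duplicate surface {e.surface!r} in {e.category}")
            seen.add(key)
        # token-tuple index for longest-match NER
        self._token_index: dict[tuple[str, ...], LexiconEntry] = {}
        self.max_surface_tokens = 1
        for e in self.entries:
            toks = e.tokens
            self._token_index.setdefault(toks, e)
            self.max_surface_tokens = max(self.max_surface_tokens, len(toks))
        self._medical_tokens: set[str] = {
            t for e in self.entries for t in e.tokens
        }
        self._vocab: set[str] = self._medical_tokens | {
            w.lower() for w in self.general_vocabulary
        }
        # length-bucketed candidate index for the corrector
        self._buckets: dict[int, list[str]] = {}
        for w in sorted(self._vocab):
            self._buckets.setdefault(len(w), []).append(w)

    def lookup_tokens(self, tokens: tuple[str, ...]) -> Optional[LexiconEntry]:
        return self._token_index.get(tokens)

    def is_medical_token(self, token: str) -> bool:
        return token in self._medical_tokens

    def __contains__(self, token: str) -> bool:
        return token.lower() in self._vocab

    def entries_for_category(self, category: str) -> list[LexiconEntry]:
        return [e for e in self.entries if e.category == category]

    def concepts(self, category: str) -> set[str]:
        return {e.concept_id for e in self.entries if e.category == category}

    def surfaces_for_concept(self, concept_id: str, category: str) -> list[str]:
        return sorted(
            e.surface
            for e in self.entries
            if e.concept_id == concept_id and e.category == category
        )

    def candidates_near(self, token: str, max_edit: int) -> Iterable[str]:
        n = len(token)
        for length in range(max(1, n - max_edit), n + max_edit + 1):
            yield from self._buckets.get(length, ())


def load_lexicon(tsv_path: str | Path, vocab_path: str | Path | None = None) -> Lexicon:
    """Read a lexicon from TSV (surface, concept_id, category).

    ``vocab_path`` is an optional one-word-per-line general vocabulary.
    """
    entries = []
    with open(tsv_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LexiconError(f"line {lineno}: expected 3 tab-separated fields")
            surface, concept_id, category = parts
            entries.append(LexiconEntry(surface.strip().lower(), concept_id.strip(), category.strip()))
    vocab: set[str] = set()
    if vocab_path is not None:
        with open(vocab_path, encoding="utf-8") as fh:
            vocab = {w.strip().lower() for w in fh if w.strip()}
    return Lexicon(entries=entries, general_vocabulary=vocab)


def bundled_lexicon() -> Lexicon:
    """The lexicon shipped with the package (12 drugs + indication surfaces)."""
    from importlib import resources

    data = resources.files("ohcmine") / "data"
    with resources.as_file(data / "lexicon.tsv") as lex, resources.as_file(
        data / "general_vocab.txt"
    ) as voc:
        return load_lexicon(lex, voc)


@dataclass(frozen=True)
class Correction:
    original: str
    corrected: str
    edit_distance: int
    position: int  # token index within the text

    def __post_init__(self) -> None:
        if self.edit_distance < 0 or self.edit_distance > MAX_EDIT_DISTANCE:
            raise ValueError("edit_distance outside allowed range")


def _levenshtein(a: str, b: str, k: int) -> int:
    """Bounded edit distance; -1 when greater than ``k``."""
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def correct_token(
    token: str, lexicon: Lexicon, max_edit: int = MAX_EDIT_DISTANCE
) -> tuple[str, Optional[Correction]]:
    """Correct a single token against the lexicon + general vocabulary.

    Returns the (possibly unchanged) token and a :class:`Correction`
    when a change was made.  Idempotent: corrected output is always
    in-vocabulary, so a second pass is the identity.
    """
    if not token:
        raise ValueError("empty token")
    low = token.lower()
    if low in lexicon:
        return token, None
    if len(low) < MIN_CORRECTABLE_LENGTH or any(c.isdigit() for c in low):
        return token, None
    best: Optional[str] = None
    best_d = max_edit + 1
    best_medical = False
    for cand in lexicon.candidates_near(low, max_edit):
        d = _levenshtein(low, cand, max_edit)
        if d < 0:
            continue
        medical = lexicon.is_medical_token(cand)
        better = d < best_d or (
            d == best_d
            and (
                (medical and not best_medical)
                or (medical == best_medical and (best is None or cand < best))
            )
        )
        if better:
            best, best_d, best_medical = cand, d, medical
    if best is None:
        return token, None
    return best, Correction(original=low, corrected=best, edit_distance=best_d, position=-1)


def correct_text(text: str, lexicon: Lexicon) -> tuple[str, list[Correction]]:
    """Spell-normalize free text.

    Token count and all non-token characters (whitespace, punctuation)
    are preserved verbatim; corrected tokens are emitted lowercase.
    ``correct_text`` is a fixed point on its own output.
    """
    out: list[str] = []
    corrections: list[Correction] = []
    cursor = 0
    for idx, (surface, start, end) in enumerate(tokenize_with_spans(text)):
        out.append(text[cursor:start])
        corrected, corr = correct_token(surface, lexicon)
        if corr is not None:
            out.append(corrected)
            corrections.append(
                Correction(
                    original=corr.original,
                    corrected=corr.corrected,
                    edit_distance=corr.edit_distance,
                    position=idx,
                )
            )
        else:
            out.append(surface)
        cursor = end
    out.append(text[cursor:])
    return "".join(out), corrections
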