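"""Post data model, line-delimited I/O, and the synthetic OHC corpus.

Real patient forums cannot be redistributed, so evaluation runs on a
synthetic corpus that emulates their structure: one JSONL record per
post (id, source forum, scrape keyword, free text), with a ground-truth
sidecar standing in for manual annotation.

The generator plants, at configurable rates, the phenomena the
pipeline must handle: irrelevant posts (general knowledge / questions
with no drug consumption), misspelled drug and condition names
(single-character substitution or deletion, verified recoverable at
edit distance <= 2), negated drug–indication statements, cross-sentence
mentions linked by an anaphor, hedged "ambiguous" posts, and off-label
versus on-label indication pairings consistent with the bundled
approved-indication map.  About 70% of posts are relevant by default,
matching the proportion observed in manually annotated forum samples.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, TYPE_CHECKING

from .spellnorm import Lexicon, correct_token, tokenize, tokenize_with_spans

if TYPE_CHECKING:  # pragma: no cover
    from .offlabel import LabelMap, OffLabelRecord


class CorpusFormatError(ValueError):
    """A malformed corpus record (message names the offending line)."""


class GeneratorConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Data model


@dataclass(frozen=True)
class Post:
    """One forum post/comment — the pipeline's unit of analysis."""

    post_id: str
    source: str
    drug_keyword: str
    text: str
    created_at: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.post_id:
            raise CorpusFormatError("empty post_id")
        if not self.drug_keyword:
            raise CorpusFormatError(f"post {self.post_id}: empty drug_keyword")
        if not self.text:
            raise CorpusFormatError(f"post {self.post_id}: empty text")


@dataclass(frozen=True)
class PlantedPair:
    drug: str
    indication: str
    negated: bool
    cross_sentence: bool


@dataclass(frozen=True)
class GroundTruth:
    """Planted annotations for one synthetic post."""

    post_id: str
    relevant: bool
    planted_pairs: tuple[PlantedPair, ...] = ()
    off_label_truth: bool = False
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.off_label_truth and not self.relevant:
            raise CorpusFormatError(
                f"post {self.post_id}: off_label_truth requires relevance"
            )


@dataclass
class GeneratorConfig:
    n_posts: int
    frac_relevant: float = 0.7
    frac_off_label: float = 0.2
    misspell_rate: float = 0.1
    negation_rate: float = 0.1
    cross_sentence_rate: float = 0.2
    ambiguous_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_posts < 0:
            raise GeneratorConfigError("n_posts must be >= 0")
        for name in (
            "frac_relevant",
            "frac_off_label",
            "misspell_rate",
            "negation_rate",
            "cross_sentence_rate",
            "ambiguous_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise GeneratorConfigError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# JSONL readers / writers

_POST_FIELDS = ("post_id", "source", "drug_keyword", "text")


def read_posts(path: str | Path) -> list[Post]:
    """Read posts from JSONL; errors name the offending line."""
    posts: list[Post] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            missing = [f for f in _POST_FIELDS if f not in rec or rec[f] in ("", None)]
            if missing:
                raise CorpusFormatError(
                    f"line {lineno}: missing required field(s) {', '.join(missing)}"
                )
            if rec["post_id"] in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate post_id {rec['post_id']!r}")
            seen.add(rec["post_id"])
            posts.append(
                Post(
                    post_id=str(rec["post_id"]),
                    source=str(rec["source"]),
                    drug_keyword=str(rec["drug_keyword"]).lower(),
                    text=str(rec["text"]),
                    created_at=rec.get("created_at"),
                )
            )
    return posts


def write_posts(posts: Iterable[Post], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = asdict(p)
            if rec["created_at"] is None:
                del rec["created_at"]
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    truths: list[GroundTruth] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            truths.append(
                GroundTruth(
                    post_id=rec["post_id"],
                    relevant=bool(rec["relevant"]),
                    planted_pairs=tuple(
                        PlantedPair(**p) for p in rec.get("planted_pairs", [])
                    ),
                    off_label_truth=bool(rec.get("off_label_truth", False)),
                    ambiguous=bool(rec.get("ambiguous", False)),
                )
            )
    return truths


def write_ground_truth(truths: Iterable[GroundTruth], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in truths:
            rec = asdict(t)
            rec["planted_pairs"] = [asdict(p) for p in t.planted_pairs]
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


_RECORD_COLUMNS = (
    "post_id",
    "drug",
    "indication",
    "off_label",
    "confidence",
    "jump_distance",
    "same_sentence",
    "substitution_used",
    "negated",
)


def write_records(
    records: Sequence["OffLabelRecord"], path: str | Path, format: str = "csv"
) -> None:
    """Write off-label records as CSV (RFC 4180) or JSONL.

    Column order is fixed; a read back with :func:`read_records`
    returns identical records.
    """
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_RECORD_COLUMNS, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            for r in records:
                writer.writerow(asdict(r))
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(asdict(r), sort_keys=True) + "\n")


def read_records(path: str | Path, format: str = "csv") -> list["OffLabelRecord"]:
    from .offlabel import OffLabelRecord

    def _build(rec: dict) -> OffLabelRecord:
        return OffLabelRecord(
            post_id=str(rec["post_id"]),
            drug=str(rec["drug"]),
            indication=str(rec["indication"]),
            off_label=_to_bool(rec["off_label"]),
            confidence=str(rec["confidence"]),
            jump_distance=int(rec["jump_distance"]),
            same_sentence=_to_bool(rec["same_sentence"]),
            substitution_used=_to_bool(rec["substitution_used"]),
            negated=_to_bool(rec["negated"]),
        )

    records: list[OffLabelRecord] = []
    if format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            for rec in csv.DictReader(fh):
                records.append(_build(rec))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    records.append(_build(json.loads(line)))
    else:
        raise ValueError(f"unknown format {format!r}")
    return records


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


# ---------------------------------------------------------------------------
# Synthetic corpus generator

FORUMS = ("medhelp", "webmd", "drugs.com", "healthboards")

# Post taxonomy: personal experience (self / family), general knowledge,
# question with no consumption.  Only the first group is "relevant".
RELEVANT_TEMPLATES = (
    "I take {drug} for my {indication} and it really helps.",
    "My doctor prescribed {drug} for {indication} last year.",
    "I have been taking {drug} for {indication} since last spring.",
    "My mother takes {drug} for her {indication} and she feels better.",
    "I was given {drug} for {indication} after my appointment.",
    "My doctor suggested {drug} to treat my {indication} and it worked.",
)

NEGATED_TEMPLATES = (
    "My doctor never prescribed {drug} for my {indication}.",
    "I do not take {drug} for {indication} anymore.",
    "I was not given {drug} for my {indication} at the clinic.",
)

CROSS_SENTENCE_TEMPLATES = (
    "My doctor prescribed {drug} last month. It helps with my {indication} a lot.",
    "I started {drug} a few weeks ago. The medication works for my {indication}.",
)

AMBIGUOUS_TEMPLATES = (
    "Someone said {drug} might help with {indication} but my experience was unclear.",
)

IRRELEVANT_TEMPLATES = (
    "Has anyone here tried {drug} before?",
    "What is the usual starting dose of {drug}?",
    "{drug} is a very common prescription medicine in many countries.",
    "Does {drug} interact with grapefruit juice or alcohol?",
    "My local pharmacy was out of {drug} again this week.",
)

_STOPWORDS = {
    "i", "my", "me", "the", "a", "an", "and", "or", "for", "with", "to",
    "of", "in", "it", "is", "was", "do", "not", "no", "never", "at",
    "she", "her", "he", "his", "has", "have", "been",
}


def _template_words() -> set[str]:
    words: set[str] = set()
    for group in (
        RELEVANT_TEMPLATES,
        NEGATED_TEMPLATES,
        CROSS_SENTENCE_TEMPLATES,
        AMBIGUOUS_TEMPLATES,
        IRRELEVANT_TEMPLATES,
    ):
        for t in group:
            words.update(tokenize(t.replace("{drug}", " ").replace("{indication}", " ")))
    return words


def _misspell(
    text: str, rng: random.Random, lexicon: Lexicon, drug_surface: str
) -> str:
    """Corrupt one token with a single-character substitution or
    deletion, never at the first character, only when the corrector
    provably recovers the original."""
    spans = tokenize_with_spans(text)
    sentence_initial = {0}
    for i in range(1, len(spans)):
        gap = text[spans[i - 1][2] : spans[i][1]]
        if any(c in ".!?" for c in gap):
            sentence_initial.add(i)
    eligible = [
        (i, s, a, b)
        for i, (s, a, b) in enumerate(spans)
        if len(s) >= 4
        and s.isalpha()
        and s.lower() not in _STOPWORDS
        and i not in sentence_initial
    ]
    if not eligible:
        return text
    # bias toward the drug token: misspelled drug names are the case
    # spelling correction exists to recover
    drug_hits = [e for e in eligible if e[1].lower() == drug_surface.lower()]
    if drug_hits and rng.random() < 0.5:
        pool = drug_hits
    else:
        pool = eligible
    rng.shuffle(pool)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for _, surface, start, end in pool:
        low = surface.lower()
        for _attempt in range(6):
            pos = rng.randrange(1, len(low))
            if rng.random() < 0.5:
                corrupted = low[:pos] + low[pos + 1 :]  # deletion
            else:
                repl = rng.choice(alphabet)
                if repl == low[pos]:
                    continue
                corrupted = low[:pos] + repl + low[pos + 1 :]
            if corrupted in lexicon:
                continue
            recovered, corr = correct_token(corrupted, lexicon)
            if corr is not None and recovered == low:
                return text[:start] + corrupted + text[end:]
    return text


def _on_label_choices(
    drug: str, lexicon: Lexicon, label_map: "LabelMap"
) -> list[str]:
    return sorted(label_map.approved_for(drug) & lexicon.concepts("indication"))


def _off_label_choices(
    drug: str, lexicon: Lexicon, label_map: "LabelMap"
) -> list[str]:
    return sorted(lexicon.concepts("indication") - set(label_map.approved_for(drug)))


def generate_synthetic_corpus(
    config: GeneratorConfig, lexicon: Lexicon, label_map: "LabelMap"
) -> tuple[list[Post], list[GroundTruth]]:
    """Generate a seeded corpus with planted ground truth.

    Deterministic: identical config yields byte-identical posts.  Every
    post has a ground-truth entry; for relevant posts the planted
    indication is approved (on-label) or not (off-label) per the label
    map, and ``off_label_truth`` is true only for non-negated off-label
    pairings.
    """
    rng = random.Random(config.seed)
    drugs = sorted(set(label_map.drugs) & lexicon.concepts("drug"))
    if not drugs:
        raise GeneratorConfigError("no drug is present in both lexicon and label map")
    for d in drugs:
        if not _on_label_choices(d, lexicon, label_map):
            raise GeneratorConfigError(f"no lexicon surface for any approved indication of {d}")
        if config.frac_off_label > 0 and not _off_label_choices(d, lexicon, label_map):
            raise GeneratorConfigError(f"no non-approved indication available for {d}")

    posts: list[Post] = []
    truths: list[GroundTruth] = []
    for i in range(config.n_posts):
        post_id = f"p{i:05d}"
        source = rng.choice(FORUMS)
        drug = rng.choice(drugs)
        relevant = rng.random() < config.frac_relevant
        if not relevant:
            text = rng.choice(IRRELEVANT_TEMPLATES).format(drug=drug)
            truth = GroundTruth(post_id=post_id, relevant=False)
        else:
            off = rng.random() < config.frac_off_label
            concepts = (
                _off_label_choices(drug, lexicon, label_map)
                if off
                else _on_label_choices(drug, lexicon, label_map)
            )
            concept = rng.choice(concepts)
            surface = rng.choice(lexicon.surfaces_for_concept(concept, "indication"))
            ambiguous = rng.random() < config.ambiguous_rate
            negated = (not ambiguous) and rng.random() < config.negation_rate
            cross = (not ambiguous) and (not negated) and rng.random() < config.cross_sentence_rate
            if ambiguous:
                template = rng.choice(AMBIGUOUS_TEMPLATES)
            elif negated:
                template = rng.choice(NEGATED_TEMPLATES)
            elif cross:
                template = rng.choice(CROSS_SENTENCE_TEMPLATES)
            else:
                template = rng.choice(RELEVANT_TEMPLATES)
            text = template.format(drug=drug, indication=surface)
            truth = GroundTruth(
                post_id=post_id,
                relevant=True,
                planted_pairs=(
                    PlantedPair(
                        drug=drug,
                        indication=concept,
                        negated=negated,
                        cross_sentence=cross,
                    ),
                ),
                off_label_truth=off and not negated,
                ambiguous=ambiguous,
            )
        if rng.random() < config.misspell_rate:
            text = _misspell(text, rng, lexicon, drug)
        # sentence-initial drug names keep forum capitalization habits
        if text and text[0].islower():
            text = text[0].upper() + text[1:]
        posts.append(
            Post(post_id=post_id, source=source, drug_keyword=drug, text=text)
        )
        truths.append(truth)
    return posts, truths
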