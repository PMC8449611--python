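"""Dependency-based drug–indication pairing.

Each sentence is parsed into a dependency tree; tokens are nodes and
each (token, head) relation is one undirected edge.  The "jump
distance" between a drug mention and an indication mention is the
shortest-path edge count between their anchor tokens, and a candidate
pair is retained only when that distance is within ``max_jumps``
(default 9, inclusive) — dependencies between far-apart words are
unreliable, so distant pairs are discarded.

When drug and indication sit in different sentences, adjacent sentences
(preceding checked first) are searched for an anaphoric substitution
word ("it", "drug", "medication"); if one is present in the
indication's sentence it is rewritten as the drug and distance is
measured within that sentence.  A pair is marked negated when a
negation cue lies on the drug–indication dependency path or hangs
directly off a path token.

The parser backend is pluggable: any callable producing valid
:class:`ParsedSentence` objects works.  A deterministic rule-based
parser is bundled; it handles the simple subject–verb–object–
prepositional-phrase shape of forum sentences and is used by the
synthetic-corpus tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import networkx as nx

from .entities import EntityMention
from .spellnorm import tokenize

ROOT_SENTINEL = -1

DEFAULT_MAX_JUMPS = 9
DEFAULT_SUBSTITUTION_WORDS = frozenset({"it", "drug", "medication"})
DEFAULT_NEGATION_CUES = frozenset({"not", "never", "no", "without", "n't"})


class ParseError(ValueError):
    """A backend produced an invalid dependency structure."""


@dataclass(frozen=True)
class DepToken:
    index: int
    surface: str
    head_index: int  # ROOT_SENTINEL or self for the root
    dep_label: str = "dep"


@dataclass
class ParsedSentence:
    """A dependency tree over one sentence's tokens.

    Invariants (checked on construction): exactly one root; every head
    is a token index or the root sentinel; the (token, head) edges form
    a tree — n tokens, n-1 edges, connected.
    """

    sentence_index: int
    tokens: list[DepToken]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise ParseError("empty sentence")
        indices = {t.index for t in self.tokens}
        if indices != set(range(n)):
            raise ParseError("token indices must be 0..n-1")
        roots = [t for t in self.tokens if t.head_index in (ROOT_SENTINEL, t.index)]
        if len(roots) != 1:
            raise ParseError(f"expected exactly one root, found {len(roots)}")
        for t in self.tokens:
            if t.head_index not in indices and t.head_index != ROOT_SENTINEL:
                raise ParseError(f"token {t.index} has dangling head {t.head_index}")
        g = nx.Graph()
        g.add_nodes_from(indices)
        g.add_edges_from(
            (t.index, t.head_index)
            for t in self.tokens
            if t.head_index != ROOT_SENTINEL and t.head_index != t.index
        )
        if g.number_of_edges() != n - 1 or not nx.is_connected(g):
            raise ParseError("head assignments do not form a tree")

    @property
    def root(self) -> int:
        for t in self.tokens:
            if t.head_index in (ROOT_SENTINEL, t.index):
                return t.index
        raise ParseError("no root")  # unreachable

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class PairingConfig:
    max_jumps: int = DEFAULT_MAX_JUMPS
    substitution_words: frozenset[str] = DEFAULT_SUBSTITUTION_WORDS
    adjacent_window: int = 1
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES

    def __post_init__(self) -> None:
        if self.max_jumps < 1:
            raise ValueError("max_jumps must be >= 1")
        self.substitution_words = frozenset(w.lower() for w in self.substitution_words)
        self.negation_cues = frozenset(w.lower() for w in self.negation_cues)


@dataclass(frozen=True)
class DrugIndicationPair:
    post_id: str
    drug: EntityMention
    indication: EntityMention
    jump_distance: int
    same_sentence: bool
    substitution_used: bool
    negated: bool

    def __post_init__(self) -> None:
        if self.jump_distance < 0:
            raise ValueError("jump_distance must be non-negative")
        if self.substitution_used and self.same_sentence:
            raise ValueError("substitution implies a cross-sentence pair")


# ---------------------------------------------------------------------------
# Rule-based fixture parser

_AUXILIARIES = {
    "am", "is", "are", "was", "were", "be", "been", "being",
    "do", "does", "did", "have", "has", "had",
    "will", "would", "can", "could", "may", "might", "shall", "should", "must",
}

_VERBS = {
    "take", "takes", "taking", "took", "taken",
    "give", "gives", "giving", "gave", "given",
    "prescribe", "prescribes", "prescribed", "prescribing",
    "use", "uses", "using", "used",
    "work", "works", "worked", "working",
    "help", "helps", "helped", "helping",
    "start", "starts", "started", "starting",
    "stop", "stops", "stopped",
    "try", "tries", "tried", "trying",
    "feel", "feels", "felt",
    "say", "says", "said",
    "hear", "heard", "tell", "told",
    "sold", "sell", "interact", "interacts",
    "suggest", "suggested", "recommend", "recommended",
    "switch", "switched", "manage", "manages", "managed",
    "treat", "treats", "treated", "ease", "eases", "eased",
    "relieve", "relieves", "relieved", "calm", "calms", "calmed",
    "wonder", "wonders", "wondered", "know", "knows", "knew",
}

_PREPOSITIONS = {
    "for", "with", "to", "of", "on", "in", "at", "by", "about",
    "after", "before", "since", "from", "against", "during", "under",
}


def _is_negation(surface: str, cues: frozenset[str]) -> bool:
    low = surface.lower()
    return low in cues or low.endswith("n't")


def parse_dependencies(
    sentence_text: str,
    sentence_index: int = 0,
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES,
) -> ParsedSentence:
    """Deterministic rule-based dependency parse.

    Heuristics: the first non-auxiliary verb is the root (falling back
    to the first auxiliary, then the first token); pre-root tokens
    attach to the root; verbs after the root conjoin to it;
    prepositions attach to the most recent verb and open a right-ward
    chain for their noun phrase; negation cues attach to the nearest
    following verb.  The output always satisfies the tree invariants.
    """
    surfaces = tokenize(sentence_text)
    if not surfaces:
        raise ParseError(f"no tokens in sentence {sentence_text!r}")
    n = len(surfaces)
    lows = surfaces  # tokenize already lowercases

    root = None
    for i, w in enumerate(lows):
        if w in _VERBS:
            root = i
            break
    if root is None:
        for i, w in enumerate(lows):
            if w in _AUXILIARIES:
                root = i
                break
    if root is None:
        root = 0

    heads = [ROOT_SENTINEL] * n
    labels = ["dep"] * n
    labels[root] = "root"

    def next_verb_after(i: int) -> Optional[int]:
        for j in range(i + 1, n):
            if lows[j] in _VERBS:
                return j
        return None

    # tokens before the root
    for i in range(root):
        if _is_negation(lows[i], negation_cues):
            tgt = next_verb_after(i)
            heads[i] = tgt if tgt is not None else root
            labels[i] = "neg"
        else:
            heads[i] = root
            labels[i] = "aux" if lows[i] in _AUXILIARIES else "nsubj"

    cur_verb = root
    chain_prev: Optional[int] = None
    for i in range(root + 1, n):
        w = lows[i]
        if w in _VERBS:
            heads[i] = root
            labels[i] = "conj"
            cur_verb = i
            chain_prev = None
        elif w in _AUXILIARIES:
            heads[i] = cur_verb
            labels[i] = "aux"
        elif _is_negation(w, negation_cues):
            tgt = next_verb_after(i)
            heads[i] = tgt if tgt is not None else cur_verb
            labels[i] = "neg"
        elif w in _PREPOSITIONS:
            heads[i] = cur_verb
            labels[i] = "prep"
            chain_prev = i
        else:
            if chain_prev is not None:
                heads[i] = chain_prev
                labels[i] = "pobj"
                chain_prev = i
            else:
                heads[i] = cur_verb
                labels[i] = "obj"

    tokens = [
        DepToken(index=i, surface=surfaces[i], head_index=heads[i], dep_label=labels[i])
        for i in range(n)
    ]
    return ParsedSentence(sentence_index=sentence_index, tokens=tokens)


ParserBackend = Callable[[str, int], ParsedSentence]


def parse_post(
    sentences: Sequence[str],
    backend: Optional[ParserBackend] = None,
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES,
) -> list[ParsedSentence]:
    """Parse a post's sentences with the bundled parser or a backend."""
    parsed = []
    for i, s in enumerate(sentences):
        if backend is not None:
            ps = backend(s, i)
            if not isinstance(ps, ParsedSentence):
                raise ParseError(f"backend returned invalid parse for sentence {i}")
        else:
            ps = parse_dependencies(s, i, negation_cues)
        parsed.append(ps)
    return parsed


def to_conllu(ps: ParsedSentence) -> str:
    """CoNLL-U-style TSV (index, surface, head, label) for fixtures and
    debugging; head index is -1 for the root."""
    lines = [
        f"{t.index}\t{t.surface}\t{t.head_index if t.head_index != t.index else ROOT_SENTINEL}\t{t.dep_label}"
        for t in ps.tokens
    ]
    return "\n".join(lines) + "\n"


def from_conllu(text: str, sentence_index: int = 0) -> ParsedSentence:
    tokens = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        idx, surface, head, label = line.split("\t")
        tokens.append(
            DepToken(index=int(idx), surface=surface, head_index=int(head), dep_label=label)
        )
    return ParsedSentence(sentence_index=sentence_index, tokens=tokens)


# ---------------------------------------------------------------------------
# Token graph + jump distance


def build_token_graph(parsed: Sequence[ParsedSentence]) -> nx.Graph:
    """Undirected graph over all tokens; one edge per dependency
    relation; no edges cross sentence boundaries."""
    g = nx.Graph()
    for ps in parsed:
        for t in ps.tokens:
            g.add_node((ps.sentence_index, t.index))
        for t in ps.tokens:
            if t.head_index not in (ROOT_SENTINEL, t.index):
                g.add_edge((ps.sentence_index, t.index), (ps.sentence_index, t.head_index))
    return g


def jump_distance(graph: nx.Graph, a, b) -> Optional[int]:
    """Shortest-path edge count between two tokens; None if unreachable."""
    if a not in graph or b not in graph:
        raise KeyError(f"token {a if a not in graph else b} not in graph")
    try:
        return nx.shortest_path_length(graph, a, b)
    except nx.NetworkXNoPath:
        return None


def mention_anchor(ps: ParsedSentence, mention: EntityMention) -> int:
    """Anchor token of a (possibly multi-token) mention: the token in
    the span whose head lies outside the span (its syntactic head)."""
    start, end = mention.token_span
    span = set(range(start, end))
    for i in range(start, end):
        h = ps.tokens[i].head_index
        if h == ROOT_SENTINEL or h == i or h not in span:
            return i
    return start


# ---------------------------------------------------------------------------
# Cross-sentence substitution


@dataclass(frozen=True)
class CrossSentenceLink:
    rewritten: ParsedSentence
    substitution_index: int  # token index of the substituted word
    jump_distance: int


def resolve_cross_sentence(
    parsed: Sequence[ParsedSentence],
    drug: EntityMention,
    indication: EntityMention,
    cfg: PairingConfig,
) -> Optional[CrossSentenceLink]:
    """Link a drug and an indication from different, adjacent sentences.

    The indication's sentence is scanned (reading order) for a
    substitution word; the first one found is rewritten as the drug
    surface and the jump distance is measured inside that rewritten
    sentence.  Returns None when the sentences are farther apart than
    ``adjacent_window`` or no substitution word exists.
    """
    if drug.sentence_index == indication.sentence_index:
        raise ValueError("mentions are in the same sentence")
    if abs(drug.sentence_index - indication.sentence_index) > cfg.adjacent_window:
        return None
    by_index = {ps.sentence_index: ps for ps in parsed}
    ind_sent = by_index[indication.sentence_index]
    sub_idx = None
    for t in ind_sent.tokens:
        if t.surface.lower() in cfg.substitution_words:
            sub_idx = t.index
            break
    if sub_idx is None:
        return None
    rewritten = ParsedSentence(
        sentence_index=ind_sent.sentence_index,
        tokens=[
            replace(t, surface=drug.surface) if t.index == sub_idx else t
            for t in ind_sent.tokens
        ],
    )
    g = build_token_graph([rewritten])
    anchor = mention_anchor(rewritten, indication)
    d = jump_distance(g, (rewritten.sentence_index, sub_idx), (rewritten.sentence_index, anchor))
    if d is None:
        return None
    return CrossSentenceLink(rewritten=rewritten, substitution_index=sub_idx, jump_distance=d)


# ---------------------------------------------------------------------------
# Negation


def detect_negation(
    ps: ParsedSentence, drug_token: int, indication_token: int, cfg: PairingConfig
) -> bool:
    """True iff a negation cue is on the drug–indication dependency
    path or is a direct dependent of a path token."""
    g = build_token_graph([ps])
    key = lambda i: (ps.sentence_index, i)
    try:
        path = nx.shortest_path(g, key(drug_token), key(indication_token))
    except nx.NetworkXNoPath:
        return False
    path_tokens = {i for (_, i) in path}
    for t in ps.tokens:
        if not _is_negation(t.surface, cfg.negation_cues):
            continue
        if t.index in path_tokens:
            return True
        if t.head_index in path_tokens and t.head_index not in (ROOT_SENTINEL, t.index):
            return True
    return False


# ---------------------------------------------------------------------------
# Pair extraction


def extract_pairs(
    post_id: str,
    drug_concept: str,
    mentions: Sequence[EntityMention],
    parsed: Sequence[ParsedSentence],
    cfg: PairingConfig | None = None,
) -> list[DrugIndicationPair]:
    """Evaluate every (drug, indication) mention combination of a post.

    Only drug mentions of ``drug_concept`` (the post's scrape keyword)
    participate.  Same-sentence distances are measured directly;
    cross-sentence candidates go through the substitution rule.  Pairs
    with distance <= ``max_jumps`` are retained (distance exactly at
    the threshold is kept) and each carries a negation flag.
    """
    cfg = cfg or PairingConfig()
    by_index = {ps.sentence_index: ps for ps in parsed}
    drugs = [m for m in mentions if m.category == "drug" and m.concept_id == drug_concept]
    indications = [m for m in mentions if m.category == "indication"]
    if not drugs or not indications:
        return []
    graph = build_token_graph(parsed)
    pairs: list[DrugIndicationPair] = []
    for dm in drugs:
        for im in indications:
            if dm.sentence_index == im.sentence_index:
                ps = by_index[dm.sentence_index]
                a = mention_anchor(ps, dm)
                b = mention_anchor(ps, im)
                d = jump_distance(
                    graph, (dm.sentence_index, a), (im.sentence_index, b)
                )
                if d is None or d > cfg.max_jumps:
                    continue
                pairs.append(
                    DrugIndicationPair(
                        post_id=post_id,
                        drug=dm,
                        indication=im,
                        jump_distance=d,
                        same_sentence=True,
                        substitution_used=False,
                        negated=detect_negation(ps, a, b, cfg),
                    )
                )
            else:
                link = resolve_cross_sentence(parsed, dm, im, cfg)
                if link is None or link.jump_distance > cfg.max_jumps:
                    continue
                anchor = mention_anchor(link.rewritten, im)
                pairs.append(
                    DrugIndicationPair(
                        post_id=post_id,
                        drug=dm,
                        indication=im,
                        jump_distance=link.jump_distance,
                        same_sentence=False,
                        substitution_used=True,
                        negated=detect_negation(
                            link.rewritten, link.substitution_index, anchor, cfg
                        ),
                    )
                )
    return pairs
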