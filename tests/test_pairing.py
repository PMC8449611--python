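from collections import deque

import pytest
from hypothesis import given, settings, strategies as st

from ohcmine.entities import EntityMention
from ohcmine.pairing import (
    DepToken,
    PairingConfig,
    ParseError,
    ParsedSentence,
    ROOT_SENTINEL,
    build_token_graph,
    detect_negation,
    extract_pairs,
    jump_distance,
    mention_anchor,
    parse_dependencies,
    parse_post,
    resolve_cross_sentence,
)


def bfs_distance(edges, n, a, b):
    """Independent breadth-first-search oracle over an edge list."""
    adj = {i: [] for i in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen = {a: 0}
    q = deque([a])
    while q:
        u = q.popleft()
        if u == b:
            return seen[u]
        for w in adj[u]:
            if w not in seen:
                seen[w] = seen[u] + 1
                q.append(w)
    return None


def chain_sentence(n, sentence_index=0, surfaces=None):
    """A path-graph tree: token i hangs off token i-1."""
    toks = [
        DepToken(
            index=i,
            surface=(surfaces[i] if surfaces else f"w{i}"),
            head_index=(ROOT_SENTINEL if i == 0 else i - 1),
        )
        for i in range(n)
    ]
    return ParsedSentence(sentence_index=sentence_index, tokens=toks)


def random_tree(heads):
    """heads[i] in [0, i) for i >= 1 — a random recursive tree."""
    n = len(heads) + 1
    toks = [DepToken(index=0, surface="w0", head_index=ROOT_SENTINEL)]
    toks += [
        DepToken(index=i, surface=f"w{i}", head_index=heads[i - 1])
        for i in range(1, n)
    ]
    return ParsedSentence(sentence_index=0, tokens=toks)


def mention(concept, category, sent=0, span=(0, 1), surface=None):
    return EntityMention(
        post_id="p", sentence_index=sent, token_span=span,
        surface=surface or concept, category=category, concept_id=concept,
    )


class TestParsedSentenceInvariants:
    def test_single_token_is_root_with_no_edges(self):
        ps = parse_dependencies("hello")
        assert ps.root == 0
        assert build_token_graph([ps]).number_of_edges() == 0

    def test_fixture_parse_matches_expected_heads(self):
        ps = parse_dependencies("I take gabapentin for pain")
        heads = {t.surface: t.head_index for t in ps.tokens}
        surfaces = [t.surface for t in ps.tokens]
        assert surfaces == ["i", "take", "gabapentin", "for", "pain"]
        assert ps.root == 1  # "take"
        assert heads["i"] == 1
        assert heads["gabapentin"] == 1
        assert heads["for"] == 1
        assert heads["pain"] == 3

    def test_cyclic_heads_rejected(self):
        toks = [
            DepToken(index=0, surface="a", head_index=1),
            DepToken(index=1, surface="b", head_index=0),
            DepToken(index=2, surface="c", head_index=ROOT_SENTINEL),
        ]
        with pytest.raises(ParseError):
            ParsedSentence(sentence_index=0, tokens=toks)

    def test_two_roots_rejected(self):
        toks = [
            DepToken(index=0, surface="a", head_index=ROOT_SENTINEL),
            DepToken(index=1, surface="b", head_index=ROOT_SENTINEL),
        ]
        with pytest.raises(ParseError):
            ParsedSentence(sentence_index=0, tokens=toks)

    def test_empty_sentence_rejected(self):
        with pytest.raises(ParseError):
            parse_dependencies("  ...  ")


class TestTokenGraph:
    def test_tree_size(self):
        ps = parse_dependencies("My doctor prescribed quetiapine last month")
        g = build_token_graph([ps])
        assert g.number_of_nodes() == 6 and g.number_of_edges() == 5

    def test_sentences_are_separate_components(self):
        parsed = parse_post(["I take gabapentin.", "It works."])
        g = build_token_graph(parsed)
        import networkx as nx

        assert nx.number_connected_components(g) == 2

    def test_root_degree_in_fixture(self):
        ps = parse_dependencies("I take gabapentin for pain")
        g = build_token_graph([ps])
        assert g.degree((0, 1)) == 3  # "take": i, gabapentin, for


class TestJumpDistance:
    def test_zero_iff_same_token(self):
        ps = parse_dependencies("I take gabapentin for pain")
        g = build_token_graph([ps])
        assert jump_distance(g, (0, 2), (0, 2)) == 0

    def test_fixture_drug_to_indication_is_three(self):
        # gabapentin - take - for - pain
        ps = parse_dependencies("I take gabapentin for pain")
        g = build_token_graph([ps])
        assert jump_distance(g, (0, 2), (0, 4)) == 3

    def test_cross_sentence_unreachable(self):
        parsed = parse_post(["I take gabapentin.", "It works."])
        g = build_token_graph(parsed)
        assert jump_distance(g, (0, 0), (1, 0)) is None

    def test_unknown_node_errors(self):
        g = build_token_graph([parse_dependencies("hello there")])
        with pytest.raises(KeyError):
            jump_distance(g, (0, 0), (9, 9))

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_bfs_oracle_on_random_trees(self, data):
        n = data.draw(st.integers(min_value=2, max_value=50))
        heads = [data.draw(st.integers(min_value=0, max_value=i - 1)) for i in range(1, n)]
        ps = random_tree(heads)
        g = build_token_graph([ps])
        edges = [(i, h) for i, h in enumerate(heads, start=1)]
        a = data.draw(st.integers(min_value=0, max_value=n - 1))
        b = data.draw(st.integers(min_value=0, max_value=n - 1))
        assert jump_distance(g, (0, a), (0, b)) == bfs_distance(edges, n, a, b)

    @settings(max_examples=50, derandomize=True)
    @given(st.data())
    def test_symmetry_and_triangle_inequality(self, data):
        n = data.draw(st.integers(min_value=3, max_value=30))
        heads = [data.draw(st.integers(min_value=0, max_value=i - 1)) for i in range(1, n)]
        g = build_token_graph([random_tree(heads)])
        a, b, c = (data.draw(st.integers(min_value=0, max_value=n - 1)) for _ in range(3))
        dab = jump_distance(g, (0, a), (0, b))
        assert dab == jump_distance(g, (0, b), (0, a))
        assert dab <= jump_distance(g, (0, a), (0, c)) + jump_distance(g, (0, c), (0, b))


def test_conllu_round_trip():
    from ohcmine.pairing import from_conllu, to_conllu

    ps = parse_dependencies("I was not given quetiapine for anxiety")
    assert from_conllu(to_conllu(ps)) == ps


class TestCrossSentence:
    def test_substitution_links_adjacent_sentences(self):
        parsed = parse_post(
            ["My doctor prescribed quetiapine.", "It works for my insomnia."]
        )
        drug = mention("quetiapine", "drug", sent=0, span=(3, 4))
        ind = mention("sleep_disorder_insomnia", "indication", sent=1, span=(4, 5),
                      surface="insomnia")
        link = resolve_cross_sentence(parsed, drug, ind, PairingConfig())
        assert link is not None
        assert link.substitution_index == 0  # "it"
        # it - works - for - my - insomnia
        assert link.jump_distance == 4
        assert link.rewritten.tokens[0].surface == "quetiapine"

    def test_no_substitute_word_means_no_pair(self):
        parsed = parse_post(
            ["My doctor prescribed quetiapine.", "My insomnia got worse."]
        )
        drug = mention("quetiapine", "drug", sent=0, span=(3, 4))
        ind = mention("sleep_disorder_insomnia", "indication", sent=1, span=(1, 2),
                      surface="insomnia")
        assert resolve_cross_sentence(parsed, drug, ind, PairingConfig()) is None

    def test_window_bound(self):
        parsed = parse_post(
            ["My doctor prescribed quetiapine.", "Nothing here.", "It works for my insomnia."]
        )
        drug = mention("quetiapine", "drug", sent=0, span=(3, 4))
        ind = mention("sleep_disorder_insomnia", "indication", sent=2, span=(4, 5),
                      surface="insomnia")
        assert resolve_cross_sentence(parsed, drug, ind, PairingConfig()) is None


class TestNegation:
    def test_cue_attached_to_path_verb(self):
        ps = parse_dependencies("I was not given quetiapine for anxiety")
        # quetiapine=4, anxiety=6; "not" hangs off "given" which is on the path
        assert detect_negation(ps, 4, 6, PairingConfig()) is True

    def test_no_cue_no_negation(self):
        ps = parse_dependencies("I take gabapentin for pain")
        assert detect_negation(ps, 2, 4, PairingConfig()) is False

    def test_cue_in_other_sentence_does_not_leak(self):
        parsed = parse_post(["I do not like winter.", "I take gabapentin for pain."])
        assert detect_negation(parsed[1], 2, 4, PairingConfig()) is False


class TestExtractPairs:
    def test_fixture_pair_retained_with_distance(self):
        parsed = parse_post(["I take gabapentin for pain"])
        ms = [
            mention("gabapentin", "drug", span=(2, 3)),
            mention("pain", "indication", span=(4, 5)),
        ]
        pairs = extract_pairs("p", "gabapentin", ms, parsed)
        assert len(pairs) == 1
        assert pairs[0].jump_distance == 3
        assert pairs[0].same_sentence and not pairs[0].negated

    @pytest.mark.parametrize("distance,retained", [(9, True), (10, False)])
    def test_threshold_boundary_inclusive_at_nine(self, distance, retained):
        ps = chain_sentence(distance + 1)
        ms = [
            mention("gabapentin", "drug", span=(0, 1)),
            mention("pain", "indication", span=(distance, distance + 1)),
        ]
        pairs = extract_pairs("p", "gabapentin", ms, [ps])
        assert bool(pairs) is retained

    def test_no_drug_mention_gives_empty(self):
        parsed = parse_post(["My pain is bad"])
        ms = [mention("pain", "indication", span=(1, 2))]
        assert extract_pairs("p", "gabapentin", ms, parsed) == []

    def test_other_drugs_do_not_participate(self):
        parsed = parse_post(["I take lorazepam for pain"])
        ms = [
            mention("lorazepam", "drug", span=(2, 3)),
            mention("pain", "indication", span=(4, 5)),
        ]
        assert extract_pairs("p", "gabapentin", ms, parsed) == []

    def test_retention_monotone_in_max_jumps(self):
        for n in (5, 9, 12, 15):
            ps = chain_sentence(n + 1)
            ms = [
                mention("d", "drug", span=(0, 1)),
                mention("i", "indication", span=(n, n + 1)),
            ]
            kept = {
                mj: len(extract_pairs("p", "d", ms, [ps], PairingConfig(max_jumps=mj)))
                for mj in (1, 5, 9, 20)
            }
            vals = [kept[k] for k in sorted(kept)]
            assert vals == sorted(vals)

    def test_multi_token_mention_anchored_at_head(self):
        parsed = parse_post(["I take gabapentin for nerve pain"])
        ps = parsed[0]
        m = mention("neuropathic_pain", "indication", span=(4, 6), surface="nerve pain")
        anchor = mention_anchor(ps, m)
        # "nerve" attaches to "for" (outside span); "pain" chains inside
        assert anchor == 4
        pairs = extract_pairs(
            "p", "gabapentin",
            [mention("gabapentin", "drug", span=(2, 3)), m],
            parsed,
        )
        assert pairs[0].jump_distance == 3  # gabapentin-take-for-nerve

    def test_cross_sentence_pair_marked_low_confidence_evidence(self):
        parsed = parse_post(
            ["My doctor prescribed quetiapine.", "It works for my insomnia."]
        )
        ms = [
            mention("quetiapine", "drug", sent=0, span=(3, 4)),
            mention("sleep_disorder_insomnia", "indication", sent=1, span=(4, 5),
                    surface="insomnia"),
        ]
        pairs = extract_pairs("p", "quetiapine", ms, parsed)
        assert len(pairs) == 1
        assert pairs[0].substitution_used and not pairs[0].same_sentence
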