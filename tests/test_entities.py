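import numpy as np
import pytest

from ohcmine.entities import (
    EmbeddingTable,
    EntityFilterConfig,
    EntityMention,
    cosine_similarity,
    filter_nonmedical,
    recognize_entities,
    split_sentences,
    train_embeddings,
)


class TestSentenceSplitter:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("", []),
            ("One sentence only", ["One sentence only"]),
            ("First here. Second there.", ["First here.", "Second there."]),
            ("Is it so? Yes!", ["Is it so?", "Yes!"]),
            # lowercase after the period: not a boundary
            ("Approx. 5 mg daily.", ["Approx. 5 mg daily."]),
        ],
    )
    def test_splitting(self, text, expected):
        assert split_sentences(text) == expected


class TestRecognizeEntities:
    def test_empty_text(self, tiny_lexicon):
        assert recognize_entities("", tiny_lexicon) == []

    def test_longest_match_wins(self, tiny_lexicon):
        ms = recognize_entities("I take gabapentin for nerve pain", tiny_lexicon)
        assert [(m.surface, m.category) for m in ms] == [
            ("gabapentin", "drug"),
            ("nerve pain", "indication"),
        ]
        assert ms[1].concept_id == "neuropathic_pain"  # not bare "pain"

    def test_repeated_mentions_have_disjoint_spans(self, tiny_lexicon):
        ms = recognize_entities("pain pain", tiny_lexicon)
        assert len(ms) == 2
        assert ms[0].token_span == (0, 1) and ms[1].token_span == (1, 2)

    def test_sentence_index_assignment(self, tiny_lexicon):
        ms = recognize_entities(
            "My doctor prescribed quetiapine. It works for my insomnia.", tiny_lexicon
        )
        assert [(m.concept_id, m.sentence_index) for m in ms] == [
            ("quetiapine", 0),
            ("sleep_disorder_insomnia", 1),
        ]

    def test_planted_mentions_fully_recovered(self, small_corpus, lexicon):
        """Exact-coverage lexicon: every planted drug and indication is found."""
        posts, truths = small_corpus
        tb = {t.post_id: t for t in truths}
        for p in posts:
            t = tb[p.post_id]
            if not t.planted_pairs or "'" in p.text:
                continue
            ms = recognize_entities(p.text, lexicon, p.post_id)
            concepts = {m.concept_id for m in ms}
            for pair in t.planted_pairs:
                # misspelled surfaces are recovered only after spellnorm;
                # this corpus uses the default 10% misspell rate, so check
                # the clean posts only
                from ohcmine.spellnorm import correct_text

                corrected, _ = correct_text(p.text, lexicon)
                concepts_after = {
                    m.concept_id for m in recognize_entities(corrected, lexicon)
                }
                assert pair.drug in concepts_after
                assert pair.indication in concepts_after


def test_mentions_jsonl_round_trip(tmp_path, tiny_lexicon):
    from ohcmine.entities import read_mentions, write_mentions

    ms = recognize_entities("I take gabapentin for nerve pain", tiny_lexicon, "p1")
    path = tmp_path / "mentions.jsonl"
    write_mentions(ms, path)
    assert read_mentions(path) == ms


class TestCosine:
    @pytest.mark.parametrize(
        "u,v,expected",
        [((1, 0), (0, 1), 0.0), ((2, 0), (1, 0), 1.0), ((1, 0), (-1, 0), -1.0)],
    )
    def test_reference_values(self, u, v, expected):
        assert cosine_similarity(np.array(u, float), np.array(v, float)) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            cosine_similarity(np.ones(2), np.ones(3))


class TestTrainEmbeddings:
    def _corpus(self):
        # drugA and condA always co-occur; noiseZ shares no sentence with drugA
        sents = []
        for _ in range(20):
            sents.append(["druga", "helps", "conda", "daily"])
            sents.append(["noisez", "random", "stuff", "here"])
        return sents

    def test_determinism(self):
        c = self._corpus()
        a = train_embeddings(c, d=16, seed=3)
        b = train_embeddings(c, d=16, seed=3)
        assert sorted(a.vectors) == sorted(b.vectors)
        for tok in a.vectors:
            np.testing.assert_array_equal(a[tok], b[tok])

    def test_dimension_respected(self):
        table = train_embeddings(self._corpus(), d=8, seed=0)
        assert all(v.shape == (8,) for v in table.vectors.values())

    def test_cooccurrence_drives_similarity(self):
        table = train_embeddings(self._corpus(), d=16, seed=1)
        close = cosine_similarity(table["druga"], table["conda"])
        far = cosine_similarity(table["druga"], table["noisez"])
        assert close > far
        assert close > 0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_embeddings([], d=8)

    def test_save_load_round_trip(self, tmp_path):
        table = train_embeddings(self._corpus(), d=8, seed=0)
        path = tmp_path / "vectors.txt"
        table.save(path)
        back = EmbeddingTable.load(path)
        assert back.dimension == 8
        for tok in table.vectors:
            np.testing.assert_allclose(back[tok], table[tok], atol=1e-6)


class TestFilterNonmedical:
    def _mention(self, surface, concept=None):
        return EntityMention(
            post_id="p", sentence_index=0, token_span=(0, 1),
            surface=surface, category="indication", concept_id=concept or surface,
        )

    def _table(self, vectors):
        return EmbeddingTable(
            vectors={k: np.asarray(v, float) for k, v in vectors.items()},
            dimension=2, window=5, min_count=1, seed=0,
        )

    def test_same_direction_retained(self):
        table = self._table({"gabapentin": (1, 0), "pain": (1, 0)})
        ms = [self._mention("pain")]
        assert filter_nonmedical("gabapentin", ms, table) == ms

    def test_negative_cosine_dropped(self):
        # cosine((1,0), (-1,0.1)) = -1/sqrt(1.01) < 0
        table = self._table({"gabapentin": (1, 0), "happy": (-1, 0.1)})
        assert filter_nonmedical("gabapentin", [self._mention("happy")], table) == []

    def test_out_of_vocabulary_mention_retained(self):
        table = self._table({"gabapentin": (1, 0)})
        ms = [self._mention("glarbles")]
        assert filter_nonmedical("gabapentin", ms, table) == ms

    def test_missing_drug_errors(self):
        table = self._table({"pain": (1, 0)})
        with pytest.raises(KeyError):
            filter_nonmedical("gabapentin", [self._mention("pain")], table)

    def test_output_is_ordered_subset(self):
        table = self._table(
            {"gabapentin": (1, 0), "pain": (1, 1), "happy": (-1, 0.1), "sleep": (0, 1)}
        )
        ms = [self._mention(s) for s in ("pain", "happy", "sleep")]
        kept = filter_nonmedical("gabapentin", ms, table)
        assert kept == [ms[0], ms[2]]
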