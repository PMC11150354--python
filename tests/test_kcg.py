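"""Keyword correlation graphs: topic model, keyword scoring, sentence
assignment and edge-weight oracles."""

import numpy as np
import pytest

from dialograph.embeddings import EncoderSpec, make_encoder
from dialograph.io import pair_questions_answers, segment_turns
from dialograph.kcg import (assign_sentences, build_kcg, build_kcg_mv,
                            fit_topic_model, score_keywords)
from dialograph.synth import GenParams, generate_corpus

VOCAB_A = ["anchor", "boat", "cargo", "dock", "engine",
           "fleet", "gulf", "harbor", "island", "jetty"]
VOCAB_B = ["kettle", "ladle", "mixer", "noodle", "oven",
           "pantry", "quiche", "recipe", "skillet", "tureen"]


@pytest.fixture(scope="module")
def two_topic_corpus():
    rng = np.random.default_rng(0)
    sents = []
    for vocab in (VOCAB_A, VOCAB_B):
        for _ in range(20):
            sents.append(" ".join(rng.choice(vocab, size=5)))
    return sents


@pytest.fixture(scope="module")
def two_topic_model(two_topic_corpus):
    return fit_topic_model(two_topic_corpus, n_topics=2, seed=0)


@pytest.fixture(scope="module")
def encoder32():
    return make_encoder(EncoderSpec(dim=32))


class TestTopicModel:
    def test_disjoint_vocabularies_separate_into_topics(self, two_topic_model):
        for t in range(2):
            top5 = [two_topic_model.vocabulary[i]
                    for i in np.argsort(-two_topic_model.topic_word[t])[:5]]
            in_a = sum(w in VOCAB_A for w in top5)
            assert in_a in (0, 5), f"topic {t} mixes vocabularies: {top5}"

    def test_factors_nonnegative(self, two_topic_model):
        assert (two_topic_model.topic_word >= 0).all()

    def test_deterministic_given_seed(self, two_topic_corpus):
        m1 = fit_topic_model(two_topic_corpus, n_topics=2, seed=3)
        m2 = fit_topic_model(two_topic_corpus, n_topics=2, seed=3)
        assert np.array_equal(m1.topic_word, m2.topic_word)
        assert m1.vocabulary == m2.vocabulary

    def test_too_few_sentences_raises(self):
        with pytest.raises(ValueError):
            fit_topic_model(["boat dock boat", "boat dock"], n_topics=3,
                            stop_words=None, min_df=1)


class TestScoreKeywords:
    def test_topic_a_transcript_gets_topic_a_keywords(self, two_topic_model,
                                                      transcript_factory):
        t = transcript_factory("TP", texts=["anchor boat cargo", "dock engine fleet"])
        kws = score_keywords(t, two_topic_model)
        assert kws, "expected keywords"
        assert all(w in VOCAB_A for w, _ in kws)

    def test_scores_match_brute_force_projection(self, two_topic_model,
                                                 transcript_factory):
        t = transcript_factory("TP", texts=["anchor boat kettle", "cargo oven"])
        kws = dict(score_keywords(t, two_topic_model))
        m = two_topic_model
        term = m.vectorizer.transform([" ".join(t.texts())])
        loading = m.nmf.transform(term)[0]
        for w, s in kws.items():
            idx = m.vocabulary.index(w)
            assert s == pytest.approx(float(loading @ m.topic_word[:, idx]))

    def test_cap_at_transcript_vocabulary(self, two_topic_model, transcript_factory):
        t = transcript_factory("TP", texts=["anchor boat", "cargo"])
        assert len(score_keywords(t, two_topic_model, k=50)) == 3

    def test_no_shared_vocabulary_empty(self, two_topic_model, transcript_factory):
        t = transcript_factory("TP", texts=["zzz yyy", "xxx www"])
        assert score_keywords(t, two_topic_model) == []


class TestAssignSentences:
    def test_containment_prefers_higher_rank(self, transcript_factory, encoder32):
        t = transcript_factory("TP", texts=["anchor cargo trip", "other words"])
        keywords = [("anchor", 3.0), ("boat", 2.0), ("cargo", 1.0)]
        emb = encoder32(t.texts())
        assignment = assign_sentences(t, keywords, emb, keyword_embedder=encoder32)
        assert 0 in assignment["anchor"]

    def test_fallback_is_argmax_cosine(self, transcript_factory, encoder32):
        t = transcript_factory("TP", texts=["no keyword here at all",
                                            "totally different words"])
        keywords = [("anchor", 2.0), ("kettle", 1.0)]
        emb = encoder32(t.texts())
        assignment = assign_sentences(t, keywords, emb, keyword_embedder=encoder32)
        kw_emb = encoder32(["anchor", "kettle"])
        for row, u in enumerate(t.utterances):
            cos = kw_emb @ emb[row]
            expected = ["anchor", "kettle"][int(np.argmax(cos))]
            assert u.index in assignment[expected]

    def test_single_keyword_takes_everything(self, transcript_factory, encoder32):
        t = transcript_factory("TPT")
        assignment = assign_sentences(t, [("anchor", 1.0)], encoder32(t.texts()),
                                      keyword_embedder=encoder32)
        assert assignment["anchor"] == {0, 1, 2}

    def test_partition_property(self, transcript_factory, encoder32):
        t = transcript_factory("TPTPTP")
        keywords = [("anchor", 2.0), ("kettle", 1.0), ("utterance", 0.5)]
        assignment = assign_sentences(t, keywords, encoder32(t.texts()),
                                      keyword_embedder=encoder32)
        all_assigned = sorted(i for s in assignment.values() for i in s)
        assert all_assigned == [0, 1, 2, 3, 4, 5]


class TestBuildKCG:
    def test_identical_singleton_sets_weight_one(self, two_topic_model,
                                                 transcript_factory, encoder32):
        t = transcript_factory("TP", texts=["anchor", "boat"])
        g = build_kcg(t, two_topic_model, encoder32(t.texts()),
                      keyword_embedder=encoder32)
        assert g.n_nodes == 2
        # singleton sets: weight is the plain cosine of the two embeddings
        emb = encoder32(t.texts())
        assert g.edges[(0, 1)] == pytest.approx(float(emb[0] @ emb[1]), abs=1e-9)

    def test_edge_weight_matches_double_loop(self, two_topic_model,
                                             transcript_factory, encoder32):
        texts = ["anchor one", "anchor two", "boat one", "boat two", "boat three"]
        t = transcript_factory("TPTPT", texts=texts)
        emb = encoder32(texts)
        g = build_kcg(t, two_topic_model, emb, keyword_embedder=encoder32)
        node_sets = {g.nodes[i].keyword: sorted(g.nodes[i].sentence_set)
                     for i in range(g.n_nodes)}
        for (i, j), w in g.edges.items():
            rows_i = node_sets[g.nodes[i].keyword]
            rows_j = node_sets[g.nodes[j].keyword]
            acc = [float(emb[a] @ emb[b] /
                         (np.linalg.norm(emb[a]) * np.linalg.norm(emb[b])))
                   for a in rows_i for b in rows_j]
            assert w == pytest.approx(np.mean(acc), abs=1e-9)

    def test_threshold_above_one_kills_all_edges(self, two_topic_model,
                                                 transcript_factory, encoder32):
        t = transcript_factory("TP", texts=["anchor boat", "cargo dock"])
        g = build_kcg(t, two_topic_model, encoder32(t.texts()),
                      kcg_threshold=1.1, keyword_embedder=encoder32)
        assert g.edges == {}

    def test_node_cap_50(self, default_corpus, encoder64):
        from dialograph.training import fit_corpus_topic_models
        train = default_corpus.subset("train")
        model = fit_corpus_topic_models(train, "kcg_baseline", 10)["global"]
        for t in train[:10]:
            g = build_kcg(t, model, encoder64(t.texts()),
                          keyword_embedder=encoder64)
            assert g.n_nodes <= 50


@pytest.fixture(scope="module")
def mv_setup(default_corpus):
    from dialograph.training import fit_corpus_topic_models
    train = default_corpus.subset("train")
    models = fit_corpus_topic_models(train, "kcg_mv", 10)
    return models["therapist"], models["patient"]


class TestKCGMultiView:
    def test_cross_edges_match_exhaustive_oracle(self, mv_setup, default_corpus,
                                                 encoder64):
        model_t, model_p = mv_setup
        for t in default_corpus.subset("train")[:10]:
            emb = encoder64(t.texts())
            pairs = pair_questions_answers(segment_turns(t))
            mv = build_kcg_mv(t, model_t, model_p, emb, pairs,
                              keyword_embedder=encoder64)
            oracle = set()
            for pair in pairs:
                for i, u in enumerate(mv.therapist_kcg.nodes):
                    for j, v in enumerate(mv.patient_kcg.nodes):
                        hit = any(q in u.sentence_set
                                  for q in pair.question_turn.utterance_indices) \
                            and any(a in v.sentence_set
                                    for a in pair.answer_turn.utterance_indices)
                        # edge requires the SAME pair to contribute q and a
                        for q in pair.question_turn.utterance_indices:
                            for a in pair.answer_turn.utterance_indices:
                                if q in u.sentence_set and a in v.sentence_set:
                                    oracle.add((i, j))
            assert mv.cross_edges == oracle

    def test_no_pairs_no_cross_edges(self, mv_setup, default_corpus, encoder64):
        model_t, model_p = mv_setup
        t = default_corpus.subset("train")[0]
        mv = build_kcg_mv(t, model_t, model_p, encoder64(t.texts()), [],
                          keyword_embedder=encoder64)
        assert mv.cross_edges == set()

    def test_sentence_sets_partition_each_view(self, mv_setup, default_corpus,
                                               encoder64):
        from dialograph.io import Speaker
        model_t, model_p = mv_setup
        for t in default_corpus.subset("train")[:10]:
            emb = encoder64(t.texts())
            pairs = pair_questions_answers(segment_turns(t))
            mv = build_kcg_mv(t, model_t, model_p, emb, pairs,
                              keyword_embedder=encoder64)
            t_ids = {u.index for u in t.utterances if u.speaker is Speaker.THERAPIST}
            p_ids = {u.index for u in t.utterances if u.speaker is Speaker.PATIENT}
            for kcg, ids in ((mv.therapist_kcg, t_ids), (mv.patient_kcg, p_ids)):
                assigned = [i for node in kcg.nodes for i in node.sentence_set]
                assert sorted(assigned) == sorted(ids)


def test_marker_keywords_separate_classes(default_corpus, encoder64):
    """Planted marker keywords surface in the top-50 of nearly all positive
    transcripts and almost no negative ones."""
    from dialograph.training import fit_corpus_topic_models
    markers = set(default_corpus.params.marker_keywords)
    train = default_corpus.subset("train")
    model = fit_corpus_topic_models(train, "kcg_baseline", 10)["global"]
    rates = {0: [], 1: []}
    for t in default_corpus.transcripts:
        kws = {w for w, _ in score_keywords(t, model, k=50)}
        rates[t.label].append(bool(kws & markers))
    assert np.mean(rates[1]) >= 0.9
    assert np.mean(rates[0]) <= 0.1
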