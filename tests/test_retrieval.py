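import datetime as dt
import io
import math

import numpy as np
import pytest

from litriage import (
    Document,
    DocumentSet,
    QuerySpec,
    bm25_score,
    boolean_search,
    build_index,
    expand_query,
    read_trec_run,
    search,
    write_trec_run,
)
from litriage.corpus import CorpusError
from litriage.retrieval import DEFAULT_B, DEFAULT_K1


def bruteforce_bm25(docs, terms, pmid, k1=DEFAULT_K1, b=DEFAULT_B):
    """Independent per-document BM25 scorer working from raw token lists."""
    token_lists = {d.pmid: d.text.lower().split() for d in docs}
    n = len(docs)
    avgdl = sum(len(t) for t in token_lists.values()) / n
    dl = len(token_lists[pmid])
    score = 0.0
    for term in dict.fromkeys(t.lower() for t in terms):
        tf = token_lists[pmid].count(term)
        if tf == 0:
            continue
        df = sum(1 for toks in token_lists.values() if term in toks)
        idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
        score += idf * tf * (k1 + 1.0) / (tf + k1 * (1.0 - b + b * dl / avgdl))
    return score


def token_corpus(rng, n_docs, vocab_size, doc_len):
    vocab = [f"t{i}" for i in range(vocab_size)]
    return DocumentSet(
        Document(
            pmid=i + 1,
            title="",
            abstract=" ".join(vocab[int(j)] for j in rng.integers(vocab_size, size=doc_len)),
            pub_date=dt.date(int(rng.integers(1990, 2014)), 1, 1),
        )
        for i in range(n_docs)
    )


class TestIndex:
    def test_single_doc_statistics(self):
        docs = DocumentSet([Document(1, "", "a b b")])
        idx = build_index(docs)
        assert idx.n_docs == 1
        assert idx.df["a"] == 1
        assert idx.postings["b"][1] == 2
        assert idx.avgdl == 3

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_index(DocumentSet())

    def test_duplicate_pmids_rejected_at_corpus_level(self):
        with pytest.raises(CorpusError):
            DocumentSet([Document(1, "a", "x"), Document(1, "b", "y")])

    def test_df_bounded_by_corpus_size(self):
        rng = np.random.default_rng(0)
        idx = build_index(token_corpus(rng, 10, 15, 20))
        assert all(df <= idx.n_docs for df in idx.df.values())

    def test_round_trips_through_dict(self):
        rng = np.random.default_rng(1)
        docs = token_corpus(rng, 5, 10, 12)
        idx = build_index(docs)
        from litriage.retrieval import Index
        again = Index.from_dict(idx.to_dict())
        assert again.df == idx.df
        assert again.postings == idx.postings
        assert again.avgdl == pytest.approx(idx.avgdl)


class TestBm25:
    def test_absent_term_scores_zero(self):
        docs = DocumentSet([Document(1, "", "x y z"), Document(2, "", "u v w")])
        idx = build_index(docs)
        assert bm25_score(idx, ["missing"], 1) == 0.0

    def test_hand_evaluated_two_doc_case(self):
        # N=2, df=1, tf=1, dl=avgdl: idf=ln 2 and the tf factor is exactly 1,
        # so the score is ln 2.
        docs = DocumentSet([Document(1, "", "apple x y"), Document(2, "", "u v w")])
        idx = build_index(docs)
        assert bm25_score(idx, ["apple"], 1) == pytest.approx(math.log(2.0), abs=1e-12)

    def test_repeated_query_terms_count_once(self):
        docs = DocumentSet([Document(1, "", "apple x"), Document(2, "", "u v")])
        idx = build_index(docs)
        assert bm25_score(idx, ["apple", "apple"], 1) == bm25_score(idx, ["apple"], 1)

    def test_unknown_pmid_rejected(self):
        idx = build_index(DocumentSet([Document(1, "", "a")]))
        with pytest.raises(KeyError):
            bm25_score(idx, ["a"], 99)

    def test_matches_bruteforce_on_random_corpora(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            docs = token_corpus(rng, 10, 12, 15)
            idx = build_index(docs)
            terms = [f"t{int(i)}" for i in rng.integers(12, size=3)]
            for doc in docs:
                assert bm25_score(idx, terms, doc.pmid) == pytest.approx(
                    bruteforce_bm25(docs, terms, doc.pmid), abs=1e-9
                )

    def test_monotone_in_term_frequency(self):
        # same document length, one more occurrence of the query term
        low = DocumentSet([Document(1, "", "apple pad pad pad"), Document(2, "", "u v w x")])
        high = DocumentSet([Document(1, "", "apple apple pad pad"), Document(2, "", "u v w x")])
        assert bm25_score(build_index(high), ["apple"], 1) > bm25_score(build_index(low), ["apple"], 1)


class TestQueryExpansion:
    def test_refinement_off_keeps_gene_and_synonyms(self):
        q = QuerySpec(gene="BTK", synonyms=("AGMX1",), axis="PPI")
        assert expand_query(q) == ["btk", "agmx1"]

    def test_ppi_refinement_appends_trigger_keywords(self):
        q = QuerySpec(gene="BTK", axis="PPI", refinement=True)
        assert expand_query(q) == ["btk", "binds", "interacts", "associates"]

    def test_ptm_refinement_appends_phosphorylates(self):
        q = QuerySpec(gene="BTK", axis="PTM", refinement=True)
        assert expand_query(q) == ["btk", "phosphorylates"]

    def test_duplicates_removed_preserving_first_occurrence(self):
        q = QuerySpec(gene="binds", axis="PPI", refinement=True, synonyms=("BINDS",))
        assert expand_query(q) == ["binds", "interacts", "associates"]


class TestSearch:
    def test_term_in_no_document_gives_empty_list(self, small_corpus):
        idx = build_index(small_corpus)
        assert search(idx, QuerySpec(gene="nonexistent")) == []

    def test_higher_tf_ranks_first_at_equal_length(self):
        docs = DocumentSet([
            Document(10, "", "alpha alpha alpha pad"),
            Document(20, "", "alpha pad pad pad"),
        ])
        ranked = search(build_index(docs), QuerySpec(gene="alpha"))
        assert [d.pmid for d in ranked] == [10, 20]

    def test_truncated_to_top_k_with_dense_ranks(self, small_corpus):
        idx = build_index(small_corpus)
        ranked = search(idx, QuerySpec(gene="alpha", top_k=1))
        assert len(ranked) == 1
        assert ranked[0].rank == 1

    def test_scores_non_increasing_and_ranks_dense(self):
        rng = np.random.default_rng(7)
        docs = token_corpus(rng, 15, 10, 20)
        ranked = search(build_index(docs), QuerySpec(gene="t3"))
        assert [d.rank for d in ranked] == list(range(1, len(ranked) + 1))
        scores = [d.engine_score for d in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_deterministic_for_fixed_corpus_and_query(self):
        rng = np.random.default_rng(9)
        docs = token_corpus(rng, 12, 8, 15)
        idx = build_index(docs)
        q = QuerySpec(gene="t1", synonyms=("t2",))
        assert search(idx, q) == search(idx, q)


class TestBooleanSearch:
    def test_and_requires_cooccurrence(self):
        docs = DocumentSet([
            Document(1, "", "alpha beta", dt.date(2001, 1, 1)),
            Document(2, "", "alpha gamma", dt.date(2002, 1, 1)),
            Document(3, "", "beta gamma", dt.date(2003, 1, 1)),
        ])
        idx = build_index(docs)
        q = QuerySpec(gene="alpha", synonyms=("beta",))
        assert [d.pmid for d in boolean_search(idx, q, mode="AND")] == [1]

    def test_or_with_universal_term_returns_all_newest_first(self):
        docs = DocumentSet([
            Document(1, "", "common x", dt.date(2001, 1, 1)),
            Document(2, "", "common y", dt.date(2010, 1, 1)),
            Document(3, "", "common z", dt.date(2005, 1, 1)),
        ])
        ranked = boolean_search(build_index(docs), QuerySpec(gene="common"), mode="OR")
        assert [d.pmid for d in ranked] == [2, 3, 1]

    def test_and_subset_of_or(self):
        rng = np.random.default_rng(5)
        docs = token_corpus(rng, 15, 6, 10)
        idx = build_index(docs)
        q = QuerySpec(gene="t0", synonyms=("t1",))
        and_pmids = {d.pmid for d in boolean_search(idx, q, mode="AND")}
        or_pmids = {d.pmid for d in boolean_search(idx, q, mode="OR")}
        assert and_pmids <= or_pmids


def test_trec_run_round_trip(small_corpus):
    idx = build_index(small_corpus)
    run = {"q0": search(idx, QuerySpec(gene="alpha"))}
    buf = io.StringIO()
    write_trec_run(run, buf)
    again = read_trec_run(io.StringIO(buf.getvalue()))
    assert [d.pmid for d in again["q0"]] == [d.pmid for d in run["q0"]]
    assert [d.rank for d in again["q0"]] == [d.rank for d in run["q0"]]
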