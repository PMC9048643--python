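"""Triplet queries, constraint relaxation and the fused ranking function."""

import dataclasses
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varlit.corpus import (
    Annotation,
    Document,
    Must,
    Should,
    evaluate_clauses,
    index_collection,
)
from varlit.nomenclature import ProteinVariant
from varlit.triage import (
    EntityRef,
    QueryError,
    ScoringConfig,
    TripletQuery,
    build_queries,
    demographic_score,
    keyword_score,
    ne_density_score,
    rank,
    relax_score,
)

CFG = ScoringConfig()
V600E = ProteinVariant("V", 600, "E")


def full_query(**overrides):
    base = dict(
        gene=EntityRef("BRAF", "GENE:BRAF"),
        variant=V600E,
        disease=EntityRef("melanoma", "DIS:MELANOMA"),
    )
    base.update(overrides)
    return TripletQuery(**base)


class TestConfig:
    def test_defaults_are_tuned_values(self):
        assert (CFG.relax_dg, CFG.relax_dv, CFG.relax_gv) == (0.95, 0.07, 0.05)
        assert (CFG.ne_disease, CFG.ne_gene, CFG.ne_drug) == (0.97, 0.51, 0.57)
        assert (CFG.demo_age_weight, CFG.demo_gender_weight) == (0.7, 0.5)
        assert (CFG.demo_match, CFG.demo_unmentioned, CFG.demo_mismatch) == (0.7, 0.4, 0.0)
        assert (CFG.kw_bonus, CFG.kw_penalty) == (0.2, -0.1)
        assert CFG.positive_stems == ("treat", "drug", "therap", "prognos", "surviv")
        assert CFG.negative_stems == ("immuno", "marker", "detect")
        assert (CFG.w_rsv, CFG.w_relax, CFG.w_ne, CFG.w_demo, CFG.w_kw) == (
            1.0, 0.65, 0.1, 0.05, 0.1)

    def test_from_file_overrides(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("w_relax = 0.0\npositive_stems = cure, remiss\n# comment\n")
        cfg = ScoringConfig.from_file(str(p))
        assert cfg.w_relax == 0.0
        assert cfg.positive_stems == ("cure", "remiss")
        assert cfg.relax_dg == 0.95            # unset keys keep defaults

    def test_from_file_rejects_unknown_key(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("bogus = 1\n")
        with pytest.raises(ValueError):
            ScoringConfig.from_file(str(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ScoringConfig(relax_dg=1.5)
        with pytest.raises(ValueError):
            ScoringConfig(kw_penalty=0.2)


class TestBuildQueries:
    def test_full_triplet_yields_four_trees(self):
        full, relaxed = build_queries(full_query())
        assert isinstance(full, Must) and len(full.children) == 3
        assert set(relaxed) == {"dg", "dv", "gv"}

    def test_mode_none_single_variant_child(self):
        full, _ = build_queries(full_query(synonym_mode="none"))
        variant_should = full.children[2]
        assert isinstance(variant_should, Should)
        assert len(variant_should.children) == 1

    def test_two_entity_query_disables_relaxation(self):
        q = TripletQuery(variant=V600E, disease=EntityRef("melanoma"))
        full, relaxed = build_queries(q)
        assert len(full.children) == 2
        assert relaxed == {}

    def test_single_entity_rejected(self):
        with pytest.raises(QueryError):
            build_queries(TripletQuery(gene=EntityRef("BRAF")))


class TestRelaxScore:
    def test_single_tree_top_hit(self):
        relaxed = {"dg": [("d1", 7.0), ("d2", 1.0)]}
        assert relax_score("d1", relaxed, CFG) == pytest.approx(0.95)

    def test_absent_doc_scores_zero(self):
        relaxed = {"dg": [("d1", 7.0), ("d2", 1.0)]}
        assert relax_score("dX", relaxed, CFG) == 0.0

    def test_top_in_all_trees_clips_to_one(self):
        relaxed = {
            "dg": [("d1", 5.0), ("d2", 0.5)],
            "dv": [("d1", 3.0), ("d2", 0.5)],
            "gv": [("d1", 2.0), ("d2", 0.5)],
        }
        # 0.95 + 0.07 + 0.05 = 1.07, clipped
        assert relax_score("d1", relaxed, CFG) == 1.0

    def test_unknown_label_rejected(self):
        with pytest.raises(QueryError):
            relax_score("d1", {"xx": [("d1", 1.0)]}, CFG)


class TestNeDensity:
    def _doc(self, n_disease=0, n_gene=0, n_drug=0):
        anns = (
            [Annotation("DIS:X", "disease", 0, 1, "x")] * n_disease
            + [Annotation("GENE:X", "gene", 0, 1, "x")] * n_gene
            + [Annotation("DRUG:X", "drug", 0, 1, "x")] * n_drug
        )
        return Document("d", body="x", annotations=tuple(anns))

    def test_no_annotations(self):
        assert ne_density_score(self._doc(), CFG) == 0.0

    def test_single_disease_mention(self):
        expected = 0.97 * 0.5 / (0.97 + 0.51 + 0.57)
        assert ne_density_score(self._doc(n_disease=1), CFG) == pytest.approx(expected)
        assert ne_density_score(self._doc(n_disease=1), CFG) == pytest.approx(0.2366, abs=1e-4)

    def test_saturates_toward_one(self):
        assert ne_density_score(self._doc(500, 500, 500), CFG) == pytest.approx(1.0, abs=1e-2)

    def test_monotone_in_counts(self):
        scores = [ne_density_score(self._doc(n_disease=k), CFG) for k in range(5)]
        assert scores == sorted(scores)


class TestDemographics:
    def test_both_match(self):
        q = full_query(age=54, gender="female")
        doc = Document("d", subject_tags=("Middle Aged", "Female"))
        assert demographic_score(q, doc, CFG) == pytest.approx(0.7)
        # (0.7*0.7 + 0.5*0.7) / 1.2 = 0.7

    def test_both_unmentioned(self):
        q = full_query(age=54, gender="female")
        doc = Document("d", subject_tags=())
        assert demographic_score(q, doc, CFG) == pytest.approx(0.4)

    def test_mismatch_zero_bonus(self):
        q = full_query(age=54, gender="female")
        doc = Document("d", subject_tags=("Child", "Male"))
        assert demographic_score(q, doc, CFG) == 0.0

    def test_mixed(self):
        q = full_query(age=54, gender="female")
        doc = Document("d", subject_tags=("middle aged",))   # age match, gender absent
        expected = (0.7 * 0.7 + 0.5 * 0.4) / 1.2
        assert demographic_score(q, doc, CFG) == pytest.approx(expected)

    def test_no_query_demographics(self):
        doc = Document("d", subject_tags=("Female",))
        assert demographic_score(full_query(), doc, CFG) == 0.0

    def test_age_only_normalizes_over_age_weight(self):
        q = full_query(age=30)
        doc = Document("d", subject_tags=("adult",))
        assert demographic_score(q, doc, CFG) == pytest.approx(0.7)

    def test_unknown_gender_rejected(self):
        with pytest.raises(QueryError):
            full_query(gender="other")

    @pytest.mark.parametrize("age, tag", [
        (0, "infant"), (4, "child, preschool"), (9, "child"), (15, "adolescent"),
        (30, "adult"), (54, "middle aged"), (80, "aged"),
    ])
    def test_age_bins(self, age, tag):
        from varlit.triage import age_group
        assert age_group(age) == tag


class TestKeywords:
    def test_counts_per_occurrence(self):
        doc = Document("d", body="Patients treated with treatment and a marker assay")
        # "treated" and "treatment" are positive-stem tokens, "marker" negative
        assert keyword_score(doc, CFG) == pytest.approx(0.3)

    def test_no_keywords(self):
        assert keyword_score(Document("d", body="plain text here"), CFG) == 0.0

    def test_clips_at_minus_one(self):
        doc = Document("d", body=" ".join(["marker"] * 20))
        assert keyword_score(doc, CFG) == -1.0

    def test_prefix_on_stem(self):
        doc = Document("d", body="prognosis prognostic survival immunotherapy detection")
        assert keyword_score(doc, CFG) == pytest.approx(0.2 * 3 - 0.1 * 2)


def _scored_corpus():
    """Small corpus where the full triplet and partial mentions both occur."""
    docs = [
        Document("full1", body="BRAF V600E in melanoma, treated with drugs",
                 pub_date="2020-01-01"),
        Document("full2", body="melanoma with BRAF V600E marker detection",
                 pub_date="2019-01-01"),
        Document("pair_dg", body="BRAF expression in melanoma tissue",
                 pub_date="2021-01-01"),
        Document("foreign", body="BRAF V600E melanoma etude", language="fr",
                 pub_date="2021-06-01"),
        Document("none", body="unrelated housekeeping report", pub_date="2018-01-01"),
    ]
    return index_collection(docs)


class TestRank:
    def test_candidates_include_relaxed_hits(self):
        idx = _scored_corpus()
        hits = rank(full_query(), idx, CFG)
        ids = {h.doc_id for h in hits}
        assert {"full1", "full2", "pair_dg", "foreign"} <= ids
        assert "none" not in ids

    def test_final_is_linear_combination(self):
        idx = _scored_corpus()
        for h in rank(full_query(), idx, CFG):
            recomputed = (CFG.w_rsv * h.rsv_norm + CFG.w_relax * h.relax
                          + CFG.w_ne * h.ne_density + CFG.w_demo * h.demo
                          + CFG.w_kw * h.kw)
            assert abs(h.final - recomputed) < 1e-9

    def test_keyword_difference_separates_ties(self):
        # identical docs except keyword content: 0.1 * (0.3 - 0) = 0.03 apart
        docs = [
            Document("kw", body="BRAF V600E melanoma treated treatment marker"),
            Document("plain", body="BRAF V600E melanoma alpha beta gamma"),
        ]
        idx = index_collection(docs)
        hits = {h.doc_id: h for h in rank(full_query(), idx, CFG)}
        assert hits["kw"].kw == pytest.approx(0.3)
        assert hits["plain"].kw == 0.0
        diff = hits["kw"].final - hits["plain"].final
        expected = (CFG.w_kw * 0.3
                    + (hits["kw"].rsv_norm - hits["plain"].rsv_norm)
                    + CFG.w_relax * (hits["kw"].relax - hits["plain"].relax))
        assert diff == pytest.approx(expected)

    def test_english_tier_precedes_other_regardless_of_score(self):
        idx = _scored_corpus()
        hits = rank(full_query(), idx, CFG)
        tiers = [h.language_tier for h in hits]
        assert tiers == sorted(tiers, key=lambda t: t != "english")
        # the foreign doc mentions the full triplet yet ranks after English docs
        assert hits[-1].doc_id == "foreign"

    def test_empty_candidate_set(self):
        idx = index_collection([Document("d", body="nothing relevant")])
        q = TripletQuery(gene=EntityRef("KRAS"), variant=ProteinVariant("G", 12, "D"),
                         disease=EntityRef("carcinoma"))
        assert rank(q, idx, CFG) == []

    def test_zero_fusion_weights_reduce_to_bm25_order(self, fixture_corpus, fixture_index):
        cfg = ScoringConfig(w_relax=0.0, w_ne=0.0, w_demo=0.0, w_kw=0.0)
        for qid, q in fixture_corpus.queries.items():
            cds = fixture_corpus.cds_by_gene[q.gene.text]
            full, _ = build_queries(q, cds)
            bm25_order = [d for d, _ in evaluate_clauses(full, fixture_index)]
            hits = rank(q, fixture_index, cfg, cds=cds)
            english = [h.doc_id for h in hits if h.language_tier == "english"]
            bm25_english = [d for d in bm25_order
                            if fixture_index.docs[d].language == "en"]
            # among full-query hits, fused order equals pure BM25 order
            assert [d for d in english if d in bm25_english] == bm25_english

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_in_each_component(self, seed):
        # raising any single component never lowers final score
        rng = random.Random(seed)
        comps = [rng.random() for _ in range(4)] + [rng.uniform(-1, 1)]
        weights = (CFG.w_rsv, CFG.w_relax, CFG.w_ne, CFG.w_demo, CFG.w_kw)
        base = sum(w * c for w, c in zip(weights, comps))
        i = rng.randrange(5)
        bumped = list(comps)
        bumped[i] = min(1.0, bumped[i] + rng.random())
        assert sum(w * c for w, c in zip(weights, bumped)) >= base


class TestSynonymRecall:
    def _full_tree_recall(self, fixture_corpus, fixture_index, mode):
        hit = total = 0
        by_query = {}
        for qid, q in fixture_corpus.queries.items():
            q = dataclasses.replace(q, synonym_mode=mode)
            cds = fixture_corpus.cds_by_gene[q.gene.text]
            full, _ = build_queries(q, cds)
            got = {d for d, _ in evaluate_clauses(full, fixture_index)}
            rel = set(fixture_corpus.relevant_docs[qid])
            by_query[qid] = got & rel
            hit += len(got & rel)
            total += len(rel)
        return hit / total, by_query

    def test_mode_ordering_strict(self, fixture_corpus, fixture_index):
        r_none, _ = self._full_tree_recall(fixture_corpus, fixture_index, "none")
        r_basic, _ = self._full_tree_recall(fixture_corpus, fixture_index, "basic")
        r_all, _ = self._full_tree_recall(fixture_corpus, fixture_index, "all")
        assert r_all > r_basic > r_none
        assert r_all == 1.0

    def test_basic_retrieves_protein_but_not_cdna_docs(self, fixture_corpus, fixture_index):
        # docs whose only variant mention is a cDNA descriptor need full expansion
        _, basic = self._full_tree_recall(fixture_corpus, fixture_index, "basic")
        _, full = self._full_tree_recall(fixture_corpus, fixture_index, "all")
        _, none = self._full_tree_recall(fixture_corpus, fixture_index, "none")
        cdna_only = {q: full[q] - basic[q] for q in full}
        three_letter = {q: basic[q] - none[q] for q in basic}
        assert any(cdna_only.values())          # some docs are cDNA-exclusive
        assert any(three_letter.values())       # some need protein expansion
        for q in basic:
            assert basic[q] <= full[q]
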