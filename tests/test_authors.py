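"""Author keys, merge rules, transitive closure, and validation arithmetic."""

import itertools

import pytest

from taxcap import authors
from taxcap.authors import AuthorRecord
from taxcap.errors import InputError


def rec(aid, name, inst=("I1",), orders=(), families=()):
    stripped, truncated = authors.make_keys(name)
    return AuthorRecord(
        author_ids={aid}, display_name=name, stripped_name=stripped,
        truncated_name=truncated, institutions=set(inst),
        orders_published=set(orders), families_published=set(families),
    )


class TestMakeKeys:
    @pytest.mark.parametrize("name,stripped,truncated", [
        ("Quirina J. Groot", "QuirinaJGroot", "QGroot"),
        ("Estupinan-Suarez, Lina", "LinaEstupinanSuarez", "LEstupinanSuarez"),
        ("Linnaeus", "Linnaeus", "LLinnaeus"),
        ("Mira Kovalen", "MiraKovalen", "MKovalen"),
    ])
    def test_key_construction(self, name, stripped, truncated):
        assert authors.make_keys(name) == (stripped, truncated)

    def test_empty_name_rejected(self):
        with pytest.raises(InputError):
            authors.make_keys("   ")


class TestMergeRules:
    def test_rule2_truncated_institution_order(self):
        a = rec("A1", "John Smith", orders={"Coleoptera"})
        b = rec("A2", "J. Smith", orders={"Coleoptera", "Diptera"})
        merged, report = authors.merge_duplicates([a, b])
        assert report.n_after == 1
        assert report.merged_pairs[0][2] == "truncated_institution_taxon"
        assert merged[0].author_ids == {"A1", "A2"}

    def test_rule1_needs_shared_institution(self):
        a = rec("A1", "John Smith", inst=("I1",))
        b = rec("A2", "John Smith", inst=("I2",))
        _, report = authors.merge_duplicates([a, b])
        assert report.n_after == 2 and report.merged_pairs == []

    def test_rule1_same_stripped_same_institution(self):
        a = rec("A1", "John R. Smith")
        b = rec("A2", "John R Smith")
        _, report = authors.merge_duplicates([a, b])
        assert report.n_after == 1
        assert report.merged_pairs[0][2] == "stripped_institution"

    def test_rule2_requires_taxon_overlap(self):
        a = rec("A1", "John Smith", orders={"Coleoptera"})
        b = rec("A2", "J. Smith", orders={"Diptera"})
        _, report = authors.merge_duplicates([a, b])
        assert report.n_after == 2

    def test_family_fallback_when_orders_missing(self):
        a = rec("A1", "John Smith", orders=set(), families={"Carabidae"})
        b = rec("A2", "J. Smith", orders={"Coleoptera"}, families={"Carabidae"})
        _, report = authors.merge_duplicates([a, b])
        assert report.n_after == 1

    def test_single_record_identity(self):
        a = rec("A1", "John Smith")
        merged, report = authors.merge_duplicates([a])
        assert merged == [a] and report.n_before == report.n_after == 1

    def test_case_insensitive_keys(self):
        a = rec("A1", "JOHN SMITH", orders={"Coleoptera"})
        b = rec("A2", "John Smith", orders={"Coleoptera"})
        _, report = authors.merge_duplicates([a, b])
        assert report.n_after == 1

    def test_idempotent_and_never_grows(self):
        records = [
            rec("A1", "John Smith", orders={"Coleoptera"}),
            rec("A2", "J. Smith", orders={"Coleoptera"}),
            rec("A3", "Mary Jones", inst=("I9",)),
        ]
        merged, report = authors.merge_duplicates(records)
        assert report.n_after <= report.n_before
        again, report2 = authors.merge_duplicates(merged)
        assert report2.n_before == report2.n_after == len(merged)

    def test_closure_matches_bruteforce_oracle(self):
        # oracle: exhaustive pairwise matching + transitive closure via networkx
        import networkx as nx
        import numpy as np

        rng = np.random.default_rng(11)
        pool = []
        for i in range(60):
            base = f"Name{i % 20:02d} Last{i % 15:02d}"
            pool.append(rec(
                f"A{i}", base if rng.random() < 0.6 else f"{base[0]}. Last{i % 15:02d}",
                inst=(f"I{int(rng.integers(0, 4))}",),
                orders={f"O{int(rng.integers(0, 3))}"},
            ))
        _, report = authors.merge_duplicates(pool)

        g = nx.Graph()
        g.add_nodes_from(min(r.author_ids) for r in pool)
        for a, b in itertools.combinations(pool, 2):
            if authors.match_rule(a, b) is not None:
                g.add_edge(min(a.author_ids), min(b.author_ids))
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(c) for c in report.components} == oracle


class TestMergeQuality:
    def make_report(self, components):
        return authors.MergeReport(
            n_before=sum(len(c) for c in components), n_after=len(components),
            components=[set(c) for c in components],
        )

    def test_perfect(self):
        report = self.make_report([{"A1", "A2"}, {"A3"}])
        truth = {"A1": "P1", "A2": "P1", "A3": "P2"}
        assert authors.merge_quality(report, truth) == (1.0, 1.0)

    def test_partial_recall(self):
        # truth: 10 duplicate pairs; system finds 8, no spurious merges
        components = [{f"A{i}a", f"A{i}b"} for i in range(8)]
        components += [{f"A{i}a"} for i in range(8, 10)]
        components += [{f"A{i}b"} for i in range(8, 10)]
        truth = {f"A{i}{s}": f"P{i}" for i in range(10) for s in "ab"}
        report = self.make_report(components)
        assert authors.merge_quality(report, truth) == (1.0, 0.8)

    def test_no_merges_convention(self):
        report = self.make_report([{"A1"}, {"A2"}])
        precision, recall = authors.merge_quality(report, {"A1": "P1", "A2": "P1"})
        assert (precision, recall) == (1.0, 0.0)

    def test_universe_mismatch_rejected(self):
        report = self.make_report([{"A1"}])
        with pytest.raises(InputError):
            authors.merge_quality(report, {"A1": "P1", "A2": "P2"})


class TestInflationBound:
    def test_validation_sample_arithmetic(self):
        assert authors.inflation_bound(9 / 200, 0.10) == pytest.approx(0.45)

    @pytest.mark.parametrize("miss,share,expected", [
        (0.0, 0.7, 0.0),
        (1.0, 1.0, 100.0),
    ])
    def test_bounds(self, miss, share, expected):
        assert authors.inflation_bound(miss, share) == expected

    def test_range_checked(self):
        with pytest.raises(InputError):
            authors.inflation_bound(1.2, 0.1)
        with pytest.raises(InputError):
            authors.inflation_bound(0.1, -0.1)


def test_extract_authors_unions_over_articles(small_backbone, keyword_config):
    from taxcap import names
    from taxcap.authors import Authorship
    from taxcap.corpus import ArticleRecord

    def article(aid, wid, abstract, country="BE"):
        a = ArticleRecord(
            article_id=wid, journal_id="S1", abstract=abstract,
            authorships=[Authorship(author_id=aid, display_name="Ann Bee",
                                    institution_ids={"I1"},
                                    country_codes={country})],
        )
        return names.annotate_article_species(a, small_backbone)

    corpus = [
        article("A1", "W1", "Carabus auratus was found."),
        article("A1", "W2", "Abies alba was found."),
        article("A9", "W3", "Abies alba again.", country="US"),
    ]
    records = authors.extract_authors(corpus, keyword_config.european_country_codes)
    assert len(records) == 1  # the US-only author is excluded
    assert records[0].orders_published == {"Coleoptera", "Pinales"}
    assert records[0].article_ids == {"W1", "W2"}


def test_extract_authors_empty_corpus(keyword_config):
    assert authors.extract_authors([], keyword_config.european_country_codes) == []
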