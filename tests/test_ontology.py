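import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from candigene import io as cio
from candigene import ontology as onto_mod


def make_ref(rows):
    df = pd.DataFrame(rows, columns=["species", "gene_name", "function", "go_terms"])
    df["go_terms"] = [frozenset(s) for s in df["go_terms"]]
    return df


class TestTransfer:
    def test_three_species_identical_sets_transfer(self):
        ref = make_ref([(f"sp{i}", "Kinase-1", "f", {"GO:a", "GO:b"}) for i in range(3)])
        targets = pd.DataFrame({"gene": ["t"], "name": ["kinase 1"]})
        out = onto_mod.transfer_annotations(targets, ref)
        assert out == {"t": {"GO:a", "GO:b"}}

    def test_two_species_insufficient(self):
        ref = make_ref([(f"sp{i}", "orphan", "f", {"GO:a"}) for i in range(2)])
        targets = pd.DataFrame({"gene": ["t"], "name": ["orphan"]})
        assert onto_mod.transfer_annotations(targets, ref) == {}

    def test_three_species_one_differing_set_rejected(self):
        ref = make_ref([("sp1", "enz", "f", {"GO:a"}), ("sp2", "enz", "f", {"GO:a"}),
                        ("sp3", "enz", "f", {"GO:a", "GO:b"})])
        targets = pd.DataFrame({"gene": ["t"], "name": ["enz"]})
        assert onto_mod.transfer_annotations(targets, ref) == {}

    def test_consensus_among_four_species(self):
        ref = make_ref([(f"sp{i}", "enz", "f", {"GO:a"}) for i in range(3)]
                       + [("sp4", "enz", "f", {"GO:z"})])
        targets = pd.DataFrame({"gene": ["t"], "name": ["enz"]})
        assert onto_mod.transfer_annotations(targets, ref) == {"t": {"GO:a"}}

    def test_same_species_repeated_does_not_count_twice(self):
        ref = make_ref([("sp1", "enz", "f", {"GO:a"})] * 3)
        targets = pd.DataFrame({"gene": ["t"], "name": ["enz"]})
        assert onto_mod.transfer_annotations(targets, ref) == {}

    def test_name_normalization_strips_like_suffix(self):
        assert onto_mod.normalize_gene_name("ADENOSINE DEAMINASE 2-like") == \
            onto_mod.normalize_gene_name("adenosine deaminase 2")

    def test_row_order_independent(self):
        rows = [(f"sp{i}", "enz", "f", {"GO:a"}) for i in range(3)] + \
               [("spX", "enz", "f", {"GO:b"}), ("spY", "other", "f", {"GO:c"})]
        targets = pd.DataFrame({"gene": ["t"], "name": ["enz"]})
        a = onto_mod.transfer_annotations(targets, make_ref(rows))
        b = onto_mod.transfer_annotations(targets, make_ref(rows[::-1]))
        assert a == b


@pytest.fixture
def chain_onto(chain_obo):
    path, ids = chain_obo
    return cio.read_ontology(path), ids


class TestPropagate:
    def test_leaf_closes_over_chain(self, chain_onto):
        onto, ids = chain_onto
        out = onto_mod.propagate({"g": {ids[2]}}, onto)
        assert out["g"] == set(ids[:3])

    def test_idempotent(self, chain_onto):
        onto, ids = chain_onto
        once = onto_mod.propagate({"g": {ids[4]}}, onto)
        twice = onto_mod.propagate(once, onto)
        assert once == twice

    def test_root_is_fixed_point(self, chain_onto):
        onto, ids = chain_onto
        assert onto_mod.propagate({"g": {ids[0]}}, onto) == {"g": {ids[0]}}


def flat_ontology(n_terms):
    """Root plus n_terms leaf terms, all biological_process."""
    g = nx.DiGraph()
    terms = {"GO:root": ("root", "biological_process")}
    g.add_node("GO:root")
    for i in range(n_terms):
        tid = f"GO:t{i}"
        terms[tid] = (f"t{i}", "biological_process")
        g.add_edge(tid, "GO:root")
    return cio.OntologyGraph(graph=g, terms=terms)


class TestEnrich:
    def test_fully_loaded_term_closed_form(self):
        """N=20, K=5, n=5, k=5 has p = 1 / C(20,5) = 1/15504."""
        onto = flat_ontology(2)
        background = {f"g{i}" for i in range(20)}
        ann = {g: {"GO:t0", "GO:root"} if i < 5 else {"GO:t1", "GO:root"}
               for i, g in enumerate(sorted(background))}
        candidates = set(sorted(background)[:5])
        table = onto_mod.enrich(candidates, background, ann, onto)
        p = table.set_index("term").loc["GO:t0", "p_value"]
        assert p == pytest.approx(1.0 / comb(20, 5, exact=True), rel=1e-12)
        assert p == pytest.approx(1.0 / 15504, rel=1e-12)

    def test_expected_count_is_not_enriched(self):
        """k at its independence expectation gives an unremarkable p."""
        onto = flat_ontology(2)
        background = {f"g{i}" for i in range(100)}
        ordered = sorted(background)
        ann = {g: {"GO:t0", "GO:root"} if i < 40 else {"GO:t1", "GO:root"}
               for i, g in enumerate(ordered)}
        candidates = set(ordered[:8] + ordered[40:52])  # k=8 of K=40, n=20: E[k]=8
        table = onto_mod.enrich(candidates, background, ann, onto).set_index("term")
        assert table.loc["GO:t0", "p_value"] > 0.3

    def test_candidates_equal_background_saturates(self):
        onto = flat_ontology(3)
        background = {f"g{i}" for i in range(12)}
        rng = np.random.default_rng(8)
        ann = {g: {f"GO:t{rng.integers(0, 3)}", "GO:root"} for g in background}
        table = onto_mod.enrich(background, background, ann, onto)
        np.testing.assert_allclose(table["p_value"], 1.0, atol=1e-9)

    def test_matches_bruteforce_hypergeometric_sum(self, rng):
        """Upper-tail p equals a direct summation of point masses."""
        onto = flat_ontology(1)
        for _ in range(20):
            N = int(rng.integers(20, 200))
            K = int(rng.integers(3, N))
            n = int(rng.integers(1, N))
            genes = [f"g{i}" for i in range(N)]
            ann = {g: ({"GO:t0", "GO:root"} if i < K else {"GO:root"})
                   for i, g in enumerate(genes)}
            cand = set(rng.choice(genes, size=n, replace=False))
            k = sum(1 for g in cand if "GO:t0" in ann[g])
            table = onto_mod.enrich(cand, set(genes), ann, onto, min_term_size=1)
            rows = table.set_index("term")
            if k < 1:
                assert "GO:t0" not in rows.index
                continue
            brute = sum(
                comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
                for j in range(k, min(K, n) + 1)
            ) / comb(N, n, exact=True)
            assert rows.loc["GO:t0", "p_value"] == pytest.approx(brute, abs=1e-12)

    def test_unannotated_candidate_changes_nothing(self):
        onto = flat_ontology(2)
        background = {f"g{i}" for i in range(20)}
        ann = {g: {"GO:t0", "GO:root"} if i < 6 else {"GO:t1", "GO:root"}
               for i, g in enumerate(sorted(background))}
        candidates = set(sorted(background)[:4])
        base = onto_mod.enrich(candidates, background, ann, onto)
        extra = onto_mod.enrich(candidates | {"ghost"}, background | {"ghost"}, ann, onto)
        pd.testing.assert_frame_equal(base, extra)

    def test_candidates_must_be_subset(self):
        onto = flat_ontology(1)
        with pytest.raises(cio.ValidationError, match="subset"):
            onto_mod.enrich({"a"}, {"b"}, {"b": {"GO:t0"}}, onto)


class TestCategorize:
    @pytest.fixture
    def deep_onto(self):
        # root <- a <- b <- c, plus root <- a2; depths: a,a2 = 1; b = 2; c = 3
        g = nx.DiGraph()
        terms = {}
        for tid in ["GO:root", "GO:a", "GO:a2", "GO:b", "GO:c"]:
            terms[tid] = (tid, "biological_process")
            g.add_node(tid)
        g.add_edge("GO:a", "GO:root")
        g.add_edge("GO:a2", "GO:root")
        g.add_edge("GO:b", "GO:a")
        g.add_edge("GO:c", "GO:b")
        return cio.OntologyGraph(graph=g, terms=terms)

    def test_deep_gene_counted_at_level_ancestor(self, deep_onto):
        ann = onto_mod.propagate({"g": {"GO:c"}}, deep_onto)
        out = onto_mod.categorize({"g"}, ann, deep_onto, level=2).set_index("term")
        assert out.loc["GO:b", "n_genes"] == 1

    def test_multi_membership_counts_in_both(self, deep_onto):
        ann = onto_mod.propagate({"g": {"GO:b", "GO:a2"}}, deep_onto)
        out = onto_mod.categorize({"g"}, ann, deep_onto, level=1).set_index("term")
        assert out.loc["GO:a", "n_genes"] == 1
        assert out.loc["GO:a2", "n_genes"] == 1

    def test_empty_gene_set_all_zero(self, deep_onto):
        out = onto_mod.categorize(set(), {}, deep_onto, level=1)
        assert (out["n_genes"] == 0).all()
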