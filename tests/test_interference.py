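"""Interference signature, the literature-evidence filter and ranking."""

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from moanet import (
    compute_interference,
    extract_connected_submodel,
    filter_prognostic_evidence,
    rank_candidates,
)

from ._bruteforce import bf_interference, bf_rank


def model_from(edges, genes):
    g = nx.Graph(edges)
    return extract_connected_submodel(g, genes)


class TestInterference:
    def test_hand_intersection(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        a = extract_connected_submodel(net, {"a", "b", "c"})
        b = extract_connected_submodel(net, {"b", "c", "d"})
        sig = compute_interference(a, b)
        assert sig.shared_nodes == {"b", "c"}
        assert sig.shared_edges == {("b", "c")}

    def test_self_interference(self, small_network):
        m = extract_connected_submodel(small_network, set(list(small_network.nodes)[:20]))
        sig = compute_interference(m, m)
        assert sig.shared_nodes == m.nodes and sig.shared_edges == m.edges

    def test_disjoint_models_give_empty_signature(self):
        net = nx.Graph([("a", "b"), ("c", "d")])
        a = extract_connected_submodel(net, {"a", "b"})
        b = extract_connected_submodel(net, {"c", "d"})
        sig = compute_interference(a, b)
        assert not sig.shared_nodes and not sig.shared_edges

    @given(st.integers(0, 10_000))
    def test_symmetry_containment_and_bruteforce(self, seed):
        from .conftest import random_scenario

        g, nodes, edges, genes, _, _ = random_scenario(seed)
        half = set(nodes[: len(nodes) // 2 + 1])
        if not genes or not half:
            return
        a = extract_connected_submodel(g, genes)
        b = extract_connected_submodel(g, half)
        s1 = compute_interference(a, b)
        s2 = compute_interference(b, a)
        assert s1 == s2
        assert s1.shared_nodes <= a.nodes and s1.shared_nodes <= b.nodes
        assert s1.shared_edges <= a.edges and s1.shared_edges <= b.edges
        exp_nodes, exp_edges = bf_interference(a.nodes, a.edges, b.nodes, b.edges)
        assert s1.shared_nodes == exp_nodes and s1.shared_edges == exp_edges


QUAL = dict(major_terms="diabetic nephropathies",
            terms="biological markers;prognosis", study_flags="human")


class TestEvidenceFilter:
    def test_empty_table(self):
        table = pd.DataFrame(columns=["gene", "publication_id", "terms", "major_terms", "study_flags"])
        assert filter_prognostic_evidence(table) == {}

    def test_qualifying_publication_counts(self):
        table = pd.DataFrame([{"gene": "G", "publication_id": "P1", **QUAL}])
        assert filter_prognostic_evidence(table) == {"G": 1}

    def test_omics_profiling_excluded(self):
        row = {"gene": "G", "publication_id": "P1", **QUAL}
        row["study_flags"] = "human;omics_profiling"
        assert filter_prognostic_evidence(pd.DataFrame([row])) == {}

    @pytest.mark.parametrize("field,value", [
        ("major_terms", "nephrosis"),                # wrong major topic
        ("terms", "biological markers"),             # missing required term
        ("study_flags", "in_vitro"),                 # no allowed context
    ])
    def test_failing_rules_drop_publication(self, field, value):
        row = {"gene": "G", "publication_id": "P1", **QUAL}
        row[field] = value
        assert filter_prognostic_evidence(pd.DataFrame([row])) == {}

    def test_case_and_whitespace_insensitive(self):
        row = {"gene": "G", "publication_id": "P1",
               "major_terms": "  Diabetic   Nephropathies ",
               "terms": "Biological  Markers; PROGNOSIS",
               "study_flags": "Human"}
        assert filter_prognostic_evidence(pd.DataFrame([row])) == {"G": 1}

    def test_duplicate_publication_counted_once(self):
        table = pd.DataFrame([{"gene": "G", "publication_id": "P1", **QUAL}] * 2)
        assert filter_prognostic_evidence(table) == {"G": 1}


class TestRank:
    def net(self):
        return nx.Graph([("a", "b"), ("b", "c"), ("c", "e"), ("e", "f")])

    def sig(self):
        net = self.net()
        m1 = extract_connected_submodel(net, {"b", "c"})
        return compute_interference(m1, m1)

    def test_tiers_and_proximity_cutoff(self):
        cand = rank_candidates(self.sig(), self.net(), {"c", "e", "f"}, proximity_max=1)
        assert list(cand["gene"]) == ["c", "e"]
        assert list(cand["tier"]) == ["in_signature", "proximal"]
        assert list(cand["distance"]) == [0, 1]

    def test_proximity_zero_is_signature_intersection(self):
        cand = rank_candidates(self.sig(), self.net(), {"c", "e", "f"}, proximity_max=0)
        assert list(cand["gene"]) == ["c"]

    def test_monotone_in_proximity(self):
        prev = set()
        for k in range(4):
            got = set(rank_candidates(self.sig(), self.net(), {"c", "e", "f"}, proximity_max=k)["gene"])
            assert prev <= got
            prev = got

    def test_empty_prognostic_set(self):
        assert rank_candidates(self.sig(), self.net(), set()).empty

    def test_negative_proximity_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates(self.sig(), self.net(), {"c"}, proximity_max=-1)

    def test_evidence_count_orders_within_tier(self):
        cand = rank_candidates(self.sig(), self.net(), {"b": 1, "c": 5}, proximity_max=0)
        assert list(cand["gene"]) == ["c", "b"]

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce(self, seed):
        from .conftest import random_scenario

        g, nodes, edges, genes, _, evidence = random_scenario(seed)
        if not genes:
            return
        m = extract_connected_submodel(g, genes)
        sig = compute_interference(m, m)
        for pmax in (0, 1, 2):
            got = rank_candidates(sig, g, evidence, proximity_max=pmax)
            exp = bf_rank(sig.shared_nodes, edges, set(nodes), evidence, pmax)
            assert [tuple(r) for r in got.itertuples(index=False)] == exp

    def test_benchmark_candidates(self, benchmark):
        """44-node signature with 10 in-signature prognostic candidates and
        3 direct-neighbour proximal candidates."""
        from moanet import FoldChangeSelector, extend_moa_model

        sel = FoldChangeSelector().fit(benchmark.expression)
        core = extract_connected_submodel(benchmark.network, benchmark.drug_literature_genes)
        moa = extend_moa_model(core, benchmark.network, sel.deregulated_)
        disease = extract_connected_submodel(benchmark.network, benchmark.disease_genes)
        sig = compute_interference(disease, moa)
        assert len(sig.shared_nodes) == 44
        evidence = filter_prognostic_evidence(benchmark.annotations)
        cand = rank_candidates(sig, benchmark.network, evidence, proximity_max=1)
        tiers = cand.groupby("tier").size().to_dict()
        assert tiers == {"in_signature": 10, "proximal": 3}
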