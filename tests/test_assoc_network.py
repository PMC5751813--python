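"""All-pairs scoring, empirical FDR, direction assignment, export."""

import numpy as np
import pytest

from conftest import make_annotation_map
from crogo2.assoc_network import (assign_directions, build_association_network,
                                  empirical_fdr, empirical_pvalues,
                                  export_network, load_network_tsv,
                                  score_all_pairs)
from crogo2.ontology_io import OntologyDAG
from crogo2.similarity import TermPairScore
from test_similarity import identity_result


def _flat_setup(n_a=2, n_b=3):
    """n_a + n_b root-less singleton terms over disjoint singleton genes."""
    dag = OntologyDAG()
    propagated, pool = {}, []
    for c, n in (("A", n_a), ("B", n_b)):
        for k in range(n):
            term, gene = f"{c.lower()}{k}", f"g_{c}{k}"
            dag.add_term(term, c)
            propagated[term] = {gene}
            pool.append(gene)
    ann = make_annotation_map(propagated,
                              {"A": {g for g in pool if "_A" in g},
                               "B": {g for g in pool if "_B" in g}})
    return dag, ann, identity_result(pool)


class TestScoreAllPairs:
    def test_cardinality_and_deterministic_order(self):
        dag, ann, result = _flat_setup(2, 3)
        scores = score_all_pairs(ann, dag, result, "A", "B")
        assert len(scores) == 6
        assert [(s.t1, s.t2) for s in scores] == sorted((s.t1, s.t2)
                                                        for s in scores)

    def test_same_category_rejected(self):
        dag, ann, result = _flat_setup()
        with pytest.raises(ValueError):
            score_all_pairs(ann, dag, result, "A", "A")

    def test_unconnected_categories_score_nonpositive(self):
        # disjoint annotation sets, identity association: no pair can exceed 0
        dag, ann, result = _flat_setup(3, 3)
        scores = score_all_pairs(ann, dag, result, "A", "B")
        assert all(s.sim <= 1e-12 for s in scores)

    def test_planted_pair_ranks_first_on_worked_example(self, wex):
        scores = score_all_pairs(wex["ann"], wex["dag"], wex["result"],
                                 "biological_process", "molecular_function")
        best = max(scores, key=lambda s: s.sim)
        assert {best.t1, best.t2} == {"GO:1000003", "GO:2000003"}


class TestEmpiricalPvalues:
    def test_score_above_every_null_sample(self):
        null = np.arange(999, dtype=float)
        assert empirical_pvalues(np.array([1e9]), null)[0] \
            == pytest.approx(1 / 1000, abs=1e-15)

    def test_score_at_the_null_minimum_is_near_one(self):
        null = np.arange(1.0, 1000.0)
        p = empirical_pvalues(np.array([1.0]), null)[0]
        assert p == 1.0

    def test_counting_formula_against_brute_force(self):
        rng = np.random.default_rng(11)
        null = rng.random(500)
        obs = rng.random(40)
        got = empirical_pvalues(obs, null)
        brute = [(1 + np.sum(null >= s)) / (1 + len(null)) for s in obs]
        assert np.allclose(got, brute, atol=1e-15)


class TestEmpiricalFdr:
    def test_deterministic_given_seed(self, wex):
        def run():
            scores = score_all_pairs(wex["ann"], wex["dag"], wex["result"],
                                     "biological_process", "molecular_function")
            scores = empirical_fdr(scores, wex["ann"], wex["dag"],
                                   wex["result"], n_null=200, seed=5)
            return [(s.p_value, s.q_value) for s in scores]
        assert run() == run()

    def test_n_null_floor_enforced(self, wex):
        scores = score_all_pairs(wex["ann"], wex["dag"], wex["result"],
                                 "biological_process", "molecular_function")
        with pytest.raises(ValueError, match="n_null"):
            empirical_fdr(scores, wex["ann"], wex["dag"], wex["result"],
                          n_null=50, seed=0)


def _edge(t1, t2, sim=0.9, q=0.01):
    return TermPairScore(t1=t1, t2=t2, sim_net=sim, sim_go=1.0, sim=sim,
                         n_genes_1=1, n_genes_2=1, p_value=0.001, q_value=q)


def _direction_dag():
    """Category A: x. Category B: chain p <- c <- gc plus unrelated u."""
    dag = OntologyDAG()
    dag.add_term("x", "A")
    for t in ("p", "c", "gc", "u"):
        dag.add_term(t, "B")
    dag.add_parent("c", "p")
    dag.add_parent("gc", "c")
    return dag


class TestAssignDirections:
    def test_edge_toward_the_ancestor_is_deleted(self):
        dag = _direction_dag()
        net = assign_directions([_edge("x", "p"), _edge("x", "c")], dag)
        directed = {(e.source, e.target) for e in net.edges}
        assert ("x", "p") not in directed
        assert ("x", "c") in directed
        # reverse direction is untouched: x has no within-A relatives in play
        assert ("p", "x") in directed and ("c", "x") in directed

    def test_unrelated_targets_both_kept(self):
        dag = _direction_dag()
        net = assign_directions([_edge("x", "c"), _edge("x", "u")], dag)
        directed = {(e.source, e.target) for e in net.edges}
        assert {("x", "c"), ("x", "u")} <= directed

    def test_chain_of_three_keeps_only_the_most_specific(self):
        dag = _direction_dag()
        net = assign_directions(
            [_edge("x", "p"), _edge("x", "c"), _edge("x", "gc")], dag)
        outgoing = {e.target for e in net.edges if e.source == "x"}
        assert outgoing == {"gc"}

    def test_term_absent_from_dag_rejected(self):
        with pytest.raises(KeyError):
            assign_directions([_edge("x", "nope")], _direction_dag())

    def test_direction_audit_no_edge_to_both_term_and_ancestor(self, wex):
        net = build_association_network(
            wex["ann"], wex["dag"], wex["result"], "biological_process",
            "molecular_function", fdr=1.5, n_null=200, seed=3)  # keep all pairs: structural test
        dag = wex["dag"]
        by_source: dict[str, set[str]] = {}
        for e in net.edges:
            by_source.setdefault(e.source, set()).add(e.target)
        for source, targets in by_source.items():
            for t in targets:
                assert not (dag.ancestors(t) & targets), \
                    f"{source} points at {t} and one of its ancestors"


class TestExport:
    def _net(self, wex):
        return build_association_network(
            wex["ann"], wex["dag"], wex["result"], "biological_process",
            "molecular_function", fdr=1.5, n_null=200, seed=3)  # keep all pairs: structural test

    def test_tsv_round_trip_preserves_edge_multiset(self, tmp_path, wex):
        net = self._net(wex)
        assert net.n_edges >= 1
        path = tmp_path / "net.tsv"
        export_network(net, path, format="tsv")
        back = load_network_tsv(path)
        orig = sorted((e.source, e.target, round(e.sim, 9)) for e in net.edges)
        got = sorted((e.source, e.target, round(e.sim, 9)) for e in back.edges)
        assert got == orig

    def test_empty_network_exports_header_only(self, tmp_path):
        from crogo2.assoc_network import AssociationNetwork
        path = tmp_path / "empty.tsv"
        export_network(AssociationNetwork(nodes={}, edges=[]), path)
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith("#")]
        assert lines == ["source\ttarget\tsource_category\ttarget_category"
                         "\tsim\tq_value"]

    def test_sif_and_graphml_formats(self, tmp_path, wex):
        net = self._net(wex)
        export_network(net, tmp_path / "net.sif", format="sif")
        assert "crogo2" in (tmp_path / "net.sif").read_text()
        import networkx as nx
        export_network(net, tmp_path / "net.graphml", format="graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == net.n_edges

    def test_unknown_format_rejected(self, tmp_path, wex):
        with pytest.raises(ValueError, match="format"):
            export_network(self._net(wex), tmp_path / "x", format="dot")
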