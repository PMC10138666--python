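"""Pathway graphs, sub-pathway extraction and starting-node selection."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacross import (MetabolicPathway, NotProducibleError,
                       PathwayValidationError, decompose_pathway,
                       extract_subpathway, load_subpathways,
                       read_pathway_graph, save_subpathways,
                       write_pathway_graph)
from metacross._generules import evaluate_rule, format_rule, parse_rule
from metacross.pathway_model import (backward_depths, define_starting_nodes,
                                     dry_run_visits)


def build(reactions, **kw):
    return MetabolicPathway.from_reactions(reactions, **kw)


CHAIN = [
    {"id": "R1", "substrates": ["M1"], "products": ["M2"], "gene_rule": "g1"},
    {"id": "R2", "substrates": ["M2"], "products": ["M3"], "gene_rule": "g2"},
]


class TestGeneRules:
    @pytest.mark.parametrize("text,expr,expected", [
        ("g1", {"g1": 0.7}, 0.7),
        ("g1 & g2", {"g1": 0.9, "g2": 0.2}, 0.2),
        ("g1 | g2", {"g1": 0.9, "g2": 0.2}, 0.9),
        ("g1 & (g2 | g3)", {"g1": 0.8, "g2": 0.1, "g3": 0.6}, 0.6),
        ("g1 AND g2", {"g1": 0.5, "g2": 0.3}, 0.3),
    ])
    def test_min_max_evaluation(self, text, expr, expected):
        assert evaluate_rule(parse_rule(text), expr) == pytest.approx(expected)

    @given(st.recursive(
        st.sampled_from(["gA", "gB", "gC", "gD"]),
        lambda children: st.tuples(st.sampled_from(["and", "or"]),
                                   st.lists(children, min_size=2, max_size=3)
                                   .map(tuple)),
        max_leaves=8))
    @settings(max_examples=50, deadline=None)
    def test_format_parse_roundtrip(self, rule):
        expr = {"gA": 0.1, "gB": 0.4, "gC": 0.7, "gD": 0.9}
        again = parse_rule(format_rule(rule))
        assert evaluate_rule(again, expr) == evaluate_rule(rule, expr)

    def test_missing_gene_raises_without_fill(self):
        with pytest.raises(KeyError):
            evaluate_rule("gX", {"g1": 0.5})


class TestPathwayValidation:
    def test_chain_json_roundtrip(self, tmp_path):
        pw = build(CHAIN)
        path = tmp_path / "pw.json"
        write_pathway_graph(pw, path, dialect="json")
        again = read_pathway_graph(path, dialect="json")
        assert again.metabolite_nodes == {"M1", "M2", "M3"}
        assert again.reaction_nodes == {"R1", "R2"}
        assert sorted(again.graph.edges()) == sorted(pw.graph.edges())

    def test_single_reaction_json(self, tmp_path):
        path = tmp_path / "one.json"
        import json
        json.dump({"reactions": [{"id": "R", "substrates": ["A"],
                                  "products": ["B"], "gene_rule": "g"}]},
                  open(path, "w"))
        pw = read_pathway_graph(path, dialect="json")
        assert len(pw.reaction_nodes) == 1
        assert len(pw.metabolite_nodes) == 2

    def test_metabolite_metabolite_edge_rejected(self, tmp_path):
        g = nx.DiGraph()
        g.add_node("A", kind="metabolite")
        g.add_node("B", kind="metabolite")
        g.add_node("R", kind="reaction", gene_rule="g", reversible=False,
                   is_reverse=False)
        g.add_edge("A", "B")
        g.add_edge("A", "R")
        g.add_edge("R", "B")
        with pytest.raises(PathwayValidationError):
            MetabolicPathway(g)

    def test_reaction_without_substrate_rejected(self):
        g = nx.DiGraph()
        g.add_node("R", kind="reaction", gene_rule="g")
        g.add_node("B", kind="metabolite")
        g.add_edge("R", "B")
        with pytest.raises(PathwayValidationError):
            MetabolicPathway(g)

    def test_reversible_expands_to_antiparallel_instances(self):
        recs = [dict(CHAIN[0]), dict(CHAIN[1])]
        recs[0]["reversible"] = True
        pw = build(recs)
        assert len(pw.reaction_nodes) == 3  # R1, R1!rev, R2
        assert ("M2", "R1!rev") in pw.graph.edges()
        assert ("R1!rev", "M1") in pw.graph.edges()
        # shared gene rule
        assert pw.gene_rule("R1!rev") == pw.gene_rule("R1")

    def test_kgml_reader(self, tmp_path):
        kgml = """<?xml version="1.0"?>
<pathway name="path:demo" title="Demo">
 <entry id="1" name="hsa:111" type="gene" reaction="rn:R001"/>
 <entry id="2" name="hsa:222 hsa:333" type="gene" reaction="rn:R002"/>
 <reaction id="10" name="rn:R001" type="irreversible">
  <substrate id="3" name="cpd:C01"/>
  <product id="4" name="cpd:C02"/>
 </reaction>
 <reaction id="11" name="rn:R002" type="reversible">
  <substrate id="4" name="cpd:C02"/>
  <product id="5" name="cpd:C03"/>
 </reaction>
</pathway>"""
        path = tmp_path / "demo.kgml"
        path.write_text(kgml)
        pw = read_pathway_graph(path, dialect="kgml")
        assert pw.metabolite_nodes == {"cpd:C01", "cpd:C02", "cpd:C03"}
        # the reversible reaction is expanded; isozymes are OR-joined
        assert pw.reaction_nodes == {"rn:R001", "rn:R002", "rn:R002!rev"}
        assert pw.gene_rule("rn:R001") == "hsa:111"
        assert pw.gene_rule("rn:R002") == ("or", ("hsa:222", "hsa:333"))

    def test_graphml_roundtrip_with_reversible(self, tmp_path):
        recs = [dict(CHAIN[0], reversible=True), dict(CHAIN[1])]
        pw = build(recs)
        path = tmp_path / "pw.graphml"
        write_pathway_graph(pw, path, dialect="graphml")
        again = read_pathway_graph(path, dialect="graphml")
        assert again.reaction_nodes == pw.reaction_nodes
        assert sorted(again.graph.edges()) == sorted(pw.graph.edges())


class TestExtractSubpathway:
    def test_chain_product_gets_whole_chain(self):
        pw = build(CHAIN)
        sub = extract_subpathway(pw, "M3")
        assert set(sub.graph.nodes) == {"M1", "R1", "M2", "R2", "M3"}
        assert sub.graph.out_degree("M3") == 0

    def test_product_consuming_reaction_excluded(self):
        recs = CHAIN + [{"id": "R3", "substrates": ["M3"], "products": ["M4"],
                         "gene_rule": "g3"}]
        pw = build(recs)
        sub = extract_subpathway(pw, "M3")
        assert "R3" not in sub.graph
        assert ("M3", "R3") not in sub.graph.edges()

    def test_upstream_cycle_retained(self):
        recs = CHAIN + [
            {"id": "R3", "substrates": ["M3"], "products": ["P"], "gene_rule": "g3"},
            {"id": "R4", "substrates": ["M3"], "products": ["M2"], "gene_rule": "g4"},
        ]
        pw = build(recs)
        sub = extract_subpathway(pw, "P")
        # the M2 -> R2 -> M3 -> R4 -> M2 feedback loop feeds P and is kept
        for edge in [("M3", "R4"), ("R4", "M2"), ("M2", "R2"), ("R2", "M3")]:
            assert edge in sub.graph.edges()

    def test_not_producible(self):
        pw = build(CHAIN)
        with pytest.raises(NotProducibleError):
            extract_subpathway(pw, "M1")

    def test_subgraph_of_input(self, small_study):
        for pw in small_study.pathways:
            for sub in decompose_pathway(pw):
                assert set(sub.graph.nodes) <= set(pw.graph.nodes)
                assert set(sub.graph.edges()) <= set(pw.graph.edges())


class TestStartingNodes:
    def test_chain_indegree_zero(self):
        pw = build(CHAIN)
        sub = define_starting_nodes(extract_subpathway(pw, "M3"))
        assert sub.starting_nodes == {"M1"}

    def test_two_branches_both_heads(self):
        recs = [
            {"id": "Ra", "substrates": ["A"], "products": ["X"], "gene_rule": "g"},
            {"id": "Rb", "substrates": ["B"], "products": ["X"], "gene_rule": "g"},
            {"id": "Rx", "substrates": ["X"], "products": ["P"], "gene_rule": "g"},
        ]
        sub = define_starting_nodes(extract_subpathway(build(recs), "P"))
        assert sub.starting_nodes == {"A", "B"}

    def test_isolated_cycle_gets_coverage_seed(self):
        # pure feedback cycle feeding the product: no indegree-0 metabolite
        recs = [
            {"id": "R1", "substrates": ["A"], "products": ["B"], "gene_rule": "g"},
            {"id": "R2", "substrates": ["B"], "products": ["A"], "gene_rule": "g"},
            {"id": "R3", "substrates": ["B"], "products": ["P"], "gene_rule": "g"},
        ]
        sub = extract_subpathway(build(recs), "P")
        step1 = {m for m in sub.metabolite_nodes
                 if m != "P" and sub.graph.in_degree(m) == 0}
        assert step1 == set()  # nothing to start from in step 1 alone
        sub = define_starting_nodes(sub)
        assert sub.starting_nodes  # step 2 seeded the cycle
        assert dry_run_visits(sub, sub.starting_nodes) == set(sub.graph.nodes)

    def test_dry_run_full_coverage_on_random_graphs(self):
        from metacross import gen_metabolic_pathway
        for seed in range(20):
            pw = gen_metabolic_pathway(8, 8, loop_frac=0.4, seed=seed)
            for sub in decompose_pathway(pw):
                if not sub.valid:
                    continue
                visited = dry_run_visits(sub, sub.starting_nodes)
                assert visited == set(sub.graph.nodes)

    def test_depth_orderings_agree_on_bipartite(self, chain_subpathways):
        for sub in chain_subpathways:
            d_all = backward_depths(sub, count="all")
            d_met = backward_depths(sub, count="metabolite")
            mets = sorted(sub.metabolite_nodes)
            order_all = sorted(mets, key=lambda m: d_all[m])
            order_met = sorted(mets, key=lambda m: d_met[m])
            assert order_all == order_met


class TestDecompose:
    def test_chain_yields_two_subpathways(self, chain_subpathways):
        products = {s.product for s in chain_subpathways}
        assert len(chain_subpathways) == 2
        assert all(p.endswith(("M2", "M3")) for p in products)

    def test_isolated_metabolite_absent(self):
        recs = CHAIN + [{"id": "R9", "substrates": ["M1", "Iso"],
                         "products": ["M2"], "gene_rule": "g9"}]
        pw = build(recs)
        products = {s.product for s in decompose_pathway(pw)}
        assert "Iso" not in products  # indegree 0: never a product

    def test_idempotent_and_deterministic(self, chain_pathway):
        a = decompose_pathway(chain_pathway)
        b = decompose_pathway(chain_pathway)
        assert [s.product for s in a] == [s.product for s in b]
        assert [sorted(s.graph.edges()) for s in a] == \
               [sorted(s.graph.edges()) for s in b]

    def test_serialization_roundtrip(self, tmp_path, small_study):
        subs = small_study.subpathways
        path = tmp_path / "subs.json"
        save_subpathways(subs, path)
        again = load_subpathways(path)
        assert len(again) == len(subs)
        for s1, s2 in zip(subs, again):
            assert s1.product == s2.product
            assert s1.starting_nodes == s2.starting_nodes
            assert sorted(s1.graph.edges()) == sorted(s2.graph.edges())
            assert {n: s1.graph.nodes[n]["kind"] for n in s1.graph} == \
                   {n: s2.graph.nodes[n]["kind"] for n in s2.graph}
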