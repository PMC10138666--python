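"""Flux propagation rules, convergence and the production matrix."""

import numpy as np
import pandas as pd
import pytest

from metacross import (MetabolicPathway, PropagationError, PropagationState,
                       acyclic_fixed_point, decompose_pathway,
                       distribute_substrate, extract_subpathway,
                       gen_metabolic_pathway, production_matrix, propagate,
                       reaction_activity, reaction_rate, update_product)
from metacross.pathway_model import define_starting_nodes
import networkx as nx


def chain_sub(activities=("g1", "g2")):
    recs = [
        {"id": "R1", "substrates": ["M1"], "products": ["M2"], "gene_rule": "g1"},
        {"id": "R2", "substrates": ["M2"], "products": ["M3"], "gene_rule": "g2"},
    ]
    pw = MetabolicPathway.from_reactions(recs)
    return define_starting_nodes(extract_subpathway(pw, "M3"))


class TestReactionActivity:
    def test_min_max_and_passthrough(self, chain_subpathways):
        sub = max(chain_subpathways, key=lambda s: len(s.reaction_nodes))
        genes = sorted(sub.enzyme_genes)
        expr = {g: 0.7 for g in genes}
        acts = reaction_activity(sub, expr)
        assert all(a == pytest.approx(0.7) for a in acts.values())

    def test_empty_rule_is_nonenzymatic(self):
        recs = [{"id": "R1", "substrates": ["M1"], "products": ["M2"],
                 "gene_rule": ""}]
        pw = MetabolicPathway.from_reactions(recs)
        sub = define_starting_nodes(extract_subpathway(pw, "M2"))
        acts = reaction_activity(sub, {"gX": 0.3})
        assert acts[("R1")] == 1.0

    def test_missing_gene_median_imputed(self):
        sub = chain_sub()
        acts = reaction_activity(sub, {"g1": 0.4, "other": 0.8})
        # g2 missing -> imputed with median(0.4, 0.8) = 0.6
        assert acts["R2"] == pytest.approx(0.6)


class TestUpdateRules:
    def test_distribute_proportional(self):
        recs = [
            {"id": "Ra", "substrates": ["S"], "products": ["A"], "gene_rule": "ga"},
            {"id": "Rb", "substrates": ["S"], "products": ["B"], "gene_rule": "gb"},
            {"id": "Rc", "substrates": ["A", "B"], "products": ["P"], "gene_rule": "gc"},
        ]
        pw = MetabolicPathway.from_reactions(recs)
        sub = define_starting_nodes(extract_subpathway(pw, "P"))
        state = PropagationState(m={"S": 0.9})
        distribute_substrate(state, "S", {"Ra": 0.2, "Rb": 0.6, "Rc": 1.0}, sub)
        assert state.w_in[("S", "Ra")] == pytest.approx(0.225)
        assert state.w_in[("S", "Rb")] == pytest.approx(0.675)
        assert sum(v for (s, _), v in state.w_in.items() if s == "S") == \
            pytest.approx(0.9)

    def test_distribute_all_zero_activities(self):
        sub = chain_sub()
        m1 = [m for m in sub.metabolite_nodes if m.endswith("M1")][0]
        state = PropagationState(m={m1: 0.5})
        distribute_substrate(state, m1, {"R1": 0.0, "R2": 0.0}, sub)
        assert state.w_in[(m1, "R1")] == 0.0

    def test_rate_min_rule(self):
        recs = [
            {"id": "Ra", "substrates": ["S1"], "products": ["A"], "gene_rule": "g"},
            {"id": "Rb", "substrates": ["S2"], "products": ["B"], "gene_rule": "g"},
            {"id": "R", "substrates": ["A", "B"], "products": ["P"], "gene_rule": "g"},
        ]
        pw = MetabolicPathway.from_reactions(recs)
        sub = define_starting_nodes(extract_subpathway(pw, "P"))
        state = PropagationState(w_in={("A", "R"): 0.6, ("B", "R"): 0.4})
        w = reaction_rate(state, "R", {"R": 0.5}, sub)
        assert w == pytest.approx(0.2)
        assert state.w_out[("R", "P")] == pytest.approx(0.2)

    def test_rate_zero_activity(self):
        sub = chain_sub()
        state = PropagationState(w_in={("M1", "R1"): 1.0})
        assert reaction_rate(state, "R1", {"R1": 0.0}, sub) == 0.0

    def test_rate_saturating_variant(self):
        sub = chain_sub()
        state = PropagationState(w_in={("M1", "R1"): 0.5})
        w = reaction_rate(state, "R1", {"R1": 1.0}, sub, rate_rule="mm", mm_k=0.5)
        assert w == pytest.approx(0.5 / (0.5 + 0.5))

    def test_update_product_single_inflow(self):
        sub = chain_sub()
        state = PropagationState(m={"M2": 0.0}, w_out={("R1", "M2"): 0.8})
        assert update_product(state, "M2", sub) == pytest.approx(0.4)
        # iterate to the fixed point: mean of inflows
        for _ in range(60):
            update_product(state, "M2", sub)
        assert state.m["M2"] == pytest.approx(0.8, abs=1e-6)

    def test_update_product_two_inflows_mean(self):
        recs = [
            {"id": "Ra", "substrates": ["A"], "products": ["P"], "gene_rule": "g"},
            {"id": "Rb", "substrates": ["B"], "products": ["P"], "gene_rule": "g"},
        ]
        pw = MetabolicPathway.from_reactions(recs)
        sub = define_starting_nodes(extract_subpathway(pw, "P"))
        state = PropagationState(m={"P": 0.0},
                                 w_out={("Ra", "P"): 0.4, ("Rb", "P"): 0.8})
        for _ in range(80):
            update_product(state, "P", sub)
        assert state.m["P"] == pytest.approx(0.6, abs=1e-6)


class TestPropagate:
    def test_single_reaction_fixed_point(self):
        sub = chain_sub()
        val, state = propagate(sub, {"R1": 0.8, "R2": 1.0})
        assert val == pytest.approx(0.8, abs=1e-5)

    def test_two_reactions_compose(self):
        sub = chain_sub()
        val, _ = propagate(sub, {"R1": 0.8, "R2": 0.5})
        assert val == pytest.approx(0.4, abs=1e-5)

    def test_lossless_chain(self):
        sub = chain_sub()
        val, _ = propagate(sub, {"R1": 1.0, "R2": 1.0})
        assert val == pytest.approx(1.0, abs=1e-5)

    def test_non_convergence_raises_with_state(self):
        sub = chain_sub()
        with pytest.raises(PropagationError) as err:
            propagate(sub, {"R1": 0.8, "R2": 0.5}, max_iter=2)
        assert err.value.state is not None
        assert err.value.state.iteration == 2

    def test_acyclic_oracle_agreement_random_graphs(self):
        """Converged values equal one-pass topological evaluation (10*tol)."""
        rng = np.random.default_rng(5)
        checked = 0
        for seed in range(40):
            pw = gen_metabolic_pathway(7, 6, loop_frac=0.0, seed=seed)
            if not nx.is_directed_acyclic_graph(pw.graph):
                continue
            for sub in decompose_pathway(pw):
                if not sub.valid:
                    continue
                acts = {r: rng.uniform(0, 1) for r in sorted(sub.reaction_nodes)}
                val, _ = propagate(sub, acts, tol=1e-6)
                oracle = acyclic_fixed_point(sub, acts)
                assert val == pytest.approx(oracle, abs=1e-5)
                checked += 1
        assert checked >= 100

    def test_loop_convergence(self):
        """Cyclic sub-pathways converge at tol=1e-6 in >=99/100 instances."""
        rng = np.random.default_rng(11)
        converged = attempts = 0
        seed = 0
        while attempts < 100:
            pw = gen_metabolic_pathway(6, 6, loop_frac=0.5, seed=seed)
            seed += 1
            if nx.is_directed_acyclic_graph(pw.graph):
                continue
            subs = [s for s in decompose_pathway(pw)
                    if s.valid and not nx.is_directed_acyclic_graph(s.graph)]
            for sub in subs:
                if attempts >= 100:
                    break
                attempts += 1
                acts = {r: rng.uniform(0.1, 1) for r in sorted(sub.reaction_nodes)}
                try:
                    val, _ = propagate(sub, acts, tol=1e-6, max_iter=1000)
                    assert 0.0 <= val <= 1.0
                    converged += 1
                except PropagationError:
                    pass
        assert converged >= 99

    def test_closure_and_conservation(self):
        """All amounts/flows stay in [0,1]; substrate splits conserve mass."""
        rng = np.random.default_rng(3)
        for seed in range(10):
            pw = gen_metabolic_pathway(8, 8, loop_frac=0.3, seed=seed)
            for sub in decompose_pathway(pw):
                if not sub.valid:
                    continue
                acts = {r: rng.uniform(0, 1) for r in sorted(sub.reaction_nodes)}
                val, state = propagate(sub, acts)
                assert 0.0 <= val <= 1.0
                assert all(0 <= v <= 1 + 1e-9 for v in state.m.values())
                assert all(0 <= v <= 1 + 1e-9 for v in state.w_in.values())
                assert all(0 <= v <= 1 + 1e-9 for v in state.w_out.values())
                for m in sub.metabolite_nodes:
                    consumers = sub.n_plus(m)
                    if consumers and any(acts[r] > 0 for r in consumers):
                        total = sum(state.w_in[(m, r)] for r in consumers)
                        assert total == pytest.approx(state.m.get(m, 0.0), abs=1e-9)


class TestProductionMatrix:
    def test_identical_samples_identical_columns(self, chain_subpathways):
        sub = max(chain_subpathways, key=lambda s: len(s.reaction_nodes))
        genes = sorted(sub.enzyme_genes)
        expr = pd.DataFrame({"s1": [0.6, 0.9], "s2": [0.6, 0.9]}, index=genes)
        prod = production_matrix([sub], expr)
        assert prod["s1"].equals(prod["s2"])

    def test_all_zero_expression_gives_zero(self, chain_subpathways):
        sub = max(chain_subpathways, key=lambda s: len(s.reaction_nodes))
        genes = sorted(sub.enzyme_genes)
        expr = pd.DataFrame({"s1": [0.0] * len(genes)}, index=genes)
        prod = production_matrix([sub], expr)
        assert (prod.to_numpy() == 0).all()

    def test_monotone_in_expression_without_competition(self):
        """On competition-free sub-pathways (one consumer per metabolite),
        raising an enzyme gene never lowers any product value."""
        rng = np.random.default_rng(8)
        for seed in range(6):
            # chain topology: every metabolite has a single consumer
            pw = gen_metabolic_pathway(6, 5, seed=seed)
            subs = [s for s in decompose_pathway(pw) if s.valid]
            genes = sorted(pw.enzyme_genes)
            base = pd.DataFrame({"s": rng.uniform(0.2, 0.8, len(genes))},
                                index=genes)
            prod0 = production_matrix(subs, base)
            for gene in genes:
                up = base.copy()
                up.loc[gene, "s"] = min(1.0, up.loc[gene, "s"] + 0.2)
                prod1 = production_matrix(subs, up)
                assert (prod1.to_numpy() >= prod0.to_numpy() - 1e-9).all()

    def test_rejects_out_of_range_expression(self, chain_subpathways):
        sub = chain_subpathways[0]
        genes = sorted(sub.enzyme_genes) or ["g"]
        expr = pd.DataFrame({"s1": [1.5] * len(genes)}, index=genes)
        with pytest.raises(ValueError):
            production_matrix([sub], expr)

    def test_determinism(self, small_study):
        subs = small_study.subpathways[:3]
        expr = small_study.expression
        a = production_matrix(subs, expr.iloc[:, :4])
        b = production_matrix(subs, expr.iloc[:, :4])
        assert a.equals(b)
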