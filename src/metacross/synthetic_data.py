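"""Synthetic studies with planted ground truth.

Generates desk-scale analogues of a paired tumor/normal expression cohort:
bipartite metabolic pathway graphs, receptor-to-effector signaling
circuits, an expression matrix on the post-normalization [0, 1] scale, a
tumor/normal pairing, and a loss-of-function variant table.  Three kinds of
signal are planted with controllable effect sizes:

* **differential production** — enzyme genes of selected products differ
  between tumor and normal by ``dpm_effect`` before noise;
* **metabolite -> circuit links** — circuit-gene expression in tumors is a
  monotone (affine) function of the planted metabolite's modeled production
  value plus Gaussian noise, so the link is only visible through the full
  production -> GP -> attribution chain;
* **gene sharing** — a fraction of circuit genes double as enzyme genes, to
  exercise the shared-gene Fisher control.

The noise model is additive Gaussian clipped to [0, 1].  No attempt is made
to emulate RNA-seq count distributions or library-size effects; the matrix
stands in for data that has already been normalized and rescaled.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._generules import Rule, rename_genes
from .flux_propagation import production_matrix
from .pathway_model import (MetabolicPathway, SubPathway, decompose_pathway,
                            read_pathway_graph, write_pathway_graph)
from .signaling_circuits import SignalingCircuit, circuit_from_dict, circuit_to_dict

PREDICTOR_COLUMNS = ["sift", "polyphen2", "fathmm", "mutation_taster",
                     "mutation_assessor"]


@dataclass
class SyntheticStudy:
    """A fully materialized synthetic study with its planted ground truth."""

    pathways: list[MetabolicPathway]
    circuits: list[SignalingCircuit]
    expression: pd.DataFrame  # genes x samples in [0, 1]
    pairing: list[tuple[str, str]]  # (tumor id, normal id)
    planted_dpms: set[str]
    planted_links: set[tuple[str, str]]  # (metabolite, circuit name)
    variant_table: pd.DataFrame
    seed: int
    subpathways: list[SubPathway] = field(default_factory=list)

    @property
    def tumor_samples(self) -> list[str]:
        return [t for t, _ in self.pairing]

    @property
    def normal_samples(self) -> list[str]:
        return [n for _, n in self.pairing]


# ---------------------------------------------------------------------------
# Graph generators
# ---------------------------------------------------------------------------


def gen_metabolic_pathway(n_metabolites: int, n_reactions: int,
                          reversible_frac: float = 0.0, loop_frac: float = 0.0,
                          genes_per_reaction: int = 1, seed: int = 0,
                          name: str = "pw", gene_prefix: str = "G") -> MetabolicPathway:
    """Connected bipartite pathway with a chain backbone.

    A ``loop_frac`` share of reactions close feedback cycles (substrate
    downstream, product upstream); a ``reversible_frac`` share is flagged
    reversible and expanded into antiparallel instances.  Multi-gene rules
    are AND-joined (enzyme complexes).  Deterministic under ``seed``.
    """
    if n_metabolites < 2 or n_reactions < 1:
        raise ValueError("need n_metabolites >= 2 and n_reactions >= 1 "
                         "for a connected pathway")
    if genes_per_reaction < 1:
        raise ValueError("genes_per_reaction must be >= 1")
    for frac, nm in ((reversible_frac, "reversible_frac"), (loop_frac, "loop_frac")):
        if not 0 <= frac <= 1:
            raise ValueError(f"{nm} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mets = [f"{name}:M{i + 1}" for i in range(n_metabolites)]

    n_loop = int(round(loop_frac * n_reactions))
    n_back = n_reactions - n_loop
    if n_back < 1:
        n_back, n_loop = 1, n_reactions - 1
    chain = mets[: min(n_metabolites, n_back + 1)]

    recs = []
    gene_counter = 0

    def next_rule() -> Rule:
        nonlocal gene_counter
        genes = []
        for _ in range(genes_per_reaction):
            gene_counter += 1
            genes.append(f"{gene_prefix}:{name}:{gene_counter}")
        return genes[0] if len(genes) == 1 else ("and", tuple(genes))

    ridx = 0
    for i in range(len(chain) - 1):
        ridx += 1
        recs.append({"id": f"{name}:R{ridx}", "substrates": [chain[i]],
                     "products": [chain[i + 1]], "gene_rule": next_rule()})
    # extra backbone reactions: parallel conversions between chain metabolites
    while ridx < n_back:
        i = int(rng.integers(0, len(chain) - 1))
        j = int(rng.integers(i + 1, len(chain)))
        ridx += 1
        recs.append({"id": f"{name}:R{ridx}", "substrates": [chain[i]],
                     "products": [chain[j]], "gene_rule": next_rule()})
    # loop-closing reactions: substrate downstream of product
    for _ in range(n_loop):
        j = int(rng.integers(1, len(chain)))
        i = int(rng.integers(0, j))
        ridx += 1
        recs.append({"id": f"{name}:R{ridx}", "substrates": [chain[j]],
                     "products": [chain[i]], "gene_rule": next_rule()})
    # attach metabolites beyond the chain as extra substrates/products
    for k, m in enumerate(mets[len(chain):]):
        r = recs[int(rng.integers(0, len(recs)))]
        if k % 2 == 0:
            r["substrates"].append(m)
        else:
            r["products"].append(m)

    n_rev = int(round(reversible_frac * len(recs)))
    for pos in rng.choice(len(recs), size=n_rev, replace=False):
        recs[int(pos)]["reversible"] = True
    return MetabolicPathway.from_reactions(recs, name=name)


def gen_signaling_circuit(n_nodes: int, n_inhibitory: int = 0,
                          genes_per_node: int = 1, seed: int = 0,
                          name: str = "circ", gene_prefix: str = "S",
                          extra_edge_prob: float = 0.3) -> SignalingCircuit:
    """Receptor-to-effector DAG: a chain backbone plus forward skip edges.

    ``n_inhibitory`` randomly chosen edges carry sign -1; every node is
    reachable from the receptor by construction.  Multi-gene node rules are
    OR-joined (isoforms).
    """
    if n_nodes < 2:
        raise ValueError("a circuit needs at least receptor and effector")
    rng = np.random.default_rng(seed)
    nodes = [f"{name}:N{i + 1}" for i in range(n_nodes)]
    g = nx.DiGraph()
    counter = 0
    for n in nodes:
        genes = []
        for _ in range(genes_per_node):
            counter += 1
            genes.append(f"{gene_prefix}:{name}:{counter}")
        rule: Rule = genes[0] if len(genes) == 1 else ("or", tuple(genes))
        g.add_node(n, gene_rule=rule)
    edges = [(nodes[i], nodes[i + 1]) for i in range(n_nodes - 1)]
    for i in range(n_nodes - 2):
        for j in range(i + 2, n_nodes):
            if rng.random() < extra_edge_prob:
                edges.append((nodes[i], nodes[j]))
    if n_inhibitory >= len(edges):
        raise ValueError("n_inhibitory must be below the number of edges")
    signs = np.ones(len(edges), dtype=int)
    if n_inhibitory:
        # keep the backbone edge into the effector activating so the circuit
        # cannot be structurally dead
        protected = len(edges) >= 2
        pool = np.arange(1 if protected else 0, len(edges))
        chosen = rng.choice(pool, size=n_inhibitory, replace=False)
        signs[chosen] = -1
    for (u, v), s in zip(edges, signs):
        g.add_edge(u, v, sign=int(s))
    return SignalingCircuit(g, receptor=nodes[0], effector=nodes[-1], name=name)


def gen_variant_table(genes: list[str], samples: list[str],
                      frac_flagged: float = 0.05,
                      votes_distribution: dict[int, float] | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Variant rows (sample, gene, five binary predictor calls).

    Each (sample, gene) pair is flagged with probability ``frac_flagged``;
    the damaging-vote count of a flagged row follows ``votes_distribution``
    (default: uniform over 1..5).
    """
    if votes_distribution is None:
        votes_distribution = {k: 0.2 for k in range(1, 6)}
    counts = sorted(votes_distribution)
    probs = np.array([votes_distribution[k] for k in counts], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("votes_distribution probabilities must sum to 1")
    if any(k < 0 or k > 5 for k in counts):
        raise ValueError("vote counts must lie in 0..5")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples:
        for gene in genes:
            if rng.random() >= frac_flagged:
                continue
            k = int(rng.choice(counts, p=probs))
            calls = np.zeros(5, dtype=int)
            calls[rng.choice(5, size=k, replace=False)] = 1
            rows.append([sample, gene, *calls.tolist()])
    return pd.DataFrame(rows, columns=["sample", "gene", *PREDICTOR_COLUMNS])


# ---------------------------------------------------------------------------
# Expression cohort with planted structure
# ---------------------------------------------------------------------------


def gen_expression_cohort(pathways: list[MetabolicPathway],
                          circuits: list[SignalingCircuit],
                          n_pairs: int = 60,
                          dpm_effect: float = 0.3,
                          link_effect: float = 0.25,
                          noise_sd: float = 0.05,
                          shared_gene_frac: float = 0.0,
                          circuit_latent_sd: float | None = None,
                          planted_dpms: set[str] | None = None,
                          planted_links: set[tuple[str, str]] | None = None,
                          variant_frac: float = 0.005,
                          seed: int = 0) -> SyntheticStudy:
    """Materialize a paired cohort around pathway/circuit skeletons.

    If planted DPMs/links are not given, one deep product per pathway is
    planted as a DPM and the first pathways' products are linked to the
    first circuits.  Gene sharing renames ``shared_gene_frac`` of circuit
    genes into randomly chosen enzyme-gene slots across the pathways.
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3")
    if dpm_effect < 0 or link_effect < 0:
        raise ValueError("effects must be >= 0")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if circuit_latent_sd is None:
        circuit_latent_sd = noise_sd  # unexplainable circuit-level variation
    rng = np.random.default_rng(seed)

    circuit_genes = sorted(set().union(*(c.genes for c in circuits)))
    if shared_gene_frac > 0:
        pathways = _share_genes(pathways, circuit_genes, shared_gene_frac, rng)

    subpathways: list[SubPathway] = []
    for pw in pathways:
        subpathways.extend(decompose_pathway(pw))
    subpathways = [s for s in subpathways if s.valid]
    sub_by_product = {s.product: s for s in subpathways}
    if not subpathways:
        raise ValueError("pathways yield no producible metabolites")

    if planted_dpms is None:
        planted_dpms = {_deepest_product(pw, sub_by_product) for pw in pathways}
    if planted_links is None:
        mets = sorted(planted_dpms)
        planted_links = {(m, c.name) for m, c in zip(mets, circuits)}
    for met, circ in planted_links:
        if met not in sub_by_product:
            raise ValueError(f"planted link metabolite {met!r} is not producible")
        if circ not in {c.name for c in circuits}:
            raise ValueError(f"planted link circuit {circ!r} unknown")

    tumor = [f"T{i + 1}" for i in range(n_pairs)]
    normal = [f"N{i + 1}" for i in range(n_pairs)]
    samples = tumor + normal
    enzyme_genes = sorted(set().union(*(pw.enzyme_genes for pw in pathways)))
    genes = sorted(set(enzyme_genes) | set(circuit_genes))
    expr = pd.DataFrame(0.0, index=genes, columns=samples)

    # enzyme genes: per-gene baseline + independent Gaussian noise, so each
    # metabolite's production varies through its own reactions' genes
    for gene in enzyme_genes:
        base = rng.uniform(0.35, 0.65)
        expr.loc[gene] = base + rng.normal(0.0, noise_sd, len(samples))

    # planted differential production: shift sub-pathway enzyme genes
    half = dpm_effect / 2.0
    for met in sorted(planted_dpms):
        for gene in sorted(sub_by_product[met].enzyme_genes):
            expr.loc[gene, tumor] += half
            expr.loc[gene, normal] -= half

    expr = expr.clip(0.0, 1.0)

    # variants are drawn before circuit genes are written so the planted
    # links can respond to the loss-of-function state of the enzymes
    variants = gen_variant_table(genes, tumor, frac_flagged=variant_frac,
                                 seed=int(rng.integers(2 ** 31)))

    # production of link metabolites on the masked tumor enzyme expression:
    # a damaging variant lowers production, and the linked circuit follows
    link_mets = sorted({m for m, _ in planted_links})
    linked_circuits = {c for _, c in planted_links}
    prod_z: dict[str, np.ndarray] = {}
    if link_mets and link_effect > 0:
        from .preprocess import lof_mask
        enz_variants = variants[variants["gene"].isin(enzyme_genes)]
        enz_tumor = lof_mask(expr.loc[enzyme_genes, tumor], enz_variants)
        prod = production_matrix([sub_by_product[m] for m in link_mets],
                                 enz_tumor)
        for m in link_mets:
            v = prod.loc[m].to_numpy()
            sd = v.std()
            prod_z[m] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    # circuit genes: baseline + per-(circuit, sample) latent + noise;
    # linked circuits additionally track the metabolite's production z-score
    enzyme_set = set(enzyme_genes)
    for c in circuits:
        latent = rng.normal(0.0, circuit_latent_sd, size=len(samples))
        link_z = np.zeros(n_pairs)
        if c.name in linked_circuits and link_effect > 0:
            met = next(m for m, cn in planted_links if cn == c.name)
            link_z = prod_z.get(met, link_z)
        for gene in sorted(c.genes):
            if gene in enzyme_set:
                continue  # shared genes keep their enzyme-side values
            vals = 0.5 + latent + rng.normal(0.0, noise_sd, len(samples))
            vals[: n_pairs] += link_effect * link_z
            expr.loc[gene] = vals
    expr = expr.clip(0.0, 1.0)
    return SyntheticStudy(
        pathways=pathways, circuits=circuits, expression=expr,
        pairing=list(zip(tumor, normal)), planted_dpms=set(planted_dpms),
        planted_links=set(planted_links), variant_table=variants,
        seed=seed, subpathways=subpathways)


def _share_genes(pathways, circuit_genes, frac, rng) -> list[MetabolicPathway]:
    """Rename enzyme genes to circuit genes to create overlap."""
    n_share = int(round(frac * len(circuit_genes)))
    if n_share == 0:
        return pathways
    enzyme_genes = sorted(set().union(*(pw.enzyme_genes for pw in pathways)))
    if n_share > len(enzyme_genes):
        raise ValueError("requested shared genes exceed available enzyme genes")
    chosen_circ = [circuit_genes[i] for i in
                   rng.choice(len(circuit_genes), size=n_share, replace=False)]
    chosen_enz = [enzyme_genes[i] for i in
                  rng.choice(len(enzyme_genes), size=n_share, replace=False)]
    mapping = dict(zip(chosen_enz, chosen_circ))
    out = []
    for pw in pathways:
        g = pw.graph.copy()
        for r in pw.reaction_nodes:
            rule = g.nodes[r].get("gene_rule")
            if rule is not None:
                g.nodes[r]["gene_rule"] = rename_genes(rule, mapping)
        out.append(MetabolicPathway(g, name=pw.name))
    return out


def _deepest_product(pw: MetabolicPathway, sub_by_product: dict) -> str:
    """The pathway's producible metabolite with the largest sub-pathway."""
    candidates = [p for p in sub_by_product
                  if p.startswith(pw.name + ":")]
    if not candidates:
        raise ValueError(f"pathway {pw.name} has no producible metabolite")
    return max(candidates,
               key=lambda p: (sub_by_product[p].graph.number_of_nodes(), p))


def make_study(n_pathways: int = 5, n_metabolites: int = 10,
               n_reactions: int = 9, n_circuits: int = 8,
               circuit_nodes: int = 5, n_pairs: int = 60,
               dpm_effect: float = 0.3, link_effect: float = 0.25,
               noise_sd: float = 0.05, shared_gene_frac: float = 0.0,
               circuit_latent_sd: float | None = None,
               reversible_frac: float = 0.0, loop_frac: float = 0.0,
               n_inhibitory: int = 0, extra_edge_prob: float = 0.3,
               seed: int = 0) -> SyntheticStudy:
    """Convenience constructor: skeleton graphs plus a planted cohort."""
    rng = np.random.default_rng(seed)
    pathways = [gen_metabolic_pathway(
        n_metabolites, n_reactions, reversible_frac=reversible_frac,
        loop_frac=loop_frac, seed=int(rng.integers(2 ** 31)), name=f"pw{i + 1}")
        for i in range(n_pathways)]
    circuits = [gen_signaling_circuit(
        circuit_nodes, n_inhibitory=n_inhibitory,
        extra_edge_prob=extra_edge_prob,
        seed=int(rng.integers(2 ** 31)), name=f"circ{i + 1}")
        for i in range(n_circuits)]
    return gen_expression_cohort(
        pathways, circuits, n_pairs=n_pairs, dpm_effect=dpm_effect,
        link_effect=link_effect, noise_sd=noise_sd,
        shared_gene_frac=shared_gene_frac, circuit_latent_sd=circuit_latent_sd,
        seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# On-disk writers / readers
# ---------------------------------------------------------------------------


def write_study(study: SyntheticStudy, out_dir: str | Path,
                graph_dialect: str = "json") -> None:
    out = Path(out_dir)
    if out.exists():
        shutil.rmtree(out)
    (out / "pathways").mkdir(parents=True)
    (out / "circuits").mkdir()
    ext = "json" if graph_dialect == "json" else "graphml"
    for pw in study.pathways:
        write_pathway_graph(pw, out / "pathways" / f"{pw.name}.{ext}",
                            dialect=graph_dialect)
    for c in study.circuits:
        with open(out / "circuits" / f"{c.name}.json", "w") as fh:
            json.dump(circuit_to_dict(c), fh, indent=1, sort_keys=True)
    study.expression.to_csv(out / "expression.tsv", sep="\t",
                            index_label="gene", float_format="%.17g")
    pd.DataFrame(study.pairing, columns=["tumor", "normal"]).to_csv(
        out / "pairing.tsv", sep="\t", index=False)
    study.variant_table.to_csv(out / "variants.tsv", sep="\t", index=False)
    with open(out / "study.json", "w") as fh:
        json.dump({
            "seed": study.seed,
            "graph_dialect": graph_dialect,
            "planted_dpms": sorted(study.planted_dpms),
            "planted_links": sorted(list(p) for p in study.planted_links),
        }, fh, indent=1, sort_keys=True)


def load_study(in_dir: str | Path) -> SyntheticStudy:
    src = Path(in_dir)
    with open(src / "study.json") as fh:
        meta = json.load(fh)
    dialect = meta.get("graph_dialect", "json")
    pathways = [read_pathway_graph(p, dialect=dialect)
                for p in sorted((src / "pathways").iterdir())]
    circuits = []
    for p in sorted((src / "circuits").iterdir()):
        with open(p) as fh:
            circuits.append(circuit_from_dict(json.load(fh)))
    expression = pd.read_csv(src / "expression.tsv", sep="\t", index_col="gene",
                             float_precision="round_trip")
    pairing = [tuple(r) for r in
               pd.read_csv(src / "pairing.tsv", sep="\t").to_numpy()]
    variants = pd.read_csv(src / "variants.tsv", sep="\t")
    subs = []
    for pw in pathways:
        subs.extend(s for s in decompose_pathway(pw) if s.valid)
    return SyntheticStudy(
        pathways=pathways, circuits=circuits, expression=expression,
        pairing=pairing, planted_dpms=set(meta["planted_dpms"]),
        planted_links={tuple(p) for p in meta["planted_links"]},
        variant_table=variants, seed=int(meta["seed"]), subpathways=subs)
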