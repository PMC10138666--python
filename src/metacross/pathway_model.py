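"""Metabolic pathway graphs and their decomposition into sub-pathways.

A metabolic pathway is a bipartite directed graph whose nodes are metabolites
and reactions; edges alternate metabolite->reaction (substrate use) and
reaction->metabolite (product formation).  Each reaction carries a boolean
gene rule over its enzyme genes and a reversibility flag; reversible
reactions are expanded at load time into two antiparallel reaction instances
sharing the gene rule, so that all traversal and flux propagation is over
plain directed edges.

The production of a metabolite (the *product*) is modeled on its
*sub-pathway*: the subgraph of all nodes from which the product can be
reached, obtained by breadth-first search against the edge direction,
with the product's own outgoing edges removed so that the producing pathway
cannot consume it.  Flux propagation starts from *starting nodes* —
metabolites with indegree zero or maximally distant from the product, plus
any additions needed so a dry propagation run covers every node.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ._generules import Rule, all_genes, format_rule, parse_rule, rule_genes

logger = logging.getLogger(__name__)

METABOLITE = "metabolite"
REACTION = "reaction"

#: suffix of the reverse instance created when expanding a reversible reaction
REV_SUFFIX = "!rev"


class PathwayValidationError(ValueError):
    """Raised when a graph violates the bipartite pathway invariants."""


class NotProducibleError(ValueError):
    """Raised when a sub-pathway is requested for a metabolite nothing produces."""


# ---------------------------------------------------------------------------
# MetabolicPathway
# ---------------------------------------------------------------------------


@dataclass
class MetabolicPathway:
    """Bipartite metabolite/reaction graph with per-reaction gene rules.

    ``graph`` node attributes: ``kind`` (metabolite/reaction); reactions also
    carry ``gene_rule`` (a :mod:`metacross._generules` rule) and ``reversible``
    (the original flag; the expansion partner has ``is_reverse=True``).
    """

    graph: nx.DiGraph
    name: str = "pathway"

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_reactions(cls, reactions: list[dict], name: str = "pathway") -> "MetabolicPathway":
        """Build from reaction records, expanding reversible reactions.

        Each record: ``{"id", "substrates": [...], "products": [...],
        "reversible": bool, "gene_rule": rule-or-text}``.
        """
        g = nx.DiGraph()
        for rec in reactions:
            rid = str(rec["id"])
            rule = rec.get("gene_rule")
            if isinstance(rule, str):
                rule = parse_rule(rule) if rule else None
            subs = [str(s) for s in rec["substrates"]]
            prods = [str(p) for p in rec["products"]]
            reversible = bool(rec.get("reversible", False))
            cls._add_reaction(g, rid, subs, prods, rule, reversible)
            if reversible:
                cls._add_reaction(g, rid + REV_SUFFIX, prods, subs, rule, True, is_reverse=True)
        return cls(g, name=name)

    @staticmethod
    def _add_reaction(g, rid, substrates, products, rule, reversible, is_reverse=False):
        g.add_node(rid, kind=REACTION, gene_rule=rule, reversible=reversible,
                   is_reverse=is_reverse)
        for s in substrates:
            g.add_node(s, kind=METABOLITE)
            g.add_edge(s, rid)
        for p in products:
            g.add_node(p, kind=METABOLITE)
            g.add_edge(rid, p)

    # -- views ---------------------------------------------------------------

    @property
    def metabolite_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == METABOLITE}

    @property
    def reaction_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == REACTION}

    def gene_rule(self, reaction: str) -> Rule | None:
        return self.graph.nodes[reaction].get("gene_rule")

    @property
    def enzyme_genes(self) -> set[str]:
        return all_genes(r for r in
                         (self.gene_rule(n) for n in self.reaction_nodes)
                         if r is not None)

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        for u, v in self.graph.edges():
            ku = self.graph.nodes[u]["kind"]
            kv = self.graph.nodes[v]["kind"]
            if ku == kv:
                raise PathwayValidationError(
                    f"edge {u!r}->{v!r} connects two {ku} nodes (graph must be bipartite)")
        for r in self.reaction_nodes:
            if self.graph.in_degree(r) < 1 or self.graph.out_degree(r) < 1:
                raise PathwayValidationError(
                    f"reaction {r!r} lacks a substrate or product edge")


# ---------------------------------------------------------------------------
# SubPathway
# ---------------------------------------------------------------------------


@dataclass
class SubPathway:
    """Product-rooted subgraph on which metabolite production is propagated."""

    product: str
    graph: nx.DiGraph
    starting_nodes: set[str] = field(default_factory=set)
    valid: bool = True
    name: str = ""

    def n_plus(self, node: str) -> list[str]:
        """Neighbors along outgoing edges."""
        return sorted(self.graph.successors(node))

    def n_minus(self, node: str) -> list[str]:
        """Neighbors along incoming edges."""
        return sorted(self.graph.predecessors(node))

    @property
    def metabolite_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == METABOLITE}

    @property
    def reaction_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == REACTION}

    def gene_rule(self, reaction: str) -> Rule | None:
        return self.graph.nodes[reaction].get("gene_rule")

    @property
    def enzyme_genes(self) -> set[str]:
        return all_genes(r for r in
                         (self.gene_rule(n) for n in self.reaction_nodes)
                         if r is not None)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_pathway_graph(path: str | Path, dialect: str = "json") -> MetabolicPathway:
    """Load a pathway from ``json`` (reaction records), ``graphml`` or ``kgml``."""
    path = Path(path)
    if dialect == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return MetabolicPathway.from_reactions(doc["reactions"],
                                               name=doc.get("name", path.stem))
    if dialect == "graphml":
        return _read_graphml(path)
    if dialect == "kgml":
        return _read_kgml(path)
    raise ValueError(f"unknown pathway dialect {dialect!r}")


def write_pathway_graph(pathway: MetabolicPathway, path: str | Path,
                        dialect: str = "json") -> None:
    path = Path(path)
    if dialect == "json":
        recs = []
        g = pathway.graph
        for r in sorted(pathway.reaction_nodes):
            d = g.nodes[r]
            if d.get("is_reverse"):
                continue  # folded back into the reversible flag
            rule = d.get("gene_rule")
            recs.append({
                "id": r,
                "substrates": sorted(g.predecessors(r)),
                "products": sorted(g.successors(r)),
                "reversible": bool(d.get("reversible", False)),
                "gene_rule": format_rule(rule) if rule is not None else "",
            })
        with open(path, "w") as fh:
            json.dump({"name": pathway.name, "reactions": recs}, fh, indent=1, sort_keys=True)
    elif dialect == "graphml":
        g = nx.DiGraph()
        for n, d in pathway.graph.nodes(data=True):
            attrs = {"kind": d["kind"]}
            if d["kind"] == REACTION:
                rule = d.get("gene_rule")
                attrs["gene_rule"] = format_rule(rule) if rule is not None else ""
                attrs["reversible"] = bool(d.get("reversible", False))
                attrs["is_reverse"] = bool(d.get("is_reverse", False))
            g.add_node(n, **attrs)
        g.add_edges_from(pathway.graph.edges())
        g.graph["name"] = pathway.name
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown pathway dialect {dialect!r}")


def _read_graphml(path: Path) -> MetabolicPathway:
    try:
        raw = nx.read_graphml(path)
    except Exception as exc:  # pragma: no cover - depends on file
        raise PathwayValidationError(f"cannot parse GraphML {path}: {exc}") from exc
    g = nx.DiGraph()
    for n, d in raw.nodes(data=True):
        kind = d.get("kind")
        if kind not in (METABOLITE, REACTION):
            raise PathwayValidationError(f"node {n!r} has unknown kind {kind!r}")
        attrs = {"kind": kind}
        if kind == REACTION:
            txt = d.get("gene_rule", "")
            attrs["gene_rule"] = parse_rule(txt) if txt else None
            attrs["reversible"] = bool(d.get("reversible", False))
            attrs["is_reverse"] = bool(d.get("is_reverse", False))
        g.add_node(n, **attrs)
    g.add_edges_from(raw.edges())
    # expand reversible reactions that lack an antiparallel partner
    for r in [n for n, d in g.nodes(data=True)
              if d.get("kind") == REACTION and d.get("reversible")
              and not d.get("is_reverse")]:
        if r + REV_SUFFIX in g:
            continue
        subs = list(g.predecessors(r))
        prods = list(g.successors(r))
        MetabolicPathway._add_reaction(g, r + REV_SUFFIX, prods, subs,
                                       g.nodes[r].get("gene_rule"), True, is_reverse=True)
    return MetabolicPathway(g, name=raw.graph.get("name", path.stem))


def _read_kgml(path: Path) -> MetabolicPathway:
    """Best-effort reader for KEGG KGML exports (compound/reaction entries)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise PathwayValidationError(f"cannot parse KGML {path}: {exc}") from exc
    root = tree.getroot()
    # map reaction name -> gene ids via entries of type gene
    genes_by_reaction: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        if entry.get("type") == "gene" and entry.get("reaction"):
            for rname in entry.get("reaction", "").split():
                genes_by_reaction.setdefault(rname, []).extend(
                    entry.get("name", "").split())
    recs = []
    for rxn in root.findall("reaction"):
        rname = rxn.get("name", rxn.get("id", ""))
        subs = [s.get("name") for s in rxn.findall("substrate")]
        prods = [p.get("name") for p in rxn.findall("product")]
        if not subs or not prods:
            raise PathwayValidationError(
                f"KGML reaction {rname!r} lacks substrate or product elements")
        genes = genes_by_reaction.get(rname, [])
        rule: Rule | None
        if not genes:
            rule = None
        elif len(genes) == 1:
            rule = genes[0]
        else:
            rule = ("or", tuple(genes))  # KGML lists isozymes
        recs.append({"id": rname, "substrates": subs, "products": prods,
                     "reversible": rxn.get("type") == "reversible",
                     "gene_rule": rule})
    return MetabolicPathway.from_reactions(recs, name=root.get("title", path.stem))


# ---------------------------------------------------------------------------
# Sub-pathway extraction
# ---------------------------------------------------------------------------


def extract_subpathway(pathway: MetabolicPathway, product: str) -> SubPathway:
    """Backward-BFS subgraph from which ``product`` is reachable.

    Feedback loops upstream of the product are retained; the product's own
    outgoing edges are removed so the sub-pathway cannot consume it.
    """
    g = pathway.graph
    if product not in g or g.nodes[product]["kind"] != METABOLITE:
        raise NotProducibleError(f"{product!r} is not a metabolite of this pathway")
    if g.in_degree(product) == 0:
        raise NotProducibleError(f"metabolite {product!r} has no producing reaction")

    visited = {product}
    queue = deque([product])
    while queue:
        node = queue.popleft()
        for pred in sorted(g.predecessors(node)):
            if pred not in visited:
                visited.add(pred)
                queue.append(pred)

    sub = nx.DiGraph()
    for n in visited:
        sub.add_node(n, **g.nodes[n])
    for u, v in g.edges():
        if u in visited and v in visited and u != product:
            sub.add_edge(u, v)
    # dropping product out-edges may leave reactions with no substrate edge;
    # prune them (and anything downstream of only-them) so every reaction
    # keeps >= 1 substrate and >= 1 product edge within the sub-pathway
    _prune_dangling(sub, product)
    return SubPathway(product=product, graph=sub, name=f"{pathway.name}:{product}")


def _prune_dangling(sub: nx.DiGraph, product: str) -> None:
    changed = True
    while changed:
        changed = False
        for r in [n for n, d in sub.nodes(data=True) if d["kind"] == REACTION]:
            if sub.in_degree(r) == 0 or sub.out_degree(r) == 0:
                sub.remove_node(r)
                changed = True
        for m in [n for n, d in sub.nodes(data=True) if d["kind"] == METABOLITE]:
            if m != product and sub.degree(m) == 0:
                sub.remove_node(m)
                changed = True


def backward_depths(sub: SubPathway, count: str = "all") -> dict[str, int]:
    """BFS depth of each node from the product, against edge direction.

    ``count='all'`` counts every hop; ``count='metabolite'`` counts only
    metabolite nodes along the path (for the alternating bipartite graph the
    two orderings coincide).
    """
    depths = {sub.product: 0}
    queue = deque([sub.product])
    g = sub.graph
    while queue:
        node = queue.popleft()
        for pred in sorted(g.predecessors(node)):
            if pred not in depths:
                depths[pred] = depths[node] + 1
                queue.append(pred)
    if count == "metabolite":
        depths = {n: d // 2 for n, d in depths.items()}
    elif count != "all":
        raise ValueError("count must be 'all' or 'metabolite'")
    return depths


def dry_run_visits(sub: SubPathway, starting: set[str]) -> set[str]:
    """Nodes reached by a topology-only propagation from ``starting``.

    Mirrors the flux rules with unit activities: a reaction fires once every
    substrate has been reached; a metabolite is reached when it is a starting
    node or any producing reaction has fired.
    """
    g = sub.graph
    visited = set(starting)
    changed = True
    while changed:
        changed = False
        for r in sub.reaction_nodes:
            if r in visited:
                continue
            subs = list(g.predecessors(r))
            if subs and all(s in visited for s in subs):
                visited.add(r)
                changed = True
                for p in g.successors(r):
                    if p not in visited:
                        visited.add(p)
        # (metabolites are added as reaction products above)
    return visited


def define_starting_nodes(sub: SubPathway, distance_count: str = "all") -> SubPathway:
    """Two-step starting-node selection.

    Step 1 takes metabolites with indegree zero within the sub-pathway plus
    those at maximal backward BFS distance from the product.  A dry
    propagation run with unit activities follows; step 2 repeatedly adds the
    farthest not-yet-covered metabolite (ties broken lexicographically) until
    the dry run covers every node — this completes coverage of feedback
    cycles that contain no indegree-zero metabolite.
    """
    g = sub.graph
    mets = sub.metabolite_nodes
    if not sub.reaction_nodes or mets == {sub.product}:
        sub.starting_nodes = set()
        sub.valid = False
        return sub

    depths = backward_depths(sub, count=distance_count)
    candidates = {m for m in mets if m != sub.product}
    starting = {m for m in candidates if g.in_degree(m) == 0}
    reachable = {m: d for m, d in depths.items() if m in candidates}
    if reachable:
        dmax = max(reachable.values())
        starting |= {m for m, d in reachable.items() if d == dmax}

    visited = dry_run_visits(sub, starting)
    todo = set(g.nodes) - visited
    while todo:
        uncovered_mets = sorted(m for m in todo if m in candidates)
        if not uncovered_mets:
            # only reactions left uncovered: their substrates are covered but
            # blocked; seed the lexicographically first substrate of one
            r = sorted(todo)[0]
            uncovered_mets = sorted(g.predecessors(r))
        # farthest first; unreachable (no finite depth) treated as farthest
        uncovered_mets.sort(key=lambda m: (-depths.get(m, 10 ** 9), m))
        starting.add(uncovered_mets[0])
        visited = dry_run_visits(sub, starting)
        todo = set(g.nodes) - visited

    sub.starting_nodes = starting
    sub.valid = True
    return sub


def decompose_pathway(pathway: MetabolicPathway,
                      distance_count: str = "all") -> list[SubPathway]:
    """One sub-pathway (with starting nodes) per producible metabolite."""
    out = []
    for m in sorted(pathway.metabolite_nodes):
        if pathway.graph.in_degree(m) >= 1:
            sub = extract_subpathway(pathway, m)
            sub = define_starting_nodes(sub, distance_count=distance_count)
            out.append(sub)
    return out


# ---------------------------------------------------------------------------
# Sub-pathway (de)serialization
# ---------------------------------------------------------------------------


def subpathway_to_dict(sub: SubPathway) -> dict:
    g = sub.graph
    nodes = []
    for n in sorted(g.nodes):
        d = g.nodes[n]
        rec = {"id": n, "kind": d["kind"]}
        if d["kind"] == REACTION:
            rule = d.get("gene_rule")
            rec["gene_rule"] = format_rule(rule) if rule is not None else ""
            rec["reversible"] = bool(d.get("reversible", False))
            rec["is_reverse"] = bool(d.get("is_reverse", False))
        nodes.append(rec)
    return {
        "product": sub.product,
        "name": sub.name,
        "valid": sub.valid,
        "starting_nodes": sorted(sub.starting_nodes),
        "nodes": nodes,
        "edges": sorted([u, v] for u, v in g.edges()),
    }


def subpathway_from_dict(doc: dict) -> SubPathway:
    g = nx.DiGraph()
    for rec in doc["nodes"]:
        attrs = {"kind": rec["kind"]}
        if rec["kind"] == REACTION:
            txt = rec.get("gene_rule", "")
            attrs["gene_rule"] = parse_rule(txt) if txt else None
            attrs["reversible"] = bool(rec.get("reversible", False))
            attrs["is_reverse"] = bool(rec.get("is_reverse", False))
        g.add_node(rec["id"], **attrs)
    g.add_edges_from((u, v) for u, v in doc["edges"])
    return SubPathway(product=doc["product"], graph=g,
                      starting_nodes=set(doc["starting_nodes"]),
                      valid=bool(doc.get("valid", True)),
                      name=doc.get("name", ""))


def save_subpathways(subs: list[SubPathway], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([subpathway_to_dict(s) for s in subs], fh, indent=1, sort_keys=True)


def load_subpathways(path: str | Path) -> list[SubPathway]:
    with open(path) as fh:
        return [subpathway_from_dict(d) for d in json.load(fh)]
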