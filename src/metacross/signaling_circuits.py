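"""Signaling-circuit activity: receptor-to-effector signal transduction.

A circuit is a signed directed graph from one receptor (indegree 0) to one
effector (outdegree 0); every node carries a gene rule giving its protein
abundance proxy ``v_n`` in [0, 1] (min/max convention shared with the
metabolic module).  The signal at the receptor is its own node value; any
downstream node transmits

    S_n = v_n * (1 - prod_{a in activators}(1 - S_a)) * prod_{i in inhibitors}(1 - S_i)

so parallel activating inputs combine as a probabilistic OR and any fully
active inhibitor silences the node.  On chains this reduces to the product
of node values.  Cyclic circuits are iterated to a fixed point.
"""

from __future__ import annotations

import json
import statistics
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from ._generules import Rule, all_genes, evaluate_rule, format_rule, parse_rule

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


class CircuitValidationError(ValueError):
    pass


class SignalConvergenceError(RuntimeError):
    pass


@dataclass
class SignalingCircuit:
    """Signed directed graph with node gene rules, one receptor, one effector."""

    graph: nx.DiGraph  # node attr gene_rule; edge attr sign in {+1, -1}
    receptor: str
    effector: str
    name: str = "circuit"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        g = self.graph
        if self.receptor not in g or self.effector not in g:
            raise CircuitValidationError("receptor/effector missing from graph")
        if g.in_degree(self.receptor) != 0:
            raise CircuitValidationError(f"receptor {self.receptor!r} has incoming edges")
        if g.out_degree(self.effector) != 0:
            raise CircuitValidationError(f"effector {self.effector!r} has outgoing edges")
        reachable = set(nx.descendants(g, self.receptor)) | {self.receptor}
        if reachable != set(g.nodes):
            missing = sorted(set(g.nodes) - reachable)
            raise CircuitValidationError(
                f"nodes unreachable from receptor: {missing}")
        for u, v, d in g.edges(data=True):
            if d.get("sign") not in (1, -1):
                raise CircuitValidationError(f"edge {u!r}->{v!r} lacks a +/-1 sign")

    def gene_rule(self, node: str) -> Rule:
        return self.graph.nodes[node]["gene_rule"]

    @property
    def genes(self) -> set[str]:
        return all_genes(self.gene_rule(n) for n in self.graph.nodes)


def node_values(circuit: SignalingCircuit, expr: Mapping[str, float],
                missing: str = "median") -> dict[str, float]:
    fill = None
    if missing == "median":
        fill = statistics.median(expr.values()) if len(expr) else 0.0
    return {n: evaluate_rule(circuit.gene_rule(n), expr, missing=fill)
            for n in circuit.graph.nodes}


def circuit_activity(circuit: SignalingCircuit, expr: Mapping[str, float],
                     tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                     missing: str = "median") -> float:
    """Effector signal for one expression profile."""
    g = circuit.graph
    v = node_values(circuit, expr, missing=missing)
    order = _bfs_order(circuit)
    signal = {n: 0.0 for n in g.nodes}
    signal[circuit.receptor] = v[circuit.receptor]
    for _ in range(max_iter):
        delta = 0.0
        for n in order:
            if n == circuit.receptor:
                continue
            act = 1.0
            inh = 1.0
            for pred in g.predecessors(n):
                if g.edges[pred, n]["sign"] > 0:
                    act *= 1.0 - signal[pred]
                else:
                    inh *= 1.0 - signal[pred]
            new = v[n] * (1.0 - act) * inh
            delta = max(delta, abs(new - signal[n]))
            signal[n] = new
        if delta < tol:
            return signal[circuit.effector]
    raise SignalConvergenceError(
        f"circuit {circuit.name!r} did not converge after {max_iter} sweeps")


def _bfs_order(circuit: SignalingCircuit) -> list[str]:
    order = []
    seen = {circuit.receptor}
    queue = deque([circuit.receptor])
    while queue:
        n = queue.popleft()
        order.append(n)
        for s in sorted(circuit.graph.successors(n)):
            if s not in seen:
                seen.add(s)
                queue.append(s)
    return order


def activity_matrix(circuits: list[SignalingCircuit], expr_matrix: pd.DataFrame,
                    tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                    missing: str = "median") -> pd.DataFrame:
    """Circuits x samples matrix of effector signals in [0, 1]."""
    rows = {}
    for c in circuits:
        rows[c.name] = [circuit_activity(c, expr_matrix[s].to_dict(), tol=tol,
                                         max_iter=max_iter, missing=missing)
                        for s in expr_matrix.columns]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(expr_matrix.columns))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def circuit_to_dict(circuit: SignalingCircuit) -> dict:
    g = circuit.graph
    return {
        "name": circuit.name,
        "receptor": circuit.receptor,
        "effector": circuit.effector,
        "nodes": [{"id": n, "gene_rule": format_rule(g.nodes[n]["gene_rule"])}
                  for n in sorted(g.nodes)],
        "edges": [[u, v, int(d["sign"])] for u, v, d in
                  sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))],
    }


def circuit_from_dict(doc: dict) -> SignalingCircuit:
    g = nx.DiGraph()
    for rec in doc["nodes"]:
        g.add_node(rec["id"], gene_rule=parse_rule(rec["gene_rule"]))
    for u, v, sign in doc["edges"]:
        g.add_edge(u, v, sign=int(sign))
    return SignalingCircuit(g, receptor=doc["receptor"], effector=doc["effector"],
                            name=doc.get("name", "circuit"))


def write_circuit(circuit: SignalingCircuit, path: str | Path,
                  dialect: str = "json") -> None:
    path = Path(path)
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(circuit_to_dict(circuit), fh, indent=1, sort_keys=True)
    elif dialect == "graphml":
        g = nx.DiGraph()
        for n in circuit.graph.nodes:
            g.add_node(n, gene_rule=format_rule(circuit.gene_rule(n)))
        for u, v, d in circuit.graph.edges(data=True):
            g.add_edge(u, v, sign=int(d["sign"]))
        g.graph.update(name=circuit.name, receptor=circuit.receptor,
                       effector=circuit.effector)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown circuit dialect {dialect!r}")


def read_circuit(path: str | Path, dialect: str = "json") -> SignalingCircuit:
    path = Path(path)
    if dialect == "json":
        with open(path) as fh:
            return circuit_from_dict(json.load(fh))
    if dialect == "graphml":
        raw = nx.read_graphml(path)
        g = nx.DiGraph()
        for n, d in raw.nodes(data=True):
            g.add_node(n, gene_rule=parse_rule(d["gene_rule"]))
        for u, v, d in raw.edges(data=True):
            g.add_edge(u, v, sign=int(d["sign"]))
        return SignalingCircuit(g, receptor=raw.graph["receptor"],
                                effector=raw.graph["effector"],
                                name=raw.graph.get("name", path.stem))
    raise ValueError(f"unknown circuit dialect {dialect!r}")
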