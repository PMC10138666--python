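"""Flux propagation: per-sample metabolite production from gene expression.

The model reads gene expression (rescaled to [0, 1]) as a proxy for enzyme
capacity and propagates a normalized flux through each product's sub-pathway:

1. every metabolite distributes its current amount to the reactions that
   consume it, proportionally to their enzyme activities
   ``w(m_s, r_i) = m_s * a(r_i) / sum_j a(r_j)``;
2. a reaction converts the least-available substrate at its enzyme capacity,
   ``w(r_i, m_p) = a(r_i) * min_s w(m_s, r_i)`` (a Michaelis-Menten-like
   saturating variant ``a * s / (s + K)`` is available behind a flag);
3. each metabolite is updated with the average of its inflows and its own
   previous amount, ``m_p <- (m_p + sum_i w(r_i, m_p)) / n`` with
   ``n = indegree + 1``, whose fixed point is the arithmetic mean of the
   inflows — non-saturating and stable on feedback loops.

Sweeps over the sub-pathway repeat until the largest change in any amount or
flow falls below a tolerance; starting metabolites are replenished to the
initial value every sweep (amounts are activities, not masses).  All values
stay in [0, 1] whenever the inputs do.
"""

from __future__ import annotations

import logging
import statistics
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._generules import evaluate_rule
from .pathway_model import SubPathway

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


class PropagationError(RuntimeError):
    """Propagation failed to converge; carries the last state."""

    def __init__(self, message: str, state: "PropagationState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass
class PropagationState:
    """Per-node amounts and per-edge flows during iteration."""

    m: dict[str, float] = field(default_factory=dict)
    w_in: dict[tuple[str, str], float] = field(default_factory=dict)   # (metabolite, reaction)
    w_out: dict[tuple[str, str], float] = field(default_factory=dict)  # (reaction, metabolite)
    iteration: int = 0
    delta: float = float("inf")


# ---------------------------------------------------------------------------
# Reaction activities from gene rules
# ---------------------------------------------------------------------------


def reaction_activity(sub: SubPathway, expr: Mapping[str, float],
                      missing: str = "median") -> dict[str, float]:
    """Evaluate every reaction's gene rule on one expression profile.

    AND connectives take the minimum of member values, OR the maximum.
    Genes absent from ``expr`` are imputed with the profile median
    (``missing='median'``) or raise (``missing='error'``).  A reaction with
    no gene rule is treated as non-enzymatic with activity 1.
    """
    if missing == "median":
        fill = statistics.median(expr.values()) if len(expr) else 0.0
    elif missing == "error":
        fill = None
    else:
        raise ValueError("missing must be 'median' or 'error'")
    acts: dict[str, float] = {}
    warned = False
    for r in sorted(sub.reaction_nodes):
        rule = sub.gene_rule(r)
        if rule is None:
            if not warned:
                logger.warning("reaction %s has no gene rule; treated as "
                               "non-enzymatic (activity 1)", r)
                warned = True
            acts[r] = 1.0
        else:
            acts[r] = evaluate_rule(rule, expr, missing=fill)
    return acts


# ---------------------------------------------------------------------------
# The three update rules
# ---------------------------------------------------------------------------


def distribute_substrate(state: PropagationState, m_s: str,
                         activities: Mapping[str, float], sub: SubPathway) -> None:
    """Split a metabolite's amount across its consuming reactions
    proportionally to their activities; all-zero consumers get zero flow."""
    consumers = sub.n_plus(m_s)
    total = sum(activities[r] for r in consumers)
    amount = state.m.get(m_s, 0.0)
    for r in consumers:
        state.w_in[(m_s, r)] = amount * activities[r] / total if total > 0 else 0.0


def reaction_rate(state: PropagationState, r_i: str,
                  activities: Mapping[str, float], sub: SubPathway,
                  rate_rule: str = "min", mm_k: float = 0.5) -> float:
    """Outflow of one reaction, limited by its scarcest substrate inflow."""
    substrates = sub.n_minus(r_i)
    if not substrates:
        raise PropagationError(f"reaction {r_i!r} has no substrate edge", state)
    s = min(state.w_in.get((m, r_i), 0.0) for m in substrates)
    a = activities[r_i]
    if rate_rule == "min":
        w = a * s
    elif rate_rule == "mm":
        w = a * s / (s + mm_k) if s > 0 else 0.0
    else:
        raise ValueError("rate_rule must be 'min' or 'mm'")
    for m_p in sub.n_plus(r_i):
        state.w_out[(r_i, m_p)] = w
    return w


def update_product(state: PropagationState, m_p: str, sub: SubPathway) -> float:
    """Average a metabolite's previous amount with its reaction inflows.

    With ``n = indegree + 1`` the fixed point under stationary inflows is the
    arithmetic mean of the inflows.
    """
    producers = sub.n_minus(m_p)
    n = len(producers) + 1
    inflow = sum(state.w_out.get((r, m_p), 0.0) for r in producers)
    state.m[m_p] = (state.m.get(m_p, 0.0) + inflow) / n
    return state.m[m_p]


# ---------------------------------------------------------------------------
# Propagation driver
# ---------------------------------------------------------------------------


def sweep_order(sub: SubPathway) -> list[str]:
    """Deterministic BFS order from the starting nodes (lexicographic ties);
    nodes unreached by plain BFS are appended sorted."""
    g = sub.graph
    order: list[str] = []
    seen: set[str] = set()
    queue = deque(sorted(sub.starting_nodes))
    seen.update(queue)
    while queue:
        node = queue.popleft()
        order.append(node)
        for nxt in sorted(g.successors(node)):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    for node in sorted(set(g.nodes) - seen):
        order.append(node)
    return order


def propagate(sub: SubPathway, activities: Mapping[str, float],
              init_value: float = 1.0, tol: float = DEFAULT_TOL,
              max_iter: int = DEFAULT_MAX_ITER, rate_rule: str = "min",
              mm_k: float = 0.5) -> tuple[float, PropagationState]:
    """Iterate the three update rules until the flux stabilizes.

    Returns the converged product amount and the final state; raises
    :class:`PropagationError` if the largest change still exceeds ``tol``
    after ``max_iter`` sweeps.
    """
    if not sub.valid or not sub.starting_nodes:
        raise PropagationError(
            f"sub-pathway for {sub.product!r} has no starting nodes", None)
    order = sweep_order(sub)
    kind = {n: sub.graph.nodes[n]["kind"] for n in order}
    state = PropagationState()
    for s in sub.starting_nodes:
        state.m[s] = init_value

    for iteration in range(1, max_iter + 1):
        delta = 0.0
        for node in order:
            if kind[node] == "metabolite":
                if node in sub.starting_nodes:
                    state.m[node] = init_value
                elif sub.graph.in_degree(node) > 0:
                    old = state.m.get(node, 0.0)
                    new = update_product(state, node, sub)
                    delta = max(delta, abs(new - old))
                if sub.graph.out_degree(node) > 0:
                    old_flows = {r: state.w_in.get((node, r), 0.0)
                                 for r in sub.n_plus(node)}
                    distribute_substrate(state, node, activities, sub)
                    for r, ov in old_flows.items():
                        delta = max(delta, abs(state.w_in[(node, r)] - ov))
            else:
                old_flows = {m: state.w_out.get((node, m), 0.0)
                             for m in sub.n_plus(node)}
                reaction_rate(state, node, activities, sub,
                              rate_rule=rate_rule, mm_k=mm_k)
                for m, ov in old_flows.items():
                    delta = max(delta, abs(state.w_out[(node, m)] - ov))
        state.iteration = iteration
        state.delta = delta
        if delta < tol:
            return state.m.get(sub.product, 0.0), state
    raise PropagationError(
        f"propagation on sub-pathway {sub.product!r} did not converge "
        f"(delta={state.delta:.3g} after {max_iter} sweeps)", state)


def acyclic_fixed_point(sub: SubPathway, activities: Mapping[str, float],
                        init_value: float = 1.0) -> float:
    """One-pass topological-order evaluation (oracle for acyclic sub-pathways).

    Metabolites take the mean of their inflows (starting nodes take
    ``init_value``); reactions apply the multiplicative-min rate.
    """
    import networkx as nx

    g = sub.graph
    m_val: dict[str, float] = {}
    w_in: dict[tuple[str, str], float] = {}
    w_out: dict[tuple[str, str], float] = {}
    for node in nx.topological_sort(g):
        if g.nodes[node]["kind"] == "metabolite":
            if node in sub.starting_nodes:
                m_val[node] = init_value
            else:
                producers = sub.n_minus(node)
                m_val[node] = (sum(w_out.get((r, node), 0.0) for r in producers)
                               / len(producers)) if producers else 0.0
            consumers = sub.n_plus(node)
            total = sum(activities[r] for r in consumers)
            for r in consumers:
                w_in[(node, r)] = (m_val[node] * activities[r] / total
                                   if total > 0 else 0.0)
        else:
            s = min(w_in.get((ms, node), 0.0) for ms in sub.n_minus(node))
            for mp in sub.n_plus(node):
                w_out[(node, mp)] = activities[node] * s
    return m_val.get(sub.product, 0.0)


# ---------------------------------------------------------------------------
# Production matrix
# ---------------------------------------------------------------------------


def production_matrix(subs: list[SubPathway], expr_matrix: pd.DataFrame,
                      init_value: float = 1.0, tol: float = DEFAULT_TOL,
                      max_iter: int = DEFAULT_MAX_ITER, rate_rule: str = "min",
                      mm_k: float = 0.5, missing: str = "median") -> pd.DataFrame:
    """Converged production value per (metabolite, sample).

    ``expr_matrix`` is genes x samples in [0, 1]; the result is metabolites x
    samples in the input column order.  Cells are computed independently;
    any non-convergent cell aborts with the full list of offending pairs.
    """
    vals = expr_matrix.to_numpy(dtype=float)
    if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
        raise ValueError("expression values must lie in [0, 1]")
    samples = list(expr_matrix.columns)
    out = np.zeros((len(subs), len(samples)))
    failed: list[tuple[str, str]] = []
    for j, sample in enumerate(samples):
        expr = expr_matrix[sample].to_dict()
        for i, sub in enumerate(subs):
            acts = reaction_activity(sub, expr, missing=missing)
            try:
                out[i, j], state = propagate(sub, acts, init_value=init_value,
                                             tol=tol, max_iter=max_iter,
                                             rate_rule=rate_rule, mm_k=mm_k)
                logger.debug("cell (%s, %s) converged in %d sweeps",
                             sub.product, sample, state.iteration)
            except PropagationError:
                failed.append((sub.product, sample))
    if failed:
        raise PropagationError(
            f"propagation did not converge for {len(failed)} cells: "
            f"{failed[:10]}{'...' if len(failed) > 10 else ''}")
    return pd.DataFrame(out, index=[s.product for s in subs], columns=samples)
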