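"""Shared-gene Fisher control and function/hallmark annotation.

A metabolite that predicts a circuit's activity could do so trivially
because the circuit and the metabolite's producing sub-pathway share enzyme
genes.  To discard that explanation, predictions are cross-tabulated as
{relevant, non-relevant} x {has shared genes, no shared genes} and tested
with a one-sided Fisher exact test for enrichment of shared genes among
relevant predictions.  Relevant circuits then propagate their effector
function terms and cancer-hallmark labels to the metabolites that regulate
them, via user-supplied mapping tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .gp_relevance import CVReport  # noqa: F401  (documented input type)
from .pathway_model import SubPathway
from .signaling_circuits import SignalingCircuit

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Counts for {relevant, non-relevant} x {shared genes, none}."""

    a: int  # relevant, shared
    b: int  # relevant, not shared
    c: int  # non-relevant, shared
    d: int  # non-relevant, not shared

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency cells must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def shared_genes(circuit: SignalingCircuit, sub: SubPathway) -> set[str]:
    """Genes used both as circuit proteins and as sub-pathway enzymes."""
    return circuit.genes & sub.enzyme_genes


def build_contingency(relevance: pd.DataFrame,
                      gene_overlap: Mapping[tuple[str, str], int],
                      r2_threshold: float = 0.5,
                      top_k: int = 1) -> ContingencyTable2x2:
    """Cross-tabulate each circuit's top-k predictive metabolites.

    ``relevance`` is the table from :func:`metacross.gp_relevance.relevance_ranking`;
    ``gene_overlap`` maps (metabolite, circuit) -> shared-gene count.
    Relevant means circuit test R^2 strictly above ``r2_threshold`` (a score
    exactly at the threshold counts as non-relevant); shared means >= 1
    common gene.
    """
    sel = relevance[relevance["rank"] <= top_k]
    a = b = c = d = 0
    for _, row in sel.iterrows():
        pair = (row["metabolite"], row["circuit"])
        has_shared = gene_overlap.get(pair, 0) >= 1
        relevant = row["circuit_test_r2"] > r2_threshold
        if relevant and has_shared:
            a += 1
        elif relevant:
            b += 1
        elif has_shared:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(table: ContingencyTable2x2,
                 alternative: str = "greater") -> float:
    """Fisher exact p-value via hypergeometric tail assembly (log-gamma based).

    ``greater`` tests enrichment of shared genes among relevant predictions;
    ``two_sided`` sums the probabilities of all tables at most as likely as
    the observed one.  An empty margin gives the degenerate p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0 or row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return 1.0
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, col1, row1)
    if alternative == "greater":
        return float(min(1.0, pmf[support >= a].sum()))
    if alternative == "two_sided":
        p_obs = pmf[support == a][0]
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))
    raise ValueError("alternative must be 'greater' or 'two_sided'")


def fisher_enumeration_oracle(table: ContingencyTable2x2,
                              alternative: str = "greater") -> float:
    """Brute-force Fisher p-value from exact binomial coefficients."""
    from math import comb

    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if n_total == 0 or row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return 1.0
    denom = comb(n_total, col1)
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    probs = {k: comb(row1, k) * comb(n_total - row1, col1 - k) / denom
             for k in range(lo, hi + 1)}
    if alternative == "greater":
        return min(1.0, sum(p for k, p in probs.items() if k >= a))
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def annotate_circuits(relevance: pd.DataFrame,
                      function_map: pd.DataFrame,
                      hallmark_map: pd.DataFrame) -> dict:
    """Propagate circuit terms to the metabolites that regulate them.

    Mapping tables have columns (circuit, term).  Each metabolite relevant
    to a circuit inherits the union of that circuit's terms; aggregate
    percentages are computed over all (metabolite, term) incidences.
    Circuits without coverage in a map are logged.
    """
    fmap = _map_to_dict(function_map)
    hmap = _map_to_dict(hallmark_map)
    rel = relevance[relevance["relevant"]]
    uncovered = sorted({c for c in rel["circuit"].unique()
                        if c not in fmap and c not in hmap})
    if uncovered:
        logger.warning("no function/hallmark terms for circuits: %s", uncovered)
    per_met_functions: dict[str, set[str]] = {}
    per_met_hallmarks: dict[str, set[str]] = {}
    for _, row in rel.iterrows():
        met, circ = row["metabolite"], row["circuit"]
        per_met_functions.setdefault(met, set()).update(fmap.get(circ, set()))
        per_met_hallmarks.setdefault(met, set()).update(hmap.get(circ, set()))
    return {
        "functions": {m: sorted(s) for m, s in per_met_functions.items()},
        "hallmarks": {m: sorted(s) for m, s in per_met_hallmarks.items()},
        "function_percentages": _percentages(per_met_functions),
        "hallmark_percentages": _percentages(per_met_hallmarks),
    }


def _map_to_dict(table: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    ccol, tcol = table.columns[0], table.columns[1]
    for _, row in table.iterrows():
        out.setdefault(str(row[ccol]), set()).add(str(row[tcol]))
    return out


def _percentages(per_met: dict[str, set[str]]) -> dict[str, float]:
    counts: dict[str, int] = {}
    for terms in per_met.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {t: 100.0 * c / total for t, c in sorted(counts.items())}
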