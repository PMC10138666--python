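"""Differential metabolite production: paired t-tests with BH-FDR control.

Tumor/normal pairs are compared metabolite-wise with a paired Student
t-test; p-values are corrected across all metabolites in the run with the
Benjamini-Hochberg step-up procedure.  An overlap report compares the
detected differentially produced metabolites (DPMs) against an external
differential-abundance list (e.g. a metabolomics study).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    Degenerate cases: zero-variance differences give p = 0 when the mean
    difference is non-zero (all pairs moved identically) and p = 1 when it
    is zero (no change at all).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean), df, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def bh_fdr(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def differential_production(prod: pd.DataFrame,
                            pairing: Sequence[tuple[str, str]],
                            alpha: float = 0.05) -> pd.DataFrame:
    """Paired tumor-vs-normal test per metabolite with BH correction.

    ``prod`` is metabolites x samples; ``pairing`` lists
    (tumor sample, normal sample) columns.  Returns one row per metabolite:
    mean_diff, t, df, p, q, significant (q < alpha).
    """
    tumor_ids = [t for t, _ in pairing]
    normal_ids = [n for _, n in pairing]
    missing = [s for s in tumor_ids + normal_ids if s not in prod.columns]
    if missing:
        raise ValueError(f"samples missing from production matrix: {sorted(set(missing))}")
    tumor = prod[tumor_ids].to_numpy(dtype=float)
    normal = prod[normal_ids].to_numpy(dtype=float)
    rows = []
    for i, met in enumerate(prod.index):
        t, df, p = paired_t_test(tumor[i], normal[i])
        rows.append((met, float(tumor[i].mean() - normal[i].mean()), t, df, p))
    table = pd.DataFrame(rows, columns=["metabolite", "mean_diff", "t", "df", "p"])
    table["q"] = bh_fdr(table["p"])
    table["significant"] = table["q"] < alpha
    return table.set_index("metabolite")


def overlap_report(dpms: set[str], external_diff: set[str]) -> dict:
    """Intersection of detected DPMs with an external differential list.

    Returns raw counts plus the fraction with respect to either denominator;
    the caller chooses which denominator to report.
    """
    dpms = set(dpms)
    external_diff = set(external_diff)
    overlap = dpms & external_diff
    return {
        "n_overlap": len(overlap),
        "n_dpms": len(dpms),
        "n_external": len(external_diff),
        "frac_of_dpms": len(overlap) / len(dpms) if dpms else 0.0,
        "frac_of_external": len(overlap) / len(external_diff) if external_diff else 0.0,
        "overlap": sorted(overlap),
    }
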