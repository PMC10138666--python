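"""Expression post-normalization and loss-of-function masking.

The pipeline consumes matrices that are already library-size normalized and
batch corrected; the steps owned here are the log transform, upper-quantile
truncation, [0, 1] rescale, quantile normalization (for metabolomics-style
tables), and the attenuation of genes carrying predicted loss-of-function
variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

VOTE_COLUMNS = 5  # SIFT / Polyphen2 / FATHMM / MutationTaster / MutationAssessor-style calls


def normalize_expression(matrix: pd.DataFrame,
                         trunc_quantile: float = 0.99) -> pd.DataFrame:
    """log2(x+1), per-gene upper clip at ``trunc_quantile``, per-gene min-max
    rescale to [0, 1].  Rows are genes, columns samples; constant genes map
    to all zeros.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("expression values must be non-negative")
    if not 0 < trunc_quantile <= 1:
        raise ValueError("trunc_quantile must lie in (0, 1]")
    logged = np.log2(vals + 1.0)
    hi = np.quantile(logged, trunc_quantile, axis=1, keepdims=True)
    clipped = np.minimum(logged, hi)
    lo = clipped.min(axis=1, keepdims=True)
    rng = clipped.max(axis=1, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (clipped - lo) / rng
    scaled[np.broadcast_to(rng == 0, scaled.shape)] = 0.0
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def lof_mask(matrix: pd.DataFrame, variants: pd.DataFrame,
             min_damaging: int = 3, factor: float = 0.001) -> pd.DataFrame:
    """Attenuate expression of genes with predicted loss-of-function variants.

    ``variants`` rows are (sample, gene, five binary predictor calls); a
    (sample, gene) cell whose damaging-vote count reaches ``min_damaging``
    is multiplied by ``factor`` (default 0.001, emulating a non-expressed
    enzyme).  Rows naming unknown genes or samples are skipped with a logged
    count.
    """
    if not 1 <= min_damaging <= VOTE_COLUMNS:
        raise ValueError(f"min_damaging must lie in 1..{VOTE_COLUMNS}")
    if not 0 < factor < 1:
        raise ValueError("factor must lie in (0, 1)")
    sample_col, gene_col = variants.columns[0], variants.columns[1]
    call_cols = list(variants.columns[2:2 + VOTE_COLUMNS])
    if len(call_cols) != VOTE_COLUMNS:
        raise ValueError(f"variant table must carry {VOTE_COLUMNS} call columns")
    calls = variants[call_cols].to_numpy()
    if not np.isin(calls, (0, 1)).all():
        raise ValueError("predictor calls must be binary")
    votes = calls.sum(axis=1)

    out = matrix.copy()
    skipped = 0
    masked = 0
    for (sample, gene, nvotes) in zip(variants[sample_col], variants[gene_col], votes):
        if gene not in out.index or sample not in out.columns:
            skipped += 1
            continue
        if nvotes >= min_damaging:
            out.loc[gene, sample] *= factor
            masked += 1
    if skipped:
        logger.warning("lof_mask skipped %d variant rows with unknown gene/sample",
                       skipped)
    logger.info("lof_mask attenuated %d (sample, gene) cells", masked)
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization (ties averaged).

    After the operation every column shares the same value distribution: the
    row-wise means of the per-column sorted values.  Single-column input is
    returned unchanged.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    n_rows, n_cols = vals.shape
    if n_cols <= 1:
        return matrix.copy()
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    positions = np.arange(1, n_rows + 1, dtype=float)
    for j in range(n_cols):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
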