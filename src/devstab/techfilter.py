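"""Technical-error filter: keep genes whose twin differences exceed measurement noise.

Technical quadruplicates (one RNA pool split into four libraries) yield, per
gene, six pairwise absolute log-expression differences that estimate pure
measurement error.  For each gene the absolute twin-pair differences are
compared with those six technical differences by a one-sided Wilcoxon
rank-sum test (H1: twin differences stochastically greater); only genes
significant at alpha = 0.01 (raw p, no multiple-testing correction) enter the
variation analyses.  Genes expressed at low levels typically fail this
filter, as their apparent variation is indistinguishable from noise.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .expr import ExpressionMatrix
from .pairs import PairDesign


def abs_pair_differences(m: ExpressionMatrix, pairs: PairDesign) -> pd.DataFrame:
    """Per-gene |x_j^i - x_j^k| for every pair; one column per pair, symmetric in (i, k)."""
    missing = [s for s in pairs.sample_ids() if s not in m.values.columns]
    if missing:
        raise ValueError(f"pair members missing from matrix: {missing}")
    cols = {}
    for idx, p in enumerate(pairs):
        cols[f"{p.i}|{p.k}"] = (m.values[p.i] - m.values[p.k]).abs()
    return pd.DataFrame(cols, index=m.gene_ids)


def technical_error(
    m: ExpressionMatrix, technical_pairs: PairDesign, require_four: bool = True
) -> pd.Series:
    """Per-gene technical error: mean of the pairwise |differences| among replicates.

    With the standard quadruplicate design this is the mean over all
    C(4,2) = 6 unordered combinations.  ``require_four=False`` lifts the
    replicate-count check for non-standard designs.
    """
    ids = sorted(set(technical_pairs.sample_ids()))
    if require_four and len(ids) != 4:
        raise ValueError(
            f"expected 4 technical replicates (6 pairs), got {len(ids)}; "
            "pass require_four=False to override"
        )
    diffs = abs_pair_differences(m, technical_pairs)
    return diffs.mean(axis=1).rename("technical_error")


def rank_sum_greater(a, b, method: str = "auto") -> float:
    """One-sided Mann-Whitney p for H1: sample ``a`` stochastically greater than ``b``.

    ``method="auto"`` uses the exact null distribution when the smaller
    sample has <= 8 observations and there are no ties across the pooled
    sample, and the mid-rank normal approximation with continuity and tie
    correction otherwise.  Degenerate all-tied input returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_greater requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method, use_continuity=True)
    return float(res.pvalue)


def filter_by_technical_error(
    m: ExpressionMatrix,
    twin_pairs: PairDesign,
    m_technical: ExpressionMatrix,
    technical_pairs: PairDesign,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene one-sided rank-sum test of twin vs technical |differences|.

    The twin sample holds one absolute difference per twin pair; the
    technical sample holds the six individual replicate-pair differences
    (the averaged technical error is reported alongside as a per-gene
    summary, but the test is run against the six raw differences).  Returns
    a DataFrame indexed by gene with columns ``n_pairs, mean_twin_diff,
    technical_error, p, passed`` where ``passed`` means p < alpha.

    Expects a matrix already restricted to low-expression-filter survivors;
    shared genes between the twin and technical matrices are tested.
    """
    if len(twin_pairs) < 2:
        raise ValueError("need at least 2 twin pairs to test against technical error")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    twin_diffs = abs_pair_differences(m, twin_pairs)
    tech_diffs = abs_pair_differences(m_technical, technical_pairs)
    genes = twin_diffs.index.intersection(tech_diffs.index)
    if genes.empty:
        raise ValueError("no shared genes between twin and technical matrices")
    twin_arr = twin_diffs.loc[genes].to_numpy()
    tech_arr = tech_diffs.loc[genes].to_numpy()
    ps = np.array(
        [rank_sum_greater(twin_arr[j], tech_arr[j]) for j in range(len(genes))]
    )
    out = pd.DataFrame(
        {
            "n_pairs": len(twin_pairs),
            "mean_twin_diff": twin_arr.mean(axis=1),
            "technical_error": tech_arr.mean(axis=1),
            "p": ps,
            "passed": ps < alpha,
        },
        index=genes,
    )
    return out


def surviving_genes(filter_result: pd.DataFrame) -> pd.Index:
    """Genes whose twin variation significantly exceeds technical error."""
    return filter_result.index[filter_result["passed"]]
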