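"""Per-gene expression stability, expression-level bias correction, and
micro/macroevolutionary expression variation.

A gene's raw variation is the mean absolute log-expression difference over a
set of pairs (twin pairs for stability, sex-matched cross-population pairs
for intraspecies variation, 1:1 ortholog mean-profile differences for
interspecies variation).  Because variation depends non-linearly on absolute
expression level, a running-median correction is applied: genes are sorted by
mean expression, the median variation within a sliding window (default 501
genes, i.e. +/-250 neighbours) is subtracted, and windows near the edges
shrink symmetrically so both sides hold equal gene counts.  Corrected values
may be negative; they are expression-level-free variation scores whose ranks
are compared across cohorts with Spearman correlation.

Gene variation tables are plain DataFrames indexed by gene id with columns
``mean_expr`` (mean log expression over the cohort), ``raw`` and, after
correction, ``corrected``; the cohort label is stored in ``df.attrs["cohort"]``.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expr import ExpressionMatrix
from .pairs import PairDesign
from .techfilter import abs_pair_differences

logger = logging.getLogger(__name__)


def gene_variation(m: ExpressionMatrix, pairs: PairDesign, cohort: str = "twin") -> pd.DataFrame:
    """Per-gene raw variation: mean |x_j^i - x_j^k| over all pairs.

    ``mean_expr`` is the mean log expression over every individual appearing
    in the pair design (the same convention for twin, intraspecies and
    interspecies tables).
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    diffs = abs_pair_differences(m, pairs)
    samples = pairs.sample_ids()
    table = pd.DataFrame(
        {
            "mean_expr": m.values[samples].mean(axis=1),
            "raw": diffs.mean(axis=1),
        },
        index=m.gene_ids,
    )
    table.attrs["cohort"] = cohort
    return table


def _running_median(raw_sorted: np.ndarray, window: int) -> np.ndarray:
    """Running median with symmetric shrink at the edges.

    Gene i uses min(i, n-1-i, (window-1)//2) neighbours per side, so the
    first and last genes have windows of size 1 (median = their own value).
    """
    n = raw_sorted.size
    half = (window - 1) // 2
    med = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        med[i] = np.median(raw_sorted[i - h : i + h + 1])
    return med


def running_median_correct(table: pd.DataFrame, window: int = 501) -> pd.DataFrame:
    """Subtract the running median of variation among similarly expressed genes.

    Genes are sorted by ``mean_expr`` (ties broken by gene id for
    determinism); each gene's window covers +/-(window-1)//2 neighbours,
    shrunk symmetrically at the edges.  Returns a copy of the table in the
    original gene order with added ``running_median`` and ``corrected``
    columns (corrected = raw - running median; may be negative).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if not {"mean_expr", "raw"} <= set(table.columns):
        raise ValueError("table needs 'mean_expr' and 'raw' columns")
    n = len(table)
    if n == 0:
        out = table.copy()
        out["running_median"] = pd.Series(dtype=float)
        out["corrected"] = pd.Series(dtype=float)
        return out
    if window > n:
        warnings.warn(
            f"window {window} exceeds table size {n}; windows shrink accordingly"
        )
    order = table.assign(_gene=table.index).sort_values(
        ["mean_expr", "_gene"], kind="mergesort"
    )
    med = _running_median(order["raw"].to_numpy(dtype=float), window)
    order = order.drop(columns="_gene")
    order["running_median"] = med
    order["corrected"] = order["raw"] - med
    out = order.loc[table.index]
    out.attrs.update(table.attrs)
    return out


def intraspecies_gene_variation(
    m_pop_a: ExpressionMatrix,
    m_pop_b: ExpressionMatrix,
    cross_pairs: PairDesign,
    window: int = 501,
) -> pd.DataFrame:
    """Per-gene mean |difference| over all sex-matched cross-population pairs,
    running-median corrected exactly as for inbred twins."""
    if not m_pop_a.gene_ids.equals(m_pop_b.gene_ids):
        raise ValueError("population matrices must share an identical gene set")
    combined = ExpressionMatrix(
        pd.concat([m_pop_a.values, m_pop_b.values], axis=1),
        pd.concat([m_pop_a.metadata, m_pop_b.metadata]),
        m_pop_a.scale,
    )
    table = gene_variation(combined, cross_pairs, cohort="intraspecies")
    return running_median_correct(table, window=window)


# ------------------------------------------------------------------ orthology

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) hit file; only columns 1, 2, 11, 12 are used."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                rows.append(
                    (parts[0], parts[1], float(parts[10]), float(parts[11]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])


def _best_hits(hits: pd.DataFrame, evalue_cutoff: float, literal_inequality: bool) -> pd.Series:
    """Best subject per query: smallest e-value, ties by larger bitscore, then
    lexicographically smaller subject id."""
    if literal_inequality:
        passing = hits[hits["evalue"] > evalue_cutoff]
    else:
        passing = hits[hits["evalue"] < evalue_cutoff]
    if passing.empty:
        return pd.Series(dtype=object)
    ranked = passing.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ranked.groupby("qseqid", sort=True).first()
    return best["sseqid"]


def resolve_rbh(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_cutoff: float = 1e-5,
    literal_inequality: bool = False,
) -> pd.DataFrame:
    """Reciprocal-best-hit 1:1 ortholog map from two tabular hit sets.

    A pair (a, b) is retained iff b is a's best hit in A->B and a is b's
    best hit in B->A, both hits passing the e-value cutoff.  Hits are kept
    when e-value < cutoff; ``literal_inequality=True`` flips the comparison
    to e-value > cutoff for strict fidelity to an inverted published filter.
    Returns a two-column DataFrame (``gene_a``, ``gene_b``); each id appears
    at most once per column.
    """
    for df in (hits_ab, hits_ba):
        if not {"qseqid", "sseqid", "evalue", "bitscore"} <= set(df.columns):
            raise ValueError("hit tables need qseqid, sseqid, evalue, bitscore columns")
    best_ab = _best_hits(hits_ab, evalue_cutoff, literal_inequality)
    best_ba = _best_hits(hits_ba, evalue_cutoff, literal_inequality)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])


def interspecies_gene_variation(
    profile_a: pd.Series,
    profile_b: pd.Series,
    ortholog_map: pd.DataFrame,
    window: int = 501,
    cohort: str = "interspecies",
) -> pd.DataFrame:
    """|mean-profile difference| per 1:1 ortholog pair, corrected against the
    species-A (reference) mean expression.

    Profiles are replicate-averaged log expressions at each species'
    phylotypic stage; ortholog pairs whose ids are missing from either
    profile are dropped (count logged).
    """
    kept, dropped = [], 0
    for a, b in ortholog_map[["gene_a", "gene_b"]].itertuples(index=False):
        if a in profile_a.index and b in profile_b.index:
            kept.append((a, b))
        else:
            dropped += 1
    if dropped:
        logger.info("interspecies_gene_variation: dropped %d ortholog pairs missing "
                    "from a profile", dropped)
    if not kept:
        table = pd.DataFrame(columns=["mean_expr", "raw"])
        table.attrs["cohort"] = cohort
        return running_median_correct(table, window=window)
    a_ids = [a for a, _ in kept]
    b_ids = [b for _, b in kept]
    xa = profile_a.loc[a_ids].to_numpy(dtype=float)
    xb = profile_b.loc[b_ids].to_numpy(dtype=float)
    table = pd.DataFrame(
        {"mean_expr": xa, "raw": np.abs(xa - xb)}, index=pd.Index(a_ids, name="gene")
    )
    table.attrs["cohort"] = cohort
    return running_median_correct(table, window=window)


# --------------------------------------------------------- correlation & splits


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, chunk: int = 100_000) -> float:
    """Two-sided exact permutation p for Spearman's rho (all n! pairings)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    obs = abs(float(rxc @ ryc / denom))
    n = x.size
    count = 0
    total = 0
    buf = []
    for perm in itertools.permutations(range(n)):
        buf.append(perm)
        if len(buf) == chunk:
            stat = np.abs(rxc[np.array(buf)] @ ryc) / denom
            count += int(np.sum(stat >= obs - 1e-12))
            total += len(buf)
            buf = []
    if buf:
        stat = np.abs(rxc[np.array(buf)] @ ryc) / denom
        count += int(np.sum(stat >= obs - 1e-12))
        total += len(buf)
    return count / total


def stability_conservation_correlation(
    t1: pd.DataFrame, t2: pd.DataFrame, column: str = "corrected"
) -> tuple[float, float]:
    """Spearman rho between two gene variation tables on their shared genes.

    The p-value for the test of no correlation uses the large-sample t
    approximation; at the minimum allowed size (10 shared genes) an exact
    permutation p is computed instead.  Fewer than 10 shared genes are
    rejected.
    """
    for t in (t1, t2):
        if column not in t.columns:
            raise ValueError(f"table lacks column {column!r}")
    shared = t1.index.intersection(t2.index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared genes, got {len(shared)}")
    x = t1.loc[shared, column].to_numpy(dtype=float)
    y = t2.loc[shared, column].to_numpy(dtype=float)
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(shared) <= 10:
        p = _spearman_exact_p(x, y)
    else:
        p = float(res.pvalue)
    return rho, p


def expression_quintile_split(table: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a variation table into 5 groups by mean expression (ascending).

    Group sizes are floor(n/5) with the remainder distributed to the lowest
    expression groups, e.g. 12 genes -> (3, 3, 2, 2, 2).
    """
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 genes to form quintiles")
    order = table.assign(_gene=table.index).sort_values(
        ["mean_expr", "_gene"], kind="mergesort"
    ).drop(columns="_gene")
    base, rem = divmod(n, 5)
    sizes = [base + (1 if g < rem else 0) for g in range(5)]
    out, start = [], 0
    for size in sizes:
        out.append(order.iloc[start : start + size])
        start += size
    return out
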