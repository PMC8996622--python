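"""Whole-embryo developmental stability and stage-wise hypothesis tests.

The whole-embryo distance between two individuals i and k is the variance of
the distribution of per-gene log-expression differences::

    y_j = x_j^i - x_j^k
    V^ik = (1/N) * sum_j (y_j - mean(y))**2

Mean-centering makes V invariant to global shifts (e.g. residual depth
differences); the population (1/N) normalisation follows the defining
formula.  Developmental stability of a stage is the average V over
sex-matched inbred twin pairs; intraspecies diversity is the same statistic
over all sex-matched pairs drawn across two wild populations.

Stage-wise differences in V are assessed with a Kruskal-Wallis omnibus test
followed by the Steel-Dwass all-pairs multiple comparison (rank-sum statistic
per pair referred to the studentized range distribution).
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expr import ExpressionMatrix
from .pairs import PairDesign


def pair_variance(x_i: np.ndarray, x_k: np.ndarray) -> float:
    """Whole-embryo variation V between two expression profiles.

    Population variance (divide by N) of the signed per-gene differences.
    Profiles must cover the same genes in the same order, N >= 2.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    if x_i.shape != x_k.shape:
        raise ValueError(f"profiles have mismatched gene sets: {x_i.shape} vs {x_k.shape}")
    if x_i.ndim != 1 or x_i.size < 2:
        raise ValueError("profiles must be 1-D with at least 2 genes")
    y = x_i - x_k
    return float(np.var(y))


def _pair_variances(values: pd.DataFrame, pairs: PairDesign) -> np.ndarray:
    missing = [s for s in pairs.sample_ids() if s not in values.columns]
    if missing:
        raise ValueError(f"pair members missing from matrix: {missing}")
    arr = values.to_numpy()
    col = {s: j for j, s in enumerate(values.columns)}
    return np.array([np.var(arr[:, col[p.i]] - arr[:, col[p.k]]) for p in pairs])


@dataclasses.dataclass
class StabilityResult:
    """Per-pair whole-embryo variations and their mean."""

    values: np.ndarray
    mean: float
    stage: str | None = None


def stage_stability(m: ExpressionMatrix, twin_pairs: PairDesign) -> StabilityResult:
    """V for every twin pair of a stage and the stage mean.

    The matrix should already be restricted to the gene universe for the
    stage (low-expression and technical-filter survivors).
    """
    if m.scale != "log10p1":
        raise ValueError("stage_stability expects a log10p1-scale matrix")
    if len(twin_pairs) < 1:
        raise ValueError("need at least one twin pair")
    vs = _pair_variances(m.values, twin_pairs)
    return StabilityResult(vs, float(vs.mean()), stage=twin_pairs.stage)


def intraspecies_diversity(
    m_pop_a: ExpressionMatrix, m_pop_b: ExpressionMatrix, cross_pairs: PairDesign
) -> StabilityResult:
    """V over all sex-matched cross-population pairs; symmetric in population order."""
    if m_pop_a.scale != "log10p1" or m_pop_b.scale != "log10p1":
        raise ValueError("intraspecies_diversity expects log10p1-scale matrices")
    if not m_pop_a.gene_ids.equals(m_pop_b.gene_ids):
        raise ValueError("population matrices must share an identical gene set")
    if len(cross_pairs) < 1:
        raise ValueError("no sex-matched cross-population pairs supplied")
    values = pd.concat([m_pop_a.values, m_pop_b.values], axis=1)
    vs = _pair_variances(values, cross_pairs)
    return StabilityResult(vs, float(vs.mean()), stage=cross_pairs.stage)


def spearman_distance(x_i: np.ndarray, x_k: np.ndarray) -> float:
    """1 - Spearman's rho between two profiles (mid-ranks for ties).

    Used as an alternative whole-embryo distance; undefined (rejected) for
    constant profiles.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    if x_i.shape != x_k.shape or x_i.size < 3:
        raise ValueError("profiles must match and contain at least 3 genes")
    if np.ptp(x_i) == 0 or np.ptp(x_k) == 0:
        raise ValueError("Spearman distance undefined for a constant profile")
    rho = stats.spearmanr(x_i, x_k).statistic
    return float(1.0 - rho)


def stage_spearman_distances(m: ExpressionMatrix, pairs: PairDesign) -> StabilityResult:
    """Mean 1 - rho over the designated pairs (consistency check against V)."""
    arr = m.values
    ds = np.array(
        [spearman_distance(arr[p.i].to_numpy(), arr[p.k].to_numpy()) for p in pairs]
    )
    return StabilityResult(ds, float(ds.mean()), stage=pairs.stage)


# --------------------------------------------------------------- hypothesis tests


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical; Kruskal-Wallis degenerate, p = 1")
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _rank_sum_z(
    pool_ranks: np.ndarray, n1: int, n2: int, tie_term: float, continuity: float = 0.0
) -> float:
    """Standardized rank-sum statistic of the first n1 pooled observations.

    ``continuity`` shrinks |W - E[W]| by 0.5 before standardizing (the usual
    continuity correction for the discrete rank-sum null); the permutation
    branch uses the uncorrected statistic since it compares like with like.
    """
    n = n1 + n2
    w = pool_ranks[:n1].sum()
    e_w = n1 * (n + 1) / 2.0
    var_w = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * n * (n - 1))
    if var_w <= 0:
        return np.nan
    return max(abs(w - e_w) - continuity, 0.0) / np.sqrt(var_w)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def steel_dwass(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """All-pairs Steel-Dwass multiple comparison; returns a symmetric p matrix.

    For each pair of groups the Wilcoxon rank-sum statistic is computed on
    that pair alone, standardized with tie and continuity correction, and
    referred to the studentized range distribution with k groups and
    infinite df divided by sqrt(2) (``method="asymptotic"``, the usual
    moderate-n approximation; the continuity correction compensates for the
    discreteness of the rank-sum null at moderate group sizes).
    ``method="permutation"`` instead compares each pair's statistic with the
    permutation distribution of the maximum standardized statistic over all
    pairs, giving a family-wise p without the asymptotic approximation.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if labels is None:
        labels = [f"group{j}" for j in range(k)]
    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)

    continuity = 0.5 if method == "asymptotic" else 0.0
    zobs: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(range(k), 2):
        pooled = np.concatenate([groups[a], groups[b]])
        if np.ptp(pooled) == 0:
            warnings.warn(f"groups {labels[a]}/{labels[b]} constant; p set to 1")
            zobs[(a, b)] = np.nan
            continue
        ranks = stats.rankdata(pooled)
        zobs[(a, b)] = _rank_sum_z(
            ranks, groups[a].size, groups[b].size, _tie_term(pooled), continuity
        )

    if method == "asymptotic":
        for (a, b), z in zobs.items():
            p = 1.0 if np.isnan(z) else float(
                stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf)
            )
            pmat.iat[a, b] = pmat.iat[b, a] = min(p, 1.0)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        sizes = [g.size for g in groups]
        pooled_all = np.concatenate(groups)
        starts = np.cumsum([0] + sizes)
        max_stats = np.empty(n_permutations)
        for t in range(n_permutations):
            perm = rng.permutation(pooled_all)
            zs = []
            for a, b in itertools.combinations(range(k), 2):
                ga = perm[starts[a] : starts[a + 1]]
                gb = perm[starts[b] : starts[b + 1]]
                sub = np.concatenate([ga, gb])
                if np.ptp(sub) == 0:
                    continue
                ranks = stats.rankdata(sub)
                zs.append(abs(_rank_sum_z(ranks, ga.size, gb.size, _tie_term(sub))))
            max_stats[t] = max(zs) if zs else 0.0
        for (a, b), z in zobs.items():
            if np.isnan(z):
                p = 1.0
            else:
                p = float((np.sum(max_stats >= abs(z)) + 1) / (n_permutations + 1))
            pmat.iat[a, b] = pmat.iat[b, a] = p
    else:
        raise ValueError(f"unknown method {method!r}")
    return pmat


@dataclasses.dataclass
class StageComparison:
    """Per-stage V collections with omnibus and pairwise test results."""

    stage_values: dict[str, np.ndarray]
    h: float
    p: float
    pairwise_p: pd.DataFrame


def compare_stages(stage_values: Mapping[str, np.ndarray], **steel_dwass_kwargs) -> StageComparison:
    """Kruskal-Wallis omnibus plus Steel-Dwass pairwise comparison of stage V values."""
    labels = list(stage_values)
    groups = [np.asarray(stage_values[s], dtype=float) for s in labels]
    h, p = kruskal_wallis(groups)
    pw = steel_dwass(groups, labels=labels, **steel_dwass_kwargs)
    return StageComparison({s: g for s, g in zip(labels, groups)}, h, p, pw)
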