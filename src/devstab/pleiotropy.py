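"""Expression pleiotropy, gene-set definitions, and GO-slim enrichment.

Spatial pleiotropy is the number of tissues (default 25 adult tissues) and
temporal pleiotropy the number of developmental stages (default 16) in which
a gene's replicate-mean TPM is >= 1.  Developmental genes are those annotated
with the developmental-process GO term (GO:0032502) or any of its
descendants; constitutive genes are expressed (log level >= 0.1) at every
sampled stage.  Enrichment of a selected gene set (e.g. the 10% of genes with
the smallest corrected variation) against the remaining genes uses one-sided
Fisher's exact tests per term with Benjamini-Hochberg control of the false
discovery rate.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEVELOPMENTAL_PROCESS = "GO:0032502"


def context_expression_count(
    context_matrices: Mapping[str, pd.DataFrame], tpm_threshold: float = 1.0
) -> pd.Series:
    """Number of contexts (tissues or stages) in which each gene is expressed.

    Each value of ``context_matrices`` is a genes x replicates DataFrame of
    TPM values; a gene counts as expressed in a context iff its replicate
    mean is >= ``tpm_threshold`` (boundary inclusive).  All contexts must
    share a gene index.
    """
    if not context_matrices:
        raise ValueError("no context matrices supplied")
    counts = None
    index = None
    for name, mat in context_matrices.items():
        if mat.shape[1] < 1:
            raise ValueError(f"context {name!r} has no replicate samples")
        if (mat.to_numpy() < 0).any():
            raise ValueError(f"context {name!r} contains negative values; expected TPM scale")
        if index is None:
            index = mat.index
            counts = np.zeros(len(index), dtype=int)
        elif not mat.index.equals(index):
            raise ValueError(f"context {name!r} gene index differs from the others")
        counts += (mat.mean(axis=1).to_numpy() >= tpm_threshold).astype(int)
    return pd.Series(counts, index=index, name="n_contexts_expressed")


def term_descendants(edges: Iterable[tuple[str, str]], root: str) -> set[str]:
    """The root term plus every term from which the root is reachable via parent edges.

    ``edges`` are (child, parent) pairs; the root must occur in the ontology.
    """
    children: dict[str, set[str]] = {}
    nodes = set()
    for child, parent in edges:
        children.setdefault(parent, set()).add(child)
        nodes.add(child)
        nodes.add(parent)
    if root not in nodes:
        raise ValueError(f"root term {root!r} absent from the ontology edge list")
    closure = {root}
    frontier = [root]
    while frontier:
        term = frontier.pop()
        for child in children.get(term, ()):
            if child not in closure:
                closure.add(child)
                frontier.append(child)
    return closure


def developmental_gene_set(
    annotations: Mapping[str, set[str]],
    ontology_edges: Iterable[tuple[str, str]],
    root: str = DEVELOPMENTAL_PROCESS,
) -> set[str]:
    """Genes annotated with the developmental-process term or any descendant."""
    closure = term_descendants(ontology_edges, root)
    return {g for g, terms in annotations.items() if terms & closure}


def constitutive_gene_set(stage_means: pd.DataFrame, threshold: float = 0.1) -> set[str]:
    """Genes whose replicate-mean log expression is >= threshold at every stage.

    ``stage_means`` is genes x stages on the log10(TPM+1) scale; the boundary
    is inclusive and an empty stage list is rejected.
    """
    if stage_means.shape[1] == 0:
        raise ValueError("no stages supplied")
    keep = (stage_means >= threshold).all(axis=1)
    return set(stage_means.index[keep])


def least_variable_fraction(table: pd.DataFrame, fraction: float = 0.10) -> set[str]:
    """The floor(fraction * n) genes with the smallest corrected variation.

    Ties at the cut are broken by gene id (ascending) for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if "corrected" not in table.columns:
        raise ValueError("table lacks a 'corrected' column; run running_median_correct first")
    k = int(np.floor(fraction * len(table)))
    order = table.assign(_gene=table.index).sort_values(
        ["corrected", "_gene"], kind="mergesort"
    )
    return set(order.index[:k])


def enrichment_test(
    selected: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment of ``selected`` vs ``background``.

    ``background`` is the remaining genes (universe minus selected); the two
    sets must be disjoint and non-empty.  For each term occurring in the
    universe the 2x2 table (selected-with, selected-without, background-with,
    background-without) is formed; the one-sided enrichment p is the
    hypergeometric upper tail, q-values are Benjamini-Hochberg over all
    terms, and fold is the term-frequency ratio selected/background
    (infinite when the term is absent from the background but present in the
    selection).
    """
    selected = set(selected)
    background = set(background)
    if not selected or not background:
        raise ValueError("selected and background sets must be non-empty")
    overlap = selected & background
    if overlap:
        raise ValueError(f"selected and background overlap: {sorted(overlap)[:5]}")
    universe = selected | background
    term_sel: dict[str, int] = {}
    term_bg: dict[str, int] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            if gene in selected:
                term_sel[term] = term_sel.get(term, 0) + 1
            else:
                term_bg[term] = term_bg.get(term, 0) + 1
    terms = sorted(set(term_sel) | set(term_bg))
    n_sel, n_bg = len(selected), len(background)
    n_tot = n_sel + n_bg
    rows = []
    for term in terms:
        k = term_sel.get(term, 0)
        k_bg = term_bg.get(term, 0)
        k_tot = k + k_bg
        p = float(stats.hypergeom.sf(k - 1, n_tot, k_tot, n_sel))
        if k_bg > 0:
            fold = (k / n_sel) / (k_bg / n_bg)
        else:
            fold = np.inf if k > 0 else np.nan
        rows.append((term, k, n_sel, k_bg, n_bg, fold, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "term", "selected_with", "selected_total",
            "background_with", "background_total", "fold", "p",
        ],
    ).set_index("term")
    out["q"] = stats.false_discovery_control(out["p"].to_numpy()) if len(out) else []
    return out


def twofold_report(
    enrichment: pd.DataFrame, fold_cut: float = 2.0, q_cut: float = 0.01
) -> pd.DataFrame:
    """Terms enriched strictly more than ``fold_cut`` times, flagged by q <= ``q_cut``.

    The fold boundary is exclusive: a term at exactly the cut is dropped.
    """
    out = enrichment[enrichment["fold"] > fold_cut].copy()
    out["significant"] = out["q"] <= q_cut
    return out
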