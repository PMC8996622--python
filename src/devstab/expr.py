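"""Expression-matrix containers, transforms, and read-depth utilities.

The central container is :class:`ExpressionMatrix`: a genes x samples table of
TPM (transcripts per million) or log10(TPM+1) values together with per-sample
metadata (developmental stage, strain, sex, twin-pair id, sample role).  All
downstream statistics operate on the log scale, so the typical entry point is
``filter_low_expression(log_transform(m))``.

:class:`CountMatrix` holds integer read counts and supports random
subsampling to a fixed depth, which is used to measure how sequencing depth
biases whole-embryo variation estimates.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("stage", "strain", "sex", "pair_id", "role")

_SCALES = ("tpm", "log10p1")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    metadata
        DataFrame indexed by sample id with columns
        ``stage, strain, sex, pair_id, role``; role is one of
        ``embryo, technical, tissue``.
    scale
        ``"tpm"`` for non-negative TPM values, ``"log10p1"`` for
        log10(TPM+1)-transformed values.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "tpm" and (arr < 0).any():
            raise ValueError("TPM-scale matrix contains negative values")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        # metadata rows follow matrix column order; extra metadata rows dropped
        self.metadata = self.metadata.reindex(self.values.columns)
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                self.metadata[col] = ""

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def profile(self, sample_id: str) -> pd.Series:
        """Expression profile (one column) of a single sample."""
        if sample_id not in self.values.columns:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.values[sample_id]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.metadata.copy(), self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)], self.metadata.loc[list(samples)], self.scale
        )

    # ------------------------------------------------------------------ I/O
    def write_tsv(self, values_path, metadata_path=None) -> None:
        """Write values (and optionally metadata) as tab-delimited text.

        The values file has a header row of sample ids and gene ids in the
        first column; the metadata file is indexed by sample id.
        """
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, values_path, metadata_path=None, scale: str = "tpm") -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        if metadata_path is not None:
            metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, keep_default_na=False)
        else:
            metadata = pd.DataFrame(index=values.columns)
        return cls(values, metadata, scale)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Transform a TPM matrix to log10(TPM+1).

    Rejects matrices already on the log scale; metadata is preserved.
    """
    if m.scale != "tpm":
        raise ValueError("log_transform expects a TPM-scale matrix")
    return ExpressionMatrix(np.log10(m.values + 1.0), m.metadata.copy(), "log10p1")


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform log10(TPM+1) values to TPM."""
    if m.scale != "log10p1":
        raise ValueError("inverse_log_transform expects a log10p1-scale matrix")
    return ExpressionMatrix(np.power(10.0, m.values) - 1.0, m.metadata.copy(), "tpm")


def filter_low_expression(m: ExpressionMatrix, threshold: float = 0.1) -> ExpressionMatrix:
    """Keep genes whose log expression is >= ``threshold`` in every sample.

    The boundary is inclusive: a gene sitting exactly at the threshold in all
    samples is retained.  The filter is defined relative to the samples in
    ``m``, i.e. to the cohort entering a given analysis.
    """
    if m.scale != "log10p1":
        raise ValueError("filter_low_expression expects a log10p1-scale matrix")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = (m.values >= threshold).all(axis=1)
    return ExpressionMatrix(m.values.loc[keep], m.metadata.copy(), m.scale)


@dataclasses.dataclass
class CountMatrix:
    """Genes x samples integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique or not self.counts.columns.is_unique:
            raise ValueError("gene and sample ids must be unique")

    @property
    def depths(self) -> pd.Series:
        """Total mapped reads per sample (column sums)."""
        return self.counts.sum(axis=0)


def subsample_counts(
    c: CountMatrix,
    depth: int,
    seed=None,
    with_replacement: bool = False,
) -> CountMatrix:
    """Randomly draw ``depth`` reads per sample from the gene-labelled pool.

    Default is sampling without replacement (multivariate hypergeometric),
    i.e. picking reads from the mapped-read pool; ``with_replacement=True``
    uses a multinomial instead, which is indistinguishable at high depth.
    """
    rng = np.random.default_rng(seed)
    depth = int(depth)
    if depth < 0:
        raise ValueError("depth must be non-negative")
    out = {}
    for sample in c.counts.columns:
        col = c.counts[sample].to_numpy()
        total = int(col.sum())
        if depth > total:
            raise ValueError(
                f"requested depth {depth} exceeds total {total} reads of sample {sample!r}"
            )
        if with_replacement:
            out[sample] = rng.multinomial(depth, col / total if total else col)
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    sub = pd.DataFrame(out, index=c.counts.index, columns=c.counts.columns)
    return CountMatrix(sub)


def counts_to_log_tpm(c: CountMatrix, metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Convert counts to a log10(TPM+1)-like matrix via per-sample proportions.

    The TPM surrogate is proportion x 1e6 with no gene-length correction
    (synthetic genes carry no length).  Zero-depth samples map to all zeros.
    """
    totals = c.counts.sum(axis=0).replace(0, 1)
    tpm = c.counts.div(totals, axis=1) * 1e6
    if metadata is None:
        metadata = pd.DataFrame(index=c.counts.columns)
    return log_transform(ExpressionMatrix(tpm, metadata, "tpm"))


def depth_bias_curve(c: CountMatrix, depths: Sequence[int], pairs, seed=None) -> pd.DataFrame:
    """Mean twin-pair variation V as a function of subsampling depth.

    For each depth, every sample is subsampled to that depth, converted to a
    log TPM surrogate, and the mean whole-embryo variation V over ``pairs``
    (a :class:`devstab.pairs.PairDesign`) is computed.  Depths must be sorted
    ascending and feasible for every sample.
    """
    from .stability import pair_variance  # local import to avoid cycle

    depths = [int(d) for d in depths]
    if sorted(depths) != depths:
        raise ValueError("depths must be sorted ascending")
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        sub = subsample_counts(c, depth, seed=rng)
        logm = counts_to_log_tpm(sub)
        vs = [
            pair_variance(logm.values[p.i].to_numpy(), logm.values[p.k].to_numpy())
            for p in pairs.pairs
        ]
        rows.append({"depth": depth, "mean_v": float(np.mean(vs))})
    return pd.DataFrame(rows)
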