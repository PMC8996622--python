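"""Synthetic data with the statistical structure the analyses assume.

The generator emulates the study design end to end without any sequencing
data: sex-matched inbred twin embryos at four developmental stages with
stage-specific biological noise (an hourglass profile by default), two wild
populations with per-gene expression divergence, technical quadruplicates
with smaller flat noise, adult-tissue and developmental-stage expression
patterns for pleiotropy, GO-style gene labels with one term planted at
elevated frequency among intrinsically stable genes, and a toy genome (TSS,
ATAC-like peaks, homozygous substitutions, proximal promoters with a known
number of planted TATA motifs).

Model (all noise on the log10(TPM+1) scale, where the statistics operate):

* baseline log expression  mu_j ~ Exponential(1)
* per-gene noise multiplier  s_j ~ LogNormal(0, gene_scale_heterogeneity)
* mean-variance coupling  g(mu) = a + b * exp(-c * mu)  (decreasing, convex,
  flattening at high expression, so the running-median correction has a real
  trend to remove)
* a twin sample at stage t:  x_j = mu_j + eps,  eps ~ N(0, (sd_t * s_j * g(mu_j))^2)
* population B baseline:  mu_j + delta_j,  delta_j ~ N(0, (divergence_sd * s_j)^2)
  -- the shared multiplier s_j plants the stability-conservation correlation
* technical replicates: 4 samples of one latent profile with flat noise sd.

Matrices are emitted on the TPM scale (TPM = 10^x - 1, floored at 0), so the
standard pipeline entry point ``log_transform`` applies.  Ground truth is
emitted alongside every data set for parameter-recovery tests.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix
from .regulome import GenomeAnnotation, TATA_MOTIFS

DEFAULT_STAGES = ("early", "phylo1", "phylo2", "hatch")
# stream ids for independent, reproducible RNG streams per operation
_STREAM_GENES = 1
_STREAM_TWINS = 2
_STREAM_POPS = 3
_STREAM_TECH = 4
_STREAM_GENOME = 5
_STREAM_GO = 6
_STREAM_CONTEXTS = 7


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: four stages with an hourglass
    noise profile (log-scale sd 0.20 / 0.10 / 0.10 / 0.25), 20 twin pairs per
    stage (the study used 13-25), and technical noise well below the
    mid-stage biological noise.
    """

    n_genes: int = 2000
    n_pairs_per_stage: int = 20
    stages: tuple[str, ...] = DEFAULT_STAGES
    stage_noise_sd: tuple[float, ...] = (0.20, 0.10, 0.10, 0.25)
    tech_noise_sd: float = 0.05
    divergence_sd: float = 0.15
    mean_variance_coupling: tuple[float, float, float] = (0.3, 1.0, 1.0)
    gene_scale_heterogeneity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_pairs_per_stage < 1:
            raise ValueError("n_pairs_per_stage must be positive")
        if not self.stages:
            raise ValueError("stages must be non-empty")
        if len(self.stage_noise_sd) != len(self.stages):
            raise ValueError("stage_noise_sd must match stages in length")
        if any(sd < 0 for sd in self.stage_noise_sd):
            raise ValueError("stage noise sds must be non-negative")
        for name in ("tech_noise_sd", "divergence_sd", "gene_scale_heterogeneity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def stage_sd(self, stage: str) -> float:
        if stage not in self.stages:
            raise ValueError(f"unknown stage {stage!r}; expected one of {self.stages}")
        return self.stage_noise_sd[self.stages.index(stage)]

    def coupling(self, mu: np.ndarray) -> np.ndarray:
        """g(mu) = a + b * exp(-c * mu): noise scale vs mean log expression."""
        a, b, c = self.mean_variance_coupling
        return a + b * np.exp(-c * np.asarray(mu, dtype=float))


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated data."""

    gene_ids: pd.Index
    mu: np.ndarray                       # baseline log expression per gene
    s: np.ndarray                        # per-gene noise multiplier
    stage_sd: dict[str, float]
    delta: np.ndarray | None = None      # per-gene population shift (pop B - pop A)
    go_labels: dict[str, set[str]] | None = None
    planted_term: str | None = None
    tata_counts: pd.Series | None = None
    context_mask: pd.DataFrame | None = None

    def noise_sd(self, stage: str, config: SimulationConfig) -> np.ndarray:
        """Per-gene noise sd at a stage: sd_t * s_j * g(mu_j)."""
        return self.stage_sd[stage] * self.s * config.coupling(self.mu)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _gene_ids(config: SimulationConfig) -> pd.Index:
    return pd.Index([f"g{j:05d}" for j in range(config.n_genes)], name="gene")


def _gene_params(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Baseline mu_j and multiplier s_j, shared across every operation of a config."""
    rng = _rng(config, _STREAM_GENES)
    mu = rng.exponential(1.0, size=config.n_genes)
    s = rng.lognormal(0.0, config.gene_scale_heterogeneity, size=config.n_genes)
    return mu, s


def _to_tpm(log_values: np.ndarray) -> np.ndarray:
    return np.maximum(np.power(10.0, np.maximum(log_values, 0.0)) - 1.0, 0.0)


def _truth(config: SimulationConfig, mu: np.ndarray, s: np.ndarray, **extra) -> SyntheticTruth:
    return SyntheticTruth(
        gene_ids=_gene_ids(config),
        mu=mu,
        s=s,
        stage_sd=dict(zip(config.stages, config.stage_noise_sd)),
        **extra,
    )


def simulate_twin_matrix(
    config: SimulationConfig, stage: str
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Sex-matched twin-pair embryos at one stage (2 x n_pairs samples, TPM scale)."""
    sd = config.stage_sd(stage)  # validates the stage label
    mu, s = _gene_params(config)
    sigma = sd * s * config.coupling(mu)
    stage_idx = config.stages.index(stage)
    rng = _rng(config, _STREAM_TWINS, stage_idx)
    cols, meta = {}, []
    for p in range(config.n_pairs_per_stage):
        pair_id = f"{stage}_p{p:02d}"
        sex = "F" if p % 2 == 0 else "M"
        for member in ("a", "b"):
            sid = f"{pair_id}{member}"
            x = mu + rng.normal(0.0, 1.0, size=config.n_genes) * sigma
            cols[sid] = _to_tpm(x)
            meta.append((sid, stage, "inbred", sex, pair_id, "embryo"))
    values = pd.DataFrame(cols, index=_gene_ids(config))
    metadata = pd.DataFrame(
        meta, columns=["sample", "stage", "strain", "sex", "pair_id", "role"]
    ).set_index("sample")
    return ExpressionMatrix(values, metadata, "tpm"), _truth(config, mu, s)


def simulate_population_matrices(
    config: SimulationConfig, stage: str
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Two wild-population cohorts at one stage with planted gene-level divergence.

    Population B's baseline is mu_j + delta_j with
    delta_j ~ N(0, (divergence_sd * s_j)^2), drawn once per gene and shared
    by every individual of population B; within-population noise follows the
    twin model.  The shared multiplier s_j couples per-gene stability to
    divergence.
    """
    sd = config.stage_sd(stage)
    mu, s = _gene_params(config)
    sigma = sd * s * config.coupling(mu)
    stage_idx = config.stages.index(stage)
    rng = _rng(config, _STREAM_POPS, stage_idx)
    delta = rng.normal(0.0, 1.0, size=config.n_genes) * (config.divergence_sd * s)
    matrices = {}
    for pop, baseline in (("popA", mu), ("popB", mu + delta)):
        cols, meta = {}, []
        for n in range(config.n_pairs_per_stage):
            sid = f"{stage}_{pop}_{n:02d}"
            sex = "F" if n % 2 == 0 else "M"
            x = baseline + rng.normal(0.0, 1.0, size=config.n_genes) * sigma
            cols[sid] = _to_tpm(x)
            meta.append((sid, stage, pop, sex, "", "embryo"))
        values = pd.DataFrame(cols, index=_gene_ids(config))
        metadata = pd.DataFrame(
            meta, columns=["sample", "stage", "strain", "sex", "pair_id", "role"]
        ).set_index("sample")
        matrices[pop] = ExpressionMatrix(values, metadata, "tpm")
    truth = _truth(config, mu, s, delta=delta)
    return matrices["popA"], matrices["popB"], truth


def simulate_technical_replicates(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Four technical replicates of one pooled latent profile (flat noise sd)."""
    mu, s = _gene_params(config)
    rng = _rng(config, _STREAM_TECH)
    cols, meta = {}, []
    for r in range(4):
        sid = f"tech_{r + 1}"
        x = mu + rng.normal(0.0, config.tech_noise_sd, size=config.n_genes)
        cols[sid] = _to_tpm(x)
        meta.append((sid, "", "inbred", "", "tech_pool", "technical"))
    values = pd.DataFrame(cols, index=_gene_ids(config))
    metadata = pd.DataFrame(
        meta, columns=["sample", "stage", "strain", "sex", "pair_id", "role"]
    ).set_index("sample")
    return ExpressionMatrix(values, metadata, "tpm"), _truth(config, mu, s)


# --------------------------------------------------------------- annotations


def simulate_go_annotations(
    config: SimulationConfig,
    n_decoy_terms: int = 20,
    planted_term: str = "GO:SYN_PLANTED",
    planted_freq: float = 0.25,
    background_freq: float = 0.05,
    stable_fraction: float = 0.10,
) -> tuple[dict[str, set[str]], SyntheticTruth]:
    """GO-style labels with one term planted at elevated frequency among
    intrinsically stable genes.

    Genes in the lowest ``stable_fraction`` of the noise multiplier s_j carry
    the planted term with probability ``planted_freq``; the remaining genes
    with ``background_freq`` (5x lower by default).  Decoy terms are assigned
    independently of stability.
    """
    mu, s = _gene_params(config)
    rng = _rng(config, _STREAM_GO)
    genes = _gene_ids(config)
    n = config.n_genes
    cutoff = np.quantile(s, stable_fraction)
    stable = s <= cutoff
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for t in range(n_decoy_terms):
        freq = rng.uniform(0.02, 0.20)
        hit = rng.random(n) < freq
        term = f"GO:SYN_{t:04d}"
        for g in genes[hit]:
            annotations[g].add(term)
    p = np.where(stable, planted_freq, background_freq)
    hit = rng.random(n) < p
    for g in genes[hit]:
        annotations[g].add(planted_term)
    truth = _truth(config, mu, s, go_labels=annotations, planted_term=planted_term)
    return annotations, truth


def simulate_pleiotropy_contexts(
    config: SimulationConfig,
    n_contexts: int = 25,
    n_replicates: int = 4,
    kind: str = "tissue",
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Per-context replicate TPM matrices with planted pleiotropy-stability coupling.

    A gene's probability of being expressed in a context decreases with its
    noise multiplier rank (stable genes are expressed more broadly).
    Expressed genes draw replicate TPM >= 1.5 and silent genes < 0.5, so the
    planted expression mask is exactly recoverable at the TPM >= 1 rule.
    """
    mu, s = _gene_params(config)
    rng = _rng(config, _STREAM_CONTEXTS, {"tissue": 0, "stage": 1}.get(kind, 2))
    genes = _gene_ids(config)
    n = config.n_genes
    rank_frac = (np.argsort(np.argsort(s)) + 0.5) / n
    p_expr = 0.85 - 0.6 * rank_frac
    mask = rng.random((n, n_contexts)) < p_expr[:, None]
    contexts: dict[str, pd.DataFrame] = {}
    for c in range(n_contexts):
        name = f"{kind}{c:02d}"
        reps = {}
        for r in range(n_replicates):
            expressed = 1.5 + rng.exponential(3.0, size=n)
            silent = 0.45 * rng.random(n)
            reps[f"{name}_rep{r}"] = np.where(mask[:, c], expressed, silent)
        contexts[name] = pd.DataFrame(reps, index=genes)
    mask_df = pd.DataFrame(mask, index=genes, columns=list(contexts))
    truth = _truth(config, mu, s, context_mask=mask_df)
    return contexts, truth


# --------------------------------------------------------------- toy genome

_GENE_SPACING = 20_000
_PROMOTER_LEN = 150


def simulate_genome_annotation(
    config: SimulationConfig,
    snp_samples: int = 8,
) -> tuple[GenomeAnnotation, SyntheticTruth]:
    """Toy genome: one TSS per gene, peaks at known offsets, SNPs, promoters.

    Genes sit on one chromosome at 20-kb spacing with alternating strand.
    Each gene receives 0-2 open-chromatin peaks at offsets within the distal
    window and 0-2 homozygous substitutions with per-sample carrier flags.
    Proximal promoters (150 bp) are built over {A, C, G} (no background T,
    hence no accidental motifs) with 0-3 planted TATA motifs separated by CC
    spacers; the exact match count under the counting rules (palindromic
    TATATATA scores 2, the others 1) is recorded as truth.
    """
    mu, s = _gene_params(config)
    rng = _rng(config, _STREAM_GENOME)
    genes = _gene_ids(config)
    tss_rows, peak_rows, snp_rows, promoters, tata_truth = [], [], [], {}, {}
    peak_offsets = np.array([-4500, -2500, 1500])
    for j, gene in enumerate(genes):
        pos = 10_000 + j * _GENE_SPACING
        strand = "+" if j % 2 == 0 else "-"
        tss_rows.append((gene, "chr1", pos, strand))
        for off in peak_offsets[rng.random(3) < 0.5]:
            length = int(rng.integers(300, 900))
            start = pos + int(off)
            peak_rows.append(("chr1", start, start + length))
        for _ in range(int(rng.integers(0, 3))):
            snp_pos = pos + int(rng.integers(-4800, 4800))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            flags = (rng.random(snp_samples) < 0.3).astype(int)
            snp_rows.append(("chr1", snp_pos, f"snp_{gene}_{snp_pos}", ref, alt, *flags))
        seq = rng.choice(list("ACG"), size=_PROMOTER_LEN)
        n_motifs = int(rng.integers(0, 4))
        count = 0
        for m in range(n_motifs):
            motif = TATA_MOTIFS[int(rng.integers(0, len(TATA_MOTIFS)))]
            at = 10 + m * 15
            seq[at - 2 : at] = ["C", "C"]
            seq[at : at + 8] = list(motif)
            seq[at + 8 : at + 10] = ["C", "C"]
            count += 2 if motif == "TATATATA" else 1
        promoters[gene] = "".join(seq)
        tata_truth[gene] = count
    sample_cols = [f"sample{i}" for i in range(snp_samples)]
    annotation = GenomeAnnotation(
        tss=pd.DataFrame(tss_rows, columns=["gene", "chrom", "pos", "strand"]).set_index("gene"),
        peaks=pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]),
        snps=pd.DataFrame(snp_rows, columns=["chrom", "pos", "id", "ref", "alt", *sample_cols]),
        promoters=promoters,
    )
    truth = _truth(config, mu, s, tata_counts=pd.Series(tata_truth, name="n_tata"))
    return annotation, truth
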