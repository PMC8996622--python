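"""Regulatory-feature extraction around transcription start sites.

Open-chromatin (ATAC) peaks are linked to the gene with the closest TSS and
retained when they overlap that gene's distal (+/-5000 bp around the TSS) or
proximal (-100 to +50 bp, strand-aware) window; a peak straddling a window
boundary is kept only if strictly more than half of its length lies inside.
Homozygous single-nucleotide substitutions falling inside a gene's retained
open-chromatin regions (within the distal flank) are counted as
(site, sample) events summed over samples.  TATA-box elements are scanned in
proximal promoter sequences as exact matches of four motifs --
TATAAAAA, TATAAATA, TATATAAA, TATATATA -- where overlapping two-base shifts
and matches of the reverse complements (the opposite strand) are counted
separately.

All genomic intervals are 0-based half-open; TSS positions are 0-based
single coordinates (VCF output converts to 1-based positions).
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TATA_MOTIFS = ("TATAAAAA", "TATAAATA", "TATATAAA", "TATATATA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class GenomeAnnotation:
    """TSS records, peak intervals, SNP sites and promoter sequences.

    ``tss``: DataFrame indexed by gene id with columns chrom, pos, strand.
    ``peaks``: DataFrame with columns chrom, start, end (0-based half-open).
    ``snps``: DataFrame with columns chrom, pos, id, ref, alt plus one 0/1
    column per resequenced sample flagging a homozygous substitution.
    ``promoters``: gene id -> proximal promoter sequence (150 bp).
    """

    tss: pd.DataFrame
    peaks: pd.DataFrame
    snps: pd.DataFrame
    promoters: dict[str, str]

    def __post_init__(self) -> None:
        if not self.tss.index.is_unique:
            raise ValueError("each gene must have exactly one TSS record")
        if (self.tss["pos"] < 0).any():
            raise ValueError("TSS positions must be non-negative")
        bad = self.peaks.index[self.peaks["start"] >= self.peaks["end"]]
        if len(bad):
            raise ValueError(f"invalid peak intervals (start >= end) at records {list(bad)[:5]}")
        if len(self.snps) and (self.snps["pos"] < 0).any():
            raise ValueError("SNP positions must be non-negative")

    @property
    def snp_sample_columns(self) -> list[str]:
        fixed = {"chrom", "pos", "id", "ref", "alt"}
        return [c for c in self.snps.columns if c not in fixed]


# ------------------------------------------------------------------ windows


def proximal_window(pos: int, strand: str, proximal: tuple[int, int] = (-100, 50)) -> tuple[int, int]:
    """Strand-aware proximal window as a half-open genomic interval.

    Offsets are along the gene: ``proximal=(-100, 50)`` spans 100 bases
    upstream through 50 bases downstream of the TSS.  Flipping the strand
    mirrors the interval about the TSS exactly.
    """
    lo, hi = proximal
    if strand == "+":
        return (pos + lo, pos + hi)
    if strand == "-":
        return (pos - hi + 1, pos - lo + 1)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_peaks(
    tss: pd.DataFrame,
    peaks: pd.DataFrame,
    distal_flank: int = 5000,
    proximal: tuple[int, int] = (-100, 50),
) -> pd.DataFrame:
    """Link every peak to the gene with the closest TSS and apply the window rule.

    Distance is from the TSS point to the peak interval (0 when the TSS lies
    inside).  Equidistant TSS ties resolve to the lexicographically smaller
    gene id.  A linked peak is ``kept`` iff strictly more than half of its
    length lies inside the union of the gene's distal and proximal windows.
    Returns one row per peak: chrom, start, end, gene, distance, overlap, kept.
    """
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks.index[peaks["start"] >= peaks["end"]]
        raise ValueError(f"invalid peak intervals at records {list(bad)[:5]}")
    rows = []
    tss_by_chrom = {c: grp for c, grp in tss.groupby("chrom")}
    for idx, peak in peaks.iterrows():
        chrom, start, end = peak["chrom"], int(peak["start"]), int(peak["end"])
        cand = tss_by_chrom.get(chrom)
        if cand is None or cand.empty:
            rows.append((idx, chrom, start, end, None, np.nan, 0, False))
            continue
        pos = cand["pos"].to_numpy()
        dist = np.maximum.reduce([start - pos, pos - (end - 1), np.zeros_like(pos)])
        best = dist.min()
        tied = sorted(cand.index[dist == best])
        gene = tied[0]
        t_pos = int(cand.loc[gene, "pos"])
        strand = cand.loc[gene, "strand"]
        windows = _merge_intervals(
            [
                (t_pos - distal_flank, t_pos + distal_flank),
                proximal_window(t_pos, strand, proximal),
            ]
        )
        ov = sum(_overlap((start, end), w) for w in windows)
        kept = 2 * ov > (end - start)
        rows.append((idx, chrom, start, end, gene, int(best), ov, kept))
    return pd.DataFrame(
        rows,
        columns=["peak", "chrom", "start", "end", "gene", "distance", "overlap", "kept"],
    ).set_index("peak")


def peaks_by_gene(assignments: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Retained peak intervals grouped by assigned gene."""
    out: dict[str, list[tuple[int, int]]] = {}
    kept = assignments[assignments["kept"]]
    for _, row in kept.iterrows():
        out.setdefault(row["gene"], []).append((int(row["start"]), int(row["end"])))
    return out


def count_snps(
    annotation: GenomeAnnotation,
    assignments: pd.DataFrame | None = None,
    distal_flank: int = 5000,
) -> pd.Series:
    """Per-gene count of (substitution, sample) events in open chromatin near the TSS.

    Each gene's retained peaks are clipped to the +/-``distal_flank`` window
    around its TSS and merged; a SNP inside those regions (half-open: the
    end coordinate is excluded) contributes its number of carrier samples.
    SNPs on chromosomes absent from the TSS table are skipped with a warning.
    """
    if assignments is None:
        assignments = assign_peaks(annotation.tss, annotation.peaks, distal_flank=distal_flank)
    sample_cols = annotation.snp_sample_columns
    counts = pd.Series(0, index=annotation.tss.index, name="n_snps", dtype=int)
    regions: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for gene, intervals in peaks_by_gene(assignments).items():
        t_pos = int(annotation.tss.loc[gene, "pos"])
        chrom = annotation.tss.loc[gene, "chrom"]
        window = (t_pos - distal_flank, t_pos + distal_flank)
        clipped = [
            (max(s, window[0]), min(e, window[1]))
            for s, e in intervals
            if _overlap((s, e), window) > 0
        ]
        regions[gene] = (chrom, _merge_intervals(clipped))
    known_chroms = set(annotation.tss["chrom"])
    for _, snp in annotation.snps.iterrows():
        if snp["chrom"] not in known_chroms:
            warnings.warn(f"SNP on unknown chromosome {snp['chrom']!r}; skipped")
            continue
        carriers = int(sum(int(snp[c]) for c in sample_cols))
        for gene, (chrom, intervals) in regions.items():
            if chrom != snp["chrom"]:
                continue
            pos = int(snp["pos"])
            if any(s <= pos < e for s, e in intervals):
                counts[gene] += carriers
    return counts


# ------------------------------------------------------------------ TATA scan


def _count_occurrences(seq: str, motif: str) -> int:
    count = 0
    start = seq.find(motif)
    while start != -1:
        count += 1
        start = seq.find(motif, start + 1)  # overlapping matches all count
    return count


def scan_tata(promoter: str, both_strands: bool = True) -> int:
    """Total exact-string TATA-box matches in a promoter sequence.

    Counts every occurrence of the four motifs at every offset (overlapping
    two-base shifts counted separately) and, with ``both_strands=True``,
    every occurrence of their reverse complements (the opposite strand
    counted separately; the palindromic TATATATA therefore counts twice at
    each site).
    """
    seq = promoter.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(set(seq) - set('ACGTN'))}")
    total = sum(_count_occurrences(seq, m) for m in TATA_MOTIFS)
    if both_strands:
        total += sum(_count_occurrences(seq, reverse_complement(m)) for m in TATA_MOTIFS)
    return total


def regulatory_features(
    annotation: GenomeAnnotation,
    assignments: pd.DataFrame | None = None,
    distal_flank: int = 5000,
) -> pd.DataFrame:
    """Per-gene regulatory feature table.

    Columns: ``n_peaks`` (retained assigned peaks), ``peak_length`` (total
    retained peak length), ``n_snps`` (substitution events in open chromatin,
    summed over samples), ``n_tata`` (TATA matches in the proximal promoter).
    """
    if assignments is None:
        assignments = assign_peaks(annotation.tss, annotation.peaks, distal_flank=distal_flank)
    genes = annotation.tss.index
    by_gene = peaks_by_gene(assignments)
    n_peaks = pd.Series({g: len(by_gene.get(g, [])) for g in genes}, dtype=int)
    lengths = pd.Series(
        {g: sum(e - s for s, e in by_gene.get(g, [])) for g in genes}, dtype=int
    )
    snps = count_snps(annotation, assignments, distal_flank=distal_flank)
    tata = pd.Series({g: scan_tata(annotation.promoters[g]) for g in genes}, dtype=int)
    return pd.DataFrame(
        {"n_peaks": n_peaks, "peak_length": lengths, "n_snps": snps, "n_tata": tata},
        index=genes,
    )


def feature_stability_correlation(
    features: pd.DataFrame, table: pd.DataFrame, column: str = "corrected"
) -> pd.DataFrame:
    """Spearman rho (and no-correlation p) of each feature vs corrected variation.

    Constant feature columns have undefined rho and are flagged
    ``defined=False``.  Requires >= 10 shared genes.
    """
    shared = features.index.intersection(table.index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared genes, got {len(shared)}")
    y = table.loc[shared, column].to_numpy(dtype=float)
    rows = []
    for feat in features.columns:
        x = features.loc[shared, feat].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((feat, np.nan, np.nan, len(shared), False))
            continue
        res = stats.spearmanr(x, y)
        rows.append((feat, float(res.statistic), float(res.pvalue), len(shared), True))
    return pd.DataFrame(
        rows, columns=["feature", "rho", "p", "n", "defined"]
    ).set_index("feature")


# ------------------------------------------------------------------ I/O


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return df


def write_tss(tss: pd.DataFrame, path) -> None:
    tss[["chrom", "pos", "strand"]].to_csv(path, sep="\t", index_label="gene")


def read_tss(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_vcf_minimal(snps: pd.DataFrame, path) -> None:
    """Write SNPs as a minimal VCF-like table (1-based POS, sample flags appended)."""
    fixed = {"chrom", "pos", "id", "ref", "alt"}
    samples = [c for c in snps.columns if c not in fixed]
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL" + "".join(f"\t{s}" for s in samples) + "\n")
        for _, row in snps.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t." + "".join(f"\t{int(row[s])}" for s in samples) + "\n"
            )


def read_vcf_minimal(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#").lower() if c in ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL")
                  else c for c in df.columns]
    df["pos"] = df["pos"].astype(int) - 1  # back to 0-based
    return df.drop(columns=["qual"])


def write_promoters_fasta(promoters: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()]
    SeqIO.write(records, path, "fasta")


def read_promoters_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
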