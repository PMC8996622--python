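"""Sample-pair designs: which samples are compared, and as what kind of pair.

A :class:`PairDesign` is an ordered list of (i, k, kind) sample pairs where
kind is ``twin`` (sex-matched inbred twins), ``cross_population`` (sex-matched
individuals from two wild populations), or ``technical`` (split aliquots of
one RNA pool).  Builders derive designs from sample metadata.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import pandas as pd

PAIR_KINDS = ("twin", "cross_population", "technical", "interspecies")


@dataclasses.dataclass(frozen=True)
class Pair:
    i: str
    k: str
    kind: str = "twin"

    def __post_init__(self) -> None:
        if self.i == self.k:
            raise ValueError(f"a pair must join two distinct samples, got {self.i!r} twice")
        if self.kind not in PAIR_KINDS:
            raise ValueError(f"unknown pair kind {self.kind!r}")


@dataclasses.dataclass
class PairDesign:
    pairs: tuple[Pair, ...]
    stage: str | None = None

    def __post_init__(self) -> None:
        self.pairs = tuple(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.i)
            seen.setdefault(p.k)
        return list(seen)


def twin_pairs(metadata: pd.DataFrame, stage: str | None = None) -> PairDesign:
    """Build twin pairs from metadata: same pair id, sex-matched, role embryo."""
    md = metadata
    if stage is not None:
        md = md[md["stage"] == stage]
    md = md[md["role"] == "embryo"]
    md = md[md["pair_id"] != ""]
    pairs = []
    for pair_id, grp in md.groupby("pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"twin pair {pair_id!r} has {len(grp)} members, expected 2")
        if grp["sex"].nunique() != 1:
            raise ValueError(f"twin pair {pair_id!r} is not sex-matched")
        i, k = grp.index
        pairs.append(Pair(i, k, "twin"))
    return PairDesign(tuple(pairs), stage=stage)


def technical_pairs(metadata: pd.DataFrame) -> PairDesign:
    """All unordered pairs among technical replicates (C(4,2)=6 for quadruplicates)."""
    ids = list(metadata.index[metadata["role"] == "technical"])
    pairs = tuple(Pair(i, k, "technical") for i, k in itertools.combinations(ids, 2))
    return PairDesign(pairs)


def cross_population_pairs(
    metadata: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    stage: str | None = None,
) -> PairDesign:
    """All sex-matched (strain_a, strain_b) pairs of embryos."""
    md = metadata[metadata["role"] == "embryo"]
    if stage is not None:
        md = md[md["stage"] == stage]
    a = md[md["strain"] == strain_a]
    b = md[md["strain"] == strain_b]
    pairs = []
    for i, sex_i in a["sex"].items():
        for k, sex_k in b["sex"].items():
            if sex_i == sex_k:
                pairs.append(Pair(i, k, "cross_population"))
    if not pairs:
        raise ValueError(
            f"no sex-matched pairs between strains {strain_a!r} and {strain_b!r}"
        )
    return PairDesign(tuple(pairs), stage=stage)


def pair_design_from_records(records: Iterable[tuple[str, str, str]], stage=None) -> PairDesign:
    return PairDesign(tuple(Pair(i, k, kind) for i, k, kind in records), stage=stage)
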