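"""Genome gene-content comparison from ortholog presence/absence matrices.

A genome annotated against an ortholog catalogue is a binary signature:
bit k says whether ortholog k is present. AND self-comparison of the packed
presence matrix yields, for every genome pair, the number of shared
orthologs. On top of those raw counts this module computes taxonomic
summaries: the average shared-gene count of a genome with the other members
of its group, the group-by-group mean shared-count matrix (within-group
diagonal excludes self-pairs, which are trivially the genome's gene count),
and selection of genome-reduced ("minimalist") organisms by annotated gene
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bitpack import SignatureMatrix
from .engine import ComparisonResult, compare_self

__all__ = [
    "TaxonomyLabels",
    "GroupSummary",
    "shared_ortholog_counts",
    "within_group_means",
    "group_pair_matrix",
    "select_minimal_genomes",
]

LEVELS = ("domain", "group", "genus")


@dataclass
class TaxonomyLabels:
    """genome id -> (domain, group, genus)."""

    table: pd.DataFrame  # index: genome id; columns: domain, group, genus

    def __post_init__(self) -> None:
        missing = [c for c in LEVELS if c not in self.table.columns]
        if missing:
            raise ValueError(f"taxonomy table lacks columns {missing}")
        for c in LEVELS:
            col = self.table[c]
            if col.isna().any() or (col.astype(str).str.len() == 0).any():
                raise ValueError(f"empty {c} label in taxonomy table")

    @classmethod
    def from_mapping(cls, mapping: Mapping[object, tuple]) -> "TaxonomyLabels":
        frame = pd.DataFrame.from_dict(
            {g: dict(zip(LEVELS, t)) for g, t in mapping.items()}, orient="index"
        )
        return cls(frame)

    def level_of(self, genomes, level: str) -> pd.Series:
        if level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
        missing = [g for g in genomes if g not in self.table.index]
        if missing:
            raise ValueError(f"no taxonomy label for genome {missing[0]!r}")
        return self.table.loc[list(genomes), level]

    def domain_counts(self) -> dict:
        return self.table["domain"].value_counts().to_dict()


@dataclass
class GroupSummary:
    """Group-level shared-gene summaries at one taxonomic level.

    ``per_genome`` holds each genome's mean shared count with the other
    members of its group (NaN for singletons, which are also listed in
    ``singleton_groups``); ``matrix`` is the symmetric group x group mean
    shared-count table with NaN diagonals for singleton groups.
    """

    level: str
    per_genome: pd.Series = None
    matrix: pd.DataFrame = None
    member_counts: pd.Series = None
    singleton_groups: list = field(default_factory=list)


def shared_ortholog_counts(presence: SignatureMatrix) -> ComparisonResult:
    """AND self-comparison: cell (i, j) = orthologs present in both genomes."""
    return compare_self(presence, "AND")


def _symmetric(counts: ComparisonResult) -> np.ndarray:
    if not counts.is_self:
        raise ValueError("group summaries expect a self-comparison result")
    return counts.counts.astype(np.float64) + counts.counts.T.astype(np.float64)


def within_group_means(
    counts: ComparisonResult, labels: TaxonomyLabels, level: str = "group"
) -> GroupSummary:
    """Per-genome mean shared count with the other genomes of its group.

    Singleton groups have no within-group pair; their genomes get NaN and the
    group is flagged in ``singleton_groups``.
    """
    genomes = counts.query_ids
    groups = labels.level_of(genomes, level)
    sym = _symmetric(counts)
    means = pd.Series(np.nan, index=pd.Index(genomes), dtype=float)
    member_counts = groups.value_counts()
    singletons = sorted(member_counts.index[member_counts == 1].tolist(), key=str)
    garr = groups.to_numpy()
    for g in member_counts.index:
        idx = np.nonzero(garr == g)[0]
        if idx.size < 2:
            continue
        block = sym[np.ix_(idx, idx)]
        means.iloc[idx] = block.sum(axis=1) / (idx.size - 1)
    return GroupSummary(
        level=level,
        per_genome=means,
        member_counts=member_counts,
        singleton_groups=singletons,
    )


def group_pair_matrix(
    counts: ComparisonResult, labels: TaxonomyLabels, level: str = "genus"
) -> GroupSummary:
    """Symmetric group x group matrix of mean shared-gene counts.

    Off-diagonal (A, B): mean over all cross pairs a in A, b in B. Diagonal
    (A, A): mean over the C(|A|, 2) within-group pairs, excluding self-pairs;
    NaN (flagged) for singleton groups.
    """
    genomes = counts.query_ids
    groups = labels.level_of(genomes, level)
    sym = _symmetric(counts)
    names = sorted(groups.unique().tolist(), key=str)
    garr = groups.to_numpy()
    idx_of = {g: np.nonzero(garr == g)[0] for g in names}
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a_pos, a in enumerate(names):
        ia = idx_of[a]
        for b in names[a_pos:]:
            ib = idx_of[b]
            if a == b:
                if ia.size < 2:
                    continue  # singleton: stays NaN, flagged below
                block = sym[np.ix_(ia, ia)]
                val = block.sum() / (ia.size * (ia.size - 1))
            else:
                val = sym[np.ix_(ia, ib)].mean()
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    member_counts = groups.value_counts()
    singletons = sorted(member_counts.index[member_counts == 1].tolist(), key=str)
    return GroupSummary(
        level=level,
        matrix=mat,
        member_counts=member_counts,
        singleton_groups=singletons,
    )


def select_minimal_genomes(
    presence: SignatureMatrix, lo: int = 200, hi: int = 600
) -> list:
    """Genomes whose annotated gene count lies in [lo, hi], inclusive."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    pops = presence.popcounts()
    keep = (pops >= lo) & (pops <= hi)
    return [g for g, k in zip(presence.signature_ids, keep) if k]
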