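"""Synthetic data emulating the engine's benchmark and both applications.

Three generators, all pure functions of (config, seed):

* :func:`gaussian_matrix` — continuous expression-like measurements, i.i.d.
  Gaussian with mean 0 and standard deviation 0.5, to be binarized at
  -0.6 / +0.6 (each tail then holds Phi(-1.2) ~ 11.5% of entries). The
  reference benchmark uses 20,000 features; the default keeps that signature
  length with 500 columns so a desk run finishes in seconds, and the full
  15,000-column table is one config away.

* :func:`lincs_like` — paired up/down signature matrices over a 22,688-gene
  universe with planted clusters of similar perturbations: members of a
  cluster draw a fixed fraction of their up and down genes from a shared
  cluster template, background signatures draw all genes at random. Ground
  truth labels come back for recovery tests.

* :func:`kegg_like` — an ortholog presence/absence matrix with taxonomic
  structure: genomes belong to groups (genera) that share a core gene set
  plus per-genome accessory genes; the three domains differ in genome size.
  The default composition is 20,624 orthologs across 4648 genomes (356
  eukaryotes, 4049 bacteria, 243 archaea).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binarize import DenseMatrix, ThresholdSpec
from .bitpack import SignatureMatrix, pack
from .genomesim import TaxonomyLabels

__all__ = [
    "GaussianConfig",
    "LincsConfig",
    "KeggConfig",
    "KEGG_REFERENCE_DOMAIN_COUNTS",
    "gaussian_matrix",
    "lincs_like",
    "kegg_like",
    "total_organisms",
]

# reference composition of the annotated-genome catalogue the generator emulates
KEGG_REFERENCE_DOMAIN_COUNTS = {"eukaryote": 356, "bacterium": 4049, "archaeon": 243}


@dataclass(frozen=True)
class GaussianConfig:
    K: int = 20_000
    N: int = 500
    sigma: float = 0.5
    cuts: ThresholdSpec = field(default_factory=ThresholdSpec)

    def __post_init__(self) -> None:
        if self.K < 1 or self.N < 1 or self.sigma <= 0:
            raise ValueError("K, N must be positive and sigma > 0")


def gaussian_matrix(config: GaussianConfig = GaussianConfig(), seed: int = 0) -> DenseMatrix:
    """K x N i.i.d. draws from N(0, sigma^2), reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, config.sigma, size=(config.K, config.N))
    return DenseMatrix(
        values=values,
        feature_ids=[f"gene{k}" for k in range(config.K)],
        sample_ids=[f"exp{j}" for j in range(config.N)],
    )


@dataclass(frozen=True)
class LincsConfig:
    K: int = 22_688  # gene universe of the expression compendium
    n_clusters: int = 5
    cluster_size: int = 10
    n_background: int = 50
    genes_per_direction: int = 150  # up genes (= down genes) per signature
    overlap_fraction: float = 0.6  # fraction of a member's genes taken from its cluster template

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if min(self.n_clusters, self.cluster_size, self.genes_per_direction) < 1:
            raise ValueError("cluster counts and signature size must be positive")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if 4 * self.genes_per_direction > self.K:
            raise ValueError(
                f"signature size {self.genes_per_direction} per direction is "
                f"infeasible for a {self.K}-gene universe"
            )

    @property
    def N(self) -> int:
        return self.n_clusters * self.cluster_size + self.n_background


def lincs_like(
    config: LincsConfig = LincsConfig(), seed: int = 0
) -> tuple[SignatureMatrix, SignatureMatrix, list]:
    """Planted-cluster up/down signature matrices.

    Returns ``(down, up, truth)``. Each cluster has disjoint up and down
    template gene sets of ``genes_per_direction`` genes; a member takes
    ``round(overlap_fraction * genes_per_direction)`` genes from each
    template and fills the rest at random outside the templates. Background
    signatures are fully random. ``truth`` labels cluster members
    ``"cluster<i>"`` and gives every background signature its own label.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    S = cfg.genes_per_direction
    n_template = round(cfg.overlap_fraction * S)
    K, N = cfg.K, cfg.N
    up = np.zeros((K, N), dtype=np.uint8)
    down = np.zeros((K, N), dtype=np.uint8)
    truth: list[str] = []
    col = 0
    for c in range(cfg.n_clusters):
        template = rng.choice(K, size=2 * S, replace=False)
        t_up, t_down = template[:S], template[S:]
        outside = np.setdiff1d(np.arange(K), template, assume_unique=False)
        for _ in range(cfg.cluster_size):
            fill = rng.choice(outside, size=2 * (S - n_template), replace=False)
            u = np.concatenate(
                [rng.choice(t_up, size=n_template, replace=False), fill[: S - n_template]]
            )
            d = np.concatenate(
                [rng.choice(t_down, size=n_template, replace=False), fill[S - n_template:]]
            )
            up[u, col] = 1
            down[d, col] = 1
            truth.append(f"cluster{c}")
            col += 1
    for b in range(cfg.n_background):
        genes = rng.choice(K, size=2 * S, replace=False)
        up[genes[:S], col] = 1
        down[genes[S:], col] = 1
        truth.append(f"background{b}")
        col += 1
    genes_ids = [f"gene{k}" for k in range(K)]
    sample_ids = [f"sig{j}" for j in range(N)]
    return (
        pack(down, genes_ids, sample_ids),
        pack(up, genes_ids, sample_ids),
        truth,
    )


@dataclass(frozen=True)
class KeggConfig:
    n_orthologs: int = 20_624
    domain_counts: dict = field(
        default_factory=lambda: dict(KEGG_REFERENCE_DOMAIN_COUNTS)
    )
    group_size: int = 8  # genomes per genus-level group (last group may be smaller)
    core_fraction: float = 0.7  # fraction of a group's genome size shared by all members
    # annotated-gene count ranges per domain, genes per genome
    size_ranges: dict = field(
        default_factory=lambda: {
            "eukaryote": (2500, 6000),
            "bacterium": (800, 2500),
            "archaeon": (600, 1500),
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.core_fraction <= 1.0:
            raise ValueError("core_fraction must lie in (0, 1]")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        for d, n in self.domain_counts.items():
            if n < 1:
                raise ValueError(f"domain {d!r} has non-positive genome count {n}")
            if d not in self.size_ranges:
                raise ValueError(f"no genome size range for domain {d!r}")
        for d, (lo, hi) in self.size_ranges.items():
            if not 0 < lo <= hi <= self.n_orthologs:
                raise ValueError(f"bad size range for domain {d!r}: ({lo}, {hi})")


def total_organisms(config: KeggConfig = KeggConfig()) -> int:
    """Validate the per-domain genome counts and return their total."""
    counts = config.domain_counts
    if not counts:
        raise ValueError("empty domain composition")
    for d, n in counts.items():
        if not isinstance(n, int) or n < 1:
            raise ValueError(f"domain {d!r} has invalid genome count {n!r}")
    return sum(counts.values())


def kegg_like(
    config: KeggConfig = KeggConfig(), seed: int = 0
) -> tuple[SignatureMatrix, TaxonomyLabels]:
    """Planted-taxonomy ortholog presence/absence matrix with labels.

    Genomes of one group share a core ortholog set (``core_fraction`` of the
    group's genome size) and add independent accessory orthologs; genome
    sizes are drawn uniformly from the domain's range. Within-group shared
    counts therefore concentrate near the core size, while cross-group
    overlaps stay near the random-subset expectation size_a * size_b / K.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    K = cfg.n_orthologs
    N = total_organisms(cfg)
    presence = np.zeros((K, N), dtype=np.uint8)
    genome_ids: list[str] = []
    labels: dict[str, tuple[str, str, str]] = {}
    col = 0
    for domain in sorted(cfg.domain_counts):
        n_dom = cfg.domain_counts[domain]
        lo, hi = cfg.size_ranges[domain]
        n_groups = math.ceil(n_dom / cfg.group_size)
        sizes = np.array_split(np.arange(n_dom), n_groups)
        for gi, members in enumerate(sizes):
            genome_size = int(rng.integers(lo, hi + 1))
            core_size = round(cfg.core_fraction * genome_size)
            core = rng.choice(K, size=core_size, replace=False)
            genus = f"{domain[:3]}_genus{gi}"
            group = f"{domain[:3]}_group{gi // 4}"
            n_mem = len(members)
            # accessory genes: independent Bernoulli outside the core, with
            # expected count genome_size - core_size per genome
            p_acc = (genome_size - core_size) / max(1, K - core_size)
            acc = rng.random((K, n_mem)) < p_acc
            acc[core, :] = False
            block = acc.astype(np.uint8)
            block[core, :] = 1
            presence[:, col : col + n_mem] = block
            for m in range(n_mem):
                gid = f"{domain[:3]}_g{col + m}"
                genome_ids.append(gid)
                labels[gid] = (domain, group, genus)
            col += n_mem
    packed = pack(
        presence,
        feature_ids=[f"K{k:05d}" for k in range(K)],
        signature_ids=genome_ids,
    )
    return packed, TaxonomyLabels.from_mapping(labels)
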