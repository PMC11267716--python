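"""Diplotype clustering over a locus, with heterozygosity and CNV overlays.

A diplotype (multi-locus genotype) is represented as per-site allele-count
vectors of length 4 (one slot per possible allele, summing to 2 at every
site). The pairwise distance between two individuals is the city-block
(Manhattan) distance between these tensors, divided by the number of sites so
that the scale is per-site and a fixed dendrogram cut height is meaningful
regardless of locus length. Complete-linkage hierarchical clustering is cut
at a fixed height, groups below a minimum size are left unassigned, and the
surviving clusters are numbered 1..k by descending size (0 = unassigned).
Selective sweeps appear as large clusters of near-identical diplotypes;
per-individual observed heterozygosity and gene copy number are overlaid to
distinguish homozygous sweep clusters from mixed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import GenotypeMatrix

__all__ = [
    "ClusterConfig",
    "ClusteringResult",
    "diplotype_distance",
    "cluster_diplotypes",
    "sample_heterozygosity",
    "cluster_variant_frequencies",
    "cluster_cnv_overlay",
]

UNASSIGNED = 0


@dataclass(frozen=True)
class ClusterConfig:
    """Dendrogram cut height (per-site Manhattan distance) and minimum
    cluster size; groups smaller than ``min_cluster_size`` are unassigned."""

    cut_height: float = 0.04
    min_cluster_size: int = 40

    def __post_init__(self) -> None:
        if self.cut_height < 0:
            raise ValueError("cut_height must be >= 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class ClusteringResult:
    """Complete-linkage tree plus flat cluster labels.

    ``labels[i]`` is the cluster of sample ``i``: 1..k by descending cluster
    size, or 0 for unassigned. ``linkage_tree`` is a scipy linkage matrix.
    """

    linkage_tree: np.ndarray
    labels: np.ndarray
    cluster_sizes: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def diplotype_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Condensed pairwise per-site Manhattan distance between diplotypes.

    distance(a, b) = (1/S) * sum over sites and 4 allele slots of
    |count_a - count_b|, with S the number of sites.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples to compute pairwise distances")
    if gm.n_sites < 1:
        raise ValueError("need at least one site to compute pairwise distances")
    flat = np.moveaxis(gm.allele_counts, 1, 0).reshape(gm.n_samples, gm.n_sites * 4)
    return pdist(flat.astype(float), metric="cityblock") / gm.n_sites


def cluster_diplotypes(
    dist: np.ndarray, config: ClusterConfig | None = None
) -> ClusteringResult:
    """Complete-linkage clustering of a condensed distance matrix.

    Flat clusters are the groups whose cophenetic distance is at most
    ``cut_height``; groups smaller than ``min_cluster_size`` are unassigned
    (label 0). Surviving clusters are relabelled 1..k by descending size,
    ties broken by the smallest member index for reproducibility.
    """
    if config is None:
        config = ClusterConfig()
    dist = np.asarray(dist, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * dist.size)) / 2))
    if dist.ndim != 1 or n * (n - 1) // 2 != dist.size or n < 2:
        raise ValueError("dist must be a condensed distance matrix over >= 2 samples")
    tree = linkage(dist, method="complete")
    raw = fcluster(tree, t=config.cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= config.min_cluster_size]
    # order by descending size, then by first-appearing member index
    first_member = {int(c): int(np.flatnonzero(raw == c)[0]) for c in keep.index}
    order = sorted(keep.index, key=lambda c: (-int(keep[c]), first_member[int(c)]))

    labels = np.full(n, UNASSIGNED, dtype=int)
    cluster_sizes: dict[int, int] = {}
    for new_label, raw_label in enumerate(order, start=1):
        labels[raw == raw_label] = new_label
        cluster_sizes[new_label] = int(keep[raw_label])
    return ClusteringResult(tree, labels, cluster_sizes)


def sample_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Observed heterozygosity per individual: fraction of sites at which the
    two alleles differ, averaged over all sites in the locus."""
    if gm.n_sites < 1:
        raise ValueError("need at least one site")
    # homozygous iff one allele slot holds both copies (max count == 2)
    het = gm.allele_counts.max(axis=2) != 2
    return het.mean(axis=0)


def cluster_variant_frequencies(
    gm: GenotypeMatrix,
    annotations: Mapping[int, str],
    result: ClusteringResult,
) -> pd.DataFrame:
    """Non-reference allele frequency of annotated variants per cluster.

    ``annotations`` maps 1-based site positions to labels (amino-acid
    changes). Frequencies are counted over the 2n alleles of each cluster's
    members; the unassigned pool is included as a baseline column.

    Returns a DataFrame indexed by variant label with one column per cluster
    (``cluster_1`` ... ``cluster_k``, ``unassigned``).
    """
    pos_index = {int(p): i for i, p in enumerate(gm.positions)}
    missing = [p for p in annotations if p not in pos_index]
    if missing:
        raise ValueError(f"annotated sites absent from genotype matrix: {sorted(missing)}")

    groups: dict[str, np.ndarray] = {
        f"cluster_{label}": result.members(label) for label in result.cluster_sizes
    }
    groups["unassigned"] = result.members(UNASSIGNED)

    out = {}
    for pos, label in annotations.items():
        site = pos_index[int(pos)]
        row = {}
        for name, members in groups.items():
            if members.size == 0:
                row[name] = np.nan
                continue
            ref = gm.allele_counts[site, members, 0].sum()
            row[name] = 1.0 - ref / (2 * members.size)
        out[label] = row
    return pd.DataFrame.from_dict(out, orient="index")


def cluster_cnv_overlay(
    result: ClusteringResult,
    copy_numbers: Mapping[str, int],
    sample_ids: list[str],
) -> pd.DataFrame:
    """Per-cluster copy-number summary: mean CN and fraction amplified (CN > 2).

    ``copy_numbers`` maps sample id to gene copy number; every clustered
    sample must be present.
    """
    if len(sample_ids) != result.labels.size:
        raise ValueError("sample_ids length must match the clustering")
    missing = [
        sample_ids[i]
        for i in range(len(sample_ids))
        if result.labels[i] != UNASSIGNED and sample_ids[i] not in copy_numbers
    ]
    if missing:
        raise ValueError(f"copy number missing for clustered samples: {missing}")

    rows = []
    for label, size in result.cluster_sizes.items():
        cns = np.array([copy_numbers[sample_ids[i]] for i in result.members(label)])
        rows.append(
            {
                "cluster": label,
                "n": size,
                "mean_copy_number": float(cns.mean()),
                "fraction_amplified": float((cns > 2).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
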