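"""Core in-memory containers shared across the pipeline.

Coordinate conventions
----------------------
Variant positions are stored 1-based (as in VCF POS). Coverage windows and
gene spans are stored 0-based half-open (as in BED/bedGraph). :class:`Region`
is the external, 1-based inclusive representation used in region strings such
as ``2L:28,545,396-28,550,748``; conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "GeneSpan",
    "HaplotypeMatrix",
    "GenotypeMatrix",
    "CoverageTrack",
]

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)\s*(?:-|to)\s*([\d,]+)$")


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval, e.g. ``2L:28,545,396-28,550,748``."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region bounds {self.start}-{self.end}")

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``contig:start-end`` (commas and ``to`` separators allowed)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {text!r}")
        contig, start, end = m.groups()
        return cls(contig, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.contig}:{self.start:,}-{self.end:,}"

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneSpan:
    """A gene interval in 0-based half-open coordinates (BED convention)."""

    gene_id: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span {self.start}-{self.end}")

    def to_region(self) -> Region:
        return Region(self.contig, self.start + 1, self.end)


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: a sites x haplotypes 0/1 matrix.

    Parameters
    ----------
    alleles
        ``(n_sites, n_haplotypes)`` array with entries in {0, 1}. No missing
        data: filtering and imputation are upstream of this container.
    positions
        Strictly increasing 1-based base-pair coordinates, one per site.
    haplotype_ids
        One label per haplotype (sample id plus phase suffix).
    contig
        Chromosome / contig name.
    """

    alleles: np.ndarray
    positions: np.ndarray
    haplotype_ids: list[str]
    contig: str

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D sites x haplotypes matrix")
        if self.positions.shape != (self.alleles.shape[0],):
            raise ValueError("positions length must equal the number of sites")
        if len(self.haplotype_ids) != self.alleles.shape[1]:
            raise ValueError("haplotype_ids length must equal the number of haplotypes")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotypes must be biallelic 0/1 with no missing calls")
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def slice_region(self, region: Region) -> "HaplotypeMatrix":
        if region.contig != self.contig:
            raise ValueError(f"region contig {region.contig!r} != {self.contig!r}")
        keep = (self.positions >= region.start) & (self.positions <= region.end)
        return HaplotypeMatrix(
            self.alleles[keep], self.positions[keep], list(self.haplotype_ids), self.contig
        )


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes as per-site allele counts.

    ``allele_counts`` is a ``(n_sites, n_samples, 4)`` tensor: for each site
    and sample, a length-4 vector of dosages (one slot per possible allele)
    summing to 2. This is the diplotype representation consumed by the
    Manhattan-distance clustering.
    """

    allele_counts: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    contig: str

    def __post_init__(self) -> None:
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int16)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.allele_counts.ndim != 3 or self.allele_counts.shape[2] != 4:
            raise ValueError("allele_counts must have shape (sites, samples, 4)")
        if self.positions.shape != (self.allele_counts.shape[0],):
            raise ValueError("positions length must equal the number of sites")
        if len(self.sample_ids) != self.allele_counts.shape[1]:
            raise ValueError("sample_ids length must equal the number of samples")
        if self.allele_counts.size:
            if (self.allele_counts < 0).any():
                raise ValueError("allele counts must be non-negative")
            if not (self.allele_counts.sum(axis=2) == 2).all():
                raise ValueError(
                    "allele counts must sum to 2 per site/sample (diploid, no missing)"
                )
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.allele_counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.allele_counts.shape[1]

    def slice_region(self, region: Region) -> "GenotypeMatrix":
        if region.contig != self.contig:
            raise ValueError(f"region contig {region.contig!r} != {self.contig!r}")
        keep = (self.positions >= region.start) & (self.positions <= region.end)
        return GenotypeMatrix(
            self.allele_counts[keep], self.positions[keep], list(self.sample_ids), self.contig
        )


@dataclass
class CoverageTrack:
    """Per-sample sequencing depth in fixed-width genomic windows.

    Windows are 0-based half-open, contiguous and non-overlapping (bedGraph
    convention); ``gc`` holds the GC fraction of each window and ``depth`` is
    a ``(n_windows, n_samples)`` matrix of raw (or normalized) depth values.
    """

    contig: str
    starts: np.ndarray
    ends: np.ndarray
    gc: np.ndarray
    depth: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.gc = np.asarray(self.gc, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        n = self.starts.size
        if self.ends.shape != (n,) or self.gc.shape != (n,):
            raise ValueError("starts, ends and gc must have identical lengths")
        if self.depth.ndim != 2 or self.depth.shape[0] != n:
            raise ValueError("depth must have shape (n_windows, n_samples)")
        if len(self.sample_ids) != self.depth.shape[1]:
            raise ValueError("sample_ids length must equal the number of samples")
        if n:
            if not (self.ends > self.starts).all():
                raise ValueError("windows must have positive width")
            if n > 1 and not (self.starts[1:] == self.ends[:-1]).all():
                raise ValueError("windows must tile the region without gaps or overlap")
            if (self.depth < 0).any():
                raise ValueError("depth must be non-negative")
            if ((self.gc < 0) | (self.gc > 1)).any():
                raise ValueError("gc fractions must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return self.starts.size

    @property
    def n_samples(self) -> int:
        return self.depth.shape[1]

    @property
    def window_size(self) -> int:
        if self.n_windows == 0:
            raise ValueError("empty track has no window size")
        return int(self.ends[0] - self.starts[0])
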