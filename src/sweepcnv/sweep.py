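"""Windowed H12 haplotype-homozygosity selection scans.

Plain haplotype homozygosity (H1) over a window of phased haplotypes is the
sum of squared haplotype frequencies, ``H1 = sum_i p_i^2``. H12 pools the two
most frequent haplotypes into a single class before squaring::

    H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2

which makes the statistic sensitive to soft sweeps (several distinct
haplotypes at elevated frequency) as well as hard sweeps. The scan computes
H12 in non-overlapping windows of a fixed number of SNPs over a cohort that
is first downsampled once to a fixed number of haplotypes, so that H12 values
are comparable across cohorts of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HaplotypeMatrix

__all__ = ["ScanConfig", "haplotype_frequency_spectrum", "h1", "h12", "scan"]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the windowed H12 scan.

    window_snps: number of SNPs per (non-overlapping) window.
    n_haplotypes_sampled: cohort is downsampled once, without replacement,
        to this many haplotypes before scanning.
    seed: seed for the downsampling draw.
    """

    window_snps: int = 1500
    n_haplotypes_sampled: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.n_haplotypes_sampled < 1:
            raise ValueError("n_haplotypes_sampled must be >= 1")


def haplotype_frequency_spectrum(window: np.ndarray) -> np.ndarray:
    """Frequencies of distinct whole-window haplotypes, sorted descending.

    Parameters
    ----------
    window
        ``(n_sites, n_haplotypes)`` allele matrix; two haplotypes belong to
        the same class iff they are identical at every site in the window.

    Returns
    -------
    1-D float array of class frequencies, descending, summing to 1.
    """
    window = np.asarray(window)
    if window.ndim != 2:
        raise ValueError("window must be 2-D (sites x haplotypes)")
    n_sites, n_haps = window.shape
    if n_haps == 0:
        raise ValueError("window contains zero haplotypes")
    if n_sites == 0:
        raise ValueError("window contains zero sites")
    # row-wise unique over haplotype columns
    _, counts = np.unique(np.ascontiguousarray(window.T), axis=0, return_counts=True)
    freqs = np.sort(counts)[::-1] / n_haps
    return freqs.astype(float)


def _check_spectrum(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("frequency spectrum must be a non-empty 1-D vector")
    if (np.diff(freqs) > 1e-12).any():
        raise ValueError("frequencies must be sorted in descending order")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {freqs.sum()!r})")
    if (freqs < 0).any():
        raise ValueError("frequencies must be non-negative")
    return freqs


def h1(freqs: np.ndarray) -> float:
    """Plain haplotype homozygosity: sum of squared class frequencies."""
    freqs = _check_spectrum(freqs)
    return float(np.square(freqs).sum())


def h12(freqs: np.ndarray) -> float:
    """H12 from a descending haplotype frequency spectrum.

    The two most frequent classes are pooled before taking the sum of
    squares. A monomorphic window (single class) returns 1.
    """
    freqs = _check_spectrum(freqs)
    if freqs.size == 1:
        return 1.0
    return float((freqs[0] + freqs[1]) ** 2 + np.square(freqs[2:]).sum())


def scan(haps: HaplotypeMatrix, config: ScanConfig | None = None) -> pd.DataFrame:
    """Windowed H12 scan over a haplotype matrix.

    The cohort is downsampled once to ``config.n_haplotypes_sampled``
    haplotypes (without replacement, seeded), then split into contiguous
    non-overlapping windows of ``config.window_snps`` SNPs; a trailing
    remainder shorter than one window is dropped.

    Returns
    -------
    DataFrame with one row per window and columns ``contig``, ``start``,
    ``end``, ``midpoint``, ``n_snps`` and ``h12``. ``midpoint`` is the
    midpoint between the window's first and last SNP; ``start``/``end``
    delimit the genomic interval the window represents — boundaries lie
    midway between adjacent windows' edge SNPs, so consecutive windows
    partition the scanned range without gaps.
    """
    if config is None:
        config = ScanConfig()
    if haps.n_haplotypes < config.n_haplotypes_sampled:
        raise ValueError(
            f"cohort has {haps.n_haplotypes} haplotypes, fewer than the "
            f"{config.n_haplotypes_sampled} requested for downsampling"
        )
    n_windows = haps.n_sites // config.window_snps
    if n_windows == 0:
        raise ValueError(
            f"{haps.n_sites} SNPs is fewer than one window of {config.window_snps}"
        )
    rng = np.random.default_rng(config.seed)
    idx = np.sort(
        rng.choice(haps.n_haplotypes, size=config.n_haplotypes_sampled, replace=False)
    )
    sub = haps.alleles[:, idx]

    rows = []
    for w in range(n_windows):
        lo = w * config.window_snps
        hi = lo + config.window_snps
        value = h12(haplotype_frequency_spectrum(sub[lo:hi]))
        first = int(haps.positions[lo])
        last = int(haps.positions[hi - 1])
        start = first if w == 0 else (int(haps.positions[lo - 1]) + first + 1) // 2
        end = (
            last
            if hi == n_windows * config.window_snps and hi >= haps.n_sites
            else (last + int(haps.positions[hi])) // 2
        )
        rows.append(
            {
                "contig": haps.contig,
                "start": start,
                "end": end,
                "midpoint": (first + last) // 2,
                "n_snps": config.window_snps,
                "h12": value,
            }
        )
    return pd.DataFrame(rows)
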