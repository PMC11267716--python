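"""Synthetic cohorts with known ground truth.

Generates the four kinds of input the analysis consumes — phased haplotypes
with planted selective sweeps, paired diploid genotypes, windowed coverage
tracks with planted multi-copy duplications, and bioassay phenotypes drawn
from a logistic model on copy number — so that every downstream statistic
can be checked against truth.

The haplotype background is a founder-mosaic model, not a coalescent: each
neutral haplotype is stitched from segments of a small founder pool (switch
points Poisson along the region) and then receives private mutations at a
fixed per-kb rate. This reproduces the feature H12 consumes — a haplotype
frequency spectrum with shared cores and individually unique haplotypes —
without simulating genealogies. A sweep plants one (hard) or several (soft)
near-identical core haplotypes on a chosen fraction of chromosomes around a
focal position, with identity decaying linearly with distance outside the
core width, mimicking recombination eroding an aging sweep.

All randomness flows from explicit seeds through ``numpy.random.default_rng``;
identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .containers import CoverageTrack, GenotypeMatrix, HaplotypeMatrix

__all__ = [
    "SimConfig",
    "CoverageSimConfig",
    "PhenotypeSimConfig",
    "SimTruth",
    "simulate_haplotypes",
    "pair_to_diplotypes",
    "simulate_coverage",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class SimConfig:
    """Haplotype-simulation parameters.

    n_samples: diploid cohort size (2*n_samples haplotypes are produced).
    n_sites: number of segregating biallelic sites in the region.
    region_span: region length in base pairs.
    mutation_density: expected private mutations per kb per haplotype,
        applied as allele flips at existing sites (breaks haplotype identity
        outside sweep cores).
    sweep_frequency: fraction of haplotypes carrying a sweep core.
    n_sweep_haplotypes: number of distinct cores (1 = hard sweep, >1 = soft).
    sweep_center / sweep_width: focal position and width (bp) of the fully
        identical core; with ``decay`` enabled, core identity fades linearly
        to zero over one further ``sweep_width`` beyond the core edge.
    n_founders: size of the neutral founder pool.
    mosaic_switches: expected founder switch points per background haplotype.
    """

    n_samples: int = 100
    n_sites: int = 5000
    region_span: int = 500_000
    mutation_density: float = 0.2
    sweep_frequency: float = 0.5
    n_sweep_haplotypes: int = 1
    sweep_center: int = 250_000
    sweep_width: int = 150_000
    n_founders: int = 20
    mosaic_switches: float = 5.0
    decay: bool = True
    contig: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not 0.0 <= self.sweep_frequency <= 1.0:
            raise ValueError("sweep_frequency must lie in [0, 1]")
        if self.n_sweep_haplotypes < 1:
            raise ValueError("n_sweep_haplotypes must be >= 1")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.region_span < self.n_sites:
            raise ValueError("region_span must be >= n_sites")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class CoverageSimConfig:
    """Coverage-simulation parameters.

    Raw depth per 300 bp window is negative-binomial with mean
    ``base_depth * gc_bias(gc) * copy_number/2`` and variance
    ``mean * overdispersion`` (Poisson at overdispersion = 1).
    ``planted_cnvs`` is a list of (sample_id, start, end, copy_number)
    intervals in 0-based half-open coordinates; copy numbers must be 0..12.
    """

    region_span: int = 90_000
    window_size: int = 300
    base_depth: float = 30.0
    gc_bias_curve: Callable[[np.ndarray], np.ndarray] | None = None
    overdispersion: float = 1.0
    planted_cnvs: Sequence[tuple[str, int, int, int]] = ()
    gc_range: tuple[float, float] = (0.30, 0.60)
    contig: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1 (variance inflation)")
        for sample, start, end, cn in self.planted_cnvs:
            if not 0 <= cn <= 12:
                raise ValueError(f"planted copy number {cn} outside 0..12")
            if not (0 <= start < end <= self.region_span):
                raise ValueError(
                    f"planted CNV {start}-{end} for {sample!r} outside region"
                )


@dataclass(frozen=True)
class PhenotypeSimConfig:
    """Inverse of the association model: survival probability is
    logistic(intercept + beta_cnv*(CN-2) + beta_covariate*cov + location
    offset) and phenotypes are Bernoulli draws from it."""

    intercept: float = 0.0
    beta_cnv: float = float(np.log(1.62))
    beta_covariate: float = 0.0
    location_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth accumulated across the simulation stages."""

    swept_haplotype_ids: set[str] = field(default_factory=set)
    sweep_core_assignment: dict[str, int] = field(default_factory=dict)
    per_sample_copy_number: dict[str, int] = field(default_factory=dict)
    per_sample_survival_prob: dict[str, float] = field(default_factory=dict)


def _founder_mosaic(
    rng: np.random.Generator, founders: np.ndarray, mean_switches: float
) -> np.ndarray:
    """One haplotype stitched from founder segments."""
    n_founders, n_sites = founders.shape
    if n_founders == 1 or mean_switches == 0:
        return founders[rng.integers(n_founders)].copy()
    n_switch = rng.poisson(mean_switches)
    cuts = np.sort(rng.integers(1, n_sites, size=n_switch)) if n_switch else np.array([], int)
    bounds = np.concatenate(([0], cuts, [n_sites]))
    hap = np.empty(n_sites, dtype=np.int8)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        hap[lo:hi] = founders[rng.integers(n_founders), lo:hi]
    return hap


def simulate_haplotypes(config: SimConfig) -> tuple[HaplotypeMatrix, SimTruth]:
    """Simulate phased haplotypes with a planted sweep; returns matrix + truth.

    Background haplotypes are founder mosaics plus private mutations. A
    fraction ``sweep_frequency`` of haplotypes then has a sweep core copied
    over it: identical within ``sweep_width`` of ``sweep_center``, and (if
    ``decay``) retained with linearly decreasing probability beyond, so
    haplotype identity erodes with distance from the focal site.
    """
    rng = np.random.default_rng(config.seed)
    n_haps = 2 * config.n_samples

    positions = np.sort(
        rng.choice(config.region_span, size=config.n_sites, replace=False) + 1
    )
    # ~1/f allele-frequency spectrum for founder alleles (log-uniform)
    p_site = np.exp(rng.uniform(np.log(0.02), np.log(0.98), size=config.n_sites))
    founders = (rng.random((config.n_founders, config.n_sites)) < p_site).astype(np.int8)

    alleles = np.empty((config.n_sites, n_haps), dtype=np.int8)
    mu = config.mutation_density * config.region_span / 1000.0
    for h in range(n_haps):
        hap = _founder_mosaic(rng, founders, config.mosaic_switches)
        n_mut = rng.poisson(mu)
        if n_mut:
            flip = rng.choice(config.n_sites, size=min(n_mut, config.n_sites), replace=False)
            hap[flip] ^= 1
        alleles[:, h] = hap

    hap_ids = [f"h{h:04d}" for h in range(n_haps)]
    truth = SimTruth()

    n_swept = int(round(config.sweep_frequency * n_haps))
    if n_swept:
        cores = np.stack(
            [
                _founder_mosaic(rng, founders, config.mosaic_switches)
                for _ in range(config.n_sweep_haplotypes)
            ]
        )
        swept = rng.choice(n_haps, size=n_swept, replace=False)
        core_of = rng.integers(config.n_sweep_haplotypes, size=n_swept)
        dist = np.abs(positions - config.sweep_center).astype(float)
        half = config.sweep_width / 2.0
        if config.decay:
            p_keep = np.clip(1.0 - (dist - half) / config.sweep_width, 0.0, 1.0)
        else:
            p_keep = np.ones_like(dist)
        for h, c in zip(swept, core_of):
            keep = rng.random(config.n_sites) < p_keep
            alleles[keep, h] = cores[c, keep]
            truth.swept_haplotype_ids.add(hap_ids[h])
            truth.sweep_core_assignment[hap_ids[h]] = int(c)

    return HaplotypeMatrix(alleles, positions, hap_ids, config.contig), truth


def pair_to_diplotypes(
    haps: HaplotypeMatrix, seed: int
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Pair haplotypes without replacement into diploid samples.

    Allele dosage per site is the sum of the two haplotypes; the returned
    pairing (list of haplotype-id pairs, one per sample, in sample order)
    lets callers propagate haplotype-level truth to samples.
    """
    if haps.n_haplotypes % 2:
        raise ValueError(f"odd number of haplotypes ({haps.n_haplotypes}); cannot pair")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(haps.n_haplotypes)
    n_samples = haps.n_haplotypes // 2
    counts = np.zeros((haps.n_sites, n_samples, 4), dtype=np.int16)
    pairing = []
    for s in range(n_samples):
        a, b = perm[2 * s], perm[2 * s + 1]
        dosage = haps.alleles[:, a].astype(np.int16) + haps.alleles[:, b]
        counts[:, s, 0] = 2 - dosage
        counts[:, s, 1] = dosage
        pairing.append((haps.haplotype_ids[a], haps.haplotype_ids[b]))
    sample_ids = [f"S{s:04d}" for s in range(n_samples)]
    return GenotypeMatrix(counts, haps.positions.copy(), sample_ids, haps.contig), pairing


def simulate_coverage(
    config: CoverageSimConfig, sample_ids: Sequence[str]
) -> tuple[CoverageTrack, np.ndarray]:
    """Simulate a raw windowed coverage track with planted duplications.

    Returns the track and the true per-window copy-number matrix
    (``n_windows x n_samples``; baseline 2 outside planted intervals).
    """
    rng = np.random.default_rng(config.seed)
    n_win = config.region_span // config.window_size
    if n_win < 1:
        raise ValueError("region shorter than one window")
    starts = np.arange(n_win, dtype=np.int64) * config.window_size
    ends = starts + config.window_size
    gc = rng.uniform(*config.gc_range, size=n_win)
    gc_mult = (
        np.ones(n_win) if config.gc_bias_curve is None else np.asarray(
            config.gc_bias_curve(gc), dtype=float
        )
    )

    sample_index = {s: i for i, s in enumerate(sample_ids)}
    cn = np.full((n_win, len(sample_ids)), 2, dtype=int)
    for sample, start, end, copy in config.planted_cnvs:
        if sample not in sample_index:
            raise ValueError(f"planted CNV names unknown sample {sample!r}")
        w = (starts < end) & (ends > start)
        cn[w, sample_index[sample]] = copy

    mean = config.base_depth * gc_mult[:, None] * cn / 2.0
    if config.overdispersion == 1.0:
        depth = rng.poisson(mean).astype(float)
    else:
        # NB with var = mean * overdispersion: r = mean/(od-1), p = r/(r+mean)
        r = mean / (config.overdispersion - 1.0)
        depth = np.where(
            mean > 0, rng.negative_binomial(np.where(mean > 0, r, 1.0),
                                            np.where(mean > 0, r / (r + mean), 1.0)), 0.0
        ).astype(float)
    track = CoverageTrack(config.contig, starts, ends, gc, depth, list(sample_ids))
    return track, cn


def simulate_phenotypes(
    config: PhenotypeSimConfig,
    copy_numbers: Sequence[int],
    covariates: Sequence[float],
    locations: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Draw dead/alive phenotypes from the logistic survival model.

    Returns ``(phenotypes, survival_probs)``; phenotype 1 = alive
    (resistant). Unknown locations raise.
    """
    cn = np.asarray(copy_numbers, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    locs = list(locations)
    if not (cn.size == cov.size == len(locs)):
        raise ValueError("copy_numbers, covariates and locations must align")
    if config.location_effects:
        unknown = sorted(set(locs) - set(config.location_effects))
        if unknown:
            raise ValueError(f"unknown locations: {unknown}")
    offsets = np.array(
        [config.location_effects.get(l, 0.0) for l in locs], dtype=float
    )
    eta = config.intercept + config.beta_cnv * (cn - 2.0) + config.beta_covariate * cov + offsets
    prob = expit(eta)
    rng = np.random.default_rng(config.seed)
    phen = (rng.random(cn.size) < prob).astype(int)
    return phen, prob
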