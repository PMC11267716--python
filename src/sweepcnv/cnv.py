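"""Copy-number calling from windowed sequencing coverage.

Depth in fixed 300 bp windows is first normalized for local nucleotide
composition: within each 2% GC bin, a sample's window depths are divided by
the sample's median depth in that bin and rescaled so that the diploid
expectation is 2. Windows falling in sparsely populated GC bins are flagged
and excluded from copy-number inference. A 13-state hidden Markov model
(copy numbers 0..12, Gaussian emissions centred on the state copy number
with a shared variance, strong self-transition) is decoded by Viterbi to
give an integer copy-number state per window. Samples whose normalized
coverage is too erratic (variance of coverage/2 above 0.2) are excluded from
gene-level calls. Gene copy number is the modal state over the windows
overlapping the gene; the genomic span of an amplification is the maximal
run of contiguous windows above the diploid state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .containers import CoverageTrack, GeneSpan

__all__ = [
    "HmmConfig",
    "NormalizedCoverage",
    "normalize_coverage",
    "estimate_emission_variance",
    "viterbi_copy_number",
    "path_log_probability",
    "coverage_variance_qc",
    "gene_copy_number",
    "cnv_span",
    "cohort_cnv_frequency",
]

GC_BIN_WIDTH = 0.02
MIN_WINDOWS_PER_BIN = 10
BASELINE_COPY_NUMBER = 2


@dataclass(frozen=True)
class HmmConfig:
    """Copy-number HMM parameters.

    The chain has 13 hidden states for copy numbers 0..12 (detecting up to a
    6-fold amplification, i.e. 10 extra copies). Emissions are Gaussian with
    mean equal to the state copy number and a shared variance; if
    ``emission_variance`` is None it is estimated per sample from
    presumed-diploid windows (trimmed variance). ``transition_prob`` is the
    per-window probability of leaving the current state, split equally among
    the other states; the default strongly favours long constant segments.
    """

    state_copy_numbers: tuple[int, ...] = tuple(range(13))
    emission_variance: float | None = None
    transition_prob: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.state_copy_numbers) < 2:
            raise ValueError("need at least two hidden states")
        if not 0 < self.transition_prob < 1:
            raise ValueError("transition_prob must lie in (0, 1)")
        if self.emission_variance is not None and self.emission_variance <= 0:
            raise ValueError("emission_variance must be positive")


@dataclass
class NormalizedCoverage:
    """GC-normalized coverage: diploid expectation 2 per window.

    ``flagged`` marks windows in GC bins with fewer than
    ``MIN_WINDOWS_PER_BIN`` members; these are excluded from HMM input.
    """

    track: CoverageTrack
    values: np.ndarray
    flagged: np.ndarray

    @property
    def usable(self) -> np.ndarray:
        return ~self.flagged


def normalize_coverage(track: CoverageTrack) -> NormalizedCoverage:
    """Normalize windowed depth for GC composition, per sample.

    Each window's depth is divided by the median depth of all the sample's
    windows in the same 2% GC bin and multiplied by 2 (diploid baseline).
    The normalization is scale-free: multiplying a sample's depths by any
    constant leaves the output unchanged.
    """
    if track.n_windows == 0:
        raise ValueError("empty coverage track")
    bins = np.minimum((track.gc / GC_BIN_WIDTH).astype(int), int(1 / GC_BIN_WIDTH) - 1)
    counts = np.bincount(bins)
    flagged = counts[bins] < MIN_WINDOWS_PER_BIN

    values = np.empty_like(track.depth, dtype=float)
    for s in range(track.n_samples):
        depth = track.depth[:, s]
        if not depth.any():
            raise ValueError(
                f"sample {track.sample_ids[s]!r} has all-zero coverage; cannot normalize"
            )
        for b in np.unique(bins):
            mask = bins == b
            med = np.median(depth[mask])
            if med == 0 and not flagged[mask].all():
                raise ValueError(
                    f"zero median depth in GC bin {b} for sample "
                    f"{track.sample_ids[s]!r}; cannot normalize"
                )
            values[mask, s] = depth[mask] / med * 2.0 if med > 0 else 0.0
    return NormalizedCoverage(track, values, flagged)


def estimate_emission_variance(values: np.ndarray, trim: float = 0.1) -> float:
    """Shared Gaussian emission variance from presumed-diploid windows.

    Takes the central ``1 - 2*trim`` fraction of the normalized values (which
    discards windows inside amplifications or deletions provided they are a
    minority) and rescales the trimmed variance by the truncated-normal
    variance ratio, so the estimator is consistent when the diploid noise is
    Gaussian. Floored at 1e-4.
    """
    from scipy.stats import norm as _norm

    values = np.sort(np.asarray(values, dtype=float))
    k = int(trim * values.size)
    core = values[k : values.size - k] if values.size > 2 * k else values
    var = float(np.var(core))
    if k:
        # Var of N(0,1) truncated to its central 1-2*trim mass
        z = _norm.ppf(1 - trim)
        ratio = 1.0 - 2.0 * z * _norm.pdf(z) / (1.0 - 2.0 * trim)
        var /= ratio
    return max(var, 1e-4)


def _hmm_log_params(config: HmmConfig, sigma2: float):
    means = np.asarray(config.state_copy_numbers, dtype=float)
    k = means.size
    log_trans = np.full((k, k), np.log(config.transition_prob / (k - 1)))
    np.fill_diagonal(log_trans, np.log1p(-config.transition_prob))
    log_init = np.full(k, -np.log(k))
    return means, log_trans, log_init


def _emission_logp(obs: np.ndarray, means: np.ndarray, sigma2: float) -> np.ndarray:
    return -0.5 * (obs[:, None] - means[None, :]) ** 2 / sigma2 - 0.5 * np.log(
        2 * np.pi * sigma2
    )


def viterbi_copy_number(values: np.ndarray, config: HmmConfig | None = None) -> np.ndarray:
    """Most probable copy-number state path for one sample's normalized coverage.

    Dynamic-programming (Viterbi) decoding under Gaussian emissions and a
    near-diagonal transition matrix. Ties are broken deterministically toward
    the lower copy number. ``values`` must already exclude flagged windows.

    Returns an integer array of copy-number states, one per window.
    """
    if config is None:
        config = HmmConfig()
    obs = np.asarray(values, dtype=float)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    sigma2 = (
        config.emission_variance
        if config.emission_variance is not None
        else estimate_emission_variance(obs)
    )
    means, log_trans, log_init = _hmm_log_params(config, sigma2)
    logb = _emission_logp(obs, means, sigma2)

    n, k = logb.shape
    delta = log_init + logb[0]
    psi = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + log_trans  # (from, to)
        psi[t] = np.argmax(scores, axis=0)  # argmax -> first max = lower CN
        delta = scores[psi[t], np.arange(k)] + logb[t]

    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return np.asarray(config.state_copy_numbers, dtype=int)[path]


def path_log_probability(
    values: np.ndarray, states: np.ndarray, config: HmmConfig | None = None
) -> float:
    """Joint log-probability of a given state path and the observations.

    Useful for verifying that the Viterbi path dominates alternatives.
    ``states`` are copy numbers (entries of ``config.state_copy_numbers``).
    """
    if config is None:
        config = HmmConfig()
    obs = np.asarray(values, dtype=float)
    states = np.asarray(states, dtype=int)
    if obs.shape != states.shape:
        raise ValueError("values and states must have equal length")
    sigma2 = (
        config.emission_variance
        if config.emission_variance is not None
        else estimate_emission_variance(obs)
    )
    means, log_trans, log_init = _hmm_log_params(config, sigma2)
    state_index = {cn: i for i, cn in enumerate(config.state_copy_numbers)}
    idx = np.array([state_index[int(s)] for s in states])
    logb = _emission_logp(obs, means, sigma2)
    total = log_init[idx[0]] + logb[0, idx[0]]
    for t in range(1, idx.size):
        total += log_trans[idx[t - 1], idx[t]] + logb[t, idx[t]]
    return float(total)


def coverage_variance_qc(
    values: np.ndarray, threshold: float = 0.2
) -> tuple[bool, float]:
    """Sample-level coverage QC.

    Computes the variance of normalized coverage on the coverage/2 scale
    across windows; the sample fails iff the variance is strictly above the
    threshold (a value exactly at the threshold is retained). High variance
    produces erratic copy-number calls.

    Returns ``(passed, variance)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two windows for variance QC")
    variance = float(np.var(values / BASELINE_COPY_NUMBER))
    return variance <= threshold, variance


def gene_copy_number(
    states: np.ndarray, track: CoverageTrack, gene: GeneSpan
) -> dict:
    """Gene-level copy number: modal state over the windows overlapping the gene.

    Ties are broken toward the diploid state 2, then toward the lower copy
    number. Returns a dict with ``gene_id``, ``copy_number`` and
    ``extra_copies`` (= copy_number - 2).
    """
    states = np.asarray(states, dtype=int)
    if states.shape != (track.n_windows,):
        raise ValueError("states must align with the track windows")
    if gene.contig != track.contig:
        raise ValueError(f"gene contig {gene.contig!r} != track contig {track.contig!r}")
    overlap = (track.starts < gene.end) & (track.ends > gene.start)
    if not overlap.any():
        raise ValueError(f"gene {gene.gene_id} overlaps no coverage window")
    counts = np.bincount(states[overlap])
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    cn = BASELINE_COPY_NUMBER if BASELINE_COPY_NUMBER in candidates else int(candidates[0])
    return {"gene_id": gene.gene_id, "copy_number": cn, "extra_copies": cn - 2}


def cnv_span(
    states: np.ndarray, track: CoverageTrack, gene: GeneSpan
) -> tuple[int, int]:
    """Genomic span of the amplification containing a gene.

    The maximal run of contiguous windows with state > 2 that overlaps the
    gene, returned as (start, end) in 0-based half-open base pairs. Raises if
    no amplified window overlaps the gene.
    """
    states = np.asarray(states, dtype=int)
    amplified = states > BASELINE_COPY_NUMBER
    overlap = (track.starts < gene.end) & (track.ends > gene.start)
    seeds = np.flatnonzero(amplified & overlap)
    if seeds.size == 0:
        raise ValueError(f"gene {gene.gene_id} is not amplified in this sample")
    lo = hi = int(seeds[0])
    while lo > 0 and amplified[lo - 1]:
        lo -= 1
    while hi + 1 < states.size and amplified[hi + 1]:
        hi += 1
    return int(track.starts[lo]), int(track.ends[hi])


def cohort_cnv_frequency(
    gene_cn: pd.DataFrame,
    metadata: pd.DataFrame,
    cohort_cols: list[str],
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Per-cohort frequency of samples carrying at least one extra gene copy.

    ``gene_cn`` must hold QC-passing samples only, with columns
    ``sample_col`` and ``copy_number``; cohorts are defined by the metadata
    columns in ``cohort_cols``. Returns frequency with Wilson 95% CI per
    cohort; empty cohorts (no genotyped samples) are skipped with a warning.
    """
    merged = metadata.merge(gene_cn[[sample_col, "copy_number"]], on=sample_col, how="left")
    rows = []
    for key, grp in merged.groupby(cohort_cols, sort=True, dropna=False):
        called = grp.dropna(subset=["copy_number"])
        if called.empty:
            warnings.warn(f"cohort {key!r} has no copy-number calls; skipped", stacklevel=2)
            continue
        n_amp = int((called["copy_number"] > BASELINE_COPY_NUMBER).sum())
        n_tot = len(called)
        lo, hi = proportion_confint(n_amp, n_tot, alpha=0.05, method="wilson")
        lo = 0.0 if n_amp == 0 else max(float(lo), 0.0)
        hi = 1.0 if n_amp == n_tot else min(float(hi), 1.0)
        row = dict(zip(cohort_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            n_amplified=n_amp,
            n_total=n_tot,
            frequency=n_amp / n_tot,
            ci_low=float(lo),
            ci_high=float(hi),
        )
        rows.append(row)
    return pd.DataFrame(rows)
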