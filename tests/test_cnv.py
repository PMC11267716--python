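"""Coverage normalization, the copy-number HMM, QC and gene summaries."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from sweepcnv import (
    CoverageSimConfig,
    CoverageTrack,
    GeneSpan,
    HmmConfig,
    cnv_span,
    cohort_cnv_frequency,
    coverage_variance_qc,
    gene_copy_number,
    normalize_coverage,
    simulate_coverage,
    viterbi_copy_number,
)
from sweepcnv.cnv import estimate_emission_variance, path_log_probability


def flat_track(depth_matrix, gc=0.45, window=300, contig="sim1"):
    depth_matrix = np.atleast_2d(np.asarray(depth_matrix, dtype=float)).T
    n = depth_matrix.shape[0]
    starts = np.arange(n) * window
    return CoverageTrack(
        contig, starts, starts + window, np.full(n, gc), depth_matrix,
        [f"s{j}" for j in range(depth_matrix.shape[1])],
    )


def brute_force_viterbi(obs, config: HmmConfig, sigma2: float):
    """Exhaustive enumeration over all state paths."""
    means = np.asarray(config.state_copy_numbers, dtype=float)
    k, n = means.size, len(obs)
    logb = (
        -0.5 * (np.asarray(obs)[:, None] - means[None, :]) ** 2 / sigma2
        - 0.5 * np.log(2 * np.pi * sigma2)
    )
    log_stay = np.log1p(-config.transition_prob)
    log_move = np.log(config.transition_prob / (k - 1))
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=n):
        score = -np.log(k) + logb[0, path[0]]
        for t in range(1, n):
            score += log_stay if path[t] == path[t - 1] else log_move
            score += logb[t, path[t]]
        if score > best_score:
            best_score, best_path = score, path
    return np.asarray(config.state_copy_numbers)[list(best_path)], best_score


class TestNormalization:
    def test_flat_depth_flat_gc_normalizes_to_two(self):
        track = flat_track(np.full(50, 30.0))
        norm = normalize_coverage(track)
        np.testing.assert_allclose(norm.values[norm.usable], 2.0)

    def test_doubled_segment_normalizes_to_four(self):
        depth = np.full(100, 30.0)
        depth[40:50] = 60.0
        norm = normalize_coverage(flat_track(depth))
        np.testing.assert_allclose(norm.values[40:50, 0], 4.0)
        np.testing.assert_allclose(norm.values[:40, 0], 2.0)

    def test_scale_free(self, rng):
        cfg = CoverageSimConfig(region_span=120_000, base_depth=25.0, seed=8,
                                planted_cnvs=[("s0", 30_000, 36_000, 4)])
        track, _ = simulate_coverage(cfg, ["s0"])
        norm1 = normalize_coverage(track)
        scaled = CoverageTrack(track.contig, track.starts, track.ends, track.gc,
                               track.depth * 7.0, track.sample_ids)
        norm2 = normalize_coverage(scaled)
        np.testing.assert_allclose(norm1.values, norm2.values)
        s1 = viterbi_copy_number(norm1.values[norm1.usable, 0])
        s2 = viterbi_copy_number(norm2.values[norm2.usable, 0])
        np.testing.assert_array_equal(s1, s2)
        assert coverage_variance_qc(norm1.values[norm1.usable, 0]) == \
            coverage_variance_qc(norm2.values[norm2.usable, 0])

    def test_sparse_gc_bins_flagged(self):
        gc = np.full(60, 0.45)
        gc[:5] = 0.95  # 5 windows in a lonely bin
        track = CoverageTrack("c", np.arange(60) * 300, np.arange(1, 61) * 300,
                              gc, np.full((60, 1), 30.0), ["s0"])
        norm = normalize_coverage(track)
        assert norm.flagged[:5].all()
        assert not norm.flagged[5:].any()

    def test_all_zero_sample_rejected(self):
        track = flat_track(np.zeros(20))
        with pytest.raises(ValueError, match="all-zero"):
            normalize_coverage(track)


class TestViterbi:
    def test_constant_coverage_tracks_state(self):
        for level in (2.0, 4.0):
            states = viterbi_copy_number(
                np.full(30, level), HmmConfig(emission_variance=0.05)
            )
            assert (states == int(level)).all()

    def test_zero_variance_limit_rounds_coverage(self):
        obs = np.array([2.0, 2.0, 3.0, 6.0, 6.0, 0.0, 1.0])
        states = viterbi_copy_number(obs, HmmConfig(emission_variance=1e-9,
                                                    transition_prob=0.5))
        np.testing.assert_array_equal(states, obs.astype(int))

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            viterbi_copy_number(np.array([]))

    def test_matches_exhaustive_enumeration_small(self, rng):
        cfg5 = HmmConfig(state_copy_numbers=tuple(range(5)),
                         emission_variance=0.2, transition_prob=0.01)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            obs = rng.uniform(0, 4.5, size=n)
            expected, best_score = brute_force_viterbi(obs, cfg5, 0.2)
            got = viterbi_copy_number(obs, cfg5)
            assert path_log_probability(obs, got, cfg5) == pytest.approx(best_score)
            np.testing.assert_array_equal(got, expected)

    def test_viterbi_dominates_random_paths(self, rng):
        cfg = HmmConfig(emission_variance=0.15)
        obs = np.clip(rng.normal(2.0, 0.4, size=40), 0, None)
        obs[10:20] = rng.normal(4.0, 0.4, size=10)
        path = viterbi_copy_number(obs, cfg)
        best = path_log_probability(obs, path, cfg)
        for _ in range(1000):
            alt = rng.integers(0, 13, size=40)
            assert best >= path_log_probability(obs, alt, cfg) - 1e-9

    def test_emission_variance_estimated_from_diploid_windows(self, rng):
        values = rng.normal(2.0, 0.3, size=500)
        values[:25] = 6.0  # amplified minority must be trimmed away
        est = estimate_emission_variance(values)
        assert est == pytest.approx(0.09, rel=0.35)


class TestQC:
    def test_constant_coverage_passes_with_zero_variance(self):
        passed, var = coverage_variance_qc(np.full(40, 2.0))
        assert passed and var == 0.0

    def test_threshold_is_strictly_above(self):
        # variance of coverage/2 exactly 0.2 -> retained
        x = 2.0 + 2.0 * np.sqrt(0.2) * np.tile([1.0, -1.0], 20)
        passed, var = coverage_variance_qc(x)
        assert var == pytest.approx(0.2, abs=1e-12)
        assert passed
        x_hi = 2.0 + 2.0 * np.sqrt(0.2001) * np.tile([1.0, -1.0], 20)
        assert not coverage_variance_qc(x_hi)[0]

    def test_mixed_cohort_retention(self):
        variances = [0.1, 0.25, 0.19, 0.3, 0.05]
        kept = 0
        for v in variances:
            x = 2.0 + 2.0 * np.sqrt(v) * np.tile([1.0, -1.0], 10)
            kept += coverage_variance_qc(x)[0]
        assert kept == 3


class TestGeneSummaries:
    def gene(self, start, end):
        return GeneSpan("g1", "sim1", start, end)

    def test_modal_state_and_extra_copies(self):
        track = flat_track(np.full(4, 30.0))
        states = np.array([4, 4, 4, 2])
        call = gene_copy_number(states, track, self.gene(0, 1200))
        assert call["copy_number"] == 4 and call["extra_copies"] == 2
        call = gene_copy_number(np.full(4, 2), track, self.gene(0, 1200))
        assert call["copy_number"] == 2 and call["extra_copies"] == 0

    def test_ties_break_toward_diploid_then_lower(self):
        track = flat_track(np.full(4, 30.0))
        assert gene_copy_number(np.array([2, 2, 4, 4]), track,
                                self.gene(0, 1200))["copy_number"] == 2
        assert gene_copy_number(np.array([3, 3, 5, 5]), track,
                                self.gene(0, 1200))["copy_number"] == 3

    def test_gene_without_overlap_rejected(self):
        track = flat_track(np.full(4, 30.0))
        with pytest.raises(ValueError, match="overlaps no"):
            gene_copy_number(np.full(4, 2), track, self.gene(5000, 6000))

    def test_span_is_maximal_contiguous_amplified_run(self):
        track = flat_track(np.full(10, 30.0))
        states = np.array([2, 2, 3, 4, 4, 3, 2, 2, 4, 2])
        start, end = cnv_span(states, track, self.gene(900, 1500))
        assert (start, end) == (600, 1800)  # windows 2..5
        # single amplified window
        start, end = cnv_span(states, track, self.gene(2400, 2700))
        assert (start, end) == (2400, 2700)

    def test_span_covers_both_genes_when_amplification_spans_them(self):
        track = flat_track(np.full(10, 30.0))
        states = np.array([2, 3, 3, 3, 3, 3, 3, 3, 2, 2])
        g1, g2 = self.gene(600, 1200), GeneSpan("g2", "sim1", 1500, 2100)
        assert cnv_span(states, track, g1) == cnv_span(states, track, g2) == (300, 2400)

    def test_unamplified_gene_rejected(self):
        track = flat_track(np.full(4, 30.0))
        with pytest.raises(ValueError, match="not amplified"):
            cnv_span(np.full(4, 2), track, self.gene(0, 600))


class TestCohortFrequency:
    def make_tables(self, cohorts):
        rows, meta = [], []
        i = 0
        for location, n_amp, n_tot in cohorts:
            for j in range(n_tot):
                sid = f"s{i}"
                rows.append({"sample_id": sid, "copy_number": 4 if j < n_amp else 2})
                meta.append({"sample_id": sid, "location": location})
                i += 1
        return pd.DataFrame(rows), pd.DataFrame(meta)

    def test_observed_study_scale_frequencies(self):
        gene_cn, meta = self.make_tables(
            [("Baguida", 28, 146), ("Obuasi", 23, 160), ("Aboisso", 0, 37)]
        )
        out = cohort_cnv_frequency(gene_cn, meta, ["location"]).set_index("location")
        assert out.loc["Baguida", "frequency"] == pytest.approx(28 / 146)
        assert round(out.loc["Baguida", "frequency"], 2) == 0.19
        assert out.loc["Obuasi", "frequency"] == pytest.approx(0.14375)
        assert out.loc["Aboisso", "frequency"] == 0.0
        assert (out["ci_low"] <= out["frequency"]).all()
        assert (out["ci_high"] >= out["frequency"]).all()

    def test_empty_cohort_skipped_with_warning(self):
        gene_cn, meta = self.make_tables([("A", 1, 10)])
        meta = pd.concat(
            [meta, pd.DataFrame([{"sample_id": "zzz", "location": "B"}])],
            ignore_index=True,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = cohort_cnv_frequency(gene_cn, meta, ["location"])
        assert list(out["location"]) == ["A"]
        assert any("skipped" in str(w.message) for w in caught)


class TestEndToEndRecovery:
    def test_planted_cn6_recovered_at_30x(self):
        hits = 0
        for seed in range(25):
            cfg = CoverageSimConfig(
                region_span=180_000, base_depth=30.0, seed=seed,
                planted_cnvs=[("s0", 88_800, 92_400, 6)],
            )
            track, _ = simulate_coverage(cfg, ["s0"])
            norm = normalize_coverage(track)
            sub = norm.values[norm.usable, 0]
            states = viterbi_copy_number(sub)
            usable_starts = track.starts[norm.usable]
            usable_ends = track.ends[norm.usable]
            gene_mask = (usable_starts < 91_500) & (usable_ends > 89_700)
            modal = np.bincount(states[gene_mask]).argmax()
            hits += modal == 6
        assert hits >= 24
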