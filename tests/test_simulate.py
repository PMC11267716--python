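"""Synthetic-data generator: determinism, degenerate cases, truth fidelity."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sweepcnv import (
    CoverageSimConfig,
    PhenotypeSimConfig,
    ScanConfig,
    SimConfig,
    normalize_coverage,
    pair_to_diplotypes,
    sample_heterozygosity,
    scan,
    simulate_coverage,
    simulate_haplotypes,
    simulate_phenotypes,
)
from sweepcnv.sweep import h12, haplotype_frequency_spectrum

SMALL = dict(n_samples=40, n_sites=600, region_span=60_000, sweep_center=30_000,
             sweep_width=20_000)


class TestHaplotypeSim:
    def test_seed_reproducibility(self):
        a, _ = simulate_haplotypes(SimConfig(**SMALL, seed=9))
        b, _ = simulate_haplotypes(SimConfig(**SMALL, seed=9))
        c, _ = simulate_haplotypes(SimConfig(**SMALL, seed=10))
        np.testing.assert_array_equal(a.alleles, b.alleles)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert not np.array_equal(a.alleles, c.alleles)

    def test_full_hard_sweep_without_decay_is_monomorphic_in_core(self):
        cfg = SimConfig(**SMALL, sweep_frequency=1.0, n_sweep_haplotypes=1,
                        decay=False, seed=2)
        haps, truth = simulate_haplotypes(cfg)
        core = (haps.positions >= 20_000) & (haps.positions <= 40_000)
        window = haps.alleles[core]
        assert haplotype_frequency_spectrum(window).tolist() == [1.0]
        assert len(truth.swept_haplotype_ids) == haps.n_haplotypes

    def test_no_variation_sources_gives_identical_haplotypes(self):
        cfg = SimConfig(**SMALL, mutation_density=0.0, sweep_frequency=0.0,
                        n_founders=1, seed=3)
        haps, truth = simulate_haplotypes(cfg)
        assert (haps.alleles == haps.alleles[:, [0]]).all()
        assert not truth.swept_haplotype_ids

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=1)
        with pytest.raises(ValueError):
            SimConfig(sweep_frequency=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_sweep_haplotypes=0)

    def test_positions_strictly_increasing(self):
        haps, _ = simulate_haplotypes(SimConfig(**SMALL, seed=4))
        assert (np.diff(haps.positions) > 0).all()

    def test_half_frequency_hard_sweep_forces_h12_core_floor(self):
        # one haplotype at frequency >= 0.5 forces H12 >= 0.25 in the core
        hits = 0
        for seed in range(30):
            cfg = SimConfig(**SMALL, sweep_frequency=0.5, seed=seed)
            haps, _ = simulate_haplotypes(cfg)
            core = (haps.positions >= 25_000) & (haps.positions <= 35_000)
            value = h12(haplotype_frequency_spectrum(haps.alleles[core]))
            hits += value >= 0.25 - 1e-9
        assert hits == 30

    def test_mean_core_h12_monotone_in_sweep_frequency(self):
        freqs = np.linspace(0.0, 0.9, 10)
        means = []
        for f in freqs:
            vals = []
            for seed in range(15):
                cfg = SimConfig(n_samples=50, n_sites=1000, region_span=100_000,
                                sweep_center=50_000, sweep_width=40_000,
                                sweep_frequency=float(f), seed=seed)
                haps, _ = simulate_haplotypes(cfg)
                track = scan(haps, ScanConfig(window_snps=200,
                                              n_haplotypes_sampled=100, seed=seed))
                mid = track.iloc[(track["midpoint"] - 50_000).abs().idxmin()]
                vals.append(mid["h12"])
            means.append(np.mean(vals))
        rho = spearmanr(freqs, means).statistic
        assert rho > 0.9


class TestPairing:
    def test_identical_haplotype_pair_is_fully_homozygous(self):
        haps, _ = simulate_haplotypes(
            SimConfig(**SMALL, mutation_density=0.0, sweep_frequency=0.0,
                      n_founders=1, seed=5)
        )
        gm, _ = pair_to_diplotypes(haps, seed=0)
        assert sample_heterozygosity(gm).max() == 0.0

    def test_dosage_forced_by_haplotype_sum(self):
        from sweepcnv import HaplotypeMatrix

        haps = HaplotypeMatrix(
            np.array([[0, 1], [1, 1]], dtype=np.int8),
            np.array([100, 200]), ["hA", "hB"], "sim1",
        )
        gm, pairing = pair_to_diplotypes(haps, seed=0)
        assert gm.n_samples == 1
        # site 1: alleles 0+1 -> het; site 2: 1+1 -> hom alt
        np.testing.assert_array_equal(gm.allele_counts[0, 0], [1, 1, 0, 0])
        np.testing.assert_array_equal(gm.allele_counts[1, 0], [0, 2, 0, 0])
        assert set(pairing[0]) == {"hA", "hB"}

    def test_allele_counts_conserved_through_pairing(self):
        haps, _ = simulate_haplotypes(SimConfig(**SMALL, seed=6))
        gm, _ = pair_to_diplotypes(haps, seed=7)
        np.testing.assert_array_equal(
            haps.alleles.sum(axis=1), gm.allele_counts[:, :, 1].sum(axis=1)
        )

    def test_odd_haplotype_count_rejected(self):
        from sweepcnv import HaplotypeMatrix

        haps = HaplotypeMatrix(
            np.zeros((2, 3), dtype=np.int8), np.array([1, 2]),
            ["a", "b", "c"], "sim1",
        )
        with pytest.raises(ValueError, match="odd"):
            pair_to_diplotypes(haps, seed=0)


class TestCoverageSim:
    def test_flat_conditions_recover_base_depth(self):
        cfg = CoverageSimConfig(region_span=60_000, base_depth=30.0, seed=1)
        track, cn = simulate_coverage(cfg, ["s0"])
        assert (cn == 2).all()
        assert track.depth.mean() == pytest.approx(30.0, rel=0.03)

    def test_planted_duplication_doubles_mean_depth(self):
        cfg = CoverageSimConfig(
            region_span=120_000, base_depth=30.0,
            planted_cnvs=[("s0", 30_000, 60_000, 4)], seed=2,
        )
        track, cn = simulate_coverage(cfg, ["s0"])
        seg = (track.starts >= 30_000) & (track.ends <= 60_000)
        ratio = track.depth[seg, 0].mean() / track.depth[~seg, 0].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_overdispersion_below_one_rejected(self):
        with pytest.raises(ValueError):
            CoverageSimConfig(overdispersion=0.5)

    def test_planted_cnv_outside_region_rejected(self):
        with pytest.raises(ValueError):
            CoverageSimConfig(region_span=1000, planted_cnvs=[("s0", 500, 2000, 4)])

    def test_normalization_recovers_flat_profile_under_known_gc_curve(self):
        cfg = CoverageSimConfig(
            region_span=1_200_000, base_depth=60.0,
            gc_bias_curve=lambda gc: 0.6 + 1.2 * gc, seed=3,
        )
        track, _ = simulate_coverage(cfg, ["s0"])
        norm = normalize_coverage(track)
        bins = (track.gc[norm.usable] / 0.02).astype(int)
        values = norm.values[norm.usable, 0]
        for b in np.unique(bins):
            assert values[bins == b].mean() == pytest.approx(2.0, rel=0.02)

    def test_negative_binomial_inflates_variance(self):
        flat = dict(region_span=600_000, base_depth=30.0, gc_range=(0.45, 0.4500001))
        t1, _ = simulate_coverage(CoverageSimConfig(**flat, overdispersion=1.0, seed=4), ["s"])
        t4, _ = simulate_coverage(CoverageSimConfig(**flat, overdispersion=4.0, seed=4), ["s"])
        assert t4.depth.var() > 2.5 * t1.depth.var()
        assert t4.depth.mean() == pytest.approx(t1.depth.mean(), rel=0.05)


class TestPhenotypeSim:
    def test_null_model_gives_half_survival(self):
        cfg = PhenotypeSimConfig(intercept=0.0, beta_cnv=0.0, beta_covariate=0.0, seed=0)
        phen, prob = simulate_phenotypes(cfg, [2] * 4000, [0] * 4000, ["L"] * 4000)
        assert (prob == 0.5).all()
        assert phen.mean() == pytest.approx(0.5, abs=0.03)

    def test_extreme_negative_intercept_kills_everything(self):
        cfg = PhenotypeSimConfig(intercept=-40.0, beta_cnv=0.0, seed=1)
        phen, _ = simulate_phenotypes(cfg, [2] * 200, [0] * 200, ["L"] * 200)
        assert phen.sum() == 0

    def test_unknown_location_rejected(self):
        cfg = PhenotypeSimConfig(location_effects={"A": 0.0}, seed=2)
        with pytest.raises(ValueError, match="unknown"):
            simulate_phenotypes(cfg, [2], [0], ["B"])
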