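"""Synthetic Pool-Seq generator: determinism, calibration, planted signal."""

import numpy as np
import pytest

from poolscan import io
from poolscan.association import chi_square_association
from poolscan.diversity import hp_window, site_allele_freq, zhp_transform
from poolscan.simulate import (
    PoolSpec,
    SimulationConfig,
    SweepSpec,
    simulate_genotype_table,
    simulate_pool_counts,
)
from poolscan.sweep import make_windows

SMALL = SimulationConfig(
    n_scaffolds=1,
    scaffold_length_bp=200_000,
    snp_density=0.002,
    pools=(PoolSpec("gray", 117), PoolSpec("white1", 25), PoolSpec("white2", 87)),
    sweep_regions=(SweepSpec("scaffold_1", 50_001, 100_000, ("white1", "white2")),),
    seed=7,
)


class TestSimulatePoolCounts:
    def test_identical_seed_identical_output(self, tmp_path):
        a = tmp_path / "a.sync"
        b = tmp_path / "b.sync"
        for path in (a, b):
            sites, _ = simulate_pool_counts(SMALL)
            io.write_sync(sites, path)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_different_output(self):
        sites_a, _ = simulate_pool_counts(SMALL)
        sites_b, _ = simulate_pool_counts(SMALL.with_seed(8))
        assert [s.position for s in sites_a] != [s.position for s in sites_b]

    def test_truth_has_one_row_per_site(self):
        sites, truth = simulate_pool_counts(SMALL)
        assert len(truth.frame) == len(sites)
        freq_cols = [c for c in truth.frame.columns if c.startswith("freq_")]
        assert len(freq_cols) == 3
        assert truth.frame[freq_cols].to_numpy().min() >= 0.0
        assert truth.frame[freq_cols].to_numpy().max() <= 1.0

    def test_complete_sweep_forces_monomorphic_windows(self):
        config = SimulationConfig(
            n_scaffolds=1,
            scaffold_length_bp=100_000,
            snp_density=0.003,
            pools=(PoolSpec("gray", 117), PoolSpec("white1", 25)),
            sweep_regions=(
                SweepSpec("scaffold_1", 1, 100_000, ("white1",), derived_freq=1.0),
            ),
            error_rate=0.0,
            seed=3,
        )
        sites, _ = simulate_pool_counts(config)
        white = [s.pools[1] for s in sites]
        afs = [site_allele_freq(p) for p in white]
        assert all(a.n_min == 0 for a in afs)
        for window in make_windows(afs, min_snps=10):
            if not window.discarded:
                assert hp_window(window.sites) == 0.0

    def test_empirical_frequency_converges_to_truth_at_high_depth(self):
        config = SimulationConfig(
            n_scaffolds=1,
            scaffold_length_bp=100_000,
            snp_density=0.01,
            pools=(PoolSpec("gray", 117, mean_depth=10_000.0),),
            error_rate=0.0,
            seed=11,
        )
        sites, truth = simulate_pool_counts(config)
        alt = truth.frame["alt"].to_numpy()
        expected = truth.frame["freq_gray"].to_numpy()
        observed = np.array(
            [
                s.pools[0].counts.get(str(a), 0) / s.pools[0].depth
                for s, a in zip(sites, alt)
            ]
        )
        assert np.abs(observed - expected).max() < 0.02

    def test_mean_depth_calibrated(self):
        config = SimulationConfig(
            n_scaffolds=1,
            scaffold_length_bp=1_000_000,
            snp_density=0.012,
            pools=(PoolSpec("gray", 117, mean_depth=44.0),),
            seed=5,
        )
        sites, _ = simulate_pool_counts(config)
        assert len(sites) >= 10_000
        depths = np.array([s.pools[0].depth for s in sites])
        assert abs(depths.mean() - 44.0) / 44.0 < 0.05

    def test_sweep_lowers_hp_in_target_pools_across_seeds(self):
        """Planted sweeps depress window Hp in target pools (20 seeds)."""
        inside_lower = 0
        for seed in range(20):
            sites, truth = simulate_pool_counts(SMALL.with_seed(seed))
            afs = [site_allele_freq(s.pools[1]) for s in sites]  # white1
            windows = [w for w in make_windows(afs, min_snps=10) if not w.discarded]
            hp = np.array([hp_window(w.sites) for w in windows])
            sweep = np.array([
                any(w.start >= sw.start and w.end <= sw.end
                    for sw in truth.sweeps)
                for w in windows
            ])
            if sweep.any() and (~sweep).any():
                if hp[sweep].mean() < hp[~sweep].mean():
                    inside_lower += 1
        assert inside_lower == 20

    def test_sweep_raises_zhp_above_genome_mean_across_seeds(self):
        """Mean -ZHp inside sweeps exceeds the scan-wide mean (20 seeds)."""
        wins = 0
        for seed in range(20):
            sites, truth = simulate_pool_counts(SMALL.with_seed(100 + seed))
            afs = [site_allele_freq(s.pools[2]) for s in sites]  # white2
            windows = [w for w in make_windows(afs, min_snps=10) if not w.discarded]
            zhp, _ = zhp_transform([hp_window(w.sites) for w in windows])
            zhp = np.asarray(zhp)
            sweep = np.array([
                any(w.start >= sw.start and w.end <= sw.end
                    for sw in truth.sweeps)
                for w in windows
            ])
            if sweep.any() and zhp[sweep].mean() > zhp.mean():
                wins += 1
        assert wins == 20

    def test_no_sweep_fst_null_matches_label_permutation(self):
        """Without sweeps, the fraction of windows above a fixed FST
        threshold matches a pool-label permutation of the same data."""
        from poolscan.diversity import fst_window

        config = SimulationConfig(
            n_scaffolds=1,
            scaffold_length_bp=500_000,
            snp_density=0.003,
            pools=(PoolSpec("gray", 117), PoolSpec("white1", 25),
                   PoolSpec("white2", 87)),
            seed=13,
        )
        sites, _ = simulate_pool_counts(config)

        def exceed_fraction(i, j, sizes):
            a = [site_allele_freq(s.pools[i]) for s in sites]
            b = [site_allele_freq(s.pools[j]) for s in sites]
            values = []
            for w in make_windows(a, min_snps=10):
                if w.discarded:
                    continue
                v = fst_window(w.sites, b, sizes)
                if v is not None:
                    values.append(v)
            values = np.asarray(values)
            return (values > 0.05).mean()

        real = exceed_fraction(0, 1, (234, 50))
        permuted = exceed_fraction(1, 0, (50, 234))
        assert abs(real - permuted) < 0.05
        assert real < 0.10  # near-null differentiation

    def test_sparse_sweep_region_warns(self):
        config = SimulationConfig(
            n_scaffolds=1,
            scaffold_length_bp=200_000,
            snp_density=0.002,
            pools=(PoolSpec("gray", 10), PoolSpec("white1", 10)),
            sweep_regions=(SweepSpec("scaffold_1", 1, 500, ("white1",)),),
            seed=1,
        )
        with pytest.warns(UserWarning, match="holds only"):
            simulate_pool_counts(config)

    def test_sweep_outside_scaffold_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimulationConfig(
                n_scaffolds=1,
                scaffold_length_bp=10_000,
                sweep_regions=(SweepSpec("scaffold_1", 5_000, 20_000, ("white1",)),),
            )

    def test_unknown_target_pool_rejected(self):
        config = SimulationConfig(
            n_scaffolds=1,
            scaffold_length_bp=50_000,
            sweep_regions=(SweepSpec("scaffold_1", 1, 10_000, ("nosuch",)),),
        )
        with pytest.raises(ValueError, match="unknown pools"):
            simulate_pool_counts(config)

    def test_low_maf_contamination_exercises_filter(self):
        from poolscan.pipeline import joint_site_filter

        config = SimulationConfig(
            n_scaffolds=1,
            scaffold_length_bp=300_000,
            snp_density=0.002,
            pools=(PoolSpec("gray", 117),),
            low_maf_fraction=0.3,
            drift_sd=0.0,
            error_rate=0.0,
            seed=21,
        )
        sites, _ = simulate_pool_counts(config)
        _, tallies = joint_site_filter(sites, ["gray"])
        assert tallies["gray"]["maf"] > 0


class TestSimulateGenotypeTable:
    def test_deterministic_under_seed(self):
        args = ([50, 60], [[0.25, 0.5, 0.25]] * 2)
        t1 = simulate_genotype_table(*args, seed=42)
        t2 = simulate_genotype_table(*args, seed=42)
        assert t1.counts == t2.counts

    def test_column_sums_match_group_sizes(self):
        table = simulate_genotype_table(
            [100, 25, 87], [[0.3, 0.4, 0.3]] * 3, seed=1
        )
        assert np.asarray(table.counts).sum(axis=0).tolist() == [100, 25, 87]

    def test_degenerate_probabilities_break_association_path(self):
        table = simulate_genotype_table(
            [50, 50], [[1.0, 0.0, 0.0]] * 2, seed=1
        )
        with pytest.raises(ValueError, match="pruning"):
            chi_square_association(table)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_genotype_table([10], [[0.5, 0.2]], genotypes=("AA", "AB"))
        with pytest.raises(ValueError, match="non-negative"):
            simulate_genotype_table([-1], [[0.5, 0.5]], genotypes=("AA", "AB"))
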