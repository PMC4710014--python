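from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pytest
from scipy import stats

from sweepscan.coalescent import (
    DemographicModel,
    MigrationEpoch,
    Population,
    SimulatedWindow,
    SizeEpoch,
    Split,
    _simulate_genealogy,
    default_dog_wolf_model,
    empirical_exceedance,
    haplotypes_to_genotypes,
    load_demography,
    null_distribution,
    simulate_window,
)
from sweepscan.fst import WindowStat, compute_site_fst


def _single_deme(N=1000.0, mu=1e-7, L=100_000, blocks=1):
    return DemographicModel(
        populations=(Population("p", (SizeEpoch(0, N),)),),
        mutation_rate=mu,
        window_length=L,
        blocks=blocks,
    )


def _two_demes(N=1000.0, mig=2.5e-4, mu=1e-7, L=100_000, blocks=10,
               split=200_000.0):
    return DemographicModel(
        populations=(
            Population("a", (SizeEpoch(0, N),)),
            Population("b", (SizeEpoch(0, N),)),
        ),
        splits=(Split(split, "b", "a"),),
        migration=(MigrationEpoch(0.0, {("a", "b"): mig, ("b", "a"): mig}),),
        mutation_rate=mu,
        window_length=L,
        blocks=blocks,
    )


def _mean_fst(records) -> float:
    vals = [s.fst for s in compute_site_fst(records) if not math.isnan(s.fst)]
    return float(np.mean(vals)) if vals else math.nan


class TestModelValidation:
    def test_split_times_must_increase(self):
        with pytest.raises(ValueError):
            DemographicModel(
                populations=(
                    Population("a", (SizeEpoch(0, 10.0),)),
                    Population("b", (SizeEpoch(0, 10.0),)),
                    Population("c", (SizeEpoch(0, 10.0),)),
                ),
                splits=(Split(5.0, "b", "a"), Split(5.0, "c", "a")),
            )

    def test_negative_migration_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel(
                populations=(
                    Population("a", (SizeEpoch(0, 10.0),)),
                    Population("b", (SizeEpoch(0, 10.0),)),
                ),
                migration=(MigrationEpoch(0.0, {("a", "b"): -1.0}),),
            )

    def test_stranded_lineages_fatal(self):
        model = DemographicModel(
            populations=(
                Population("a", (SizeEpoch(0, 10.0),)),
                Population("b", (SizeEpoch(0, 10.0),)),
            )
        )  # two demes, no migration, no split
        with pytest.raises(ValueError, match="stranded"):
            simulate_window(model, {"a": 2, "b": 2}, seed=0)

    def test_shipped_demography_config_loads(self):
        path = resources.files("sweepscan").joinpath(
            "data/dog_wolf_demography.yaml"
        )
        model = load_demography(str(path))
        assert {p.name for p in model.populations} == {"dog", "wolf"}
        assert model.splits[0].derived == "dog"
        simulate_window(model, {"dog": 4, "wolf": 4}, seed=1)  # runs


class TestSingleDemeCalibration:
    def test_pairwise_tmrca_near_two_n(self):
        model = _single_deme(N=1000.0)
        rng = np.random.default_rng(10)
        tm = [
            _simulate_genealogy(model, ["p", "p"], rng)[1][2]
            for _ in range(3000)
        ]
        se = 2000.0 / math.sqrt(len(tm))  # exponential: sd = mean
        assert abs(np.mean(tm) - 2000.0) < 3 * se

    def test_coalescence_waiting_times_exponential(self):
        """First-event times with k lineages in a deme of size N follow
        Exp(k(k-1)/(4N))."""
        k, N = 5, 500.0
        model = _single_deme(N=N)
        rng = np.random.default_rng(11)
        first = [
            _simulate_genealogy(model, ["p"] * k, rng)[1][k]
            for _ in range(10_000)
        ]
        rate = k * (k - 1) / (4 * N)
        ks = stats.kstest(first, "expon", args=(0, 1 / rate))
        assert ks.pvalue > 0.01

    def test_pairwise_diversity_near_theta(self):
        model = _single_deme(N=1000.0, mu=1e-7, L=100_000)
        diffs = []
        for i in range(400):
            w = simulate_window(model, {"p": 2}, seed=1000 + i)
            diffs.append(
                float((w.haplotypes[0] != w.haplotypes[1]).sum())
                / model.window_length
            )
        theta = 4 * 1000.0 * 1e-7
        se = np.std(diffs, ddof=1) / math.sqrt(len(diffs))
        assert abs(np.mean(diffs) - theta) < 3 * se

    def test_site_frequency_spectrum_matches_neutral_expectation(self):
        n = 8
        model = _single_deme(N=500.0, mu=2e-6, L=50_000, blocks=5)
        counts = np.zeros(n, dtype=float)
        for i in range(300):
            w = simulate_window(model, {"p": n}, seed=i)
            if w.n_sites:
                freq = w.haplotypes.sum(axis=0)
                for f in freq:
                    counts[f] += 1
        observed = counts[1:n] / counts[1:n].sum()
        expected = (1.0 / np.arange(1, n)) / np.sum(1.0 / np.arange(1, n))
        assert np.abs(observed - expected).max() < 0.03


class TestTwoDemeCalibration:
    def test_island_model_fst_near_closed_form(self):
        # two-deme symmetric island model: Fst ~ 1/(1 + 16 N m)
        N, mig = 1000.0, 2.5e-4
        model = _two_demes(N=N, mig=mig)
        null = null_distribution(model, {"a": 20, "b": 20}, 80, seed=7)
        expected = 1.0 / (1.0 + 16 * N * mig)
        assert abs(np.nanmean(null) - expected) < 0.05

    def test_agrees_with_established_coalescent_simulator(self):
        """Cross-check mean Fst against msprime run with matched demography."""
        msprime = pytest.importorskip("msprime")
        N, mig = 1000.0, 2.5e-4
        model = _two_demes(N=N, mig=mig, blocks=10, L=100_000)
        mine = np.nanmean(
            null_distribution(model, {"a": 20, "b": 20}, 60, seed=5)
        )
        dem = msprime.Demography()
        dem.add_population(name="a", initial_size=N)
        dem.add_population(name="b", initial_size=N)
        dem.add_population(name="anc", initial_size=N)
        dem.add_population_split(time=200_000, derived=["a", "b"],
                                 ancestral="anc")
        dem.set_migration_rate("a", "b", mig)
        dem.set_migration_rate("b", "a", mig)
        theirs = []
        for rep in range(60):
            ts = msprime.sim_ancestry(
                samples={"a": 10, "b": 10}, demography=dem,
                sequence_length=10_000, ploidy=2, random_seed=rep + 1,
            )
            mts = msprime.sim_mutations(
                ts, rate=1e-7, random_seed=rep + 1, discrete_genome=False
            )
            G = mts.genotype_matrix()
            if G.shape[0] == 0:
                continue
            window = SimulatedWindow(
                haplotypes=G.T.astype(np.uint8),
                positions=np.arange(1, G.shape[0] + 1),
                sample_populations=("a",) * 20 + ("b",) * 20,
                window_length=10_000,
            )
            theirs.append(_mean_fst(haplotypes_to_genotypes(window)))
        assert abs(mine - np.nanmean(theirs)) < 0.04

    def test_mean_fst_decreases_with_migration(self):
        N = 500.0
        means = []
        for mig in (5e-5, 5e-4, 5e-3):
            model = _two_demes(N=N, mig=mig, blocks=5, L=50_000, mu=2e-7)
            null = null_distribution(model, {"a": 10, "b": 10}, 50, seed=3)
            means.append(float(np.nanmean(null)))
        assert means[0] > means[1] > means[2]

    def test_ancient_split_without_migration_gives_high_fst(self):
        model = DemographicModel(
            populations=(
                Population("a", (SizeEpoch(0, 200.0),)),
                Population("b", (SizeEpoch(0, 200.0),)),
            ),
            splits=(Split(50_000.0, "b", "a"),),
            mutation_rate=1e-6,
            window_length=50_000,
            blocks=5,
        )
        null = null_distribution(model, {"a": 10, "b": 10}, 20, seed=1)
        assert np.nanmean(null) > 0.9

    def test_panmictic_pair_has_near_zero_fst(self):
        model = _two_demes(N=500.0, mig=0.05, blocks=5, L=50_000, mu=2e-7)
        null = null_distribution(model, {"a": 10, "b": 10}, 50, seed=9)
        assert abs(np.nanmean(null)) < 0.03


class TestHaplotypePooling:
    def test_sample_counts_pool_into_diploids(self):
        model = _two_demes(mu=2e-7)
        w = simulate_window(model, {"a": 134, "b": 14}, seed=2)
        records = haplotypes_to_genotypes(w)
        assert records, "expected segregating sites"
        for r in records:
            assert r.counts["a"].size == 67
            assert r.counts["b"].size == 7

    def test_het_from_discordant_haplotype_pair(self):
        w = SimulatedWindow(
            haplotypes=np.array([[0], [1]], dtype=np.uint8),
            positions=np.array([5]),
            sample_populations=("a", "a"),
            window_length=10,
        )
        (r,) = haplotypes_to_genotypes(w)
        assert r.counts["a"].het == 1

    def test_every_simulated_column_is_segregating(self):
        model = _single_deme(mu=1e-6, L=20_000)
        w = simulate_window(model, {"p": 10}, seed=4)
        sums = w.haplotypes.sum(axis=0)
        assert ((sums > 0) & (sums < 10)).all()

    def test_odd_haplotype_count_fatal(self):
        w = SimulatedWindow(
            haplotypes=np.zeros((3, 0), dtype=np.uint8),
            positions=np.zeros(0, dtype=int),
            sample_populations=("a", "a", "a"),
            window_length=10,
        )
        with pytest.raises(ValueError, match="odd"):
            haplotypes_to_genotypes(w)


class TestDeterminismAndNull:
    def test_same_seed_identical_windows(self):
        model = _two_demes()
        w1 = simulate_window(model, {"a": 6, "b": 6}, seed=42)
        w2 = simulate_window(model, {"a": 6, "b": 6}, seed=42)
        assert np.array_equal(w1.haplotypes, w2.haplotypes)
        assert np.array_equal(w1.positions, w2.positions)

    def test_null_distribution_reproducible_and_sized(self):
        model = _two_demes(blocks=2, L=20_000)
        n1 = null_distribution(model, {"a": 6, "b": 6}, 25, seed=8)
        n2 = null_distribution(model, {"a": 6, "b": 6}, 25, seed=8)
        assert len(n1) == 25
        assert np.array_equal(n1, n2, equal_nan=True)


class TestExceedance:
    def _window(self, mean, outlier=False):
        return WindowStat("chr1", 1, 100, 10, mean, mean, None, outlier)

    def test_observed_below_null_near_one(self):
        report = empirical_exceedance(
            [self._window(0.01)], null=[0.2, 0.3, 0.4]
        )
        assert report.per_window[0][4] == pytest.approx(1.0)

    def test_observed_above_null_hits_floor(self):
        report = empirical_exceedance(
            [self._window(0.9, outlier=True)], null=[0.2, 0.3, 0.4]
        )
        assert report.per_window[0][4] == pytest.approx(1 / 4)
        assert report.gap == pytest.approx(0.5)
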