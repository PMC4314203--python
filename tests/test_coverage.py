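"""Depth/GDV mixture fitting and homogeneity testing."""

import math

import numpy as np
import pytest

from gdvprof.coverage import (
    CoverageHistogram,
    InsufficientReadsError,
    MixtureFit,
    NoCoverageError,
    NonConvergenceError,
    StartDistanceHistogram,
    _log_components_poisson_tail,
    coverage_histogram,
    estimate_gdv,
    estimate_profile,
    fit_geometric_mixture,
    fit_poisson_tail_mixture,
    ks_homogeneity,
    quality_band,
    start_distance_histogram,
)
from gdvprof.simulate import (
    CommunitySpec,
    OrganismSpec,
    ReferenceSpec,
    simulate_community,
)

from conftest import make_table


def hist_from_samples(x, genome_length=None):
    b = np.bincount(x)
    counts = {int(i): int(c) for i, c in enumerate(b) if c}
    return CoverageHistogram(counts, genome_length or len(x))


class TestCoverageHistogram:
    def test_single_read(self):
        table = make_table([("r", "s", 100, 100, 0)])
        h = coverage_histogram(table, "s")
        assert h.counts == {0: 900, 1: 100}
        assert sum(h.counts.values()) == h.genome_length == 1000

    def test_stacked_reads(self):
        table = make_table([("a", "s", 100, 100, 0), ("b", "s", 100, 100, 0)])
        assert coverage_histogram(table, "s").counts == {0: 900, 2: 100}

    def test_multi_sequence_organism(self):
        table = make_table(
            [("a", "s1", 0, 100, 0), ("b", "s2", 0, 100, 0)],
            ref_lengths={"s1": 500, "s2": 300},
            grouping={"s1": "org", "s2": "org"},
        )
        h = coverage_histogram(table, "org")
        assert h.genome_length == 800
        assert h.counts == {0: 600, 1: 200}

    def test_simulated_depth_matches_truth(self):
        spec = CommunitySpec(
            organisms=[OrganismSpec("o", 50_000, 5.0)],
            references=[ReferenceSpec("r", "o", 1.0, divergence=0.0)],
            seed=3,
        )
        table = simulate_community(spec).to_alignment_table()
        h = coverage_histogram(table, "r")
        # mean depth ~ Poisson(5) mean; SE ~ sqrt(5 * read_len / L)
        assert h.mean_depth == pytest.approx(5.0, abs=3 * math.sqrt(5 * 100 / 50_000))


class TestPoissonTailMixture:
    def test_pure_poisson_recovery(self):
        rng = np.random.default_rng(1)
        fit = fit_poisson_tail_mixture(hist_from_samples(rng.poisson(3, 1_000_000)))
        assert fit.converged
        assert fit.alpha[0] <= 0.02
        assert fit.lam == pytest.approx(3.0, abs=0.05)

    def test_zero_inflated_recovery(self):
        rng = np.random.default_rng(2)
        zeros = rng.random(1_000_000) < 0.4
        x = np.where(zeros, 0, rng.poisson(5, 1_000_000))
        fit = fit_poisson_tail_mixture(hist_from_samples(x))
        assert fit.alpha[0] == pytest.approx(0.40, abs=0.02)
        assert fit.lam == pytest.approx(5.0, abs=0.1)
        assert estimate_gdv(fit) == pytest.approx(0.60, abs=0.02)

    def test_all_zero_histogram_raises(self):
        with pytest.raises(NoCoverageError, match="no coverage evidence"):
            fit_poisson_tail_mixture(CoverageHistogram({0: 10**6}, 10**6))

    def test_loglik_monotone_per_iteration(self):
        rng = np.random.default_rng(3)
        fit = fit_poisson_tail_mixture(hist_from_samples(rng.poisson(2, 10_000)))
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-7 * (np.abs(path[:-1]) + 1))

    def test_alpha_is_a_distribution(self):
        rng = np.random.default_rng(4)
        fit = fit_poisson_tail_mixture(hist_from_samples(rng.poisson(4, 50_000)))
        assert all(0 <= a <= 1 for a in fit.alpha)
        assert sum(fit.alpha) == pytest.approx(1.0, abs=1e-9)

    def test_mixture_density_normalized(self):
        # all three components must sum to 1 over the support
        lam = 3.7
        xs = np.arange(0, 200)
        logs = _log_components_poisson_tail(xs, lam)
        for comp in range(3):
            total = np.exp(logs[comp]).sum()
            assert total == pytest.approx(1.0, abs=1e-6)


class TestGeometricMixture:
    def test_single_geometric_recovery(self):
        rng = np.random.default_rng(5)
        d = rng.geometric(0.01, 100_000)
        b = np.bincount(d)
        hist = StartDistanceHistogram(
            {int(i): int(c) for i, c in enumerate(b) if c},
            n_reads=100_001,
            genome_length=10_000_000,
        )
        fit = fit_geometric_mixture(hist)
        assert fit.converged
        # method-of-moments oracle: p ~ 1 / mean spacing
        mom_p = 1.0 / np.mean(d)
        p_eff = 1.0 - math.exp(-fit.lam)
        assert p_eff == pytest.approx(mom_p, abs=5e-4)
        assert p_eff == pytest.approx(0.01, abs=5e-4)

    def test_too_few_distances_raises(self):
        hist = StartDistanceHistogram({100: 5}, n_reads=6, genome_length=10_000)
        with pytest.raises(InsufficientReadsError):
            fit_geometric_mixture(hist)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(6)
        d = np.concatenate([rng.geometric(0.02, 500), rng.geometric(0.0005, 50)])
        b = np.bincount(d)
        hist = StartDistanceHistogram(
            {int(i): int(c) for i, c in enumerate(b) if c}, 551, 1_000_000
        )
        fit = fit_geometric_mixture(hist)
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) >= -1e-7 * (np.abs(path[:-1]) + 1))

    def test_components_sorted_by_success_probability(self):
        rng = np.random.default_rng(7)
        d = np.concatenate([rng.geometric(0.05, 2000), rng.geometric(0.001, 200)])
        b = np.bincount(d)
        hist = StartDistanceHistogram(
            {int(i): int(c) for i, c in enumerate(b) if c}, 2201, 1_000_000
        )
        fit = fit_geometric_mixture(hist)
        ps = [p for _, p in fit.components]
        assert ps == sorted(ps, reverse=True)


class TestEstimateGdv:
    @pytest.mark.parametrize("a1,expected", [(0.2, 0.8), (1.0, 0.0), (0.0, 1.0)])
    def test_poisson_tail_gdv_is_one_minus_zero_weight(self, a1, expected):
        fit = MixtureFit(
            alpha=(a1, 1 - a1, 0.0), lam=5.0, variant="poisson_tail",
            loglik=0.0, n_iter=10, converged=True,
        )
        assert estimate_gdv(fit) == pytest.approx(expected)

    def test_nonconverged_fit_raises_with_iteration_count(self):
        fit = MixtureFit(
            alpha=(0.5, 0.5, 0.0), lam=1.0, variant="poisson_tail",
            loglik=0.0, n_iter=123, converged=False,
        )
        with pytest.raises(NonConvergenceError) as exc:
            estimate_gdv(fit)
        assert exc.value.n_iter == 123


class TestQualityBands:
    @pytest.mark.parametrize(
        "gdv,band",
        [(0.85, "high"), (0.81, "high"), (0.8, "informative"), (0.5, "informative"),
         (0.2, "informative"), (0.19, "caution"), (0.02, "caution")],
    )
    def test_band_thresholds(self, gdv, band):
        assert quality_band(gdv) == band


class TestKsHomogeneity:
    def _uniform_table(self, rng, n=10_000, genome=1_000_000, read_len=100):
        starts = rng.integers(0, genome - read_len, size=n)
        alns = [(f"r{i}", "s", int(p), read_len, 0) for i, p in enumerate(starts)]
        return make_table(alns, ref_lengths={"s": genome})

    def test_uniform_starts_rarely_rejected(self):
        rng = np.random.default_rng(8)
        pvals = [
            ks_homogeneity(self._uniform_table(rng, n=2000), "s") for _ in range(20)
        ]
        assert sum(p > 0.05 for p in pvals) >= 19

    def test_stacked_reads_strongly_rejected(self):
        alns = [(f"r{i}", "s", 5000, 100, 0) for i in range(50)]
        table = make_table(alns, ref_lengths={"s": 100_000})
        assert ks_homogeneity(table, "s") < 1e-6

    def test_two_reads_returns_valid_p(self):
        table = make_table([("a", "s", 10, 100, 0), ("b", "s", 500, 100, 0)])
        p = ks_homogeneity(table, "s")
        assert 0.0 <= p <= 1.0

    def test_single_read_not_testable(self):
        table = make_table([("a", "s", 10, 100, 0)])
        assert ks_homogeneity(table, "s") is None


class TestEstimateProfile:
    def _sim_profile(self, depth, f, seed, genome=200_000):
        spec = CommunitySpec(
            organisms=[OrganismSpec("o", genome, depth)],
            references=[ReferenceSpec("r", "o", f)],
            seed=seed,
        )
        table = simulate_community(spec).to_alignment_table()
        return estimate_profile(table, "r")

    def test_high_depth_shared_fraction_recovery(self):
        prof = self._sim_profile(10.0, 0.8, seed=9, genome=300_000)
        assert prof.variant == "poisson_tail"
        assert prof.gdv == pytest.approx(0.8, abs=0.05)
        assert prof.depth == pytest.approx(10.0, abs=0.5)

    def test_low_depth_dispatches_to_geometric(self):
        prof = self._sim_profile(0.5, 1.0, seed=10)
        assert prof.variant == "geometric"
        assert prof.depth == pytest.approx(0.5, abs=0.1)

    def test_gdv_monotone_in_true_shared_fraction(self):
        gdvs = [
            self._sim_profile(5.0, f, seed=11).gdv for f in (0.2, 0.5, 0.8, 1.0)
        ]
        assert gdvs == sorted(gdvs)

    def test_fit_failure_reported_not_raised(self):
        # 3 reads at tiny coverage: too few spacings for the geometric model
        alns = [(f"r{i}", "s", i * 1000, 100, 0) for i in range(3)]
        table = make_table(alns, ref_lengths={"s": 100_000})
        prof = estimate_profile(table, "s")
        assert prof.fit_failed
        assert prof.gdv == 0.0
        assert prof.quality_band == "caution"

    def test_profile_carries_support_statistics(self):
        alns = [("u1", "s", 0, 100, 5), ("u2", "s", 200, 100, 0)]
        table = make_table(alns, ref_lengths={"s": 10_000})
        prof = estimate_profile(table, "s")
        assert prof.n_reads == prof.n_unique_reads == 2
        assert prof.error_rate == pytest.approx(0.025)


class TestStartDistanceHistogram:
    def test_distances_within_sequences_pooled(self):
        alns = [
            ("a", "s1", 100, 50, 0),
            ("b", "s1", 400, 50, 0),
            ("c", "s2", 10, 50, 0),
            ("d", "s2", 15, 50, 0),
        ]
        table = make_table(
            alns,
            ref_lengths={"s1": 1000, "s2": 1000},
            grouping={"s1": "org", "s2": "org"},
        )
        h = start_distance_histogram(table, "org")
        assert h.counts == {300: 1, 5: 1}  # no cross-sequence distance
        assert h.n_reads == 4

    def test_duplicate_starts_clamped_to_one(self):
        alns = [("a", "s", 100, 50, 0), ("b", "s", 100, 50, 0)]
        table = make_table(alns)
        assert start_distance_histogram(table, "s").counts == {1: 1}
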