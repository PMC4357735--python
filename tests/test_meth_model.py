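"""Window construction, count aggregation, beta-binomial fitting and scoring."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from methbind.io import CpGRecord, GenomicInterval
from methbind.meth_model import (
    BetaParams,
    InsufficientDataError,
    KAPPA_MAX,
    MethylationModel,
    WindowCounts,
    aggregate_counts,
    betabinom_logpmf,
    build_windows,
    fit_beta_mom,
    fit_methylation_model,
    methylation_score,
    qc_filter_training,
)
from methbind.scan import CandidateSite


def make_site(chrom="chr1", start=1000, end=1019, sid="s0"):
    return CandidateSite(GenomicInterval(chrom, start, end), 0.0, sid)


class TestBuildWindows:
    def test_default_layout_is_21_adjacent_windows(self):
        layout = build_windows(make_site(), chrom_length=10_000)
        assert layout.n_slots == layout.n_windows == 21
        expected_first = [(700, 730), (730, 760)]
        assert [(w.start, w.end) for w in layout.windows[:2]] == expected_first
        assert (layout.windows[9].start, layout.windows[9].end) == (970, 1000)
        assert (layout.windows[10].start, layout.windows[10].end) == (1000, 1019)
        assert (layout.windows[11].start, layout.windows[11].end) == (1019, 1049)
        assert (layout.windows[20].start, layout.windows[20].end) == (1289, 1319)
        # flanks are exactly window_size wide and tile without gaps
        for left, right in zip(layout.windows, layout.windows[1:]):
            assert left.end == right.start

    def test_no_flanks_reduces_to_motif_window(self):
        layout = build_windows(make_site(), n_flank=0)
        assert layout.n_slots == 1
        assert (layout.windows[0].start, layout.windows[0].end) == (1000, 1019)

    def test_chromosome_start_clipping_preserves_indices(self):
        layout = build_windows(
            make_site(start=10, end=25), window_size=30, n_flank=10, chrom_length=10_000
        )
        assert layout.n_slots == 21
        # windows 0..8 fall entirely before the chromosome and are dropped
        assert all(w is None for w in layout.windows[:9])
        assert (layout.windows[9].start, layout.windows[9].end) == (0, 10)
        assert (layout.windows[10].start, layout.windows[10].end) == (10, 25)
        assert layout.n_windows == 12

    def test_window_size_20_gives_a_valid_layout(self):
        layout = build_windows(make_site(), window_size=20, chrom_length=10_000)
        assert layout.n_windows == 21
        assert layout.windows[0].start == 1000 - 10 * 20

    def test_motif_outside_chromosome_errors(self):
        with pytest.raises(ValueError, match="outside"):
            build_windows(make_site(start=9_990, end=10_009), chrom_length=10_000)


class TestAggregateCounts:
    def test_sums_covered_cpgs(self):
        layout = build_windows(
            CandidateSite(GenomicInterval("chr1", 0, 30), 0.0, "s"), n_flank=0
        )
        records = [
            CpGRecord("chr1", 5, "CG", 3, 5),
            CpGRecord("chr1", 20, "CG", 0, 4),
        ]
        wc = aggregate_counts(layout, records)
        assert (wc.x[0], wc.n[0], wc.cg[0]) == (3, 9, 2)

    def test_uncovered_window_is_all_zero(self):
        layout = build_windows(
            CandidateSite(GenomicInterval("chr1", 0, 30), 0.0, "s"), n_flank=0
        )
        wc = aggregate_counts(layout, [CpGRecord("chr1", 5, "CG", 0, 0)])
        assert (wc.x[0], wc.n[0], wc.cg[0]) == (0, 0, 0)

    def test_matches_per_position_brute_force(self, rng):
        site = make_site()
        layout = build_windows(site, chrom_length=10_000)
        records = [
            CpGRecord("chr1", int(p), "CG", int(m), int(m) + int(u))
            for p, m, u in zip(
                rng.integers(600, 1400, size=50),
                rng.integers(0, 5, size=50),
                rng.integers(0, 5, size=50),
            )
        ]
        wc = aggregate_counts(layout, records)
        for j, window in enumerate(layout.windows):
            in_win = [
                r
                for r in records
                if window.start <= r.pos < window.end and r.total_count >= 1
            ]
            assert wc.x[j] == sum(r.meth_count for r in in_win)
            assert wc.n[j] == sum(r.total_count for r in in_win)
            assert wc.cg[j] == len(in_win)


def counts(x, n, context="CG"):
    x = np.asarray(x)
    n = np.asarray(n)
    return WindowCounts(x=x, n=n, cg=(n > 0).astype(int), context=context)


class TestQcFilter:
    def test_low_coverage_windows_masked_at_threshold_boundary(self):
        sites = [make_site()]
        wc = [counts([1, 2, 3], [4, 5, 12])]
        _, (filtered,) = qc_filter_training(sites, wc, cpg_islands=[], min_reads=5)
        np.testing.assert_array_equal(filtered.fit_mask, [False, True, True])
        np.testing.assert_array_equal(filtered.usable, [False, True, True])

    def test_island_candidates_dropped(self):
        sites = [make_site(sid="in"), make_site(start=5000, end=5019, sid="out")]
        wc = [counts([0], [5]), counts([0], [5])]
        kept, _ = qc_filter_training(
            sites, wc, cpg_islands=[GenomicInterval("chr1", 990, 1100)]
        )
        assert [s.site_id for s in kept] == ["out"]

    def test_matches_brute_force_rule_oracle(self, rng):
        islands = [GenomicInterval("chr1", int(s), int(s) + 200) for s in range(0, 4000, 700)]
        sites, wcs = [], []
        for i in range(20):
            start = int(rng.integers(0, 5000))
            sites.append(make_site(start=start, end=start + 19, sid=f"s{i}"))
            n = rng.integers(0, 12, size=21)
            wcs.append(counts(np.zeros(21, int), n))
        kept, kept_wc = qc_filter_training(sites, wcs, islands, min_reads=5)
        expected = [
            (s, wc)
            for s, wc in zip(sites, wcs)
            if not any(s.interval.overlaps(isl) for isl in islands)
        ]
        assert [s.site_id for s, _ in expected] == [s.site_id for s in kept]
        for (_, wc_in), wc_out in zip(expected, kept_wc):
            np.testing.assert_array_equal(wc_out.fit_mask, wc_in.n >= 5)


class TestFitBetaMom:
    def test_closed_form_two_point_example(self):
        # proportions 0.25 and 0.75: m1=0.5, v=0.125 -> kappa=1, alpha=beta=0.5
        params = fit_beta_mom([1, 3], [4, 4])
        assert params.alpha == pytest.approx(0.5)
        assert params.beta == pytest.approx(0.5)

    def test_recovers_beta_parameters_from_seeded_draws(self):
        rng = np.random.default_rng(7)
        p = rng.beta(2, 8, size=10_000)
        n = np.full(10_000, 100)
        params = fit_beta_mom(np.round(p * n), n)
        assert params.alpha == pytest.approx(2.0, rel=0.1)
        assert params.beta == pytest.approx(8.0, rel=0.1)

    def test_zero_variance_clamps_concentration_and_preserves_mean(self):
        params = fit_beta_mom([3, 3, 3], [10, 10, 10])
        assert params.alpha + params.beta == pytest.approx(KAPPA_MAX)
        assert params.mean == pytest.approx(0.3)

    def test_extreme_overdispersion_clamps_low(self):
        # proportions 0 and 1: v = 0.5 >= m1(1-m1) = 0.25
        params = fit_beta_mom([0, 10], [10, 10])
        assert params.alpha + params.beta == pytest.approx(0.01)

    def test_too_few_observations_error_mentions_fallback(self):
        with pytest.raises(InsufficientDataError, match="background"):
            fit_beta_mom([3], [10])
        with pytest.raises(InsufficientDataError):
            fit_beta_mom([1, 2], [0, 0])  # no usable coverage


class TestFitMethylationModel:
    @staticmethod
    def simulate_counts(rng, means, kappa, n_sites, coverage=30):
        out = []
        for _ in range(n_sites):
            p = rng.beta(np.asarray(means) * kappa, (1 - np.asarray(means)) * kappa)
            n = rng.poisson(coverage, size=len(means))
            x = rng.binomial(n, p)
            out.append(counts(x, n))
        return out

    def test_recovers_dip_shape_and_background(self):
        rng = np.random.default_rng(1)
        profile = np.concatenate(
            [np.linspace(0.8, 0.2, 11), np.linspace(0.2, 0.8, 11)[1:]]
        )
        bound = self.simulate_counts(rng, profile, kappa=50, n_sites=400)
        unbound = self.simulate_counts(rng, np.full(21, 0.85), kappa=50, n_sites=400)
        model = fit_methylation_model(bound, unbound)
        np.testing.assert_allclose(model.binding_means, profile, atol=0.05)
        assert model.background.mean == pytest.approx(0.85, abs=0.05)

    def test_null_fit_binding_means_equal_background(self):
        rng = np.random.default_rng(2)
        flat = np.full(21, 0.85)
        bound = self.simulate_counts(rng, flat, kappa=50, n_sites=300)
        unbound = self.simulate_counts(rng, flat, kappa=50, n_sites=300)
        model = fit_methylation_model(bound, unbound)
        np.testing.assert_allclose(
            model.binding_means, model.background.mean, atol=0.05
        )

    def test_sparse_window_inherits_background(self, caplog):
        rng = np.random.default_rng(3)
        bound = self.simulate_counts(rng, np.full(21, 0.3), kappa=20, n_sites=5)
        for wc in bound:  # starve window 0 of data
            wc.n[0] = 0
            wc.x[0] = 0
            wc.cg[0] = 0
        unbound = self.simulate_counts(rng, np.full(21, 0.85), kappa=20, n_sites=5)
        with caplog.at_level("WARNING"):
            model = fit_methylation_model(bound, unbound)
        assert model.binding[0] == model.background
        assert "background" in caplog.text

    def test_serialization_roundtrip_is_identity(self, tmp_path):
        rng = np.random.default_rng(4)
        bound = self.simulate_counts(rng, np.full(21, 0.4), kappa=20, n_sites=10)
        unbound = self.simulate_counts(rng, np.full(21, 0.85), kappa=20, n_sites=10)
        model = fit_methylation_model(bound, unbound)
        path = tmp_path / "meth_model.json"
        model.save(path)
        back = MethylationModel.load(path)
        assert back == model

    def test_version_mismatch_rejected(self):
        payload = MethylationModel(
            binding=[BetaParams(1, 1)] * 21,
            background=BetaParams(1, 1),
            window_size=30,
            n_flank=10,
            context="CG",
        ).to_dict()
        payload["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            MethylationModel.from_dict(payload)


class TestBetaBinomLogpmf:
    def test_uniform_marginal_when_alpha_beta_one(self):
        for x in range(6):
            assert betabinom_logpmf(x, 5, BetaParams(1, 1)) == pytest.approx(
                math.log(1 / 6)
            )

    def test_empty_observation_has_probability_one(self):
        assert betabinom_logpmf(0, 0, BetaParams(2, 5)) == pytest.approx(0.0)

    def test_matches_numerical_quadrature(self):
        params = BetaParams(2, 5)

        def integrand(p):
            return (
                math.comb(7, 2)
                * p**2
                * (1 - p) ** 5
                * stats.beta.pdf(p, params.alpha, params.beta)
            )

        expected, _ = integrate.quad(integrand, 0, 1, epsabs=1e-13, epsrel=1e-13)
        assert math.exp(betabinom_logpmf(2, 7, params)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_matches_scipy_reference_distribution(self):
        # independent cross-check against scipy's beta-binomial
        for alpha, beta, n in [(0.5, 3.0, 12), (4.0, 4.0, 30), (10.0, 0.2, 7)]:
            x = np.arange(n + 1)
            ours = betabinom_logpmf(x, np.full(n + 1, n), BetaParams(alpha, beta))
            ref = stats.betabinom.logpmf(x, n, alpha, beta)
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 5.0])
    @pytest.mark.parametrize("beta", [0.3, 1.0, 8.0])
    @pytest.mark.parametrize("n", [0, 1, 7, 50])
    def test_pmf_normalizes(self, alpha, beta, n):
        x = np.arange(n + 1)
        total = np.exp(betabinom_logpmf(x, np.full(n + 1, n), BetaParams(alpha, beta))).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            betabinom_logpmf(5, 3, BetaParams(1, 1))
        with pytest.raises(ValueError):
            betabinom_logpmf(-1, 3, BetaParams(1, 1))


def flat_model(binding_params, background_params):
    return MethylationModel(
        binding=[binding_params] * 21,
        background=background_params,
        window_size=30,
        n_flank=10,
        context="CG",
    )


class TestMethylationScore:
    def test_zero_when_hypotheses_identical(self, rng):
        model = flat_model(BetaParams(3, 7), BetaParams(3, 7))
        n = rng.integers(0, 30, size=21)
        x = rng.binomial(n, 0.4)
        wc = counts(x, n)
        assert methylation_score(wc, model) == 0.0

    def test_zero_without_covered_windows(self):
        model = flat_model(BetaParams(1, 9), BetaParams(9, 1))
        wc = counts(np.zeros(21, int), np.zeros(21, int))
        assert methylation_score(wc, model) == 0.0

    def test_closed_form_value_on_uniform_counts(self):
        binding, background = BetaParams(1, 9), BetaParams(9, 1)
        model = flat_model(binding, background)
        wc = counts(np.ones(21, int), np.full(21, 10))
        expected = 21 * (
            betabinom_logpmf(1, 10, binding) - betabinom_logpmf(1, 10, background)
        )
        got = methylation_score(wc, model)
        assert got == pytest.approx(expected)
        assert got > 0  # hypomethylated counts favor the binding model

    def test_additive_over_windows_and_order_invariant(self, rng):
        binding = [BetaParams(float(a), float(b)) for a, b in rng.uniform(0.5, 9, (21, 2))]
        background = BetaParams(8, 2)
        model = MethylationModel(
            binding=binding, background=background,
            window_size=30, n_flank=10, context="CG",
        )
        n = rng.integers(0, 20, size=21)
        x = rng.binomial(n, 0.5)
        wc = counts(x, n)
        per_window = [
            betabinom_logpmf(x[j], n[j], binding[j])
            - betabinom_logpmf(x[j], n[j], background)
            for j in range(21)
            if n[j] > 0
        ]
        assert methylation_score(wc, model) == pytest.approx(sum(per_window))

    def test_monotone_in_methylated_count_when_binding_hypomethylated(self):
        model = flat_model(BetaParams(2, 8), BetaParams(8, 2))
        n = np.full(21, 12)
        scores = []
        for x0 in range(13):
            x = np.full(21, 6)
            x[0] = x0
            scores.append(methylation_score(counts(x, n), model))
        # decreasing x in a hypomethylation window never decreases the score
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_layout_length_mismatch_rejected(self):
        model = flat_model(BetaParams(1, 1), BetaParams(1, 1))
        with pytest.raises(ValueError, match="slots"):
            methylation_score(counts([1], [2]), model)
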