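"""Similarity metrics: identities, formula oracles, invariance harness."""

import numpy as np
import pytest

from dgsep.metrics import (
    cosine_similarity,
    hamming_distance,
    instantaneous_rate_correlation,
    invariance_harness,
    mean_curves,
    mutual_information,
    normalize_rates,
    normalized_euclidean,
    rate_correlation,
    smoothed_rates,
)
from dgsep.patterns import base_pattern_pair, generate_base_pattern, morph_patterns

RNG = np.random.default_rng(123)


class TestVectorMetrics:
    def test_self_comparison_identities(self):
        F = RNG.uniform(0, 10, 50)
        assert hamming_distance(F, F) == 0.0
        assert normalized_euclidean(F, F) == 0.0
        assert cosine_similarity(F, F) == pytest.approx(1.0)
        assert rate_correlation(F, F) == pytest.approx(1.0)

    def test_hamming_textbook_case(self):
        assert hamming_distance([1, 0, 1], [1, 1, 1]) == pytest.approx(1.0)

    def test_ned_textbook_case(self):
        assert normalized_euclidean([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_formula_oracles_on_random_vectors(self):
        F0, Fb = RNG.uniform(0, 20, 80), RNG.uniform(0, 20, 80)
        n0, nb = normalize_rates(F0, Fb)
        assert hamming_distance(F0, Fb) == pytest.approx(np.abs(n0 - nb).sum())
        assert normalized_euclidean(F0, Fb) == pytest.approx(
            np.sqrt(((n0 - nb) ** 2).sum() / 80))
        assert cosine_similarity(F0, Fb) == pytest.approx(
            F0 @ Fb / np.linalg.norm(F0) / np.linalg.norm(Fb))
        cov = np.cov(F0, Fb)
        assert rate_correlation(F0, Fb) == pytest.approx(
            cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))

    def test_orthogonal_supports_cosine_zero(self):
        assert cosine_similarity([1, 1, 0, 0], [0, 0, 2, 3]) == 0.0

    def test_affine_invariance_of_pearson(self):
        F = RNG.uniform(0, 10, 60)
        assert rate_correlation(F, 2.5 * F + 1.0) == pytest.approx(1.0)

    def test_undefined_markers(self):
        assert np.isnan(rate_correlation(np.ones(10), RNG.uniform(0, 1, 10)))
        assert np.isnan(cosine_similarity(np.zeros(5), np.ones(5)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance([1, 2], [1, 2, 3])


class TestMutualInformation:
    def test_copy_equals_marginal_entropy(self):
        F = RNG.uniform(0, 10, 500)
        mi = mutual_information(F, F, bins=10)
        counts, _ = np.histogram(F, bins=10)
        p = counts / counts.sum()
        h = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert mi == pytest.approx(h, rel=1e-9)

    def test_two_symbol_diagonal_is_one_bit(self):
        F0 = np.array([0.0] * 50 + [1.0] * 50)
        assert mutual_information(F0, F0, bins=2) == pytest.approx(1.0)

    def test_independent_samples_near_zero(self):
        F0, Fb = RNG.uniform(0, 1, 10_000), RNG.uniform(0, 1, 10_000)
        assert mutual_information(F0, Fb, bins=10) < 0.05  # plug-in bias bound

    def test_degenerate_single_bin(self):
        assert mutual_information(np.ones(10), np.ones(10)) == 0.0


class TestInstantaneousRateCorrelation:
    def test_identical_patterns_give_one(self):
        P = generate_base_pattern(20, 10.0, 1000.0, seed=9)
        R = instantaneous_rate_correlation(P.trains, P.trains, (0, 1000.0))
        assert R == pytest.approx(1.0)

    def test_relabeling_symmetry(self):
        P = generate_base_pattern(15, 10.0, 1000.0, seed=10)
        Q = generate_base_pattern(15, 10.0, 1000.0, seed=11)
        R1 = instantaneous_rate_correlation(P.trains, Q.trains, (0, 1000.0))
        perm = np.random.default_rng(1).permutation(15)
        R2 = instantaneous_rate_correlation([P.trains[i] for i in perm],
                                            [Q.trains[i] for i in perm],
                                            (0, 1000.0))
        assert R1 == pytest.approx(R2, abs=1e-12)

    def test_small_case_against_bruteforce_pipeline(self):
        """Independent reimplementation: binning, Gaussian smoothing,
        pairwise Pearson matrices, upper-triangle Pearson."""
        trains0 = [np.array([100.0, 400.0, 700.0]), np.array([150.0, 820.0]),
                   np.array([50.0, 500.0, 950.0]), np.array([300.0])]
        trainsb = [np.array([110.0, 390.0]), np.array([600.0, 800.0]),
                   np.array([75.0, 525.0]), np.array([200.0, 900.0])]
        window, dt = (0.0, 1000.0), 2.0

        def brute_smooth(trains):
            n_bins = int(1000.0 / dt)
            out = []
            for t in trains:
                f = len(t) / 1.0  # Hz over a 1 s window
                sigma = 1000.0 / (10.0 * f)
                grid = np.arange(n_bins) * dt
                series = np.zeros(n_bins)
                for s in t:
                    series += np.exp(-0.5 * ((grid - (s // dt) * dt) / sigma) ** 2)
                return_series = series
                out.append(return_series)
            return np.array(out)

        def brute_R(t0, tb):
            X0, Xb = brute_smooth(t0), brute_smooth(tb)
            C0 = np.corrcoef(X0)
            Cb = np.corrcoef(Xb)
            iu = np.triu_indices(len(t0), k=1)
            return np.corrcoef(C0[iu], Cb[iu])[0, 1]

        got = instantaneous_rate_correlation(trains0, trainsb, window, dt_ms=dt)
        expected = brute_R(trains0, trainsb)
        # same pipeline up to kernel truncation/normalization conventions
        assert got == pytest.approx(expected, abs=0.05)

    def test_too_few_trains_undefined(self):
        t = [np.array([1.0]), np.array([2.0])]
        assert np.isnan(instantaneous_rate_correlation(t, t, (0, 10.0)))

    def test_silent_trains_handled(self):
        trains = [np.array([100.0, 300.0]), np.empty(0), np.array([500.0]),
                  np.array([700.0, 900.0])]
        sm = smoothed_rates(trains, (0, 1000.0))
        assert np.all(sm[1] == 0.0)
        R = instantaneous_rate_correlation(trains, trains, (0, 1000.0))
        assert np.isfinite(R)


class TestInvarianceHarness:
    def test_distribution_factor_runs_and_r_is_invariant(self):
        h = invariance_harness(["r", "HD"], "distribution", n_sets=3, seed=21,
                               n_trains=150, duration_ms=1000.0)
        m = mean_curves(h)
        r_curves = {s: g.sort_values("beta")["value"].to_numpy()
                    for s, g in m[m.metric_id == "r"].groupby("setting")}
        vals = list(r_curves.values())
        assert np.max(np.abs(vals[0] - vals[1])) < 0.15

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError):
            invariance_harness(["r"], "nonsense")

    def test_monotone_in_beta(self):
        P0, P1 = base_pattern_pair(200, 8.0, 1500.0, seed=31)
        fam = morph_patterns(P0, P1, seed=32)
        f0 = None
        from dgsep.metrics import compute_metric
        vals = [compute_metric("r", fam[0], P) for P in fam]
        diffs = np.diff(vals)
        assert (diffs < 0.1).all()          # non-increasing up to noise
        assert vals[0] > vals[-1]
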