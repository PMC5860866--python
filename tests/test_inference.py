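"""Partial correlations, variance partitioning, nonparametric tests,
noise ceilings, and the split-group reproducibility permutation test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from rsapart import (
    NoiseCeiling,
    fdr_adjust,
    noise_ceiling,
    partial_correlation,
    reproducibility_test,
    signed_rank_test,
    variance_partition,
    vectorize_rdm,
)
from rsapart.rdm import RDM, correlate_rdms, unvectorize_rdm

from conftest import random_rdm


class TestPartialCorrelation:
    def test_orthogonal_covariates_equal_zero_order(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = x + 0.5 * rng.standard_normal(n)
        z = rng.standard_normal(n)
        # orthogonalize z against both x and y (and the intercept)
        D = np.column_stack([np.ones(n), x, y])
        z -= D @ np.linalg.lstsq(D, z, rcond=None)[0]
        r0 = correlate_rdms(y, x, "pearson")
        assert partial_correlation(y, x, [z]) == pytest.approx(r0, abs=1e-10)

    def test_single_covariate_closed_form(self, rng):
        n = 100
        z = rng.standard_normal(n)
        x = 0.6 * z + rng.standard_normal(n)
        y = 0.3 * z + 0.4 * x + rng.standard_normal(n)
        rxy = stats.pearsonr(x, y).statistic
        rxz = stats.pearsonr(x, z).statistic
        ryz = stats.pearsonr(y, z).statistic
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_correlation(y, x, [z]) == pytest.approx(expected, abs=1e-10)

    def test_y_equal_to_covariate_gives_error(self, rng):
        z = rng.standard_normal(50)
        x = rng.standard_normal(50)
        with pytest.raises(ValueError, match="zero residual variance"):
            partial_correlation(z, x, [z])

    def test_no_covariates_is_pearson(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        assert partial_correlation(y, x) == pytest.approx(
            correlate_rdms(y, x, "pearson"), abs=1e-12
        )

    def test_collinear_covariates_rejected(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        z = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(y, x, [z, 2 * z])


class TestVariancePartition:
    def test_single_source_limit(self, rng):
        n = 435
        A = rng.standard_normal(n)
        B, C = rng.standard_normal(n), rng.standard_normal(n)
        part = variance_partition(A, A, B, C)
        assert part.unique["A"] == pytest.approx(part.r2_full, abs=0.02)
        for k, v in part.shared.items():
            assert abs(v) < 0.02
        assert part.r2_full == pytest.approx(1.0)

    def test_full_redundancy_limit(self, rng):
        n = 435
        A = rng.standard_normal(n)
        B = A + 1e-6 * rng.standard_normal(n)  # near-exact copy
        C = rng.standard_normal(n)
        y = A + B
        part = variance_partition(y, A, B, C)
        assert abs(part.unique["A"]) < 1e-3
        assert abs(part.unique["B"]) < 1e-3
        # chance variance picked up by C (r2 ~ 1/n) keeps this from exact equality
        assert part.shared[frozenset({"A", "B"})] == pytest.approx(
            part.r2_full, abs=0.03
        )
        assert part.shared[frozenset({"A", "B"})] > 0.9

    def test_matches_normal_equations_oracle(self, rng):
        n = 435
        X = rng.standard_normal((n, 3))
        y = X @ [0.8, 0.4, 0.2] + rng.standard_normal(n)
        part = variance_partition(y, X[:, 0], X[:, 1], X[:, 2])

        def r2_via_normal_equations(cols):
            D = np.column_stack([np.ones(n), X[:, cols]])
            beta = np.linalg.solve(D.T @ D, D.T @ y)
            resid = y - D @ beta
            return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)

        r2 = {c: r2_via_normal_equations(list(c)) for k in (1, 2, 3)
              for c in itertools.combinations(range(3), k)}
        uA = r2[(0, 1, 2)] - r2[(1, 2)]
        uB = r2[(0, 1, 2)] - r2[(0, 2)]
        uC = r2[(0, 1, 2)] - r2[(0, 1)]
        sAB = r2[(0, 2)] + r2[(1, 2)] - r2[(0, 1, 2)] - r2[(2,)]
        sAC = r2[(0, 1)] + r2[(1, 2)] - r2[(0, 1, 2)] - r2[(1,)]
        sBC = r2[(0, 1)] + r2[(0, 2)] - r2[(0, 1, 2)] - r2[(0,)]
        sABC = (r2[(0,)] + r2[(1,)] + r2[(2,)] - r2[(0, 1)] - r2[(0, 2)]
                - r2[(1, 2)] + r2[(0, 1, 2)])
        assert part.unique["A"] == pytest.approx(uA, abs=1e-10)
        assert part.unique["B"] == pytest.approx(uB, abs=1e-10)
        assert part.unique["C"] == pytest.approx(uC, abs=1e-10)
        assert part.shared[frozenset({"A", "B"})] == pytest.approx(sAB, abs=1e-10)
        assert part.shared[frozenset({"A", "C"})] == pytest.approx(sAC, abs=1e-10)
        assert part.shared[frozenset({"B", "C"})] == pytest.approx(sBC, abs=1e-10)
        assert part.shared[frozenset({"A", "B", "C"})] == pytest.approx(sABC, abs=1e-10)

    def test_components_sum_to_full_r2(self, rng):
        for _ in range(50):
            X = rng.standard_normal((60, 3))
            y = X @ rng.standard_normal(3) + rng.standard_normal(60)
            part = variance_partition(y, X[:, 0], X[:, 1], X[:, 2])
            assert part.components_sum() == pytest.approx(part.r2_full, abs=1e-10)

    def test_percentage_view_clips_and_flags(self, rng):
        n = 300
        z = rng.standard_normal(n)
        A = z + 0.1 * rng.standard_normal(n)
        B = -z + 0.1 * rng.standard_normal(n)  # suppressor structure
        C = rng.standard_normal(n)
        y = A + B + 0.5 * rng.standard_normal(n)
        part = variance_partition(y, A, B, C)
        assert all(v >= 0 for v in part.percentages.values())
        negatives = [k for k, v in {**part.unique,
                     **{"&".join(sorted(s, key=list(part.predictors).index)): v
                        for s, v in part.shared.items()}}.items() if v < 0]
        if negatives:
            assert part.clipped

    def test_rank_deficient_design_rejected(self, rng):
        A = rng.standard_normal(50)
        with pytest.raises(ValueError, match="collinear"):
            variance_partition(rng.standard_normal(50), A, 2 * A, rng.standard_normal(50))

    def test_parameter_recovery_rank_order(self, rng):
        """Mixing weights over orthonormalized predictors map onto unique r2."""
        from rsapart.synthetic import gen_composite_rdm, gen_model_rdms

        hits = 0
        n_seeds = 100
        weights = (1.0, 0.6, 0.3)
        for seed in range(n_seeds):
            models, _ = gen_model_rdms(
                n_items=20, target_pairwise_r=0.0, n_features=150, rng_seed=seed
            )
            y_rdm, _ = gen_composite_rdm(
                models, weights, noise_sd=0.4, rng_seed=seed, orthonormalize=True
            )
            vecs = [vectorize_rdm(m) for m in models]
            part = variance_partition(vectorize_rdm(y_rdm), *vecs)
            u = [part.unique[k] for k in ("A", "B", "C")]
            if u[0] > u[1] > u[2]:
                hits += 1
        assert hits >= 95


class TestSignedRank:
    def test_all_positive_n20_gives_w210(self, rng):
        values = rng.uniform(0.1, 1.0, size=20)
        res = signed_rank_test(values, sided="one")
        assert res.W == 210  # 20 * 21 / 2, the maximum possible
        assert res.p < 0.0001

    def test_sign_flip_antisymmetry(self, rng):
        values = rng.standard_normal(15)
        values = values[values != 0]
        n = values.size
        res_pos = signed_rank_test(values, sided="two")
        res_neg = signed_rank_test(-values, sided="two")
        assert res_pos.W + res_neg.W == pytest.approx(n * (n + 1) / 2)
        assert res_pos.p == pytest.approx(res_neg.p, abs=1e-12)

    def test_exact_p_matches_exhaustive_sign_enumeration(self, rng):
        values = rng.standard_normal(12)
        res = signed_rank_test(values, sided="one")
        ranks = stats.rankdata(np.abs(values))
        count = 0
        for signs in itertools.product([0, 1], repeat=12):
            w = sum(r for s, r in zip(signs, ranks) if s)
            if w >= res.W:
                count += 1
        assert res.p == pytest.approx(count / 2**12, abs=1e-12)

    def test_paired_mode_equals_difference_mode(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        res_paired = signed_rank_test(a, paired_with=b, sided="two")
        res_diff = signed_rank_test(a - b, sided="two")
        assert res_paired.W == res_diff.W and res_paired.p == res_diff.p

    def test_zero_differences_dropped(self):
        values = np.array([0.0, 0.0, 1.0, 2.0, 3.0, -1.5, 2.5, 0.5])
        res = signed_rank_test(values, sided="two")
        assert res.n == 6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            signed_rank_test(np.zeros(8))


class TestFDR:
    def test_hand_computed_family(self):
        adj = fdr_adjust([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.05, 0.05], atol=1e-12)

    def test_single_and_equal_families(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])
        np.testing.assert_allclose(fdr_adjust([0.02, 0.02, 0.02]), [0.02] * 3)

    def test_never_decreases_p(self, rng):
        p = rng.uniform(1e-6, 1.0, size=30)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)

    def test_families_adjusted_independently(self):
        p = [0.01, 0.02, 0.04, 0.05, 0.01, 0.02, 0.04, 0.05]
        fams = [0, 0, 0, 0, 1, 1, 1, 1]
        adj = fdr_adjust(p, fams)
        np.testing.assert_allclose(adj[:4], adj[4:])
        np.testing.assert_allclose(adj[:4], [0.04, 0.04, 0.05, 0.05])

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_adjust([])


class TestNoiseCeiling:
    def test_identical_rdms_hit_one(self, rng):
        rdm = random_rdm(8, rng)
        nc = noise_ceiling([rdm] * 5)
        assert nc.upper == pytest.approx(1.0)
        assert nc.lower == pytest.approx(1.0)

    def test_lower_below_upper_for_heterogeneous_group(self, rng):
        rdms = [random_rdm(8, rng) for _ in range(6)]
        nc = noise_ceiling(rdms)
        assert nc.lower < nc.upper

    def test_matches_leave_one_out_loop_oracle(self, rng):
        rdms = [random_rdm(7, rng) for _ in range(10)]
        nc = noise_ceiling(rdms)
        vecs = [vectorize_rdm(r) for r in rdms]
        grand = np.mean(vecs, axis=0)
        upper = np.mean([stats.pearsonr(v, grand).statistic for v in vecs])
        lowers = []
        for i in range(10):
            rest = np.mean([vecs[j] for j in range(10) if j != i], axis=0)
            lowers.append(stats.pearsonr(vecs[i], rest).statistic)
        assert nc.upper == pytest.approx(upper, abs=1e-12)
        assert nc.lower == pytest.approx(np.mean(lowers), abs=1e-12)

    def test_bound_violation_raises(self):
        with pytest.raises(ValueError):
            NoiseCeiling(upper=0.2, lower=0.5)

    def test_requires_three_participants(self, rng):
        with pytest.raises(ValueError, match="3 participants"):
            noise_ceiling([random_rdm(5, rng)] * 2)


class TestReproducibility:
    def test_identical_groups_give_max_statistic(self, rng):
        rdms = [random_rdm(8, rng) for _ in range(4)]
        res = reproducibility_test(rdms, list(rdms), n_perm=500, n_boot=200, rng_seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / (1 + res.n_permutations))

    def test_three_category_null_matches_exhaustive_enumeration(self, rng):
        g1 = [random_rdm(3, rng) for _ in range(3)]
        g2 = [random_rdm(3, rng) for _ in range(3)]
        res = reproducibility_test(g1, g2, n_perm=6, n_boot=100, rng_seed=1)
        from rsapart.behavior import average_rdms

        a1, a2 = average_rdms(g1), average_rdms(g2)
        v1 = vectorize_rdm(a1)
        expected = []
        for perm in itertools.permutations(range(3)):
            P = np.array(perm)
            permuted = a2.values[np.ix_(P, P)]
            v2 = permuted[np.tril_indices(3, k=-1)]
            expected.append(stats.pearsonr(v1, v2).statistic)
        assert res.n_permutations == 6
        np.testing.assert_allclose(sorted(res.null_distribution), sorted(expected), atol=1e-12)

    def test_ci_contains_r_for_stable_groups(self, rng):
        base = random_rdm(10, rng)
        spread = vectorize_rdm(base).std()
        noisy = lambda: unvectorize_rdm(
            vectorize_rdm(base) + 0.5 * spread * rng.standard_normal(45), base.labels
        )
        res = reproducibility_test(
            [noisy() for _ in range(6)], [noisy() for _ in range(6)],
            n_perm=300, n_boot=500, rng_seed=2,
        )
        assert res.ci is not None
        lo, hi = res.ci
        # resampling participants duplicates noise, slightly attenuating the
        # bootstrap correlations; allow the upper bound to sit marginally
        # below the observed r (the result reports it either way)
        assert lo <= res.r
        assert hi >= res.r - 0.02
        assert hi - lo < 0.3

    def test_single_participant_group_omits_ci(self, rng):
        g1 = [random_rdm(5, rng) for _ in range(3)]
        g2 = [random_rdm(5, rng)]
        with pytest.warns(UserWarning, match="CI omitted"):
            res = reproducibility_test(g1, g2, n_perm=120, n_boot=50, rng_seed=3)
        assert res.ci is None

    def test_small_n_perm_warns(self, rng):
        g = [random_rdm(5, rng) for _ in range(3)]
        with pytest.warns(UserWarning, match="coarse"):
            reproducibility_test(g, g, n_perm=50, n_boot=50, rng_seed=4)
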