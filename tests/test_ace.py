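import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from otuherit.ace import (
    AceEstimate,
    PairedTrait,
    ace_loglik,
    falconer_estimate,
    fit_ace,
    fit_all,
    paired_trait_from_matrix,
    profile_ci,
)
from otuherit.preprocess import TraitMatrix
from otuherit.synthetic_data import simulate_twin_traits
from otuherit.tables_io import EmptyDesignError, TwinPairSet, Zygosity


def brute_force_loglik(a, c, e, mu, data):
    """Independent oracle: explicit 2x2 covariance densities via scipy."""
    V = a * a + c * c + e * e
    total = 0.0
    for pairs, k in ((data.mz, a * a + c * c), (data.dz, 0.5 * a * a + c * c)):
        cov = np.array([[V, k], [k, V]])
        total += multivariate_normal(mean=[mu, mu], cov=cov).logpdf(pairs).sum()
    return total


class TestAceLoglik:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a, c, e = rng.uniform(0.2, 1.5, 3)
            mu = rng.normal()
            data = PairedTrait(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)))
            assert ace_loglik(a, c, e, mu, data) == pytest.approx(
                brute_force_loglik(a, c, e, mu, data), rel=1e-10
            )

    def test_collapses_to_univariate_when_a_c_zero(self):
        rng = np.random.default_rng(1)
        data = PairedTrait(rng.normal(size=(6, 2)), rng.normal(size=(5, 2)))
        e, mu = 1.3, 0.2
        expect = norm(mu, e).logpdf(np.concatenate([data.mz.ravel(), data.dz.ravel()])).sum()
        assert ace_loglik(0.0, 0.0, e, mu, data) == pytest.approx(expect, rel=1e-10)

    def test_symmetric_under_within_pair_swap(self):
        rng = np.random.default_rng(2)
        data = PairedTrait(rng.normal(size=(8, 2)), rng.normal(size=(7, 2)))
        swapped = PairedTrait(data.mz[:, ::-1], data.dz[:, ::-1])
        assert ace_loglik(0.7, 0.4, 0.9, 0.1, data) == pytest.approx(
            ace_loglik(0.7, 0.4, 0.9, 0.1, swapped)
        )

    def test_singular_covariance_returns_neg_inf(self):
        data = PairedTrait(np.ones((3, 2)), np.ones((3, 2)))
        assert ace_loglik(1.0, 0.0, 0.0, 0.0, data) == -np.inf


class TestFalconer:
    def make_with_correlations(self, r_mz, r_dz, n=4000, seed=0):
        # construction gives exact population correlations; sample r is close
        rng = np.random.default_rng(seed)
        def pairs(r, n):
            z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
            return z
        return PairedTrait(pairs(r_mz, n), pairs(r_dz, n))

    def double_entry_r(self, p):
        x = np.concatenate([p[:, 0], p[:, 1]])
        y = np.concatenate([p[:, 1], p[:, 0]])
        return np.corrcoef(x, y)[0, 1]

    @pytest.mark.parametrize(
        "r_mz,r_dz,expect",
        [(0.6, 0.4, (0.4, 0.2, 0.4)), (0.3, 0.3, (0.0, 0.3, 0.7))],
    )
    def test_closed_form(self, r_mz, r_dz, expect):
        data = self.make_with_correlations(r_mz, r_dz)
        # oracle: recompute the double-entry correlations directly
        rm, rd = self.double_entry_r(data.mz), self.double_entry_r(data.dz)
        A, C, E = falconer_estimate(data)
        assert A == pytest.approx(2 * (rm - rd), abs=1e-12)
        assert C == pytest.approx(2 * rd - rm, abs=1e-12)
        assert E == pytest.approx(1 - rm, abs=1e-12)
        assert np.allclose((A, C, E), expect, atol=0.06)

    def test_equal_correlations_give_zero_A(self):
        data = self.make_with_correlations(0.5, 0.5, n=8000, seed=3)
        A, C, E = falconer_estimate(data)
        assert abs(A) < 0.05 and abs(C - 0.5) < 0.05

    def test_zero_variance_rejected(self):
        data = PairedTrait(np.ones((4, 2)), np.ones((4, 2)))
        with pytest.raises(ValueError, match="variance"):
            falconer_estimate(data)


class TestFitAce:
    def test_perfect_pair_identity_forces_shared_environment(self):
        rng = np.random.default_rng(4)
        mz = np.repeat(rng.normal(size=(40, 1)), 2, axis=1)
        dz = np.repeat(rng.normal(size=(40, 1)), 2, axis=1)
        fit = fit_ace(PairedTrait(mz, dz), seed=0)
        assert fit.C > 0.95 and fit.A < 0.05 and fit.E < 0.02

    def test_uncorrelated_pairs_are_pure_unique_environment(self):
        rng = np.random.default_rng(5)
        fit = fit_ace(PairedTrait(rng.normal(size=(400, 2)), rng.normal(size=(400, 2))), seed=0)
        assert fit.E > 0.9 and fit.A < 0.1 and fit.C < 0.1

    def test_recovers_interior_truth_at_large_n(self):
        data = simulate_twin_traits(10_000, 10_000, 0.4, 0.2, 0.4, seed=6)
        fit = fit_ace(data, seed=0)
        fal = falconer_estimate(data)
        assert fit.converged
        for est, truth in zip((fit.A, fit.C, fit.E), (0.4, 0.2, 0.4)):
            assert abs(est - truth) < 0.03
        # interior solutions agree with the closed form
        assert abs(fit.A - fal[0]) < 0.02
        assert abs(fit.C - fal[1]) < 0.02
        assert abs(fit.E - fal[2]) < 0.02

    def test_standardized_estimates_affine_invariant(self):
        data = simulate_twin_traits(300, 300, 0.4, 0.2, 0.4, seed=7)
        scaled = PairedTrait(5.0 * data.mz + 2.0, 5.0 * data.dz + 2.0)
        f1 = fit_ace(data, seed=0)
        f2 = fit_ace(scaled, seed=0)
        assert abs(f1.A - f2.A) < 1e-5
        assert abs(f1.C - f2.C) < 1e-5
        assert abs(f1.E - f2.E) < 1e-5

    def test_solution_beats_falconer_start(self):
        data = simulate_twin_traits(200, 200, 0.3, 0.2, 0.5, seed=8)
        fit = fit_ace(data, seed=0)
        A0, C0, E0 = np.clip(falconer_estimate(data), 0.01, 0.97)
        s = A0 + C0 + E0
        sd = np.concatenate([data.mz.ravel(), data.dz.ravel()]).std()
        start_ll = ace_loglik(np.sqrt(A0 / s) * sd, np.sqrt(C0 / s) * sd,
                              np.sqrt(E0 / s) * sd, 0.0, data)
        assert fit.loglik >= start_ll - 1e-6

    def test_components_sum_to_one(self):
        data = simulate_twin_traits(100, 100, 0.2, 0.3, 0.5, seed=9)
        fit = fit_ace(data, seed=0)
        assert fit.A + fit.C + fit.E == pytest.approx(1.0, abs=1e-8)
        assert all(0 <= v <= 1 for v in (fit.A, fit.C, fit.E))


class TestProfileCi:
    def test_interval_contains_point_estimate(self):
        for seed in range(4):
            data = simulate_twin_traits(150, 150, 0.3, 0.1, 0.6, seed=20 + seed)
            fit = fit_ace(data, seed=0)
            lo, hi = profile_ci(data, fit, "A")
            assert 0.0 <= lo <= fit.A <= hi <= 1.0

    def test_interval_narrows_with_sample_size(self):
        small = simulate_twin_traits(100, 100, 0.4, 0.1, 0.5, seed=30)
        big = simulate_twin_traits(4000, 4000, 0.4, 0.1, 0.5, seed=30)
        f_small, f_big = fit_ace(small, seed=0), fit_ace(big, seed=0)
        w_small = np.diff(profile_ci(small, f_small, "A"))[0]
        w_big = np.diff(profile_ci(big, f_big, "A"))[0]
        assert w_big < w_small


class TestFitAll:
    def make_traits(self, n_otus=3, n_mz=30, n_dz=25, seed=0):
        rng = np.random.default_rng(seed)
        n_samples = 2 * (n_mz + n_dz)
        sample_ids = [f"s{i}" for i in range(n_samples)]
        pairs = []
        for p in range(n_mz + n_dz):
            zyg = Zygosity.MZ if p < n_mz else Zygosity.DZ
            pairs.append((sample_ids[2 * p], sample_ids[2 * p + 1], f"F{p}", zyg))
        tps = TwinPairSet(pairs, n_mz=n_mz, n_dz=n_dz)
        values = rng.normal(size=(n_otus, n_samples))
        return TraitMatrix([f"o{i}" for i in range(n_otus)], sample_ids, values, "m"), tps

    def test_one_estimate_per_otu(self):
        traits, pairs = self.make_traits()
        profile = fit_all(traits, pairs, seed=0, compute_ci=False)
        assert [e.otu_id for e in profile.estimates] == traits.otu_ids
        assert profile.mean_A == pytest.approx(np.mean([e.A for e in profile.estimates]))

    def test_empty_traits_rejected(self):
        traits, pairs = self.make_traits()
        empty = TraitMatrix([], traits.sample_ids, np.empty((0, len(traits.sample_ids))), "m")
        with pytest.raises(EmptyDesignError):
            fit_all(empty, pairs)

    def test_rerun_same_seed_is_bit_identical(self):
        traits, pairs = self.make_traits()
        p1 = fit_all(traits, pairs, seed=3, compute_ci=True)
        p2 = fit_all(traits, pairs, seed=3, compute_ci=True)
        assert p1.to_dataframe().equals(p2.to_dataframe())

    def test_pair_order_invariance(self):
        traits, pairs = self.make_traits()
        flipped = TwinPairSet(
            [(s2, s1, f, z) for s1, s2, f, z in pairs.pairs], pairs.n_mz, pairs.n_dz
        )
        d1 = paired_trait_from_matrix(traits.values[0], traits.sample_ids, pairs)
        d2 = paired_trait_from_matrix(traits.values[0], traits.sample_ids, flipped)
        f1, f2 = fit_ace(d1, seed=0), fit_ace(d2, seed=0)
        assert f1.A == pytest.approx(f2.A, abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
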