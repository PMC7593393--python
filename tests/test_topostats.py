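import itertools

import numpy as np
import pytest

from toposep import topostats as ts
from toposep.topostats import DesignSpec, gfp, gfp_test, normalize_map, t_map, tanova, tct


class TestGFP:
    def test_identities(self):
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)
        assert gfp(np.array([5.0, 5.0, 5.0])) == 0.0
        assert gfp(np.array([3.0, -1.0, -1.0, -1.0])) == pytest.approx(np.sqrt(3))

    def test_equals_population_sd_on_random_maps(self, rng):
        X = rng.normal(size=(1000, 32))
        ref = np.sqrt(np.mean((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1))
        assert np.max(np.abs(gfp(X, axis=1) - ref)) < 1e-12

    def test_invariant_to_constant_offset(self, rng):
        v = rng.normal(size=30)
        assert gfp(v + 42.0) == pytest.approx(gfp(v), abs=1e-10)

    def test_normalize(self, rng):
        assert np.allclose(normalize_map(np.array([2.0, -2.0])), [1.0, -1.0])
        v = rng.normal(size=(20,))
        assert gfp(normalize_map(v)) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="zero"):
            normalize_map(np.zeros(8))


def brute_force_tanova_p(X):
    """Exhaustive within-subject label-permutation p for (S, 2, K) maps."""
    def stat(Y):
        Yn = Y / Y.std(axis=2, keepdims=True)
        L = Yn.mean(axis=0)
        G = L.mean(axis=0)
        return sum(np.std(L[c] - G) for c in range(Y.shape[1]))

    obs = stat(X)
    null = []
    for flips in itertools.product([0, 1], repeat=X.shape[0]):
        Xp = X.copy()
        for s, f in enumerate(flips):
            if f:
                Xp[s] = Xp[s, ::-1]
        null.append(stat(Xp))
    return sum(1 for v in null if v >= obs - 1e-12) / len(null)


class TestTanova:
    def test_exhaustive_equals_enumeration_oracle(self, rng):
        X = rng.normal(size=(4, 2, 8))
        d = DesignSpec(within_levels=("a", "b"), n_perm=16, seed=0)
        res = tanova(X, d, exhaustive=True)["within"]
        assert res.p == pytest.approx(brute_force_tanova_p(X))
        assert res.n_perm == 16

    def test_identical_maps_give_zero_effect_p_one(self):
        one = np.tile(np.array([1.0, -1.0, 2.0, -2.0]), (6, 3, 1))
        d = DesignSpec(within_levels=("a", "b", "c"), n_perm=199, seed=0)
        res = tanova(one, d)["within"]
        assert res.effect == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_orthogonal_patterns_reach_p_floor(self, rng):
        # noise-free orthogonal topographies: every label permutation that
        # mixes the two patterns lowers the dissimilarity, so p sits at its
        # floor (up to the rare draws that flip *every* subject the same
        # way, which reproduce the observed statistic: probability 2/2^S)
        K, S = 16, 12
        u = np.zeros(K); u[0], u[1] = 1, -1
        v = np.zeros(K); v[2], v[3] = 1, -1
        X = np.stack([np.stack([u, v]) for _ in range(S)])
        d = DesignSpec(within_levels=("a", "b"), n_perm=1999, seed=3)
        res = tanova(X, d)["within"]
        assert res.p <= (1 + 5) / 2000.0
        assert res.effect > 0

    def test_invariant_to_global_rescaling(self, rng):
        X = rng.normal(size=(6, 2, 12))
        d = DesignSpec(within_levels=("a", "b"), n_perm=299, seed=5)
        r1 = tanova(X, d)["within"]
        r2 = tanova(X * 7.3, d)["within"]
        assert r1.effect == pytest.approx(r2.effect)
        assert r1.p == r2.p

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(8, 3, 10, 5))
        d = DesignSpec(within_levels=("a", "b", "c"), n_perm=499, seed=11)
        p1 = tanova(X, d)["within"].p
        p2 = tanova(X, d)["within"].p
        assert np.array_equal(p1, p2)

    def test_between_factor_and_interaction(self, rng):
        X = rng.normal(size=(10, 2, 8))
        groups = ("g1",) * 5 + ("g2",) * 5
        d = DesignSpec(within_levels=("a", "b"), groups=groups,
                       n_perm=199, seed=1)
        res = tanova(X, d)
        assert set(res) == {"within", "between", "within*between"}
        for r in res.values():
            assert 1 / 200 <= r.p <= 1.0

    def test_incomplete_design_rejected(self, rng):
        X = rng.normal(size=(4, 2, 8))
        X[1, 0] = np.nan
        d = DesignSpec(within_levels=("a", "b"), n_perm=99, seed=0)
        with pytest.raises(ValueError, match="empty cells"):
            tanova(X, d)


class TestGFPTest:
    def test_strength_topography_dissociation(self, rng):
        # same topography, condition B scaled x0.5: GFP test fires,
        # TANOVA stays null
        K, S = 16, 10
        template = rng.normal(size=K)
        template -= template.mean()
        X = np.stack([np.stack([template * np.exp(rng.normal(0, 0.05)),
                                0.5 * template * np.exp(rng.normal(0, 0.05))])
                      for _ in range(S)])
        d = DesignSpec(within_levels=("a", "b"), n_perm=999, seed=2)
        assert gfp_test(X, d)["within"].p <= 0.05
        assert tanova(X, d)["within"].p == 1.0  # maps exactly proportional

    def test_single_subject_errors(self, rng):
        X = rng.normal(size=(1, 2, 8))
        d = DesignSpec(within_levels=("a", "b"), n_perm=99, seed=0)
        with pytest.raises(ValueError, match="subjects"):
            gfp_test(X, d)

    def test_not_invariant_to_rescaling_one_condition(self, rng):
        X = rng.normal(size=(8, 2, 12))
        d = DesignSpec(within_levels=("a", "b"), n_perm=199, seed=5)
        base = gfp_test(X, d)["within"].effect
        X2 = X.copy()
        X2[:, 1] *= 3.0
        assert gfp_test(X2, d)["within"].effect != pytest.approx(float(base))


class TestTCT:
    def test_shared_map_reaches_minimum_p(self, rng):
        template = rng.normal(size=24)
        X = np.tile(template, (8, 1))
        res = tct(X, n_perm=999, seed=0)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_single_subject_errors(self):
        with pytest.raises(ValueError, match="subjects"):
            tct(np.zeros((1, 10)), n_perm=99, seed=0)

    def test_reproducible(self, rng):
        X = rng.normal(size=(6, 16, 4))
        a = tct(X, n_perm=199, seed=9)
        b = tct(X, n_perm=199, seed=9)
        assert np.array_equal(a.p, b.p)


class TestTMap:
    def test_identical_conditions_zero(self, rng):
        a = rng.normal(size=(6, 10))
        assert np.allclose(t_map(a, a.copy(), paired=True), 0.0)

    def test_paired_matches_textbook_formula(self):
        a = np.array([[1.0], [2.0], [4.0]])
        b = np.array([[0.5], [1.0], [2.5]])
        d = (a - b)[:, 0]
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t_map(a, b, paired=True)[0] == pytest.approx(expect)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=(2, 7, 5))
        assert np.allclose(t_map(a, b, paired=False), -t_map(b, a, paired=False))

    def test_paired_requires_equal_sets(self, rng):
        with pytest.raises(ValueError):
            t_map(rng.normal(size=(5, 4)), rng.normal(size=(6, 4)), paired=True)


class TestMarkerStatistics:
    def test_identical_maps_p_one_and_timewise_consistency(self, rng):
        X = np.tile(rng.normal(size=8), (5, 2, 1))
        d = DesignSpec(within_levels=("a", "b"), n_perm=99, seed=0)
        res = ts.marker_statistics(X, d, test="tanova")["within"]
        assert res.p == 1.0
        # single maps behave exactly like a length-1 time series
        res_tw = tanova(X[..., None], d)["within"]
        assert res_tw.p[0] == res.p

    def test_exhaustive_small_n_matches_oracle(self, rng):
        X = rng.normal(size=(4, 2, 6))
        d = DesignSpec(within_levels=("a", "b"), n_perm=16, seed=0)
        res = tanova(X, d, exhaustive=True)["within"]
        assert res.p == pytest.approx(brute_force_tanova_p(X))
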