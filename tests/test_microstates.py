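import numpy as np
import pytest

from toposep import microstates as tms
from toposep.microstates import aahc, assign_states, cross_validate_k
from toposep.synth import make_microstate_dataset


def label_purity(labels, truth):
    """Best one-to-one relabeling accuracy."""
    import itertools

    k = int(truth.max()) + 1
    best = 0.0
    for perm in itertools.permutations(range(k)):
        best = max(best, np.mean([perm[l] == t for l, t in zip(labels, truth)]))
    return best


class TestAAHC:
    def test_orthogonal_maps_recovered_exactly(self, rng):
        maps, templates, seq = make_microstate_dataset(
            n_subjects=1, n_states=3, samples_per_state=10, noise_sd=0.02, seed=3)
        model = aahc(maps[0], 3)
        assert label_purity(model.labels, seq) == 1.0
        corr = np.abs(tms._corr_to_prototypes(templates, model.prototypes))
        assert corr.max(axis=1).min() >= 0.999
        assert model.gev >= 0.999
        assert np.max(np.abs(tms.gfp(model.prototypes, axis=1) - 1.0)) < 1e-9

    def test_k_equals_distinct_maps_gives_gev_one(self, rng):
        X = rng.normal(size=(6, 10))
        X -= X.mean(axis=1, keepdims=True)
        model = aahc(X, 6)
        assert model.gev == pytest.approx(1.0)

    def test_two_channel_hand_trace(self):
        # four 2-channel maps: a=(1,-1), b=(1.2,-1.2), c=(-2,2), d=(0.1,-0.1)
        # sensitive mode, k=2.  All maps are proportional to (1,-1) up to
        # sign, so correlations are exactly +-1 and GEV contributions reduce
        # to summed gfp^2.  Trace: singleton d (gfp 0.1) is atomized first
        # and joins a (first cluster with corr +1); the cluster {a, d}
        # (contribution 1.01) is then the weakest, its members migrate to b;
        # final clusters {a, b, d} vs {c} with GEV = 1.
        X = np.array([[1.0, -1.0], [1.2, -1.2], [-2.0, 2.0], [0.1, -0.1]])
        model = aahc(X, 2)
        assert model.labels[0] == model.labels[1] == model.labels[3]
        assert model.labels[2] != model.labels[0]
        assert model.gev == pytest.approx(1.0)
        # prototypes normalized to unit GFP, first cluster positive at ch0
        assert model.prototypes[model.labels[0]][0] == pytest.approx(1.0)

    def test_gev_monotone_in_k(self, rng):
        maps, _, _ = make_microstate_dataset(n_subjects=1, n_states=4,
                                             noise_sd=0.5, seed=1)
        models = aahc(maps[0], range(2, 9))
        gevs = [models[k].gev for k in sorted(models)]
        assert all(b >= a - 1e-12 for a, b in zip(gevs, gevs[1:]))

    def test_labels_invariant_to_global_scaling(self, rng):
        maps, _, _ = make_microstate_dataset(n_subjects=1, n_states=3,
                                             noise_sd=0.3, seed=2)
        m1 = aahc(maps[0], 3)
        m2 = aahc(maps[0] * 11.0, 3)
        assert np.array_equal(m1.labels, m2.labels)

    def test_polarity_modes_on_sign_flip(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=12); u -= u.mean()
        v = rng.normal(size=12); v -= v.mean()
        v -= u * (u @ v) / (u @ u)  # orthogonalize
        X = np.concatenate([np.tile(u, (5, 1)), np.tile(v, (5, 1)),
                            -u[None, :] * 1.01])
        sens = aahc(X, 2, polarity_mode="sensitive")
        ign = aahc(X, 2, polarity_mode="ignorant")
        # sensitive: -u anti-correlates with the u prototype; with only two
        # clusters it lands wherever correlation is larger, but flipping it
        # back must restore the u label
        X2 = X.copy(); X2[-1] *= -1
        sens2 = aahc(X2, 2, polarity_mode="sensitive")
        assert sens2.labels[-1] == sens2.labels[0]
        # ignorant: sign is irrelevant, -u clusters with u
        assert ign.labels[-1] == ign.labels[0]

    def test_k_out_of_range_rejected(self, rng):
        X = rng.normal(size=(5, 8))
        with pytest.raises(ValueError, match="k_target"):
            aahc(X, 0)
        with pytest.raises(ValueError, match="k_target"):
            aahc(X, 6)


class TestAssignStates:
    def test_zero_gfp_maps_unassigned(self, rng):
        protos = rng.normal(size=(2, 8))
        protos -= protos.mean(axis=1, keepdims=True)
        maps = np.vstack([protos[0], np.zeros(8)])
        labels, corr = assign_states(maps, protos)
        assert labels[0] == 0 and labels[1] == -1
        assert corr[1] == 0.0


class TestCrossValidation:
    def test_identical_maps_flat_curve_picks_smallest_k(self):
        template = np.arange(10.0) - 4.5
        X = np.tile(template, (6, 20, 1))
        cv = cross_validate_k(X, k_grid=range(3, 7), n_repeats=5, seed=0)
        assert np.allclose(cv.mean_correlation, 1.0)
        assert cv.chosen_k == 3

    def test_too_few_subjects_error(self, rng):
        with pytest.raises(ValueError, match="4 subjects"):
            cross_validate_k(rng.normal(size=(3, 20, 8)), k_grid=[3],
                             n_repeats=2, seed=0)

    def test_k_grid_beyond_time_points_error(self, rng):
        with pytest.raises(ValueError, match="k_grid"):
            cross_validate_k(rng.normal(size=(6, 5, 8)), k_grid=[3, 10],
                             n_repeats=2, seed=0)

    def test_recovers_true_k_on_one_seed(self):
        maps, _, _ = make_microstate_dataset(n_subjects=20, n_states=4,
                                             noise_sd=1.0, seed=7)
        cv = cross_validate_k(maps, k_grid=range(3, 13), n_repeats=20, seed=7)
        assert cv.chosen_k == 4

    def test_reproducible_from_seed(self, rng):
        maps = rng.normal(size=(8, 30, 12))
        a = cross_validate_k(maps, k_grid=range(3, 6), n_repeats=4, seed=5)
        b = cross_validate_k(maps, k_grid=range(3, 6), n_repeats=4, seed=5)
        assert np.array_equal(a.mean_correlation, b.mean_correlation)
        assert a.chosen_k == b.chosen_k


class TestAssignAndCompare:
    def _series(self, rng, scale_b=1.0, S=6):
        maps, templates, seq = make_microstate_dataset(
            n_subjects=S, n_states=3, samples_per_state=20, noise_sd=0.2, seed=4)
        time = np.arange(maps.shape[1]) * 10.0 - 20.0
        X = np.stack([maps, maps * scale_b], axis=1)  # (S, 2, T, K)
        return X, time, templates

    def test_identical_conditions_all_p_one(self, rng):
        X, time, templates = self._series(rng)
        model = aahc(X[:, 0].mean(axis=0), 3)
        out = tms.assign_and_compare(model, X, time, window_ms=(0.0, 500.0),
                                     n_perm=199, seed=0)
        assert all(float(r.p) == 1.0 for r in out["tests"].values())

    def test_amplitude_scaling_hits_mean_gfp_not_labels(self, rng):
        X, time, templates = self._series(rng, scale_b=0.5, S=8)
        model = aahc(X[:, 0].mean(axis=0), 3)
        out = tms.assign_and_compare(model, X, time, window_ms=(0.0, 500.0),
                                     n_perm=499, seed=1)
        gfp_ps = [float(out["tests"][(j, "mean_gfp")].p) for j in range(3)]
        assert min(gfp_ps) <= 0.05
        # label sequences identical across conditions -> durations match
        dur = out["subject_parameters"][0]  # (k, S, C) durations
        assert np.allclose(dur[:, :, 0], dur[:, :, 1])

    def test_series_shorter_than_window_errors(self, rng):
        X, time, _ = self._series(rng)
        model = aahc(X[:, 0].mean(axis=0), 3)
        with pytest.raises(ValueError, match="window"):
            tms.assign_and_compare(model, X, time, window_ms=(20.0, 2000.0))
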