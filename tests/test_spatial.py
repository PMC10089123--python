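import numpy as np
import pytest

from micross import (
    BandSpec,
    ClassCovariances,
    EpochSet,
    SyntheticConfig,
    bandpass_filter,
    bandpower_features,
    class_mean_covariance,
    csp_fit,
    generate_subject,
    logvar_features,
    rcsp_covariance,
    rcsp_fit,
)
from micross.spatial import logvar_from_covariances, trial_covariances


def _random_spd(rng, c):
    Q = rng.standard_normal((c, c))
    return Q @ Q.T + c * np.eye(c)


class TestClassMeanCovariance:
    def test_trace_is_one(self, labeled_epochs):
        for k in (+1, -1):
            C = class_mean_covariance(labeled_epochs, k)
            assert abs(np.trace(C) - 1.0) < 1e-10

    def test_mean_of_normalized_trials(self, rng):
        data = rng.standard_normal((2, 3, 50))
        epochs = EpochSet(data, fs=100.0, channels=("a", "b", "c"),
                          labels=np.array([1, 1]))
        covs = [X @ X.T for X in data]
        covs = [C / np.trace(C) for C in covs]
        np.testing.assert_allclose(
            class_mean_covariance(epochs, 1), (covs[0] + covs[1]) / 2, atol=1e-12
        )

    def test_empty_class_raises(self, rng):
        epochs = EpochSet(rng.standard_normal((2, 3, 50)), fs=100.0,
                          channels=("a", "b", "c"), labels=np.array([1, 1]))
        with pytest.raises(ValueError, match="class -1"):
            class_mean_covariance(epochs, -1)


class TestCSPFit:
    def test_diagonal_closed_form(self):
        """C1=diag(2,1), C2=diag(1,2): generalized eigenvalues are exactly
        2/3 (filter along e1) and 1/3 (filter along e2)."""
        model = csp_fit(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]), n_pairs=1)
        np.testing.assert_allclose(model.eigenvalues, [2 / 3, 1 / 3], atol=1e-12)
        w_top, w_bot = model.W[:, 0], model.W[:, 1]
        assert abs(w_top[0]) > 100 * abs(w_top[1])  # e1 direction
        assert abs(w_bot[1]) > 100 * abs(w_bot[0])  # e2 direction

    def test_scaling_contract(self, rng):
        C1, C2 = _random_spd(rng, 6), _random_spd(rng, 6)
        model = csp_fit(C1, C2, n_pairs=3)
        gram = model.W.T @ (C1 + C2) @ model.W
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_swap_maps_eigenvalues(self, rng):
        C1, C2 = _random_spd(rng, 4), _random_spd(rng, 4)
        a = csp_fit(C1, C2, n_pairs=2)
        b = csp_fit(C2, C1, n_pairs=2)
        np.testing.assert_allclose(np.sort(a.eigenvalues),
                                   np.sort(1 - b.eigenvalues), atol=1e-10)
        # top filters of one problem equal bottom filters of the swapped one
        np.testing.assert_allclose(
            np.abs(a.W[:, :2]), np.abs(b.W[:, 2:][:, ::-1]), atol=1e-8
        )

    def test_recombination_invariance(self, rng):
        """Congruence C -> M^T C M maps filters w -> M^{-1} w (up to sign)."""
        C1, C2 = _random_spd(rng, 4), _random_spd(rng, 4)
        M = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        a = csp_fit(C1, C2, n_pairs=2)
        b = csp_fit(M.T @ C1 @ M, M.T @ C2 @ M, n_pairs=2)
        mapped = np.linalg.solve(M, np.ones((4, 1))) * 0 + np.linalg.inv(M) @ a.W
        for j in range(4):
            u = mapped[:, j] / np.linalg.norm(mapped[:, j])
            v = b.W[:, j] / np.linalg.norm(b.W[:, j])
            assert abs(abs(u @ v) - 1) < 1e-8

    def test_too_many_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            csp_fit(np.eye(3), np.eye(3), n_pairs=2)


class TestRCSPCovariance:
    def test_beta_one_gamma_zero_is_target(self, rng):
        Ct, Cs = _random_spd(rng, 3), _random_spd(rng, 3)
        cc = ClassCovariances(C_target=Ct, C_source=Cs, n_target=10, n_source=50)
        np.testing.assert_allclose(rcsp_covariance(cc, 1.0, 0.0), Ct, atol=1e-12)

    def test_gamma_one_is_scaled_identity(self, rng):
        Ct, Cs = _random_spd(rng, 3), _random_spd(rng, 3)
        cc = ClassCovariances(C_target=Ct, C_source=Cs, n_target=10, n_source=50)
        out = rcsp_covariance(cc, 0.4, 1.0)
        mix = (0.4 * 10 * Ct + 0.6 * 50 * Cs) / (0.4 * 10 + 0.6 * 50)
        np.testing.assert_allclose(out, (np.trace(mix) / 3) * np.eye(3), atol=1e-12)

    def test_hand_mixture(self):
        """N_l=10, N_s=90, beta=0.5, C_t=2I, C_s=I: (10I + 45I)/50 = 1.1 I."""
        cc = ClassCovariances(C_target=2 * np.eye(2), C_source=np.eye(2),
                              n_target=10, n_source=90)
        np.testing.assert_allclose(rcsp_covariance(cc, 0.5, 0.0),
                                   1.1 * np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("beta", [0.0, 0.3, 1.0])
    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
    def test_output_spd(self, rng, beta, gamma):
        cc = ClassCovariances(C_target=_random_spd(rng, 4), C_source=_random_spd(rng, 4),
                              n_target=5, n_source=20)
        out = rcsp_covariance(cc, beta, gamma)
        assert np.all(np.linalg.eigvalsh(out) > 0)

    def test_degenerate_mixture_rejected(self, rng):
        cc = ClassCovariances(C_target=np.eye(2), C_source=None,
                              n_target=5, n_source=0)
        with pytest.raises(ValueError, match="degenerate"):
            rcsp_covariance(cc, 0.0, 0.0)


class TestRCSPFit:
    def test_beta_one_reduces_to_target_csp(self, labeled_epochs, rng):
        other = EpochSet(rng.standard_normal((10, 4, 250)), fs=250.0,
                         channels=labeled_epochs.channels,
                         labels=np.tile([1, -1], 5))
        reduced = rcsp_fit(labeled_epochs, other, beta=1.0, gamma=0.0, n_pairs=2)
        direct = csp_fit(class_mean_covariance(labeled_epochs, 1),
                         class_mean_covariance(labeled_epochs, -1), n_pairs=2)
        np.testing.assert_allclose(reduced.W, direct.W, atol=1e-10)

    def test_beta_zero_ignores_target(self, labeled_epochs, rng):
        source = EpochSet(rng.standard_normal((10, 4, 250)), fs=250.0,
                          channels=labeled_epochs.channels,
                          labels=np.tile([1, -1], 5))
        a = rcsp_fit(labeled_epochs, source, beta=0.0, gamma=0.0)
        b = rcsp_fit(None, source, beta=0.0, gamma=0.0)
        np.testing.assert_allclose(a.W, b.W, atol=1e-12)

    def test_recovers_planted_direction(self):
        """At strong effect the leading filter aligns (in the whitened
        geometry) with the planted mixing column; cross-checked in the
        acceptance suite with the analytic threshold."""
        from micross.synthetic import _subject_mixing
        from scipy.linalg import sqrtm

        cfg = SyntheticConfig(seed=5)
        s = generate_subject(cfg, 0)
        s = bandpass_filter(s, *cfg.planted_band, order=4)
        model = rcsp_fit(s, s, beta=1.0, gamma=0.0, n_pairs=2)
        C1 = class_mean_covariance(s, +1)
        C2 = class_mean_covariance(s, -1)
        Shalf = np.real(sqrtm(C1 + C2))
        u = Shalf @ model.W[:, 0]
        v = np.linalg.solve(Shalf, _subject_mixing(cfg, 0)[:, 0])
        cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        assert cos >= 0.9


class TestFeatures:
    def test_logvar_hand_example(self):
        """Projected variances 1 and 3 give [log(1/4), log(3/4)]."""
        covs = np.diag([1.0, 3.0])[None]
        feats = logvar_from_covariances(covs, np.eye(2))
        np.testing.assert_allclose(feats[0], [np.log(0.25), np.log(0.75)], atol=1e-12)

    def test_equal_variances_symmetric(self, rng):
        covs = np.eye(5)[None]
        feats = logvar_from_covariances(covs, np.eye(5))
        np.testing.assert_allclose(feats[0], np.log(1 / 5), atol=1e-12)

    def test_amplitude_scale_invariance(self, labeled_epochs):
        model = csp_fit(class_mean_covariance(labeled_epochs, 1),
                        class_mean_covariance(labeled_epochs, -1))
        f1 = logvar_features(labeled_epochs, model)
        scaled = labeled_epochs.evolve(data=10.0 * labeled_epochs.data)
        f2 = logvar_features(scaled, model)
        np.testing.assert_allclose(f1, f2, atol=1e-10)

    def test_logvar_signal_and_covariance_routes_agree(self, labeled_epochs):
        model = csp_fit(class_mean_covariance(labeled_epochs, 1),
                        class_mean_covariance(labeled_epochs, -1))
        via_signal = logvar_features(labeled_epochs, model)
        via_cov = logvar_from_covariances(
            trial_covariances(labeled_epochs, normalize=False), model.W
        )
        np.testing.assert_allclose(via_signal, via_cov, atol=1e-12)

    def test_bandpower_sinusoid(self):
        fs = 250.0
        t = np.arange(2000) / fs
        data = np.sin(2 * np.pi * 20.0 * t)[None, None, :]
        epochs = EpochSet(data, fs=fs, channels=("c0",))
        spec = BandSpec(bands=((18.0, 22.0),))
        feats = bandpower_features(epochs, spec)
        # unit sinusoid mean square = 1/2; band filter passes it nearly whole
        assert abs(np.exp(feats[0, 0]) - 0.5) < 0.05

    def test_bandpower_shape_and_zero_floor(self, rng):
        epochs = EpochSet(np.zeros((2, 3, 500)), fs=250.0, channels=("a", "b", "c"))
        from micross import make_cfb

        feats = bandpower_features(epochs, make_cfb())
        assert feats.shape == (2, 10 * 3)
        np.testing.assert_allclose(feats, np.log(1e-12), atol=1e-9)
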