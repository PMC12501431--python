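"""eTRCA / TDCA: eigen solutions vs brute force, projector algebra,
end-to-end decoding on synthetic data."""

import numpy as np
import pytest
from scipy import optimize as sopt

from ssvepkit import (
    EpochedEEG, crop_window, etrca_fit, etrca_predict, synth_dataset,
    tdca_delay_embed, tdca_fit, tdca_predict, tdca_reference_projection,
    trca_spatial_filter, filter_bank_weights, default_12class_config,
)
from ssvepkit.classical import etrca_scores, tdca_scores


def _rayleigh(w, S, Q):
    return (w @ S @ w) / (w @ Q @ w)


def _trca_matrices(X):
    """Independent loop-based construction of the TRCA (S, Q) pair."""
    nt, nc, ns = X.shape
    Xc = X - X.mean(axis=2, keepdims=True)
    S = np.zeros((nc, nc))
    Q = np.zeros((nc, nc))
    for h1 in range(nt):
        Q += Xc[h1] @ Xc[h1].T / ns
        for h2 in range(nt):
            if h1 != h2:
                S += Xc[h1] @ Xc[h2].T / ns
    return S, Q


class TestTRCAFilter:
    def test_common_signal_channel_dominates(self):
        # channel 0 repeats across trials, channel 1 is strong fresh noise:
        # the filter must concentrate on channel 0
        rng = np.random.default_rng(0)
        common = rng.standard_normal(200)
        trials = np.stack([
            np.stack([common + 0.05 * rng.standard_normal(200),
                      5.0 * rng.standard_normal(200)])
            for _ in range(6)
        ])
        w = trca_spatial_filter(trials)
        assert abs(w[1] / w[0]) < 0.05
        # brute-force Rayleigh maximisation over a dense unit-vector grid
        S, Q = _trca_matrices(trials)
        thetas = np.linspace(0, np.pi, 200_001)
        vals = [_rayleigh(np.array([np.cos(t), np.sin(t)]), S, Q) for t in thetas]
        assert _rayleigh(w, S, Q) >= max(vals) - 1e-4 * abs(max(vals))

    def test_sign_convention_and_quotient_symmetry(self):
        rng = np.random.default_rng(1)
        trials = rng.standard_normal((4, 3, 100))
        w = trca_spatial_filter(trials)
        S, Q = _trca_matrices(trials)
        assert _rayleigh(w, S, Q) == pytest.approx(_rayleigh(-w, S, Q))
        assert w[np.argmax(np.abs(w))] > 0
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_duplicated_trials_closed_form(self):
        # identical trials: S = Nt(Nt-1) Cov, Q = Nt Cov, so the quotient is
        # (Nt - 1) for every direction in the covariance range
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 80))
        trials = np.stack([x] * 5)
        w = trca_spatial_filter(trials)
        S, Q = _trca_matrices(trials)
        assert _rayleigh(w, S, Q) == pytest.approx(4.0, abs=1e-8)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            trca_spatial_filter(np.zeros((1, 2, 10)))

    def test_gen_eig_matches_brute_force_on_random_spd_pairs(self):
        # property over random small SPD pencils (2-D: dense angular grid)
        rng = np.random.default_rng(3)
        for _ in range(20):
            A = rng.standard_normal((2, 2))
            B = rng.standard_normal((2, 2))
            S = A @ A.T
            Q = B @ B.T + 0.5 * np.eye(2)
            from ssvepkit.classical import _lead_gev
            w = _lead_gev(S, Q)[:, 0]
            thetas = np.linspace(0, np.pi, 100_001)
            best = max(_rayleigh(np.array([np.cos(t), np.sin(t)]), S, Q)
                       for t in thetas)
            assert _rayleigh(w, S, Q) >= best - 1e-4 * abs(best)


class TestETRCA:
    def test_filter_bank_layout(self, small_synth):
        epochs, _, _ = small_synth
        model = etrca_fit(epochs, n_bands=3)
        assert model.bank == ((8.0, 90.0), (16.0, 90.0), (24.0, 90.0))
        assert model.filters.shape == (3, epochs.n_channels, 12)
        np.testing.assert_allclose(
            model.bank_weights, np.arange(1, 4) ** -1.25 + 0.25)

    def test_fit_deterministic(self, small_synth):
        epochs, _, _ = small_synth
        m1 = etrca_fit(epochs, n_bands=2)
        m2 = etrca_fit(epochs, n_bands=2)
        np.testing.assert_array_equal(m1.filters, m2.filters)

    def test_template_fed_back_scores_its_own_class(self):
        cfg = default_12class_config(snr_db=np.inf, n_trials_per_class=3)
        epochs, _ = synth_dataset(cfg)
        model = etrca_fit(epochs, n_bands=2)
        for k in (0, 5, 11):
            template = epochs.class_trials(k).mean(axis=0)
            label, scores = etrca_predict(model, template, return_scores=True)
            assert label == k
            # per-band self-correlation is 1, so the combined score reaches
            # the sum of the bank weights
            assert scores[k] == pytest.approx(model.bank_weights.sum(), abs=1e-6)

    def test_label_permutation_equivariance(self, small_synth):
        epochs, _, _ = small_synth
        perm = np.random.default_rng(0).permutation(12)
        permuted = epochs.replace(labels=perm[epochs.labels])
        m = etrca_fit(epochs, n_bands=1)
        mp = etrca_fit(permuted, n_bands=1)
        x = epochs.data[7]
        assert perm[etrca_predict(m, x)] == etrca_predict(mp, x)

    def test_invalid_band_count(self, small_synth):
        epochs, _, _ = small_synth
        with pytest.raises(ValueError):
            etrca_fit(epochs, n_bands=12)  # 12*8 >= 90 Hz


class TestDelayEmbed:
    def test_zero_delay_identity(self):
        x = np.random.default_rng(0).standard_normal((3, 10))
        np.testing.assert_array_equal(tdca_delay_embed(x, 0), x)

    def test_row_count_for_published_setting(self):
        x = np.zeros((8, 125))
        assert tdca_delay_embed(x, 5).shape == (48, 125)

    def test_trailing_zero_padding_exact(self):
        x = np.arange(20.0).reshape(2, 10)
        out = tdca_delay_embed(x, 3)
        for d in range(4):
            block = out[2 * d: 2 * d + 2]
            if d:
                assert np.all(block[:, -d:] == 0.0)
            np.testing.assert_array_equal(block[:, : 10 - d], x[:, d:])

    def test_real_data_used_when_available(self):
        x = np.arange(24.0).reshape(2, 12)
        out = tdca_delay_embed(x, 2, n_samples=10)
        # delayed blocks read the trailing real samples instead of zeros
        np.testing.assert_array_equal(out[2:4], x[:, 1:11])

    def test_excessive_delay_rejected(self):
        with pytest.raises(ValueError):
            tdca_delay_embed(np.zeros((2, 5)), 5)


class TestReferenceProjection:
    def test_projector_idempotent_symmetric(self):
        P = tdca_reference_projection(10.0, 5, 125, 250.0)
        np.testing.assert_allclose(P @ P, P, atol=1e-8)
        np.testing.assert_allclose(P, P.T, atol=1e-8)

    def test_reference_fixed_by_its_projector(self):
        f, Nh, Ns, fs = 11.0, 4, 125, 250.0
        P = tdca_reference_projection(f, Nh, Ns, fs)
        t = np.arange(1, Ns + 1) / fs
        Y = np.vstack([fn(2 * np.pi * k * f * t)
                       for k in range(1, Nh + 1) for fn in (np.sin, np.cos)])
        np.testing.assert_allclose(Y @ P, Y, atol=1e-8)

    def test_rank_equals_twice_harmonics(self):
        P = tdca_reference_projection(9.25, 5, 250, 250.0)
        rank = np.sum(np.linalg.svd(P, compute_uv=False) > 1e-8)
        assert rank == 10

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError):
            tdca_reference_projection(30.0, 5, 100, 250.0)


class TestTDCA:
    def test_secondary_augmentation_width(self, small_synth):
        epochs, _, cfg = small_synth
        model = tdca_fit(epochs, cfg.stim_freqs, l=2, N_h=3)
        assert model.class_centers.shape[-1] == 2 * epochs.n_samples

    def test_duplicated_classes_have_equal_centers(self):
        # identical data under two labels -> zero between-class scatter
        rng = np.random.default_rng(0)
        block = rng.standard_normal((4, 2, 50))
        data = np.concatenate([block, block])
        e = EpochedEEG(data, np.repeat([0, 1], 4), 100.0, ("a", "b"))
        model = tdca_fit(e, (10.0, 10.0), l=1, N_h=2, K_dims=1)
        np.testing.assert_allclose(model.class_centers[0, 0],
                                   model.class_centers[0, 1], atol=1e-10)

    def test_fisher_direction_matches_brute_force(self):
        # 1-D discriminant on a 2-channel toy vs high-precision angular search
        rng = np.random.default_rng(1)
        n = 20
        c0 = np.stack([np.vstack([rng.standard_normal(30) + 2.0,
                                  rng.standard_normal(30)]) for _ in range(n)])
        c1 = np.stack([np.vstack([rng.standard_normal(30) - 2.0,
                                  rng.standard_normal(30)]) for _ in range(n)])
        e = EpochedEEG(np.concatenate([c0, c1]), np.repeat([0, 1], n),
                       64.0, ("a", "b"))
        model = tdca_fit(e, (8.0, 12.0), l=0, N_h=1, K_dims=1)
        w = model.W_lda[0][:, 0]
        # independent scatter assembly + scalar optimisation over direction,
        # on the same sub-band-filtered data the fit sees
        from ssvepkit import FilterSpec, bandpass
        from ssvepkit.classical import _secondary_augment
        ef = bandpass(e, FilterSpec(8.0, min(90.0, 0.99 * 64.0 / 2)))
        P = [tdca_reference_projection(f, 1, 30, 64.0) for f in (8.0, 12.0)]
        Xa = [np.stack([_secondary_augment(tdca_delay_embed(x, 0), P[k])
                        for x in ef.class_trials(k)]) for k in (0, 1)]
        cen = [a.mean(axis=0) for a in Xa]
        grand = 0.5 * (cen[0] + cen[1])
        Sb = sum((c - grand) @ (c - grand).T for c in cen)
        Sw = np.zeros((2, 2))
        for a, c in zip(Xa, cen):
            for trial in a:
                d = trial - c
                Sw += d @ d.T

        def neg_ratio(theta):
            v = np.array([np.cos(theta), np.sin(theta)])
            return -(v @ Sb @ v) / (v @ Sw @ v)

        res = [sopt.minimize_scalar(neg_ratio, bounds=(a, a + np.pi / 4),
                                    method="bounded", options={"xatol": 1e-12})
               for a in np.linspace(0, np.pi, 9, endpoint=False)]
        th = min(res, key=lambda r: r.fun).x
        v = np.array([np.cos(th), np.sin(th)])
        angle = np.arccos(min(abs(v @ w) / np.linalg.norm(w), 1.0))
        assert angle < 1e-4

    def test_center_fed_back_and_scale_invariance(self):
        cfg = default_12class_config(snr_db=np.inf, n_trials_per_class=3)
        epochs, _ = synth_dataset(cfg)
        model = tdca_fit(epochs, cfg.stim_freqs)
        x = epochs.class_trials(4)[0]
        assert tdca_predict(model, x) == 4
        s1 = tdca_scores(model, x)
        s2 = tdca_scores(model, 7.3 * x)
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestSNRMonotonicity:
    def test_accuracy_non_decreasing_in_snr(self):
        # tolerance: one resampled test trial per step
        accs = {"etrca": [], "tdca": []}
        n_test = 12
        for snr in (-10.0, 0.0, 10.0):
            cfg = default_12class_config(snr_db=snr, n_trials_per_class=5,
                                         mixing_seed=1, noise_seed=2)
            epochs, _ = synth_dataset(cfg)
            epochs = crop_window(epochs, 0.0, 0.5)
            test_idx = np.arange(4, 60, 5)   # last repetition of each class
            train_idx = np.setdiff1d(np.arange(60), test_idx)
            train = epochs.replace(data=epochs.data[train_idx],
                                   labels=epochs.labels[train_idx])
            em = etrca_fit(train, n_bands=1)
            tm = tdca_fit(train, cfg.stim_freqs, n_bands=1)
            accs["etrca"].append(np.mean(
                [etrca_predict(em, epochs.data[i]) == epochs.labels[i]
                 for i in test_idx]))
            accs["tdca"].append(np.mean(
                [tdca_predict(tm, epochs.data[i]) == epochs.labels[i]
                 for i in test_idx]))
        slack = 1.0 / n_test
        for vals in accs.values():
            assert vals[1] >= vals[0] - slack
            assert vals[2] >= vals[1] - slack


def test_filter_bank_weight_conventions():
    np.testing.assert_allclose(filter_bank_weights(3),
                               [1.25, 2 ** -1.25 + 0.25, 3 ** -1.25 + 0.25])
    np.testing.assert_allclose(filter_bank_weights(3, uniform=True), 1.0)
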