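import numpy as np
import pytest

from thetanet.connectivity import (
    MVARModel,
    UnstableModelError,
    band_average_dtf,
    companion_spectral_radius,
    dtf,
    dtf_analysis,
    fit_mvar,
    global_dtf,
    hub_flows,
    node_dtf,
    region_dtf,
    region_pair_matrix,
    transfer_matrix,
)
from thetanet.montage import RegionMap
from thetanet.simulate import simulate_mvar_eeg

FS = 256.0


def model_from(coeffs, fs=FS, labels=None):
    coeffs = np.asarray(coeffs, dtype=float)
    k = coeffs.shape[1]
    labels = labels or tuple(f"ch{i}" for i in range(k))
    return MVARModel(coeffs=coeffs, noise_cov=np.eye(k), fs=fs,
                     channel_labels=labels)


def unidirectional_2ch(b=0.5, a=0.6):
    """Channel 1 drives channel 2 with lag-1 coefficient b; no reverse."""
    return model_from([[[a, 0.0], [b, a]]])


class TestFitMvar:
    def test_white_noise_fit_is_null(self, rng):
        data = rng.normal(size=(1, 3, 50_000))
        m = fit_mvar(data, order=1, fs=FS, channel_labels=("a", "b", "c"))
        se = 1.0 / np.sqrt(50_000)
        assert np.abs(m.coeffs).max() < 3 * se * 3  # within +-3 SE of zero
        assert (np.abs(m.coeffs) < 0.05).mean() >= 0.99

    def test_recovers_known_order2_coefficients(self, rng):
        true = np.array(
            [[[0.5, 0.2], [0.0, 0.4]], [[-0.3, 0.0], [0.1, -0.2]]]
        )
        rec = simulate_mvar_eeg(true, 1.0, 50_000, FS, rng)
        m = fit_mvar(rec.data[None], order=2, fs=FS,
                     channel_labels=rec.channel_labels)
        assert np.abs(m.coeffs - true).max() < 0.05

    def test_auto_order_selects_generator_order(self, rng):
        true = np.zeros((3, 2, 2))
        true[0] = [[0.4, 0.2], [0.0, 0.3]]
        true[2] = [[-0.3, 0.0], [0.2, -0.35]]
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rec = simulate_mvar_eeg(true, 1.0, 20_000, FS, seed)
            m = fit_mvar(rec.data[None], order="auto", criterion="bic",
                         max_order=8, fs=FS, channel_labels=rec.channel_labels)
            hits += m.order == 3
        assert hits >= 0.8 * n_seeds

    def test_insufficient_data_rejected(self, rng):
        data = rng.normal(size=(1, 4, 30))
        with pytest.raises(ValueError):
            fit_mvar(data, order=10, fs=FS, channel_labels=tuple("abcd"))

    def test_regressors_never_span_epoch_boundaries(self, rng):
        # a fit on epochs must not see the artificial jump between them
        a = rng.normal(size=(40, 2, 200))
        stacked = a.reshape(1, 2, -1)
        m_epochs = fit_mvar(a, order=2, fs=FS, channel_labels=("x", "y"))
        m_concat = fit_mvar(stacked, order=2, fs=FS, channel_labels=("x", "y"))
        # both are valid on white noise, but they differ: boundaries excluded
        assert not np.allclose(m_epochs.coeffs, m_concat.coeffs)


class TestTransferMatrix:
    def test_zero_coefficients_give_identity(self):
        m = model_from(np.zeros((1, 3, 3)))
        h = transfer_matrix(m, np.array([1.0, 6.0, 20.0]))
        for hf in h:
            np.testing.assert_allclose(hf, np.eye(3), atol=1e-12)

    def test_diagonal_model_gives_diagonal_h(self):
        m = model_from([np.diag([0.5, -0.3])])
        h = transfer_matrix(m, np.array([6.0]))
        assert abs(h[0][0, 1]) == 0 and abs(h[0][1, 0]) == 0

    def test_matches_symbolic_2x2_inverse(self):
        a, b = 0.6, 0.5
        m = unidirectional_2ch(b=b, a=a)
        freqs = np.array([2.0, 6.0, 10.0])
        h = transfer_matrix(m, freqs)
        z = np.exp(-2j * np.pi * freqs / FS)
        # A(f) = [[1-a z, 0], [-b z, 1-a z]] -> closed-form inverse
        h11 = 1.0 / (1 - a * z)
        h21 = b * z / (1 - a * z) ** 2
        np.testing.assert_allclose(h[:, 0, 0], h11, atol=1e-10)
        np.testing.assert_allclose(h[:, 1, 0], h21, atol=1e-10)
        np.testing.assert_allclose(h[:, 0, 1], 0, atol=1e-14)

    def test_unstable_model_rejected(self):
        m = model_from([[[1.05]]])
        with pytest.raises(UnstableModelError):
            transfer_matrix(m, np.array([6.0]))


class TestDtf:
    freqs = np.arange(0.5, FS / 2, 0.5)

    def test_independent_channels_have_identity_dtf(self):
        m = model_from([np.diag([0.5, -0.2, 0.3])])
        g = dtf(m, self.freqs)
        np.testing.assert_allclose(g, np.broadcast_to(np.eye(3), g.shape),
                                   atol=1e-12)

    def test_unidirectional_coupling_is_one_way(self):
        g = dtf(unidirectional_2ch(), self.freqs)
        # sink 2 <- source 1 present; sink 1 <- source 2 absent (zero up to
        # the floating-point noise of the matrix inversion)
        assert g[:, 1, 0].max() > 0.1
        assert np.abs(g[:, 0, 1]).max() < 1e-20

    def test_rows_sum_to_one_everywhere(self, rng):
        rec = simulate_mvar_eeg(
            np.array([[[0.4, 0.1, 0.0], [0.2, 0.3, 0.1], [0.0, 0.1, 0.5]]]),
            1.0, 20_000, FS, rng,
        )
        m = fit_mvar(rec.data[None], order=1, fs=FS,
                     channel_labels=rec.channel_labels)
        g = dtf(m, self.freqs)
        assert np.abs(g.sum(axis=2) - 1).max() < 1e-10
        assert g.min() >= 0 and g.max() <= 1

    def test_matches_closed_form_for_2x2(self):
        a, b = 0.6, 0.5
        g = dtf(unidirectional_2ch(b=b, a=a), self.freqs)
        z = np.exp(-2j * np.pi * self.freqs / FS)
        h21 = np.abs(b * z / (1 - a * z) ** 2) ** 2
        h22 = np.abs(1 / (1 - a * z)) ** 2
        np.testing.assert_allclose(g[:, 1, 0], h21 / (h21 + h22), atol=1e-8)

    def test_amplitude_invariance(self):
        m = unidirectional_2ch()
        scaled = MVARModel(coeffs=m.coeffs, noise_cov=4.0 * np.eye(2),
                           fs=m.fs, channel_labels=m.channel_labels)
        np.testing.assert_allclose(
            dtf(m, self.freqs), dtf(scaled, self.freqs), atol=1e-14
        )

    def test_label_permutation_equivariance(self, rng):
        coeffs = np.array(
            [[[0.4, 0.1, 0.0], [0.2, 0.3, 0.1], [0.0, 0.1, 0.5]]]
        )
        m = model_from(coeffs, labels=("a", "b", "c"))
        perm = [2, 0, 1]
        m_p = model_from(coeffs[:, perm][:, :, perm],
                         labels=tuple("cab"))
        g = dtf(m, self.freqs)
        g_p = dtf(m_p, self.freqs)
        np.testing.assert_allclose(g[:, perm][:, :, perm], g_p, atol=1e-12)


class TestFittedVsTrueGamma:
    def test_oracle_equivalence_small_network(self, rng):
        """Fitted-model DTF matches generator-truth DTF on long data."""
        true = np.zeros((2, 3, 3))
        true[0] = [[0.5, 0.0, 0.0], [0.3, 0.4, 0.0], [0.0, 0.2, 0.45]]
        true[1] = np.diag([-0.2, -0.1, -0.15])
        rec = simulate_mvar_eeg(true, 1.0, 50_000, FS, rng)
        fitted = fit_mvar(rec.data[None], order=2, fs=FS,
                          channel_labels=rec.channel_labels)
        freqs = np.arange(0.5, FS / 2, 0.5)
        g_true = dtf(model_from(true), freqs)
        g_fit = dtf(fitted, freqs)
        assert np.abs(g_true - g_fit).max() < 0.02


def region_map_4x4():
    return RegionMap({"Fz": "F", "Cz": "C", "Oz": "O", "T7": "T"})


class TestAggregation:
    def test_global_dtf_identity_and_constant(self):
        assert global_dtf(np.eye(5)) == 0.0
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 0.9)
        assert global_dtf(m) == pytest.approx(0.3)

    def test_global_dtf_matches_bruteforce(self, rng):
        m = rng.uniform(size=(4, 4))
        acc = sum(
            m[i, j] for i in range(4) for j in range(4) if i != j
        )
        assert global_dtf(m) == pytest.approx(acc / (4 * 3))

    def test_node_dtf_two_channel_reduction(self):
        m = np.array([[0.9, 0.1], [0.4, 0.6]])
        assert node_dtf(m, 0) == pytest.approx((0.1 + 0.4) / 2)

    def test_node_dtf_matches_bruteforce(self, rng):
        m = rng.uniform(size=(5, 5))
        for i in range(5):
            expected = sum(
                m[j, i] + m[i, j] for j in range(5) if j != i
            ) / (2 * 4)
            assert node_dtf(m, i) == pytest.approx(expected)

    def test_node_dtf_constant_offdiagonal(self):
        m = np.full((6, 6), 0.2)
        for i in range(6):
            assert node_dtf(m, i) == pytest.approx(0.2)

    def test_node_dtf_unknown_label(self):
        with pytest.raises(KeyError):
            node_dtf(np.eye(3), "Pz", channel_labels=("Fz", "Cz", "Oz"))

    def test_region_dtf_matches_bruteforce(self, rng):
        labels = ("Fz", "FCz", "Cz", "Pz", "Oz", "T7")
        rm = RegionMap(
            {"Fz": "F", "FCz": "F", "Cz": "C", "Pz": "C", "Oz": "O", "T7": "T"}
        )
        m = rng.uniform(size=(6, 6))
        # F -> C: sinks {Cz,Pz} rows 2,3; sources {Fz,FCz} cols 0,1
        expected = m[np.ix_([2, 3], [0, 1])].mean()
        assert region_dtf(m, rm, "F", "C", labels) == pytest.approx(expected)
        # within-F excludes the diagonal
        expected_ff = (m[0, 1] + m[1, 0]) / 2
        assert region_dtf(m, rm, "F", "F", labels) == pytest.approx(expected_ff)

    def test_region_pair_matrix_uniform(self):
        labels = ("Fz", "Cz", "Oz", "T7")
        m = np.full((4, 4), 0.25)
        out = region_pair_matrix(m, region_map_4x4(), labels).to_numpy(float)
        off = out[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.25)
        # single-channel regions have no within-region DTF
        assert np.isnan(np.diag(out)).all()

    def test_hub_flows_symmetry_and_uniform(self, rng):
        labels = ("Fz", "Cz", "Oz", "T7")
        rm = region_map_4x4()
        sym = rng.uniform(size=(4, 4))
        sym = (sym + sym.T) / 2
        out, inn = hub_flows(sym, rm, "F", labels)
        assert out == pytest.approx(inn)
        uni = np.full((4, 4), 0.4)
        out, inn = hub_flows(uni, rm, "F", labels)
        assert out == pytest.approx(0.4) and inn == pytest.approx(0.4)

    def test_band_average_matches_bruteforce(self, rng):
        freqs = np.arange(0.5, 20.0, 0.5)
        g = rng.uniform(size=(len(freqs), 3, 3))
        out = band_average_dtf(g, freqs, (4.0, 8.0))
        mask = [i for i, f in enumerate(freqs) if 4.0 <= f < 8.0]
        np.testing.assert_allclose(out, g[mask].mean(axis=0))
        with pytest.raises(ValueError):
            band_average_dtf(g, freqs, (50.0, 60.0))


class TestNullCalibration:
    def test_independent_channels_have_low_offdiagonal_dtf(self):
        from thetanet.experiments import null_connectivity_dtf

        worst = null_connectivity_dtf(n_seeds=2, base_seed=3)
        assert worst < 0.05


class TestDtfAnalysis:
    def test_bundle_consistency(self, rng):
        from thetanet.montage import default_region_map
        from thetanet.simulate import SimulationConfig, build_cohort_generator

        cfg = SimulationConfig(n_per_group=1, n_channels=16, seed=5)
        gt = build_cohort_generator(cfg)
        m = model_from(gt.coupling["con01"]["task"], labels=cfg.channels)
        res = dtf_analysis(m, default_region_map())
        assert res.dtf_g == pytest.approx(global_dtf(res.band_gamma))
        assert np.abs(res.gamma.sum(axis=2) - 1).max() < 1e-10
        assert res.dtf_kl.shape == (4, 4)
        assert companion_spectral_radius(m.coeffs) < 1
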