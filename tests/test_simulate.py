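import dataclasses
import json

import numpy as np
import pytest

from thetanet.connectivity import companion_spectral_radius
from thetanet.io import load_recording, read_behavior, read_events
from thetanet.montage import default_region_map
from thetanet.simulate import (
    GROUP_LABELS,
    SimulationConfig,
    build_cohort_generator,
    generate_cohort,
    simulate_behavior,
    simulate_mvar_eeg,
    simulate_subject_recording,
    write_cohort,
)
from thetanet.spectral import stft_psd

FS = 256.0


class TestSimulateMvarEeg:
    def test_zero_coefficients_give_unit_white_noise(self):
        rec = simulate_mvar_eeg(np.zeros((1, 2, 2)), 1.0, 50_000, FS, seed=0)
        var = rec.data.var(axis=1)
        assert np.all(np.abs(var - 1.0) < 0.05)

    def test_ar1_lag_autocorrelation(self):
        coeffs = np.array([[[0.5, 0.0], [0.0, 0.5]]])
        rec = simulate_mvar_eeg(coeffs, 1.0, 50_000, FS, seed=1)
        for ch in rec.data:
            rho = np.corrcoef(ch[:-1], ch[1:])[0, 1]
            assert abs(rho - 0.5) < 0.02

    def test_same_seed_is_bit_identical(self):
        coeffs = np.array([[[0.5, 0.1], [0.0, 0.4]]])
        a = simulate_mvar_eeg(coeffs, 1.0, 1000, FS, seed=42)
        b = simulate_mvar_eeg(coeffs, 1.0, 1000, FS, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unstable_coefficients_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            simulate_mvar_eeg(np.array([[[1.01]]]), 1.0, 1000, FS, seed=0)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            simulate_mvar_eeg(np.array([[[np.nan]]]), 1.0, 1000, FS, seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            simulate_mvar_eeg(np.zeros((3, 2, 2)), 1.0, 25, FS, seed=0)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(impairment_factor=0.0),
            dict(impairment_factor=1.5),
            dict(acc_base=0.0),
            dict(rest_duration=-1.0),
            dict(n_trials=0),
            dict(pole_radius=1.0),
            dict(n_channels=7),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_montage_selection(self):
        assert len(SimulationConfig(n_channels=34).channels) == 34
        assert len(SimulationConfig(n_channels=16).channels) == 16
        custom = SimulationConfig(channels=("Fz", "Cz", "Oz", "T7", "Fp1"))
        assert custom.n_channels == 5


class TestCohortGenerator:
    def test_every_subject_grouped_and_stable(self, ground_truth):
        gt = ground_truth
        assert sorted(gt.subjects) == sorted(gt.group_labels)
        assert len(gt.subjects) == 3 * gt.config.n_per_group
        for s in gt.subjects:
            for tensor in gt.coupling[s].values():
                assert companion_spectral_radius(tensor) < 1
            assert gt.impaired_flags[s] == (gt.group_labels[s] == "TLE-WM")

    def test_hub_outflow_scales_with_impairment_exactly(self, ground_truth):
        gt = ground_truth
        cfg = gt.config
        hub = cfg.channels.index(cfg.hub_channel)
        for s in gt.subjects:
            delta = gt.coupling[s]["task"] - gt.coupling[s]["rest"]
            norm = np.linalg.norm(delta[0][:, hub])
            n_targets = np.count_nonzero(delta[0][:, hub])
            factor = cfg.impairment_factor if gt.impaired_flags[s] else 1.0
            expected = factor * gt.hub_gains[s] * np.sqrt(n_targets)
            assert norm == pytest.approx(expected)
            # hub terms go only to non-hub rows; nothing else changes
            assert delta[0][hub, hub] == 0.0
            mask = np.ones_like(delta, dtype=bool)
            mask[0, :, hub] = False
            assert np.all(delta[mask] == 0.0)

    def test_null_impairment_factor_gives_identical_construction(self):
        cfg = SimulationConfig(n_per_group=2, n_channels=16, impairment_factor=1.0, seed=3)
        gt = build_cohort_generator(cfg)
        hub = cfg.channels.index(cfg.hub_channel)
        norms = {
            g: [
                np.linalg.norm(
                    (gt.coupling[s]["task"] - gt.coupling[s]["rest"])[0][:, hub]
                )
                / gt.hub_gains[s]
                for s in gt.subjects
                if gt.group_labels[s] == g
            ]
            for g in GROUP_LABELS
        }
        # per-subject normalized outflow norms agree across all groups
        flat = np.concatenate(list(norms.values()))
        assert np.allclose(flat, flat[0])

    def test_impairment_monotonicity(self):
        norms = []
        for factor in (1.0, 0.7, 0.4):
            cfg = SimulationConfig(
                n_per_group=1, n_channels=16, impairment_factor=factor, seed=9
            )
            gt = build_cohort_generator(cfg)
            s = [x for x in gt.subjects if gt.impaired_flags[x]][0]
            delta = gt.coupling[s]["task"] - gt.coupling[s]["rest"]
            norms.append(np.linalg.norm(delta))
        assert norms[0] > norms[1] > norms[2]

    def test_spectral_placement_in_theta(self, ground_truth):
        rec, _ = simulate_subject_recording(ground_truth, "con01")
        psd = stft_psd(rec)
        peak = psd.freqs[np.argmax(psd.values.mean(axis=0))]
        assert 4.0 <= peak < 8.0

    def test_determinism_of_full_cohort(self, tiny_config):
        a = generate_cohort(tiny_config)
        b = generate_cohort(tiny_config)
        for s in a.ground_truth.subjects:
            np.testing.assert_array_equal(
                a.recordings[s].data, b.recordings[s].data
            )
            assert a.behavior[s].equals(b.behavior[s])


class TestBehavior:
    def test_sixty_trials_rt_only_for_correct(self, tiny_cohort):
        for s, table in tiny_cohort.behavior.items():
            assert len(table) == tiny_cohort.ground_truth.config.n_trials
            assert table.loc[~table["correct"], "rt_ms"].isna().all()
            assert table.loc[table["correct"], "rt_ms"].notna().all()

    def test_null_link_group_rt_equal_in_distribution(self):
        """With no latent link and no impairment shift, group mean RTs
        differ only by sampling noise: t-test p-values are uniform."""
        from scipy import stats as sps

        from thetanet.stats import summarize_behavior

        pvals = []
        for seed in range(100):
            cfg = SimulationConfig(
                n_per_group=8,
                n_channels=16,
                behavior_link=0.0,
                rt_impaired_shift_sd=0.0,
                acc_impaired_logit=0.0,
                latent_impaired_shift=0.0,
                seed=seed,
            )
            gt = build_cohort_generator(cfg)
            beh = simulate_behavior(gt)
            rts = {
                g: [
                    summarize_behavior(s, beh[s]).mean_rt_correct
                    for s in gt.subjects
                    if gt.group_labels[s] == g
                ]
                for g in ("Con", "TLE-WM")
            }
            pvals.append(sps.ttest_ind(rts["Con"], rts["TLE-WM"]).pvalue)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_impaired_group_shifted(self, tiny_cohort):
        gt = tiny_cohort.ground_truth
        from thetanet.stats import summarize_behavior

        rt = {
            g: np.mean(
                [
                    summarize_behavior(s, tiny_cohort.behavior[s]).mean_rt_correct
                    for s in gt.subjects
                    if gt.group_labels[s] == g
                ]
            )
            for g in ("Con", "TLE-WM")
        }
        assert rt["TLE-WM"] > rt["Con"] + 1.5 * gt.config.rt_sd_ms


class TestWriteCohort:
    def test_round_trip_and_manifest(self, tiny_cohort, tmp_path):
        out = tmp_path / "cohort"
        manifest_path = write_cohort(tiny_cohort, out)
        manifest = json.loads(manifest_path.read_text())
        cfg = tiny_cohort.ground_truth.config
        assert len(manifest["subjects"]) == 3 * cfg.n_per_group
        s = manifest["subjects"][0]
        rec = load_recording(out / s / "eeg.csv", fs=cfg.fs)
        np.testing.assert_array_equal(rec.data, tiny_cohort.recordings[s].data)
        ev = read_events(out / s / "events.tsv")
        assert len(ev) == cfg.n_trials
        beh = read_behavior(out / s / "behavior.tsv")
        assert len(beh) == cfg.n_trials

    def test_rewriting_same_config_is_byte_identical(self, tiny_config, tmp_path):
        a = write_cohort(generate_cohort(tiny_config), tmp_path / "a").parent
        b = write_cohort(generate_cohort(tiny_config), tmp_path / "b").parent
        subject = json.loads((a / "cohort_manifest.json").read_text())["subjects"][0]
        for rel in (
            "cohort_manifest.json",
            f"{subject}/eeg.csv",
            f"{subject}/events.tsv",
            f"{subject}/behavior.tsv",
        ):
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_refuses_nonempty_dir(self, tiny_cohort, tmp_path):
        out = tmp_path / "cohort"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_cohort(tiny_cohort, out)
        write_cohort(tiny_cohort, out, overwrite=True)

    def test_edf_round_trip_within_quantization(self, tiny_cohort, tmp_path):
        out = tmp_path / "edf_cohort"
        write_cohort(tiny_cohort, out, eeg_format="edf")
        gt = tiny_cohort.ground_truth
        s = gt.subjects[0]
        rec = load_recording(out / s / "eeg.edf")
        orig = tiny_cohort.recordings[s]
        n = orig.n_samples
        step = (orig.data.max(axis=1) - orig.data.min(axis=1)) / 65535
        err = np.abs(rec.data[:, :n] - orig.data).max(axis=1)
        assert np.all(err <= step + 1e-9)
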