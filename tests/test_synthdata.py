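"""Synthetic study generator: forward model, waveforms, noise, determinism."""

import numpy as np
import pytest
from scipy.signal import hilbert

import fusednet as fn
from fusednet.synthdata import noise_covariance_true


class TestHeadModel:
    def test_coincident_sensor_source_pairs_have_unit_gain(self):
        # 8 sensors and 8 sources share angular positions on concentric spheres
        head, lead = fn.make_head_model(8, 8)
        assert np.allclose(np.diag(lead.G), 1.0)

    def test_deterministic(self):
        _, a = fn.make_head_model(16, 64, seed=1)
        _, b = fn.make_head_model(16, 64, seed=1)
        assert np.array_equal(a.G, b.G)

    def test_full_row_rank(self, head64):
        _, lead = head64
        sv = np.linalg.svd(lead.G, compute_uv=False)
        assert (sv > 1e-10).sum() == 16

    def test_geometry_invariants(self, head64):
        head, lead = head64
        assert np.allclose(np.linalg.norm(head.sensor_positions, axis=1), 1.0)
        r = np.linalg.norm(head.source_positions, axis=1)
        assert np.all((r > 0) & (r < 1))
        assert np.isfinite(lead.G).all()
        assert np.all(np.abs(lead.G).sum(axis=0) > 0)

    @pytest.mark.parametrize("m,s", [(4, 64), (16, 8), (0, 10)])
    def test_rejects_bad_dimensions(self, m, s):
        with pytest.raises(ValueError):
            fn.make_head_model(m, s)


class TestSimulateSources:
    def test_no_active_dipoles_gives_zero_currents(self):
        truth = fn.GroundTruth(n_sources=32)
        t = np.arange(100) / 250
        assert np.all(fn.simulate_sources(truth, t, "any") == 0)

    def test_unit_envelope_peak(self, epoch_time_axis):
        t = epoch_time_axis
        lat = t[np.argmin(np.abs(t - 0.5))]  # latency on a sample
        phi = np.pi / 2 - 2 * np.pi * 10.0 * lat  # sin term = 1 at the latency
        truth = fn.GroundTruth(
            64, {3: fn.WaveformParams({"c": 1.0}, lat, 0.1, 10.0, phase=phi)}
        )
        J = fn.simulate_sources(truth, t, "c", background_frac=0.0)
        assert J[3, np.argmin(np.abs(t - lat))] == pytest.approx(1.0)

    def test_constant_phase_lag_pair(self, epoch_time_axis):
        t = epoch_time_axis
        amp = {"c": 1.0}
        truth = fn.GroundTruth(
            64,
            {
                3: fn.WaveformParams(amp, 0.65, 0.45, 10.0),
                9: fn.WaveformParams(amp, 0.65, 0.45, 10.0),
            },
            phase_lags={(3, 9): np.pi / 2},
        )
        J = fn.simulate_sources(truth, t, "c", background_frac=0.0)
        d = np.angle(hilbert(J[3])) - np.angle(hilbert(J[9]))
        d = (d + np.pi) % (2 * np.pi) - np.pi
        support = np.abs(t - 0.65) < 0.45
        assert np.abs(d[support] - np.pi / 2).max() < 0.01

    def test_unknown_condition_rejected(self):
        truth = fn.GroundTruth(8, {0: fn.WaveformParams({"c": 1.0}, 0.5, 0.1, 10.0)})
        with pytest.raises(KeyError):
            fn.simulate_sources(truth, np.arange(50) / 250, "nope")


class TestProjectToSensors:
    def test_infinite_snr_is_noise_free(self, head64, rng):
        _, lead = head64
        J = rng.standard_normal((64, 50))
        Y = fn.project_to_sensors(lead.G, J, snr=np.inf)[:, :, 0]
        assert np.array_equal(Y, lead.G @ J)

    def test_zero_sources_give_zero_mean_noise(self, head64):
        _, lead = head64
        Y = fn.project_to_sensors(lead.G, np.zeros((64, 40)), snr=3, seed=0,
                                  n_trials=1000)
        n = Y.size
        sem = Y.std() / np.sqrt(n)
        assert abs(Y.mean()) < 3 * sem

    def test_seed_reproducibility(self, head64, rng):
        _, lead = head64
        J = rng.standard_normal((64, 30))
        a = fn.project_to_sensors(lead.G, J, snr=2, seed=5, n_trials=3)
        b = fn.project_to_sensors(lead.G, J, snr=2, seed=5, n_trials=3)
        assert np.array_equal(a, b)

    def test_dimension_mismatch_rejected(self, head64, rng):
        _, lead = head64
        with pytest.raises(ValueError):
            fn.project_to_sensors(lead.G, rng.standard_normal((63, 10)), snr=1)

    @pytest.mark.parametrize("snr", [1.0, 3.0, 5.0])
    def test_realized_snr_within_5_percent(self, head64, snr):
        _, lead = head64
        truth = fn.GroundTruth(
            64, {5: fn.WaveformParams({"c": 1.0}, 1.0, 0.3, 10.0)}
        )
        t = np.arange(500) / 250  # d >= 400 samples
        J = fn.simulate_sources(truth, t, "c", rng=1)
        signal = lead.G @ J
        Y = fn.project_to_sensors(lead.G, J, snr=snr, seed=2)[:, :, 0]
        eps = Y - signal
        realized = (signal**2).mean() / (eps**2).mean()
        assert realized == pytest.approx(snr**2, rel=0.05)


class TestSimulateBold:
    def test_noiseless_active_voxel_is_scaled_regressor(self):
        hrf = fn.canonical_hrf(0.1)
        from fusednet.fmriprior import convolve_feature_train

        onsets = [10.0, 30.0]
        bold = fn.simulate_bold([1.0, 2.0], onsets, hrf, [0], 3, 50, 2.0,
                                noise_sd=0.0, seed=0, beta=2.0)
        expected = 2.0 * convolve_feature_train([1.0, 2.0], onsets, hrf, 2.0, 50)
        assert np.allclose(bold[0], expected)
        assert np.all(bold[1:] == 0)

    def test_zero_features_make_active_indistinguishable(self):
        from scipy import stats

        hrf = fn.canonical_hrf(0.1)
        onsets = 10.0 + 4.0 * np.arange(40)
        bold = fn.simulate_bold(np.zeros(40), onsets, hrf, [0, 1], 100, 200, 2.0,
                                noise_sd=1.0, seed=3)
        t, _ = stats.ttest_ind(bold[:2].ravel(), bold[2:].ravel())
        assert abs(t) < 4

    def test_single_impulse_reproduces_hrf_shape(self):
        hrf = fn.canonical_hrf(0.5)
        tr = 2.0
        bold = fn.simulate_bold([1.0], [0.0], hrf, [0], 1, 20, tr,
                                noise_sd=0.0, seed=0, beta=1.0)
        expected = hrf.samples[:: int(tr / hrf.dt)][:20]
        assert np.allclose(bold[0][: expected.size], expected)

    def test_onset_beyond_scan_rejected(self):
        hrf = fn.canonical_hrf(0.1)
        with pytest.raises(ValueError):
            fn.simulate_bold([1.0], [100.0], hrf, [0], 2, 10, 2.0, 0.1)


class TestGenerateStudy:
    def test_epoch_sample_count(self, tiny_study):
        # round(1.7 s * 250 Hz) + 1 inclusive endpoints
        assert tiny_study.time_axis.size == 426
        for cond, arr in tiny_study.subjects[0].eeg.items():
            assert arr.shape[1] == 426

    def test_bit_identical_for_same_seed(self):
        cfg = fn.StudyConfig(n_subjects=2, n_trials=2, n_sources=100,
                             n_voxels=120, n_volumes=100)
        a = fn.generate_study(cfg, seed=7)
        b = fn.generate_study(cfg, seed=7)
        for ra, rb in zip(a.subjects, b.subjects):
            for c in ra.eeg:
                assert np.array_equal(ra.eeg[c], rb.eeg[c])
            assert np.array_equal(ra.bold, rb.bold)
        assert np.array_equal(a.voxel_positions, b.voxel_positions)

    def test_subject_count_and_seed_stability(self):
        cfg2 = fn.StudyConfig(n_subjects=2, n_trials=2, n_sources=100,
                              n_voxels=120, n_volumes=100)
        cfg3 = fn.StudyConfig(n_subjects=3, n_trials=2, n_sources=100,
                              n_voxels=120, n_volumes=100)
        a = fn.generate_study(cfg2, seed=4)
        b = fn.generate_study(cfg3, seed=4)
        assert len(a.subjects) == 2 and len(b.subjects) == 3
        # adding a subject must not reshuffle earlier subjects
        for c in a.subjects[0].eeg:
            assert np.array_equal(a.subjects[0].eeg[c], b.subjects[0].eeg[c])

    def test_fifteen_subject_default_design(self):
        cfg = fn.StudyConfig(n_trials=1, n_sources=100, n_voxels=120,
                             n_volumes=100)
        study = fn.generate_study(cfg, seed=1)
        assert len(study.subjects) == 15
        assert set(study.subjects[0].eeg) == {
            "neutral-watch", "negative-watch", "negative-reappraisal"
        }

    def test_save_load_roundtrip(self, tiny_study, tmp_path):
        fn.save_study(tiny_study, tmp_path / "study")
        back = fn.load_study(tmp_path / "study")
        assert back.seed == tiny_study.seed
        assert np.array_equal(back.lead_field.G, tiny_study.lead_field.G)
        rec0, back0 = tiny_study.subjects[0], back.subjects[0]
        for c in rec0.eeg:
            assert np.array_equal(rec0.eeg[c], back0.eeg[c])
        assert back.truth.waveform_params.keys() == tiny_study.truth.waveform_params.keys()


def test_true_noise_covariance_has_common_mode(head64):
    C = noise_covariance_true(16)
    assert np.allclose(C, C.T)
    off = C[0, 1]
    assert off > 0  # non-diagonal by construction
    assert np.all(np.linalg.eigvalsh(C) > 0)
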