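"""Preprocessing chain: each step against its analytic or planted oracle."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import signal

from nirswalk.preprocessing import (
    OpticalDensitySeries,
    PreprocessConfig,
    bandpass,
    detect_motion_artifacts,
    extract_walk_block,
    intensity_to_od,
    mbll,
    pca_remove_systemic,
    preprocess,
    spline_correct,
    HbSeries,
)
from nirswalk.synthetic import (
    NoiseSpec,
    PD_SPEC,
    RawRecording,
    generate_subject_fc_target,
    simulate_recording,
)

FS = 11.0


def _od(data, fs=FS):
    return OpticalDensitySeries(data=data, fs=fs)


class TestIntensityToOD:
    def test_constant_intensity_gives_zero(self, montage, timeline):
        n = timeline.n_samples(FS)
        rec = RawRecording("s", "PD", 0, timeline, montage,
                           np.full((2, 30, n), 0.7))
        od = intensity_to_od(rec)
        assert np.max(np.abs(od.data)) == 0.0

    def test_log10_identity(self, montage, timeline):
        n = timeline.n_samples(FS)
        intensity = np.ones((2, 30, n))
        # one sample at I_ref/10 (I_ref ~ 1 for large n) -> OD ~ 1
        intensity[0, 0, 100] = 0.1
        rec = RawRecording("s", "PD", 0, timeline, montage, intensity)
        od = intensity_to_od(rec)
        assert od.data[0, 0, 100] == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_intensity_names_location(self, montage, timeline):
        n = timeline.n_samples(FS)
        intensity = np.ones((2, 30, n))
        rec = RawRecording("s", "PD", 0, timeline, montage, intensity)
        rec.intensity[1, 4, 17] = -1.0  # bypass constructor check
        with pytest.raises(ValueError, match="channel 5, sample 17"):
            intensity_to_od(rec)


class TestArtifactDetection:
    def test_smooth_sinusoid_unflagged(self):
        t = np.arange(0, 75, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)[None, None, :].repeat(2, 0)
        mask = detect_motion_artifacts(_od(x), PreprocessConfig())
        assert not mask.any()

    def test_large_spike_flagged_with_padding(self):
        rng = np.random.default_rng(0)
        n = 825
        x = 0.01 * rng.standard_normal((2, 1, n))
        mad = np.median(np.abs(x - np.median(x)))
        x[:, 0, 400:406] += 20 * mad
        cfg = PreprocessConfig()
        mask = detect_motion_artifacts(_od(x), cfg)
        pad = int(cfg.spline_pad_s * FS)
        assert mask[0, 400:406].all()
        assert mask[0, 400 - pad] and mask[0, 405 + pad]

    def test_sensitivity_on_simulated_artifacts(self, montage, timeline):
        """At default settings, >= 90% of injected artifact samples are
        flagged across 20 seeded recordings."""
        cfg = PreprocessConfig()
        noise = NoiseSpec(artifact_rate_per_min=4.0)
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            target = generate_subject_fc_target(PD_SPEC, rng)
            rec = simulate_recording(target, timeline, montage, noise, rng)
            truth = rec.ground_truth["artifact_samples"]
            if not truth:
                continue
            mask = detect_motion_artifacts(intensity_to_od(rec), cfg)
            for ch, samples in truth.items():
                hits += int(mask[ch, samples].sum())
                total += len(samples)
        assert total > 0
        assert hits / total >= 0.90


class TestSplineCorrection:
    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 3, 200))
        od = _od(x)
        out = spline_correct(od, np.zeros((3, 200), dtype=bool))
        np.testing.assert_array_equal(out.data, x)

    def test_step_artifact_edges_continuous(self):
        t = np.arange(0, 75, 1 / FS)
        n = t.size
        x = 0.02 * np.sin(2 * np.pi * 0.05 * t)
        x_step = x.copy()
        x_step[420:] += 1.0                       # +1 OD step
        mask = np.zeros((1, n), dtype=bool)
        mask[0, 410:440] = True
        data = x_step[None, None, :].repeat(2, 0)
        out = spline_correct(_od(data), mask).data[0, 0]
        assert abs(out[410] - out[409]) < 0.05
        assert abs(out[440] - out[439]) < 0.05

    def test_rmse_improves_on_spiked_recordings(self, montage, timeline):
        """Correction moves the OD series closer to the artifact-free truth
        on every one of 20 seeds."""
        cfg = PreprocessConfig()
        quiet = NoiseSpec(cardiac_amp_um=0, respiratory_amp_um=0,
                          mayer_amp_um=0, measurement_noise_sd=0,
                          artifact_rate_per_min=0)
        noisy = replace(quiet, artifact_rate_per_min=4.0)
        improved = 0
        tried = 0
        for seed in range(20):
            rng_a = np.random.default_rng(500 + seed)
            target = generate_subject_fc_target(PD_SPEC, rng_a)
            clean = simulate_recording(target, timeline, montage, quiet,
                                       np.random.default_rng(900 + seed))
            arted = simulate_recording(target, timeline, montage, noisy,
                                       np.random.default_rng(900 + seed))
            if not arted.ground_truth["artifact_samples"]:
                continue
            tried += 1

            def centered(x):
                return x - x.mean(axis=-1, keepdims=True)

            od_clean = centered(intensity_to_od(clean).data)
            od_art = intensity_to_od(arted)
            mask = detect_motion_artifacts(od_art, cfg)
            od_fix = centered(spline_correct(od_art, mask).data)
            rmse_before = np.sqrt(np.mean((centered(od_art.data) - od_clean) ** 2))
            rmse_after = np.sqrt(np.mean((od_fix - od_clean) ** 2))
            improved += rmse_after < rmse_before
        assert tried >= 15
        assert improved >= tried - 1

    def test_fully_flagged_recording_detrended(self):
        x = np.linspace(0, 1, 200)[None, None, :].repeat(2, 0)
        mask = np.ones((1, 200), dtype=bool)
        out = spline_correct(_od(x), mask).data
        assert np.max(np.abs(out)) < 1e-8  # cubic detrend removes the ramp


class TestBandpass:
    def test_constant_removed(self):
        x = np.full(2000, 3.7)
        assert np.max(np.abs(bandpass(x, FS))) < 1e-6 * 3.7

    def test_cardiac_probe_attenuated_40db(self):
        t = np.arange(0, 600, 1 / FS)
        x = np.sin(2 * np.pi * 1.1 * t)
        out = bandpass(x, FS)
        atten_db = -20 * np.log10(out[1000:-1000].std() / x.std())
        assert atten_db >= 40

    def test_passband_within_1db(self):
        t = np.arange(0, 600, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(x, FS)
        gain = out[1000:-1000].std() / x[1000:-1000].std()
        assert 0.89 <= gain <= 1.0

    def test_zero_phase(self):
        rng = np.random.default_rng(4)
        sos = signal.butter(4, [0.03, 0.15], btype="band", fs=FS, output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(4000))
        y = bandpass(x, FS)
        lags = signal.correlation_lags(len(x), len(y))
        xc = signal.correlate(x - x.mean(), y - y.mean())
        assert lags[np.argmax(xc)] == 0

    def test_short_series_rejected_with_hint(self):
        with pytest.raises(ValueError, match="need >"):
            bandpass(np.ones(10), FS)


class TestMBLL:
    def test_zero_od_gives_zero_concentration(self, montage):
        od = _od(np.zeros((2, 30, 100)))
        hb = mbll(od, montage)
        assert np.max(np.abs(hb.hbo)) == 0 and np.max(np.abs(hb.hbr)) == 0

    def test_identity_extinction_decouples(self, montage):
        """With identity extinction and d*DPF = 1 the system decouples:
        HbO equals OD at the first wavelength (in mM -> x1000 uM)."""
        cfg = PreprocessConfig(extinction=np.eye(2), dpf=(1.0, 1.0))
        sep_cm = montage.channels[0].separation_mm / 10.0
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2, 30, 50))
        hb = mbll(_od(data), montage, cfg)
        np.testing.assert_allclose(hb.hbo, data[0] / sep_cm * 1000, rtol=1e-12)

    def test_singular_extinction_rejected_at_config_time(self):
        with pytest.raises(ValueError, match="ill-conditioned"):
            PreprocessConfig(extinction=np.array([[1.0, 1.0], [1.0, 1.0000001]]))

    @pytest.mark.parametrize("scale", [0.8, 1.2])
    def test_fc_insensitive_to_dpf_scale(self, clean_recording, scale):
        """Pearson connectivity is scale invariant: rescaling the pathlength
        (DPF +-20% at both wavelengths) rescales concentrations uniformly
        and leaves the walking-block correlation matrix unchanged."""
        od = intensity_to_od(clean_recording)
        base = PreprocessConfig()
        pert = PreprocessConfig(dpf=(base.dpf[0] * scale, base.dpf[1] * scale))

        def block_corr(cfg):
            hb = mbll(od, clean_recording.montage, cfg)
            blk = extract_walk_block(hb, clean_recording.timeline, cfg=cfg)
            return np.corrcoef(blk.hbo)

        assert np.max(np.abs(block_corr(base) - block_corr(pert))) < 1e-12


class TestPCARemoval:
    def test_k0_returns_centered_input(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((5, 300)) + 3.0
        hb = HbSeries(hbo=x, hbr=-x / 3, fs=FS)
        out = pca_remove_systemic(hb, PreprocessConfig(n_pca_components_removed=0))
        np.testing.assert_allclose(out.hbo, x - x.mean(1, keepdims=True))

    def test_rank1_dominated_data_cleaned(self):
        rng = np.random.default_rng(7)
        common = rng.standard_normal(800)
        x = np.tile(common, (6, 1)) + 0.01 * rng.standard_normal((6, 800))
        hb = HbSeries(hbo=x, hbr=-x / 3, fs=FS)
        out = pca_remove_systemic(hb, PreprocessConfig(n_pca_components_removed=1))
        assert out.hbo.var(axis=1).max() < 0.01 * x.var(axis=1).min()

    def test_global_sinusoid_projected_out(self):
        rng = np.random.default_rng(8)
        t = np.arange(800) / FS
        s = np.sin(2 * np.pi * 0.1 * t)
        x = 0.3 * rng.standard_normal((8, 800)) + 5.0 * s
        hb = HbSeries(hbo=x, hbr=-x / 3, fs=FS)
        out = pca_remove_systemic(hb, PreprocessConfig(n_pca_components_removed=1))
        for ch in out.hbo:
            assert abs(np.corrcoef(ch, s)[0, 1]) < 0.05

    def test_k_too_large_rejected(self):
        hb = HbSeries(hbo=np.ones((3, 50)), hbr=np.ones((3, 50)), fs=FS)
        with pytest.raises(ValueError, match="cannot remove"):
            pca_remove_systemic(hb, PreprocessConfig(n_pca_components_removed=3))


class TestWalkBlock:
    def test_constant_signal_gives_zero_block(self, timeline):
        hb = HbSeries(hbo=np.full((4, 825), 2.5), hbr=np.zeros((4, 825)), fs=FS)
        blk = extract_walk_block(hb, timeline)
        assert np.max(np.abs(blk.hbo)) == 0

    def test_step_at_walk_onset_gives_unit_block(self, timeline):
        x = np.zeros((2, 825))
        x[:, 330:] = 1.0       # walk starts at floor(30*11) = 330
        hb = HbSeries(hbo=x, hbr=np.zeros_like(x), fs=FS)
        blk = extract_walk_block(hb, timeline)
        np.testing.assert_allclose(blk.hbo, 1.0)

    def test_block_length_385(self, timeline):
        hb = HbSeries(hbo=np.zeros((2, 825)), hbr=np.zeros((2, 825)), fs=FS)
        assert extract_walk_block(hb, timeline).hbo.shape[1] == 385

    def test_short_recording_rejected(self, timeline):
        hb = HbSeries(hbo=np.zeros((2, 400)), hbr=np.zeros((2, 400)), fs=FS)
        with pytest.raises(ValueError, match="does not cover"):
            extract_walk_block(hb, timeline)


class TestFullChain:
    def test_composition_matches_hand_chain(self, clean_recording):
        cfg = PreprocessConfig()
        auto = preprocess(clean_recording, cfg)
        od = intensity_to_od(clean_recording)
        mask = detect_motion_artifacts(od, cfg)
        od = spline_correct(od, mask)
        from nirswalk.preprocessing import bandpass_od
        od = bandpass_od(od, cfg)
        hb = mbll(od, clean_recording.montage, cfg)
        hb = pca_remove_systemic(hb, cfg)
        manual = extract_walk_block(hb, clean_recording.timeline, cfg=cfg)
        np.testing.assert_array_equal(auto.hbo, manual.hbo)

    def test_deterministic(self, default_recording):
        a = preprocess(default_recording)
        b = preprocess(default_recording)
        np.testing.assert_array_equal(a.hbo, b.hbo)

    def test_provenance_records_printed_order(self, default_recording):
        blk = preprocess(default_recording)
        steps = " > ".join(blk.provenance)
        order = ["intensity_to_od", "spline_correct", "bandpass", "mbll",
                 "pca_remove", "extract_walk_block"]
        positions = [steps.index(s) for s in order]
        assert positions == sorted(positions)

    def test_linearity_without_artifact_detection(self, clean_recording):
        """Bandpass, Beer-Lambert and PCA-free extraction are linear:
        scaling the concentration signal scales the output."""
        cfg = PreprocessConfig(correct_artifacts=False,
                               n_pca_components_removed=0)
        base = preprocess(clean_recording, cfg)
        # doubling optical density doubles the recovered concentrations
        doubled = RawRecording(
            "s", "PD", 0, clean_recording.timeline, clean_recording.montage,
            10.0 ** (2 * np.log10(clean_recording.intensity)),
        )
        out2 = preprocess(doubled, cfg)
        np.testing.assert_allclose(out2.hbo, 2 * base.hbo, atol=1e-9)
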