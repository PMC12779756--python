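"""Generator tests: stimulus waveform, phase-locked spiking, LFP structure,
artifact injection, and whole-session assembly."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import i0, i1

from sacskit.core import StimProtocol
from sacskit.spikemetrics import PhaseSet, plv, sqrt_abs_ppc
from sacskit.synthgen import (
    SynthConfig,
    gen_lfp,
    gen_session,
    gen_spiketrain,
    gen_stim_waveform,
    inject_artifact,
)


class TestStimWaveform:
    def test_whole_cycles_between_onset_and_offset(self):
        p = StimProtocol(40.0, 100.0, onset=60.0, offset=120.0, sampling_rate=1200.0)
        assert p.n_cycles() == 2400
        wav = gen_stim_waveform(p, 180.0)
        # zero crossings with positive slope inside the window count the cycles
        on = wav[int(60 * 1200) : int(120 * 1200)]
        crossings = np.sum((on[:-1] < 0) & (on[1:] >= 0))
        assert abs(crossings - 2400) <= 1

    def test_zero_outside_window_and_zero_scale(self):
        p = StimProtocol(10.0, 50.0, onset=1.0, offset=2.0, sampling_rate=1000.0)
        wav = gen_stim_waveform(p, 3.0)
        assert np.all(wav[:1000] == 0) and np.all(wav[2000:] == 0)
        assert not np.all(wav[1000:2000] == 0)
        assert np.all(gen_stim_waveform(p, 3.0, scale=0.0) == 0)

    def test_value_at_onset_is_sin_of_onset_phase(self):
        p = StimProtocol(10.0, 50.0, 1.0, 2.0, 1000.0, phase_at_onset=0.7)
        wav = gen_stim_waveform(p, 3.0, scale=2.0)
        assert wav[1000] == pytest.approx(2.0 * np.sin(0.7), abs=1e-12)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            StimProtocol(100.0, 50.0, 0.0, 1.0, sampling_rate=300.0)

    def test_duration_must_cover_offset(self):
        p = StimProtocol(10.0, 50.0, 1.0, 2.0, 1000.0)
        with pytest.raises(ValueError):
            gen_stim_waveform(p, 1.5)


class TestSpikeTrain:
    def test_kappa_zero_is_homogeneous_at_nominal_rate(self):
        p = StimProtocol(40.0, 100.0, 0.0, 200.0, 1200.0)
        tr = gen_spiketrain(5.0, 200.0, 0.0, 0.0, p, seed=1)
        rate = tr.n_spikes / 200.0
        assert rate == pytest.approx(5.0, abs=3 * np.sqrt(5.0 / 200.0))

    def test_large_kappa_concentrates_phases(self):
        p = StimProtocol(40.0, 100.0, 0.0, 60.0, 1200.0)
        tr = gen_spiketrain(10.0, 60.0, 50.0, np.pi, p, seed=2)
        phases = p.phase(tr.times)
        # circular distance to the preferred phase stays within a narrow band
        d = np.angle(np.exp(1j * (phases - np.pi)))
        assert np.quantile(np.abs(d), 0.95) < 0.5

    def test_kappa2_plv_matches_bessel_ratio(self):
        # mean resultant length of von Mises: I1(κ)/I0(κ), cross-checked by
        # numerical integration of the density
        kappa = 2.0
        target = i1(kappa) / i0(kappa)
        num, _ = quad(
            lambda x: np.cos(x) * np.exp(kappa * np.cos(x)) / (2 * np.pi * i0(kappa)),
            -np.pi,
            np.pi,
        )
        assert num == pytest.approx(target, abs=1e-10)
        p = StimProtocol(40.0, 100.0, 0.0, 300.0, 1200.0)
        tr = gen_spiketrain(20.0, 300.0, kappa, np.pi, p, seed=3)
        assert plv(PhaseSet(p.phase(tr.times))) == pytest.approx(target, abs=0.02)

    def test_rate_conservation_under_modulation(self):
        # normalized von Mises modulation leaves the time-averaged rate at r0
        p = StimProtocol(40.0, 100.0, 0.0, 300.0, 1200.0)
        tr = gen_spiketrain(8.0, 300.0, 3.0, 1.0, p, seed=4)
        rate = tr.n_spikes / 300.0
        assert rate == pytest.approx(8.0, abs=3 * np.sqrt(8.0 / 300.0))

    def test_zero_rate_gives_empty_train(self):
        tr = gen_spiketrain(0.0, 60.0, 0.0, 0.0, None, seed=0)
        assert tr.n_spikes == 0

    def test_sqrt_abs_ppc_monotone_in_kappa(self):
        p = StimProtocol(40.0, 100.0, 0.0, 120.0, 1200.0)
        vals = []
        for kappa in (0.5, 1.0, 2.0, 4.0):
            est = []
            for s in range(5):
                tr = gen_spiketrain(15.0, 120.0, kappa, 1.0, p, seed=100 + s)
                est.append(sqrt_abs_ppc(PhaseSet(p.phase(tr.times))))
            vals.append(np.mean(est))
        assert np.all(np.diff(vals) > 0)


class TestLfp:
    def test_background_spectral_slope_near_minus_two(self):
        from scipy.signal import welch

        # isolate the 1/f² background component (the sensor-noise floor is a
        # separate additive term with its own flat spectrum)
        cfg = SynthConfig(n_channels=1, grid_shape=(1, 1), duration=120.0,
                          sensor_noise_std=0.0)
        rec = gen_lfp(cfg, 120.0, seed=5)
        f, psd = welch(rec.samples[0], fs=rec.rate, nperseg=8192)
        sel = (f > 1.0) & (f < 30.0)
        slope = np.polyfit(np.log10(f[sel]), np.log10(psd[sel]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.2)

    def test_full_depth_modulation_spans_dynamic_range(self):
        from sacskit.pac_mi import extract_phase_amp

        cfg = SynthConfig(
            n_channels=1, grid_shape=(1, 1), duration=30.0,
            pac_spec=(6.0, 60.0, 1.0), background_std=0.0, sensor_noise_std=0.0,
            lf_osc_amplitude=5.0,
        )
        rec = gen_lfp(cfg, 30.0, seed=6)
        s = extract_phase_amp(rec.samples[0], rec.rate, 6.0, 2.0, 60.0, 5.0)
        bins = (s.phase / (2 * np.pi / 18)).astype(int).clip(0, 17)
        prof = np.array([s.amplitude[bins == b].mean() for b in range(18)])
        assert prof.min() < 0.25 * prof.max()

    def test_duration_must_be_positive(self):
        cfg = SynthConfig(n_channels=1, grid_shape=(1, 1))
        with pytest.raises(ValueError):
            gen_lfp(cfg, 0.0, seed=0)


class TestArtifact:
    def test_zero_gradient_identical_on_all_channels(self):
        p = StimProtocol(40.0, 100.0, 1.0, 3.0, 1200.0)
        cfg = SynthConfig(duration=4.0, background_std=0.0, sensor_noise_std=0.0)
        rec = gen_lfp(cfg, 4.0, seed=0)
        rec.samples[:] = 0.0
        out = inject_artifact(rec, p, (0.0, 0.0), base_amplitude=100.0)
        assert np.allclose(out.samples, out.samples[0])
        # amplitude via RMS is exact despite the discrete sampling grid
        on = out.samples[0, int(1.0 * 1200) : int(3.0 * 1200)]
        assert np.sqrt(2) * on.std() == pytest.approx(100.0, rel=1e-2)

    def test_missing_geometry_rejected(self):
        from sacskit.core import Recording

        rec = Recording(samples=np.zeros((2, 1200)), rate=1200.0, geometry=None)
        p = StimProtocol(40.0, 100.0, 0.0, 1.0, 1200.0)
        with pytest.raises(ValueError):
            inject_artifact(rec, p, (1.0, 0.0))


class TestSession:
    def test_determinism_identical_seed_identical_session(self):
        p = StimProtocol(40.0, 100.0, 5.0, 10.0, 1200.0)
        cfg = SynthConfig(duration=15.0, frac_entrained=0.3, rng_seed=9,
                          n_neurons_per_channel=2)
        s1 = gen_session(cfg, [p], seed=9)
        s2 = gen_session(cfg, [p], seed=9)
        assert np.array_equal(s1.lfp.samples, s2.lfp.samples)
        assert all(
            np.array_equal(a.times, b.times)
            for a, b in zip(s1.spiketrains, s2.spiketrains)
        )
        assert s1.ground_truth.equals(s2.ground_truth)

    def test_overlapping_protocols_rejected(self):
        p1 = StimProtocol(40.0, 100.0, 0.0, 10.0, 1200.0)
        p2 = StimProtocol(10.0, 100.0, 5.0, 15.0, 1200.0)
        cfg = SynthConfig(duration=20.0)
        with pytest.raises(ValueError):
            gen_session(cfg, [p1, p2], seed=0)

    def test_paradigm_segment_lengths(self):
        from sacskit.cli import paradigm_structure

        dur, seg, protos = paradigm_structure("oneminute")
        assert seg == {"pre": (0.0, 60.0), "stim": (60.0, 120.0), "post": (120.0, 180.0)}
        assert protos[0].onset == 60.0 and protos[0].offset == 120.0

        dur, seg, protos = paradigm_structure("twentyminute")
        assert seg["pre"] == (0.0, 1200.0)
        assert seg["stim"] == (1200.0, 2400.0)
        assert seg["post"][1] - seg["post"][0] >= 600.0

        dur, seg, protos = paradigm_structure("sham")
        assert protos == []

    def test_ground_truth_records_rate_change_and_kappa(self):
        p = StimProtocol(40.0, 100.0, 5.0, 10.0, 1200.0)
        cfg = SynthConfig(
            duration=15.0, frac_entrained=0.5, frac_suppressed=0.25,
            n_neurons_per_channel=2, rng_seed=3,
        )
        s = gen_session(cfg, [p], seed=3)
        gt = s.ground_truth
        assert set(gt.columns) >= {
            "neuron_id", "channel_id", "class", "baseline_rate_hz",
            "true_delta_fr_hz", "kappa", "preferred_phase_rad",
        }
        assert (gt.loc[gt["class"] == "entrained", "kappa"] == cfg.kappa).all()
        assert (gt.loc[gt["class"] == "suppressed", "true_delta_fr_hz"] < 0).all()
        assert s.channel_truth["artifact_gx_mv_per_mm"].nunique() == 1
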