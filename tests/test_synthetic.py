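import numpy as np
import pandas as pd
import pytest

import tectovis.synthetic as syn
from tectovis import photometry as photo


class TestRunningTrace:
    def test_zero_sd_constant(self):
        tr = syn.generate_running_trace(10.0, mean_speed=7.0, sd=0.0, seed=1)
        assert (tr["speed"] == 7.0).all()

    def test_determinism(self):
        a = syn.generate_running_trace(20.0, seed=42)
        b = syn.generate_running_trace(20.0, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_trace(self):
        a = syn.generate_running_trace(20.0, seed=1)
        b = syn.generate_running_trace(20.0, seed=2)
        assert not np.array_equal(a["speed"], b["speed"])

    def test_nonnegative(self):
        tr = syn.generate_running_trace(60.0, mean_speed=2.0, sd=5.0, seed=0)
        assert (tr["speed"] >= 0).all()

    def test_mean_within_3se(self):
        # Monte-Carlo over 20 seeds: OU sample mean close to the target.
        # effective sample count ~ duration / (2 tau) per trace
        means = [syn.generate_running_trace(600.0, 10.0, 3.0, tau=2.0,
                                            seed=s)["speed"].mean()
                 for s in range(20)]
        n_eff = 20 * 600.0 / (2 * 2.0)
        se = 3.0 / np.sqrt(n_eff)
        assert abs(np.mean(means) - 10.0) < 3 * se

    def test_bad_params(self):
        with pytest.raises(syn.ParameterError):
            syn.generate_running_trace(-1.0)
        with pytest.raises(syn.ParameterError):
            syn.generate_running_trace(10.0, tau=0.0)


class TestCoupledReplayTrials:
    def test_constant_running_closed_form(self):
        # 10 cm/s at gain 2 -> 20 deg/s -> 40 deg in 2 s
        run = syn.generate_running_trace(100.0, 10.0, sd=0.0, dt=0.05, seed=0)
        table, traces, exhausted = syn.generate_coupled_replay_trials(
            run, n_pairs=3, gain=2.0, seed=0)
        assert not exhausted
        coupled = table[table.condition == "coupled"]
        for _, tr in coupled.iterrows():
            assert tr.offset_s - tr.onset_s == pytest.approx(2.0, abs=0.05)
            assert (traces[tr.trial_id]["dot_speed"] == 20.0).all()

    def test_replay_equality_exact(self):
        run = syn.generate_running_trace(400.0, seed=3)
        table, traces, _ = syn.generate_coupled_replay_trials(run, 5, seed=3)
        for _, u in table[table.condition == "uncoupled"].iterrows():
            np.testing.assert_array_equal(
                traces[u.trial_id]["dot_speed"].to_numpy(),
                traces[u.link_id]["dot_speed"].to_numpy())

    def test_travel_reaches_40deg(self):
        run = syn.generate_running_trace(400.0, seed=4)
        table, traces, _ = syn.generate_coupled_replay_trials(run, 5, seed=4)
        for _, c in table[table.condition == "coupled"].iterrows():
            tr = traces[c.trial_id]
            dt = tr["time_s"].iloc[1] - tr["time_s"].iloc[0]
            travel = tr["dot_speed"].sum() * dt
            assert travel >= 40.0
            # one sample less would not reach 40 deg
            assert travel - tr["dot_speed"].iloc[-1] * dt < 40.0

    def test_exhaustion_warns_and_truncates(self):
        run = syn.generate_running_trace(30.0, seed=0)
        with pytest.warns(UserWarning, match="exhausted"):
            table, _, exhausted = syn.generate_coupled_replay_trials(
                run, n_pairs=50, seed=0)
        assert exhausted
        assert (table.condition == "coupled").sum() < 50

    def test_intertrial_gap(self):
        run = syn.generate_running_trace(200.0, seed=1)
        table, _, _ = syn.generate_coupled_replay_trials(run, 3, iti_s=4.0,
                                                         seed=1)
        t = table.sort_values("onset_s")
        gaps = t.onset_s.to_numpy()[1:] - t.offset_s.to_numpy()[:-1]
        assert (gaps >= 4.0 - 0.06).all()


class TestWidefieldSession:
    def test_full_silencing_zeroes_evoked(self, small_config):
        cfg = small_config
        cfg.g = {name: 1.0 for name in cfg.g}
        trials = syn.make_trials(2, condition="ttx")
        ses = syn.generate_widefield_session(cfg, trials, silencing="ttx")
        for name, r in ses["truth"]["evoked_timeseries"].items():
            np.testing.assert_array_equal(r, 0.0)

    def test_noiseless_peak_equals_amplitude(self, small_config):
        trials = syn.make_trials(1)
        ses = syn.generate_widefield_session(small_config, trials)
        masks = small_config.masks()
        for name, mask in masks.items():
            area_trace = ses["signal"].data[:, mask].mean(axis=1)
            f0 = small_config.f0
            peak_dff = (area_trace.max() - f0) / f0
            assert peak_dff == pytest.approx(
                small_config.area_amplitude(name), rel=1e-9)

    def test_hemodynamic_only_channels_match(self):
        cfg = syn.GroundTruthConfig(shape=(32, 32), sigma_noise=0.0,
                                    h_amp=0.02, amplitude=1e-12, seed=0)
        trials = syn.make_trials(2)
        ses = syn.generate_widefield_session(cfg, trials, isosbestic=True)
        sig = ses["signal"].data.mean(axis=(1, 2))
        iso = ses["isosbestic"].data.mean(axis=(1, 2))
        assert np.corrcoef(sig, iso)[0, 1] > 0.999

    def test_isosbestic_never_contains_evoked(self):
        # without an artifact the isosbestic channel is exactly flat even
        # while large responses are evoked in the signal channel
        cfg = syn.GroundTruthConfig(shape=(32, 32), sigma_noise=0.0,
                                    h_amp=0.0, seed=0)
        trials = syn.make_trials(5)
        ses = syn.generate_widefield_session(cfg, trials, isosbestic=True)
        iso = ses["isosbestic"].data[:, cfg.masks()["V1"]].mean(axis=1)
        assert np.ptp(iso) == 0.0
        assert ses["truth"]["evoked_timeseries"]["V1"].max() > 0

    def test_isosbestic_artifact_is_pure_artifact(self):
        # with an artifact present the isosbestic trace is an exact affine
        # function of the artifact: regressing it out leaves nothing that
        # could correlate with the evoked regressor
        cfg = syn.GroundTruthConfig(shape=(32, 32), sigma_noise=0.0,
                                    h_amp=0.02, seed=0)
        trials = syn.make_trials(5)
        ses = syn.generate_widefield_session(cfg, trials, isosbestic=True)
        iso = ses["isosbestic"].data[:, cfg.masks()["V1"]].mean(axis=1)
        h = ses["truth"]["hemodynamic"]
        a, b = np.polyfit(h, iso, 1)
        resid = iso - (a * h + b)
        evoked = ses["truth"]["evoked_timeseries"]["V1"]
        assert np.abs(resid).max() < 1e-9
        assert abs(np.dot(resid - resid.mean(), evoked - evoked.mean())) \
            < 1e-6

    def test_determinism(self):
        cfg = syn.GroundTruthConfig(shape=(32, 32), seed=7)
        trials = syn.make_trials(2)
        a = syn.generate_widefield_session(cfg, trials)
        b = syn.generate_widefield_session(cfg, trials)
        np.testing.assert_array_equal(a["signal"].data, b["signal"].data)

    def test_overlapping_masks_rejected(self):
        areas = (syn.AreaSpec("A", (0.5, 0.5), (0.3, 0.3)),
                 syn.AreaSpec("B", (0.5, 0.5), (0.3, 0.3)))
        cfg = syn.GroundTruthConfig(areas=areas, g={"A": 0, "B": 0},
                                    shape=(32, 32))
        with pytest.raises(syn.ConfigError, match="overlap"):
            syn.generate_widefield_session(cfg, syn.make_trials(1))

    def test_invalid_g_rejected(self):
        with pytest.raises(syn.ParameterError):
            syn.GroundTruthConfig(g={"V1": 1.5})


class TestSpikeSession:
    @staticmethod
    def _trials(n, cond, t0=0.0):
        t = syn.make_trials(n, stim_type="grating", condition=cond,
                            stim_s=0.9)
        return t.assign(trial_id=t.trial_id + int(t0),
                        onset_s=t.onset_s + t0, offset_s=t.offset_s + t0)

    def test_null_unit_flat_psth(self):
        from tectovis import ephys as ep
        units = [syn.UnitTruth(10.0, 10.0, 0.0)]
        trials = self._trials(80, "control")
        ses = syn.generate_spike_session(units, trials, seed=0)
        p = ep.build_psth(ses["units"][0]["spike_times"], trials,
                          pre_s=0.5, post_s=1.0, bin_s=0.05)
        # all bins within sampling error of 10 Hz
        se = np.sqrt(10.0 / (80 * 0.05))
        assert np.all(np.abs(p.rate - 10.0) < 4 * se)

    def test_full_reduction_matches_baseline(self):
        units = [syn.UnitTruth(5.0, 30.0, 1.0)]
        trials = pd.concat([self._trials(100, "control"),
                            self._trials(100, "opto", 400.0)],
                           ignore_index=True)
        ses = syn.generate_spike_session(units, trials, silencing="opto",
                                         seed=1)
        from tectovis import ephys as ep
        st = ses["units"][0]["spike_times"]
        opto = trials[trials.condition == "opto"]
        rate = ep.trial_counts(st, opto).mean() / 0.9
        assert rate == pytest.approx(5.0, abs=3 * np.sqrt(5.0 / (100 * 0.9)))

    def test_poisson_count(self):
        units = [syn.UnitTruth(5.0, 5.0, 0.0)]
        trials = self._trials(1, "control")
        trials.loc[0, ["onset_s", "offset_s"]] = [1.0, 99.0]
        counts = []
        for s in range(10):
            ses = syn.generate_spike_session(units, trials, seed=s)
            counts.append(ses["units"][0]["spike_times"].size)
        # ~500 spikes per 100 s session
        assert abs(np.mean(counts) - 500) < 3 * np.sqrt(500 / 10)

    def test_negative_rate_rejected(self):
        with pytest.raises(syn.ParameterError):
            syn.UnitTruth(-1.0, 5.0, 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(syn.ParameterError):
            syn.generate_spike_session([syn.UnitTruth(5, 10, 0)],
                                       self._trials(1, "control"), fs=1000.0)

    def test_waveform_classes_differ(self):
        rs = syn.make_waveform("RS")
        fs_wf = syn.make_waveform("FS")
        def t2p(wf):
            tr = np.argmin(wf)
            return np.argmax(wf[tr:])
        assert t2p(rs) > 2 * t2p(fs_wf)


class TestAnatomySections:
    PARAMS = {"POR": {"gfp": (1.0, 0.3, 0.08)}}

    def test_zero_amplitude_flat_corrected(self):
        from tectovis import anatomy as anat
        gen = syn.generate_anatomy_sections(
            {"X": {"gfp": (0.0, 0.3, 0.1)}}, n_sections=1, noise_sd=0.0)
        sec = gen["sections"]["X"][0]
        raw = anat.depth_density_profile(sec["images"]["gfp"], sec["bbox"])
        base = anat.background_profile(sec["images"]["gfp"],
                                       sec["background_points"], raw.size)
        corrected = anat.subtract_autofluorescence(raw, base)
        assert np.max(np.abs(corrected)) < 1e-9

    def test_band_recovered_at_depth(self):
        from tectovis import anatomy as anat
        gen = syn.generate_anatomy_sections(self.PARAMS, n_sections=1,
                                            noise_sd=0.0)
        sec = gen["sections"]["POR"][0]
        img = sec["images"]["gfp"]
        raw = anat.depth_density_profile(img, sec["bbox"])
        base = anat.background_profile(img, sec["background_points"], raw.size)
        profile = anat.subtract_autofluorescence(raw, base)
        depth = np.argmax(profile) / (profile.size - 1)
        assert depth == pytest.approx(0.3, abs=1.0 / profile.size)

    def test_determinism(self):
        a = syn.generate_anatomy_sections(self.PARAMS, n_sections=3,
                                          noise_sd=0.1, seed=5)
        b = syn.generate_anatomy_sections(self.PARAMS, n_sections=3,
                                          noise_sd=0.1, seed=5)
        np.testing.assert_array_equal(a["sections"]["POR"][2]["images"]["gfp"],
                                      b["sections"]["POR"][2]["images"]["gfp"])

    def test_bad_depth_rejected(self):
        with pytest.raises(syn.ParameterError):
            syn.generate_anatomy_sections({"X": {"gfp": (1.0, 1.3, 0.1)}})


class TestPhotometrySession:
    @staticmethod
    def _trials(labels):
        t = syn.make_trials(len(labels), stim_type="dot",
                            condition="coupled", stim_s=2.0)
        cond = ["coupled" if lab == "" else "uncoupled" for lab in labels]
        return t.assign(vmd_label=labels, condition=cond)

    def test_null_effect_matches_distribution(self):
        trials = self._trials([""] * 5 + ["positive"] * 5)
        ses, truth = syn.generate_photometry_session(
            0.5, s_pos=0.0, s_neg=0.0, trials=trials, sigma_noise=0.0, seed=0)
        amps = truth["amplitudes"]
        assert len(set(amps.values())) == 1

    def test_s_pos_closed_form(self):
        trials = self._trials(["", "positive"])
        ses, truth = syn.generate_photometry_session(
            0.5, s_pos=0.5, s_neg=0.0, trials=trials, sigma_noise=0.0, seed=0)
        assert truth["amplitudes"][1] == pytest.approx(0.75)
        assert truth["amplitudes"][1] / truth["amplitudes"][0] == \
            pytest.approx(1.5)

    def test_artifact_only_correction_shrinks_variance(self):
        trials = self._trials([""] * 5)
        ses, _ = syn.generate_photometry_session(
            0.0, 0.0, 0.0, trials=trials, sigma_noise=0.0, h_amp=0.05, seed=0)
        dff, corrected = photo.isosbestic_correct(ses)
        assert corrected
        raw = (ses.signal - ses.signal.mean()) / ses.signal.mean()
        assert dff.var() < 0.1 * raw.var()
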