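import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tectovis.synthetic as syn
from tectovis import ephys as ep


class TestDetectSpikes:
    FS = 25_000.0

    def test_flat_trace_no_spikes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ep.detect_spikes(np.zeros(int(2 * self.FS)), self.FS)
        assert out.size == 0

    def test_insertion_recovery(self):
        rng = np.random.default_rng(0)
        true = np.sort(rng.uniform(0.1, 9.9, 50))
        while np.any(np.diff(true) < 0.002):
            true = np.sort(rng.uniform(0.1, 9.9, 50))
        wf = syn.make_waveform("RS", self.FS)
        trace = syn.synthesize_trace(true, wf, 10.0, self.FS, noise_sd=1.0,
                                     spike_amp=8.0, noise_smooth_samples=12.0,
                                     seed=0)
        det = ep.detect_spikes(trace, self.FS)
        matched = sum(np.min(np.abs(det - t)) < 0.001 for t in true)
        false_pos = sum(np.min(np.abs(true - d)) > 0.001 for d in det)
        assert matched == 50
        assert false_pos <= 2

    def test_refractory_merge(self):
        # two crossings 0.5 ms apart collapse into one event
        trace = np.random.default_rng(1).normal(0, 1, int(2 * self.FS))
        i = int(self.FS)
        trace[i] = -20.0
        trace[i + int(0.0005 * self.FS)] = -18.0
        det = ep.detect_spikes(trace, self.FS)
        near = det[np.abs(det - 1.0) < 0.002]
        assert near.size == 1

    def test_separated_events_kept(self):
        trace = np.random.default_rng(1).normal(0, 1, int(2 * self.FS))
        i = int(self.FS)
        trace[i] = -20.0
        trace[i + int(0.003 * self.FS)] = -18.0
        det = ep.detect_spikes(trace, self.FS)
        near = det[np.abs(det - 1.0) < 0.005]
        assert near.size == 2

    def test_short_trace_error(self):
        with pytest.raises(ep.EphysError):
            ep.detect_spikes(np.zeros(100), self.FS)


class TestClassifyUnits:
    FS = 25_000.0

    def _waveforms(self, n_each=10, rs_t2p=0.9, fs_t2p=0.25):
        wfs = [syn.make_waveform("RS", self.FS, trough_to_peak_ms=rs_t2p,
                                 rng=np.random.default_rng(i))
               for i in range(n_each)]
        wfs += [syn.make_waveform("FS", self.FS, trough_to_peak_ms=fs_t2p,
                                  rng=np.random.default_rng(100 + i))
                for i in range(n_each)]
        return np.array(wfs)

    def test_bimodal_perfect_split(self):
        labels = ep.classify_units(self._waveforms(), self.FS, seed=0)
        assert labels[:10] == ["RS"] * 10
        assert labels[10:] == ["FS"] * 10

    def test_deterministic(self):
        wfs = self._waveforms()
        a = ep.classify_units(wfs, self.FS, seed=3)
        b = ep.classify_units(wfs, self.FS, seed=3)
        assert a == b

    def test_single_unit_error(self):
        with pytest.raises(ep.EphysError):
            ep.classify_units(self._waveforms()[:1], self.FS)

    def test_identical_waveforms_degenerate(self):
        wf = syn.make_waveform("RS", self.FS)
        with pytest.raises(ep.EphysError, match="degenerate"):
            ep.classify_units(np.tile(wf, (5, 1)), self.FS)

    def test_features_separate_classes(self):
        feats = ep.waveform_features(self._waveforms(), self.FS)
        assert feats[:10, 0].min() > feats[10:, 0].max()


class TestUnitResponsive:
    def test_09s_class_2sd(self):
        base = np.array([3.0, 5.0, 4.0, 4.0])  # mean 4, sd ~0.8
        assert ep.unit_responsive(np.full(4, 6.5), base, 0.9) is True

    def test_k_switch_between_classes(self):
        # borderline unit: fails the 2-SD rule but passes the 1-SD rule
        base = np.array([3.0, 5.0, 3.0, 5.0])  # mean 4, sd 1.155
        evoked = np.full(4, 5.5)
        assert ep.unit_responsive(evoked, base, 0.9) is False
        assert ep.unit_responsive(evoked, base, 1.5) is True

    def test_zero_sd_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            assert ep.unit_responsive(np.ones(3), np.full(3, 4.0), 0.9) is None

    def test_unknown_duration(self):
        with pytest.raises(ep.EphysError):
            ep.unit_responsive(np.ones(3), np.arange(3.0), 1.2)


class TestBestDirection:
    def test_tie_lowest_index(self):
        assert ep.best_direction(np.array([2.0, 5.0, 3.0, 5.0])) == 1

    def test_single_direction(self):
        assert ep.best_direction(np.array([4.0])) == 0

    def test_tuned_unit_recovered(self):
        rates = np.array([4.0, 6.0, 12.0, 6.0])
        assert ep.best_direction(rates, baseline_rate=4.0) == 2


class TestZScore:
    def test_hand_arithmetic(self):
        base = np.array([2.0, 6.0, 2.0, 6.0])  # mean 4, sd (n-1) = 2.309
        base = np.array([4.0 - 2.0, 4.0 + 2.0, 4.0 - 2.0, 4.0 + 2.0])
        sd = base.std(ddof=1)
        z = ep.zscore_fr(np.full(4, 4.0 + 2 * sd), base)
        assert z == pytest.approx(2.0)

    def test_null_zero(self):
        base = np.array([3.0, 5.0, 4.0])
        assert ep.zscore_fr(np.full(3, 4.0), base) == pytest.approx(0.0)

    def test_zero_sd_error(self):
        with pytest.raises(ep.EphysError):
            ep.zscore_fr(np.ones(3), np.full(3, 2.0))

    def test_null_monte_carlo(self):
        # Poisson baseline and evoked at the same rate: E[Z] ~ 0
        rng = np.random.default_rng(0)
        zs = []
        for _ in range(200):
            base = rng.poisson(5.0, 30) / 1.0
            ev = rng.poisson(5.0, 30) / 1.0
            if base.std(ddof=1) == 0:
                continue
            zs.append(ep.zscore_fr(ev, base))
        se = np.std(zs, ddof=1) / np.sqrt(len(zs))
        assert abs(np.mean(zs)) < 3 * se + 0.05


class TestPSTH:
    def _trials(self, n=20):
        return syn.make_trials(n, stim_type="grating", condition="control",
                               stim_s=1.0)

    def test_normalization_against_control_max(self):
        trials = self._trials(4)
        # control: one 10 Hz bin; opto measured against it
        st_ctrl = np.concatenate(
            [tr.onset_s + np.full(2, 0.01) + np.arange(2) * 0.001
             for _, tr in trials.iterrows()])
        p_ctrl = ep.build_psth(st_ctrl, trials, pre_s=0.0, post_s=1.0,
                               bin_s=0.05)
        assert p_ctrl.normalized.max() == pytest.approx(1.0)
        opto_trials = trials.assign(condition="opto")
        st_opto = np.array([tr.onset_s + 0.01
                            for _, tr in opto_trials.iterrows()])
        p_opto = ep.build_psth(st_opto, opto_trials, pre_s=0.0, post_s=1.0,
                               bin_s=0.05, condition="opto",
                               norm_value=p_ctrl.norm_value)
        # 2 spikes/bin control vs 1 spike/bin opto -> 0.5; scale to example
        assert p_opto.normalized.max() == pytest.approx(0.5)

    def test_spike_count_conservation_exact(self, rng):
        trials = self._trials(15)
        st = np.sort(rng.uniform(0, trials.offset_s.max() + 1.0, 3000))
        p = ep.build_psth(st, trials, pre_s=0.5, post_s=1.5, bin_s=0.05)
        total = sum(int(((st >= tr.onset_s - 0.5) &
                         (st < tr.onset_s + 1.5)).sum())
                    for _, tr in trials.iterrows())
        assert (p.rate * 0.05 * p.n_trials).sum() == pytest.approx(
            total, abs=1e-9)

    def test_homogeneous_rate_flat(self):
        trials = self._trials(100)
        rng = np.random.default_rng(2)
        dur = trials.offset_s.max() + 1.0
        st = np.sort(rng.uniform(0, dur, int(20 * dur)))  # ~20 Hz
        p = ep.build_psth(st, trials, pre_s=0.5, post_s=1.0, bin_s=0.05)
        se = np.sqrt(20.0 / (100 * 0.05))
        assert np.all(np.abs(p.rate - 20.0) < 4 * se)

    def test_misaligned_bin_error(self):
        with pytest.raises(ep.EphysError, match="tile"):
            ep.build_psth(np.array([1.0]), self._trials(2), pre_s=0.5,
                          post_s=1.5, bin_s=0.3)

    def test_zero_control_max_warns(self):
        trials = self._trials(2)
        with pytest.warns(UserWarning, match="dropped"):
            p = ep.build_psth(np.array([]), trials, pre_s=0.0, post_s=1.0,
                              bin_s=0.05)
        assert (p.normalized == 0).all()


class TestPercentReduction:
    @pytest.mark.parametrize("ctrl,laser,expected", [
        (10.0, 2.0, 80.0), (10.0, 0.0, 100.0), (10.0, 12.0, -20.0)])
    def test_hand_arithmetic(self, ctrl, laser, expected):
        assert ep.percent_reduction(ctrl, laser) == pytest.approx(expected)

    def test_zero_control_excluded(self):
        with pytest.raises(ep.EphysError, match="excluded"):
            ep.percent_reduction(0.0, 2.0)

    def test_generator_recovery(self):
        # truth reduction 0.8 recovered within 5 points at 50 trials
        hits = 0
        for seed in range(10):
            units = [syn.UnitTruth(4.0, 24.0, 0.8)]
            tt = pd.concat([
                syn.make_trials(50, "grating", "control", stim_s=0.9),
                syn.make_trials(50, "grating", "opto", stim_s=0.9).assign(
                    trial_id=lambda d: d.trial_id + 100,
                    onset_s=lambda d: d.onset_s + 200,
                    offset_s=lambda d: d.offset_s + 200),
            ]).reset_index(drop=True)
            ses = syn.generate_spike_session(units, tt, silencing="opto",
                                             seed=seed)
            st = ses["units"][0]["spike_times"]
            est = {}
            for cond in ("control", "opto"):
                sel = tt[tt.condition == cond]
                ev = ep.trial_counts(st, sel).mean() / 0.9
                bl = ep.trial_counts(st, sel, window=(-0.7, 0.0)).mean() / 0.7
                est[cond] = ev - bl
            red = ep.percent_reduction(est["control"], est["opto"])
            hits += abs(red - 80.0) <= 5.0
        assert hits >= 9


def wilcoxon_exact_enumeration(a, b):
    """Two-sided signed-rank p-value by enumerating all sign patterns."""
    d = np.asarray(a, float) - np.asarray(b, float)
    ranks = stats.rankdata(np.abs(d))
    W = ranks[d > 0].sum()
    ws = np.array([(ranks * np.array(signs)).sum()
                   for signs in itertools.product([0, 1], repeat=d.size)])
    p_le = (ws <= W).mean()
    p_ge = (ws >= W).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestPopulationReduction:
    def test_wilcoxon_matches_enumeration(self, rng):
        for n in (5, 8, 10):
            for _ in range(3):
                ctrl = rng.normal(10, 2, n)
                laser = ctrl - rng.normal(1, 2, n)
                d = ctrl - laser
                if np.any(d == 0) or np.unique(np.abs(d)).size < n:
                    continue
                out = ep.population_reduction(ctrl, laser)
                assert out["p_value"] == pytest.approx(
                    wilcoxon_exact_enumeration(ctrl, laser))

    def test_zero_control_units_dropped(self):
        out = ep.population_reduction(np.array([10.0, 0.0]),
                                      np.array([2.0, 1.0]))
        assert out["n_units"] == 1
        assert out["mean_reduction_pct"] == pytest.approx(80.0)

    def test_identical_conditions_p_one(self):
        v = np.array([3.0, 4.0, 5.0])
        assert ep.population_reduction(v, v.copy())["p_value"] == 1.0
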