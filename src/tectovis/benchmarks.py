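"""End-to-end recovery benchmarks on ground-truth synthetic data.

Each function simulates data with the :mod:`tectovis.synthetic` generators,
runs the corresponding analysis stages, and returns recovery metrics.
These back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import anatomy as anat
from . import ephys as ep
from . import photometry as photo
from . import response as rq
from . import synthetic as syn
from . import vmd as vm
from . import widefield as wf

#: truth SC-dependence used for the recovery benchmark (distinct values
#: for the graded areas, zero elsewhere)
BENCH_G = {"POR": 0.85, "LI": 0.7, "P": 0.55, "LM": 0.35, "V1": 0.0,
           "AL": 0.0, "RL": 0.0, "AM": 0.0, "PM": 0.0}
GRADED_AREAS = ("POR", "LI", "P", "LM", "V1")


def sc_dependence_recovery(seed: int, n_trials: int = 60,
                           shape: tuple[int, int] = (64, 64)) -> dict:
    """Estimate per-area silencing reductions from a simulated session pair.

    Control and TTX moving-dot sessions are generated at default noise,
    ΔF/F is computed per trial, the top 50% of pixels are selected from the
    condition-averaged mean image, and reductions come from
    :func:`tectovis.response.percent_change_intra`.
    """
    cfg_c = syn.GroundTruthConfig(shape=shape, g=dict(BENCH_G), seed=seed)
    cfg_t = syn.GroundTruthConfig(shape=shape, g=dict(BENCH_G),
                                  seed=seed + 10_000)
    trials_c = syn.make_trials(n_trials, stim_type="dot", condition="control")
    trials_t = syn.make_trials(n_trials, stim_type="dot", condition="ttx")
    ses_c = syn.generate_widefield_session(cfg_c, trials_c)
    ses_t = syn.generate_widefield_session(cfg_t, trials_t, silencing="ttx")
    dff_c = wf.compute_dff(ses_c["signal"], trials_c)
    dff_t = wf.compute_dff(ses_t["signal"], trials_t)
    masks = cfg_c.masks()
    mean_c = np.mean([dff_c.clips[i][dff_c.response_window(i)].mean(axis=0)
                      for i in range(n_trials)], axis=0)
    mean_t = np.mean([dff_t.clips[i][dff_t.response_window(i)].mean(axis=0)
                      for i in range(n_trials)], axis=0)
    estimates = {}
    for area, mask in masks.items():
        pix = rq.select_top_pixels([mean_c, mean_t], mask, fraction=0.5)
        ctrl = rq.trial_response(dff_c, pix).mean()
        treat = rq.trial_response(dff_t, pix).mean()
        estimates[area] = rq.percent_change_intra(float(ctrl),
                                                  float(treat))[1]
    errors = {a: estimates[a] - 100.0 * BENCH_G[a] for a in estimates}
    est = [estimates[a] for a in GRADED_AREAS]
    truth = [BENCH_G[a] for a in GRADED_AREAS]
    rho = stats.spearmanr(est, truth).statistic
    rank_exact = np.array_equal(np.argsort(est), np.argsort(truth))
    return {"estimates": estimates, "errors": errors,
            "max_abs_error": max(abs(e) for e in errors.values()),
            "spearman": float(rho), "rank_order_exact": bool(rank_exact)}


VMD_AREAS = {"POR": {"amplitude": 1.0, "s_pos": 0.5, "s_neg": 0.0},
             "LI": {"amplitude": 0.8, "s_pos": 0.5, "s_neg": 0.0},
             "V1": {"amplitude": 1.2, "s_pos": 0.0, "s_neg": 0.0}}


def vmd_comparison(seed: int, areas: dict | None = None,
                   n_mice: int = 4, n_pairs: int = 30) -> dict:
    """Coupled-vs-uncoupled comparison per area on a simulated cohort.

    Runs the analysis end-to-end: divergence from the stimulus/running
    traces, the 25% classification rule, V1-coupled normalization, and the
    per-mouse paired comparison with BH correction across timepoints.
    """
    if areas is None:
        areas = VMD_AREAS
    cohort = syn.simulate_vmd_cohort(n_mice=n_mice, n_pairs=n_pairs,
                                     areas=areas, seed=seed)
    out = {}
    for name in areas:
        per_mouse = []
        for m in cohort:
            trials = m["trials"]
            records = vm.build_vmd_records(trials, m["stim_traces"],
                                           m["running"], gain=2.0)
            label_of = {r.trial_id: r.label for r in records}
            coup = (trials["condition"] == "coupled").to_numpy()
            pos = np.array([label_of.get(int(t)) == "positive"
                            for t in trials["trial_id"]])
            v1_cm = float(m["traces"]["V1"][coup].mean())
            norm, _ = vm.normalize_timecourses(
                {name: m["traces"][name]}, v1_cm, m["frame_rate"])
            arr = norm[name]
            per_mouse.append({"coupled": arr[coup],
                              "uncoupled": {"positive": arr[pos]}})
        out[name] = vm.coupled_uncoupled_comparison(per_mouse, "positive")
    return out


def vmd_null_rejection_fraction(n_runs: int = 100, seed: int = 0,
                                n_pairs: int = 20) -> dict:
    """Per-timepoint BH-rejected fraction under the null generator."""
    null_areas = {"POR": {"amplitude": 1.0, "s_pos": 0.0, "s_neg": 0.0},
                  "V1": {"amplitude": 1.2, "s_pos": 0.0, "s_neg": 0.0}}
    fracs = []
    skipped = 0
    for run in range(n_runs):
        try:
            res = vmd_comparison(seed * 100_000 + run, areas=null_areas,
                                 n_pairs=n_pairs)
        except vm.VMDError:
            # a mouse happened to draw zero positive-label trials; label
            # counts are independent of the test statistic under the null,
            # so skipping such runs does not bias the rejection fraction
            skipped += 1
            continue
        fracs.append(res["POR"]["bh_reject"].mean())
    fracs = np.asarray(fracs)
    se = fracs.std(ddof=1) / np.sqrt(len(fracs))
    return {"mean_fraction": float(fracs.mean()), "se": float(se),
            "bound": 0.05 + 3 * float(se), "n_runs": int(len(fracs)),
            "skipped": skipped}


def bh_bruteforce(p: np.ndarray, alpha: float) -> np.ndarray:
    """Literal step-up definition: largest rank k with p_(k) <= k alpha/m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def bh_oracle_agreement(seed: int, n_vectors: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 11))
        p = np.round(rng.random(n), 3)
        rej, _ = vm.benjamini_hochberg(p, 0.05)
        if not np.array_equal(rej, bh_bruteforce(p, 0.05)):
            mismatches += 1
    return {"n_vectors": n_vectors, "mismatches": mismatches}


def ephys_reduction_recovery(seed: int, truth_reduction: float = 0.8,
                             n_trials: int = 50) -> float:
    """Percent reduction recovered from a simulated opto-silencing session."""
    units = [syn.UnitTruth(4.0, 24.0, truth_reduction)]
    tt = pd.concat([
        syn.make_trials(n_trials, "grating", "control", stim_s=0.9),
        syn.make_trials(n_trials, "grating", "opto", stim_s=0.9).assign(
            trial_id=lambda d: d.trial_id + 1000,
            onset_s=lambda d: d.onset_s + 500.0,
            offset_s=lambda d: d.offset_s + 500.0),
    ]).reset_index(drop=True)
    ses = syn.generate_spike_session(units, tt, silencing="opto", seed=seed)
    st = ses["units"][0]["spike_times"]
    evoked = {}
    for cond in ("control", "opto"):
        sel = tt[tt["condition"] == cond]
        ev = ep.trial_counts(st, sel).mean() / 0.9
        bl = ep.trial_counts(st, sel, window=(-0.7, 0.0)).mean() / 0.7
        evoked[cond] = float(ev - bl)
    return ep.percent_reduction(evoked["control"], evoked["opto"])


def psth_conservation_error(seed: int) -> float:
    """Absolute spike-count error of the PSTH binning (should be 0)."""
    rng = np.random.default_rng(seed)
    trials = syn.make_trials(15, "grating", "control", stim_s=1.0)
    st = np.sort(rng.uniform(0, trials["offset_s"].max() + 1.0, 3000))
    p = ep.build_psth(st, trials, pre_s=0.5, post_s=1.5, bin_s=0.05)
    total = sum(int(((st >= tr.onset_s - 0.5) & (st < tr.onset_s + 1.5)).sum())
                for _, tr in trials.iterrows())
    return float(abs((p.rate * 0.05 * p.n_trials).sum() - total))


def rsfs_classification_accuracy(seed: int, n_each: int = 20,
                                 within_sd_ms: float = 0.05) -> dict:
    """RS/FS label accuracy with 4x class separation on trough-to-peak."""
    rng = np.random.default_rng(seed)
    fs = 25_000.0
    wfs, truth = [], []
    for cls, mean_t2p in (("RS", 0.9), ("FS", 0.25)):
        for i in range(n_each):
            t2p = mean_t2p + within_sd_ms * rng.standard_normal()
            wfs.append(syn.make_waveform(cls, fs, trough_to_peak_ms=t2p))
            truth.append(cls)
    labels = ep.classify_units(np.array(wfs), fs, seed=seed)
    labels2 = ep.classify_units(np.array(wfs), fs, seed=seed)
    acc = float(np.mean([a == b for a, b in zip(labels, truth)]))
    return {"accuracy": acc, "deterministic": labels == labels2}


ANATOMY_PARAMS = {"POR": {"gfp": (1.0, 0.3, 0.1)},
                  "LI": {"gfp": (0.6, 0.3, 0.1)},
                  "LM": {"gfp": (0.2, 0.3, 0.1)}}


def anatomy_recovery(seed: int, noise_sd: float = 0.02) -> dict:
    """Fractions, amplitude ranking and peak depth from synthetic sections."""
    gen = syn.generate_anatomy_sections(ANATOMY_PARAMS, n_sections=2,
                                        noise_sd=noise_sd, seed=seed)
    totals = {}
    peak_depth = {}
    for area, sections in gen["sections"].items():
        corrected = []
        for sec in sections:
            img = sec["images"]["gfp"]
            raw = anat.depth_density_profile(img, sec["bbox"])
            base = anat.background_profile(img, sec["background_points"],
                                           raw.size)
            corrected.append(anat.subtract_autofluorescence(raw, base))
        totals[area] = sum(float(c.sum()) for c in corrected)
        full = anat.concatenate_bins(corrected, n_bins=10)
        peak_depth[area] = (int(np.argmax(full)) + 0.5) / 10.0
    fractions = anat.fraction_of_total(totals)
    ranking_ok = fractions["POR"] > fractions["LI"] > fractions["LM"]
    return {"fractions": fractions,
            "fraction_sum": float(sum(fractions.values())),
            "ranking_ok": bool(ranking_ok),
            "peak_depth": peak_depth}


def correction_benchmark(seed: int) -> dict:
    """Artifact-only correction quality for photometry and widefield."""
    # photometry
    trials = syn.make_trials(10, stim_type="dot", condition="coupled",
                             stim_s=2.0, gap_s=4.0).assign(vmd_label="")
    ses, truth = syn.generate_photometry_session(
        0.0, 0.0, 0.0, trials, sigma_noise=0.0, h_amp=0.05, seed=seed)
    dff, _ = photo.isosbestic_correct(ses)
    raw = (ses.signal - ses.signal.mean()) / ses.signal.mean()
    photo_ratio = float(dff.var() / raw.var())
    # a residual that is float noise (<< raw fluctuation) carries no
    # artifact; report 0 rather than the chance correlation of rounding
    photo_corr = (0.0 if dff.std() < 1e-6 * raw.std() else
                  float(np.corrcoef(dff, truth["hemodynamic"])[0, 1]))
    # widefield
    cfg = syn.GroundTruthConfig(shape=(32, 32), sigma_noise=0.0, h_amp=0.05,
                                amplitude=1e-12, seed=seed)
    wtrials = syn.make_trials(3)
    wses = syn.generate_widefield_session(cfg, wtrials, isosbestic=True)
    out, _ = wf.hemodynamic_correct(wses["signal"], wses["isosbestic"],
                                    wtrials)
    raw_trace = wses["signal"].data.mean(axis=(1, 2))
    cor_trace = out.data.mean(axis=(1, 2))
    wfield_ratio = float(cor_trace.var() / raw_trace.var())
    wfield_corr = (0.0 if cor_trace.std() < 1e-6 * raw_trace.std() else float(
        np.corrcoef(cor_trace, wses["truth"]["hemodynamic"])[0, 1]))
    return {"photometry_variance_ratio": photo_ratio,
            "photometry_artifact_corr": photo_corr,
            "widefield_variance_ratio": wfield_ratio,
            "widefield_artifact_corr": wfield_corr}


def replay_identity_check(seed: int) -> dict:
    """Divergence of coupled trials against their own running traces."""
    running = syn.generate_running_trace(300.0, seed=seed)
    table, traces, _ = syn.generate_coupled_replay_trials(running, 4,
                                                          gain=2.0,
                                                          seed=seed)
    rt = running["time_s"].to_numpy()
    rs = running["speed"].to_numpy()
    divs = []
    for _, c in table[table["condition"] == "coupled"].iterrows():
        sel = (rt >= c.onset_s) & (rt < c.offset_s)
        div, _ = vm.compute_vmd(traces[c.trial_id]["dot_speed"].to_numpy(),
                                rs[sel], gain=2.0)
        divs.append(div)
    labels = vm.classify_trials([0.30, -0.30, 0.10])
    return {"self_divergences": divs,
            "all_exactly_zero": all(d == 0.0 for d in divs),
            "labels": labels,
            "labels_ok": labels == ["positive", "negative", "matched"]}
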