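"""Spike-level quantification: threshold detection, RS/FS classification,
responsiveness, Z-scored firing rates, PSTHs and silencing effect sizes.

Full template-matching spike sorting is out of scope; traces are reduced
to spike times by absolute-value threshold crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans


class EphysError(ValueError):
    pass


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_spikes(trace: np.ndarray, fs: float, threshold_sd: float = 4.0,
                  refractory_s: float = 0.001) -> np.ndarray:
    """Spike times from threshold crossings of the raw trace.

    The threshold is ``threshold_sd`` times the SD of the whole trace,
    applied to the absolute value (extracellular spikes may deflect either
    way). Crossings within ``refractory_s`` are merged and each event is
    timed at its trough (largest absolute deflection).
    """
    trace = np.asarray(trace, dtype=float)
    if fs <= 0:
        raise EphysError("fs must be positive")
    if trace.size < fs:
        raise EphysError("trace must be at least 1 s long for SD estimation")
    sd = trace.std()
    if sd == 0:
        warnings.warn("constant trace: no spikes detected")
        return np.empty(0)
    thresh = threshold_sd * sd
    above = np.abs(trace) > thresh
    # rising edges of the supra-threshold mask
    edges = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    refrac = int(round(refractory_s * fs))
    times = []
    last = -np.inf
    for e in edges:
        if e - last < refrac:
            continue
        # event window: until trace drops below threshold or refractory ends
        end = e
        while end < trace.size and abs(trace[end]) > thresh:
            end += 1
        end = max(end, min(e + refrac, trace.size))
        trough = e + int(np.argmax(np.abs(trace[e:end])))
        times.append(trough)
        last = e
    return np.array(times) / fs


# ---------------------------------------------------------------------------
# waveform classification
# ---------------------------------------------------------------------------

def waveform_features(waveforms: np.ndarray, fs: float) -> np.ndarray:
    """Per-waveform (trough-to-peak duration ms, repolarization slope)."""
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    feats = np.empty((waveforms.shape[0], 2))
    for i, wf in enumerate(waveforms):
        trough = int(np.argmin(wf))
        after = wf[trough:]
        peak = trough + int(np.argmax(after))
        t2p = (peak - trough) / fs * 1000.0
        # mean slope from trough to peak, per ms
        dur = max(peak - trough, 1)
        slope = (wf[peak] - wf[trough]) / (dur / fs * 1000.0)
        feats[i] = (t2p, slope)
    return feats


def classify_units(waveforms: np.ndarray, fs: float,
                   seed: int = 0) -> list[str]:
    """K-means (k=2) split into RS / FS on z-scored waveform features.

    The cluster with the shorter mean trough-to-peak duration is labeled
    FS. Deterministic under a fixed seed.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if waveforms.shape[0] < 2:
        raise EphysError("need >= 2 units to classify")
    feats = waveform_features(waveforms, fs)
    sd = feats.std(axis=0)
    if np.allclose(feats, feats[0]):
        raise EphysError("degenerate clustering: all waveforms identical")
    z = (feats - feats.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    t2p_means = [feats[km.labels_ == c, 0].mean() for c in (0, 1)]
    fs_cluster = int(np.argmin(t2p_means))
    return ["FS" if lab == fs_cluster else "RS" for lab in km.labels_]


# ---------------------------------------------------------------------------
# rates, responsiveness, Z-scores
# ---------------------------------------------------------------------------

def trial_counts(spike_times: np.ndarray, trials: pd.DataFrame,
                 window: tuple[float, float] | None = None) -> np.ndarray:
    """Spike counts per trial in [onset+w0, onset+w1) (default full stim)."""
    spike_times = np.asarray(spike_times)
    out = np.empty(len(trials), dtype=int)
    for i, (_, tr) in enumerate(trials.iterrows()):
        if window is None:
            lo, hi = tr.onset_s, tr.offset_s
        else:
            lo, hi = tr.onset_s + window[0], tr.onset_s + window[1]
        out[i] = int(((spike_times >= lo) & (spike_times < hi)).sum())
    return out


#: pre-stimulus baseline window per stimulus-duration class (seconds)
BASELINE_WINDOWS = {0.9: 0.7, 1.5: 0.3}
#: responsiveness criterion in baseline SDs per stimulus-duration class
RESPONSIVE_SD = {0.9: 2.0, 1.5: 1.0}


def unit_responsive(evoked_rates: np.ndarray, baseline_rates: np.ndarray,
                    stim_duration: float) -> bool | None:
    """Responsiveness under the duration-dependent criterion.

    0.9-s stimuli require the mean evoked rate to exceed baseline by 2
    baseline SDs, 1.5-s stimuli by 1 SD. Returns ``None`` when the
    baseline SD is zero (unit excluded with a warning).
    """
    if stim_duration not in RESPONSIVE_SD:
        raise EphysError(
            f"stim_duration must be one of {sorted(RESPONSIVE_SD)}")
    k = RESPONSIVE_SD[stim_duration]
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    sd = baseline_rates.std(ddof=1)
    if sd == 0:
        warnings.warn("baseline SD is zero; unit excluded")
        return None
    return bool(np.mean(evoked_rates) > baseline_rates.mean() + k * sd)


def best_direction(per_direction_rates: np.ndarray,
                   baseline_rate: float = 0.0) -> int:
    """Index of the grating direction evoking the largest baseline-
    subtracted response; ties go to the lowest index."""
    rates = np.asarray(per_direction_rates, dtype=float) - baseline_rate
    if rates.size == 0:
        raise EphysError("need at least one direction")
    return int(np.argmax(rates))  # argmax returns the first maximum


def zscore_fr(evoked_rates: np.ndarray, baseline_rates: np.ndarray) -> float:
    """(mean evoked rate - mean baseline rate) / baseline-rate SD."""
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    sd = baseline_rates.std(ddof=1)
    if sd == 0:
        raise EphysError("baseline SD is zero")
    return float((np.mean(evoked_rates) - baseline_rates.mean()) / sd)


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

@dataclass
class PSTH:
    """Trial-averaged firing-rate histogram on a fixed bin grid."""

    edges: np.ndarray      # bin edges, seconds relative to onset
    rate: np.ndarray       # Hz per bin (trial-averaged)
    normalized: np.ndarray # rate / normalization constant
    n_trials: int
    condition: str
    norm_value: float


def build_psth(spike_times: np.ndarray, trials: pd.DataFrame,
               pre_s: float = 0.5, post_s: float = 1.5,
               bin_s: float = 0.05, condition: str = "control",
               norm_value: float | None = None) -> PSTH:
    """Per-unit PSTH at ``bin_s`` resolution.

    Bins must tile ``[-pre_s, post_s]`` exactly. Control PSTHs are
    normalized by their own maximum bin; pass that maximum as
    ``norm_value`` to normalize a manipulation PSTH by the same unit's
    control maximum.
    """
    n_bins_f = (pre_s + post_s) / bin_s
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9:
        raise EphysError(
            f"bin width {bin_s}s does not tile window [{-pre_s}, {post_s}]s")
    sel = trials[trials["condition"] == condition]
    if len(sel) == 0:
        raise EphysError(f"no trials with condition {condition!r}")
    edges = -pre_s + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    st = np.asarray(spike_times)
    for _, tr in sel.iterrows():
        rel = st[(st >= tr.onset_s - pre_s) & (st < tr.onset_s + post_s)] \
            - tr.onset_s
        idx = np.floor((rel + pre_s) / bin_s).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    rate = counts / (len(sel) * bin_s)
    if norm_value is None:
        norm_value = rate.max() if rate.max() > 0 else 0.0
    if norm_value == 0:
        warnings.warn("control PSTH maximum is zero; unit dropped")
        normalized = np.zeros_like(rate)
    else:
        normalized = rate / norm_value
    return PSTH(edges=edges, rate=rate, normalized=normalized,
                n_trials=len(sel), condition=condition,
                norm_value=float(norm_value))


def population_psth(psths: list[PSTH]) -> np.ndarray:
    """Unweighted mean of per-unit normalized PSTHs."""
    if not psths:
        raise EphysError("no PSTHs to average")
    return np.mean([p.normalized for p in psths], axis=0)


# ---------------------------------------------------------------------------
# silencing effect size
# ---------------------------------------------------------------------------

def percent_reduction(control_evoked: float, laser_evoked: float) -> float:
    """(1 - laser / control) * 100, both baseline-subtracted rates."""
    if control_evoked == 0:
        raise EphysError("zero control response; unit excluded")
    return (1.0 - laser_evoked / control_evoked) * 100.0


def population_reduction(control_evoked: np.ndarray,
                         laser_evoked: np.ndarray) -> dict:
    """Per-unit reductions plus a Wilcoxon signed-rank population test.

    Units with zero control response are excluded. Uses the exact null
    distribution for small n (scipy default).
    """
    control_evoked = np.asarray(control_evoked, dtype=float)
    laser_evoked = np.asarray(laser_evoked, dtype=float)
    keep = control_evoked != 0
    if keep.sum() == 0:
        raise EphysError("all units have zero control response")
    red = (1.0 - laser_evoked[keep] / control_evoked[keep]) * 100.0
    d = control_evoked[keep] - laser_evoked[keep]
    if np.allclose(d, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(control_evoked[keep],
                                 laser_evoked[keep]).pvalue)
    return {"reduction_pct": red, "mean_reduction_pct": float(red.mean()),
            "p_value": p, "n_units": int(keep.sum()),
            "test_name": "Wilcoxon signed-rank"}
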