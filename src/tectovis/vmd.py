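"""Visuo-motor divergence statistics for coupled/replay experiments.

An "uncoupled" trial replays the dot-speed trace of a preceding "coupled"
trial. Its divergence compares the replayed stimulus speed with the
running-equivalent speed during the replay; positive divergence means the
stimulus moved faster than the animal was running.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class VMDError(ValueError):
    pass


@dataclass
class VMDRecord:
    """Divergence statistics for one uncoupled trial."""

    trial_id: int
    link_id: int
    divergence: float
    label: str
    mean_running_cms: float
    mean_stimulus_degs: float
    degenerate: bool = False  # zero running speed during replay


def compute_vmd(stimulus_speed: np.ndarray, running_speed: np.ndarray,
                gain: float) -> tuple[float, bool]:
    """Relative difference between replayed stimulus and running speed.

    divergence = (mean stim speed - gain * mean running) / (gain * mean running)

    Returns ``(divergence, degenerate)``; when the mean running speed is
    zero the divergence is ``+inf`` and the degenerate flag is set.
    """
    if gain <= 0:
        raise VMDError("gain must be positive")
    stim = float(np.mean(stimulus_speed))
    run_equiv = gain * float(np.mean(running_speed))
    if run_equiv == 0:
        return float("inf"), True
    return (stim - run_equiv) / run_equiv, False


def classify_divergence(divergence: float, threshold: float = 0.25) -> str:
    """Sort a divergence value into positive / negative / matched."""
    if threshold <= 0:
        raise VMDError("threshold must be positive")
    if divergence >= threshold:
        return "positive"
    if divergence <= -threshold:
        return "negative"
    return "matched"


def classify_trials(divergences: np.ndarray, threshold: float = 0.25) -> list[str]:
    return [classify_divergence(float(d), threshold) for d in np.asarray(divergences)]


def build_vmd_records(
    trials: pd.DataFrame,
    stim_traces: dict[int, pd.DataFrame],
    running: pd.DataFrame,
    gain: float,
    threshold: float = 0.25,
) -> list[VMDRecord]:
    """Compute divergence and label for every uncoupled trial.

    ``stim_traces`` maps trial_id to a frame with columns ``time_s`` and
    ``dot_speed`` covering the trial; ``running`` has ``time_s``/``speed``.
    """
    rt = running["time_s"].to_numpy()
    rs = running["speed"].to_numpy()
    records = []
    for _, tr in trials.iterrows():
        if tr.condition != "uncoupled":
            continue
        st = stim_traces[int(tr.trial_id)]
        sel = (rt >= tr.onset_s) & (rt < tr.offset_s)
        if not sel.any():
            raise VMDError(f"no running samples inside trial {tr.trial_id}")
        div, degen = compute_vmd(st["dot_speed"].to_numpy(), rs[sel], gain)
        label = "positive" if degen else classify_divergence(div, threshold)
        records.append(VMDRecord(
            trial_id=int(tr.trial_id), link_id=int(tr.link_id),
            divergence=div, label=label,
            mean_running_cms=float(rs[sel].mean()),
            mean_stimulus_degs=float(st["dot_speed"].mean()),
            degenerate=degen,
        ))
    return records


def records_to_frame(records: list[VMDRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def normalize_timecourses(
    area_traces: dict[str, np.ndarray],
    v1_coupled_mean: float,
    frame_rate: float,
    window_s: float = 1.7,
    trial_durations: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Normalize area traces by the scalar mean V1 coupled response.

    Traces (shape ``(n_trials, T)``, time axis starting at stimulus onset)
    are divided by ``v1_coupled_mean`` and truncated at ``window_s``. When
    ``trial_durations`` is given, the fraction of trials whose stimulus is
    still present at each retained timepoint is also returned.
    """
    if v1_coupled_mean <= 0:
        raise VMDError("v1_coupled_mean must be positive")
    n_keep = int(round(window_s * frame_rate))
    out = {}
    for name, arr in area_traces.items():
        arr = np.asarray(arr, dtype=float)
        out[name] = arr[..., :n_keep] / v1_coupled_mean
    frac = None
    if trial_durations is not None:
        t = np.arange(n_keep) / frame_rate
        frac = (np.asarray(trial_durations)[:, None] > t[None, :]).mean(axis=0)
    return out, frac


# ---------------------------------------------------------------------------
# false-discovery-rate control
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values, alpha: float = 0.05):
    """Benjamini–Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)``; adjusted p-values are monotone
    nondecreasing in the rank of the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise VMDError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    # step-up: largest k with p_(k) <= k/m * alpha
    thresholds = (np.arange(1, m + 1) / m) * alpha
    passing = np.nonzero(ranked <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1]
        reject[order[:k + 1]] = True
    # adjusted p: running minimum from the largest rank downwards
    adj_sorted = ranked * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return reject, p_adj


# ---------------------------------------------------------------------------
# coupled vs uncoupled comparisons
# ---------------------------------------------------------------------------

def coupled_uncoupled_comparison(
    per_mouse: list[dict],
    label: str = "positive",
    alpha: float = 0.05,
) -> dict:
    """Per-timepoint paired comparison of coupled vs uncoupled responses.

    Parameters
    ----------
    per_mouse
        One dict per mouse: ``{"coupled": (n_c, T) array, "uncoupled":
        {label: (n_u, T) array}}`` of already-normalized traces.
    label
        Which uncoupled class to compare against coupled trials.

    Each mouse contributes one mean trace per condition; tests are paired
    across mice at every timepoint with BH correction across timepoints.
    The summary scalar is the per-mouse mean over the window, compared with
    a paired t-test.
    """
    if len(per_mouse) < 2:
        raise VMDError("need >= 2 mice")
    coup = []
    unc = []
    for m in per_mouse:
        arr_u = np.asarray(m["uncoupled"][label], dtype=float)
        arr_c = np.asarray(m["coupled"], dtype=float)
        if arr_u.shape[0] == 0 or arr_c.shape[0] == 0:
            raise VMDError("a mouse lacks trials for the requested label")
        coup.append(arr_c.mean(axis=0))
        unc.append(arr_u.mean(axis=0))
    coup = np.array(coup)
    unc = np.array(unc)
    T = coup.shape[1]
    pvals = np.empty(T)
    for t in range(T):
        d = unc[:, t] - coup[:, t]
        pvals[t] = 1.0 if np.allclose(d, 0) else stats.ttest_rel(
            unc[:, t], coup[:, t]).pvalue
    reject, p_adj = benjamini_hochberg(pvals, alpha=alpha)
    cs = coup.mean(axis=1)
    us = unc.mean(axis=1)
    d = us - cs
    summary_p = 1.0 if np.allclose(d, 0) else float(stats.ttest_rel(us, cs).pvalue)
    return {
        "mean_difference": (unc - coup).mean(axis=0),
        "p_values": pvals,
        "bh_reject": reject,
        "p_adjusted": p_adj,
        "coupled_mouse_means": cs,
        "uncoupled_mouse_means": us,
        "summary_p": summary_p,
    }


def bin_by_divergence(divergences: np.ndarray, differences: np.ndarray,
                      bin_edges: np.ndarray) -> pd.DataFrame:
    """Mean uncoupled-minus-coupled difference per divergence bin.

    Empty bins are reported with ``NaN`` mean and count 0, never as zero.
    """
    divergences = np.asarray(divergences, dtype=float)
    differences = np.asarray(differences, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(divergences, bin_edges) - 1
    rows = []
    for b in range(bin_edges.size - 1):
        sel = idx == b
        rows.append({
            "bin_left": bin_edges[b],
            "bin_right": bin_edges[b + 1],
            "n_trials": int(sel.sum()),
            "mean_difference": float(differences[sel].mean()) if sel.any() else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavioural controls
# ---------------------------------------------------------------------------

def running_gain_check(responses: np.ndarray, speeds: np.ndarray,
                       n_bins: int = 5) -> dict:
    """Response vs running-speed summary for coupled trials.

    Bins speeds into ``n_bins`` equal-count bins and reports per-bin mean
    responses plus a Spearman rank correlation across trials.
    """
    responses = np.asarray(responses, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    if np.unique(speeds).size < 2:
        raise VMDError("need at least two distinct running speeds")
    edges = np.quantile(speeds, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        raise VMDError("fewer than 2 non-empty speed bins")
    idx = np.clip(np.digitize(speeds, edges) - 1, 0, edges.size - 2)
    bin_means = np.array([responses[idx == b].mean()
                          if (idx == b).any() else np.nan
                          for b in range(edges.size - 1)])
    rho, p = stats.spearmanr(speeds, responses)
    return {"bin_edges": edges, "bin_means": bin_means,
            "spearman_rho": float(rho), "p_value": float(p)}


def eye_position_control(coupled_xy: np.ndarray, uncoupled_xy: np.ndarray) -> dict:
    """Per-axis eye-position offsets between conditions, mean ± SD and p.

    Inputs are arrays of shape ``(n, 2)`` (azimuth, elevation) in degrees.
    """
    coupled_xy = np.atleast_2d(np.asarray(coupled_xy, dtype=float))
    uncoupled_xy = np.atleast_2d(np.asarray(uncoupled_xy, dtype=float))
    if coupled_xy.shape[0] < 2 or uncoupled_xy.shape[0] < 2:
        raise VMDError("need >= 2 samples per condition")
    out = {}
    for ax, name in enumerate(("azimuth", "elevation")):
        a = uncoupled_xy[:, ax]
        b = coupled_xy[:, ax]
        p = float(stats.ttest_ind(a, b).pvalue)
        out[name] = {
            "offset_mean": float(a.mean() - b.mean()),
            "offset_sd": float(np.sqrt(a.var(ddof=1) + b.var(ddof=1))),
            "p_value": p,
            "significant": p <= 0.05,
        }
    return out
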