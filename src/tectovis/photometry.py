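"""Fiber-photometry trace processing and VMD comparison.

Consumes demodulated two-channel traces (calcium-dependent excitation plus
an isosbestic control channel). Hardware demodulation is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vmd import benjamini_hochberg, bin_by_divergence


class PhotometryError(ValueError):
    pass


@dataclass
class PhotometrySession:
    """Two-channel photometry recording plus trial metadata.

    ``signal`` is the calcium-dependent channel, ``control`` the isosbestic
    channel; both in arbitrary fluorescence units at ``sample_rate`` Hz.
    """

    signal: np.ndarray
    control: np.ndarray | None
    sample_rate: float
    trials: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
            if self.control.shape != self.signal.shape:
                raise PhotometryError("signal and control must share shape")
        if self.sample_rate <= 0:
            raise PhotometryError("sample_rate must be positive")

    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.sample_rate


def _stimulus_mask(n: int, rate: float, trials: pd.DataFrame | None,
                   pad_s: float = 0.5) -> np.ndarray:
    """Boolean mask of samples inside any (padded) stimulus window."""
    mask = np.zeros(n, dtype=bool)
    if trials is None:
        return mask
    t = np.arange(n) / rate
    for _, tr in trials.iterrows():
        mask |= (t >= tr.onset_s) & (t < tr.offset_s + pad_s)
    return mask


def isosbestic_correct(session: PhotometrySession) -> tuple[np.ndarray, bool]:
    """Remove the hemodynamic/motion artifact using the control channel.

    The control channel is least-squares fitted to the signal over
    inter-trial samples only (to avoid absorbing evoked signal), subtracted,
    and the residual converted to ΔF/F against the fitted baseline.

    Returns
    -------
    dff, corrected
        ΔF/F trace and whether the control channel was actually used.
        A missing or zero-variance control channel degrades gracefully to
        uncorrected ΔF/F with a warning.
    """
    sig = session.signal
    if not np.any(sig != 0):
        raise PhotometryError("signal channel is all zero")
    stim = _stimulus_mask(sig.size, session.sample_rate, session.trials)
    fit = ~stim
    if fit.sum() < 2:
        fit = np.ones(sig.size, dtype=bool)

    ctrl = session.control
    corrected = False
    resid = sig.astype(float).copy()
    if ctrl is None or np.var(ctrl[fit]) == 0:
        warnings.warn("control channel missing or constant; "
                      "proceeding without isosbestic correction")
    else:
        a, b = np.polyfit(ctrl[fit], sig[fit], 1)
        fitted = a * ctrl + b
        resid = sig - fitted + np.mean(fitted[fit])
        corrected = True
    f0 = float(np.mean(resid[fit]))
    if f0 <= 0:
        raise PhotometryError("fitted baseline is non-positive")
    dff = (resid - f0) / f0
    return dff, corrected


def trial_traces(dff: np.ndarray, rate: float, trials: pd.DataFrame,
                 pre_s: float = 1.0, window_s: float = 1.7) -> dict[int, np.ndarray]:
    """Per-trial ΔF/F snippets from ``-pre_s`` to ``window_s`` around onset."""
    n_pre = int(round(pre_s * rate))
    n_post = int(round(window_s * rate))
    out = {}
    for _, tr in trials.iterrows():
        i0 = int(round(tr.onset_s * rate))
        if i0 - n_pre < 0 or i0 + n_post > dff.size:
            raise PhotometryError(
                f"trial {tr.trial_id} window exceeds trace extent")
        out[int(tr.trial_id)] = dff[i0 - n_pre:i0 + n_post]
    return out


def photometry_vmd_summary(
    sessions: list[dict],
    labels: tuple[str, ...] = ("positive", "negative", "matched"),
    alpha: float = 0.05,
    bin_edges: np.ndarray | None = None,
) -> dict:
    """Coupled/uncoupled comparison of photometry responses per VMD label.

    Parameters
    ----------
    sessions
        One dict per mouse with keys:

        - ``"coupled"``: array (n_coupled_trials, T) of ΔF/F snippets
          (baseline period included; samples before ``"n_pre"`` are
          pre-stimulus),
        - ``"uncoupled"``: dict label -> array (n_trials, T),
        - ``"n_pre"``: number of pre-stimulus samples,
        - optional ``"divergence"``: per-uncoupled-trial divergence values
          aligned with the concatenation of label groups (for binning).

    Returns per-label normalized mean curves, per-timepoint BH-corrected
    p-value masks (paired across mice), summary means, and, when divergences
    are supplied, a divergence-binned difference curve.
    """
    from scipy import stats

    if len(sessions) < 2:
        raise PhotometryError("need >= 2 mice for statistics")

    norm_sessions = []
    for ses in sessions:
        coup = np.asarray(ses["coupled"], dtype=float)
        if coup.shape[0] == 0:
            raise PhotometryError("a session has no coupled trials")
        n_pre = int(ses["n_pre"])
        # normalize by the mean coupled response over the analysis window,
        # then subtract the pre-stimulus baseline
        scale = float(np.mean(coup[:, n_pre:]))
        if scale <= 0:
            raise PhotometryError("mean coupled response is non-positive")

        def _norm(arr: np.ndarray) -> np.ndarray:
            arr = arr / scale
            base = arr[:, :n_pre].mean(axis=1, keepdims=True) if n_pre else 0.0
            return arr - base

        entry = {"coupled": _norm(coup), "n_pre": n_pre, "uncoupled": {}}
        for lab in labels:
            arr = np.asarray(ses["uncoupled"].get(lab, np.empty((0, coup.shape[1]))),
                             dtype=float)
            entry["uncoupled"][lab] = _norm(arr) if arr.size else arr
        if "divergence" in ses:
            entry["divergence"] = np.asarray(ses["divergence"], dtype=float)
        norm_sessions.append(entry)

    result: dict = {"labels": {}, "n_mice": len(norm_sessions)}
    for lab in labels:
        coup_means = np.array([s["coupled"].mean(axis=0) for s in norm_sessions])
        unc_means = []
        for s in norm_sessions:
            arr = s["uncoupled"][lab]
            if arr.shape[0] == 0:
                unc_means.append(np.full(coup_means.shape[1], np.nan))
            else:
                unc_means.append(arr.mean(axis=0))
        unc_means = np.array(unc_means)
        ok = ~np.isnan(unc_means).any(axis=1)
        lab_res = {
            "coupled_mean": coup_means.mean(axis=0),
            "uncoupled_mean": np.nanmean(unc_means, axis=0)
            if ok.any() else np.full(coup_means.shape[1], np.nan),
        }
        if ok.sum() >= 2:
            n_pre = norm_sessions[0]["n_pre"]
            pvals = np.ones(coup_means.shape[1])
            for t in range(n_pre, coup_means.shape[1]):
                diffs = unc_means[ok, t] - coup_means[ok, t]
                if np.allclose(diffs, 0):
                    pvals[t] = 1.0
                else:
                    pvals[t] = stats.ttest_rel(unc_means[ok, t],
                                               coup_means[ok, t]).pvalue
            rej, padj = benjamini_hochberg(pvals[n_pre:], alpha=alpha)
            mask = np.zeros(coup_means.shape[1], dtype=bool)
            mask[n_pre:] = rej
            lab_res["p_values"] = pvals
            lab_res["bh_mask"] = mask
            # summary scalar comparison over the analysis window
            cs = coup_means[ok, n_pre:].mean(axis=1)
            us = unc_means[ok, n_pre:].mean(axis=1)
            d = us - cs
            lab_res["coupled_summary_mean"] = float(cs.mean())
            lab_res["uncoupled_summary_mean"] = float(us.mean())
            lab_res["summary_p"] = 1.0 if np.allclose(d, 0) else float(
                stats.ttest_rel(us, cs).pvalue)
        result["labels"][lab] = lab_res

    if bin_edges is not None and all("divergence" in s for s in norm_sessions):
        divs, diffs = [], []
        for s in norm_sessions:
            n_pre = s["n_pre"]
            cmean = float(s["coupled"][:, n_pre:].mean())
            arr = np.concatenate([s["uncoupled"][lab] for lab in labels
                                  if s["uncoupled"][lab].size], axis=0)
            divs.append(s["divergence"])
            diffs.append(arr[:, n_pre:].mean(axis=1) - cmean)
        binned = bin_by_divergence(np.concatenate(divs), np.concatenate(diffs),
                                   np.asarray(bin_edges))
        result["binned_difference"] = binned
    return result
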