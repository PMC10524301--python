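"""ΔF/F computation, hemodynamic correction, patch-based area delineation
and session registration for widefield movies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.measure import label as cc_label
from skimage.registration import phase_cross_correlation

from .io_core import WidefieldMovie


class BaselineError(ValueError):
    """Degenerate (non-positive) baseline fluorescence."""


class DelineationError(ValueError):
    pass


class RegistrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------

@dataclass
class TrialAlignedDff:
    """Per-trial ΔF/F clips with their baselines.

    ``clips[i]`` has shape ``(n_frames_i, h, w)`` and spans
    ``[onset - baseline_window, offset + post_offset)`` for trial ``i``;
    ``t_rel[i]`` gives frame times relative to stimulus onset.
    """

    trials: pd.DataFrame
    clips: list[np.ndarray]
    t_rel: list[np.ndarray]
    f0: np.ndarray  # (n_trials, h, w)
    frame_rate: float

    def response_window(self, i: int) -> np.ndarray:
        """Frame selector for [onset, offset + post] of trial ``i``."""
        dur = self.trials.iloc[i].offset_s - self.trials.iloc[i].onset_s
        post = self.t_rel[i][-1] - dur if self.t_rel[i][-1] > dur else 0.0
        return (self.t_rel[i] >= 0) & (self.t_rel[i] < dur + post + 1e-9)


def compute_dff(movie: WidefieldMovie, trials: pd.DataFrame,
                baseline_window_s: float = 1.0,
                post_offset_s: float = 0.5) -> TrialAlignedDff:
    """Trial-aligned ΔF/F with a per-trial pixelwise pre-stimulus baseline.

    For each trial, F0 is the pixel mean over the ``baseline_window_s``
    preceding onset; ΔF/F = (F - F0) / F0 for frames in
    ``[onset - baseline_window_s, offset + post_offset_s)``.
    """
    fr = movie.frame_rate
    data = movie.data
    clips, t_rels, f0s = [], [], []
    n_base = int(round(baseline_window_s * fr))
    for _, tr in trials.iterrows():
        i_on = int(round(tr.onset_s * fr))
        i_end = int(round((tr.offset_s + post_offset_s) * fr))
        i0 = i_on - n_base
        if i0 < 0:
            raise ValueError(
                f"trial {tr.trial_id} lacks {baseline_window_s}s of "
                "pre-stimulus frames")
        if i_end > data.shape[0]:
            raise ValueError(f"trial {tr.trial_id} extends past movie end")
        f0 = data[i0:i_on].mean(axis=0)
        bad = int((f0 <= 0).sum())
        if bad:
            raise BaselineError(
                f"trial {tr.trial_id}: {bad} pixel(s) with F0 <= 0")
        clip = (data[i0:i_end] - f0) / f0
        clips.append(clip)
        t_rels.append((np.arange(i0, i_end) - i_on) / fr)
        f0s.append(f0)
    return TrialAlignedDff(trials=trials.reset_index(drop=True), clips=clips,
                           t_rel=t_rels, f0=np.array(f0s), frame_rate=fr)


# ---------------------------------------------------------------------------
# hemodynamic correction
# ---------------------------------------------------------------------------

def hemodynamic_correct(signal: WidefieldMovie, isosbestic: WidefieldMovie,
                        trials: pd.DataFrame | None = None,
                        pad_s: float = 1.0) -> tuple[WidefieldMovie, bool]:
    """Subtract the isosbestic channel after pixelwise least-squares scaling.

    The scaling is fitted over non-stimulus frames only. Returns the
    corrected movie and a flag; a zero-variance isosbestic channel skips
    the correction with a warning (flag False).
    """
    if signal.shape != isosbestic.shape:
        raise ValueError("channel shapes differ")
    s = signal.data.astype(float)
    iso = isosbestic.data.astype(float)
    n = s.shape[0]
    fit = np.ones(n, dtype=bool)
    if trials is not None:
        t = np.arange(n) / signal.frame_rate
        for _, tr in trials.iterrows():
            fit &= ~((t >= tr.onset_s) & (t < tr.offset_s + pad_s))
        if fit.sum() < 2:
            fit = np.ones(n, dtype=bool)
    iso_f = iso[fit]
    s_f = s[fit]
    iso_mean = iso_f.mean(axis=0)
    var = ((iso_f - iso_mean) ** 2).sum(axis=0)
    if np.all(var == 0):
        warnings.warn("isosbestic channel has zero variance; "
                      "correction skipped")
        return WidefieldMovie(s, signal.frame_rate, "signal"), False
    cov = ((iso_f - iso_mean) * (s_f - s_f.mean(axis=0))).sum(axis=0)
    a = np.zeros_like(var)
    nz = var > 0
    a[nz] = cov[nz] / var[nz]
    corrected = s - a[None] * (iso - iso_mean[None])
    return WidefieldMovie(corrected, signal.frame_rate, "signal"), True


# ---------------------------------------------------------------------------
# patch maps and area delineation
# ---------------------------------------------------------------------------

def map_patch_responses(dff: TrialAlignedDff) -> dict[int, np.ndarray]:
    """Trial-averaged mean-response image per patch location.

    Averages ΔF/F over the stimulus window and over all trials of each
    patch index present in the trial table.
    """
    patches = sorted(p for p in dff.trials["patch_index"].unique() if p >= 0)
    if not patches:
        raise ValueError("trial table contains no patch trials")
    maps: dict[int, np.ndarray] = {}
    for p in patches:
        idx = np.nonzero((dff.trials["patch_index"] == p).to_numpy())[0]
        if idx.size == 0:
            raise ValueError(f"patch {p} has zero trials")
        imgs = [dff.clips[i][dff.response_window(i)].mean(axis=0)
                for i in idx]
        maps[int(p)] = np.mean(imgs, axis=0)
    return maps


@dataclass
class AreaMaskSet:
    """Named boolean pixel masks for V1 and HVAs."""

    masks: dict[str, np.ndarray]
    hemisphere: str = "left"
    threshold_frac: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = None
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            self.masks[name] = m
            total = m.astype(int) if total is None else total + m
        if total is not None and (total > 1).any():
            raise ValueError("area masks overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)


def delineate_areas(
    patch_maps: dict[int, np.ndarray],
    template: dict[str, tuple[float, float]],
    threshold_frac: float = 0.5,
    min_pixels: int = 4,
) -> AreaMaskSet:
    """Binarize patch maps, overlay, and name connected components.

    Each map is binarized at ``threshold_frac`` of its own maximum. Pixels
    above threshold in several maps are assigned to the map with the larger
    response there (ties to the lower patch index). Connected components of
    the resolved overlay are matched to ``template`` — area name ->
    expected centroid as (row, col) fractions of the image — by minimal
    total centroid distance.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    if not patch_maps:
        raise ValueError("no patch maps supplied")
    keys = sorted(patch_maps)
    shape = patch_maps[keys[0]].shape
    above = {}
    for p in keys:
        m = patch_maps[p]
        mx = m.max()
        if mx <= 0:
            raise DelineationError(f"patch map {p} has no responsive pixels")
        above[p] = m >= threshold_frac * mx
    # ownership: highest response among maps claiming the pixel,
    # ties resolved toward the lower patch index (iteration order)
    owner = np.full(shape, -1, dtype=int)
    best = np.full(shape, -np.inf)
    for p in keys:
        claim = above[p] & (patch_maps[p] > best)
        owner[claim] = p
        best[claim] = patch_maps[p][claim]
    union = owner >= 0

    components = cc_label(union, connectivity=2)
    n_comp = components.max()
    comps = []
    for c in range(1, n_comp + 1):
        mask = components == c
        if mask.sum() < min_pixels:
            continue
        rr, cc = np.nonzero(mask)
        comps.append((mask, (rr.mean() / shape[0], cc.mean() / shape[1])))
    if not comps:
        raise DelineationError("no connected components above threshold")

    names = list(template)
    cost = np.zeros((len(comps), len(names)))
    for i, (_, cen) in enumerate(comps):
        for j, name in enumerate(names):
            ty, tx = template[name]
            cost[i, j] = (cen[0] - ty) ** 2 + (cen[1] - tx) ** 2
    rows, cols = linear_sum_assignment(cost)
    masks = {names[j]: comps[i][0] for i, j in zip(rows, cols)}
    return AreaMaskSet(masks=masks, threshold_frac=threshold_frac,
                       extra={"owner": owner})


def default_template(areas) -> dict[str, tuple[float, float]]:
    """Relative-position template from a sequence of generator AreaSpecs."""
    return {a.name: a.center for a in areas}


# ---------------------------------------------------------------------------
# session registration
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_sessions(reference: np.ndarray, moving: np.ndarray,
                      min_correlation: float = 0.2) -> tuple[int, int]:
    """Integer rigid shift aligning ``moving`` to ``reference``.

    Maximizes cross-correlation; raises :class:`RegistrationError` when the
    normalized correlation of the aligned overlap stays below
    ``min_correlation``.
    """
    shift, _, _ = phase_cross_correlation(reference, moving, upsample_factor=1,
                                          normalization=None)
    # phase_cross_correlation returns the shift aligning moving to the
    # reference; report the displacement of moving relative to reference
    dy, dx = -int(shift[0]), -int(shift[1])
    shifted = np.roll(np.roll(moving, -dy, axis=0), -dx, axis=1)
    score = _ncc(reference, shifted)
    if score < min_correlation:
        raise RegistrationError(
            f"registration failed: peak correlation {score:.3f} < "
            f"{min_correlation}")
    return dy, dx


def apply_shift(mask: np.ndarray, displacement: tuple[int, int]) -> np.ndarray:
    """Align a moving-session mask to the reference by undoing the
    displacement found by :func:`register_sessions` (wrap-free: rolled-in
    edges zeroed)."""
    dy, dx = -displacement[0], -displacement[1]
    out = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
    if dy > 0:
        out[:dy] = 0
    elif dy < 0:
        out[dy:] = 0
    if dx > 0:
        out[:, :dx] = 0
    elif dx < 0:
        out[:, dx:] = 0
    return out
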