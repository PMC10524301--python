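"""ROI pixel selection, trial response extraction, responsiveness filtering
and silencing effect sizes (intra- and inter-hemispheric).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .widefield import TrialAlignedDff


class ResponseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pixel selection
# ---------------------------------------------------------------------------

def select_top_pixels(ranking_images, mask: np.ndarray,
                      fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of the top ``fraction`` of pixels inside ``mask``.

    ``ranking_images`` is one image or a sequence of images (e.g. control
    and experimental mean responses) that are averaged before ranking, so
    pixel selection does not favour either condition. Ties are broken by
    row-major pixel index. Selects ``ceil(fraction * |mask|)`` pixels.
    """
    if not 0.0 < fraction <= 1.0:
        raise ResponseError("fraction must be in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ResponseError("empty mask")
    if isinstance(ranking_images, np.ndarray) and ranking_images.ndim == 2:
        ranking = ranking_images
    else:
        ranking = np.mean([np.asarray(im, dtype=float)
                           for im in ranking_images], axis=0)
    flat_idx = np.nonzero(mask.ravel())[0]
    values = ranking.ravel()[flat_idx]
    k = math.ceil(fraction * flat_idx.size)
    order = np.argsort(-values, kind="stable")  # stable: ties -> lower index
    chosen = flat_idx[order[:k]]
    out = np.zeros(mask.size, dtype=bool)
    out[chosen] = True
    return out.reshape(mask.shape)


# ---------------------------------------------------------------------------
# trial responses
# ---------------------------------------------------------------------------

@dataclass
class AreaResponse:
    area: str
    condition: str
    per_trial: np.ndarray
    mean: float
    pixels: np.ndarray
    baseline_sd: float


def trial_response(dff: TrialAlignedDff, pixels: np.ndarray) -> np.ndarray:
    """Per-trial scalar response: ΔF/F averaged over the analysis window
    (onset to 0.5 s after offset) and over the selected pixels."""
    pixels = np.asarray(pixels, dtype=bool)
    if not pixels.any():
        raise ResponseError("empty pixel selection")
    out = np.empty(len(dff.clips))
    for i, clip in enumerate(dff.clips):
        win = dff.response_window(i)
        out[i] = clip[win][:, pixels].mean()
    return out


def baseline_samples(dff: TrialAlignedDff, pixels: np.ndarray) -> np.ndarray:
    """Per-trial mean ΔF/F over the pre-stimulus window and selected pixels."""
    pixels = np.asarray(pixels, dtype=bool)
    out = np.empty(len(dff.clips))
    for i, clip in enumerate(dff.clips):
        pre = dff.t_rel[i] < 0
        out[i] = clip[pre][:, pixels].mean()
    return out


def area_responsive(responses: np.ndarray, baseline: np.ndarray,
                    n_sd: float = 2.0) -> bool | None:
    """True when the mean response exceeds baseline mean + ``n_sd`` SDs.

    Returns ``None`` (indeterminate, to be excluded) when the baseline SD
    is zero. Sample SD (n-1 denominator) throughout.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size < 2:
        raise ResponseError("need >= 2 baseline samples")
    sd = baseline.std(ddof=1)
    if sd == 0:
        warnings.warn("baseline SD is zero; responsiveness indeterminate")
        return None
    return bool(np.mean(responses) >= baseline.mean() + n_sd * sd)


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def percent_change_intra(control_mean: float,
                         treated_mean: float) -> tuple[float, float]:
    """Remaining fraction and percent reduction for a within-hemisphere
    silencing comparison. Reductions may be negative (an increase) and are
    never clipped."""
    if control_mean <= 0:
        raise ResponseError("control mean must be positive")
    remaining = treated_mean / control_mean
    return remaining, (1.0 - remaining) * 100.0


def interhemispheric_compare(
    treated: dict[str, np.ndarray],
    control: dict[str, np.ndarray],
    v1_key: str = "V1",
) -> pd.DataFrame:
    """Per-area relative response between hemispheres, V1-normalized.

    Each area's mean response is divided by the same-hemisphere V1 mean;
    the relative response is treated-normalized / control-normalized, and
    reduction% = (1 - relative) * 100. The V1 division makes the result
    invariant to any global gain difference between hemispheres.
    """
    for name, side in (("treated", treated), ("control", control)):
        if v1_key not in side:
            raise ResponseError(f"{name} hemisphere lacks {v1_key}")
        if np.mean(side[v1_key]) <= 0:
            raise ResponseError(f"{name} {v1_key} mean response <= 0")
    v1_t = float(np.mean(treated[v1_key]))
    v1_c = float(np.mean(control[v1_key]))
    rows = []
    for area in treated:
        if area not in control:
            continue
        rel = (float(np.mean(treated[area])) / v1_t) / (
            float(np.mean(control[area])) / v1_c)
        rows.append({"area": area, "relative_response": rel,
                     "reduction_pct": (1.0 - rel) * 100.0})
    return pd.DataFrame(rows)


def compare_conditions(group_a: np.ndarray, group_b: np.ndarray,
                       paired: bool = False,
                       alpha: float = 0.05) -> dict:
    """Two-sided t-test between conditions.

    Paired comparisons use a paired t-test (intra-hemispheric design),
    unpaired an independent t-test (inter-hemispheric design). Identical
    paired vectors report p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ResponseError("need >= 2 observations per group")
    if paired:
        if a.size != b.size:
            raise ResponseError("paired groups must have equal length")
        if np.allclose(a - b, 0):
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        name = "paired t-test"
    else:
        res = stats.ttest_ind(a, b)
        t, p = float(res.statistic), float(res.pvalue)
        name = "unpaired t-test"
    return {"statistic": t, "p_value": p, "test_name": name,
            "significant": p <= alpha}


def results_frame(entries: list[dict]) -> pd.DataFrame:
    """Tidy results table: one row per area x condition x statistic."""
    cols = ["area", "condition", "n_trials", "mean", "sd",
            "remaining_fraction", "reduction_pct", "p_value", "test_name"]
    df = pd.DataFrame(entries)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]
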