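"""Laminar depth profiles and per-area fractions of axonal fluorescence.

Section images are oriented with the x-axis (columns) spanning cortical
depth from pia (left) to white matter (right) and the y-axis (rows)
spanning the area's tangential extent. Depth is normalized to [0, 1] per
bounding box so sections of different thickness align.
"""

from __future__ import annotations

import numpy as np


class AnatomyError(ValueError):
    pass


def depth_density_profile(image: np.ndarray,
                          bbox: tuple[int, int, int, int] | None = None
                          ) -> np.ndarray:
    """Raw fluorescence density vs depth: mean over rows at each column.

    ``bbox`` is ``(row0, row1, col0, col1)`` (half-open); the default is
    the whole image.
    """
    image = np.asarray(image, dtype=float)
    if bbox is None:
        bbox = (0, image.shape[0], 0, image.shape[1])
    r0, r1, c0, c1 = bbox
    box = image[r0:r1, c0:c1]
    if box.size == 0:
        raise AnatomyError("empty bounding box")
    return box.mean(axis=0)


def background_profile(image: np.ndarray,
                       points: list[tuple[int, int]],
                       n_depth: int) -> np.ndarray:
    """Autofluorescence baseline interpolated from unlabeled sample points.

    ``points`` are (row, col) positions with no visible labeling; columns
    index depth on the same grid as the profile (length ``n_depth``).
    Samples at the same depth are averaged; interpolation between sampled
    depths is piecewise linear. The samples must span at least half of the
    depth range.
    """
    if not points:
        raise AnatomyError("no background points supplied")
    image = np.asarray(image, dtype=float)
    cols = np.array([c for _, c in points])
    vals = np.array([image[r, c] for r, c in points])
    uniq = np.unique(cols)
    if (uniq.max() - uniq.min()) < 0.5 * (n_depth - 1):
        raise AnatomyError(
            "background points cover less than 50% of the depth range")
    means = np.array([vals[cols == c].mean() for c in uniq])
    return np.interp(np.arange(n_depth), uniq, means)


def subtract_autofluorescence(profile: np.ndarray,
                              baseline: np.ndarray) -> np.ndarray:
    """Corrected density: raw minus baseline. Negatives are retained —
    clipping would bias downstream fraction totals."""
    profile = np.asarray(profile, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if profile.shape != baseline.shape:
        raise AnatomyError("profile and baseline lengths differ")
    return profile - baseline


def normalize_profiles(profiles: dict[str, list[np.ndarray]]
                       ) -> dict[str, list[np.ndarray]]:
    """Divide every profile by the per-fluorophore maximum across all of a
    mouse's sections (each fluorophore normalized independently)."""
    out: dict[str, list[np.ndarray]] = {}
    for fluor, plist in profiles.items():
        if not plist:
            raise AnatomyError(f"no profiles for fluorophore {fluor}")
        mx = max(float(np.max(p)) for p in plist)
        if mx <= 0:
            raise AnatomyError(f"non-positive maximum for fluorophore {fluor}")
        out[fluor] = [np.asarray(p, dtype=float) / mx for p in plist]
    return out


def rebin_profile(profile: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Average a depth profile into ``n_bins`` equal-width half-open bins."""
    profile = np.asarray(profile, dtype=float)
    idx = np.minimum((np.arange(profile.size) * n_bins) // profile.size,
                     n_bins - 1)
    return np.array([profile[idx == b].mean() for b in range(n_bins)])


def concatenate_bins(section_profiles: list[np.ndarray],
                     n_bins: int = 10) -> np.ndarray:
    """Combine multi-section profiles into one full-depth profile.

    Each of the ``n_bins`` equal-width depth bins is taken from the section
    with the greatest mean density inside that bin (ties to the lowest
    section id).
    """
    if not section_profiles:
        raise AnatomyError("zero sections")
    binned = np.array([rebin_profile(p, n_bins) for p in section_profiles])
    best = np.argmax(binned, axis=0)  # first max -> lowest section id
    return binned[best, np.arange(n_bins)]


def fraction_of_total(totals: dict[str, float]) -> dict[str, float]:
    """Fraction of summed fluorescence per area; fractions sum to 1."""
    values = np.array(list(totals.values()), dtype=float)
    s = values.sum()
    if s <= 0:
        raise AnatomyError("all area totals are non-positive")
    return {area: float(v / s) for area, v in zip(totals, values)}


def total_fluorescence(image: np.ndarray,
                       bbox: tuple[int, int, int, int] | None = None,
                       baseline: np.ndarray | None = None) -> float:
    """Sum of pixels across the bounding box, optionally baseline-corrected
    per depth column before summation."""
    image = np.asarray(image, dtype=float)
    if bbox is None:
        bbox = (0, image.shape[0], 0, image.shape[1])
    r0, r1, c0, c1 = bbox
    box = image[r0:r1, c0:c1]
    if baseline is not None:
        box = box - np.asarray(baseline, dtype=float)[None, :]
    return float(box.sum())
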