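"""Readers/writers, trial tables and configuration shared by all stages.

Conventions (fixed across the package):

- time is in seconds; frames are 0-based; trial intervals are half-open
  ``[onset, offset)``;
- pixel coordinates are ``(row, col)``, 0-based, row 0 = anterior edge;
- movies are multi-page TIFF; tables and traces are CSV; configuration and
  result summaries are JSON (YAML accepted for configuration).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("tectovis")

#: stimulus types the pipeline understands
STIM_TYPES = ("patch", "dot", "grating", "blank")

#: required columns of a trial table CSV
TRIAL_COLUMNS = (
    "trial_id",
    "stim_type",
    "condition",
    "onset_s",
    "offset_s",
    "link_id",
    "patch_index",
)


class SchemaError(ValueError):
    """A file does not conform to its documented column schema."""


class ValidationError(ValueError):
    """Values in a file violate the format's invariants."""


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

@dataclass
class WidefieldMovie:
    """A time x height x width fluorescence stack.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, height, width)``.
    frame_rate
        Sampling rate in Hz.
    channel
        ``"signal"`` (calcium-dependent) or ``"isosbestic"``.
    """

    data: np.ndarray
    frame_rate: float
    channel: str = "signal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"movie data must be 3-D (t, h, w), got shape {self.data.shape}"
            )
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.channel not in ("signal", "isosbestic"):
            raise ValidationError(f"unknown channel tag {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) / self.frame_rate


def write_movie(movie: WidefieldMovie, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF with frame-rate/channel metadata."""
    path = Path(path)
    meta = {"frame_rate": movie.frame_rate, "channel": movie.channel}
    tifffile.imwrite(path, movie.data, metadata=meta,
                     photometric="minisblack")


def read_movie(path: str | Path, frame_rate: float | None = None,
               channel: str | None = None) -> WidefieldMovie:
    """Read a multi-page TIFF written by :func:`write_movie`.

    ``frame_rate``/``channel`` override or supply missing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt file
        raise OSError(f"could not read movie {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate")
    if fr is None:
        raise ValidationError(f"no frame rate stored in or supplied for {path}")
    ch = channel if channel is not None else meta.get("channel", "signal")
    return WidefieldMovie(data=data, frame_rate=float(fr), channel=ch)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a trial table; returns a typed copy."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing required column(s): {missing}")
    df = df.copy()
    df["trial_id"] = df["trial_id"].astype(int)
    df["onset_s"] = df["onset_s"].astype(float)
    df["offset_s"] = df["offset_s"].astype(float)
    bad = df["offset_s"] <= df["onset_s"]
    if bad.any():
        ids = df.loc[bad, "trial_id"].tolist()
        raise ValidationError(f"offset_s <= onset_s for trial(s) {ids}")
    unknown = set(df["stim_type"]) - set(STIM_TYPES)
    if unknown:
        raise ValidationError(
            f"unknown stim_type(s) {sorted(unknown)}; allowed: {list(STIM_TYPES)}"
        )
    if df["trial_id"].duplicated().any():
        raise ValidationError("duplicate trial_id values")
    return df


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    return validate_trial_table(pd.read_csv(path))


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(df).to_csv(path, index=False, float_format="%.9g")


def read_trace(path: str | Path) -> pd.DataFrame:
    """Read a trace CSV (first column time_s, remaining columns values)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"trace file {path} lacks a time_s column")
    return df


def write_trace(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All analysis constants with their documented defaults.

    Defaults follow the published quantification procedure; every value can
    be overridden from a JSON/YAML file via :func:`load_config`.
    """

    #: relative-speed threshold sorting uncoupled trials into VMD classes
    vmd_threshold: float = 0.25
    #: SDs above baseline for an area to count as visually responsive
    responsive_sd: float = 2.0
    #: fraction of most responsive pixels used for moving-dot analyses
    top_pixel_fraction: float = 0.5
    #: analysed portion of VMD time courses, seconds from stimulus onset
    timecourse_window_s: float = 1.7
    #: PSTH bin width in seconds
    psth_bin_s: float = 0.05
    #: number of depth bins for anatomy profiles
    n_depth_bins: int = 10
    #: significance level / FDR target
    alpha: float = 0.05
    #: patch-map binarization threshold as a fraction of per-map maximum
    area_threshold_frac: float = 0.5
    #: pre-stimulus baseline window for ΔF/F, seconds
    baseline_window_s: float = 1.0
    #: post-offset extension of the response window, seconds
    post_offset_s: float = 0.5
    #: spike detection threshold in trace SDs
    spike_threshold_sd: float = 4.0
    #: refractory merge window for spike detection, seconds
    spike_refractory_s: float = 0.001

    def digest(self) -> str:
        """Hex digest of the configuration, for provenance logging."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a JSON or YAML file.

    An empty or missing file yields full defaults; unknown keys are rejected.
    """
    if path is None:
        return AnalysisConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown config key(s) {sorted(unknown)}; allowed: {sorted(known)}"
        )
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# session bundles
# ---------------------------------------------------------------------------

@dataclass
class SessionBundle:
    """Paths and metadata tying one session's files together."""

    root: Path
    movie_paths: dict[str, str] = field(default_factory=dict)
    trial_table_path: str | None = None
    running_trace_path: str | None = None
    stimulus_trace_path: str | None = None
    eye_trace_path: str | None = None
    mask_path: str | None = None
    frame_rate: float | None = None
    hemisphere: str | None = None

    def resolve(self, rel: str) -> Path:
        return Path(self.root) / rel

    def validate(self) -> None:
        """Check referenced files exist and channels are consistent."""
        for name, rel in self.movie_paths.items():
            if not self.resolve(rel).exists():
                raise FileNotFoundError(f"{name} movie missing: {self.resolve(rel)}")
        for attr in ("trial_table_path", "running_trace_path",
                     "stimulus_trace_path", "eye_trace_path", "mask_path"):
            rel = getattr(self, attr)
            if rel is not None and not self.resolve(rel).exists():
                raise FileNotFoundError(f"{attr} missing: {self.resolve(rel)}")
        shapes = {}
        for name, rel in self.movie_paths.items():
            with tifffile.TiffFile(self.resolve(rel)) as tif:
                shapes[name] = tif.asarray().shape
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"channel shapes differ across movies: {shapes}")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["root"] = str(self.root)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionBundle":
        path = Path(path)
        d = json.loads(path.read_text())
        d["root"] = Path(d.get("root", path.parent))
        return cls(**d)


def log_stage(stage: str, config: AnalysisConfig, **inputs: str) -> None:
    """Emit one structured provenance line for a pipeline stage."""
    hashes = {}
    for key, value in inputs.items():
        p = Path(str(value))
        if p.exists() and p.is_file():
            hashes[key] = hashlib.sha256(p.read_bytes()).hexdigest()[:12]
        else:
            hashes[key] = str(value)
    logger.info("stage=%s config=%s inputs=%s", stage, config.digest(),
                json.dumps(hashes, sort_keys=True))
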