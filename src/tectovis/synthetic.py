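"""Ground-truth synthetic data for every modality of the pipeline.

Every generator is a pure function of its configuration and seed, and each
modality draws from a named independent random sub-stream so that adding
one modality never shifts another's draws.

The widefield response model per area and trial is

    r_hat = A * (1 - g * silenced) * (1 + gamma * running)
              * (1 + s_pos * [positive VMD] + s_neg * [negative VMD])

with pixel fluorescence ``F0 * (1 + r(t)) * (1 + h(t)) + noise`` in the
signal channel and ``F0 * (1 + h(t)) + noise`` in the isosbestic channel:
the artifact ``h`` is shared between channels, the evoked component never
enters the isosbestic channel.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io_core import WidefieldMovie, validate_trial_table
from .photometry import PhotometrySession


class ParameterError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named sub-stream of ``seed``."""
    tag = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:8], "little")
    return np.random.default_rng([seed, tag])


# ---------------------------------------------------------------------------
# cortical layout and ground-truth configuration
# ---------------------------------------------------------------------------

@dataclass
class AreaSpec:
    """One elliptical cortical area on the pixel grid.

    ``center``/``radii`` are fractions of the image shape, rows anterior
    to posterior. ``patch_weights`` optionally restricts which patch-map
    stimuli the area responds to (default: all patches equally).
    """

    name: str
    center: tuple[float, float]
    radii: tuple[float, float]
    patch_weights: dict[int, float] | None = None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        cy, cx = self.center[0] * h, self.center[1] * w
        ry, rx = self.radii[0] * h, self.radii[1] * w
        return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 < 1.0


#: default 9-area layout: V1 plus 8 higher areas on a lateromedial gradient
DEFAULT_AREAS = (
    AreaSpec("V1", (0.62, 0.34), (0.18, 0.14)),
    AreaSpec("LM", (0.52, 0.60), (0.08, 0.07)),
    AreaSpec("AL", (0.36, 0.58), (0.07, 0.06)),
    AreaSpec("RL", (0.26, 0.47), (0.06, 0.05)),
    AreaSpec("AM", (0.24, 0.28), (0.06, 0.06)),
    AreaSpec("PM", (0.40, 0.16), (0.08, 0.06)),
    AreaSpec("LI", (0.66, 0.70), (0.08, 0.06)),
    AreaSpec("POR", (0.845, 0.72), (0.08, 0.06)),
    AreaSpec("P", (0.82, 0.50), (0.06, 0.06)),
)

#: default SC-dependence, strongest in the most lateral areas
DEFAULT_G = {"POR": 0.85, "LI": 0.7, "P": 0.55, "LM": 0.35, "V1": 0.0,
             "AL": 0.0, "RL": 0.0, "AM": 0.0, "PM": 0.0}


@dataclass
class GroundTruthConfig:
    """Generator parameters with recoverable ground truth."""

    areas: tuple[AreaSpec, ...] = DEFAULT_AREAS
    shape: tuple[int, int] = (64, 64)
    g: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_G))
    s_pos: dict[str, float] = field(default_factory=dict)
    s_neg: dict[str, float] = field(default_factory=dict)
    gamma: float = 0.0              # running gain, (dF/F)/(cm/s)
    amplitude: dict[str, float] | float = 0.5  # evoked dF/F amplitude
    f0: float = 100.0               # baseline fluorescence, a.u.
    sigma_noise: float = 1.0        # pixel noise SD, a.u.
    h_amp: float = 0.0              # hemodynamic artifact amplitude
    frame_rate: float = 10.0
    tau_rise: float = 0.1
    tau_decay: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in self.g.items():
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"g[{name}]={val} outside [0, 1]")
        if self.f0 <= 0 or self.frame_rate <= 0:
            raise ParameterError("f0 and frame_rate must be positive")
        if isinstance(self.amplitude, dict):
            if any(a <= 0 for a in self.amplitude.values()):
                raise ParameterError("amplitudes must be positive")
        elif self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")

    def area_amplitude(self, name: str) -> float:
        if isinstance(self.amplitude, dict):
            return self.amplitude.get(name, 0.0)
        return self.amplitude

    def masks(self) -> dict[str, np.ndarray]:
        masks = {a.name: a.mask(self.shape) for a in self.areas}
        total = np.zeros(self.shape, dtype=int)
        for m in masks.values():
            total += m
        if (total > 1).any():
            raise ConfigError("area masks overlap")
        return masks


def evoked_kernel(t_rel: np.ndarray, tau_rise: float = 0.1,
                  tau_decay: float = 0.8) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, peak sample normalized to 1."""
    t = np.asarray(t_rel, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


# ---------------------------------------------------------------------------
# running and stimulus traces
# ---------------------------------------------------------------------------

def generate_running_trace(duration: float, mean_speed: float = 10.0,
                           sd: float = 3.0, tau: float = 2.0,
                           dt: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Clipped mean-reverting (OU-style) running-speed trace.

    Returns a frame with columns ``time_s`` and ``speed`` (cm/s, >= 0).
    """
    if duration <= 0 or tau <= 0 or dt <= 0:
        raise ParameterError("duration, tau and dt must be positive")
    if mean_speed < 0 or sd < 0:
        raise ParameterError("mean_speed and sd must be non-negative")
    rng = _rng(seed, "running")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    speed = np.empty(n)
    speed[0] = mean_speed
    if sd == 0:
        speed[:] = mean_speed
    else:
        decay = np.exp(-dt / tau)
        innov_sd = sd * np.sqrt(1 - decay ** 2)
        eps = rng.standard_normal(n - 1)
        for i in range(1, n):
            speed[i] = mean_speed + (speed[i - 1] - mean_speed) * decay \
                + innov_sd * eps[i - 1]
            if speed[i] < 0:
                speed[i] = 0.0
    return pd.DataFrame({"time_s": t, "speed": speed})


def generate_coupled_replay_trials(
    running: pd.DataFrame,
    n_pairs: int,
    gain: float = 2.0,
    travel_deg: float = 40.0,
    iti_s: float = 4.0,
    start_s: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame], bool]:
    """Coupled trials driven by running, each replayed as an uncoupled trial.

    The coupled dot speed is ``gain * running`` and a trial ends when the
    cumulative dot travel reaches ``travel_deg``. The paired uncoupled
    trial replays the coupled dot-speed trace verbatim. Returns the trial
    table, a dict trial_id -> stimulus trace (``time_s``, ``dot_speed``,
    ``dot_position``), and an exhausted flag when the running trace could
    not accommodate all requested pairs.
    """
    if gain <= 0:
        raise ParameterError("gain must be positive")
    t = running["time_s"].to_numpy()
    v = running["speed"].to_numpy()
    dt = float(t[1] - t[0])
    rows = []
    traces: dict[int, pd.DataFrame] = {}
    trial_id = 0
    cursor = int(round(start_s / dt))
    exhausted = False
    for _ in range(n_pairs):
        # coupled trial: integrate dot travel until travel_deg
        speeds = []
        travel = 0.0
        i = cursor
        while travel < travel_deg:
            if i >= t.size:
                exhausted = True
                break
            speeds.append(gain * v[i])
            travel += gain * v[i] * dt
            i += 1
        if exhausted:
            break
        speeds = np.array(speeds)
        onset = t[cursor]
        # keep the offset on the sampling grid so half-open window selections
        # pick exactly the samples the trial was built from
        end = cursor + speeds.size
        offset = t[end] if end < t.size else t[cursor] + speeds.size * dt
        coupled_id = trial_id
        rows.append(dict(trial_id=coupled_id, stim_type="dot",
                         condition="coupled", onset_s=onset, offset_s=offset,
                         link_id=-1, patch_index=-1))
        rel = np.arange(speeds.size) * dt
        traces[coupled_id] = pd.DataFrame({
            "time_s": onset + rel, "dot_speed": speeds,
            "dot_position": np.cumsum(speeds) * dt})
        trial_id += 1
        # uncoupled replay after the inter-trial gap
        u_start = i + int(round(iti_s / dt))
        if u_start + speeds.size > t.size:
            exhausted = True
            break
        u_onset = t[u_start]
        u_end = u_start + speeds.size
        u_offset = t[u_end] if u_end < t.size else u_onset + speeds.size * dt
        rows.append(dict(trial_id=trial_id, stim_type="dot",
                         condition="uncoupled", onset_s=u_onset,
                         offset_s=u_offset,
                         link_id=coupled_id, patch_index=-1))
        traces[trial_id] = pd.DataFrame({
            "time_s": u_onset + rel, "dot_speed": speeds.copy(),
            "dot_position": np.cumsum(speeds) * dt})
        trial_id += 1
        cursor = u_start + speeds.size + int(round(iti_s / dt))
    if exhausted:
        warnings.warn("running trace exhausted; returning fewer trial pairs")
    table = pd.DataFrame(rows, columns=["trial_id", "stim_type", "condition",
                                        "onset_s", "offset_s", "link_id",
                                        "patch_index"])
    if len(table):
        table = validate_trial_table(table)
    return table, traces, exhausted


# ---------------------------------------------------------------------------
# trial-table helpers
# ---------------------------------------------------------------------------

def make_trials(n: int, stim_type: str = "dot", condition: str = "control",
                stim_s: float = 1.0, pre_s: float = 1.0, gap_s: float = 1.0,
                patch_indices: list[int] | None = None) -> pd.DataFrame:
    """Regularly spaced trial table: onset every ``pre_s+stim_s+gap_s+0.5``."""
    period = pre_s + stim_s + 0.5 + gap_s
    rows = []
    for i in range(n):
        onset = pre_s + i * period
        rows.append(dict(
            trial_id=i, stim_type=stim_type, condition=condition,
            onset_s=onset, offset_s=onset + stim_s, link_id=-1,
            patch_index=patch_indices[i] if patch_indices is not None else -1))
    return validate_trial_table(pd.DataFrame(rows))


def make_patch_trials(n_per_patch: int, stim_s: float = 1.0,
                      pre_s: float = 1.0, gap_s: float = 1.0,
                      n_patches: int = 5, seed: int = 0) -> pd.DataFrame:
    """Interleaved patch-mapping trials over ``n_patches`` locations."""
    idx = np.repeat(np.arange(n_patches), n_per_patch)
    _rng(seed, "patch-order").shuffle(idx)
    return make_trials(idx.size, stim_type="patch", condition="control",
                       stim_s=stim_s, pre_s=pre_s, gap_s=gap_s,
                       patch_indices=list(idx))


# ---------------------------------------------------------------------------
# widefield movies
# ---------------------------------------------------------------------------

def _hemodynamic(n_frames: int, frame_rate: float, h_amp: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency (< 1 Hz) multiplicative artifact trace."""
    if h_amp == 0:
        return np.zeros(n_frames)
    raw = rng.standard_normal(n_frames + int(4 * frame_rate))
    smooth = gaussian_filter1d(raw, sigma=frame_rate)  # ~1 s smoothing
    smooth = smooth[int(2 * frame_rate):int(2 * frame_rate) + n_frames]
    sd = smooth.std()
    return h_amp * (smooth / sd if sd > 0 else smooth)


def trial_amplitudes(config: GroundTruthConfig, trials: pd.DataFrame,
                     silencing: str | None = None,
                     running: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ground-truth evoked amplitude per trial and area (the model above)."""
    names = [a.name for a in config.areas]
    rows = []
    for _, tr in trials.iterrows():
        silenced = silencing is not None and tr.condition == silencing
        run_factor = 1.0
        if running is not None and config.gamma != 0:
            rt = running["time_s"].to_numpy()
            sel = (rt >= tr.onset_s) & (rt < tr.offset_s)
            if sel.any():
                run_factor = 1.0 + config.gamma * float(
                    running["speed"].to_numpy()[sel].mean())
        label = tr.get("vmd_label", "")
        row = {"trial_id": int(tr.trial_id)}
        for name in names:
            amp = config.area_amplitude(name)
            amp *= 1.0 - config.g.get(name, 0.0) * silenced
            amp *= run_factor
            amp *= 1.0 + config.s_pos.get(name, 0.0) * (label == "positive") \
                + config.s_neg.get(name, 0.0) * (label == "negative")
            if tr.stim_type == "patch":
                spec = next(a for a in config.areas if a.name == name)
                if spec.patch_weights is not None:
                    amp *= spec.patch_weights.get(int(tr.patch_index), 0.0)
            elif tr.stim_type == "blank":
                amp = 0.0
            row[name] = amp
        rows.append(row)
    return pd.DataFrame(rows).set_index("trial_id")


def generate_widefield_session(
    config: GroundTruthConfig,
    trials: pd.DataFrame,
    silencing: str | None = None,
    running: pd.DataFrame | None = None,
    isosbestic: bool = False,
) -> dict:
    """Synthesize a widefield movie (plus optional isosbestic channel).

    Returns a dict with ``"signal"`` (:class:`WidefieldMovie`), optional
    ``"isosbestic"``, and ``"truth"`` (masks plus per-trial amplitudes).
    """
    masks = config.masks()  # raises on overlap
    fr = config.frame_rate
    n_frames = int(np.ceil((trials["offset_s"].max() + 2.0) * fr))
    h, w = config.shape
    amps = trial_amplitudes(config, trials, silencing=silencing,
                            running=running)

    # per-area evoked time series
    t = np.arange(n_frames) / fr
    r = {name: np.zeros(n_frames) for name in masks}
    for tid, tr in trials.set_index("trial_id").iterrows():
        sel = (t >= tr.onset_s) & (t < tr.offset_s + 4 * config.tau_decay)
        k = evoked_kernel(t[sel] - tr.onset_s, config.tau_rise,
                          config.tau_decay)
        for name in masks:
            r[name][sel] += amps.loc[tid, name] * k

    rng = _rng(config.seed, "widefield")
    hemo = _hemodynamic(n_frames, fr, config.h_amp, _rng(config.seed, "hemo"))

    evoked = np.zeros((n_frames, h, w))
    for name, mask in masks.items():
        evoked[:, mask] += r[name][:, None]
    signal = config.f0 * (1.0 + evoked) * (1.0 + hemo)[:, None, None]
    if config.sigma_noise > 0:
        signal = signal + config.sigma_noise * rng.standard_normal(signal.shape)
    out = {
        "signal": WidefieldMovie(signal, frame_rate=fr, channel="signal"),
        "truth": {"masks": masks, "amplitudes": amps,
                  "evoked_timeseries": r, "hemodynamic": hemo},
    }
    if isosbestic:
        iso = config.f0 * np.ones((n_frames, h, w)) * (1.0 + hemo)[:, None, None]
        if config.sigma_noise > 0:
            iso = iso + config.sigma_noise * rng.standard_normal(iso.shape)
        out["isosbestic"] = WidefieldMovie(iso, frame_rate=fr,
                                           channel="isosbestic")
    return out


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

@dataclass
class UnitTruth:
    baseline_hz: float
    evoked_hz: float
    reduction: float  # evoked-rate reduction fraction under silencing
    cls: str = "RS"   # RS or FS

    def __post_init__(self) -> None:
        if self.baseline_hz < 0 or self.evoked_hz < 0:
            raise ParameterError("rates must be non-negative")
        if self.cls not in ("RS", "FS"):
            raise ParameterError("cls must be RS or FS")


def make_waveform(cls: str, fs: float = 25_000.0,
                  trough_to_peak_ms: float | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Template extracellular waveform: broad for RS, narrow for FS."""
    if trough_to_peak_ms is None:
        trough_to_peak_ms = 0.9 if cls == "RS" else 0.25
    n = int(round(0.003 * fs))  # 3 ms
    t = (np.arange(n) - n // 3) / fs * 1000.0  # ms, trough at 0
    trough = -np.exp(-(t / 0.12) ** 2)
    peak_amp = 0.35 if cls == "RS" else 0.5
    peak_w = 0.35 if cls == "RS" else 0.12
    peak = peak_amp * np.exp(-((t - trough_to_peak_ms) / peak_w) ** 2)
    wf = trough + peak
    if rng is not None:
        wf = wf + 0.01 * rng.standard_normal(n)
    return wf


def _poisson_times(rate: float, t0: float, t1: float,
                   rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def generate_spike_session(
    units: list[UnitTruth],
    trials: pd.DataFrame,
    silencing: str = "opto",
    fs: float = 25_000.0,
    seed: int = 0,
) -> dict:
    """Poisson spike trains per unit with silencing-dependent evoked rates.

    During a stimulus the rate is ``baseline + (evoked - baseline) *
    (1 - reduction * silenced)``; elsewhere it is the baseline rate.
    """
    if fs < 20_000:
        raise ParameterError("fs must be >= 20 kHz")
    duration = float(trials["offset_s"].max() + 2.0)
    out_units = []
    for ui, u in enumerate(units):
        rng = _rng(seed, f"spikes-{ui}")
        # piecewise-constant rate segments
        cursor = 0.0
        spikes = []
        for _, tr in trials.sort_values("onset_s").iterrows():
            if tr.onset_s > cursor:
                spikes.append(_poisson_times(u.baseline_hz, cursor,
                                             tr.onset_s, rng))
            silenced = tr.condition == silencing
            evoked = u.baseline_hz + (u.evoked_hz - u.baseline_hz) * (
                1.0 - u.reduction * silenced)
            spikes.append(_poisson_times(evoked, tr.onset_s, tr.offset_s, rng))
            cursor = tr.offset_s
        if duration > cursor:
            spikes.append(_poisson_times(u.baseline_hz, cursor, duration, rng))
        times = np.concatenate(spikes) if spikes else np.empty(0)
        wf = make_waveform(u.cls, fs=fs, rng=_rng(seed, f"wf-{ui}"))
        out_units.append({"spike_times": times, "waveform": wf,
                          "truth": u})
    return {"units": out_units, "fs": fs, "duration": duration,
            "trials": trials}


def synthesize_trace(spike_times: np.ndarray, waveform: np.ndarray,
                     duration: float, fs: float, noise_sd: float = 1.0,
                     spike_amp: float = 8.0, noise_smooth_samples: float = 0.0,
                     seed: int = 0) -> np.ndarray:
    """Raw extracellular trace: Gaussian noise plus inserted waveforms.

    ``spike_amp`` scales the unit waveform in units of the noise SD.
    ``noise_smooth_samples`` > 0 band-limits the noise (Gaussian smoothing,
    renormalized to ``noise_sd``), mimicking the temporal correlation of
    filtered extracellular recordings; white noise at typical sampling
    rates crosses a 4-SD threshold far more often than real noise does.
    """
    rng = _rng(seed, "trace-noise")
    n = int(round(duration * fs))
    trace = rng.standard_normal(n)
    if noise_smooth_samples > 0:
        trace = gaussian_filter1d(trace, noise_smooth_samples)
        trace /= trace.std()
    trace = noise_sd * trace
    trough = int(np.argmin(waveform))
    wf = waveform / np.abs(waveform.min()) * spike_amp * noise_sd
    for st in np.asarray(spike_times):
        i0 = int(round(st * fs)) - trough
        if i0 < 0 or i0 + wf.size > n:
            continue
        trace[i0:i0 + wf.size] += wf
    return trace


# ---------------------------------------------------------------------------
# anatomy sections
# ---------------------------------------------------------------------------

def generate_anatomy_sections(
    area_params: dict[str, dict[str, tuple[float, float, float]]],
    n_sections: int = 2,
    shape: tuple[int, int] = (60, 80),
    noise_sd: float = 0.0,
    baseline_slope: float = 0.3,
    baseline_offset: float = 0.2,
    seed: int = 0,
) -> dict:
    """Coronal-section images with laminar fluorescence bands.

    ``area_params[area][fluorophore] = (amplitude, peak_depth, width)`` with
    depth normalized 0 (pia) to 1 (white matter). Image columns span depth;
    the labeled area occupies an interior row band (the bounding box), rows
    outside it carry only the depth-dependent autofluorescence baseline and
    are returned as background sample points.
    """
    for area, fluors in area_params.items():
        for fl, (amp, depth, width) in fluors.items():
            if amp < 0:
                raise ParameterError(f"amplitude < 0 for {area}/{fl}")
            if not 0.0 <= depth <= 1.0:
                raise ParameterError(f"depth outside [0,1] for {area}/{fl}")
    h, w = shape
    depth = np.arange(w) / (w - 1)
    r0, r1 = h // 4, 3 * h // 4  # bounding-box rows of the labeled band
    bg_rows = [h // 8, h - 1 - h // 8]
    sections: dict[str, list[dict]] = {}
    truth: dict[str, dict] = {}
    rng = _rng(seed, "anatomy")
    for area, fluors in area_params.items():
        area_sections = []
        # per-section brightness factors (section 0 kept at 1.0)
        factors = np.concatenate([[1.0], 0.5 + 0.4 * rng.random(n_sections - 1)])
        for s in range(n_sections):
            images = {}
            for fl, (amp, pk, width) in fluors.items():
                baseline = baseline_offset + baseline_slope * depth
                img = np.tile(baseline, (h, 1))
                band = amp * factors[s] * np.exp(-((depth - pk) / width) ** 2)
                img[r0:r1, :] += band[None, :]
                if noise_sd > 0:
                    img = img + noise_sd * rng.standard_normal(img.shape)
                images[fl] = img
            area_sections.append({
                "images": images,
                "bbox": (r0, r1, 0, w),
                "background_points": [
                    (r, c) for r in bg_rows
                    for c in sorted({*range(0, w, max(1, w // 16)), w - 1})],
            })
        sections[area] = area_sections
        truth[area] = {fl: {"amplitude": p[0], "peak_depth": p[1],
                            "width": p[2], "section_factors": factors}
                       for fl, p in fluors.items()}
    return {"sections": sections, "truth": truth, "shape": shape}


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def generate_photometry_session(
    coupled_amplitude: float,
    s_pos: float,
    s_neg: float,
    trials: pd.DataFrame,
    sample_rate: float = 20.0,
    f0: float = 100.0,
    sigma_noise: float = 0.0,
    h_amp: float = 0.0,
    tau_rise: float = 0.1,
    tau_decay: float = 0.8,
    seed: int = 0,
) -> tuple[PhotometrySession, dict]:
    """Two-channel 1-D photometry traces with the widefield response model.

    ``trials`` must carry a ``vmd_label`` column for uncoupled trials.
    """
    if coupled_amplitude < 0:
        raise ParameterError("coupled_amplitude must be >= 0")
    n = int(np.ceil((trials["offset_s"].max() + 2.0) * sample_rate))
    t = np.arange(n) / sample_rate
    r = np.zeros(n)
    truth_amp = {}
    for _, tr in trials.iterrows():
        label = tr.get("vmd_label", "")
        amp = coupled_amplitude * (1.0 + s_pos * (label == "positive")
                                   + s_neg * (label == "negative"))
        truth_amp[int(tr.trial_id)] = amp
        sel = (t >= tr.onset_s) & (t < tr.offset_s + 4 * tau_decay)
        r[sel] += amp * evoked_kernel(t[sel] - tr.onset_s, tau_rise, tau_decay)
    hemo = _hemodynamic(n, sample_rate, h_amp, _rng(seed, "photo-hemo"))
    rng = _rng(seed, "photometry")
    signal = f0 * (1.0 + r) * (1.0 + hemo)
    control = 0.8 * f0 * (1.0 + hemo)
    if sigma_noise > 0:
        signal = signal + sigma_noise * rng.standard_normal(n)
        control = control + sigma_noise * rng.standard_normal(n)
    session = PhotometrySession(signal=signal, control=control,
                                sample_rate=sample_rate, trials=trials)
    return session, {"amplitudes": truth_amp, "evoked": r, "hemodynamic": hemo}


# ---------------------------------------------------------------------------
# lightweight VMD cohort (trace-level, no pixels)
# ---------------------------------------------------------------------------

def simulate_vmd_cohort(
    n_mice: int = 4,
    n_pairs: int = 40,
    areas: dict[str, dict[str, float]] | None = None,
    gain: float = 2.0,
    frame_rate: float = 10.0,
    window_s: float = 2.0,
    noise_sd: float = 0.05,
    vmd_threshold: float = 0.25,
    gamma: float = 0.0,
    seed: int = 0,
) -> list[dict]:
    """Per-mouse coupled/replay sessions with per-area trial traces.

    ``areas`` maps area name to ``{"amplitude", "s_pos", "s_neg"}``. The
    running trace, trial structure and stimulus replays come from
    :func:`generate_running_trace` / :func:`generate_coupled_replay_trials`;
    each trial then gets a (n_timepoints,) evoked trace per area with the
    VMD effect applied according to the trial's true divergence.

    Returns one dict per mouse: ``trials``, ``stim_traces``, ``running``,
    ``traces`` (area -> (n_trials, T) aligned to trial onset) and
    ``truth_labels`` (trial_id -> label).
    """
    if areas is None:
        areas = {"POR": {"amplitude": 1.0, "s_pos": 0.5, "s_neg": 0.0},
                 "LI": {"amplitude": 0.8, "s_pos": 0.5, "s_neg": 0.0},
                 "V1": {"amplitude": 1.2, "s_pos": 0.0, "s_neg": 0.0}}
    from .vmd import compute_vmd, classify_divergence

    cohort = []
    T = int(round(window_s * frame_rate))
    t_rel = np.arange(T) / frame_rate
    kern = evoked_kernel(t_rel)
    for m in range(n_mice):
        mouse_seed = seed * 1000 + m
        running = generate_running_trace(duration=20.0 + n_pairs * 14.0,
                                         seed=mouse_seed)
        trials, stim_traces, _ = generate_coupled_replay_trials(
            running, n_pairs=n_pairs, gain=gain, seed=mouse_seed)
        rt = running["time_s"].to_numpy()
        rs = running["speed"].to_numpy()
        labels: dict[int, str] = {}
        for _, tr in trials.iterrows():
            if tr.condition == "uncoupled":
                sel = (rt >= tr.onset_s) & (rt < tr.offset_s)
                div, degen = compute_vmd(
                    stim_traces[int(tr.trial_id)]["dot_speed"].to_numpy(),
                    rs[sel], gain)
                labels[int(tr.trial_id)] = (
                    "positive" if degen else classify_divergence(div,
                                                                 vmd_threshold))
            else:
                labels[int(tr.trial_id)] = "coupled"
        rng = _rng(mouse_seed, "vmd-traces")
        traces = {}
        for name, pars in areas.items():
            arr = np.empty((len(trials), T))
            for i, (_, tr) in enumerate(trials.iterrows()):
                lab = labels[int(tr.trial_id)]
                sel = (rt >= tr.onset_s) & (rt < tr.offset_s)
                run_factor = 1.0 + gamma * float(rs[sel].mean()) if sel.any() else 1.0
                amp = pars["amplitude"] * run_factor * (
                    1.0 + pars.get("s_pos", 0.0) * (lab == "positive")
                    + pars.get("s_neg", 0.0) * (lab == "negative"))
                arr[i] = amp * kern + noise_sd * rng.standard_normal(T)
            traces[name] = arr
        cohort.append({"trials": trials, "stim_traces": stim_traces,
                       "running": running, "traces": traces,
                       "truth_labels": labels, "frame_rate": frame_rate})
    return cohort
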