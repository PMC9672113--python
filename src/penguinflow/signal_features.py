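"""Per-sample derived variables from raw sensor channels.

Raw tri-axial acceleration is decomposed into a static (gravity/posture)
component — a 2 s centred running mean — and a dynamic component
(raw minus static).  Posture angles and VeDBA follow the standard
conventions:

    pitch = atan2(static_surge, sqrt(static_sway^2 + static_heave^2))
    roll  = atan2(static_sway, static_heave)
    VeDBA = ||(dyn_surge, dyn_sway, dyn_heave)||

Rolling standard deviations of the raw axes (2/10/30/60 s), of roll (30 s)
and of pitch and VeDBA (60 s) capture behaviour-specific signal variability
at several temporal scales.  Pressure is zeroed on the mode of its
distribution (the logger's surface reading) and converted to depth in metres.
All windows are centred with shrinking edges.
"""

from __future__ import annotations

import logging
from dataclasses import replace as _dc_replace

import numpy as np
import pandas as pd

from penguinflow.synthetic_data import RawDeployment

log = logging.getLogger(__name__)

SD_WINDOWS_S = (2, 10, 30, 60)

#: columns of a FeatureFrame, in writing order
FEATURE_COLUMNS = (
    ["time_s", "surge", "sway", "heave",
     "static_surge", "static_sway", "static_heave",
     "dyn_surge", "dyn_sway", "dyn_heave",
     "pitch", "roll", "vedba"]
    + [f"sd_{ax}_{w}s" for ax in ("surge", "sway", "heave") for w in SD_WINDOWS_S]
    + ["sd_roll_30s", "sd_pitch_60s", "sd_vedba_60s",
       "depth", "depth_raw", "depth_change", "temperature"]
)


def subsample_25hz(dep: RawDeployment) -> RawDeployment:
    """Bring a deployment to 25 Hz; 100 Hz input is decimated (every 4th sample)."""
    if dep.sample_rate_hz == 25:
        return dep
    if dep.sample_rate_hz != 100:
        raise ValueError(f"unsupported sample rate {dep.sample_rate_hz} Hz (need 25 or 100)")
    sl = slice(None, None, 4)
    return _dc_replace(
        dep,
        time=dep.time[sl],
        ax=dep.ax[sl], ay=dep.ay[sl], az=dep.az[sl],
        true_labels=None if dep.true_labels is None else dep.true_labels[sl],
        sample_rate_hz=25,
    )


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _running_sd(x: np.ndarray, window: int) -> np.ndarray:
    # population form (ddof=0); a single-sample window has SD 0
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).std(ddof=0).to_numpy()
    )


def static_dynamic(dep: RawDeployment, window_s: float = 2.0):
    """Static (centred running mean) and dynamic (raw - static) acceleration.

    Returns ((static_x, static_y, static_z), (dyn_x, dyn_y, dyn_z)); the
    decomposition is exact per sample: raw = static + dynamic.
    """
    if dep.n_samples == 0:
        raise ValueError("empty acceleration trace")
    w = max(1, int(round(window_s * dep.sample_rate_hz)))
    static = tuple(_running_mean(a, w) for a in (dep.ax, dep.ay, dep.az))
    dynamic = tuple(a - s for a, s in zip((dep.ax, dep.ay, dep.az), static))
    return static, dynamic


def pitch_roll_vedba(static, dynamic):
    """Posture angles (deg) from the static vector and VeDBA (g) from the dynamic."""
    sx, sy, sz = static
    dx, dy, dz = dynamic
    norm_yz = np.hypot(sy, sz)
    zero = (np.abs(sx) < 1e-12) & (norm_yz < 1e-12)
    if zero.any():
        log.warning("pitch/roll undefined at %d samples (zero static vector)", zero.sum())
    with np.errstate(invalid="ignore"):
        pitch = np.degrees(np.arctan2(sx, norm_yz))
        roll = np.degrees(np.arctan2(sy, sz))
    pitch = np.where(zero, np.nan, pitch)
    roll = np.where(zero, np.nan, roll)
    vedba = np.sqrt(dx * dx + dy * dy + dz * dz)
    return pitch, roll, vedba


def windowed_sds(dep: RawDeployment, pitch, roll, vedba) -> dict[str, np.ndarray]:
    """Rolling SDs of the raw axes and of roll/pitch/VeDBA at their set windows."""
    fs = dep.sample_rate_hz
    out = {}
    for ax_name, a in zip(("surge", "sway", "heave"), (dep.ax, dep.ay, dep.az)):
        for w_s in SD_WINDOWS_S:
            out[f"sd_{ax_name}_{w_s}s"] = _running_sd(a, w_s * fs)
    out["sd_roll_30s"] = _running_sd(roll, 30 * fs)
    out["sd_pitch_60s"] = _running_sd(pitch, 60 * fs)
    out["sd_vedba_60s"] = _running_sd(vedba, 60 * fs)
    return out


def pressure_to_depth(pressure_mbar: np.ndarray):
    """Depth (m) and per-second depth change (m/s) from 1 Hz pressure.

    The surface offset is the mode of the pressure distribution on 1 mbar
    bins; depth = (pressure - mode) / 100.  Negative depths are clipped to 0
    in `depth` (used for segmentation) and kept in `depth_raw`.
    """
    p = np.asarray(pressure_mbar, dtype=float)
    if len(p) < 60:
        raise ValueError("need at least 60 s of pressure")
    binned = np.round(p).astype(int)
    vals, counts = np.unique(binned, return_counts=True)
    mode = vals[np.argmax(counts)]
    depth_raw = (p - mode) / 100.0
    depth = np.clip(depth_raw, 0.0, None)
    depth_change = np.diff(depth_raw, prepend=depth_raw[0])
    return depth, depth_raw, depth_change


def build_features(dep: RawDeployment) -> pd.DataFrame:
    """Assemble the full 25 Hz FeatureFrame for one deployment.

    1 Hz channels (depth, depth change, temperature) are upsampled by
    sample-and-hold; if the deployment carries ground-truth labels they are
    attached as `behaviour_true` (and per-second context as `context_true`).
    """
    dep = subsample_25hz(dep)
    static, dynamic = static_dynamic(dep)
    pitch, roll, vedba = pitch_roll_vedba(static, dynamic)
    sds = windowed_sds(dep, pitch, roll, vedba)
    depth, depth_raw, depth_change = pressure_to_depth(dep.pressure_mbar)

    sec = np.minimum(np.floor(dep.time).astype(int), len(depth) - 1)
    frame = pd.DataFrame(
        {
            "time_s": dep.time,
            "surge": dep.ax, "sway": dep.ay, "heave": dep.az,
            "static_surge": static[0], "static_sway": static[1], "static_heave": static[2],
            "dyn_surge": dynamic[0], "dyn_sway": dynamic[1], "dyn_heave": dynamic[2],
            "pitch": pitch, "roll": roll, "vedba": vedba,
            **sds,
            "depth": depth[sec],
            "depth_raw": depth_raw[sec],
            "depth_change": depth_change[sec],
            "temperature": dep.temp_c[sec],
        }
    )
    if dep.true_labels is not None:
        frame["behaviour_true"] = dep.true_labels
    if dep.true_context is not None:
        frame["context_true"] = dep.true_context[sec]
    frame.attrs["at_25hz"] = True
    frame.attrs["individual_id"] = dep.individual_id
    frame.attrs["season_id"] = dep.season_id
    frame.attrs["trip_id"] = dep.trip_id
    frame.attrs["species"] = dep.species
    frame.attrs["sex"] = dep.sex
    return frame
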