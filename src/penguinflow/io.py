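"""Delimited-text readers/writers for deployments, features and run artifacts.

Raw deployments use the logger-style dialect
`time_s,ax_g,ay_g,az_g,pressure_mbar,temp_c`: acceleration on every 25 Hz
row, pressure/temperature only on 1 Hz ticks (blank in between, or repeated
with `dialect="repeat"`).  Ground-truth labels go to a sidecar file
`<name>.labels.csv` so the main file stays a plain sensor record.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from penguinflow.synthetic_data import RawDeployment


def write_deployment(dep: RawDeployment, path, dialect: str = "blank") -> Path:
    """Write a deployment (and a label sidecar if labelled); lossless round-trip."""
    if dep.n_samples == 0:
        raise ValueError("no samples")
    if dialect not in ("blank", "repeat"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    fs = dep.sample_rate_hz
    n = dep.n_samples
    tick = np.arange(n) % fs == 0
    sec = (np.arange(n) // fs).clip(max=len(dep.pressure_mbar) - 1)
    press = dep.pressure_mbar[sec].astype(object)
    temp = dep.temp_c[sec].astype(object)
    if dialect == "blank":
        press[~tick] = ""
        temp[~tick] = ""
    df = pd.DataFrame(
        {
            "time_s": dep.time,
            "ax_g": dep.ax, "ay_g": dep.ay, "az_g": dep.az,
            "pressure_mbar": press, "temp_c": temp,
        }
    )
    try:
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write deployment to {path}: {exc}") from exc
    meta = {
        "individual_id": dep.individual_id,
        "season_id": dep.season_id,
        "trip_id": dep.trip_id,
        "species": dep.species,
        "sample_rate_hz": dep.sample_rate_hz,
        "sex": dep.sex,
        "tag_pitch_offset_deg": dep.tag_pitch_offset_deg,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    if dep.true_labels is not None:
        pd.DataFrame({"time_s": dep.time, "behaviour": dep.true_labels}).to_csv(
            path.with_suffix(".labels.csv"), index=False
        )
    return path


def read_deployment(path) -> RawDeployment:
    """Read a deployment written by `write_deployment`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    fs = int(meta.get("sample_rate_hz", 25))
    tick = df["pressure_mbar"].notna().to_numpy()
    labels = None
    label_path = path.with_suffix(".labels.csv")
    if label_path.exists():
        labels = pd.read_csv(label_path)["behaviour"].to_numpy(dtype=object)
    return RawDeployment(
        individual_id=meta.get("individual_id", path.stem),
        season_id=meta.get("season_id", ""),
        trip_id=meta.get("trip_id", path.stem),
        species=meta.get("species", "adelie"),
        time=df["time_s"].to_numpy(),
        ax=df["ax_g"].to_numpy(),
        ay=df["ay_g"].to_numpy(),
        az=df["az_g"].to_numpy(),
        pressure_time=np.flatnonzero(tick) / fs,
        pressure_mbar=df.loc[tick, "pressure_mbar"].to_numpy(dtype=float),
        temp_c=df.loc[tick, "temp_c"].to_numpy(dtype=float),
        sample_rate_hz=fs,
        true_labels=labels,
        sex=meta.get("sex"),
        tag_pitch_offset_deg=float(meta.get("tag_pitch_offset_deg", 0.0)),
    )


def write_model_json(model, path) -> Path:
    """Serialise a ClusterModel (weights/means/covariances/BIC/labels) to JSON."""
    payload = {
        "subset": model.subset,
        "K": model.K,
        "weights": model.weights.tolist(),
        "means_scaled": model.means.tolist(),
        "means_unscaled": model.means_unscaled.tolist(),
        "covariances": model.covariances.tolist(),
        "loglik": model.loglik,
        "bic": model.bic,
        "n_obs": model.n_obs,
        "variables": model.variables,
        "labels": model.labels,
        "selection_criterion": "BIC",
        "family": "gaussian_full_covariance",
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def dump_config_yaml(cfg, path) -> Path:
    """Write any dataclass config (nested) as YAML."""
    path = Path(path)

    def clean(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: clean(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        return x

    path.write_text(yaml.safe_dump(clean(cfg), sort_keys=False))
    return path


def load_synth_config_yaml(path):
    """Read a generator config written by `dump_config_yaml`."""
    from penguinflow.synthetic_data import Behaviour, SynthConfig

    raw = yaml.safe_load(Path(path).read_text())
    raw["behaviour_grammar"] = {
        name: Behaviour(**params) for name, params in raw["behaviour_grammar"].items()
    }
    for key in ("seasons", "surface_phase_bounds_s", "bottom_phase_bounds_s",
                "dive_depth_range_m", "ice_rest_bounds_s"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SynthConfig(**raw)
    cfg.validate()
    return cfg
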