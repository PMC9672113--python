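"""End-to-end study runs: one-season and two-season training designs.

`run_one_season` trains the forest on rows sampled from every Season-1 trip
and predicts Season-1 hold-out rows plus all of Season 2; `run_two_season`
samples half-of-smallest-season trips from each season, trains on those, and
reports agreement in four groups (trained-on vs predicted, by season).
`run_energetics` converts Season-1 Adelie labels from both routes into coarse
budgets, activity-specific VeDBA and daily energy expenditure, and compares
the two methods with OLS/AIC.  Every stage is seeded from the pipeline seed;
rerunning a config reproduces the report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from penguinflow import comparison, energetics, supervised
from penguinflow.em_behaviour import (
    label_clusters,
    merge_minor_classes,
    scale_center,
    select_k,
    select_variables,
)
from penguinflow.energetics import DEECoefficients, SYNTHETIC_COEFFICIENTS
from penguinflow.signal_features import build_features
from penguinflow.supervised import PREDICTORS, adjust_pitch, predict_behaviours, train_forest
from penguinflow.synthetic_data import SynthConfig, default_config, generate_dataset
from penguinflow.trip_segmentation import detect_trips, split_subsets

log = logging.getLogger(__name__)


@dataclass
class EMSettings:
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    short_iter: int | None = 25  # burn-in per start; best start runs to convergence


@dataclass
class RFSettings:
    tree_grid: tuple[int, ...] = (100, 500, 1000, 1500)
    mtry: int = 4
    test_fraction: float = 0.25
    cv_folds: int = 10
    oob_tolerance: float = 0.002


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=default_config)
    seed: int = 42
    em: EMSettings = field(default_factory=EMSettings)
    rf: RFSettings = field(default_factory=RFSettings)
    sampling_cap: int = 1000
    dee_coefficients: DEECoefficients = SYNTHETIC_COEFFICIENTS
    mode: str = "two_season"


@dataclass
class TripRecord:
    """Features, EM labels and provenance for one processed trip."""

    trip_id: str
    individual_id: str
    season_id: str
    species: str
    sex: str | None
    frame: pd.DataFrame
    in_trip: np.ndarray                 # frame indices inside the trip
    em_labels: pd.Series                # post-merge behaviour per in-trip sample
    em_labels_raw: pd.Series            # before swim_cruise_2 merge
    models: dict = field(default_factory=dict)
    train_idx: np.ndarray | None = None  # rows drawn into the training table
    pool_idx: np.ndarray | None = None


def _trip_seed(seed: int, trip_id: str) -> np.random.SeedSequence:
    from penguinflow.synthetic_data import stable_hash

    return np.random.SeedSequence([seed, stable_hash(trip_id)])


def process_deployment(dep, cfg: PipelineConfig) -> TripRecord | None:
    """Features, segmentation and per-subset EM labelling for one deployment."""
    frame = build_features(dep)
    species = dep.species
    frame = adjust_pitch(frame, species)
    trips = detect_trips(
        frame,
        water_temp_c=cfg.synth.water_temp_c,
        land_temp_c=cfg.synth.land_temp_c,
        species=species,
    )
    if not trips:
        log.warning("deployment %s: no at-sea trip detected; skipped", dep.trip_id)
        return None
    segments = split_subsets(frame, trips, species)
    in_trip = np.concatenate([np.arange(s, e) for s, e in trips])
    dives_present = any(s.subset == "diving" for s in segments)

    labels = pd.Series(index=in_trip, dtype=object)
    models = {}
    ss = _trip_seed(cfg.seed, dep.trip_id)
    subset_types = [st for st in ("diving", "surface", "land_ice")
                    if any(s.subset == st for s in segments)]
    children = ss.spawn(len(subset_types))
    for subset_type, child in zip(subset_types, children):
        idx = np.concatenate(
            [np.arange(s.start, s.end) for s in segments if s.subset == subset_type]
        )
        variables = select_variables(subset_type)
        X = frame.loc[idx, variables].ffill().bfill().to_numpy()
        if len(X) <= 2 * len(variables) + 1:
            log.warning("%s/%s: too few samples for EM; skipped",
                        dep.trip_id, subset_type)
            continue
        Xs, scaling = scale_center(X)
        model = select_k(
            Xs, subset_type, dives_present, child,
            n_starts=cfg.em.n_starts, max_iter=cfg.em.max_iter, tol=cfg.em.tol,
            scaling=scaling, variables=variables, short_iter=cfg.em.short_iter,
        )
        mapping = label_clusters(model, subset_type, species)
        assign = model.predict(Xs)
        labels.loc[idx] = np.asarray([mapping[k] for k in range(model.K)], dtype=object)[assign]
        models[subset_type] = model

    keep = labels.notna()
    labels = labels[keep]
    merged = pd.Series(merge_minor_classes(labels.to_numpy()), index=labels.index)
    return TripRecord(
        trip_id=dep.trip_id, individual_id=dep.individual_id,
        season_id=dep.season_id, species=species, sex=dep.sex,
        frame=frame, in_trip=labels.index.to_numpy(),
        em_labels=merged, em_labels_raw=labels, models=models,
    )


def _build_training_table(records, training_trip_ids, cfg: PipelineConfig):
    parts = []
    for rec in records:
        if rec.trip_id not in training_trip_ids:
            continue
        labelled = pd.DataFrame(
            {"behaviour": rec.em_labels}, index=rec.em_labels.index
        )
        seed = _trip_seed(cfg.seed, "sample:" + rec.trip_id)
        train_idx, pool_idx = supervised.sample_training_rows(
            labelled, cap=cfg.sampling_cap, seed=seed
        )
        rec.train_idx, rec.pool_idx = train_idx, pool_idx
        rows = rec.frame.loc[train_idx, PREDICTORS].copy()
        rows["behaviour"] = rec.em_labels.loc[train_idx]
        rows["individual_id"] = rec.individual_id
        rows["trip_id"] = rec.trip_id
        rows["season_id"] = rec.season_id
        parts.append(rows)
    if not parts:
        raise ValueError("no training rows collected")
    return pd.concat(parts, ignore_index=True)


def _config_hash(cfg: PipelineConfig) -> str:
    from penguinflow.io import dump_config_yaml  # noqa: F401  (same cleaner)
    import dataclasses

    def clean(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: clean(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        return x

    blob = json.dumps(clean(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, mode: str | None = None) -> dict:
    """Full study run; returns the run report (see keys below)."""
    mode = mode or cfg.mode
    if mode not in ("one_season", "two_season"):
        raise ValueError(f"unknown mode {mode!r}")
    t0 = _time.time()
    seasons = list(cfg.synth.seasons)
    if len(seasons) < 2:
        raise ValueError("need two seasons of data")

    deployments, manifest = generate_dataset(cfg.synth)
    records = [r for r in (process_deployment(d, cfg) for d in deployments) if r]
    t_em = _time.time()

    trips_by_season = {
        s: [r.trip_id for r in records if r.season_id == s] for s in seasons
    }
    if mode == "one_season":
        training_ids = set(trips_by_season[seasons[0]])
    else:
        sampled = supervised.sample_trips_two_season(
            trips_by_season, seed=np.random.SeedSequence([cfg.seed, 17])
        )
        training_ids = set().union(*sampled.values())

    table = _build_training_table(records, training_ids, cfg)
    forest = train_forest(
        table,
        tree_grid=cfg.rf.tree_grid,
        mtry=cfg.rf.mtry,
        seed=np.random.SeedSequence([cfg.seed, 23]),
        cv_folds=cfg.rf.cv_folds,
        test_fraction=cfg.rf.test_fraction,
        oob_tolerance=cfg.rf.oob_tolerance,
    )
    t_rf = _time.time()

    per_trip_rows = []
    confusions = []
    for rec in records:
        trained_on = rec.trip_id in training_ids
        if trained_on:
            idx = rec.pool_idx  # leakage guard: training rows excluded
        else:
            idx = rec.in_trip
        if idx is None or len(idx) == 0:
            continue
        pred, _votes = predict_behaviours(forest, rec.frame.loc[idx])
        em = rec.em_labels.loc[idx].to_numpy()
        agr = comparison.agreement(em, pred)
        per_trip_rows.append(
            dict(
                trip_id=rec.trip_id, individual_id=rec.individual_id,
                season_id=rec.season_id, role="trained_on" if trained_on else "predicted",
                agreement=agr, n_samples=len(idx),
            )
        )
        confusions.append(comparison.confusion(em, pred, classes=forest.classes))
    per_trip = pd.DataFrame(per_trip_rows)
    summary = comparison.agreement_summary(per_trip)
    total_confusion = sum(confusions[1:], confusions[0].copy()) if confusions else None
    rpt = comparison.repeatability_table(table)

    report = {
        "mode": mode,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "manifest": manifest,
        "n_deployments": len(deployments),
        "n_trips": len(records),
        "training_trips": sorted(training_ids),
        "training_table_rows": len(table),
        "forest": forest,
        "per_trip_agreement": per_trip,
        "agreement_summary": summary,
        "confusion": total_confusion,
        "repeatability": rpt,
        "records": records,
        "training_table": table,
        "timing_s": {
            "em_and_features": round(t_em - t0, 2),
            "random_forest": round(t_rf - t_em, 2),
            "total": round(_time.time() - t0, 2),
        },
    }
    return report


def run_one_season(cfg: PipelineConfig) -> dict:
    """Train on all Season-1 trips; predict Season-1 hold-out and Season 2."""
    return run_pipeline(cfg, mode="one_season")


def run_two_season(cfg: PipelineConfig) -> dict:
    """Train on half-of-smallest-season trips sampled from both seasons."""
    return run_pipeline(cfg, mode="two_season")


def run_energetics(cfg: PipelineConfig, report: dict) -> dict:
    """Per-trip DEE by both methods on Season-1 trips, plus the OLS comparison.

    The DEE calibration is species-specific to the Adelie penguin; little
    penguin runs are rejected.
    """
    if cfg.synth.species != "adelie":
        raise ValueError("DEE calibration is Adelie-specific")
    season1 = cfg.synth.seasons[0]
    forest = report["forest"]
    coeffs = cfg.dee_coefficients
    fs = cfg.synth.sample_rate_hz

    rows = []
    n_missing_sex = 0
    budgets = []
    for rec in report["records"]:
        if rec.season_id != season1:
            continue
        if rec.sex not in ("F", "M"):
            n_missing_sex += 1
            log.warning("trip %s lacks sex; excluded from energetics", rec.trip_id)
            continue
        idx = rec.in_trip
        duration_h = len(idx) / fs / 3600.0
        vedba = rec.frame.loc[idx, "vedba"].to_numpy()
        em = rec.em_labels.loc[idx].to_numpy()
        rf, _ = predict_behaviours(forest, rec.frame.loc[idx])
        res = {}
        for method, labels in (("EM", em), ("RF", rf)):
            fine = energetics.fine_budget(labels)
            coarse = energetics.coarse_aggregate(fine)
            act_v = energetics.activity_vedba(vedba, labels)
            res[method] = (coarse, act_v,
                           energetics.dee(rec.trip_id, method, rec.sex, act_v,
                                          duration_h, coeffs))
            budgets.append(
                dict(trip_id=rec.trip_id, method=method,
                     **{f"p_{c}": coarse[c] for c in energetics.COARSE_COMPONENTS})
            )
        coarse_em, _, dee_em = res["EM"]
        coarse_rf, _, dee_rf = res["RF"]
        rows.append(
            dict(
                trip_id=rec.trip_id, sex=rec.sex, duration_h=duration_h,
                dee_em=dee_em.dee_kj_day, dee_rf=dee_rf.dee_kj_day,
                total_em=dee_em.total_energy_kj, total_rf=dee_rf.total_energy_kj,
                **{f"diff_{c}": float(coarse_em[c] - coarse_rf[c])
                   for c in energetics.COARSE_COMPONENTS},
            )
        )
    paired = pd.DataFrame(rows)
    out = {
        "paired": paired,
        "budgets": pd.DataFrame(budgets),
        "n_trips": len(paired),
        "n_excluded_missing_sex": n_missing_sex,
        "coefficients_provenance": coeffs.provenance,
    }
    if len(paired) >= 3:
        out["comparison"] = energetics.compare_dee(paired)
    else:
        log.warning("fewer than 3 paired trips; OLS comparison skipped")
    return out
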