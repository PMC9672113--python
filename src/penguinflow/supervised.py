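"""Supervised upscaling: sampling rules, pitch adjustment and Random Forest.

Training rows are drawn per trip and behaviour class under the balanced rule
n* = min(floor(smallest-class-size / 2), 1000), which always leaves at least
half of every class for testing; for the two-season design the number of
trips sampled per season is half the trip count of the smaller season.
Tag-attachment differences are removed by subtracting, per deployment, the
median pitch of near-surface reference samples (depth >= 2 m and pitch < 60
deg for Adelie, depth >= 1 m for little penguins).  The forest is trained
with mtry = 4 variables per split over a tree-count grid (100/500/1000/1500),
selected on minimal OOB-error decrease, and evaluated with a stratified 75/25
split, optional 10-fold cross-validation and one-vs-rest ROC/AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

log = logging.getLogger(__name__)

#: the twelve RF predictors
PREDICTORS = [
    "vedba", "pitch_adj", "depth", "depth_change",
    "sd_heave_2s", "sd_heave_10s", "sd_heave_30s", "sd_heave_60s",
    "sd_roll_30s", "sd_pitch_60s", "sd_vedba_60s", "sd_surge_2s",
]

TREE_GRID = (100, 500, 1000, 1500)
MTRY = 4


def adjust_pitch(frame: pd.DataFrame, species: str) -> pd.DataFrame:
    """Add `pitch_adj` = pitch minus the deployment's near-surface median pitch.

    The reference set proxies the tag's null position: depth >= 2 m with
    pitch < 60 deg (Adelie) or depth >= 1 m (little).  With no reference
    samples the pitch is left unchanged (with a warning).
    """
    pitch = frame["pitch"]
    depth = frame["depth"]
    if species == "adelie":
        ref = (depth >= 2.0) & (pitch < 60.0)
    elif species == "little":
        ref = depth >= 1.0
    else:
        raise ValueError(f"unknown species {species!r}")
    if not ref.any():
        log.warning("no near-surface reference samples; pitch left unadjusted")
        median = 0.0
    else:
        median = float(pitch[ref].median())
    frame = frame.copy()
    frame["pitch_adj"] = pitch - median
    frame.attrs["pitch_reference_median"] = median
    return frame


def training_sample_size(cluster_sizes, cap: int = 1000) -> int:
    """Per-class sample count: min(floor(smallest cluster / 2), cap)."""
    sizes = [int(s) for s in cluster_sizes]
    if not sizes or min(sizes) < 0:
        raise ValueError("cluster sizes must be non-negative and non-empty")
    return min(min(sizes) // 2, cap)


def sample_training_rows(
    labelled: pd.DataFrame,
    label_col: str = "behaviour",
    cap: int = 1000,
    seed=0,
):
    """Per-class uniform draw from one trip; returns (train_idx, pool_idx).

    Classes with fewer than 2 rows are skipped (warned); the remaining rows
    of every class form the prediction pool, so no row is in both sets.
    """
    rng = np.random.default_rng(seed)
    counts = labelled[label_col].value_counts()
    usable = counts[counts >= 2]
    for name in counts.index.difference(usable.index):
        log.warning("class %r has < 2 rows in trip; skipped from training", name)
    if usable.empty:
        raise ValueError("no class with >= 2 rows")
    n_star = training_sample_size(usable.to_numpy(), cap)
    train_idx = []
    for name in usable.index:
        rows = labelled.index[labelled[label_col] == name].to_numpy()
        take = rng.choice(rows, size=min(n_star, len(rows)), replace=False)
        train_idx.append(take)
    train_idx = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], int)
    pool_idx = labelled.index.difference(train_idx).to_numpy()
    return train_idx, pool_idx


def n_trips_two_season(season_sizes) -> int:
    """Trips sampled per season: floor(smallest season's trip count / 2)."""
    sizes = [int(s) for s in season_sizes]
    if len(sizes) != 2 or min(sizes) < 2:
        raise ValueError("need two seasons with at least 2 trips each")
    return min(sizes) // 2


def sample_trips_two_season(trips_by_season: dict, seed=0) -> dict:
    """Uniform per-season draw of floor(min-season/2) trips; rest predicted."""
    rng = np.random.default_rng(seed)
    n = n_trips_two_season([len(v) for v in trips_by_season.values()])
    out = {}
    for season, trips in trips_by_season.items():
        trips = list(trips)
        take = rng.choice(len(trips), size=n, replace=False)
        out[season] = sorted(trips[i] for i in take)
    return out


@dataclass
class ForestModel:
    """Selected random forest plus the evaluation metrics of the whole grid."""

    estimator: RandomForestClassifier
    n_trees: int
    mtry: int
    oob_error: dict[int, float]          # per tree count
    classes: list[str]
    predictors: list[str]
    auc: dict[str, float] = field(default_factory=dict)   # one-vs-rest, hold-out
    cv_accuracy: np.ndarray | None = None
    importances: np.ndarray | None = None
    seed: int | None = None

    def predict(self, rows: pd.DataFrame):
        return predict_behaviours(self, rows)


def train_forest(
    table: pd.DataFrame,
    label_col: str = "behaviour",
    tree_grid=TREE_GRID,
    mtry: int = MTRY,
    seed=0,
    cv_folds: int = 10,
    test_fraction: float = 0.25,
    oob_tolerance: float = 0.002,
) -> ForestModel:
    """Train forests over the tree grid and select on minimal OOB decrease.

    The selection takes the smallest tree count whose OOB error is within
    `oob_tolerance` of the grid minimum.  ROC/AUC is computed one-vs-rest on
    the stratified hold-out; `cv_folds` > 0 adds a stratified k-fold CV
    accuracy estimate on the training split.
    """
    missing = [c for c in PREDICTORS if c not in table.columns]
    if missing:
        raise KeyError(f"missing predictor column(s): {missing}")
    y = table[label_col]
    if y.nunique() < 2:
        raise ValueError("training table needs at least 2 classes")
    X = table[PREDICTORS]
    rng_seed = int(np.random.default_rng(seed).integers(2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=rng_seed
    )

    forests, oob = {}, {}
    for n_trees in tree_grid:
        rf = RandomForestClassifier(
            n_estimators=int(n_trees), max_features=mtry, oob_score=True,
            random_state=rng_seed, n_jobs=1,
        )
        rf.fit(X_tr, y_tr)
        forests[n_trees] = rf
        oob[n_trees] = 1.0 - rf.oob_score_

    best_oob = min(oob.values())
    selected = min(n for n, e in oob.items() if e <= best_oob + oob_tolerance)
    rf = forests[selected]

    proba = rf.predict_proba(X_te)
    classes = list(rf.classes_)
    auc = {}
    y_bin = pd.get_dummies(y_te).reindex(columns=classes, fill_value=0)
    for i, cls in enumerate(classes):
        if y_bin[cls].nunique() < 2:
            auc[cls] = float("nan")
        else:
            auc[cls] = float(roc_auc_score(y_bin[cls], proba[:, i]))

    cv_scores = None
    if cv_folds and cv_folds > 1:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
        cv_scores = cross_val_score(
            RandomForestClassifier(
                n_estimators=selected, max_features=mtry,
                random_state=rng_seed, n_jobs=1,
            ),
            X_tr, y_tr, cv=skf, scoring="accuracy",
        )

    return ForestModel(
        estimator=rf, n_trees=selected, mtry=mtry, oob_error=oob,
        classes=classes, predictors=list(PREDICTORS), auc=auc,
        cv_accuracy=cv_scores, importances=rf.feature_importances_, seed=seed,
    )


def predict_behaviours(model: ForestModel, rows: pd.DataFrame):
    """Majority-vote class and per-class vote fractions for feature rows."""
    missing = [c for c in model.predictors if c not in rows.columns]
    if missing:
        raise KeyError(f"missing predictor column(s): {missing}")
    X = rows[model.predictors]
    votes = model.estimator.predict_proba(X)
    pred = np.asarray(model.classes)[np.argmax(votes, axis=1)]
    votes = pd.DataFrame(votes, columns=model.classes, index=rows.index)
    return pred, votes
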