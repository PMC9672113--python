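"""Cross-method agreement, confusion structure and repeatability.

Agreement is the raw proportion of samples assigned the same behaviour class
by the unsupervised (EM) and supervised (RF) routes, reported per trip and
summarised (mean +/- sd) by role group (trained-on vs predicted, by season).
Repeatability R = V_between / (V_between + V_within) is estimated from
one-way variance components with the individual bird as the grouping factor
(Lessells & Boag moment estimator, unbalanced-design coefficient n0), for
pitch and VeDBA within each behaviour: values near 0 mean high
within-individual or low between-individual variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def agreement(em_labels, rf_labels) -> float:
    """Proportion of samples with identical class in the two label vectors."""
    em = np.asarray(em_labels)
    rf = np.asarray(rf_labels)
    if em.shape != rf.shape:
        raise ValueError(f"label vectors differ in length: {em.shape} vs {rf.shape}")
    if em.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(em == rf))


def agreement_summary(per_trip: pd.DataFrame, group_cols=("role", "season_id")) -> pd.DataFrame:
    """Mean +/- sd of per-trip agreement within each role group."""
    g = per_trip.groupby(list(group_cols))["agreement"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "agreement_mean", "std": "agreement_sd", "count": "n_trips"})


def confusion(em_labels, rf_labels, classes=None) -> pd.DataFrame:
    """Counts matrix (EM rows x RF columns); marginals conserved by construction."""
    em = np.asarray(em_labels)
    rf = np.asarray(rf_labels)
    if em.shape != rf.shape:
        raise ValueError("label vectors differ in length")
    if classes is None:
        classes = sorted(set(em) | set(rf))
    else:
        unknown = (set(em) | set(rf)) - set(classes)
        if unknown:
            raise ValueError(f"unknown class(es): {sorted(unknown)}")
    mat = pd.crosstab(pd.Series(em, name="em"), pd.Series(rf, name="rf"))
    mat = mat.reindex(index=classes, columns=classes, fill_value=0)
    mat.index.name, mat.columns.name = "em", "rf"
    return mat


def confusion_rates(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-class recall (over EM rows) and precision (over RF columns)."""
    diag = np.diag(mat.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = diag / mat.sum(axis=1).to_numpy()
        precision = diag / mat.sum(axis=0).to_numpy()
    return pd.DataFrame({"recall": recall, "precision": precision}, index=mat.index)


@dataclass(frozen=True)
class RepeatabilityResult:
    behaviour: str
    variable: str
    R: float
    var_between: float
    var_within: float
    n_groups: int
    n_obs: int


def repeatability_anova(values, groups, behaviour: str = "", variable: str = "") -> RepeatabilityResult:
    """One-way variance-components repeatability (Lessells & Boag 1987 form).

    V_between = (MS_among - MS_within) / n0, truncated at 0, with
    n0 = (N - sum(n_i^2)/N) / (a - 1) the unbalanced-design group size.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    uniq, inv = np.unique(groups, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 individuals")
    n_i = np.bincount(inv)
    if (n_i < 2).any():
        log.warning("group(s) with a single observation in repeatability")
    N = int(n_i.sum())
    grand = values.mean()
    group_means = np.bincount(inv, weights=values) / n_i
    ss_among = float(np.sum(n_i * (group_means - grand) ** 2))
    ss_within = float(np.sum((values - group_means[inv]) ** 2))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - np.sum(n_i ** 2) / N) / (a - 1)
    var_between = max(0.0, (ms_among - ms_within) / n0)
    var_within = ms_within
    total = var_between + var_within
    R = float(np.clip(var_between / total if total > 0 else 0.0, 0.0, 1.0))
    return RepeatabilityResult(behaviour, variable, R, var_between, var_within, a, N)


def repeatability_table(
    table: pd.DataFrame,
    variables=("pitch_adj", "vedba"),
    label_col: str = "behaviour",
    group_col: str = "individual_id",
) -> pd.DataFrame:
    """Repeatability of each variable within each behaviour of a training table."""
    rows = []
    for behaviour, sub in table.groupby(label_col):
        if sub[group_col].nunique() < 2:
            log.warning("behaviour %r has a single individual; skipped", behaviour)
            continue
        for var in variables:
            r = repeatability_anova(sub[var], sub[group_col], behaviour, var)
            rows.append(
                dict(behaviour=behaviour, variable=var, R=r.R,
                     var_between=r.var_between, var_within=r.var_within,
                     n_individuals=r.n_groups, n_obs=r.n_obs)
            )
    return pd.DataFrame(rows)
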