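"""Activity budgets, activity-specific VeDBA and daily energy expenditure.

Fine behaviour labels are aggregated into three coarse components —
`preen_flap_water`, `water` (all swimming and within-dive behaviours) and
`land_ice` — matching the component structure of the Adelie DEE calibration.
Activity-specific VeDBA for component c is the time-weighted mean
V_c = sum(VeDBA over samples in c) / (total trip samples), so the components
decompose the trip-mean VeDBA exactly.  DEE follows the linear form

    DEE = beta0 + beta_sex * 1[male] + sum_c beta_c * V_c        [kJ/day]

with coefficients supplied by configuration (the published calibration is an
external input, never re-derived here; package defaults are synthetic
placeholders and are flagged as such).  Total trip energy = DEE * hours / 24.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

COARSE_COMPONENTS = ("preen_flap_water", "water", "land_ice")

COARSE_MAP = {
    "preen_flap_water": "preen_flap_water",
    "descend": "water",
    "ascend": "water",
    "hunt": "water",
    "swim_cruise": "water",
    "swim_cruise_2": "water",
    "slow_surface_swim": "water",
    "swim_porpoise": "water",
    "still": "water",
    "walk": "land_ice",
    "stand": "land_ice",
    "lie_toboggan": "land_ice",
    "preen_flap_land": "land_ice",
}


@dataclass(frozen=True)
class DEECoefficients:
    """Linear DEE model coefficients (kJ/day per unit activity-specific VeDBA)."""

    beta0: float
    beta_sex_male: float
    betas: dict[str, float]  # per coarse component
    provenance: str = "synthetic-demo placeholder (not published values)"


#: closed-loop default used by the test-suite; NOT a published calibration
SYNTHETIC_COEFFICIENTS = DEECoefficients(
    beta0=1500.0,
    beta_sex_male=150.0,
    betas={"preen_flap_water": 900.0, "water": 2400.0, "land_ice": 600.0},
)


def fine_budget(labels) -> pd.Series:
    """Proportion of trip samples per fine behaviour class."""
    s = pd.Series(labels)
    n = len(s)
    if n == 0:
        raise ValueError("no labels")
    n_missing = s.isna().sum()
    if n_missing > 0.01 * n:
        log.warning("unlabelled gap covers %.1f%% of trip", 100 * n_missing / n)
    return s.value_counts(normalize=True, dropna=True).sort_index()


def coarse_aggregate(fine: pd.Series) -> pd.Series:
    """Aggregate a fine budget into the three coarse components (exactly)."""
    unknown = set(fine.index) - set(COARSE_MAP)
    if unknown:
        raise ValueError(f"unknown behaviour class(es): {sorted(unknown)}")
    coarse = fine.groupby(fine.index.map(COARSE_MAP)).sum()
    return coarse.reindex(COARSE_COMPONENTS, fill_value=0.0)


def activity_vedba(vedba, labels) -> pd.Series:
    """Time-weighted component VeDBA: V_c sums to the trip-mean VeDBA."""
    vedba = np.asarray(vedba, dtype=float)
    coarse = pd.Series(labels).map(COARSE_MAP)
    if coarse.isna().any():
        bad = sorted(set(np.asarray(labels)[coarse.isna().to_numpy()]))
        raise ValueError(f"unknown behaviour class(es): {bad}")
    df = pd.DataFrame({"vedba": vedba, "component": coarse.to_numpy()})
    v = df.groupby("component")["vedba"].sum() / len(df)
    return v.reindex(COARSE_COMPONENTS, fill_value=0.0)


@dataclass(frozen=True)
class DEEResult:
    trip_id: str
    method: str
    sex: str
    activity_vedba: pd.Series
    dee_kj_day: float
    total_energy_kj: float
    duration_h: float
    coefficients: DEECoefficients = field(repr=False, default=SYNTHETIC_COEFFICIENTS)


def dee(
    trip_id: str,
    method: str,
    sex: str,
    act_vedba: pd.Series,
    duration_h: float,
    coefficients: DEECoefficients,
) -> DEEResult:
    """Daily energy expenditure and total trip energy for one trip/method."""
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    value = coefficients.beta0 + coefficients.beta_sex_male * (sex == "M")
    for comp in COARSE_COMPONENTS:
        value += coefficients.betas.get(comp, 0.0) * float(act_vedba.get(comp, 0.0))
    return DEEResult(
        trip_id=trip_id, method=method, sex=sex, activity_vedba=act_vedba,
        dee_kj_day=float(value), total_energy_kj=float(value * duration_h / 24.0),
        duration_h=duration_h, coefficients=coefficients,
    )


def compare_dee(paired: pd.DataFrame):
    """OLS agreement models between the two methods' DEE estimates.

    `paired` needs columns dee_em, dee_rf and (optionally) per-component
    budget differences named diff_<component>.  Fits dee_em ~ dee_rf plus
    every subset of the difference covariates, reports coefficients, adjusted
    R^2 and AIC per model, flags the lowest-AIC model and any covariate pair
    with |correlation| > 0.8.
    """
    if len(paired) < 3:
        raise ValueError("need at least 3 paired trips")
    diff_cols = [c for c in paired.columns if c.startswith("diff_")]
    usable = []
    for c in diff_cols:
        if np.ptp(paired[c].to_numpy()) == 0:
            log.warning("constant covariate %r skipped", c)
        else:
            usable.append(c)

    models = []
    for r in range(len(usable) + 1):
        for combo in itertools.combinations(usable, r):
            cols = ["dee_rf", *combo]
            X = sm.add_constant(paired[cols])
            fit = sm.OLS(paired["dee_em"], X).fit()
            models.append(
                dict(
                    covariates=cols,
                    params=fit.params.to_dict(),
                    aic=float(fit.aic),
                    adj_r2=float(fit.rsquared_adj),
                    pvalues=fit.pvalues.to_dict(),
                )
            )
    best = min(models, key=lambda m: m["aic"])
    collinear = []
    cols = ["dee_rf", *usable]
    corr = paired[cols].corr()
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if abs(corr.loc[a, b]) > 0.8:
                collinear.append((a, b, float(corr.loc[a, b])))
    return {"models": models, "best": best, "collinear_pairs": collinear}
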