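"""Synthetic penguin deployments with known per-sample behaviour labels.

A deployment emulates one logger record from an "Axy-Trek-like" tag: tri-axial
acceleration (surge/sway/heave, in g) at 25 Hz plus pressure (mbar) and
temperature (degC) at 1 Hz.  Behaviour sequencing is a semi-Markov chain
(exponential dwell times, 1 s minimum) organised into contexts — land/ice
blocks, surface phases and dive cycles (descend / bottom hunting & cruising /
ascend) — so that dive-context behaviours only occur at depth and the depth
trace integrates each behaviour's vertical speed.  Emissions place the gravity
vector at the behaviour's target pitch/roll (per-individual, per-season and
per-deployment tag-attachment offsets applied) and add zero-mean dynamic noise
calibrated so the VeDBA recovered downstream matches the configured mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

CHI3_MEAN = math.sqrt(2.0) * math.gamma(2.0) / math.gamma(1.5)  # E|N(0,I_3)|


def stable_hash(s: str) -> int:
    """Process-independent 31-bit hash for seed derivation."""
    import hashlib as _hashlib

    return int.from_bytes(
        _hashlib.blake2s(s.encode(), digest_size=4).digest(), "little"
    ) & 0x7FFFFFFF

DIVE, SURFACE, LAND = "dive", "surface", "land_ice"


@dataclass(frozen=True)
class Behaviour:
    """Emission and sequencing parameters for one behavioural class."""

    context: str                 # dive | surface | land_ice
    mean_dwell_s: float
    transitions: dict[str, float]  # within-context successor probabilities
    pitch_deg: float             # target posture
    pitch_sd_deg: float          # within-bout posture jitter (AR(1) sd)
    vedba_g: float               # target mean recovered VeDBA
    vedba_sd_g: float            # between-bout intensity jitter
    heave_amp_g: float           # extra dorso-ventral dynamics (hunt: wiggle)
    roll_amp_deg: float          # slow roll oscillation amplitude
    vertical_speed_ms: float     # m/s, positive = going deeper


def _adelie_grammar() -> dict[str, Behaviour]:
    g = {
        # diving
        "descend": Behaviour(DIVE, 10, {}, -60, 4, 0.25, 0.03, 0.05, 2, 1.2),
        "ascend": Behaviour(DIVE, 10, {}, 55, 4, 0.30, 0.03, 0.05, 2, -1.2),
        "hunt": Behaviour(DIVE, 12, {"swim_cruise": 1.0}, -15, 6, 0.80, 0.08, 0.35, 4, 0.0),
        "swim_cruise": Behaviour(
            DIVE, 20, {"hunt": 0.85, "swim_cruise_2": 0.15}, 0, 3, 0.20, 0.02, 0.05, 2, 0.0
        ),
        # rare variant; emission deliberately identical to swim_cruise (the
        # variant signal structure is disabled by default)
        "swim_cruise_2": Behaviour(
            DIVE, 15, {"hunt": 0.6, "swim_cruise": 0.4}, 0, 3, 0.20, 0.02, 0.05, 2, 0.0
        ),
        # surface
        "slow_surface_swim": Behaviour(
            SURFACE, 25, {"swim_porpoise": 0.5, "preen_flap_water": 0.5},
            5, 4, 0.15, 0.02, 0.04, 3, 0.0,
        ),
        "swim_porpoise": Behaviour(
            SURFACE, 12, {"slow_surface_swim": 1.0}, 10, 5, 0.90, 0.08, 0.30, 5, 0.0
        ),
        "preen_flap_water": Behaviour(
            SURFACE, 15, {"slow_surface_swim": 1.0}, 0, 5, 0.40, 0.05, 0.10, 40, 0.0
        ),
        # land / ice
        "walk": Behaviour(
            LAND, 20, {"stand": 0.5, "lie_toboggan": 0.3, "preen_flap_land": 0.2},
            80, 4, 0.50, 0.05, 0.15, 5, 0.0,
        ),
        "stand": Behaviour(
            LAND, 30, {"walk": 0.5, "lie_toboggan": 0.3, "preen_flap_land": 0.2},
            80, 3, 0.05, 0.01, 0.01, 2, 0.0,
        ),
        "lie_toboggan": Behaviour(
            LAND, 40, {"stand": 0.6, "walk": 0.4}, 5, 4, 0.10, 0.02, 0.05, 3, 0.0
        ),
        "preen_flap_land": Behaviour(
            LAND, 15, {"stand": 0.5, "walk": 0.5}, 45, 5, 0.40, 0.05, 0.10, 35, 0.0
        ),
    }
    return g


def _little_grammar() -> dict[str, Behaviour]:
    g = _adelie_grammar()
    for name in ("stand", "lie_toboggan", "preen_flap_land"):
        del g[name]
    # little penguins: resting afloat ("still") instead of ice behaviours;
    # the single land-context class covers colony attendance ashore
    g["walk"] = replace(g["walk"], transitions={"walk": 1.0})
    g["slow_surface_swim"] = replace(
        g["slow_surface_swim"],
        transitions={"swim_porpoise": 0.35, "preen_flap_water": 0.35, "still": 0.3},
    )
    g["still"] = Behaviour(SURFACE, 30, {"slow_surface_swim": 1.0}, 10, 3, 0.02, 0.005, 0.0, 1, 0.0)
    return g


@dataclass
class SynthConfig:
    """Study-design and emission parameters for the synthetic generator."""

    species: str = "adelie"
    n_individuals_per_season: int = 20
    trips_per_individual: int = 1
    seasons: tuple[str, ...] = ("S1", "S2")
    sample_rate_hz: int = 25
    behaviour_grammar: dict[str, Behaviour] = field(default_factory=_adelie_grammar)
    individual_effect_sd: dict[str, float] = field(
        default_factory=lambda: {"pitch_deg": 3.0, "vedba_g": 0.02}
    )
    season_effect: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "S1": {"pitch_deg": 0.0, "vedba_g": 0.0},
            "S2": {"pitch_deg": 2.0, "vedba_g": 0.02},
        }
    )
    tag_pitch_offset_sd: float = 5.0
    water_temp_c: float = -1.0
    land_temp_c: float = 8.0
    separation: float = 1.0     # scales between-behaviour emission contrast
    seed: int = 42
    # deployment structure (seconds)
    land_block_s: float = 150.0
    at_sea_duration_s: float = 360.0
    surface_phase_mean_s: float = 45.0
    surface_phase_bounds_s: tuple[float, float] = (20.0, 100.0)
    bottom_phase_mean_s: float = 45.0
    bottom_phase_bounds_s: tuple[float, float] = (15.0, 90.0)
    dive_depth_range_m: tuple[float, float] = (6.0, 22.0)
    ice_rest_prob: float = 0.18      # per dive cycle, Adelie only
    ice_rest_mean_s: float = 90.0
    ice_rest_bounds_s: tuple[float, float] = (45.0, 200.0)
    surface_draft_m: float = 0.35    # sensor submersion while at the surface
    atm_pressure_mbar: float = 1013.0
    pressure_noise_mbar: float = 0.3
    missing_sex_prob: float = 0.1
    roll_freq_hz: float = 0.08
    wiggle_freq_hz: float = 3.0

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_individuals_per_season <= 0:
            raise ValueError("need at least one individual per season")
        if not 1 <= self.trips_per_individual <= 3:
            raise ValueError("trips_per_individual must be in 1..3")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not self.behaviour_grammar:
            raise ValueError("behaviour grammar is empty")
        contexts = set()
        for name, b in self.behaviour_grammar.items():
            if b.mean_dwell_s <= 0:
                raise ValueError(f"non-positive dwell for {name!r}")
            if min(b.pitch_sd_deg, b.vedba_sd_g, b.heave_amp_g, b.roll_amp_deg) < 0:
                raise ValueError(f"negative emission SD/amplitude for {name!r}")
            for succ in b.transitions:
                if succ not in self.behaviour_grammar:
                    raise ValueError(f"dangling transition {name!r} -> {succ!r}")
            contexts.add(b.context)


def default_config(species: str = "adelie", **overrides) -> SynthConfig:
    """Default study conditions for one species (Adelie: 12 classes, little: 10)."""
    if species == "adelie":
        cfg = SynthConfig(species="adelie", behaviour_grammar=_adelie_grammar())
    elif species == "little":
        cfg = SynthConfig(
            species="little",
            behaviour_grammar=_little_grammar(),
            dive_depth_range_m=(3.0, 10.0),
            ice_rest_prob=0.0,
        )
    else:
        raise ValueError(f"unknown species {species!r}")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class RawDeployment:
    """One logger record: 25 Hz acceleration, 1 Hz pressure/temperature."""

    individual_id: str
    season_id: str
    trip_id: str
    species: str
    time: np.ndarray          # s from start, at sample_rate_hz
    ax: np.ndarray            # surge, g
    ay: np.ndarray            # sway, g
    az: np.ndarray            # heave, g
    pressure_time: np.ndarray  # s, 1 Hz
    pressure_mbar: np.ndarray
    temp_c: np.ndarray
    sample_rate_hz: int = 25
    true_labels: np.ndarray | None = None   # per 25 Hz sample
    true_context: np.ndarray | None = None  # per second
    sex: str | None = None
    tag_pitch_offset_deg: float = 0.0

    @property
    def n_samples(self) -> int:
        return len(self.time)


# --------------------------------------------------------------------------
# sequencing

def _trunc_exp(rng, mean, lo=1.0, hi=None):
    d = rng.exponential(mean)
    d = max(lo, d)
    if hi is not None:
        d = min(hi, d)
    return int(round(d))


def _semi_markov(rng, grammar, context, total_s, start=None):
    """Bout list [(behaviour, seconds)] covering total_s within one context."""
    states = [n for n, b in grammar.items() if b.context == context]
    if not states:
        raise ValueError(f"behaviour grammar has no state in context {context!r}")
    cur = start if start is not None else states[int(rng.integers(len(states)))]
    bouts, t = [], 0
    while t < total_s:
        b = grammar[cur]
        dur = min(_trunc_exp(rng, b.mean_dwell_s), int(total_s) - t)
        dur = max(dur, 1)
        bouts.append((cur, dur))
        t += dur
        succ = b.transitions
        if succ:
            names = list(succ)
            probs = np.array([succ[n] for n in names], dtype=float)
            cur = names[int(rng.choice(len(names), p=probs / probs.sum()))]
        # absorbing state: stay
    return bouts


def _schedule(cfg: SynthConfig, rng) -> list[tuple[str, int, str, float]]:
    """Per-bout schedule: (behaviour, seconds, context, vertical speed m/s).

    Dive cycles are built explicitly so ascent returns exactly to the surface.
    """
    g = cfg.behaviour_grammar
    out: list[tuple[str, int, str, float]] = []

    def land_block(seconds):
        for name, dur in _semi_markov(rng, g, LAND, seconds):
            out.append((name, dur, LAND, 0.0))

    def surface_block(seconds):
        for name, dur in _semi_markov(rng, g, SURFACE, seconds):
            out.append((name, dur, SURFACE, 0.0))

    has_land = any(b.context == LAND for b in g.values())
    has_dive = any(b.context == DIVE for b in g.values())
    if has_land:
        land_block(cfg.land_block_s)

    t_sea = 0.0
    while t_sea < cfg.at_sea_duration_s:
        lo, hi = cfg.surface_phase_bounds_s
        s_dur = _trunc_exp(rng, cfg.surface_phase_mean_s, lo, hi)
        surface_block(s_dur)
        t_sea += s_dur
        if not has_dive or t_sea >= cfg.at_sea_duration_s:
            continue
        # one dive cycle
        depth = rng.uniform(*cfg.dive_depth_range_m)
        v_desc = abs(g["descend"].vertical_speed_ms)
        v_asc = abs(g["ascend"].vertical_speed_ms)
        d_sec = max(2, int(round(depth / v_desc)))
        depth_reached = d_sec * v_desc
        out.append(("descend", d_sec, DIVE, depth_reached / d_sec))
        blo, bhi = cfg.bottom_phase_bounds_s
        b_dur = _trunc_exp(rng, cfg.bottom_phase_mean_s, blo, bhi)
        for name, dur in _semi_markov(rng, g, DIVE, b_dur, start="swim_cruise"):
            if name in ("descend", "ascend"):
                name = "swim_cruise"
            out.append((name, dur, DIVE, 0.0))
        a_sec = max(2, int(round(depth_reached / v_asc)))
        out.append(("ascend", a_sec, DIVE, -depth_reached / a_sec))
        t_sea += d_sec + b_dur + a_sec
        if has_land and cfg.ice_rest_prob > 0 and rng.random() < cfg.ice_rest_prob:
            ilo, ihi = cfg.ice_rest_bounds_s
            i_dur = _trunc_exp(rng, cfg.ice_rest_mean_s, ilo, ihi)
            land_block(i_dur)
            t_sea += i_dur
    if has_land:
        land_block(cfg.land_block_s)
    return out


# --------------------------------------------------------------------------
# emission calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(16)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _expected_norm(sx: float, sy: float, sz: float, wiggle_amp: float) -> float:
    """E||(sx Z1, sy Z2, sz Z3 + A sin(phase))|| by Gauss-Hermite quadrature."""
    z = _GH_NODES
    w = _GH_WEIGHTS
    phases = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    x = sx * z[:, None, None, None]
    y = sy * z[None, :, None, None]
    if wiggle_amp > 0:
        h = sz * z[None, None, :, None] + wiggle_amp * np.sin(phases)[None, None, None, :]
    else:
        h = sz * z[None, None, :, None] + np.zeros(1)[None, None, None, :]
    norms = np.sqrt(x * x + y * y + h * h)
    ww = w[:, None, None, None] * w[None, :, None, None] * w[None, None, :, None]
    return float((norms * ww).mean(axis=-1).sum())


def _scaled_emissions(cfg: SynthConfig) -> dict[str, dict[str, float]]:
    """Apply the separation contrast to pitch/VeDBA/amplitude emissions.

    Vertical speeds are left untouched: they are the kinematic scaffolding of
    the dive profile, not a signal-contrast parameter.
    """
    g = cfg.behaviour_grammar
    names = list(g)
    mean_pitch = float(np.mean([g[n].pitch_deg for n in names]))
    mean_vedba = float(np.mean([g[n].vedba_g for n in names]))
    mean_heave = float(np.mean([g[n].heave_amp_g for n in names]))
    mean_roll = float(np.mean([g[n].roll_amp_deg for n in names]))
    s = cfg.separation
    out = {}
    for n in names:
        b = g[n]
        out[n] = {
            "pitch": mean_pitch + s * (b.pitch_deg - mean_pitch),
            "vedba": max(0.005, mean_vedba + s * (b.vedba_g - mean_vedba)),
            "heave_amp": max(0.0, mean_heave + s * (b.heave_amp_g - mean_heave)),
            "roll_amp": max(0.0, mean_roll + s * (b.roll_amp_deg - mean_roll)),
        }
    return out


def _deployment_rng(cfg: SynthConfig, season_id: str, individual_id: str, trip_id: str):
    key = [cfg.seed, stable_hash(season_id), stable_hash(individual_id),
           stable_hash(trip_id)]
    return np.random.default_rng(np.random.SeedSequence(key))


def individual_effects(cfg: SynthConfig, season_id: str, individual_id: str):
    """Per-individual mean shifts, drawn once per individual (seed-stable)."""
    key = [cfg.seed, 7919, stable_hash(season_id), stable_hash(individual_id)]
    rng = np.random.default_rng(np.random.SeedSequence(key))
    d_pitch = rng.normal(0.0, cfg.individual_effect_sd.get("pitch_deg", 0.0))
    d_vedba = rng.normal(0.0, cfg.individual_effect_sd.get("vedba_g", 0.0))
    sex = "F" if rng.random() < 0.5 else "M"
    if rng.random() < cfg.missing_sex_prob:
        sex = None
    return d_pitch, d_vedba, sex


def generate_deployment(
    cfg: SynthConfig, individual_id: str, season_id: str, trip_id: str
) -> RawDeployment:
    """Simulate one deployment; fully reproducible from (config, ids)."""
    cfg.validate()
    if season_id not in cfg.seasons:
        raise ValueError(f"unknown season {season_id!r}")
    fs = cfg.sample_rate_hz
    rng = _deployment_rng(cfg, season_id, individual_id, trip_id)
    ind_pitch, ind_vedba, sex = individual_effects(cfg, season_id, individual_id)
    sea = cfg.season_effect.get(season_id, {})
    sea_pitch, sea_vedba = sea.get("pitch_deg", 0.0), sea.get("vedba_g", 0.0)
    tag_offset = rng.normal(0.0, cfg.tag_pitch_offset_sd)

    bouts = _schedule(cfg, rng)
    n_sec = int(sum(d for _, d, _, _ in bouts))
    n = n_sec * fs
    emis = _scaled_emissions(cfg)
    g = cfg.behaviour_grammar

    # per-second context/label/vertical-speed, then depth by integration
    sec_label = np.empty(n_sec, dtype=object)
    sec_ctx = np.empty(n_sec, dtype=object)
    sec_vs = np.zeros(n_sec)
    t0 = 0
    for name, dur, ctx, vs in bouts:
        sec_label[t0:t0 + dur] = name
        sec_ctx[t0:t0 + dur] = ctx
        sec_vs[t0:t0 + dur] = vs
        t0 += dur
    depth_sec = np.cumsum(sec_vs)
    depth_sec = np.where(np.abs(depth_sec) < 1e-9, 0.0, depth_sec)
    # surface draft + slow bobbing (kept clear of the 0.5 m submergence cut)
    at_surface = (sec_ctx == SURFACE)
    bob = np.zeros(n_sec)
    alpha = 0.85
    for i in np.flatnonzero(at_surface):
        prev = bob[i - 1] if i > 0 and at_surface[i - 1] else 0.0
        bob[i] = alpha * prev + rng.normal(0, 0.02)
    depth_sec = np.where(
        at_surface, np.clip(cfg.surface_draft_m + bob, 0.25, 0.45), depth_sec
    )
    depth_sec = np.where(sec_ctx == LAND, 0.0, depth_sec)

    pressure = cfg.atm_pressure_mbar + depth_sec * 100.0 + rng.normal(
        0, cfg.pressure_noise_mbar, n_sec
    )
    temp = np.where(depth_sec > 0.2, cfg.water_temp_c, cfg.land_temp_c) + rng.normal(
        0, 0.05, n_sec
    )

    # 25 Hz emission synthesis -------------------------------------------
    labels = np.repeat(sec_label, fs)
    t = np.arange(n) / fs

    pitch_target = np.empty(n)
    roll_amp = np.empty(n)
    pitch_sd = np.empty(n)
    sig_x = np.empty(n)
    sig_y = np.empty(n)
    sig_z = np.empty(n)
    wig_amp = np.empty(n)
    roll_phase = np.empty(n)
    wig_phase = np.empty(n)

    shrink = math.sqrt(1.0 - 1.0 / (2 * fs))  # 2 s running-mean leakage
    cal_cache: dict[str, tuple[float, float, float, float]] = {}
    i0 = 0
    for name, dur, ctx, _vs in bouts:
        m = dur * fs
        sl = slice(i0, i0 + m)
        e = emis[name]
        b = g[name]
        target_v = max(0.005, e["vedba"] + ind_vedba + sea_vedba
                       + rng.normal(0, b.vedba_sd_g))
        if name not in cal_cache:
            base_v = max(0.005, e["vedba"] + ind_vedba + sea_vedba)
            s0 = base_v / CHI3_MEAN
            is_hunt = name == "hunt"
            a0 = 0.0 if is_hunt else e["heave_amp"]
            w0 = e["heave_amp"] if is_hunt else 0.0
            e_norm = _expected_norm(
                s0 * shrink, s0 * shrink,
                math.hypot(s0, a0) * shrink, w0,
            )
            cal_cache[name] = (s0, a0, w0, e_norm)
        s0, a0, w0, e_norm = cal_cache[name]
        lam = target_v / max(e_norm, 1e-12)
        sig_x[sl] = lam * s0
        sig_y[sl] = lam * s0
        sig_z[sl] = lam * math.hypot(s0, a0)
        wig_amp[sl] = lam * w0
        pitch_target[sl] = e["pitch"] + ind_pitch + sea_pitch + tag_offset
        pitch_sd[sl] = b.pitch_sd_deg
        roll_amp[sl] = e["roll_amp"]
        roll_phase[sl] = rng.uniform(0, 2 * np.pi)
        wig_phase[sl] = rng.uniform(0, 2 * np.pi)
        i0 += m

    # AR(1) posture jitter (tau ~ 1 s), unit stationary sd, scaled per bout
    a_coef = math.exp(-1.0 / fs)
    innov_sd = math.sqrt(1 - a_coef ** 2)
    ar_innov = rng.normal(0, innov_sd, n)
    ar_innov[0] = rng.normal()
    ar = lfilter([1.0], [1.0, -a_coef], ar_innov)

    pitch = np.clip(pitch_target + pitch_sd * ar, -89.5, 89.5)
    roll = roll_amp * np.sin(2 * np.pi * cfg.roll_freq_hz * t + roll_phase)

    pr = np.deg2rad(pitch)
    rr = np.deg2rad(roll)
    static_x = np.sin(pr)
    static_y = np.cos(pr) * np.sin(rr)
    static_z = np.cos(pr) * np.cos(rr)

    dyn_x = rng.normal(0, 1, n) * sig_x
    dyn_y = rng.normal(0, 1, n) * sig_y
    dyn_z = rng.normal(0, 1, n) * sig_z
    dyn_z = dyn_z + wig_amp * np.sin(2 * np.pi * cfg.wiggle_freq_hz * t + wig_phase)

    return RawDeployment(
        individual_id=individual_id,
        season_id=season_id,
        trip_id=trip_id,
        species=cfg.species,
        time=t,
        ax=static_x + dyn_x,
        ay=static_y + dyn_y,
        az=static_z + dyn_z,
        pressure_time=np.arange(n_sec, dtype=float),
        pressure_mbar=pressure,
        temp_c=temp,
        sample_rate_hz=fs,
        true_labels=labels,
        true_context=sec_ctx,
        sex=sex,
        tag_pitch_offset_deg=float(tag_offset),
    )


def generate_dataset(cfg: SynthConfig):
    """All deployments of the study design plus a manifest table.

    Returns (deployments, manifest): n_individuals_per_season x
    trips_per_individual deployments per season; individual effects are drawn
    once per individual, the tag-attachment pitch offset once per deployment.
    """
    cfg.validate()
    deployments: list[RawDeployment] = []
    rows = []
    for season in cfg.seasons:
        for i in range(cfg.n_individuals_per_season):
            ind = f"{season}_I{i:03d}"
            for k in range(cfg.trips_per_individual):
                trip = f"{ind}_T{k}"
                dep = generate_deployment(cfg, ind, season, trip)
                deployments.append(dep)
                rows.append(
                    dict(
                        individual_id=ind,
                        season_id=season,
                        trip_id=trip,
                        species=cfg.species,
                        sex=dep.sex,
                        n_samples=dep.n_samples,
                        tag_pitch_offset_deg=dep.tag_pitch_offset_deg,
                    )
                )
    return deployments, pd.DataFrame(rows)
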