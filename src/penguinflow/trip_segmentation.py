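"""Foraging-trip detection and coarse subset splitting.

A trip is bracketed by the first and last at-sea sample, where "at sea" means
the temperature has dropped below the water/land midpoint or the depth exceeds
the species' dive threshold; separate trips are split on a sustained
(>= 30 min by default) land signature.  Within a trip every sample is assigned
to exactly one coarse subset: `diving` (contiguous submerged episodes whose
maximum depth exceeds the species threshold — 2 m for Adelie, 1 m for little
penguins, strict), `land_ice` (Adelie only: positive temperatures, walking
posture reinforcing) or `surface`.  Short runs (< 3 s) are absorbed into their
neighbours so the mixture clustering never sees single-sample segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIVE_THRESHOLD_M = {"adelie": 2.0, "little": 1.0}
SUBSETS = ("diving", "surface", "land_ice")


@dataclass(frozen=True)
class Segment:
    """Maximal run of one subset within a trip; [start, end) on the 25 Hz frame."""

    trip_id: str
    subset: str
    start: int
    end: int
    species: str

    def __len__(self) -> int:
        return self.end - self.start


def _runs(mask: np.ndarray):
    """Start/end pairs (half-open) of True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return list(zip(idx[0::2], idx[1::2]))


def detect_trips(
    frame: pd.DataFrame,
    water_temp_c: float = -1.0,
    land_temp_c: float = 8.0,
    min_land_gap_s: float = 1800.0,
    species: str | None = None,
    fs: int = 25,
):
    """At-sea trip spans [(start, end), ...] on the feature frame."""
    species = species or frame.attrs.get("species", "adelie")
    midpoint = 0.5 * (water_temp_c + land_temp_c)
    threshold = DIVE_THRESHOLD_M[_check_species(species)]
    at_sea = (frame["temperature"].to_numpy() < midpoint) | (
        frame["depth"].to_numpy() > threshold
    )
    if not at_sea.any():
        log.info("no at-sea samples: no trips detected")
        return []
    first, last = np.flatnonzero(at_sea)[[0, -1]]
    gap = int(min_land_gap_s * fs)
    trips = []
    start = first
    land_runs = _runs(~at_sea[first:last + 1])
    for s, e in land_runs:
        if e - s >= gap:
            trips.append((start, first + s))
            start = first + e
    trips.append((start, last + 1))
    return trips


def _check_species(species: str) -> str:
    if species not in DIVE_THRESHOLD_M:
        raise ValueError(f"unknown species {species!r}")
    return species


def dive_filter(
    frame: pd.DataFrame, species: str, submergence_m: float = 0.5
) -> np.ndarray:
    """Boolean mask of diving samples.

    Submerged episodes (contiguous depth > `submergence_m`) whose maximum
    depth does not exceed the species threshold (strict >) count as surface,
    not diving.  Idempotent: the mask depends on depth only.
    """
    threshold = DIVE_THRESHOLD_M[_check_species(species)]
    depth = frame["depth"].to_numpy()
    submerged = depth > submergence_m
    mask = np.zeros(len(depth), dtype=bool)
    for s, e in _runs(submerged):
        if depth[s:e].max() > threshold:
            mask[s:e] = True
    return mask


def split_subsets(
    frame: pd.DataFrame,
    trips,
    species: str,
    ice_temp_c: float = 0.0,
    walk_pitch_deg: float = 60.0,
    min_run_s: float = 3.0,
    fs: int = 25,
) -> list[Segment]:
    """Partition every in-trip sample into diving / surface / land_ice segments."""
    _check_species(species)
    trip_id = frame.attrs.get("trip_id", "trip")
    diving = dive_filter(frame, species)
    temp = frame["temperature"].to_numpy()
    segments: list[Segment] = []
    min_run = max(1, int(min_run_s * fs))
    for t_idx, (start, end) in enumerate(trips):
        code = np.zeros(end - start, dtype=np.int8)  # 0 surface, 1 diving, 2 land
        code[diving[start:end]] = 1
        if species == "adelie":
            on_ice = (temp[start:end] > ice_temp_c) & ~diving[start:end]
            code[on_ice] = 2
        code = _absorb_short_runs(code, min_run)
        tid = trip_id if len(trips) == 1 else f"{trip_id}_{t_idx}"
        for s, e, c in _coded_runs(code):
            segments.append(
                Segment(tid, ("surface", "diving", "land_ice")[c], start + s, start + e, species)
            )
    return segments


def _coded_runs(code: np.ndarray):
    bounds = np.flatnonzero(np.diff(code)) + 1
    edges = np.r_[0, bounds, len(code)]
    return [(edges[i], edges[i + 1], code[edges[i]]) for i in range(len(edges) - 1)]


def _absorb_short_runs(code: np.ndarray, min_run: int) -> np.ndarray:
    """Merge runs shorter than min_run into their left (else right) neighbour."""
    code = code.copy()
    changed = True
    while changed:
        changed = False
        runs = _coded_runs(code)
        if len(runs) <= 1:
            break
        for i, (s, e, c) in enumerate(runs):
            if e - s < min_run:
                nb = runs[i - 1][2] if i > 0 else runs[i + 1][2]
                code[s:e] = nb
                changed = True
                break
    return code


def segments_table(segments, fs: int = 25) -> pd.DataFrame:
    """Segment list as a table (`trip_id,subset,start_s,end_s`)."""
    return pd.DataFrame(
        [
            dict(trip_id=s.trip_id, subset=s.subset,
                 start_s=s.start / fs, end_s=s.end / fs)
            for s in segments
        ]
    )
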