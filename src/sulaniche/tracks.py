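"""Foraging-trip segmentation and trip/step metrics for central-place foragers.

A foraging trip is a maximal run of consecutive fixes farther than the
colony exclusion radius from the colony center, bounded by fixes inside the
radius on both sides.  Runs that touch the start or end of an individual's
record lack a departure or return crossing and are flagged incomplete;
they are excluded from metrics by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import aeq_forward, haversine_km
from .synthetic import ColonySpec

__all__ = [
    "ForagingTrip",
    "dedupe_fixes",
    "outlier_filter",
    "segment_trips",
    "step_kinematics",
    "trip_metrics",
    "trip_metrics_table",
]


@dataclass
class ForagingTrip:
    """One departure-to-return excursion outside the colony radius."""

    individual_id: str
    trip_index: int  # 1-based, temporal order within the individual
    fixes: pd.DataFrame  # columns id, timestamp, lat, lon (all outside radius)
    complete: bool = True

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


def _check_sorted(fixes: pd.DataFrame) -> pd.DataFrame:
    """Validate per-individual strictly increasing timestamps; drop duplicates."""
    out = []
    for bird, grp in fixes.groupby("id", sort=False):
        ts = grp["timestamp"]
        if ts.is_monotonic_decreasing and len(ts) > 1:
            raise ValueError(f"timestamps for individual {bird!r} are not sorted")
        if not ts.is_monotonic_increasing:
            raise ValueError(f"timestamps for individual {bird!r} are not sorted")
        dup = ts.duplicated()
        if dup.any():
            warnings.warn(
                f"individual {bird!r}: dropped {int(dup.sum())} duplicate-timestamp fixes (kept first)",
                stacklevel=3,
            )
            grp = grp[~dup]
        out.append(grp)
    return pd.concat(out, ignore_index=True) if out else fixes


def dedupe_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Public wrapper for timestamp validation/deduplication."""
    return _check_sorted(fixes)


def segment_trips(
    fixes: pd.DataFrame,
    colony: ColonySpec,
    include_incomplete: bool = False,
) -> list[ForagingTrip]:
    """Split each individual's record into foraging trips.

    Fixes within the exclusion radius never enter a trip.  A trip is
    complete when at least one inside-radius fix precedes and follows it
    (the bird demonstrably departed and returned).
    """
    if fixes.empty:
        return []
    fixes = _check_sorted(fixes)
    trips: list[ForagingTrip] = []
    for bird, grp in fixes.groupby("id", sort=False):
        grp = grp.reset_index(drop=True)
        dist_km = haversine_km(grp["lat"], grp["lon"], colony.latitude, colony.longitude)
        outside = np.asarray(dist_km) > colony.exclusion_radius_km
        # run-length encode the outside mask
        idx = 1
        n = len(grp)
        start = None
        for i in range(n + 1):
            if i < n and outside[i]:
                if start is None:
                    start = i
            elif start is not None:
                run = grp.iloc[start:i]
                complete = start > 0 and i < n
                if complete or include_incomplete:
                    trips.append(ForagingTrip(str(bird), idx, run.reset_index(drop=True), complete))
                    idx += 1
                start = None
    return trips


def trip_metrics(trip: ForagingTrip, colony: ColonySpec) -> dict:
    """Duration (h), total path length (km), maximum colony distance (km).

    Duration is last minus first fix time; total is the sum of great-circle
    distances between successive fixes; max is the largest fix-to-colony
    distance.
    """
    f = trip.fixes
    if len(f) == 0:
        raise ValueError("trip has no fixes")
    duration_h = (f["timestamp"].iloc[-1] - f["timestamp"].iloc[0]).total_seconds() / 3600.0
    lat = f["lat"].to_numpy()
    lon = f["lon"].to_numpy()
    total_km = float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]))) if len(f) > 1 else 0.0
    max_km = float(np.max(haversine_km(lat, lon, colony.latitude, colony.longitude)))
    return {
        "id": trip.individual_id,
        "trip": trip.trip_index,
        "duration_h": duration_h,
        "total_km": total_km,
        "max_km": max_km,
        "n_fixes": len(f),
    }


def trip_metrics_table(trips: list[ForagingTrip], colony: ColonySpec) -> pd.DataFrame:
    """Per-trip metrics CSV layout: id, trip, duration_h, total_km, max_km, n_fixes."""
    return pd.DataFrame([trip_metrics(t, colony) for t in trips])


def outlier_filter(fixes: pd.DataFrame, max_speed_kmh: float = 150.0) -> pd.DataFrame:
    """Remove single-fix GPS spikes.

    A fix is a spike when the implied speeds both into and out of it exceed
    ``max_speed_kmh`` (well above sulid flight speed at the default).
    Applied per individual until a fixed point, so the filter is idempotent.
    """
    if max_speed_kmh <= 0:
        raise ValueError("max_speed_kmh must be > 0")
    if fixes.empty:
        return fixes

    def one_pass(grp: pd.DataFrame) -> pd.DataFrame:
        if len(grp) < 3:
            return grp
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        dt = grp["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
        seg = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        with np.errstate(divide="ignore"):
            speed = np.where(dt > 0, seg / (dt / 3600.0), np.inf)
        spike = np.zeros(len(grp), dtype=bool)
        spike[1:-1] = (speed[:-1] > max_speed_kmh) & (speed[1:] > max_speed_kmh)
        return grp[~spike]

    out = []
    for _, grp in fixes.groupby("id", sort=False):
        grp = grp.reset_index(drop=True)
        while True:
            filtered = one_pass(grp)
            if len(filtered) == len(grp):
                break
            grp = filtered.reset_index(drop=True)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def step_kinematics(fixes: pd.DataFrame, center: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-step (speed, turn) pairs from an ordered fix sequence.

    Row i describes interior fix i (i = 1..n-2): speed_kmh is the
    displacement i -> i+1 over its time step, turn_rad is the absolute angle
    in [0, pi] between displacements (i-1 -> i) and (i -> i+1), computed on
    the local azimuthal-equidistant plane.  Midpoint position and dt_s are
    carried along for time weighting.
    """
    n = len(fixes)
    if n < 3:
        raise ValueError("step kinematics needs >= 3 fixes")
    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    if center is None:
        center = (float(np.mean(lat)), float(np.mean(lon)))
    x, y = aeq_forward(lat, lon, center[0], center[1])
    dt = fixes["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
    dx = np.diff(x)
    dy = np.diff(y)
    seg = np.hypot(dx, dy)
    if np.any((dt <= 0) & (seg > 0)):
        raise ValueError("zero or negative dt between distinct fixes; deduplicate timestamps upstream")
    speed = seg / (dt / 3600.0)
    # angle between successive displacement vectors
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
    turn = np.abs(np.arctan2(cross, dot))
    out = pd.DataFrame(
        {
            "speed_kmh": speed[1:],  # displacement i -> i+1 for interior fix i
            "turn_rad": turn,
            "dt_s": dt[1:],
            "lat": lat[1:-1],
            "lon": lon[1:-1],
        }
    )
    if "id" in fixes.columns:
        out.insert(0, "id", fixes["id"].to_numpy()[1:-1])
    return out
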