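"""Synthetic data generators for every pipeline input.

The study system is a colony of Peruvian boobies (*Sula variegata*) breeding
on an island off northern Peru, sampled in two seasons with contrasting
oceanographic conditions.  No raw data are distributed with this package, so
these generators emulate the structure of each field dataset:

* GPS tracks: a semi-Markov multi-state correlated random walk producing
  out-and-back central-place foraging trips from the colony, with four
  kinematic states (low/high speed x low/high turn) and a retained
  ground-truth state label per fix for classifier validation.
* Isotopes: group-structured bivariate-normal (d13C, d15N) blood values for
  the four sex x year groups.
* Regurgitates: anchoveta-dominated prey-item tables with sex-specific
  prey-size distributions.
* Morphometrics: multivariate-normal (mass, culmen, tarsus, wing) draws per
  sex, reverse-dimorphic (females larger).

Every generator is a pure function of (spec, seed): identical inputs give
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import aeq_inverse

STATE_LABELS = ("LL", "LH", "HL", "HH")


@dataclass(frozen=True)
class ColonySpec:
    """Colony center and the exclusion radius defining 'at the colony'.

    The exclusion radius (default 300 m) mirrors the processing rule that
    removes all fixes within 300 m of the colony center before trips are
    delimited.
    """

    latitude: float
    longitude: float
    exclusion_radius_m: float = 300.0

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.exclusion_radius_m <= 0:
            raise ValueError("exclusion_radius_m must be > 0")

    @property
    def exclusion_radius_km(self) -> float:
        return self.exclusion_radius_m / 1000.0


@dataclass(frozen=True)
class StateKinematics:
    """Kinematics of one behavioral state of the correlated random walk.

    turn_concentration is the wrapped-normal concentration (mean resultant length) rho in [0, 1);
    states whose label has a high-turn axis ('H' second letter) draw turning
    angles centered at +/-2.5 rad (strong but incomplete reversals, the
    signature of area-restricted search), low-turn states at 0 (straight).
    """

    state_label: str
    speed_mean_kmh: float
    speed_sd_kmh: float
    turn_concentration: float
    dwell_mean_s: float

    def __post_init__(self):
        if self.state_label not in STATE_LABELS:
            raise ValueError(f"state_label must be one of {STATE_LABELS}")
        if self.speed_mean_kmh < 0:
            raise ValueError("speed_mean_kmh must be >= 0")
        if self.speed_sd_kmh <= 0:
            raise ValueError("speed_sd_kmh must be > 0")
        if not 0.0 <= self.turn_concentration < 1.0:
            raise ValueError("turn_concentration must be in [0, 1)")
        if self.dwell_mean_s <= 0:
            raise ValueError("dwell_mean_s must be > 0")

    @property
    def turn_center(self) -> float:
        return 2.5 if self.state_label[1] == "H" else 0.0


@dataclass(frozen=True)
class IsotopeGroupSpec:
    """Bivariate-normal spec for one sex x year isotope group (per mil)."""

    group_id: str
    mean_d13C: float
    mean_d15N: float
    sd_d13C: float
    sd_d15N: float
    correlation: float = 0.0
    n: int = 10

    def __post_init__(self):
        if self.sd_d13C <= 0 or self.sd_d15N <= 0:
            raise ValueError("isotope sds must be > 0")
        if not abs(self.correlation) < 1.0:
            raise ValueError("|correlation| must be < 1")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass(frozen=True)
class RegurgitateSpec:
    """Prey-item spec for one sex group.

    mean/sd_prey_length_cm describe the distribution of *per-sample mean*
    prey lengths across regurgitates (the quantity the field summaries
    report); items within a sample scatter around the sample mean with sd
    0.25 x sd_prey_length_cm.  Masses follow mass_g = a * length_cm ** b.
    """

    group_id: str
    mean_prey_length_cm: float
    sd_prey_length_cm: float
    mean_n_items: float
    species_weights: dict = field(default_factory=lambda: {"anchoveta": 1.0})
    length_mass_a: float = 0.0055
    length_mass_b: float = 3.0
    year: int = 2019

    def __post_init__(self):
        if self.sd_prey_length_cm <= 0:
            raise ValueError("sd_prey_length_cm must be > 0")
        if self.length_mass_a < 0 or self.length_mass_b < 0:
            raise ValueError("allometric coefficients must be non-negative")
        total = sum(self.species_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"species_weights must sum to 1 (got {total})")


@dataclass(frozen=True)
class MorphoGroupSpec:
    """Multivariate-normal spec for one sex: (mass g, culmen mm, tarsus mm, wing mm)."""

    sex: str
    mean: tuple  # (mass_g, culmen_mm, tarsus_mm, wing_mm)
    sd: tuple
    n: int
    correlation: float = 0.5  # common off-diagonal correlation
    year: int = 2019

    def covariance(self) -> np.ndarray:
        sd = np.asarray(self.sd, dtype=float)
        corr = np.full((4, 4), self.correlation)
        np.fill_diagonal(corr, 1.0)
        cov = corr * np.outer(sd, sd)
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance is not positive definite")
        return cov

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2 per sex")
        if any(s <= 0 for s in self.sd):
            raise ValueError("sds must be > 0")


# ---------------------------------------------------------------------------
# Study-condition defaults
# ---------------------------------------------------------------------------

def default_colony() -> ColonySpec:
    """Isla Guanape Norte (8.545 S, 78.964 W), 300-m exclusion radius."""
    return ColonySpec(latitude=-8.545, longitude=-78.964, exclusion_radius_m=300.0)


def default_states() -> list[StateKinematics]:
    """Kinematics of the four at-sea behaviors of a plunge-diving sulid.

    Resting (LL) drifts slowly on the water; intensive foraging/searching
    (LH) is slow and tortuous; traveling (HL) is fast, directed flight near
    40 km/h; relocating / extensive searching (HH) is fast with frequent
    course changes.
    """
    return [
        StateKinematics("LL", speed_mean_kmh=1.5, speed_sd_kmh=0.7, turn_concentration=0.85, dwell_mean_s=180.0),
        StateKinematics("LH", speed_mean_kmh=3.5, speed_sd_kmh=1.2, turn_concentration=0.60, dwell_mean_s=120.0),
        StateKinematics("HL", speed_mean_kmh=40.0, speed_sd_kmh=6.0, turn_concentration=0.95, dwell_mean_s=300.0),
        StateKinematics("HH", speed_mean_kmh=28.0, speed_sd_kmh=6.0, turn_concentration=0.50, dwell_mean_s=90.0),
    ]


def default_isotope_specs() -> list[IsotopeGroupSpec]:
    """Four sex x year groups with means/SDs on the scale of the study's blood values."""
    return [
        IsotopeGroupSpec("female_2016", -15.0, 12.6, 0.4, 0.2, n=14),
        IsotopeGroupSpec("male_2016", -15.1, 12.6, 0.4, 0.3, n=9),
        IsotopeGroupSpec("female_2019", -14.7, 12.0, 0.4, 0.2, n=20),
        IsotopeGroupSpec("male_2019", -14.8, 12.0, 0.3, 0.2, n=12),
    ]


def default_regurgitate_specs() -> list[RegurgitateSpec]:
    """Anchoveta-only 2019 diets; females take larger, less variable prey."""
    return [
        RegurgitateSpec("female", mean_prey_length_cm=13.6, sd_prey_length_cm=0.6, mean_n_items=8.3),
        RegurgitateSpec("male", mean_prey_length_cm=11.6, sd_prey_length_cm=2.8, mean_n_items=7.9),
    ]


def default_morpho_specs() -> list[MorphoGroupSpec]:
    """Pooled-year sex means/SDs; reverse dimorphism (females larger)."""
    return [
        MorphoGroupSpec("female", mean=(1542.0, 96.3, 53.4, 409.0), sd=(89.0, 3.0, 2.1, 8.0), n=25),
        MorphoGroupSpec("male", mean=(1274.0, 90.5, 50.5, 395.0), sd=(80.0, 3.1, 1.5, 9.0), n=14),
    ]


# ---------------------------------------------------------------------------
# Track generator
# ---------------------------------------------------------------------------

def _wrapped_turn(rng: np.random.Generator, center: float, rho: float, size=None) -> np.ndarray:
    """Wrapped-normal turning angles on (-pi, pi].

    ``rho`` is the mean resultant length; the underlying normal has
    sd = sqrt(-2 ln rho) (the wrapped-normal concentration relation), and
    rho = 0 degenerates to a uniform angle.
    """
    if rho <= 0.0:
        theta = rng.uniform(-np.pi, np.pi, size=size)
    else:
        theta = rng.normal(center, np.sqrt(-2.0 * np.log(rho)), size=size)
    theta = np.asarray(theta) - center + center  # no-op, keeps array/scalar shape
    return np.mod(theta + np.pi, 2.0 * np.pi) - np.pi


def _step(rng, state: StateKinematics, heading: float, dt_s: float):
    """One CRW step: returns (dx, dy, new_heading) in km.

    The turn center's sign is drawn per step so high-turn states zig-zag
    rather than curl consistently.
    """
    speed = max(0.0, rng.normal(state.speed_mean_kmh, state.speed_sd_kmh))
    center = state.turn_center * (1.0 if rng.random() < 0.5 else -1.0)
    heading = heading + float(_wrapped_turn(rng, center, state.turn_concentration))
    d = speed * dt_s / 3600.0
    return d * np.sin(heading), d * np.cos(heading), heading


def gen_tracks(
    colony: ColonySpec | None = None,
    states: list[StateKinematics] | None = None,
    n_individuals: int = 20,
    trips_per_individual: int = 2,
    fix_interval_s: float = 10.0,
    seed: int = 0,
    start_time: str = "2019-11-20T06:00:00Z",
    id_prefix: str = "bird",
) -> pd.DataFrame:
    """Simulate central-place foraging tracks for ``n_individuals``.

    Each trip has an outbound traveling phase (HL), an area-restricted phase
    switching semi-Markov-style among all four states (exponential dwell
    times), and a directed return phase (HL) that re-enters the colony
    radius, so downstream segmentation closes every trip.  Returns a fix
    table ``id, timestamp, lat, lon, true_state``; colony fixes are labeled
    LL (resting).
    """
    colony = colony or default_colony()
    states = list(states) if states is not None else default_states()
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if trips_per_individual < 0:
        raise ValueError("trips_per_individual must be >= 0")
    if fix_interval_s <= 0:
        raise ValueError("fix_interval_s must be > 0")
    labels = [s.state_label for s in states]
    if sorted(labels) != sorted(STATE_LABELS) or len(set(labels)) != 4:
        raise ValueError(f"states must contain each of {STATE_LABELS} exactly once")
    by_label = {s.state_label: s for s in states}

    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start_time)
    dt = float(fix_interval_s)
    radius_km = colony.exclusion_radius_km
    rows_id, rows_t, rows_x, rows_y, rows_state = [], [], [], [], []

    for i in range(n_individuals):
        bird = f"{id_prefix}{i:03d}"
        t = t0 + pd.Timedelta(seconds=int(rng.uniform(0, 1800)))
        x = y = 0.0

        def emit(state):
            rows_id.append(bird)
            rows_t.append(t)
            rows_x.append(x)
            rows_y.append(y)
            rows_state.append(state)

        def colony_rest(n_fix):
            nonlocal t, x, y
            for _ in range(n_fix):
                x, y = rng.normal(0.0, radius_km * 0.1, size=2)
                emit("LL")
                t = t + pd.Timedelta(seconds=dt)

        colony_rest(5)
        for _ in range(trips_per_individual):
            heading = float(rng.uniform(0, 2 * np.pi))
            hl = by_label["HL"]
            # outbound: traveling flight with a persistent heading (the turn
            # between successive fixes is then a single wrapped-Cauchy draw)
            n_out = int(rng.uniform(0.3, 0.9) * 3600.0 / dt)
            for _ in range(n_out):
                dx, dy, heading = _step(rng, hl, heading, dt)
                x += dx
                y += dy
                emit("HL")
                t = t + pd.Timedelta(seconds=dt)
                if 1e-6 < np.hypot(x, y) < 3.0:
                    outward = np.arctan2(x, y)
                    err = np.mod(outward - heading + np.pi, 2 * np.pi) - np.pi
                    heading += float(np.clip(err, -0.3, 0.3))
            # area-restricted phase: semi-Markov over the four states
            ars_s = rng.uniform(0.4, 1.2) * 3600.0
            elapsed = 0.0
            while elapsed < ars_s:
                st = by_label[STATE_LABELS[rng.choice(4, p=[0.25, 0.35, 0.15, 0.25])]]
                dwell = max(dt, rng.exponential(st.dwell_mean_s))
                n_steps = max(1, int(round(dwell / dt)))
                for _ in range(n_steps):
                    dx, dy, heading = _step(rng, st, heading, dt)
                    x += dx
                    y += dy
                    emit(st.state_label)
                    t = t + pd.Timedelta(seconds=dt)
                    if np.hypot(x, y) < 3.0:
                        # steer the search away from the colony: birds do not
                        # forage inside the colony's immediate surroundings
                        outward = np.arctan2(x, y)
                        err = np.mod(outward - heading + np.pi, 2 * np.pi) - np.pi
                        heading += float(np.clip(err, -0.3, 0.3))
                elapsed += n_steps * dt
            # return: traveling flight homing on the colony; the heading stays
            # persistent with a bounded per-step correction toward the colony
            # bearing so realized turns keep the HL turn distribution
            heading = float(np.arctan2(-x, -y))
            max_return = int(10 * 3600.0 / dt)
            for _ in range(max_return):
                dist = float(np.hypot(x, y))
                if dist <= radius_km * 0.5:
                    break
                if dist <= 1.0:
                    # final approach: fly straight at the colony so the track
                    # cannot graze the exclusion radius and re-exit
                    speed = max(5.0, rng.normal(hl.speed_mean_kmh, hl.speed_sd_kmh))
                    step_len = min(speed * dt / 3600.0, dist)
                    heading = float(np.arctan2(-x, -y))
                    x += step_len * np.sin(heading)
                    y += step_len * np.cos(heading)
                else:
                    dx, dy, heading = _step(rng, hl, heading, dt)
                    bearing = np.arctan2(-(x + dx), -(y + dy))
                    err = np.mod(bearing - heading + np.pi, 2 * np.pi) - np.pi
                    heading += float(np.clip(err, -0.08, 0.08))
                    x += dx
                    y += dy
                emit("HL")
                t = t + pd.Timedelta(seconds=dt)
            # force the final fix inside the radius in case noise left us out
            if np.hypot(x, y) > radius_km:
                x = y = 0.0
                emit("LL")
                t = t + pd.Timedelta(seconds=dt)
            colony_rest(5)

    lat, lon = aeq_inverse(np.array(rows_x), np.array(rows_y), colony.latitude, colony.longitude)
    return pd.DataFrame(
        {
            "id": rows_id,
            "timestamp": rows_t,
            "lat": np.atleast_1d(lat),
            "lon": np.atleast_1d(lon),
            "true_state": rows_state,
        }
    )


# ---------------------------------------------------------------------------
# Isotopes, regurgitates, morphometrics
# ---------------------------------------------------------------------------

def _split_group_id(group_id: str):
    if "_" in group_id:
        sex, _, year = group_id.partition("_")
        try:
            return sex, int(year)
        except ValueError:
            return group_id, None
    return group_id, None


def gen_isotopes(specs: list[IsotopeGroupSpec] | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw per-group bivariate-normal (d13C, d15N) observations.

    Returns columns ``id, group, sex, year, d13C, d15N``; sex/year are parsed
    from ``group_id`` when it has the form ``<sex>_<year>``.
    """
    specs = list(specs) if specs is not None else default_isotope_specs()
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        cov = np.array(
            [
                [spec.sd_d13C**2, spec.correlation * spec.sd_d13C * spec.sd_d15N],
                [spec.correlation * spec.sd_d13C * spec.sd_d15N, spec.sd_d15N**2],
            ]
        )
        draws = rng.multivariate_normal([spec.mean_d13C, spec.mean_d15N], cov, size=spec.n)
        sex, year = _split_group_id(spec.group_id)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{spec.group_id}_{k:03d}" for k in range(spec.n)],
                    "group": spec.group_id,
                    "sex": sex,
                    "year": year,
                    "d13C": draws[:, 0],
                    "d15N": draws[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_regurgitates(
    specs: list[RegurgitateSpec] | None = None,
    n_samples: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw regurgitate prey items: long table ``sample_id, sex, year, species, length_mm, mass_g``.

    Per sample: item count ~ Poisson(mean_n_items) truncated at >= 1,
    species sampled by weight, item lengths positive-truncated normal around
    a per-sample mean, masses allometric.
    """
    specs = list(specs) if specs is not None else default_regurgitate_specs()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for spec in specs:
        species = list(spec.species_weights)
        weights = np.array([spec.species_weights[s] for s in species], dtype=float)
        for k in range(n_samples):
            sid = f"{spec.group_id}_{spec.year}_{k:03d}"
            n_items = 0
            while n_items < 1:
                n_items = int(rng.poisson(spec.mean_n_items))
            sample_mean = rng.normal(spec.mean_prey_length_cm, spec.sd_prey_length_cm)
            within_sd = 0.25 * spec.sd_prey_length_cm
            for _ in range(n_items):
                length_cm = -1.0
                while length_cm <= 0.0:
                    length_cm = rng.normal(sample_mean, within_sd)
                sp = species[int(rng.choice(len(species), p=weights))]
                records.append(
                    {
                        "sample_id": sid,
                        "sex": spec.group_id,
                        "year": spec.year,
                        "species": sp,
                        "length_mm": length_cm * 10.0,
                        "mass_g": spec.length_mass_a * length_cm**spec.length_mass_b,
                    }
                )
    return pd.DataFrame.from_records(records)


def gen_morphometrics(specs: list[MorphoGroupSpec] | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw per-sex multivariate-normal morphometrics.

    Returns ``id, sex, year, mass_g, culmen_mm, tarsus_mm, wing_mm``.
    """
    specs = list(specs) if specs is not None else default_morpho_specs()
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        draws = rng.multivariate_normal(np.asarray(spec.mean, dtype=float), spec.covariance(), size=spec.n)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{spec.sex}_{spec.year}_{k:03d}" for k in range(spec.n)],
                    "sex": spec.sex,
                    "year": spec.year,
                    "mass_g": draws[:, 0],
                    "culmen_mm": draws[:, 1],
                    "tarsus_mm": draws[:, 2],
                    "wing_mm": draws[:, 3],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
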