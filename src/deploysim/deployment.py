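"""Receiver-station placement strategies and coverage accounting.

Three deployment strategies are supported: uniform-random placement in the
unit-square arena, placement at (a subset of) the animals' homes, and mobile
stations that perform an isotropic random walk (the a = 0 limit of the animal
movement rule applied to the stations themselves).

Two coverage quantities recur throughout the analyses and are easy to
conflate:

* the expected *covered fraction* of the arena, ``f = 1 - (1 - p)^x`` with
  ``p = pi r^2 / A`` — the probability that a uniformly-placed point falls
  inside at least one of ``x`` independently-placed reception discs; and
* the *total reception area* ``x * pi * r^2`` — disc areas summed with
  overlaps NOT subtracted, which is the deployment-cost axis used when
  comparing transfer curves across station counts and radii.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .movement import as_rng, random_directions

__all__ = [
    "StationSet",
    "CoverageSummary",
    "place_random",
    "place_at_homes",
    "step_mobile",
    "covered_fraction",
    "total_reception_area",
    "write_stations_csv",
    "read_stations_csv",
]


@dataclass
class StationSet:
    """A deployment of receiver stations.

    positions: (x, 2) initial station coordinates, inside [0,1]^2.
    radius: shared reception radius r (> 0), arena units.
    mobile: whether stations random-walk each step.
    station_speed: per-step displacement of mobile stations (ignored if static).
    """

    positions: np.ndarray
    radius: float
    mobile: bool = False
    station_speed: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if not np.isfinite(self.radius) or self.radius <= 0.0:
            raise ValueError(f"reception radius must be > 0, got {self.radius}")
        if self.station_speed < 0.0:
            raise ValueError("station_speed must be >= 0")
        if self.positions.size and (
            self.positions.min() < 0.0 or self.positions.max() > 1.0
        ):
            raise ValueError("initial station positions must lie in [0,1]^2")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class CoverageSummary:
    """Coverage accounting for x stations of radius r in an arena of area A."""

    p: float            # single-station covered fraction, pi r^2 / A
    f: float            # expected union-covered fraction, 1 - (1 - p)^x
    total_area: float   # x * pi * r^2, overlaps not subtracted
    arena_area: float


def place_random(x: int, radius: float, rng_seed, *, mobile: bool = False,
                 station_speed: float = 0.0) -> StationSet:
    """Place ``x`` stations i.i.d. uniform on the unit square."""
    if int(x) != x or x < 0:
        raise ValueError(f"station count must be a nonnegative integer, got {x}")
    rng = as_rng(rng_seed)
    positions = rng.uniform(0.0, 1.0, (int(x), 2))
    return StationSet(positions, radius, mobile=mobile, station_speed=station_speed)


def place_at_homes(homes: np.ndarray, x: int, radius: float, rng_seed) -> StationSet:
    """Place stations at the animals' homes, at most one station per home.

    ``min(x, n_homes)`` stations go on a uniformly-sampled subset of distinct
    homes; any excess beyond the number of homes is placed uniformly at random
    in the arena (a regime the deployment analyses never rely on).
    """
    if int(x) != x or x < 0:
        raise ValueError(f"station count must be a nonnegative integer, got {x}")
    homes = np.asarray(homes, dtype=float).reshape(-1, 2)
    if homes.shape[0] == 0 and x > 0:
        raise ValueError("cannot place stations at homes: no homes given")
    rng = as_rng(rng_seed)
    n_at_home = min(int(x), homes.shape[0])
    idx = rng.choice(homes.shape[0], size=n_at_home, replace=False)
    chosen = homes[idx]
    overflow = rng.uniform(0.0, 1.0, (int(x) - n_at_home, 2))
    return StationSet(np.vstack([chosen, overflow]), radius)


def step_mobile(stations: StationSet, rng: np.random.Generator) -> StationSet:
    """Advance mobile stations one step: displacement ``station_speed`` along an
    independent uniform random direction per station (unbounded plane)."""
    if not stations.mobile:
        raise ValueError("step_mobile called on a static StationSet")
    nu = random_directions(rng, len(stations))
    new_pos = stations.positions + stations.station_speed * nu
    out = replace(stations)
    out.positions = new_pos  # may leave [0,1]^2: mobile stations are unbounded
    return out


def covered_fraction(r: float, arena_area: float, x: int) -> CoverageSummary:
    """Evaluate the expected covered fraction f = 1 - (1 - p)^x, p = pi r^2 / A."""
    if r <= 0.0 or arena_area <= 0.0:
        raise ValueError("radius and arena area must be > 0")
    if int(x) != x or x < 0:
        raise ValueError(f"station count must be a nonnegative integer, got {x}")
    p = np.pi * r * r / arena_area
    if p > 1.0:
        raise ValueError(
            f"single-station coverage pi*r^2/A = {p:.4g} exceeds 1: radius too "
            "large for the arena"
        )
    f = 1.0 - (1.0 - p) ** int(x)
    return CoverageSummary(p=p, f=f, total_area=total_reception_area(x, r),
                           arena_area=arena_area)


def total_reception_area(x: int, r: float) -> float:
    """Total reception area x * pi * r^2 (disc areas summed, overlaps ignored)."""
    if int(x) != x or x < 0:
        raise ValueError(f"station count must be a nonnegative integer, got {x}")
    if r <= 0.0:
        raise ValueError("radius must be > 0")
    return int(x) * np.pi * r * r


def write_stations_csv(path, stations: StationSet) -> None:
    """Write station positions as CSV with header ``station_id,x,y``."""
    pd.DataFrame(
        {
            "station_id": np.arange(len(stations)),
            "x": stations.positions[:, 0],
            "y": stations.positions[:, 1],
        }
    ).to_csv(path, index=False)


def read_stations_csv(path, radius: float, *, mobile: bool = False,
                      station_speed: float = 0.0) -> StationSet:
    df = pd.read_csv(path).sort_values("station_id")
    return StationSet(df[["x", "y"]].to_numpy(), radius, mobile=mobile,
                      station_speed=station_speed)
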