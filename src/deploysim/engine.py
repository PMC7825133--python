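"""Simulation engine: couples movement, deployment and sensor buffers.

Per time step the order of events is: (1) animals move, (2) mobile stations
move (if any), (3) every sensor generates one data package, (4) every animal
within Euclidean distance <= r of ANY station flushes its whole buffer —
including the package generated this step — as a single transmission event.
An animal in range of several stations still flushes once: packages are
deleted on transmission and cannot be delivered twice.

The headline observable is the transfer function <T>, the average number of
transmitted packages per unit time per animal,
``<T> = total transmitted / (N * n_steps)``; since generation is one package
per animal per step, <T> is also the fraction of all generated packages that
the receiver array recovers, and 0 <= <T> <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fast import build_station_grid, detect_mobile, detect_static_grid
from .deployment import StationSet, covered_fraction
from .movement import MovementParams, as_rng, random_directions, simulate_trajectory

__all__ = [
    "TransmissionLog",
    "RunResult",
    "detect_in_range",
    "events_from_detection",
    "run",
    "transfer_static_limit",
    "write_events_csv",
]


@dataclass
class TransmissionLog:
    """Per-animal flush events: 1-based step times and package counts."""

    event_times: list  # list of int arrays, strictly increasing per animal
    event_sizes: list  # list of int arrays, each entry >= 1

    @property
    def n_animals(self) -> int:
        return len(self.event_times)

    def inter_event_times(self) -> np.ndarray:
        """Pooled inter-event intervals tau = diff of consecutive event times
        of the same animal, over all animals."""
        gaps = [np.diff(t) for t in self.event_times if t.size >= 2]
        if not gaps:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(gaps)


@dataclass
class RunResult:
    """Outcome of one simulation run.

    transmitted/stored/generated are per-animal package counts; conservation
    ``generated == transmitted + stored`` holds per animal.  ``log`` is None
    when event logging was disabled (bulk sweeps).
    """

    T_mean: float
    transmitted: np.ndarray
    stored: np.ndarray
    generated: np.ndarray
    n_steps: int | None = None
    log: TransmissionLog | None = None


def detect_in_range(positions: np.ndarray, stations: StationSet,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Boolean (n_steps, N) matrix: animal within <= r of any station, per step.

    ``positions`` is the (n_steps+1, N, 2) trajectory; detection applies to the
    post-move positions t = 1 .. n_steps.  For mobile station sets with
    nonzero speed the station random walk is drawn from ``rng``.
    """
    pos = np.ascontiguousarray(positions[1:])
    n_steps, n_animals = pos.shape[0], pos.shape[1]
    out = np.zeros((n_steps, n_animals), dtype=np.bool_)
    if len(stations) == 0:
        return out
    r2 = stations.radius * stations.radius
    if stations.mobile and stations.station_speed > 0.0:
        if rng is None:
            raise ValueError("mobile stations require a random generator")
        dirs = random_directions(rng, (n_steps, len(stations)))
        station_pos = stations.positions[None, :, :] + stations.station_speed * np.cumsum(dirs, axis=0)
        detect_mobile(pos, np.ascontiguousarray(station_pos), r2, out)
    else:
        station_xy = np.ascontiguousarray(stations.positions)
        ncell, cell_start, cell_items = build_station_grid(station_xy, stations.radius)
        detect_static_grid(pos, station_xy, stations.radius, ncell,
                           cell_start, cell_items, r2, out)
    return out


def events_from_detection(in_range: np.ndarray):
    """Apply the buffer rules to a detection matrix.

    Given in_range (n_steps, N), returns (transmitted, log): per-animal total
    transmitted packages and the full TransmissionLog.  Because one package is
    generated per step and a flush empties the buffer, the event at (1-based)
    step t has size t - t_prev, and the total transmitted equals the time of
    the last flush.
    """
    in_range = np.asarray(in_range, dtype=bool)
    n_steps, n_animals = in_range.shape
    cols = in_range.T  # contiguous per-animal rows
    times, sizes = [], []
    transmitted = np.zeros(n_animals, dtype=np.int64)
    for i in range(n_animals):
        t_i = np.flatnonzero(cols[i]).astype(np.int64) + 1
        s_i = np.diff(t_i, prepend=0)
        times.append(t_i)
        sizes.append(s_i)
        if t_i.size:
            transmitted[i] = t_i[-1]
    return transmitted, TransmissionLog(times, sizes)


def _transmitted_fast(in_range: np.ndarray) -> np.ndarray:
    """Per-animal transmitted totals without building the event log."""
    n_steps = in_range.shape[0]
    any_event = in_range.any(axis=0)
    last = n_steps - 1 - np.argmax(in_range[::-1], axis=0)
    return np.where(any_event, last + 1, 0).astype(np.int64)


def run(
    movement: MovementParams,
    stations: StationSet,
    n_steps: int,
    rng_seed,
    *,
    homes: np.ndarray | None = None,
    collect_log: bool = True,
) -> RunResult:
    """Simulate one realization and return the transfer statistics.

    One seeded generator drives the whole realization: homes (when not given),
    then animal directions, then mobile-station directions.  Pass precomputed
    ``homes`` when the station layout depends on them (at-home placement).
    """
    if int(n_steps) != n_steps or n_steps < 1:
        raise ValueError(f"n_steps must be a positive integer, got {n_steps}")
    n_steps = int(n_steps)
    rng = as_rng(rng_seed)
    positions = simulate_trajectory(movement, n_steps, rng, homes=homes)
    in_range = detect_in_range(positions, stations, rng)

    if collect_log:
        transmitted, log = events_from_detection(in_range)
    else:
        transmitted, log = _transmitted_fast(in_range), None
    generated = np.full(movement.n_animals, n_steps, dtype=np.int64)
    stored = generated - transmitted
    t_mean = transmitted.sum() / (movement.n_animals * n_steps)
    return RunResult(T_mean=float(t_mean), transmitted=transmitted, stored=stored,
                     generated=generated, n_steps=n_steps, log=log)


def transfer_static_limit(movement: MovementParams, stations: StationSet) -> float:
    """Analytic <T> prediction in the static limit a = 1, v << r.

    With a = 1 every animal sits on a circle of radius v around its home, so
    <T> equals the probability that a uniform home falls in the union of the
    reception discs — the expected covered fraction f = 1 - (1 - pi r^2)^x.
    """
    if movement.a != 1.0:
        raise ValueError("static-limit prediction requires a = 1")
    if movement.v >= stations.radius:
        warnings.warn(
            "static-limit approximation assumes v << r; prediction may be poor",
            stacklevel=2,
        )
    if len(stations) == 0:
        return 0.0
    return covered_fraction(stations.radius, 1.0, len(stations)).f


def write_events_csv(path, log: TransmissionLog) -> None:
    """Write flush events as CSV with header ``animal_id,event_time,event_size``."""
    ids = np.concatenate(
        [np.full(t.size, i, dtype=np.int64) for i, t in enumerate(log.event_times)]
    ) if log.n_animals else np.empty(0, dtype=np.int64)
    times = np.concatenate(log.event_times) if log.n_animals else np.empty(0, dtype=np.int64)
    sizes = np.concatenate(log.event_sizes) if log.n_animals else np.empty(0, dtype=np.int64)
    pd.DataFrame(
        {"animal_id": ids, "event_time": times, "event_size": sizes}
    ).to_csv(path, index=False)
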