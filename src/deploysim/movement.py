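"""Central-place stochastic movement model.

A population of ``N`` animals moves in discrete time on an unbounded plane.
Each animal ``i`` carries a fixed home site ``x_h_i`` and updates its position
as::

    x_i(t+1) = x_i(t) + v * nu_i(t) - a * (x_i(t) - x_h_i)

where ``v`` is the step speed, ``nu_i(t)`` is an independent unit vector with
direction uniform on [0, 2*pi), and ``a`` in [0, 1] is the home-attraction
constant.  ``a = 0`` gives an isotropic random walk; ``a = 1`` pins every
post-step position onto the circle of radius ``v`` around the home.  Homes are
drawn uniformly in the unit square [0,1]^2 (the deployment arena); trajectories
themselves are not bounded — for ``a > 0`` the contraction term confines an
animal within distance ``v/a`` of its home asymptotically.

Space is normalised so the deployment arena is 1 x 1; one time step is the
package-generation interval of the attached sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fast import integrate_positions

__all__ = [
    "MovementParams",
    "AnimalState",
    "random_directions",
    "init_population",
    "step",
    "simulate_trajectory",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

TWO_PI = 2.0 * np.pi


def as_rng(seed) -> np.random.Generator:
    """Return ``seed`` itself if it is already a Generator, else seed a new one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MovementParams:
    """Parameters of the equation of motion.

    v: step speed, in arena units per time step (arena side = 1).
    a: home-attraction constant in [0, 1].
    n_animals: population size N.
    """

    v: float
    a: float
    n_animals: int

    def __post_init__(self):
        if not np.isfinite(self.v) or self.v < 0.0:
            raise ValueError(f"speed v must be finite and >= 0, got {self.v}")
        if not np.isfinite(self.a) or not 0.0 <= self.a <= 1.0:
            raise ValueError(f"home attraction a must lie in [0, 1], got {self.a}")
        if int(self.n_animals) != self.n_animals or self.n_animals < 1:
            raise ValueError(f"n_animals must be a positive integer, got {self.n_animals}")


@dataclass
class AnimalState:
    """Positions and homes of the population at one time step.

    positions and homes are (N, 2) arrays; homes are immutable over a run.
    """

    positions: np.ndarray
    homes: np.ndarray
    time: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.homes = np.asarray(self.homes, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if self.positions.shape != self.homes.shape:
            raise ValueError("positions and homes must have identical shape")
        if self.time < 0:
            raise ValueError("time must be nonnegative")

    @property
    def n_animals(self) -> int:
        return self.positions.shape[0]


def random_directions(rng: np.random.Generator, shape) -> np.ndarray:
    """Unit vectors with directions uniform on [0, 2*pi); output shape ``shape + (2,)``."""
    angles = rng.uniform(0.0, TWO_PI, shape)
    return np.stack((np.cos(angles), np.sin(angles)), axis=-1)


def init_population(params: MovementParams, rng_seed) -> AnimalState:
    """Draw homes i.i.d. uniform on [0,1]^2 and start every animal at its home.

    Starting at the home places each trajectory in its attractor basin from
    t = 0 and makes the a = 1 circle property exact from the first step.
    """
    rng = as_rng(rng_seed)
    homes = rng.uniform(0.0, 1.0, (params.n_animals, 2))
    return AnimalState(positions=homes.copy(), homes=homes, time=0)


def step(state: AnimalState, params: MovementParams, rng: np.random.Generator) -> AnimalState:
    """Advance the population one time step; returns a new state, homes unchanged."""
    nu = random_directions(rng, state.n_animals)
    new_pos = state.positions + params.v * nu - params.a * (state.positions - state.homes)
    return AnimalState(positions=new_pos, homes=state.homes, time=state.time + 1)


def simulate_trajectory(
    params: MovementParams,
    n_steps: int,
    rng_seed,
    homes: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the whole population for ``n_steps`` steps.

    Returns positions of shape (n_steps + 1, N, 2) for t = 0 .. n_steps, with
    positions[0] equal to the homes.  If ``homes`` is None they are drawn from
    the generator first (exactly as :func:`init_population` would), so a fixed
    seed reproduces the trajectory bitwise.  The random-number stream is
    identical to calling :func:`step` ``n_steps`` times.
    """
    if int(n_steps) != n_steps or n_steps < 1:
        raise ValueError(f"n_steps must be a positive integer, got {n_steps}")
    n_steps = int(n_steps)
    rng = as_rng(rng_seed)
    if homes is None:
        homes = rng.uniform(0.0, 1.0, (params.n_animals, 2))
    else:
        homes = np.ascontiguousarray(homes, dtype=float)
        if homes.shape != (params.n_animals, 2):
            raise ValueError("homes must have shape (n_animals, 2)")
    # Batched draw: row-major fill gives the same stream as per-step draws.
    angles = rng.uniform(0.0, TWO_PI, (n_steps, params.n_animals))
    vdirs = np.empty((n_steps, params.n_animals, 2))
    np.multiply(np.cos(angles), params.v, out=vdirs[..., 0])
    np.multiply(np.sin(angles), params.v, out=vdirs[..., 1])
    out = np.empty((n_steps + 1, params.n_animals, 2))
    integrate_positions(homes, homes, vdirs, params.a, out)
    return out


def write_trajectory_csv(path, positions: np.ndarray) -> None:
    """Write positions (T, N, 2) as CSV with header ``animal_id,t,x,y``."""
    n_times, n_animals, _ = positions.shape
    animal = np.repeat(np.arange(n_animals), n_times)
    t = np.tile(np.arange(n_times), n_animals)
    # one block per animal, ordered by time within each block
    xy = positions.transpose(1, 0, 2).reshape(-1, 2)
    pd.DataFrame(
        {"animal_id": animal, "t": t, "x": xy[:, 0], "y": xy[:, 1]}
    ).to_csv(path, index=False)


def read_trajectory_csv(path) -> np.ndarray:
    """Read a trajectory CSV written by :func:`write_trajectory_csv` back to (T, N, 2)."""
    df = pd.read_csv(path)
    n_animals = df["animal_id"].nunique()
    n_times = df["t"].nunique()
    df = df.sort_values(["animal_id", "t"])
    return df[["x", "y"]].to_numpy().reshape(n_animals, n_times, 2).transpose(1, 0, 2)
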