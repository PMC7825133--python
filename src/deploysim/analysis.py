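"""Summary analyses of the transfer function.

Builds the curves a deployment designer actually reads off: <T> versus station
count (or versus total reception area), the R90 threshold (stations needed to
recover 90% of all packages), the (a, station-count) phase diagram, the
inter-event-time distribution, and the two nonlinear fits:

* saturating exponential ``T(area) = c * (1 - exp(-d * area))`` — ``d`` is the
  growth rate of the transfer function per unit covered area;
* four-parameter decay ``y(x) = y0 + A * exp(-(x - x0) / t1)`` — used for R90
  as a function of the reception radius, ``t1`` is the decay scale.

The decay form is over-parameterised: only ``y0``, ``t1`` and the combination
``B = A * exp(x0 / t1)`` are identifiable (the model equals
``y0 + B * exp(-x / t1)``).  All four parameters are reported for convenience,
but only the identifiable ones should be compared across fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import engine
from .deployment import covered_fraction, place_at_homes, place_random, total_reception_area
from .movement import MovementParams, as_rng

__all__ = [
    "SweepResult",
    "FitResult",
    "R90Result",
    "InterEventDistribution",
    "FitError",
    "saturating_exponential",
    "shifted_exponential_decay",
    "sweep_stations",
    "compute_R90",
    "fit_transfer_vs_area",
    "fit_R90_vs_radius",
    "phase_diagram",
    "inter_event_pdf",
    "d_vs_a",
]

#: realizations used when a caller does not say otherwise; reference runs in
#: the literature for this model average over 100.
DEFAULT_REALIZATIONS = 100


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the optimizer diagnostics."""


@dataclass
class SweepResult:
    """Tidy grid of mean transfer values.

    ``table`` columns: n_stations, covered_area, a, v, r, n_animals, n_steps,
    strategy, T_mean, T_std (ddof=1 across realizations), T_sem,
    n_realizations.  One row per grid point.
    """

    table: pd.DataFrame
    n_realizations: int


@dataclass(frozen=True)
class FitResult:
    """Nonlinear least-squares estimates with standard errors from the
    parameter covariance, plus the residual sum of squares."""

    model: str
    params: dict
    stderr: dict
    rss: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "saturating_exponential":
            return saturating_exponential(x, self.params["c"], self.params["d"])
        return shifted_exponential_decay(
            x, self.params["y0"], self.params["A"], self.params["x0"], self.params["t1"]
        )


@dataclass(frozen=True)
class R90Result:
    """Smallest swept station count whose mean <T> reaches 0.9.

    ``reached`` is False when the sweep plateaus below 0.9; then r90 and
    covered_fraction_at_r90 are None.  covered_fraction_at_r90 is the expected
    covered fraction f = 1 - (1 - pi r^2)^R90 at that count.
    """

    reached: bool
    r90: int | None
    covered_fraction_at_r90: float | None


@dataclass(frozen=True)
class InterEventDistribution:
    """Normalized density of inter-event times over log-spaced bins.

    ``density`` integrates to 1 against the linear bin widths:
    sum(density * diff(bin_edges)) == 1.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    n_samples: int


def saturating_exponential(x, c, d):
    return c * (1.0 - np.exp(-d * np.asarray(x, dtype=float)))


def shifted_exponential_decay(x, y0, a, x0, t1):
    return y0 + a * np.exp(-(np.asarray(x, dtype=float) - x0) / t1)


def _run_one(movement, x, radius, n_steps, rng, strategy, station_speed,
             collect_log=False):
    """Place stations per strategy and run one realization off one generator."""
    homes = None
    if strategy == "random":
        stations = place_random(x, radius, rng)
    elif strategy == "at_home":
        homes = rng.uniform(0.0, 1.0, (movement.n_animals, 2))
        stations = place_at_homes(homes, x, radius, rng)
    elif strategy == "mobile":
        stations = place_random(x, radius, rng, mobile=True,
                                station_speed=station_speed)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return engine.run(movement, stations, n_steps, rng, homes=homes,
                      collect_log=collect_log)


def sweep_stations(
    movement: MovementParams,
    counts,
    radius: float,
    n_steps: int,
    n_realizations: int,
    seed: int,
    *,
    strategy: str = "random",
    station_speed: float = 0.0,
) -> SweepResult:
    """Mean/std of <T> over realizations for each station count.

    Realization k of the batch for the j-th count uses seed
    ``seed + j * n_realizations + k``, so curves are reproducible and
    realizations are independent across the grid.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    rows = []
    for j, x in enumerate(counts):
        t_vals = np.empty(n_realizations)
        for k in range(n_realizations):
            rng = as_rng(seed + j * n_realizations + k)
            t_vals[k] = _run_one(movement, x, radius, n_steps, rng, strategy,
                                 station_speed).T_mean
        std = float(np.std(t_vals, ddof=1)) if n_realizations > 1 else 0.0
        rows.append(
            {
                "n_stations": int(x),
                "covered_area": total_reception_area(x, radius),
                "a": movement.a,
                "v": movement.v,
                "r": radius,
                "n_animals": movement.n_animals,
                "n_steps": int(n_steps),
                "strategy": strategy,
                "T_mean": float(t_vals.mean()),
                "T_std": std,
                "T_sem": std / np.sqrt(n_realizations),
                "n_realizations": n_realizations,
            }
        )
    return SweepResult(table=pd.DataFrame(rows), n_realizations=n_realizations)


def compute_R90(sweep: SweepResult) -> R90Result:
    """Smallest swept station count with mean <T> >= 0.9 (no interpolation).

    Because each animal generates one package per step, <T> >= 0.9 is the same
    statement as "at least 90% of all generated packages were recovered".
    """
    table = sweep.table.sort_values("n_stations")
    hit = table[table["T_mean"] >= 0.9]
    if hit.empty:
        return R90Result(reached=False, r90=None, covered_fraction_at_r90=None)
    row = hit.iloc[0]
    f = covered_fraction(float(row["r"]), 1.0, int(row["n_stations"])).f
    return R90Result(reached=True, r90=int(row["n_stations"]),
                     covered_fraction_at_r90=float(f))


def _fit(func, x, y, p0, names, model, bounds=(-np.inf, np.inf)):
    try:
        popt, pcov = curve_fit(func, x, y, p0=p0, bounds=bounds, maxfev=20000,
                               xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except RuntimeError as exc:  # no convergence
        raise FitError(f"{model} fit failed: {exc}; p0={p0}, n={len(x)}") from exc
    stderr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((np.asarray(y) - func(np.asarray(x), *popt)) ** 2))
    return FitResult(
        model=model,
        params=dict(zip(names, map(float, popt))),
        stderr=dict(zip(names, map(float, stderr))),
        rss=rss,
    )


def fit_transfer_vs_area(areas, t_means) -> FitResult:
    """Fit T(area) = c * (1 - exp(-d * area)) by nonlinear least squares.

    The saturation level c is the asymptotically recovered fraction of
    packages, so it is constrained to (0, 1]; d is constrained positive.
    Without the constraint, sweeps that stop short of saturation let (c, d)
    wander along the c*d = slope degeneracy into unphysical c > 1.
    Initialization: c0 = max observed T (clipped into bounds),
    d0 = 1 / mean(area).
    """
    areas = np.asarray(areas, dtype=float)
    t_means = np.asarray(t_means, dtype=float)
    if areas.size < 4:
        raise ValueError("need at least 4 points for the saturating fit")
    if np.any(np.diff(areas) <= 0):
        raise ValueError("areas must be strictly increasing")
    c0 = float(np.clip(t_means.max(), 1e-6, 1.0))
    d0 = 1.0 / float(areas.mean()) if areas.mean() > 0 else 1.0
    return _fit(saturating_exponential, areas, t_means, [c0, d0], ["c", "d"],
                "saturating_exponential", bounds=([0.0, 0.0], [1.0, np.inf]))


def fit_R90_vs_radius(radii, r90s) -> FitResult:
    """Fit R90(r) = y0 + A * exp(-(r - x0) / t1).

    Initialization: y0 = min y, A = range of y, x0 = min x, t1 = x-range / 3.
    The decay scale t1 (and y0, and B = A * exp(x0 / t1)) are the identifiable
    quantities; see the module docstring.
    """
    radii = np.asarray(radii, dtype=float)
    r90s = np.asarray(r90s, dtype=float)
    if radii.size < 5:
        raise ValueError("need at least 5 points for the 4-parameter decay fit")
    y0 = float(r90s.min())
    amp = float(np.ptp(r90s)) or 1.0
    x0 = float(radii.min())
    t1 = float(np.ptp(radii)) / 3.0 or 1.0
    return _fit(shifted_exponential_decay, radii, r90s, [y0, amp, x0, t1],
                ["y0", "A", "x0", "t1"], "shifted_exponential_decay")


def phase_diagram(
    a_values,
    counts,
    radius: float,
    v: float,
    n_animals: int,
    n_steps: int,
    n_realizations: int,
    seed: int,
) -> SweepResult:
    """Mean <T> over the (home attraction, station count) grid, random placement."""
    a_values = list(a_values)
    counts = list(counts)
    if not a_values or not counts:
        raise ValueError("a_values and counts must be non-empty")
    tables = []
    for ai, a in enumerate(a_values):
        movement = MovementParams(v=v, a=a, n_animals=n_animals)
        sub = sweep_stations(movement, counts, radius, n_steps, n_realizations,
                             seed + ai * 100_000)
        tables.append(sub.table)
    return SweepResult(table=pd.concat(tables, ignore_index=True),
                       n_realizations=n_realizations)


def inter_event_pdf(logs, n_bins: int = 30) -> InterEventDistribution:
    """Log-binned probability density of pooled inter-event times.

    ``logs`` is an iterable of TransmissionLog; intervals tau are pooled over
    animals and realizations.  Bins are equal-width in log10(tau); the density
    is per unit (linear) tau, so it integrates to 1 over the bins.  A
    degenerate pool (all tau equal, e.g. permanently-in-range animals) yields
    a single unit-width bin holding all the mass.
    """
    taus = [log.inter_event_times() for log in logs]
    taus = [t for t in taus if t.size]
    if not taus:
        return InterEventDistribution(
            bin_edges=np.empty(0), density=np.empty(0),
            counts=np.empty(0, dtype=np.int64), n_samples=0,
        )
    tau = np.concatenate(taus).astype(float)
    lo, hi = tau.min(), tau.max()
    if lo == hi:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max sample
    counts, _ = np.histogram(tau, bins=edges)
    widths = np.diff(edges)
    density = counts / (counts.sum() * widths)
    return InterEventDistribution(bin_edges=edges, density=density,
                                  counts=counts.astype(np.int64),
                                  n_samples=int(tau.size))


def d_vs_a(
    a_values,
    counts,
    radius: float,
    v: float,
    n_animals: int,
    n_steps: int,
    n_realizations: int,
    seed: int,
) -> pd.DataFrame:
    """Fitted growth rate d (with c and standard errors) for each home attraction.

    Runs one random-placement sweep per ``a`` and fits the saturating
    exponential against total reception area.  Fit failures propagate.
    """
    rows = []
    for ai, a in enumerate(a_values):
        movement = MovementParams(v=v, a=a, n_animals=n_animals)
        sweep = sweep_stations(movement, counts, radius, n_steps, n_realizations,
                               seed + ai * 100_000)
        fit = fit_transfer_vs_area(sweep.table["covered_area"], sweep.table["T_mean"])
        rows.append(
            {
                "a": a,
                "d": fit.params["d"],
                "d_stderr": fit.stderr["d"],
                "c": fit.params["c"],
                "c_stderr": fit.stderr["c"],
                "rss": fit.rss,
            }
        )
    return pd.DataFrame(rows)
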