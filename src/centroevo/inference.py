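"""Parameter fitting to extra-centrosome time courses and sensitivity scans.

The observable is the fraction of cells with supernumerary centrosomes
scored on each observation day.  Free parameters are fitted by
unweighted least squares on those fractions (optionally inverse-variance
weighted by the binomial sampling variance when per-day cell counts are
known), using a deterministic multi-start grid followed by bounded local
refinement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .population import (
    Model,
    PopulationParams,
    Trajectory,
    build_matrix,
    extra_centrosome_fraction,
    initial_state,
    integrate,
)
from .steady_state import steady_state_extra_fraction

# Fitting ranges for the free parameters (both models).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "v": (0.0, 0.6),
    "r_S": (0.5, 1.0),
    "b_C2": (0.8, 1.2),
    "b_C4": (0.6, 1.0),
    "q": (0.975, 1.0),
}

DEFAULT_OBSERVATION_DAYS = (0, 2, 4, 6, 8, 10, 12)


@dataclass(frozen=True)
class TimeCourseDataset:
    """Observed per-day extra-centrosome fractions for one cell line."""

    cell_line: str
    days: np.ndarray
    extra_fractions: np.ndarray
    n_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        fr = np.asarray(self.extra_fractions, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "extra_fractions", fr)
        if len(days) != len(fr):
            raise ValueError("days and extra_fractions must have equal length")
        if len(np.unique(days)) != len(days):
            raise ValueError("days must be unique")
        if np.any((fr < 0) | (fr > 1)):
            raise ValueError("extra_fractions must lie in [0, 1]")
        if self.n_cells is not None:
            n = np.asarray(self.n_cells, dtype=int)
            object.__setattr__(self, "n_cells", n)
            if len(n) != len(days) or np.any(n <= 0):
                raise ValueError("n_cells must be positive and match days")

    def sorted_by_day(self) -> "TimeCourseDataset":
        order = np.argsort(self.days)
        return TimeCourseDataset(
            cell_line=self.cell_line,
            days=self.days[order],
            extra_fractions=self.extra_fractions[order],
            n_cells=None if self.n_cells is None else self.n_cells[order],
        )


@dataclass(frozen=True)
class FitResult:
    fitted: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    loss: float
    residuals: np.ndarray
    days: np.ndarray
    fixed: PopulationParams
    model: Model
    alpha: float
    converged: bool
    n_starts: int
    messages: tuple[str, ...] = field(default=(), repr=False)

    def params(self) -> PopulationParams:
        return self.fixed.replace(**self.fitted)


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    grid: np.ndarray
    metric: np.ndarray
    metric_kind: str
    direction: str  # "increasing" | "decreasing" | "non-monotone" | "flat" | "single-point"

    @property
    def normalized_range(self) -> float:
        """Spread of the metric over the scan, used to rank sensitivities."""
        return float(np.max(self.metric) - np.min(self.metric))


def predict_extra_fractions(
    params: PopulationParams,
    model: Model,
    alpha: float,
    days: np.ndarray,
    sc_seeding: str = "by_v",
    include_C6: bool = True,
) -> np.ndarray:
    """Model-predicted extra-centrosome fraction at each observation day."""
    matrix = build_matrix(params, model)
    state0 = initial_state(alpha, 1.0, params, model, sc_seeding=sc_seeding)
    days = np.asarray(days, dtype=float)
    # integrate needs strictly increasing times starting at t0
    t = days if days[0] > 0 else days[1:]
    out = np.empty(len(days))
    k = 0
    if days[0] == 0:
        out[0] = extra_centrosome_fraction(state0, include_C6)
        k = 1
    if len(t):
        traj: Trajectory = integrate(matrix, state0, t)
        for i in range(len(t)):
            out[k + i] = extra_centrosome_fraction(traj.state_at(i), include_C6)
    return out


def _loss(theta, names, dataset, fixed, model, alpha, sc_seeding, weights):
    params = fixed.replace(**dict(zip(names, theta)))
    pred = predict_extra_fractions(params, model, alpha, dataset.days, sc_seeding)
    resid = pred - dataset.extra_fractions
    return float(np.sum(weights * resid**2))


def fit(
    dataset: TimeCourseDataset,
    free: dict[str, tuple[float, float]] | list[str],
    fixed: PopulationParams,
    model: Model = "II",
    alpha: float = 0.10,
    sc_seeding: str = "by_v",
    n_grid: int = 5,
    weight_by_variance: bool = False,
) -> FitResult:
    """Least-squares fit of the free parameters to an observed time course.

    ``free`` names a subset of v, r_S, b_C2, b_C4, q, each with optional
    bounds (defaults: the standard fitting ranges).  A full grid of
    ``n_grid`` points per free dimension seeds bounded L-BFGS-B
    refinements; the best local optimum wins.  Deterministic — no
    randomness is involved.
    """
    if isinstance(free, (list, tuple, set)):
        unknown = [n for n in free if n not in DEFAULT_BOUNDS]
        if unknown:
            raise ValueError(f"{unknown} are not fittable parameters")
        free = {name: DEFAULT_BOUNDS[name] for name in free}
    for name, (lo, hi) in free.items():
        if name not in DEFAULT_BOUNDS:
            raise ValueError(f"{name!r} is not a fittable parameter")
        dlo, dhi = DEFAULT_BOUNDS[name]
        if lo < dlo - 1e-12 or hi > dhi + 1e-12:
            raise ValueError(f"bounds for {name} exceed the allowed range {DEFAULT_BOUNDS[name]}")
    dataset = dataset.sorted_by_day()
    if len(dataset.days) < len(free):
        raise ValueError(
            f"{len(dataset.days)} observations cannot constrain {len(free)} free parameters"
        )
    if weight_by_variance and dataset.n_cells is not None:
        f = np.clip(dataset.extra_fractions, 1e-3, 1 - 1e-3)
        weights = dataset.n_cells / (f * (1 - f))
    else:
        weights = np.ones(len(dataset.days))

    names = sorted(free)
    bounds = [free[n] for n in names]
    grids = [np.linspace(lo, hi, n_grid) for lo, hi in bounds]

    best = None
    messages = []
    for start in itertools.product(*grids):
        res = minimize(
            _loss, np.array(start),
            args=(names, dataset, fixed, model, alpha, sc_seeding, weights),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
        if not res.success:
            messages.append(str(res.message))
    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    fitted = dict(zip(names, map(float, theta)))
    pred = predict_extra_fractions(
        fixed.replace(**fitted), model, alpha, dataset.days, sc_seeding
    )
    return FitResult(
        fitted=fitted,
        bounds=dict(zip(names, bounds)),
        loss=float(best.fun),
        residuals=pred - dataset.extra_fractions,
        days=dataset.days,
        fixed=fixed,
        model=model,
        alpha=alpha,
        converged=bool(best.success),
        n_starts=int(np.prod([len(g) for g in grids])),
        messages=tuple(messages),
    )


def goodness_of_fit(result: FitResult, dataset: TimeCourseDataset) -> pd.DataFrame:
    """RMS residual and per-day residual table for a completed fit."""
    dataset = dataset.sorted_by_day()
    if len(dataset.days) != len(result.days) or not np.allclose(dataset.days, result.days):
        raise ValueError("dataset does not match the one the fit was produced from")
    table = pd.DataFrame({
        "day": dataset.days,
        "observed": dataset.extra_fractions,
        "predicted": dataset.extra_fractions + result.residuals,
        "residual": result.residuals,
    })
    table.attrs["rms"] = float(np.sqrt(np.mean(result.residuals**2)))
    return table


def sensitivity_scan(
    params: PopulationParams,
    model: Model,
    name: str,
    grid: np.ndarray,
    metric: str = "steady_state",
    alpha: float = 0.10,
    final_day: float = 12.0,
    sc_seeding: str = "by_v",
) -> SensitivityResult:
    """Evaluate the extra-centrosome metric over a one-parameter grid.

    ``metric`` is either ``"steady_state"`` (limiting extra-centrosome
    fraction from the leading eigenpair) or ``"final_day"`` (fraction at
    ``final_day`` from integration); all other parameters stay fixed.
    """
    if name not in PopulationParams.__dataclass_fields__:
        raise ValueError(f"unknown parameter {name!r}")
    if metric not in ("steady_state", "final_day"):
        raise ValueError(f"unknown metric {metric!r}")
    grid = np.asarray(grid, dtype=float)
    values = np.empty(len(grid))
    for i, g in enumerate(grid):
        p = params.replace(**{name: float(g)})
        if metric == "steady_state":
            values[i] = steady_state_extra_fraction(build_matrix(p, model))
        else:
            values[i] = predict_extra_fractions(p, model, alpha, np.array([final_day]), sc_seeding)[0]
    if len(grid) == 1:
        direction = "single-point"
    else:
        d = np.diff(values)
        if np.all(np.abs(d) < 1e-12):
            direction = "flat"
        elif np.all(d >= -1e-12):
            direction = "increasing"
        elif np.all(d <= 1e-12):
            direction = "decreasing"
        else:
            direction = "non-monotone"
    return SensitivityResult(
        parameter=name, grid=grid, metric=values, metric_kind=metric, direction=direction
    )
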