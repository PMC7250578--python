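"""Deterministic population dynamics of centrosome classes.

Cell types are labelled by mitotic centrosome number: C2 (normal), C4
(doubled, the newly formed tetraploid state), C6 (tripled), and — in
Model II — SC ("super-clustering") cells, C4-like cells that cluster
their extra centrosomes with high efficiency and divide bipolarly with
the rates of normal cells.

Both models are linear constant-coefficient ODE systems dX/dt = P·X.
Model I tracks (C2, C4, C6); Model II adds SC.  The coefficient matrix
entries combine per-day division rates (b_C2, b_C4), death rates (d_C2,
d_C4, d_C6) and the division-fate probabilities:

* q   — probability a C2 division is normal (1−q = cytokinesis failure,
        which creates a cell with doubled centrosomes);
* p_bipolar — probability a C4 cell manages a bipolar division by
        clustering its centrosomes;
* r   — probability that bipolar division clusters symmetrically
        (2 C4 daughters); otherwise asymmetric 3:1 clustering yields
        C2 + C6;
* fs  — probability the sole potentially viable daughter (a C4) of a
        multipolar C4 division survives (combined parameter);
* v   — probability a cytokinesis-failure product is an SC cell
        (Model II only);
* r_S — probability an SC division is symmetric (SC+SC); otherwise it
        is asymmetric (C2 + C6) (Model II only).

Time unit is days throughout; all rates are per day.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

Model = Literal["I", "II"]

STATE_LABELS = ("C2", "C4", "SC", "C6")


@dataclass(frozen=True)
class PopulationParams:
    """Rate and probability constants of Models I and II.

    Rates are per day; all probabilities in [0, 1].  ``v`` and ``r_S``
    are ignored by Model I.
    """

    b_C2: float
    b_C4: float
    q: float
    p_bipolar: float
    r: float
    fs: float
    d_C2: float
    d_C4: float
    d_C6: float
    v: float = 0.0
    r_S: float = 1.0

    def __post_init__(self) -> None:
        for name in ("b_C2", "b_C4", "d_C2", "d_C4", "d_C6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative rate")
        for name in ("q", "p_bipolar", "r", "fs", "v", "r_S"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")

    def replace(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)


# Table-derived named defaults for the two studied cell lines.
PRESETS: dict[str, PopulationParams] = {
    "dld1": PopulationParams(
        b_C2=1.2, b_C4=1.0, q=0.975, p_bipolar=0.33, r=0.5, fs=0.4,
        d_C2=0.0, d_C4=0.5, d_C6=1.5, v=0.22, r_S=0.93,
    ),
    "rpe1_p53ko": PopulationParams(
        b_C2=0.94, b_C4=0.6, q=0.975, p_bipolar=0.25, r=0.7, fs=0.7,
        d_C2=0.0, d_C4=0.12, d_C6=1.5, v=0.32, r_S=0.90,
    ),
}

# Day-0 fractions of cells with extra centrosomes observed after the
# cytokinesis block (G1 scoring): 90% DLD-1, 87.3% RPE-1 p53-null.
DAY0_ALPHA: dict[str, float] = {"dld1": 0.10, "rpe1_p53ko": 0.127}


@dataclass(frozen=True)
class PopulationState:
    """Cell-type abundances at one time point (counts or unit-total fractions)."""

    time: float
    C2: float
    C4: float
    SC: float = 0.0
    C6: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.C2, self.C4, self.SC, self.C6])

    @property
    def total(self) -> float:
        return self.C2 + self.C4 + self.SC + self.C6


@dataclass(frozen=True)
class RateMatrix:
    """Coefficient matrix P of the linear system dX/dt = P·X."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    model: Model


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_times, n_types), columns ordered as labels
    labels: tuple[str, ...]

    def state_at(self, i: int) -> PopulationState:
        row = dict(zip(self.labels, self.states[i]))
        return PopulationState(time=float(self.times[i]), **row)

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(len(self.times) - 1)


@dataclass(frozen=True)
class FractionTrajectory:
    times: np.ndarray
    fractions: np.ndarray  # rows sum to 1
    totals: np.ndarray     # normalizer C(t) = total population
    labels: tuple[str, ...]


def build_matrix(params: PopulationParams, model: Model) -> RateMatrix:
    """Coefficient matrix of Model I (3×3, order C2,C4,C6) or Model II (4×4, order C2,C4,SC,C6)."""
    b2, b4 = params.b_C2, params.b_C4
    q, p, r, fs = params.q, params.p_bipolar, params.r, params.fs
    d2, d4, d6 = params.d_C2, params.d_C4, params.d_C6
    c4_self = b4 * (2 * p * r + (1 - p) * fs - 1) - d4
    if model == "I":
        mat = np.array([
            [b2 * (2 * q - 1) - d2, b4 * p * (1 - r), 0.0],
            [b2 * (1 - q), c4_self, 0.0],
            [0.0, b4 * p * (1 - r), -d6],
        ])
        return RateMatrix(labels=("C2", "C4", "C6"), matrix=mat, model="I")
    if model == "II":
        v, rS = params.v, params.r_S
        mat = np.array([
            [b2 * (2 * q - 1) - d2, b4 * p * (1 - r), b2 * (1 - rS), 0.0],
            [b2 * (1 - q) * (1 - v), c4_self, 0.0, 0.0],
            [b2 * (1 - q) * v, 0.0, b2 * (2 * rS - 1) - d2, 0.0],
            [0.0, b4 * p * (1 - r), b2 * (1 - rS), -d6],
        ])
        return RateMatrix(labels=("C2", "C4", "SC", "C6"), matrix=mat, model="II")
    raise ValueError(f"unknown model {model!r}")


def initial_state(
    alpha: float,
    total: float = 1.0,
    params: PopulationParams | None = None,
    model: Model = "II",
    sc_seeding: Literal["by_v", "none"] = "by_v",
) -> PopulationState:
    """Day-0 state: fraction alpha of normal C2 cells, the rest carrying extra centrosomes.

    The extra-centrosome pool was created by one induced cytokinesis-
    failure event, so under the default rule a fraction v of it is
    seeded as SC and the rest as C4.  Model I (or ``sc_seeding="none"``)
    puts the whole pool in C4.  C6 starts at zero.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    extra = (1.0 - alpha) * total
    if model == "I" or sc_seeding == "none":
        return PopulationState(time=0.0, C2=alpha * total, C4=extra, SC=0.0, C6=0.0)
    if params is None:
        raise ValueError("params required for Model II seeding by v")
    return PopulationState(
        time=0.0,
        C2=alpha * total,
        C4=(1.0 - params.v) * extra,
        SC=params.v * extra,
        C6=0.0,
    )


def _state_vector(state: PopulationState, labels: Sequence[str]) -> np.ndarray:
    lookup = {"C2": state.C2, "C4": state.C4, "SC": state.SC, "C6": state.C6}
    return np.array([lookup[lab] for lab in labels])


def integrate(
    matrix: RateMatrix,
    state0: PopulationState,
    times: Iterable[float],
    method: Literal["expm", "ivp"] = "expm",
) -> Trajectory:
    """Solve dX/dt = P·X at the requested times.

    The default path is the matrix exponential, exact for a linear
    constant-coefficient system up to floating point; ``method="ivp"``
    runs an adaptive Runge–Kutta integrator (rtol 1e-10/atol 1e-12) as
    an independent cross-check.
    """
    t = np.asarray(list(times), dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a non-empty strictly increasing sequence")
    if t[0] < state0.time:
        raise ValueError("times must start at or after state0.time")
    x0 = _state_vector(state0, matrix.labels)
    P = matrix.matrix
    if not np.all(np.isfinite(P)) or not np.all(np.isfinite(x0)):
        raise FloatingPointError("non-finite matrix or state entries")
    if method == "expm":
        out = np.empty((len(t), len(x0)))
        for i, ti in enumerate(t):
            out[i] = expm(P * (ti - state0.time)) @ x0
    elif method == "ivp":
        sol = solve_ivp(
            lambda _t, x: P @ x, (state0.time, t[-1]), x0,
            t_eval=t, method="DOP853", rtol=1e-10, atol=1e-12,
        )
        if not sol.success:
            raise FloatingPointError(f"integration failed: {sol.message}")
        out = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")
    return Trajectory(times=t, states=out, labels=matrix.labels)


def fractions(trajectory: Trajectory) -> FractionTrajectory:
    """Normalize abundances to per-type fractions f_i(t) = X_i(t) / Σ_j X_j(t)."""
    totals = trajectory.states.sum(axis=1)
    if np.any(totals <= 0):
        raise ZeroDivisionError("total population is zero at some output time")
    return FractionTrajectory(
        times=trajectory.times,
        fractions=trajectory.states / totals[:, None],
        totals=totals,
        labels=trajectory.labels,
    )


def extra_centrosome_fraction(state: PopulationState, include_C6: bool = True) -> float:
    """Fraction of the population carrying supernumerary centrosomes.

    C4 and SC cells always count; C6 cells count by default (any cell
    with more than one centrosome), with an option to exclude them.
    """
    total = state.total
    if total <= 0:
        raise ZeroDivisionError("total population is zero")
    extra = state.C4 + state.SC + (state.C6 if include_C6 else 0.0)
    return extra / total


def sc_share_of_extra(state: PopulationState) -> float:
    """Share of the extra-centrosome pool made up of SC cells: SC/(C4+SC+C6)."""
    extra = state.C4 + state.SC + state.C6
    if extra <= 0:
        raise ZeroDivisionError("no extra-centrosome cells")
    return state.SC / extra


def fraction_ode_rhs(P: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Right-hand side of the nonlinear fraction dynamics df/dt = P·f − C(t)·f.

    C(t) = 1ᵀP·f is the instantaneous per-capita growth rate.  Used as
    an independent oracle for :func:`fractions`.
    """
    Pf = P @ f
    return Pf - Pf.sum() * f
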