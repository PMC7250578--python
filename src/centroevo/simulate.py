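"""Stochastic agent-based lineage simulation and synthetic-data generation.

Two simulators share the per-cell fate rules of the deterministic
models:

* :func:`simulate_lineages` — a continuous-time (Gillespie) birth-death
  simulation over the cell-type counts (C2, C4, SC, C6).  Its ensemble
  mean converges to the linear ODE trajectories; it is the generator of
  synthetic extra-centrosome time courses.
* :func:`simulate_karyotype_evolution` — the same fate machinery with a
  per-cell replicated karyotype attached, where multipolar divisions
  partition chromosomes at random among 3 or 4 poles and a viability
  rule (nullisomy lethal; optional monosomy penalty) culls daughters.
  It emits per-day chromosome-count histograms.

Observation noise is emulated by :func:`sample_observations`: on each
sampling day n cells are scored and the extra-centrosome count is
binomial in the true fraction.

Fate table (division events; death events simply remove the cell):

====  ====================================================================
type  outcome
====  ====================================================================
C2    prob q: 2 C2 (normal bipolar); prob 1−q: cytokinesis failure →
      one binucleate cell, SC with prob v (Model II) else C4
C4    prob p·r: 2 C4 (bipolar symmetric); prob p·(1−r): C2 + C6 (bipolar
      asymmetric 3:1 clustering); prob 1−p: multipolar — one C4
      daughter survives with prob fs, otherwise all progeny die
SC    prob r_S: 2 SC (symmetric); prob 1−r_S: C2 + C6 (asymmetric)
C6    never divides viably; removed at rate d_C6
====  ====================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import TimeCourseDataset
from .partition import partition_karyotype
from .population import Model, PopulationParams

_TYPES = ("C2", "C4", "SC", "C6")
_C2, _C4, _SC, _C6 = range(4)


@dataclass(frozen=True)
class SimConfig:
    """Run geometry for the stochastic simulators."""

    seed: int
    n0: int = 5000
    alpha: float = 0.10
    duration: float = 12.0
    cap: int = 20_000
    sampling_days: tuple[float, ...] = (0, 2, 4, 6, 8, 10, 12)
    n_sample: int = 300

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.cap < self.n0:
            raise ValueError("cap must be >= n0")
        if any(d < 0 or d > self.duration for d in self.sampling_days):
            raise ValueError("sampling days must lie within [0, duration]")


@dataclass(frozen=True)
class LineageEvent:
    time: float
    cell_id: int
    cell_type: str
    kind: str  # bipolar-symmetric | bipolar-asymmetric | multipolar-survive |
    #            multipolar-fatal | cytokinesis-failure | death
    daughters: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True)
class KaryotypeSimConfig:
    """Settings of the karyotype-evolution branch."""

    n_chromosome_types: int = 23
    ploidy: int = 4
    tripolar_prob: float = 0.5  # remainder is tetrapolar
    nullisomy_lethal: bool = True
    monosomy_survival: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tripolar_prob <= 1.0:
            raise ValueError("tripolar_prob must lie in [0, 1]")
        if not 0.0 <= self.monosomy_survival <= 1.0:
            raise ValueError("monosomy_survival must lie in [0, 1]")
        if self.n_chromosome_types < 1 or self.ploidy < 1:
            raise ValueError("invalid chromosome/ploidy settings")


@dataclass
class LineageResult:
    counts: pd.DataFrame  # columns time_days, C2, C4, SC, C6
    events: list[LineageEvent] = field(default_factory=list)
    extinct: bool = False


def _initial_counts(config: SimConfig, params: PopulationParams, model: Model,
                    rng: np.random.Generator) -> np.ndarray:
    """Multinomial day-0 assignment: alpha → C2; the rest SC w.p. v (Model II) else C4."""
    n = np.zeros(4, dtype=np.int64)
    p_sc = (1 - config.alpha) * params.v if model == "II" else 0.0
    draw = rng.multinomial(config.n0, [config.alpha, 1 - config.alpha - p_sc, p_sc, 0.0])
    n[:] = draw
    return n


def _division_outcome(cell_type: int, params: PopulationParams, model: Model,
                      u: float, u2: float) -> tuple[str, list[int]]:
    """Map uniform draws to (event kind, daughter types) for one division."""
    if cell_type == _C2:
        if u < params.q:
            return "bipolar-symmetric", [_C2, _C2]
        if model == "II" and u2 < params.v:
            return "cytokinesis-failure", [_SC]
        return "cytokinesis-failure", [_C4]
    if cell_type == _C4:
        p, r = params.p_bipolar, params.r
        if u < p * r:
            return "bipolar-symmetric", [_C4, _C4]
        if u < p:
            return "bipolar-asymmetric", [_C2, _C6]
        if u2 < params.fs:
            return "multipolar-survive", [_C4]
        return "multipolar-fatal", []
    if cell_type == _SC:
        if u < params.r_S:
            return "bipolar-symmetric", [_SC, _SC]
        return "bipolar-asymmetric", [_C2, _C6]
    raise AssertionError("C6 cells do not divide")


def simulate_lineages(
    params: PopulationParams,
    model: Model,
    config: SimConfig,
    record_events: bool = False,
) -> LineageResult:
    """Exact continuous-time simulation of the cell-type counting process.

    Each cell of type i divides at rate b_i and dies at rate d_i
    (exponential waiting times); division outcomes follow the fate
    table.  When the population exceeds ``config.cap`` a uniformly
    random cell is discarded (passaging by subsampling — unbiased for
    the type fractions).  Counts are recorded at ``config.sampling_days``.

    With ``record_events=True`` an event log with stable cell ids is
    kept; intended for small populations.
    """
    rng = np.random.default_rng(config.seed)
    b = np.array([params.b_C2, params.b_C4, params.b_C2, 0.0])
    d = np.array([params.d_C2, params.d_C4, params.d_C2, params.d_C6])
    n = _initial_counts(config, params, model, rng)

    events: list[LineageEvent] = []
    pools: list[list[int]] | None = None
    next_id = 0
    if record_events:
        pools = [[], [], [], []]
        for t_idx in range(4):
            for _ in range(int(n[t_idx])):
                pools[t_idx].append(next_id)
                next_id += 1

    sample_times = sorted(config.sampling_days)
    recorded: list[tuple[float, np.ndarray]] = []
    si = 0
    t = 0.0
    # pre-drawn uniform/exponential blocks to cut per-event RNG overhead
    BLOCK = 8192
    exps = rng.exponential(size=BLOCK)
    unis = rng.random(size=(BLOCK, 3))
    ptr = 0

    def refill():
        nonlocal exps, unis, ptr
        exps = rng.exponential(size=BLOCK)
        unis = rng.random(size=(BLOCK, 3))
        ptr = 0

    while True:
        rates = n * (b + d)
        total_rate = rates.sum()
        if total_rate == 0.0:
            break
        if ptr >= BLOCK:
            refill()
        dt = exps[ptr] / total_rate
        u_type, u_fate, u_fate2 = unis[ptr]
        ptr += 1
        t_next = t + dt
        while si < len(sample_times) and sample_times[si] <= t_next:
            recorded.append((sample_times[si], n.copy()))
            si += 1
        if si >= len(sample_times) or t_next > config.duration:
            t = t_next
            break
        t = t_next

        # pick (type, division-vs-death) proportional to rates
        x = u_type * total_rate
        cum = 0.0
        cell_type, is_division = 0, True
        done = False
        for i in range(4):
            cum += n[i] * b[i]
            if x < cum:
                cell_type, is_division = i, True
                done = True
                break
            cum += n[i] * d[i]
            if x < cum:
                cell_type, is_division = i, False
                done = True
                break
        if not done:  # numerical edge: attribute to the last nonzero channel
            cell_type, is_division = _C6, False

        if record_events:
            pool = pools[cell_type]
            j = int(u_fate2 * len(pool)) % len(pool)
            pool[j], pool[-1] = pool[-1], pool[j]
            mother_id = pool.pop()
        n[cell_type] -= 1

        if is_division:
            kind, daughters = _division_outcome(cell_type, params, model, u_fate, u_fate2)
            for dtype in daughters:
                n[dtype] += 1
            if record_events:
                d_ids = []
                for dtype in daughters:
                    pools[dtype].append(next_id)
                    d_ids.append((next_id, _TYPES[dtype]))
                    next_id += 1
                events.append(LineageEvent(t, mother_id, _TYPES[cell_type], kind, tuple(d_ids)))
        else:
            if record_events:
                events.append(LineageEvent(t, mother_id, _TYPES[cell_type], "death"))

        # passaging: discard uniformly random cells while above cap
        while n.sum() > config.cap:
            probs = n / n.sum()
            victim = rng.choice(4, p=probs)
            n[victim] -= 1
            if record_events:
                pool = pools[victim]
                j = rng.integers(len(pool))
                pool[j], pool[-1] = pool[-1], pool[j]
                pool.pop()

    for s in sample_times[si:]:
        recorded.append((s, n.copy()))

    counts = pd.DataFrame(
        [{"time_days": tt, **dict(zip(_TYPES, cc))} for tt, cc in recorded]
    )
    return LineageResult(counts=counts, events=events, extinct=bool(n.sum() == 0))


def sample_observations(
    counts: pd.DataFrame,
    sampling_days: tuple[float, ...],
    n: int,
    seed: int,
    cell_line: str = "synthetic",
) -> TimeCourseDataset:
    """Score n cells per sampling day; extra-centrosome count is binomial.

    ``counts`` is a trajectory table with columns time_days, C2, C4, SC,
    C6 (output of :func:`simulate_lineages`, or an ODE trajectory dumped
    to the same layout).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fractions = []
    for day in sampling_days:
        row = counts[np.isclose(counts["time_days"], day)]
        if row.empty:
            raise ValueError(f"sampling day {day} not present in trajectory")
        r = row.iloc[0]
        total = r["C2"] + r["C4"] + r["SC"] + r["C6"]
        if total <= 0:
            raise ValueError(f"empty population at day {day}")
        true_frac = (r["C4"] + r["SC"] + r["C6"]) / total
        fractions.append(rng.binomial(n, true_frac) / n)
    return TimeCourseDataset(
        cell_line=cell_line,
        days=np.asarray(sampling_days, dtype=float),
        extra_fractions=np.asarray(fractions),
        n_cells=np.full(len(sampling_days), n),
    )


def make_synthetic_time_course(
    params: PopulationParams,
    model: Model,
    config: SimConfig,
    cell_line: str = "synthetic",
) -> TimeCourseDataset:
    """Convenience: lineage simulation + per-day binomial scoring in one call."""
    result = simulate_lineages(params, model, config)
    return sample_observations(
        result.counts, tuple(sorted(config.sampling_days)), config.n_sample,
        seed=config.seed + 1, cell_line=cell_line,
    )


def daughter_viable(
    copy_numbers: np.ndarray, kconfig: KaryotypeSimConfig, u: float
) -> bool:
    """Viability rule for a multipolar daughter.

    Nullisomy (zero copies of any chromosome) is lethal when
    ``nullisomy_lethal``; if any chromosome is monosomic the cell
    survives with probability ``monosomy_survival`` (default 1 — only
    certain monosomies are lethal in reality, so the penalty is off
    unless configured).
    """
    if kconfig.nullisomy_lethal and np.any(copy_numbers == 0):
        return False
    if np.any(copy_numbers == 1) and u >= kconfig.monosomy_survival:
        return False
    return True


def simulate_karyotype_evolution(
    params: PopulationParams,
    kconfig: KaryotypeSimConfig,
    config: SimConfig,
    model: Model = "II",
) -> dict[float, np.ndarray]:
    """Couple the lineage fate rules to per-cell chromosome bookkeeping.

    Every cell carries a replicated-copy-number vector (length M).  The
    population starts with alpha·n0 diploid C2 non-responders (ploidy
    k/2) and the rest tetraploid (ploidy k, split SC/C4 as in the
    lineage simulator).  Bipolar divisions copy the karyotype to both
    daughters (no missegregation); cytokinesis failure doubles it;
    multipolar divisions of C4 cells partition each replicated
    chromosome among 3 or 4 poles (tripolar with ``tripolar_prob``).
    In a tripolar division the mother's four centrosomes split 2:1:1,
    so one daughter is C4-like and the rest C2-like; in a tetrapolar
    division every daughter is C2-like.  Multipolar daughters survive
    or die by the karyotype viability rule (which replaces the bulk
    survival parameter fs in this mechanistic branch).

    Returns ``{day: histogram}`` where ``histogram[c]`` counts cells
    whose chromatid total is c at that day (length = max count + 1).
    """
    rng = np.random.default_rng(config.seed)
    M, k = kconfig.n_chromosome_types, kconfig.ploidy
    if k % 2 != 0:
        raise ValueError("ploidy must be even (diploid non-responders carry k/2 copies)")
    b = np.array([params.b_C2, params.b_C4, params.b_C2, 0.0])
    d = np.array([params.d_C2, params.d_C4, params.d_C2, params.d_C6])

    types: list[int] = []
    karyos: list[np.ndarray] = []
    n_c2 = int(round(config.alpha * config.n0))
    diploid = np.full(M, k // 2, dtype=np.int64)
    tetra = np.full(M, k, dtype=np.int64)
    for _ in range(n_c2):
        types.append(_C2)
        karyos.append(diploid.copy())
    for _ in range(config.n0 - n_c2):
        is_sc = model == "II" and rng.random() < params.v
        types.append(_SC if is_sc else _C4)
        karyos.append(tetra.copy())

    by_type: list[list[int]] = [[], [], [], []]
    for idx, ct in enumerate(types):
        by_type[ct].append(idx)
    alive = [True] * len(types)

    def remove(idx: int) -> None:
        alive[idx] = False
        pool = by_type[types[idx]]
        pool.remove(idx)  # pools stay small at desk scale

    def add(ct: int, karyo: np.ndarray) -> int:
        types.append(ct)
        karyos.append(karyo)
        alive.append(True)
        by_type[ct].append(len(types) - 1)
        return len(types) - 1

    sample_times = sorted(config.sampling_days)
    histograms: dict[float, np.ndarray] = {}
    si = 0
    t = 0.0

    def snapshot(day: float) -> None:
        # chromosome count at spreads = sum of replicated copies per cell
        counts = np.array([karyos[i].sum() for i in range(len(types)) if alive[i]])
        histograms[day] = np.bincount(counts) if len(counts) else np.zeros(1, dtype=np.int64)

    while True:
        n_by_type = np.array([len(p) for p in by_type])
        rates = n_by_type * (b + d)
        total_rate = rates.sum()
        if total_rate == 0.0:
            break
        t_next = t + rng.exponential() / total_rate
        while si < len(sample_times) and sample_times[si] <= t_next:
            snapshot(sample_times[si])
            si += 1
        if si >= len(sample_times) or t_next > config.duration:
            break
        t = t_next

        x = rng.random() * total_rate
        cum = 0.0
        cell_type, is_division = _C6, False
        for i in range(4):
            cum += n_by_type[i] * b[i]
            if x < cum:
                cell_type, is_division = i, True
                break
            cum += n_by_type[i] * d[i]
            if x < cum:
                cell_type, is_division = i, False
                break
        pool = by_type[cell_type]
        idx = pool[rng.integers(len(pool))]
        mother = karyos[idx]
        remove(idx)
        if is_division:
            if cell_type == _C2:
                if rng.random() < params.q:
                    add(_C2, mother.copy())
                    add(_C2, mother.copy())
                else:
                    is_sc = model == "II" and rng.random() < params.v
                    add(_SC if is_sc else _C4, 2 * mother)
            elif cell_type == _SC:
                if rng.random() < params.r_S:
                    add(_SC, mother.copy())
                    add(_SC, mother.copy())
                else:
                    add(_C2, mother.copy())
                    add(_C6, mother.copy())
            elif cell_type == _C4:
                u = rng.random()
                if u < params.p_bipolar * params.r:
                    add(_C4, mother.copy())
                    add(_C4, mother.copy())
                elif u < params.p_bipolar:
                    add(_C2, mother.copy())
                    add(_C6, mother.copy())
                else:
                    n_poles = 3 if rng.random() < kconfig.tripolar_prob else 4
                    daughters = partition_karyotype(mother, n_poles, rng)
                    c4_pole = rng.integers(n_poles) if n_poles == 3 else -1
                    for pole in range(n_poles):
                        if daughter_viable(daughters[pole], kconfig, rng.random()):
                            add(_C4 if pole == c4_pole else _C2, daughters[pole])
        # passaging
        total_alive = sum(len(p) for p in by_type)
        while total_alive > config.cap:
            probs = np.array([len(p) for p in by_type]) / total_alive
            vt = rng.choice(4, p=probs)
            pool = by_type[vt]
            remove(pool[rng.integers(len(pool))])
            total_alive -= 1

    for s in sample_times[si:]:
        snapshot(s)
    return histograms
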