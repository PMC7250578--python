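"""Chromosome-partitioning outcomes of multipolar divisions.

A *k*-ploid cell (k replicated copies of each of M nonhomologous
chromosomes, i.e. k sister-chromatid pairs per chromosome type) divides
with p spindle poles.  Each sister pair is split between a uniformly
random unordered pair of distinct poles — sister chromatids never
co-segregate — and chromosomes partition independently.  Under these
assumptions the probability that one fixed daughter ends up nullisomic
(0 copies) or monosomic (exactly 1 copy) for a given chromosome has a
closed form, and the number of affected chromosomes per daughter is
binomial.

Terminology: "nullisomy" and "monosomy" are per-pole (per-daughter)
events; no factor of p for the choice of daughter is applied.  The
per-chromosome binomial parameter is called ``q_event`` throughout to
avoid collision with the population model's cytokinesis parameter ``q``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Literal

import numpy as np
from scipy import stats as sps

EventKind = Literal["nullisomy", "monosomy", "nullisomy_or_monosomy"]

_EVENT_KINDS = ("nullisomy", "monosomy", "nullisomy_or_monosomy")


@dataclass(frozen=True)
class PartitionSpec:
    """Geometry of one multipolar division.

    Parameters
    ----------
    n_chromosome_types : int
        M, number of nonhomologous chromosomes (23 for human).
    ploidy : int
        k, replicated copies per chromosome type = sister-chromatid
        pairs per type (4 for a tetraploid mitosis).
    n_poles : int
        p ≥ 2, number of spindle poles.
    """

    n_chromosome_types: int
    ploidy: int
    n_poles: int

    def __post_init__(self) -> None:
        if self.n_chromosome_types < 1:
            raise ValueError("n_chromosome_types must be >= 1")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.n_poles < 2:
            raise ValueError("n_poles must be >= 2")


@dataclass(frozen=True)
class DaughterKaryotype:
    """Copies of each chromosome type received by one pole."""

    copy_numbers: tuple[int, ...]


@dataclass(frozen=True)
class EventDistribution:
    """Binomial law of the number of affected chromosomes per daughter."""

    event_kind: EventKind
    per_chromosome_prob: float
    pmf: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return (len(self.pmf) - 1) * self.per_chromosome_prob


def count_partitions(spec: PartitionSpec) -> int:
    """Number of equally likely pole assignments of one chromosome type.

    Each of the k sister pairs picks one of C(p,2) unordered pole pairs,
    so the count is C(p,2)**k.
    """
    return comb(spec.n_poles, 2) ** spec.ploidy


def per_chromosome_nullisomy_prob(spec: PartitionSpec) -> float:
    """P(a fixed pole receives 0 copies of a given chromosome) = ((p-2)/p)^k."""
    p, k = spec.n_poles, spec.ploidy
    return ((p - 2) / p) ** k


def per_chromosome_monosomy_prob(spec: PartitionSpec) -> float:
    """P(a fixed pole receives exactly 1 copy) = 2k(p-2)^(k-1) / p^k."""
    p, k = spec.n_poles, spec.ploidy
    return 2 * k * (p - 2) ** (k - 1) / p**k


def per_chromosome_combined_prob(spec: PartitionSpec) -> float:
    """P(nullisomy or monosomy at a fixed pole); the events are exclusive."""
    p, k = spec.n_poles, spec.ploidy
    return ((p - 2) ** k + 2 * k * (p - 2) ** (k - 1)) / p**k


_PER_CHROMOSOME = {
    "nullisomy": per_chromosome_nullisomy_prob,
    "monosomy": per_chromosome_monosomy_prob,
    "nullisomy_or_monosomy": per_chromosome_combined_prob,
}


def cell_event_prob(per_chromosome_prob: float, n_chromosome_types: int) -> float:
    """Probability the event hits at least one of M independent chromosomes.

    1 - (1 - q_event)^M.
    """
    if not 0.0 <= per_chromosome_prob <= 1.0:
        raise ValueError("per_chromosome_prob must lie in [0, 1]")
    if n_chromosome_types < 1:
        raise ValueError("n_chromosome_types must be >= 1")
    return 1.0 - (1.0 - per_chromosome_prob) ** n_chromosome_types


def event_count_distribution(spec: PartitionSpec, event_kind: EventKind) -> EventDistribution:
    """Binomial pmf B(M, q_event) of the per-daughter count of affected chromosomes."""
    if event_kind not in _EVENT_KINDS:
        raise ValueError(f"unknown event kind {event_kind!r}")
    q_event = _PER_CHROMOSOME[event_kind](spec)
    m = spec.n_chromosome_types
    pmf = sps.binom.pmf(np.arange(m + 1), m, q_event)
    return EventDistribution(event_kind=event_kind, per_chromosome_prob=q_event, pmf=pmf)


def enumerate_exact_probs(ploidy: int, n_poles: int) -> dict[str, Fraction]:
    """Exhaustive-enumeration oracle for the per-chromosome event probabilities.

    Enumerates all C(p,2)^k sister-pair assignments for one chromosome
    type in exact rational arithmetic and counts, for pole 0, the
    assignments leaving it with 0 or exactly 1 chromatid.  Intended for
    small k, p; cost is C(p,2)^k.
    """
    pole_pairs = list(itertools.combinations(range(n_poles), 2))
    null_count = mono_count = total = 0
    for assignment in itertools.product(pole_pairs, repeat=ploidy):
        copies_at_pole0 = sum(1 for pair in assignment for pole in pair if pole == 0)
        total += 1
        if copies_at_pole0 == 0:
            null_count += 1
        elif copies_at_pole0 == 1:
            mono_count += 1
    return {
        "nullisomy": Fraction(null_count, total),
        "monosomy": Fraction(mono_count, total),
        "nullisomy_or_monosomy": Fraction(null_count + mono_count, total),
    }


def simulate_partition(
    spec: PartitionSpec,
    n_divisions: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo draws of daughter karyotypes from multipolar divisions.

    Returns an integer array of shape (n_divisions, p, M): copies of
    each chromosome type at each pole.  For every chromosome type, each
    of the k sister pairs independently picks a uniform unordered pair
    of distinct poles and deposits one chromatid at each; per-division
    chromatid totals are conserved (sum over poles = 2k per type).
    """
    if n_divisions <= 0:
        raise ValueError("n_divisions must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p, k, m = spec.n_poles, spec.ploidy, spec.n_chromosome_types
    pole_pairs = np.array(list(itertools.combinations(range(p), 2)))  # (C(p,2), 2)
    # (n_divisions, M, k) indices into pole_pairs
    idx = rng.integers(0, len(pole_pairs), size=(n_divisions, m, k))
    chosen = pole_pairs[idx]  # (n, M, k, 2)
    out = np.zeros((n_divisions, p, m), dtype=np.int64)
    flat = chosen.reshape(n_divisions, m, 2 * k)
    for pole in range(p):
        out[:, pole, :] = (flat == pole).sum(axis=2)
    return out


def partition_karyotype(
    copy_numbers: np.ndarray, n_poles: int, rng: np.random.Generator
) -> np.ndarray:
    """Partition one (possibly aneuploid) replicated karyotype among poles.

    ``copy_numbers[m]`` is the number of replicated copies (sister-chromatid
    pairs) of chromosome type m in the mother.  Each pair independently
    picks a uniform unordered pair of distinct poles, one chromatid to
    each.  Returns a (n_poles, M) array of daughter copy numbers; column
    sums equal ``2 * copy_numbers``.
    """
    if n_poles < 2:
        raise ValueError("n_poles must be >= 2")
    copy_numbers = np.asarray(copy_numbers, dtype=np.int64)
    pole_pairs = np.array(list(itertools.combinations(range(n_poles), 2)))
    out = np.zeros((n_poles, len(copy_numbers)), dtype=np.int64)
    for m, c in enumerate(copy_numbers):
        if c == 0:
            continue
        chosen = pole_pairs[rng.integers(0, len(pole_pairs), size=c)]
        for pole in chosen.ravel():
            out[pole, m] += 1
    return out


def daughters_from_array(division: np.ndarray) -> list[DaughterKaryotype]:
    """Wrap one division's (p, M) copy-number array as DaughterKaryotype objects."""
    return [DaughterKaryotype(tuple(int(c) for c in row)) for row in division]
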