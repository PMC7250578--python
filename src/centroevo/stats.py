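"""Small bespoke statistics: the DNA-distribution symmetry score and
karyotype-category classification.

The symmetry score quantifies how evenly an ana-/telophase cell
distributes its DNA among spindle poles.  Each pole's measured share of
total DNA signal is divided by the share expected under a perfectly even
split (1/p), and the score is the standard deviation of those ratios —
zero for a perfectly symmetric division, growing with asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class PoleIntensityProfile:
    """Per-pole DNA signal shares of one dividing cell (sum to 1)."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        p = len(self.fractions)
        if p not in (2, 3, 4):
            raise ValueError("profiles support 2, 3 or 4 poles")
        if any(f < 0 or f > 1 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.fractions) - 1.0) > _SUM_TOL:
            raise ValueError("pole fractions must sum to 1")

    @property
    def n_poles(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class KaryotypeBins:
    """Chromosome-count intervals for near-diploid / near-tetraploid calls.

    Defaults are 46 ± ~10% and 92 ± ~10%; the edges are an explicit
    configuration choice, not a measured quantity.
    """

    near_diploid: tuple[int, int] = (41, 51)
    near_tetraploid: tuple[int, int] = (83, 101)

    def __post_init__(self) -> None:
        d_lo, d_hi = self.near_diploid
        t_lo, t_hi = self.near_tetraploid
        if d_lo > d_hi or t_lo > t_hi:
            raise ValueError("bin intervals must be non-empty")
        if d_hi >= t_lo:
            raise ValueError("near-diploid bin must lie strictly below near-tetraploid")


def symmetry_score(profile: PoleIntensityProfile, ddof: int = 0) -> float:
    """Standard deviation of per-pole observed/expected DNA-share ratios.

    With p poles the expected share per pole is 1/p; ratio_i =
    fraction_i * p.  The default is the population standard deviation
    (ddof=0): the poles of one cell are its complete set of
    measurements, not a sample.  ``ddof=1`` gives the sample convention.
    """
    ratios = np.asarray(profile.fractions) * profile.n_poles
    return float(np.std(ratios, ddof=ddof))


def classify_karyotype(count: int, bins: KaryotypeBins = KaryotypeBins()) -> str:
    """Assign a chromosome count to near-diploid / near-tetraploid / highly aneuploid.

    Every positive count maps to exactly one category: counts outside
    both configured intervals are "highly aneuploid".
    """
    if count < 1:
        raise ValueError("chromosome count must be >= 1")
    if bins.near_diploid[0] <= count <= bins.near_diploid[1]:
        return "near-diploid"
    if bins.near_tetraploid[0] <= count <= bins.near_tetraploid[1]:
        return "near-tetraploid"
    return "highly aneuploid"


def classify_histogram(histogram: np.ndarray, bins: KaryotypeBins = KaryotypeBins()) -> dict[str, float]:
    """Category fractions of a chromosome-count histogram (``histogram[c]`` = cells with count c)."""
    total = histogram.sum()
    if total == 0:
        raise ValueError("empty histogram")
    out = {"near-diploid": 0.0, "highly aneuploid": 0.0, "near-tetraploid": 0.0}
    for count, n in enumerate(histogram):
        if n and count >= 1:
            out[classify_karyotype(count, bins)] += n / total
    return out
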