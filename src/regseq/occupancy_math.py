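"""Closed-form occupancy calculus for multimeric TF binding models.

Combinatorics of k-TF motif chains over an n-TF repertoire, expected
perfect-match counts in a genome of size G, Poisson specificity of binding
site clusters in a fixed window, and master-regulator-constrained variants.
All quantities are elementary closed forms over :class:`OccupancyParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OccupancyParams",
    "NONE_LE_6",
    "possible_combinations",
    "cooperating_fraction",
    "expected_motif_count",
    "individual_hit_expectation",
    "total_hit_expectation",
    "uniqueness_arity",
    "site_hit_probability",
    "poisson_tail",
    "min_sites_for_specificity",
    "mr_adjusted_probability",
    "mr_constrained_combinations",
    "tf_count_for_target_sites",
    "table2_frame",
    "round_sig",
]

#: sentinel returned when no arity k <= 6 (or no TF count) satisfies a scan
NONE_LE_6 = None

DEFAULT_EFFECTIVE_LENGTHS: Mapping[int, float] = {
    1: 6.0,
    2: 8.0,
    3: 12.25,
    4: 16.25,
    5: 21.0,
    6: 25.5,
}


@dataclass(frozen=True)
class OccupancyParams:
    """Constants of the occupancy calculus.

    ``strand_factor`` switches between single-strand (1, default) and
    double-strand (2) match-expectation conventions for individual motif
    hits.
    """

    n_tf: int = 1600
    cooperativity: float = 0.03
    genome_size: float = 3e9
    effective_lengths: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTIVE_LENGTHS)
    )
    window: int = 200
    site_length: int = 6
    #: rounded per-TF per-window hit probability used by the Poisson
    #: specificity calculus (~ window / 4**site_length; the exact value is
    #: exposed by site_hit_probability)
    site_probability: float = 1 / 20
    n_master: int = 0
    active_band: tuple[float, float] = (30_000.0, 200_000.0)
    strand_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.cooperativity <= 1:
            raise ValueError("cooperativity must be in [0, 1]")
        if self.genome_size < 0:
            raise ValueError("genome_size must be >= 0")
        ks = sorted(self.effective_lengths)
        vals = [self.effective_lengths[k] for k in ks]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("effective_lengths must be strictly increasing in arity")
        if self.active_band[0] > self.active_band[1]:
            raise ValueError("active_band must be a non-empty interval")


def possible_combinations(n: int, k: int) -> float:
    """Ordered k-sequences over n TFs, collapsed for reverse-complement symmetry.

    n for k = 1, else n**k / 2 (every chain and its reversal describe the
    same double-stranded motif).
    """
    if n < 0 or k < 1:
        raise ValueError("need n >= 0 and k >= 1")
    if k == 1:
        return float(n)
    return float(n) ** k / 2.0


def cooperating_fraction(c: float, k: int) -> float:
    """Fraction of k-chains in which all k-1 adjacent pairs cooperate: c**(k-1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return c ** (k - 1)


def expected_motif_count(p: OccupancyParams, k: int) -> float:
    """Expected number of distinct cooperative k-TF motifs."""
    return possible_combinations(p.n_tf, k) * cooperating_fraction(p.cooperativity, k)


def individual_hit_expectation(p: OccupancyParams, k: int) -> float:
    """Expected perfect matches of one k-TF motif in the genome.

    strand_factor * G * 4**(-L_eff(k)); the default single-strand convention
    (strand_factor = 1).
    """
    leff = p.effective_lengths[k]
    return p.strand_factor * p.genome_size * 4.0 ** (-leff)


def total_hit_expectation(p: OccupancyParams, k: int) -> float:
    """Genome-wide expected hits summed over all cooperative k-TF motifs."""
    return expected_motif_count(p, k) * individual_hit_expectation(p, k)


def uniqueness_arity(p: OccupancyParams, n_regulatory: float = 3e6) -> int | None:
    """Smallest arity whose motif diversity exceeds the regulatory-site count.

    Returns the smallest k <= 6 with expected_motif_count(k) > n_regulatory,
    or ``None`` if no such arity exists.
    """
    if n_regulatory <= 0:
        raise ValueError("n_regulatory must be > 0")
    for k in sorted(p.effective_lengths):
        if expected_motif_count(p, k) > n_regulatory:
            return k
    return NONE_LE_6


def site_hit_probability(p: OccupancyParams) -> float:
    """Probability of a perfect single-TF site in one window: w / 4**site_length, capped at 1."""
    return min(p.window / 4.0 ** p.site_length, 1.0)


def poisson_tail(n_active: int, x: int, p: OccupancyParams = OccupancyParams()) -> float:
    """P(Poisson(lambda) >= x) with lambda = n_active * p.site_probability (1/20)."""
    if n_active < 0 or x < 0:
        raise ValueError("n_active and x must be >= 0")
    lam = n_active * p.site_probability
    return float(stats.poisson.sf(x - 1, lam))


def min_sites_for_specificity(
    n_active: int,
    p: OccupancyParams = OccupancyParams(),
    max_positive_fraction: float = 0.03,
) -> int:
    """Smallest X with P(>= X site hits per window) <= max_positive_fraction."""
    if not 0 < max_positive_fraction < 1:
        raise ValueError("max_positive_fraction must be in (0, 1)")
    x = 0
    while poisson_tail(n_active, x, p) > max_positive_fraction:
        x += 1
    return x


def mr_adjusted_probability(
    n_active: int, x: int, m: int, p: OccupancyParams = OccupancyParams()
) -> float:
    """Tail probability multiplied by P(exactly one master-regulator hit).

    The MR factor is PoissonPMF(1; m * per-window site probability).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    lam_mr = m * p.site_probability
    return poisson_tail(n_active, x, p) * float(stats.poisson.pmf(1, lam_mr))


def mr_constrained_combinations(n: int, k: int, m: int) -> float:
    """Ordered k-sequences over n TFs containing at least one of m designated
    master regulators, collapsed by the factor-2 strand symmetry:
    (n**k - (n-m)**k) / 2.
    """
    if not 0 <= m <= n:
        raise ValueError("need 0 <= m <= n")
    if k < 1:
        raise ValueError("k must be >= 1")
    return (float(n) ** k - float(n - m) ** k) / 2.0


def mr_total_hit_expectation(p: OccupancyParams, k: int, m: int) -> float:
    """Genome-wide expected k-TF hits when a master-regulator member is obligatory."""
    return (
        mr_constrained_combinations(p.n_tf, k, m)
        * cooperating_fraction(p.cooperativity, k)
        * individual_hit_expectation(p, k)
    )


def tf_count_for_target_sites(
    k: int, p: OccupancyParams = OccupancyParams(), step: int = 100
) -> int | None:
    """Smallest multiple of ``step`` TFs whose total k-TF hit expectation lies
    within the active band; ``None`` if none up to p.n_tf does."""
    if step < 1:
        raise ValueError("step must be >= 1")
    lo, hi = p.active_band
    n = step
    while n <= p.n_tf:
        val = total_hit_expectation(replace(p, n_tf=n), k)
        if lo <= val <= hi:
            return n
        n += step
    return NONE_LE_6


def table2_frame(p: OccupancyParams = OccupancyParams()) -> pd.DataFrame:
    """Six-column summary of the combinatoric calculus, one column per arity."""
    ks = sorted(p.effective_lengths)
    rows = {
        "possible_combinations": [possible_combinations(p.n_tf, k) for k in ks],
        "percent_that_cooperate": [100 * cooperating_fraction(p.cooperativity, k) for k in ks],
        "expected_number_of_motifs": [expected_motif_count(p, k) for k in ks],
        "effective_motif_length": [p.effective_lengths[k] for k in ks],
        "individual_motif_hits": [individual_hit_expectation(p, k) for k in ks],
        "total_motif_hits": [total_hit_expectation(p, k) for k in ks],
    }
    return pd.DataFrame(rows, index=[f"{k}_TF" for k in ks]).T


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
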