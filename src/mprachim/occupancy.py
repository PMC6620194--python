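"""Poisson model of template-per-micelle occupancy in emulsion PCR.

With T template molecules distributed independently and uniformly over M >> 1
micelles, the number of templates per micelle is Poisson with mean
lambda = T / M.  Chimeras require a micelle to hold at least two templates of
distinct variants, which is why the template amount is kept orders of
magnitude below the micelle count.  With k equally abundant distinct variants,
two co-encapsulated templates are identical with probability 1/k: a
two-variant system (k = 2) wastes half of its double inclusions on identical
pairs and therefore underestimates the chimera potential of a diverse library
(k in the tens of thousands) by a factor approaching 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OccupancyParams",
    "occupancy_pmf",
    "distinct_pair_fraction",
    "chimera_potential",
    "occupancy_table",
]

_J_MAX = 60  # Poisson tail beyond this is < 1e-12 for lambda <= 10


@dataclass(frozen=True)
class OccupancyParams:
    """Template count T, micelle count M and number of distinct variants k."""

    n_templates: int
    n_micelles: int
    n_distinct_variants: int = 2

    def __post_init__(self) -> None:
        if min(self.n_templates, self.n_micelles, self.n_distinct_variants) < 1:
            raise ValueError("all counts must be >= 1")

    @property
    def lam(self) -> float:
        return self.n_templates / self.n_micelles


def occupancy_pmf(params: OccupancyParams, j: int) -> float:
    """Probability that a micelle holds exactly ``j`` template molecules."""
    if j < 0:
        raise ValueError("j must be >= 0")
    return float(stats.poisson.pmf(j, params.lam))


def distinct_pair_fraction(params: OccupancyParams, j: int = 2) -> float:
    """Probability that a micelle with ``j`` templates holds >= 2 distinct variants.

    Templates are drawn independently from k equally abundant variants, so all
    ``j`` are identical with probability ``k**(1-j)``; for j = 2 this is the
    familiar ``1 - 1/k`` (0.5 in a two-variant system).
    """
    if j < 2:
        raise ValueError("a distinct pair needs at least 2 templates")
    k = params.n_distinct_variants
    return 1.0 - float(k) ** (1 - j)


def chimera_potential(params: OccupancyParams) -> float:
    """Expected fraction of templates sharing a micelle with a distinct variant.

    ``sum_{j>=2} P(j) * j * (1 - k**(1-j)) / lambda``: the per-template
    probability of having at least one distinct-variant partner.  Monotone
    non-decreasing in both lambda and k; identically 0 for k = 1.
    """
    k = params.n_distinct_variants
    if k == 1:
        return 0.0
    lam = params.lam
    j = np.arange(2, _J_MAX + 1)
    pmf = stats.poisson.pmf(j, lam)
    return float(np.sum(pmf * j * (1.0 - float(k) ** (1 - j))) / lam)


def occupancy_table(
    n_templates: list[int], n_micelles: list[int], n_variants: list[int]
) -> pd.DataFrame:
    """Grid of occupancy statistics over (T, M, k) combinations."""
    rows = []
    for T in n_templates:
        for M in n_micelles:
            for k in n_variants:
                p = OccupancyParams(T, M, k)
                p_ge2 = 1.0 - float(stats.poisson.cdf(1, p.lam))
                rows.append(
                    {
                        "n_templates": T,
                        "n_micelles": M,
                        "n_variants": k,
                        "lambda": p.lam,
                        "p_multiple_occupancy": p_ge2,
                        "distinct_pair_fraction": distinct_pair_fraction(p),
                        "chimera_potential": chimera_potential(p),
                    }
                )
    return pd.DataFrame(rows)
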