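"""Lorenz curves and Gini coefficients of genetic-map heterogeneity.

The Lorenz curve plots cumulative genetic distance against cumulative
physical distance after sorting map intervals by rate; the Gini coefficient
is twice the area between the curve and the diagonal.  A perfectly uniform
map gives G = 0; a map whose crossovers all fall in a vanishing fraction of
the sequence approaches G = 1.  Intervals are weighted by physical length
(bp), since SNP spacing is irregular and the axes are physical vs genetic
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import RhoMap

__all__ = ["LorenzResult", "lorenz_gini", "gini_pairwise"]


@dataclass
class LorenzResult:
    """Lorenz curve points from (0,0) to (1,1) and the Gini coefficient."""

    physical_fraction: np.ndarray
    genetic_fraction: np.ndarray
    gini: float


def lorenz_gini(rho_map: RhoMap) -> LorenzResult:
    """Lorenz curve and Gini coefficient of a recombination map.

    Intervals are sorted by rate ascending (ties broken by position, to
    which the result is invariant); each interval contributes its share of
    physical length on x and its share of total rho mass on y.  The Gini
    coefficient is ``1 - 2 * trapezoidal area`` under the polyline.
    """
    lengths = rho_map.interval_lengths
    mass = rho_map.rates * lengths
    total_mass = mass.sum()
    if total_mass <= 0:
        raise ValueError("map has zero total rho; Lorenz curve undefined")
    order = np.lexsort((np.arange(rho_map.rates.size), rho_map.rates))
    x = np.concatenate([[0.0], np.cumsum(lengths[order]) / lengths.sum()])
    y = np.concatenate([[0.0], np.cumsum(mass[order]) / total_mass])
    x[-1] = 1.0
    y[-1] = 1.0
    gini = 1.0 - 2.0 * float(np.trapezoid(y, x))
    return LorenzResult(physical_fraction=x, genetic_fraction=y, gini=gini)


def gini_pairwise(values: np.ndarray) -> float:
    """Gini of equally weighted values via mean absolute pairwise difference.

    ``G = sum_ij |x_i - x_j| / (2 n^2 mean)``.  Used as an independent
    cross-check of :func:`lorenz_gini` on maps with equal-length intervals;
    O(n^2), so only suitable for small n.
    """
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2.0 * x.size**2 * mean))
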