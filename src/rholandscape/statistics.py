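"""Broad-scale map summaries: weighted means, cM anchoring, windows, Ne.

All averages over a recombination map are frequency-weighted: the rate of
each inter-SNP interval is weighted by the number of bases separating the
SNP pair, so ``mean rho = sum(rate_i * d_i) / sum(d_i)``.  Anchoring rescales
cumulative rho so the chromosome's total genetic length matches an external
linkage map (e.g. the Cox map), giving positions in centimorgans.  Ne follows
from ``rho = 4*Ne*r`` once r is fixed by a pedigree-based cM/Mb estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .maps import GeneticAnchor, RhoMap

__all__ = [
    "WindowSeries",
    "AnchoredMap",
    "NeEstimate",
    "weighted_mean_rho",
    "anchor_to_centimorgans",
    "window_series",
    "correlate_windows",
    "estimate_ne",
]

CM_PER_MB_TO_R_PER_BP = 1e-8  # 1 cM/Mb = 1e-8 crossovers per bp per generation


@dataclass
class WindowSeries:
    """Per-window weighted-mean rates along one chromosome.

    ``values`` is NaN for windows whose map coverage falls below the
    configured minimum (missing, not zero).  Windows are half-open
    ``[start, end)`` anchored at coordinate 0.
    """

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    coverage: np.ndarray

    def __len__(self) -> int:
        return int(self.starts.size)


@dataclass
class AnchoredMap:
    """Genetic-map positions: SNP coordinates with cumulative centimorgans."""

    chromosome: str
    positions: np.ndarray  # 1-based bp, same grid as the source RhoMap
    cm: np.ndarray  # cumulative cM, cm[0] == 0, cm[-1] == anchor total
    total_cm: float


@dataclass
class NeEstimate:
    """Effective population size implied by rho_bar = 4 * Ne * r."""

    rho_bar: float
    r_per_bp: float
    ne: float

    @property
    def ne_rounded(self) -> int:
        """Ne rounded to the nearest 1,000 (presentation convention)."""
        return int(round(self.ne / 1000.0) * 1000)


def weighted_mean_rho(
    rho_map: RhoMap, region: tuple[float, float] | None = None
) -> float:
    """Frequency-weighted mean rho/bp, optionally clipped to ``region``.

    ``region`` is a (start, end) pair on the map's own 1-based coordinate
    axis, half-open.  Raises if the region does not intersect the map span
    (distinct from a genuine zero rate).
    """
    lo, hi = rho_map.span if region is None else region
    left = rho_map.positions[:-1].astype(float)
    right = rho_map.positions[1:].astype(float)
    clipped = np.minimum(right, hi) - np.maximum(left, lo)
    clipped = np.clip(clipped, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise ValueError(f"region [{lo}, {hi}) does not intersect map span")
    return float(np.sum(rho_map.rates * clipped) / total)


def anchor_to_centimorgans(rho_map: RhoMap, anchor: GeneticAnchor) -> AnchoredMap:
    """Rescale cumulative rho so the chromosome totals ``anchor.total_cm``.

    cM(j) = total_cm * cum_rho(j) / cum_rho(last); the first SNP maps to 0
    and the last SNP to the anchor length exactly.  Rank order of interval
    rates is preserved (the transform is a positive global rescaling).
    """
    cum = rho_map.cumulative_rho()
    if cum[-1] <= 0:
        raise ValueError("total map rho is zero; cannot anchor")
    cm = anchor.total_cm * (cum / cum[-1])
    cm[-1] = anchor.total_cm  # exact, no float residue
    return AnchoredMap(rho_map.chromosome, rho_map.positions.copy(), cm, anchor.total_cm)


def _window_grid(
    span_end: float, size: float, mode: str, offset: float | None
) -> tuple[np.ndarray, np.ndarray]:
    if size <= 0:
        raise ValueError("window size must be positive")
    if mode == "nonoverlapping":
        starts = np.arange(0.0, span_end, size)
    elif mode == "sliding":
        if not offset or offset <= 0:
            raise ValueError("sliding mode requires a positive offset")
        last_start = span_end - size
        if last_start < 0:
            starts = np.array([0.0])
        else:
            starts = np.arange(0.0, last_start + offset * 0.5, offset)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return starts, starts + size


def window_series(
    source: RhoMap | AnchoredMap,
    size: float,
    mode: str = "nonoverlapping",
    offset: float | None = None,
    min_coverage: float = 0.5,
) -> WindowSeries:
    """Windowed weighted-mean rates along a map.

    For a :class:`RhoMap` the window value is the weighted mean rho/bp; for
    an :class:`AnchoredMap` it is cM/Mb (genetic distance accumulated in the
    window divided by window megabases).  Coverage is the fraction of the
    window that lies inside the map span; windows below ``min_coverage``
    carry NaN.
    """
    if isinstance(source, AnchoredMap):
        positions = source.positions.astype(float)
        cum = source.cm
        per_mb = True
    else:
        positions = source.positions.astype(float)
        cum = source.cumulative_rho()
        per_mb = False
    span_lo, span_hi = positions[0], positions[-1]
    starts, ends = _window_grid(span_hi, size, mode, offset)

    def cum_at(x: np.ndarray) -> np.ndarray:
        return np.interp(np.clip(x, span_lo, span_hi), positions, cum)

    covered = np.clip(ends, span_lo, span_hi) - np.clip(starts, span_lo, span_hi)
    coverage = covered / (ends - starts)
    mass = cum_at(ends) - cum_at(starts)
    with np.errstate(invalid="ignore", divide="ignore"):
        if per_mb:
            values = mass / ((ends - starts) / 1e6)
        else:
            values = mass / covered
    values = np.where(coverage >= min_coverage, values, np.nan)
    chromosome = source.chromosome
    return WindowSeries(chromosome, starts, ends, values, coverage)


def correlate_windows(
    a: WindowSeries, b: WindowSeries, method: str = "pearson"
) -> tuple[float, float, int]:
    """Correlation between two aligned window series.

    Windows must be on identical grids; windows missing (NaN) in either
    series are dropped pairwise.  Returns (coefficient, p-value, n used).
    """
    if len(a) != len(b) or not np.array_equal(a.starts, b.starts):
        raise ValueError("window series are not on the same grid")
    keep = ~(np.isnan(a.values) | np.isnan(b.values))
    x, y = a.values[keep], b.values[keep]
    if x.size < 3:
        raise ValueError(f"only {x.size} shared windows; need >= 3")
    if method == "pearson":
        result = stats.pearsonr(x, y)
    elif method == "spearman":
        result = stats.spearmanr(x, y)
    elif method == "kendall":
        result = stats.kendalltau(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(result.statistic), float(result.pvalue), int(x.size)


def estimate_ne(rho_bar: float, cm_per_mb: float) -> NeEstimate:
    """Ne from a scaled rate and a pedigree-based recombination fraction.

    With rho_bar = 4*Ne*r and r = cm_per_mb * 1e-8 per bp per generation,
    Ne = rho_bar / (4 * r).
    """
    if rho_bar <= 0 or cm_per_mb <= 0:
        raise ValueError("rho_bar and cm_per_mb must be positive")
    r = cm_per_mb * CM_PER_MB_TO_R_PER_BP
    return NeEstimate(rho_bar=rho_bar, r_per_bp=r, ne=rho_bar / (4.0 * r))
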