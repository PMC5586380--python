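"""Hotspot calling against local background and overlap randomization.

A putative recombination hotspot is a short window (default 2 kb) whose
weighted-mean rate is at least ``ratio`` times (default 5x, inclusive) the
weighted-mean rate of the surrounding flanking sequence (default 80 kb in
total, 40 kb per side, excluding the window itself).  Runs of adjacent
flagged windows are merged, so hotspots wider than one window emerge from
the merge rule.  Significance of overlap with an independent interval set
(e.g. double-strand-break hotspots) is assessed by re-placing the query
intervals uniformly at random within their own chromosomes and taking the
maximum overlap count across replicates as the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import IntervalSet, RhoMap, snp_to_bed

__all__ = [
    "HotspotConfig",
    "call_hotspots",
    "count_overlaps",
    "randomized_overlap_null",
    "OverlapNullResult",
]


@dataclass
class HotspotConfig:
    """Window/flank geometry and threshold for the hotspot caller."""

    window: int = 2_000
    flank_total: int = 80_000
    ratio: float = 5.0
    min_flank_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.flank_total <= self.window:
            raise ValueError("flank_total must exceed window")
        if self.ratio <= 1:
            raise ValueError("ratio must exceed 1")


class _MassProfile:
    """Cumulative rho mass and coverage on the 0-based coordinate axis."""

    def __init__(self, rho_map: RhoMap):
        self.edges = (rho_map.positions - 1).astype(float)  # 0-based
        self.cum = rho_map.cumulative_rho()
        self.lo = self.edges[0]
        self.hi = self.edges[-1]

    def mass_and_cover(self, start: float, end: float) -> tuple[float, float]:
        a = np.clip(start, self.lo, self.hi)
        b = np.clip(end, self.lo, self.hi)
        mass = np.interp(b, self.edges, self.cum) - np.interp(a, self.edges, self.cum)
        return float(mass), float(b - a)


def call_hotspots(
    rho_map: RhoMap,
    config: HotspotConfig | None = None,
    chromosome_length: int | None = None,
) -> IntervalSet:
    """Call hotspot intervals on one chromosome map.

    The chromosome is tiled into nonoverlapping ``config.window`` bp windows
    from coordinate 0.  For each window the background is the weighted-mean
    rate over ``flank_total/2`` bp on each side (excluding the window,
    truncated at chromosome ends); windows whose available flank covers less
    than ``min_flank_coverage`` of the nominal total are skipped.  A window
    is flagged when focal mean >= ratio x background (inclusive); a zero
    background with positive focal mass is flagged and annotated
    ``zero-background``.  Adjacent flagged windows are merged.

    Returns an :class:`IntervalSet` (BED semantics) with ``score`` = maximum
    focal/background ratio among merged windows and a ``note`` column.
    """
    config = config or HotspotConfig()
    profile = _MassProfile(rho_map)
    end_coord = chromosome_length if chromosome_length is not None else profile.hi
    half_flank = (config.flank_total - config.window) / 2.0

    starts = np.arange(0.0, end_coord, config.window)
    flagged: list[tuple[int, int, float, str]] = []
    for ws in starts:
        we = min(ws + config.window, end_coord)
        focal_mass, focal_cover = profile.mass_and_cover(ws, we)
        if focal_cover <= 0:
            continue
        focal = focal_mass / focal_cover
        lm, lc = profile.mass_and_cover(ws - half_flank, ws)
        rm, rc = profile.mass_and_cover(we, we + half_flank)
        flank_cover = lc + rc
        if flank_cover < config.min_flank_coverage * (config.flank_total - config.window):
            continue
        background = (lm + rm) / flank_cover
        if background <= 0:
            if focal > 0:
                flagged.append((int(ws), int(we), np.inf, "zero-background"))
            continue
        ratio = focal / background
        if ratio >= config.ratio:
            flagged.append((int(ws), int(we), ratio, ""))

    # merge runs of adjacent flagged windows
    merged: list[list] = []
    for ws, we, score, note in flagged:
        if merged and merged[-1][1] == ws:
            merged[-1][1] = we
            merged[-1][2] = max(merged[-1][2], score)
            if note and note not in merged[-1][3]:
                merged[-1][3] = (merged[-1][3] + "," + note).strip(",")
        else:
            merged.append([ws, we, score, note])
    df = pd.DataFrame(merged, columns=["start", "end", "score", "note"])
    df.insert(0, "chrom", rho_map.chromosome)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "score", "note"])
    return IntervalSet(df)


def count_overlaps(a: IntervalSet, b: IntervalSet, symmetric: bool = False) -> int:
    """Number of intervals in ``b`` overlapping >= 1 bp of any interval in ``a``.

    Half-open coordinates: abutting intervals do not overlap.  With
    ``symmetric`` the a-side count is added (each side counted once).
    """
    count = _one_sided_overlaps(a, b)
    if symmetric:
        count += _one_sided_overlaps(b, a)
    return count


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s < me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


def _one_sided_overlaps(a: IntervalSet, b: IntervalSet) -> int:
    total = 0
    for chrom in b.chromosomes():
        a_starts, a_ends = a.for_chromosome(chrom)
        if a_starts.size == 0:
            continue
        ms, me = _merge_intervals(a_starts, a_ends)
        b_starts, b_ends = b.for_chromosome(chrom)
        idx = np.searchsorted(ms, b_ends, side="left")
        hit = (idx > 0) & (me[np.maximum(idx - 1, 0)] > b_starts)
        total += int(hit.sum())
    return total


@dataclass
class OverlapNullResult:
    """Observed overlap count against a within-chromosome randomization null."""

    observed: int
    null_counts: np.ndarray
    threshold: int  # max over replicates, ~ (1/replicates) significance level
    seed: int | None = None
    replicates: int = field(default=0)

    @property
    def empirical_p(self) -> float:
        """Fraction of null replicates with count >= observed (add-one)."""
        n = self.null_counts.size
        return float((1 + np.sum(self.null_counts >= self.observed)) / (1 + n))


def randomized_overlap_null(
    query: IntervalSet,
    target: IntervalSet,
    chromosome_lengths: dict[str, int],
    replicates: int = 1000,
    seed: int | None = None,
    permute_chromosomes: bool = False,
) -> OverlapNullResult:
    """Randomization test of interval overlap.

    Per replicate every query interval is re-placed uniformly at a start in
    ``[0, L - length]`` on its own chromosome (lengths preserved, placements
    independent, overlaps among placed intervals permitted) and the b-side
    overlap count against ``target`` is recorded.  The maximum null count
    serves as an approximate ``1/replicates`` significance threshold.  With
    ``permute_chromosomes`` the chromosome labels of the query intervals are
    additionally shuffled each replicate before re-placement.
    """
    rng = np.random.default_rng(seed)
    chroms = query.df["chrom"].to_numpy()
    lengths_bp = (query.df["end"] - query.df["start"]).to_numpy()
    for chrom in np.unique(chroms):
        if chrom not in chromosome_lengths:
            raise ValueError(f"no length for chromosome {chrom!r}")
    max_len = {c: chromosome_lengths[c] for c in np.unique(chroms)}
    for c, interval_len in zip(chroms, lengths_bp):
        if interval_len > max_len[c]:
            raise ValueError(f"interval of {interval_len} bp exceeds chromosome {c}")

    observed = count_overlaps(query, target)
    null_counts = np.empty(replicates, dtype=np.int64)
    for rep in range(replicates):
        rep_chroms = chroms
        if permute_chromosomes:
            rep_chroms = rng.permutation(chroms)
        limits = np.array([chromosome_lengths[c] for c in rep_chroms]) - lengths_bp
        if np.any(limits < 0):
            raise ValueError("interval longer than its assigned chromosome")
        new_starts = rng.integers(0, limits + 1)
        placed = IntervalSet(
            pd.DataFrame(
                {
                    "chrom": rep_chroms,
                    "start": new_starts,
                    "end": new_starts + lengths_bp,
                }
            )
        )
        null_counts[rep] = count_overlaps(placed, target)
    return OverlapNullResult(
        observed=observed,
        null_counts=null_counts,
        threshold=int(null_counts.max()) if replicates else 0,
        seed=seed,
        replicates=replicates,
    )
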