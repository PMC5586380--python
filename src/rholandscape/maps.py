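"""Data model and I/O for recombination-rate maps and genomic interval sets.

The central container is :class:`RhoMap`, a per-chromosome piecewise-constant
map of the population-scaled recombination rate ``rho = 4*Ne*r`` per base pair
between adjacent SNPs, as emitted by LD-based estimators (LDhat, LDhelmet).
Interval sets (hotspots, double-strand-break locations) use BED conventions:
0-based half-open coordinates.  SNP positions are 1-based, matching estimator
output; conversions between the two conventions are centralized here
(:func:`snp_to_bed`, :func:`bed_to_snp`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RhoMap",
    "IntervalSet",
    "GeneticAnchor",
    "RhoMapError",
    "read_rho_map",
    "write_rho_map",
    "read_bed",
    "write_bed",
    "stitch_windows",
    "snp_to_bed",
    "bed_to_snp",
]


class RhoMapError(ValueError):
    """Malformed recombination-map input."""


def snp_to_bed(position: int) -> int:
    """Convert a 1-based SNP coordinate to a 0-based BED coordinate."""
    return int(position) - 1


def bed_to_snp(coordinate: int) -> int:
    """Convert a 0-based BED coordinate to a 1-based SNP coordinate."""
    return int(coordinate) + 1


@dataclass
class RhoMap:
    """Piecewise-constant scaled recombination-rate map for one chromosome.

    Parameters
    ----------
    chromosome
        Chromosome label.
    positions
        Strictly increasing 1-based physical SNP coordinates (bp).  The map
        has ``len(positions) - 1`` intervals.
    rates
        Scaled recombination rate rho/bp (dimensionless, ``4*Ne*r`` per bp)
        for each interval between adjacent positions.  All non-negative.
    provenance
        Free-form metadata (estimator name, block penalty, window scheme,
        gap-bridging notes).  Carried through, never interpreted.
    """

    chromosome: str
    positions: np.ndarray
    rates: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.positions.size < 2:
            raise RhoMapError("a RhoMap needs at least 2 SNP positions")
        if self.rates.size != self.positions.size - 1:
            raise RhoMapError(
                f"expected {self.positions.size - 1} rates for "
                f"{self.positions.size} positions, got {self.rates.size}"
            )
        if np.any(np.diff(self.positions) <= 0):
            bad = int(np.flatnonzero(np.diff(self.positions) <= 0)[0]) + 1
            raise RhoMapError(f"positions not strictly increasing at index {bad}")
        if np.any(self.rates < 0):
            raise RhoMapError("negative recombination rate")

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)

    @property
    def interval_lengths(self) -> np.ndarray:
        """Physical length (bp) of each inter-SNP interval."""
        return np.diff(self.positions).astype(np.float64)

    @property
    def span(self) -> tuple[int, int]:
        """(first, last) SNP position, 1-based inclusive."""
        return int(self.positions[0]), int(self.positions[-1])

    def total_rho(self) -> float:
        """Total map mass: sum over intervals of rate x length (units of rho)."""
        return float(np.sum(self.rates * self.interval_lengths))

    def cumulative_rho(self) -> np.ndarray:
        """Cumulative rho at each SNP position, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.rates * self.interval_lengths)])

    def equals(self, other: "RhoMap") -> bool:
        return (
            self.chromosome == other.chromosome
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.rates, other.rates)
        )


@dataclass
class GeneticAnchor:
    """Known total genetic length of a chromosome, used to scale rho to cM."""

    chromosome: str
    total_cm: float

    def __post_init__(self) -> None:
        if not self.total_cm > 0:
            raise ValueError("total_cm must be positive")


class IntervalSet:
    """Set of genomic intervals in BED semantics (0-based, half-open).

    Stored as a pandas DataFrame with columns ``chrom``, ``start``, ``end``
    plus any extra columns preserved opaquely; records are kept sorted by
    (chrom, start, end).
    """

    def __init__(
        self,
        records: pd.DataFrame | Iterable[tuple],
        chromosome_lengths: dict[str, int] | None = None,
    ):
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame(list(records), columns=["chrom", "start", "end"])
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ValueError("records need chrom/start/end columns")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
            bad = int(np.flatnonzero(df["start"].to_numpy() >= df["end"].to_numpy())[0])
            raise ValueError(f"empty or inverted interval at record {bad}")
        if len(df) and np.any(df["start"].to_numpy() < 0):
            raise ValueError("negative start coordinate")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if chromosome_lengths is not None:
            for _, row in df.iterrows():
                length = chromosome_lengths.get(row["chrom"])
                if length is not None and row["end"] > length:
                    raise ValueError(
                        f"interval end {row['end']} exceeds length of {row['chrom']}"
                    )
        self.df = df
        self.chromosome_lengths = chromosome_lengths

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield row

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def for_chromosome(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def total_span(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


# ---------------------------------------------------------------------------
# rho-map text I/O
# ---------------------------------------------------------------------------

def _as_text_stream(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    return open(source, "r")


def read_rho_map(
    source,
    dialect: str = "per_bp",
    chromosome: str | None = None,
    gap_tolerant: bool = False,
) -> RhoMap:
    """Parse whitespace-delimited estimator output into a :class:`RhoMap`.

    Rows are ``left_pos right_pos rate [extra columns ignored]``; comment or
    header lines begin with '#' or '%'.  A ``# chromosome=<label>`` header
    (as written by :func:`write_rho_map`) sets the chromosome unless the
    ``chromosome`` argument overrides it.  ``dialect`` is ``"per_bp"``
    (LDhelmet) or ``"per_kbp"`` (LDhat, divided by 1000 on read) and is never
    sniffed from the file.  Adjacent rows must be contiguous
    (``right_pos[i] == left_pos[i+1]``); with ``gap_tolerant`` a gap is
    bridged by a zero-rate interval recorded in ``provenance["gaps"]``.
    """
    if dialect not in ("per_bp", "per_kbp"):
        raise ValueError(f"unknown dialect {dialect!r}")
    scale = 1.0 if dialect == "per_bp" else 1e-3

    header_chromosome: str | None = None
    stream = _as_text_stream(source)
    positions: list[int] = []
    rates: list[float] = []
    gaps: list[tuple[int, int]] = []
    row_idx = 0
    for line in stream:
        text = line.strip()
        if not text or text[0] in "#%":
            if text.startswith("#") and "chromosome=" in text:
                header_chromosome = text.split("chromosome=", 1)[1].split()[0]
            continue
        row_idx += 1
        parts = text.split()
        if len(parts) < 3:
            raise RhoMapError(f"row {row_idx}: expected >=3 columns, got {len(parts)}")
        try:
            left, right = int(float(parts[0])), int(float(parts[1]))
            rate = float(parts[2]) * scale
        except ValueError as exc:
            raise RhoMapError(f"row {row_idx}: unparseable field ({exc})") from None
        if right <= left:
            raise RhoMapError(f"row {row_idx}: non-monotone positions {left} >= {right}")
        if rate < 0:
            raise RhoMapError(f"row {row_idx}: negative rate {rate}")
        if not positions:
            positions.extend([left, right])
            rates.append(rate)
            continue
        prev_right = positions[-1]
        if left < prev_right:
            raise RhoMapError(
                f"row {row_idx}: left position {left} precedes previous right {prev_right}"
            )
        if left > prev_right:
            if not gap_tolerant:
                raise RhoMapError(
                    f"row {row_idx}: gap between {prev_right} and {left}; "
                    "pass gap_tolerant=True to bridge with a zero-rate interval"
                )
            gaps.append((prev_right, left))
            positions.append(left)
            rates.append(0.0)
        positions.append(right)
        rates.append(rate)
    if len(positions) < 2:
        raise RhoMapError("no data rows")
    provenance = {"dialect": dialect}
    if gaps:
        provenance["gaps"] = gaps
    label = chromosome or header_chromosome or "chr"
    return RhoMap(label, np.array(positions), np.array(rates), provenance)


def write_rho_map(rho_map: RhoMap, sink) -> None:
    """Write a map in the three-column per-bp text format (full precision)."""
    own = not hasattr(sink, "write")
    stream = open(sink, "w") if own else sink
    try:
        stream.write(f"# chromosome={rho_map.chromosome}\n")
        stream.write("# left_pos right_pos rate_per_bp\n")
        for left, right, rate in zip(
            rho_map.positions[:-1], rho_map.positions[1:], rho_map.rates
        ):
            stream.write(f"{left} {right} {float(rate)!r}\n")
    finally:
        if own:
            stream.close()


def rho_map_round_trip(rho_map: RhoMap) -> RhoMap:
    """Serialize and re-parse a map (identity on positions and rates)."""
    buffer = io.StringIO()
    write_rho_map(rho_map, buffer)
    buffer.seek(0)
    return read_rho_map(buffer, chromosome=rho_map.chromosome)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(source, chromosome_lengths: dict[str, int] | None = None) -> IntervalSet:
    """Read BED3+ into an :class:`IntervalSet`; extra columns kept opaquely."""
    stream = _as_text_stream(source)
    rows = []
    n_extra = 0
    for line_no, line in enumerate(stream, start=1):
        text = line.rstrip("\n")
        if not text.strip() or text.startswith(("#", "track", "browser")):
            continue
        parts = text.split()
        if len(parts) < 3:
            raise ValueError(f"line {line_no}: BED needs >=3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ValueError(f"line {line_no}: non-integer coordinates") from None
        if start >= end:
            raise ValueError(f"line {line_no}: start {start} >= end {end}")
        n_extra = max(n_extra, len(parts) - 3)
        rows.append([parts[0], start, end, *parts[3:]])
    columns = ["chrom", "start", "end"] + [f"extra{i}" for i in range(1, n_extra + 1)]
    df = pd.DataFrame(
        [row + [None] * (len(columns) - len(row)) for row in rows], columns=columns
    )
    return IntervalSet(df, chromosome_lengths=chromosome_lengths)


def write_bed(intervals: IntervalSet, sink) -> None:
    own = not hasattr(sink, "write")
    stream = open(sink, "w") if own else sink
    try:
        for row in intervals.df.itertuples(index=False):
            fields = [str(v) for v in row if v is not None]
            stream.write("\t".join(fields) + "\n")
    finally:
        if own:
            stream.close()


# ---------------------------------------------------------------------------
# Window stitching
# ---------------------------------------------------------------------------

def stitch_windows(window_maps: Sequence[RhoMap], overlap_snps: int) -> RhoMap:
    """Concatenate overlapping per-window estimates into one chromosome map.

    Consecutive windows must share exactly ``overlap_snps`` SNP positions
    (the estimator is run on e.g. 4400-SNP windows overlapping by 200 SNPs).
    Within each overlap the duplicated intervals are resolved by splitting at
    the overlap midpoint: the earlier window supplies the left half, the
    later window the right half.  The stitched SNP count is
    ``sum(window sizes) - overlap_snps * (n_windows - 1)``.
    """
    if not window_maps:
        raise ValueError("no windows to stitch")
    if overlap_snps < 2:
        raise ValueError("overlap_snps must be >= 2 (shared positions)")
    first = window_maps[0]
    positions = list(first.positions)
    rates = list(first.rates)
    for window in window_maps[1:]:
        if window.chromosome != first.chromosome:
            raise RhoMapError("windows from different chromosomes")
        tail = np.asarray(positions[-overlap_snps:])
        head = window.positions[:overlap_snps]
        if tail.size < overlap_snps or not np.array_equal(tail, head):
            mism = (
                int(head[np.flatnonzero(tail != head)[0]])
                if tail.size == head.size
                else int(head[0])
            )
            raise RhoMapError(f"overlap positions disagree at {mism}")
        n_shared_intervals = overlap_snps - 1
        n_from_earlier = n_shared_intervals // 2
        # replace the right half of the overlap's intervals with the later
        # window's estimates, then append everything beyond the overlap
        replace = n_shared_intervals - n_from_earlier
        if replace:
            rates[-replace:] = list(window.rates[n_from_earlier:n_shared_intervals])
        positions.extend(window.positions[overlap_snps:])
        rates.extend(window.rates[n_shared_intervals:])
    provenance = dict(first.provenance)
    provenance["stitched"] = {
        "n_windows": len(window_maps),
        "overlap_snps": overlap_snps,
    }
    return RhoMap(first.chromosome, np.array(positions), np.array(rates), provenance)
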