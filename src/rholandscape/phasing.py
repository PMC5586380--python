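"""Phasing quality control: pseudofemales, switch errors, error injection.

A pseudofemale merges two haploid sequences (e.g. two male X chromosomes)
into a synthetic diploid whose true phase is known, giving ground truth for
evaluating statistical phasing.  A switch error is an incorrectly resolved
relative phase between consecutive heterozygous sites; the primary rate
reported here divides the number of orientation flips by the total number of
heterozygous sites (the convention used when the statistic was defined for
pseudofemale benchmarking), with the textbook ``n_het - 1`` denominator also
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PhasedPair",
    "SwitchErrorReport",
    "make_pseudofemale",
    "switch_error_rate",
    "inject_switch_errors",
]

MISSING = frozenset("Nn-?.")


@dataclass
class PhasedPair:
    """Two haplotype allele vectors over ordered heterozygous sites."""

    positions: np.ndarray
    hap_a: np.ndarray
    hap_b: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hap_a = np.asarray(self.hap_a, dtype="U1")
        self.hap_b = np.asarray(self.hap_b, dtype="U1")
        if not (self.positions.size == self.hap_a.size == self.hap_b.size):
            raise ValueError("positions and haplotypes must have equal length")
        if np.any(self.hap_a == self.hap_b):
            bad = int(np.flatnonzero(self.hap_a == self.hap_b)[0])
            raise ValueError(f"site {bad} is not heterozygous")

    @property
    def n_het(self) -> int:
        return int(self.positions.size)

    def swapped(self) -> "PhasedPair":
        return PhasedPair(self.positions.copy(), self.hap_b.copy(), self.hap_a.copy())


@dataclass
class SwitchErrorReport:
    """Switch-error summary for one inferred phasing against truth."""

    n_het: int
    n_switches: int
    rate: float  # n_switches / n_het
    rate_conventional: float  # n_switches / (n_het - 1)


def make_pseudofemale(
    hap1: Sequence[str], hap2: Sequence[str], positions: Sequence[int] | None = None
) -> tuple[list[frozenset], PhasedPair]:
    """Merge two haploid sequences into genotypes plus a truth phasing.

    Returns (genotypes, truth): genotypes is one unordered allele pair per
    input site; truth is a :class:`PhasedPair` restricted to sites where the
    haplotypes differ and neither base is missing (N/-/?/.).
    """
    h1 = np.asarray(list(hap1), dtype="U1")
    h2 = np.asarray(list(hap2), dtype="U1")
    if h1.size != h2.size:
        raise ValueError(f"haplotype lengths differ: {h1.size} vs {h2.size}")
    pos = (
        np.arange(1, h1.size + 1, dtype=np.int64)
        if positions is None
        else np.asarray(positions, dtype=np.int64)
    )
    if pos.size != h1.size:
        raise ValueError("positions length mismatch")
    genotypes = [frozenset((a, b)) for a, b in zip(h1, h2)]
    usable = np.array(
        [a != b and a not in MISSING and b not in MISSING for a, b in zip(h1, h2)]
    )
    truth = PhasedPair(pos[usable], h1[usable], h2[usable])
    return genotypes, truth


def switch_error_rate(truth: PhasedPair, inferred: PhasedPair) -> SwitchErrorReport:
    """Count orientation flips between an inferred phasing and the truth.

    At each site the inferred first haplotype either matches the truth's
    first haplotype or its second; a switch is a flip of that orientation
    between consecutive sites.  The result is invariant to globally swapping
    haplotype labels in either argument.  Raises if the positions or the
    unordered allele pairs disagree anywhere (a genotype mismatch, not a
    switch).
    """
    if not np.array_equal(truth.positions, inferred.positions):
        raise ValueError("truth and inferred phasings cover different positions")
    match_a = inferred.hap_a == truth.hap_a
    match_b = inferred.hap_a == truth.hap_b
    if np.any(~(match_a | match_b)) or np.any(inferred.hap_b == inferred.hap_a):
        bad = int(np.flatnonzero(~(match_a | match_b))[0])
        raise ValueError(f"allele pair mismatch at site index {bad}")
    if np.any((inferred.hap_b != truth.hap_a) & (inferred.hap_b != truth.hap_b)):
        bad = int(
            np.flatnonzero(
                (inferred.hap_b != truth.hap_a) & (inferred.hap_b != truth.hap_b)
            )[0]
        )
        raise ValueError(f"allele pair mismatch at site index {bad}")
    orientation = match_a  # True: inferred A tracks truth A
    n_switches = int(np.sum(orientation[1:] != orientation[:-1]))
    n_het = truth.n_het
    return SwitchErrorReport(
        n_het=n_het,
        n_switches=n_switches,
        rate=n_switches / n_het if n_het else 0.0,
        rate_conventional=n_switches / (n_het - 1) if n_het > 1 else 0.0,
    )


def inject_switch_errors(
    pair: PhasedPair, error_rate: float, seed: int | None = None
) -> PhasedPair:
    """Introduce switch errors at heterozygous sites with a given probability.

    An independent Bernoulli(``error_rate``) draw is made per site in
    position order; each success toggles a running swap state, and alleles
    are emitted swapped while the state is active.  Each event therefore
    creates exactly one orientation flip, mimicking a spurious crossover.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    toggles = rng.random(pair.n_het) < error_rate
    swapped_state = np.cumsum(toggles) % 2 == 1
    hap_a = np.where(swapped_state, pair.hap_b, pair.hap_a)
    hap_b = np.where(swapped_state, pair.hap_a, pair.hap_b)
    return PhasedPair(pair.positions.copy(), hap_a, hap_b)
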