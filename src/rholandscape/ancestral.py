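"""Ancestral-allele polarization and mutation-model estimation.

Polarization uses two outgroup alignments: when both outgroups carry the
same base, that base is assigned ancestral and given a prior of 0.91 with
0.03 on each remaining base (allowing for misinference through homoplasy or
back mutation); when the outgroups disagree or either shows an alignment
gap, the site is unresolved and the prior falls back to the stationary
distribution of the mutation matrix.  The matrix itself is estimated from
resolved, non-CpG-prone biallelic sites (CpG-prone sites are hypermutable
and would distort the spectrum); CpG-prone means preceded by C or followed
by G in any of the aligned species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "BASES",
    "MutationModel",
    "classify_cpg_prone",
    "assign_ancestral_prior",
    "build_mutation_model",
    "stationary_distribution",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_VALID = frozenset(BASES)


@dataclass
class MutationModel:
    """4x4 row-stochastic mutation matrix with its stationary distribution.

    ``matrix[i, j]`` is the probability of base j given a mutation-process
    step from base i (rows ordered A, C, G, T); ``stationary`` is the left
    eigenvector with eigenvalue 1, normalized to sum 1.  ``resolved_prior``
    is the mass placed on the inferred ancestral base at resolved sites
    (default 0.91, remainder split equally over the other three bases).
    """

    matrix: np.ndarray
    stationary: np.ndarray
    resolved_prior: float = 0.91

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.stationary = np.asarray(self.stationary, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("matrix rows must sum to 1")
        if not np.isclose(self.stationary.sum(), 1.0, atol=1e-10):
            raise ValueError("stationary must sum to 1")
        if not np.allclose(self.stationary @ self.matrix, self.stationary, atol=1e-8):
            raise ValueError("stationary is not invariant under the matrix")
        if not 0 < self.resolved_prior < 1:
            raise ValueError("resolved_prior must be in (0, 1)")

    @property
    def unresolved_mass(self) -> float:
        return (1.0 - self.resolved_prior) / 3.0

    def resolved_prior_vector(self, base: str) -> np.ndarray:
        prior = np.full(4, self.unresolved_mass)
        prior[_BASE_INDEX[base]] = self.resolved_prior
        return prior


def classify_cpg_prone(
    contexts: Iterable[tuple[str | None, str | None]]
) -> bool:
    """CpG-prone test from per-species (left, right) neighbor bases.

    True iff the site is preceded by C or followed by G in ANY species;
    missing context (None, gap, N) contributes False for that species.
    """
    for left, right in contexts:
        if left is not None and left.upper() == "C":
            return True
        if right is not None and right.upper() == "G":
            return True
    return False


def assign_ancestral_prior(
    focal_alleles: Sequence[str],
    outgroup1: str | None,
    outgroup2: str | None,
    model: MutationModel,
) -> tuple[str, np.ndarray]:
    """Ancestral prior for one polymorphic site from two outgroup bases.

    Returns ("resolved", prior) when the outgroups agree on a valid base
    (prior 0.91 on that base, 0.03 elsewhere), otherwise ("unresolved",
    stationary distribution) — covering outgroup disagreement, gaps, and
    missing data.  The prior always sums to 1.
    """
    o1 = (outgroup1 or "").upper()
    o2 = (outgroup2 or "").upper()
    if o1 in _VALID and o2 in _VALID and o1 == o2:
        return "resolved", model.resolved_prior_vector(o1)
    return "unresolved", model.stationary.copy()


def stationary_distribution(matrix: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Left unit-eigenvector of a row-stochastic matrix, cross-checked.

    Computed by eigen-decomposition and verified against fixed-point
    iteration; disagreement beyond 1e-10 raises (it would indicate a
    reducible or periodic chain for which the stationary law is not
    unique).
    """
    matrix = np.asarray(matrix, dtype=float)
    values, vectors = linalg.eig(matrix.T)
    idx = int(np.argmin(np.abs(values - 1.0)))
    pi = np.real(vectors[:, idx])
    pi = pi / pi.sum()
    # verification by power iteration on the lazy chain (P + I)/2, which has
    # the same stationary law but cannot oscillate on periodic chains
    lazy = 0.5 * (matrix + np.eye(matrix.shape[0]))
    it = np.full(matrix.shape[0], 1.0 / matrix.shape[0])
    for _ in range(100_000):
        nxt = it @ lazy
        if np.max(np.abs(nxt - it)) < tol:
            it = nxt
            break
        it = nxt
    if np.max(np.abs(it - pi)) > 1e-10:
        raise ValueError("eigen and iterative stationary estimates disagree")
    return pi


def build_mutation_model(
    polarized_sites: Iterable[tuple[str, str]],
    off_diagonal_scale: float = 1.0,
    pseudocount: float = 0.0,
    resolved_prior: float = 0.91,
) -> MutationModel:
    """Estimate a mutation matrix from (ancestral, derived) base pairs.

    Off-diagonal entry (a, b) is proportional to the count of resolved sites
    with ancestral a and derived b; each row's off-diagonal mass is the
    observed conditional spectrum scaled by ``off_diagonal_scale`` (default
    1, a pure jump chain; the stationary distribution is invariant to this
    scale), with the diagonal absorbing the remainder.  An ancestral base
    with zero observations raises with a suggestion to pass a pseudocount.
    """
    if not 0 < off_diagonal_scale <= 1:
        raise ValueError("off_diagonal_scale must be in (0, 1]")
    counts = np.full((4, 4), float(pseudocount))
    np.fill_diagonal(counts, 0.0)
    for ancestral, derived in polarized_sites:
        a, d = ancestral.upper(), derived.upper()
        if a not in _VALID or d not in _VALID or a == d:
            continue
        counts[_BASE_INDEX[a], _BASE_INDEX[d]] += 1.0
    row_totals = counts.sum(axis=1)
    if np.any(row_totals <= 0):
        missing = [BASES[i] for i in np.flatnonzero(row_totals <= 0)]
        raise ValueError(
            f"no observations with ancestral base {missing}; "
            "pass pseudocount > 0 to regularize"
        )
    conditional = counts / row_totals[:, None]
    matrix = off_diagonal_scale * conditional
    np.fill_diagonal(matrix, 0.0)
    np.fill_diagonal(matrix, 1.0 - matrix.sum(axis=1))
    pi = stationary_distribution(matrix)
    return MutationModel(matrix=matrix, stationary=pi, resolved_prior=resolved_prior)
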