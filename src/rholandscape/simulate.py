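"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the validation design used for
LD-based map inference from a small population sample: neutrally evolving
sequence with theta = 0.01 (the genome-wide diversity of the emulated
population), scaled recombination rates spanning 2e-6 to 2e1 per bp, 0.5 Mb
replicates, and samples of 20 haplotypes.  Haplotypes come from a coalescent
with recombination (msprime) rather than forward simulation; at neutral
equilibrium the two give identical expectations for the statistics used
here.  Landscape, polarization-site, and gene-table generators are pure
NumPy and carry their ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .ancestral import BASES, MutationModel
from .maps import IntervalSet, RhoMap

__all__ = [
    "SimConfig",
    "HaplotypeSample",
    "simulate_landscape",
    "simulate_haplotypes",
    "simulate_polarization_sites",
    "simulate_gene_table",
    "four_gamete_violations",
    "write_ldhat_sites",
    "write_ldhat_locs",
]

DEFAULT_RHO_GRID = tuple(2.0 * 10.0**e for e in range(-6, 2))  # 2e-6 .. 2e1


@dataclass
class SimConfig:
    """Study conditions for haplotype simulation.

    theta: scaled mutation rate 4*Ne*mu per bp (default 0.01).
    rho_values: grid of scaled recombination rates rho/bp.
    length: sequence length per replicate (default 0.5 Mb).
    n_haplotypes: sampled chromosomes (default 20, i.e. 10 diploids).
    replicates: repeats per rho value (default 20).
    population_size: the diploid N of the emulated forward design (1000);
        recorded as provenance, the coalescent works directly in scaled units.
    """

    theta: float = 0.01
    rho_values: tuple = DEFAULT_RHO_GRID
    length: int = 500_000
    n_haplotypes: int = 20
    replicates: int = 20
    population_size: int = 1_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.length <= 0 or self.n_haplotypes < 2:
            raise ValueError("invalid simulation configuration")


@dataclass
class HaplotypeSample:
    """A sample of haplotypes at biallelic sites with ground truth attached."""

    positions: np.ndarray  # bp; fractional under the infinite-sites model
    matrix: np.ndarray  # (n_haplotypes, n_sites) of 0 (ancestral) / 1 (derived)
    ancestral: np.ndarray | None = None  # per-site ancestral base
    derived: np.ndarray | None = None  # per-site derived base
    provenance: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_haplotypes(self) -> int:
        return int(self.matrix.shape[0])

    def mean_pairwise_diversity(self) -> float:
        """Mean pairwise diversity per bp over the simulated length."""
        n = self.n_haplotypes
        freq = self.matrix.sum(axis=0)
        pair_diffs = freq * (n - freq)
        length = self.provenance.get("length")
        if length is None:
            raise ValueError("provenance lacks sequence length")
        return float(pair_diffs.sum() / (n * (n - 1) / 2) / length)


def simulate_landscape(
    background_mean: float,
    hotspots_per_mb: float,
    intensity: float,
    width: int = 2_000,
    length: int = 1_000_000,
    seed: int | None = None,
    segment: int = 2_000,
    gamma_shape: float = 50.0,
    flank_total: int = 80_000,
    min_separation: int | None = None,
) -> tuple[RhoMap, IntervalSet]:
    """Piecewise-constant rho landscape with planted hotspots.

    Background segment rates are gamma-distributed with the requested mean
    (shape 50 by default: mild, realistic local variation).  Hotspot
    segments are chosen uniformly away from chromosome ends, separated by at
    least ``min_separation`` segments (default: far enough apart that no
    hotspot lies inside another's ``flank_total`` flank, so each planted
    focal/flank intensity is exact relative to the background it will be
    judged against).  The hotspot rate is ``intensity`` times the
    weighted-mean background over ``(flank_total - width)/2`` bp on each
    side, the same flank geometry the caller uses.  Returns the map (SNP
    grid every ``segment`` bp, first position 1) and the truth intervals in
    BED coordinates.
    """
    if intensity <= 1:
        raise ValueError("intensity must exceed 1")
    if width != segment:
        raise ValueError("planted hotspot width must equal the segment size")
    rng = np.random.default_rng(seed)
    n_segments = length // segment
    rates = rng.gamma(gamma_shape, background_mean / gamma_shape, size=n_segments)

    half_flank = (flank_total - width) / 2.0
    n_hot = int(round(hotspots_per_mb * length / 1e6))
    margin_segs = int(np.ceil(half_flank / segment))
    if min_separation is None:
        min_separation = int(np.ceil(half_flank / segment)) + 1
    candidates = np.arange(margin_segs, max(margin_segs, n_segments - margin_segs))
    if n_hot > 0 and (
        candidates.size < n_hot or n_hot * min_separation > candidates.size
    ):
        raise ValueError("hotspot density too high for the requested length")
    chosen: list[int] = []
    for _ in range(100_000):
        if len(chosen) == n_hot:
            break
        pick = int(rng.choice(candidates))
        if all(abs(pick - c) >= min_separation for c in chosen):
            chosen.append(pick)
    if len(chosen) < n_hot:
        raise ValueError("could not place separated hotspots at this density")
    chosen.sort()

    # weighted-mean background over the exact flank geometry (fractional
    # segment coverage at the flank edges included)
    edges = np.arange(n_segments + 1, dtype=float) * segment
    cum = np.concatenate([[0.0], np.cumsum(rates * segment)])

    def flank_mean(ws: float, we: float) -> float:
        a0, a1 = max(0.0, ws - half_flank), ws
        b0, b1 = we, min(float(length), we + half_flank)
        mass = (np.interp(a1, edges, cum) - np.interp(a0, edges, cum)) + (
            np.interp(b1, edges, cum) - np.interp(b0, edges, cum)
        )
        return mass / ((a1 - a0) + (b1 - b0))

    flank_means = {idx: flank_mean(idx * segment, (idx + 1) * segment) for idx in chosen}
    for idx in chosen:
        rates[idx] = intensity * flank_means[idx]

    positions = np.arange(n_segments + 1, dtype=np.int64) * segment + 1
    truth = IntervalSet(
        pd.DataFrame(
            {
                "chrom": "sim",
                "start": [i * segment for i in chosen],
                "end": [(i + 1) * segment for i in chosen],
            }
        )
        if chosen
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    rho_map = RhoMap(
        "sim",
        positions,
        rates,
        provenance={"seed": seed, "background_mean": background_mean},
    )
    return rho_map, truth


def _split_seed(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]


def simulate_haplotypes(
    config: SimConfig,
    rho_map: RhoMap | float,
    mutation_model: MutationModel | None = None,
    seed: int | None = None,
) -> HaplotypeSample:
    """Sample haplotypes under the coalescent with recombination.

    ``rho_map`` is either a constant rho/bp or a :class:`RhoMap` whose span
    sets the sequence length.  The coalescent runs on haploid lineages with
    a unit time scale (pairwise coalescence time 1), so per-generation rates
    are half the scaled rates: r = rho/2 and mu = theta/2, giving
    E[pairwise diversity] = theta and the standard scaled-rho LD decay.
    Sites are strictly biallelic 0/1; when a mutation model is supplied,
    ancestral bases are drawn from its stationary distribution and derived
    bases from the corresponding matrix row.  Bit-reproducible under a
    fixed seed.
    """
    seed = seed if seed is not None else config.seed
    ms_seed, base_seed = _split_seed(seed, 2)

    if isinstance(rho_map, RhoMap):
        # shift the map so its first SNP sits at coordinate 0
        edges = (rho_map.positions - rho_map.positions[0]).astype(float)
        length = int(edges[-1])
        recomb = msprime.RateMap(position=edges, rate=rho_map.rates / 2.0)
    else:
        length = int(config.length)
        recomb = float(rho_map) / 2.0

    ts = msprime.sim_ancestry(
        samples=config.n_haplotypes,
        ploidy=1,
        population_size=1.0,
        sequence_length=length,
        recombination_rate=recomb,
        discrete_genome=True,
        random_seed=ms_seed,
    )
    # continuous-genome mutations: every site has a unique position and a
    # single origin, i.e. exact infinite-sites behavior (E[diversity] = theta)
    mts = msprime.sim_mutations(
        ts,
        rate=config.theta / 2.0,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=ms_seed,
    )
    positions, columns = [], []
    for variant in mts.variants():
        g = variant.genotypes
        if 0 < g.sum() < g.size:
            positions.append(variant.site.position)
            columns.append(g.astype(np.int8))
    positions = np.asarray(positions, dtype=np.float64)
    matrix = (
        np.column_stack(columns)
        if columns
        else np.empty((config.n_haplotypes, 0), dtype=np.int8)
    )

    ancestral = derived = None
    if mutation_model is not None and positions.size:
        rng = np.random.default_rng(base_seed)
        anc_idx = rng.choice(4, size=positions.size, p=mutation_model.stationary)
        off = mutation_model.matrix.copy()
        np.fill_diagonal(off, 0.0)
        off = off / off.sum(axis=1, keepdims=True)
        der_idx = np.array(
            [rng.choice(4, p=off[a]) for a in anc_idx], dtype=np.int64
        )
        bases = np.array(list(BASES))
        ancestral, derived = bases[anc_idx], bases[der_idx]

    return HaplotypeSample(
        positions=positions,
        matrix=matrix,
        ancestral=ancestral,
        derived=derived,
        provenance={"seed": seed, "length": length, "theta": config.theta},
    )


def four_gamete_violations(matrix: np.ndarray) -> int:
    """Number of adjacent site pairs exhibiting all four gametes.

    Under the infinite-sites model a four-gamete pair requires at least one
    recombination event between the sites, so the count grows with rho.
    """
    m = np.asarray(matrix)
    if m.shape[1] < 2:
        return 0
    left, right = m[:, :-1], m[:, 1:]
    combos = left * 2 + right
    seen = np.zeros((m.shape[1] - 1, 4), dtype=bool)
    for k in range(4):
        seen[:, k] = np.any(combos == k, axis=0)
    return int(np.sum(seen.all(axis=1)))


def simulate_polarization_sites(
    model: MutationModel,
    n_sites: int,
    outgroup_error: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Quartet sites with known ancestral truth for polarization tests.

    Ancestral bases are drawn from the model's stationary distribution and
    derived bases from the conditional off-diagonal of its matrix.  Both
    outgroups copy the ancestral base and are independently perturbed with
    probability ``outgroup_error`` to a uniformly chosen different base.
    Columns: ancestral, derived, outgroup1, outgroup2.
    """
    if not 0 <= outgroup_error <= 1:
        raise ValueError("outgroup_error must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list(BASES))
    anc_idx = rng.choice(4, size=n_sites, p=model.stationary)
    off = model.matrix.copy()
    np.fill_diagonal(off, 0.0)
    off = off / off.sum(axis=1, keepdims=True)
    cum = np.cumsum(off, axis=1)
    der_idx = (rng.random(n_sites)[:, None] < cum[anc_idx]).argmax(axis=1)

    def perturb(idx: np.ndarray) -> np.ndarray:
        out = idx.copy()
        hit = rng.random(n_sites) < outgroup_error
        shift = rng.integers(1, 4, size=n_sites)  # 1..3 -> a different base
        out[hit] = (out[hit] + shift[hit]) % 4
        return out

    return pd.DataFrame(
        {
            "ancestral": bases[anc_idx],
            "derived": bases[der_idx],
            "outgroup1": bases[perturb(anc_idx)],
            "outgroup2": bases[perturb(anc_idx)],
        }
    )


def simulate_gene_table(
    n_genes: int,
    tau: float,
    seed: int | None = None,
    rho_median: float = 0.009,
    rho_sigma: float = 0.6,
    pi_median: float = 0.008,
    pi_sigma: float = 0.5,
    d_median: float = 0.17,
    d_sigma: float = 0.15,
) -> pd.DataFrame:
    """Gene table with a target Kendall correlation between rho_bar and pi.

    (rho_bar, pi) are drawn from a Gaussian copula with Pearson parameter
    ``sin(pi_const * tau / 2)`` — the closed-form inverse of Kendall's tau
    for elliptical copulas — with lognormal marginals at realistic scales
    (median rho/bp near the genome-wide mean, fourfold diversity near 0.8%,
    mouse-rat fourfold divergence near 0.17).  d_rat is independent of both.
    """
    if not -1 < tau < 1:
        raise ValueError("target tau must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    r = np.sin(np.pi * tau / 2.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
    rho_bar = np.exp(np.log(rho_median) + rho_sigma * z[:, 0])
    pi_vals = np.exp(np.log(pi_median) + pi_sigma * z[:, 1])
    d_rat = np.exp(np.log(d_median) + d_sigma * rng.standard_normal(n_genes))
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "rho_bar": rho_bar,
            "pi": pi_vals,
            "d_rat": d_rat,
            "pi_over_d": pi_vals / d_rat,
        }
    )


# ---------------------------------------------------------------------------
# estimator-ready writers
# ---------------------------------------------------------------------------

def write_ldhat_sites(sample: HaplotypeSample, sink) -> None:
    """Write haplotypes in the sites format used by LD-based estimators."""
    own = not hasattr(sink, "write")
    stream = open(sink, "w") if own else sink
    try:
        stream.write(f"{sample.n_haplotypes} {sample.n_sites} 1\n")
        for i in range(sample.n_haplotypes):
            stream.write(f">hap{i}\n")
            stream.write("".join(map(str, sample.matrix[i])) + "\n")
    finally:
        if own:
            stream.close()


def write_ldhat_locs(sample: HaplotypeSample, sink, length: int | None = None) -> None:
    """Write the matching locs file (positions in kb, L-flagged)."""
    own = not hasattr(sink, "write")
    stream = open(sink, "w") if own else sink
    length = length or sample.provenance.get("length")
    try:
        stream.write(f"{sample.n_sites} {length / 1000:.3f} L\n")
        stream.write("\n".join(f"{p / 1000:.3f}" for p in sample.positions) + "\n")
    finally:
        if own:
            stream.close()
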