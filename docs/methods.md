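# Methods

This note records the models, conventions, and design choices behind each
module, including where the design was genuinely open and what the synthetic
data do and do not establish about real data.

## Coordinates and map representation

SNP positions are 1-based (matching LD-estimator output); interval sets are
0-based half-open (BED). All conversion happens in `maps` (`snp_to_bed`,
`bed_to_snp`); the interval between SNPs at 1-based positions p and q covers
0-based [p−1, q−1). A `RhoMap` is piecewise constant: `rates[i]` applies
between `positions[i]` and `positions[i+1]`, in units of ρ = 4Nₑr per bp.
Estimator block penalties and window schemes are carried as provenance and
never interpreted.

Gap handling on read is explicit: by default a gap between consecutive rows
is an error naming the row; with `gap_tolerant=True` a bridging zero-rate
interval is inserted and recorded in provenance, so missing rows can never
silently inflate genetic map length. The per-bp vs per-kbp dialect is an
explicit flag and never sniffed — silent unit errors are the dominant
failure mode for these files.

**Window stitching.** Overlapping per-window estimates (w SNPs, k shared)
are concatenated by splitting each overlap at its midpoint: of the k−1
duplicated intervals, the earlier window supplies the first ⌊(k−1)/2⌋ and
the later window the rest. The rule is symmetric and deterministic, and the
stitched SNP count obeys the closed form Σwᵢ − k(m−1). Which copy of an
overlapping estimate to keep is not determined by the statistic itself; the
midpoint split is this package's choice and the result is independent of it
whenever the two windows agree in the overlap.

## Broad-scale statistics

All map averages are frequency-weighted: ρ̄ = Σρᵢdᵢ/Σdᵢ with dᵢ the physical
interval length, clipped exactly at region boundaries. An empty
map-region intersection is an error, deliberately distinct from a zero rate.

**Centimorgan anchoring.** cM(j) = C · cumρ(j)/cumρ(last), where C is the
chromosome's total genetic length from an external linkage map (the bundled
Cox-map table, `datasets.cox_anchors`). The first SNP maps to 0 and the last
to C exactly (the final value is set, not accumulated, to avoid float
residue). The transform is a positive rescaling, so the rank order of
interval rates is preserved.

**Windows.** Half-open [s, s+size) anchored at coordinate 0, nonoverlapping
or sliding with a positive offset. The final partial window is kept; each
window carries a coverage fraction, and windows below `min_coverage`
(default 0.5) are missing (NaN), never zero. Correlations drop missing
windows pairwise and refuse fewer than 3 shared windows; windows are
weighted equally, not by SNP count — a choice, made once, where either
convention is defensible.

**Nₑ.** From ρ̄ = 4Nₑr with r = (cM/Mb) × 10⁻⁸ per bp per generation.
Presentation rounding (nearest 1,000) is available as `ne_rounded`.
Per-chromosome published rates used by the examples and the acceptance
script live in `datasets.mouse_chromosome_rates`.

## Lorenz/Gini heterogeneity

Intervals are sorted by rate ascending (ties by position; the result is
invariant to tie order, which is tested), each contributing its share of
physical length on x and of total ρ mass on y; G = 1 − 2·(trapezoidal area).
Intervals are weighted by physical length, not counted equally, because SNP
spacing is irregular and the Lorenz axes are physical vs genetic distance.
Raw map intervals are used rather than fixed-size bins — binning smooths the
curve and shrinks G, and the raw-interval curve is the one the piecewise
model actually defines. On equal-length intervals the trapezoid G equals the
mean-absolute-pairwise-difference form Σ|xᵢ−xⱼ|/(2n²x̄) to 10⁻¹², used as an
independent oracle. An all-zero map has no Lorenz curve and raises.

## Hotspot caller and overlap null

The chromosome is tiled into nonoverlapping 2 kb windows from coordinate 0.
The background for each window is the weighted-mean rate over
(flank_total − window)/2 = 39 kb on each side, excluding the focal window
("surrounding" would be contradicted by including the window, which would
also dilute its own signal). Flanks are truncated at chromosome ends and
must retain ≥ `min_flank_coverage` (default 0.5) of the nominal extent. The
threshold is inclusive (focal ≥ 5 × background). Zero background with
positive focal mass is flagged and annotated `zero-background` rather than
dividing by zero. Adjacent flagged windows are merged, so hotspots wider
than one window arise only from the merge rule.

**Randomization null.** Each query interval is re-placed uniformly at a
start in [0, L − len] on its own chromosome (lengths preserved, placements
independent, collisions among placed intervals permitted — the bias from
forbidding collisions is negligible at realistic densities and the permitted
version is exactly enumerable, which the tests exploit). Overlap counting is
b-side (how many target intervals hit ≥ 1 query interval), with a symmetric
variant available. The maximum count over replicates (default 1000) serves
as an ≈ 0.1% significance threshold. Whether "randomized with respect to
chromosome" should also permute chromosome assignment is ambiguous; 
within-chromosome re-placement is the default and chromosome permutation is
exposed as `permute_chromosomes` without any claim about precedent. One RNG
is seeded per run and the seed is recorded in the result.

## Phasing QC

A pseudofemale merges two haploid sequences into genotypes whose true phase
is known; only sites where the haplotypes differ and neither base is missing
enter the truth pairing. Switch-error counting assigns each site an
orientation (inferred hap A tracks truth hap A or truth hap B) and counts
flips between consecutive sites, so a globally swapped labelling has rate 0.
The primary rate divides by the total number of heterozygous sites — the
convention under which the pseudofemale benchmark statistic was defined —
and the conventional n_het − 1 denominator is reported alongside
(`rate_conventional`); they differ by (n−1)/n.

Error injection draws an independent Bernoulli(e) per site in position
order and toggles a running swap state, so each event creates exactly one
orientation flip (a spurious crossover). Under this scheme
E[measured rate] = e·(n−1)/n, which the round-trip tests verify within
binomial error at e ∈ {0.001, 0.0046, 0.05}. Read-aware phasing itself and
BAM-level pseudofemale variant recalling are out of scope: the statistic is
defined at the haplotype/genotype level and that is where this module
operates.

## Variant filtering

The cascade keeps biallelic SNPs with QUAL ≥ 30, all individuals at
GQ ≥ 15 (one failing individual removes the site), optional per-individual
depth bounds (disabled by default — the final filter set of the emulated
pipeline names only GQ and QUAL), and exact-HWE p ≥ 0.002. Each removed site
is attributed to the first failing rule; filtering is idempotent.

The HWE test is the exact conditional ("probability-ordering", two-sided)
test: given the minor-allele count m in n genotypes, the heterozygote count
h has P(h) ∝ n!/(n_AA! h! n_aa!)·2ʰ, and the p-value sums P(h′) over all h′
with P(h′) ≤ P(h_obs). Weights are exact integers, so the ≤ comparison has
no rounding ambiguity. CpG-prone sites are *not* removed here — they are
retained for map inference (excluding them would discard roughly half the
data) and handled only in mutation-matrix estimation.

## Ancestral inference

CpG-prone: preceded by C or followed by G in any of the three aligned
species; missing context contributes false for that species. Polarization
is two-outgroup agreement parsimony, exactly: agreement on a valid base
resolves the site with prior 0.91/0.03/0.03/0.03; disagreement, gap, or
missing data leaves it unresolved with the stationary distribution as the
prior. No probabilistic polarization is attempted — the 0.91 prior *is* the
uncertainty device.

The mutation matrix is estimated from resolved non-CpG-prone sites as row
conditional spectra: off-diagonal (a,b) ∝ count(ancestral a → derived b),
scaled by `off_diagonal_scale` (default 1, a pure jump chain) with the
diagonal absorbing the remainder. The stationary distribution is invariant
to that scale, which is the property downstream code relies on; the
estimator-specific diagonal convention is left configurable because no
single convention is canonical. The stationary law is computed by
eigen-decomposition and verified against power iteration on the lazy chain
(P+I)/2 (immune to periodicity); disagreement beyond 10⁻¹⁰ raises, which is
also how reducible count patterns (no unique stationary law) surface. An
ancestral base with zero observations raises with a pseudocount suggestion
rather than silently regularizing.

## Gene correlates

Fourfold degenerate sites are third codon positions whose first two bases
form a fourfold family (CT, GT, TC, CC, AC, GC, CG, GG) in the focal species
and both outgroups; minus-strand genes are evaluated on the reverse
complement and CpG context is taken in reading direction. Per-site
π = (pairwise differences)/C(n,2) from sample allele counts, with n
rescaled per site when alleles are missing; per-gene π averages over sites.
Divergence to rat is the mismatch fraction between the focal aligned base
and the rat base; π/d is defined only when d > 0. QC flags: > 80% of
fourfold sites missing (`high_missing`), and every comparable non-CpG
fourfold site mismatching rat with at least one such site
(`all_rat_mismatch`) — both symptomatic of alignment failure. A gene with
zero usable sites is flagged, never NaN-propagated. Per-gene ρ̄ uses the
gene span only (no flanks); GC content is computed over the focal gene
span. Correlations are tie-corrected Kendall τ-b via scipy, with all-tied
vectors rejected as undefined.

## Synthetic data

The generators' defaults are the emulated study conditions: θ = 0.01
(≈ genome-wide wild-mouse diversity), ρ grids 2×10⁻⁶ … 2×10¹ per bp, 0.5 Mb
replicates, 20 haplotypes, 20 replicates per condition, and an emulated
forward-design population size of 1000 recorded as provenance.

**Haplotypes.** Coalescent with recombination (msprime) instead of forward
simulation — at neutral equilibrium the expectations of every statistic
used here coincide, and the coalescent is orders of magnitude faster. The
haploid-lineage model runs on a unit time scale (pairwise coalescence time
1), so per-generation rates are half the scaled ones: r = ρ/2, μ = θ/2,
giving E[π] = θ exactly. Mutations are placed on a continuous genome, so
every site has a unique (fractional) position and a single origin — exact
infinite-sites behavior; with ρ = 0 no adjacent site pair can show four
gametes, and the four-gamete count grows with ρ. Derived/ancestral bases
are optionally assigned from a supplied mutation model after the fact.

**Landscapes.** Background rates are gamma with the requested mean and
shape 50 (coefficient of variation ≈ 0.14 — mild, smooth local variation;
heavier-tailed backgrounds are available via the shape parameter but make
"background" windows themselves hotspot-like). Planted hotspots occupy one
2 kb grid segment each, are kept away from chromosome ends, and by default
are separated far enough that no hotspot lies inside another's 80 kb flank;
their rate is `intensity` × the weighted-mean background over exactly the
flank geometry the caller uses. This makes the planted focal/flank ratio
exact by construction, so "planted at 6×" means precisely 6× relative to
the background it will be judged against — without the separation rule,
neighboring hotspots inflate each other's backgrounds and the nominal
intensity is not the realized one.

**Polarization quartets.** Ancestral bases from the model's stationary law,
derived from its conditional rows, outgroups copying the ancestor with
independent perturbation to a uniformly chosen different base. At error
rate 1 the resolution rate has the closed form 1/3 (two independent uniform
choices among three bases), which is tested.

**Gene tables.** A Gaussian copula with Pearson parameter sin(πτ*/2) — the
exact inverse of Kendall's τ for elliptical copulas — and lognormal
marginals at realistic scales (ρ̄ median 0.009, fourfold π median 0.008,
mouse–rat fourfold divergence median 0.17). d_rat is independent of both.

**What the synthetic data do not show.** The generators produce equilibrium,
neutrally evolving, panmictic data with strictly biallelic single-origin
sites and exactly known truth. Real data add selection at linked sites,
population structure, genotyping and phasing error correlated along the
genome, CpG hypermutability, and alignment artefacts. Passing the recovery
tests therefore demonstrates correctness of the *computations* under their
stated models, not robustness of LD-based inference to those violations.

## Problem sizes and numerical choices

Test and acceptance-script scales are chosen to keep the full run in the
low minutes on one CPU: θ-recovery uses L = 10⁵ over 30 seeds; four-gamete
monotonicity uses L = 5×10⁴ with 5 replicates per ρ level; hotspot recovery
uses 20 seeds × 1 Mb at 10 hotspots/Mb; switch-error round trips use
n_het = 10⁵; mutation-model recovery uses 10⁵ quartets; gene-table recovery
uses 2,000 genes; the overlap null uses 1,000 replicates. Monte-Carlo
assertions use 3 standard errors of the relevant sampling distribution
(binomial or empirical across seeds). Exact identities (Gini closed forms,
HWE enumeration, stationary residuals) are asserted at 10⁻¹⁰–10⁻¹².

## Known limitations

- The estimator itself (composite-likelihood rjMCMC) is consumed, never
  run; Fig-style detection-floor experiments are emulated only up to data
  generation and LD summaries.
- Genome-scale quantities (total hotspot counts, genome-wide Gini values,
  DSB-overlap percentages, real switch-error rates) require the full mouse
  dataset and are deliberately outside the test surface; the package
  provides the machinery, not those numbers.
- The X chromosome is included in chromosome-level correlations by default
  (excludable by flag); sex-specific maps are out of scope.
- VCF support covers biallelic SNP records with GT/GQ/DP; no genotype
  calling or liftover between genome builds.
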