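# rho-landscape

Post-processing and validation toolkit for LD-based recombination-rate maps,
built around the analyses used to characterize the recombination landscape
of wild house mice (*Mus musculus castaneus*) from population genomic data.

Coalescent methods (LDhat, LDhelmet) infer the population-scaled
recombination rate **ρ = 4Nₑr** per base pair between adjacent SNPs from a
sample of phased haplotypes. Turning that raw output into biology requires a
chain of downstream steps, each of which this package implements as tested,
reusable code:

- **Map assembly and I/O** — parsing estimator output (per-bp or per-kbp
  dialects), stitching overlapping per-window estimates (e.g. 4400-SNP
  windows overlapping by 200 SNPs) into chromosome-scale maps.
- **Broad-scale statistics** — frequency-weighted mean rates
  (ρ̄ = Σρᵢdᵢ/Σdᵢ, weighting each SNP pair by the bases separating it),
  anchoring cumulative ρ to a pedigree-based linkage map to express positions
  in centimorgans, windowed map-vs-map correlations, and effective population
  size via Nₑ = ρ̄/(4r) with r fixed by a cM/Mb estimate.
- **Fine-scale heterogeneity** — Lorenz curves and Gini coefficients of the
  genetic map (G = 0 uniform, G → 1 all crossovers in a tiny fraction of
  sequence).
- **Hotspot analysis** — the 2 kb-window caller flagging windows ≥ 5× the
  weighted-mean rate of the surrounding 80 kb (merging adjacent flagged
  windows), and a within-chromosome randomization null for overlap with
  independent interval sets such as double-strand-break (DSB) hotspot maps.
- **Phasing QC** — pseudofemale construction from two haploid sequences
  (e.g. male X chromosomes), switch-error rates (orientation flips between
  consecutive heterozygous sites over total heterozygous sites), and
  switch-error injection for sensitivity analyses.
- **Variant filtering** — biallelic-SNP selection with QUAL/GQ/depth
  thresholds (any-individual semantics) and the exact conditional
  Hardy–Weinberg test.
- **Ancestral inference** — two-outgroup polarization (prior 0.91 on the
  agreed base, 0.03 elsewhere; stationary-distribution prior at unresolved
  sites), CpG-prone classification, and mutation-matrix estimation.
- **Gene correlates** — per-gene π, divergence to rat, π/d and GC content at
  fourfold degenerate sites, with Kendall rank correlations against ρ̄.
- **Synthetic data** — generators with known ground truth for every stage:
  gamma-background landscapes with planted hotspots, coalescent haplotypes
  (msprime; θ = 0.01 study conditions), polarization quartets from a known
  mutation matrix, and gene tables with a target rank correlation.

## Worked example

```python
import numpy as np
from scipy import stats
from rholandscape import (estimate_ne, simulate_landscape, call_hotspots,
                          count_overlaps, lorenz_gini)
from rholandscape.datasets import mouse_chromosome_rates

# Chromosome-level rates: LD-based rho vs the Cox linkage map
table = mouse_chromosome_rates()
est = estimate_ne(0.0079, 0.50)   # chromosome 1: rho_bar, cM/Mb
print(f"chromosome 1: rho_bar = {est.rho_bar}, r = {est.r_per_bp:.2e}/bp, "
      f"Ne ~ {est.ne_rounded:,}")
auto = table[table.chromosome != "X"]
print(f"autosomal mean rho/bp = {auto.castaneus_rho_per_bp.mean():.4f}")
r, p = stats.pearsonr(table.cox_cm_per_mb, table.castaneus_rho_per_bp)
print(f"chromosome-level Pearson r = {r:.2f} (P = {p:.3f}, n = {len(table)})")

# Hotspot calling on a synthetic landscape with known truth
rho_map, truth = simulate_landscape(0.003, 10.0, 6.0, length=1_000_000, seed=1)
called = call_hotspots(rho_map)
print(f"planted {len(truth)} hotspots, called {len(called)}, "
      f"recovered {count_overlaps(called, truth)}")
print(f"landscape Gini = {lorenz_gini(rho_map).gini:.3f}")
```

prints

```
chromosome 1: rho_bar = 0.0079, r = 5.00e-09/bp, Ne ~ 395,000
autosomal mean rho/bp = 0.0092
chromosome-level Pearson r = 0.68 (P = 0.001, n = 20)
planted 10 hotspots, called 10, recovered 10
landscape Gini = 0.155
```

The first three lines reproduce the whole-chromosome summary for the wild
mouse map: an effective population size near 4 × 10⁵ for chromosome 1, a
genome-wide weighted-mean ρ/bp of 0.0092, and a strong correlation between
the LD-based scaled rates and pedigree-based cM/Mb across the 20
chromosomes. The last two lines show the hotspot caller recovering every
planted hotspot on a synthetic landscape whose mild background variation
yields a low Gini coefficient.

A command-line interface mirrors the main operations:

```bash
rho-landscape convert raw.txt map.txt --dialect per_kbp
rho-landscape stitch win1.txt win2.txt --overlap 200 --out chr1.txt
rho-landscape hotspots chr1.txt --out hotspots.bed
rho-landscape overlap-test hotspots.bed dsb.bed --lengths lengths.tsv \
    --reps 1000 --seed 1
rho-landscape gini chr1.txt
rho-landscape switch-error truth.txt inferred.txt
```

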