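# chickld

Linkage-disequilibrium decay, LD-based effective population size, and
IBS/MDS diversity for multi-line SNP-array genotype panels.

Conservation flocks and breeding-stock lines — the motivating case is
native chicken lines kept by public institutes and private breeders — are
routinely genotyped on dense SNP arrays to decide how to manage their
diversity. The questions such a panel answers are: how fast does LD decay
with marker distance within each line, what effective population size
(Ne) trajectory does that LD imply, and how distinct are the lines from
each other? `chickld` implements that pipeline end to end for PLINK 1
binary panels, and ships a Wright–Fisher forward simulator so every stage
can be validated against a known ground truth.

## The statistics at the core

**Pairwise r² from EM haplotype frequencies.** For two biallelic loci
with unphased diploid genotypes, the four haplotype frequencies
p₁₁, p₁₂, p₂₁, p₂₂ are estimated by maximum likelihood with an EM
algorithm (double heterozygotes are split between coupling and repulsion
phases in ratio p₁₁p₂₂ : p₁₂p₂₁ and re-counted to a fixed point). Then

    D  = p₁₁p₂₂ − p₁₂p₂₁
    r² = D² / (p_A(1−p_A) · p_B(1−p_B))

computed for every same-chromosome pair within 1 Mb and averaged in
distance windows (20, 50, 100, 200, 500, 1000 kb), plus an OLS decay
regression r² ~ distance.

**Sved's equation for Ne.** At drift–recombination equilibrium,
E(r²) = 1/(4·Ne·c + 1) for genetic distance c Morgans, inverting to
Ne = (1/4c)(1/r² − 1), interpreted as the effective size t = 1/(2c)
generations ago. Physical distance converts to c through a per-chromosome
linkage map (cM/Mb), or a preset window→cM table. A single Ne can also be
fitted to the whole decay curve by non-linear least squares, optionally
correcting observed r² for the 1/(2n) finite-sample inflation.

**Diversity.** 1 − IBS distances (pairwise-complete) and classical
four-dimensional MDS by eigendecomposition of the double-centred squared
distance matrix.

Marker QC precedes everything: drop call rate < 0.90, Hardy-Weinberg
exact-test p < 1e-4 (conditional exact test, no mid-p), MAF < 0.01, and
non-autosomal markers (sex chromosomes and unassigned linkage groups,
counted separately), with a removal ledger per filter.

## Worked example

```python
from chickld import (SimConfig, diverge_lines, apply_qc, split_by_line,
                     pairwise_ld_scan, bin_ld_by_distance, ne_trajectory,
                     GeneticMap)

cfg = SimConfig(true_ne=250, n_generations=80, n_chromosomes=3,
                chrom_length_bp=2_000_000, n_snps_per_chrom=150, seed=1)
panel, truth = diverge_lines(cfg, n_lines=2, divergence_generations=40,
                             line_sizes=[23, 6], line_ne=[250, 40])
clean, report = apply_qc(panel)
for line, part in split_by_line(clean).items():
    pairs = pairwise_ld_scan(part, max_dist_bp=1_000_000)
    bins = bin_ld_by_distance(pairs)
    print(line, part.n_samples, round(bins.table.iloc[0]["mean_r2"], 2))
```

On the full 14-line reference panel (`analysis/01_simulate_panel.py`,
seed 1: 189 samples × 450 SNPs), the drivers print:

```
QC: 450 -> 376 SNPs; removed {'call_rate': 12, 'hwe': 12, 'maf': 50} (planted (12, 8, 10))
mean r² at ≤20 kb: min 0.18 (L03), max 0.68 (L11)
decay slopes (r² per Mb): -0.412 .. -0.097
median |relative error| of per-line NLS Ne: 0.19
```

Reading: the cleaning cascade recovers every planted defect (the extra
HWE and MAF removals are genuine Wahlund-effect failures created by
pooling diverged lines); large commercial-style lines (Ne 250, n=23)
show low short-range LD while the small conserved lines (Ne 40, n=6)
show high LD; and the per-line NLS Ne estimates land within ~20% of the
simulated truth in the median. The MDS driver separates all 14 lines on
the leading axes.

## Analysis drivers

Numbered scripts under `analysis/` run the study on the reference
simulated panel, each writing tables under `results/`:

1. `01_simulate_panel.py` — 14-line Wright–Fisher panel + planted QC defects
2. `02_qc_filtering.py` — cleaning cascade, chromosome-class counts
3. `03_ld_decay.py` — per-line r² windows, decay regression, LD-profile correlations
4. `04_ne_trajectory.py` — per-line Ne trajectories and NLS fits vs truth
5. `05_diversity_mds.py` — 1−IBS MDS coordinates and scatter

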