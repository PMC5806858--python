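# Methods

## Scope and data model

`chickld` analyses diploid biallelic SNP panels stored as PLINK 1 binary
trios (.bed/.bim/.fam). Calls count copies of .bim allele1 (A1, minor by
PLINK convention); all downstream statistics — MAF, Hardy-Weinberg p, r²
— are invariant under allele relabelling, so the orientation convention
is cosmetic (asserted in tests). Variants are re-sorted by (chromosome,
bp) on load, numeric chromosome labels sorting numerically before
alphabetic ones; ties on bp keep file order. The autosome whitelist
(default "1".."28", the chicken karyotype) is configuration, not
hard-coded.

## Marker QC

Filters: call rate < 0.90, Hardy-Weinberg exact p < 1e-4, MAF < 0.01,
applied with *strict* inequalities so a marker sitting exactly on a
threshold is retained. The Hardy-Weinberg test is the conditional exact
test given allele counts (probabilities of heterozygote counts with the
rare-allele parity, log-space gammaln evaluation, no mid-p); the package
verifies it against an exact-rational enumeration for n ≤ 200. Filters
default to sequential application in the order call rate → HWE → MAF
(each counting removals among the survivors of the previous step), with
an independent mode that evaluates all filters on the input set and
removes the union; overlapping counts are reconciled in the report by an
explicit correction entry so the ledger always balances. QC is applied
to the combined multi-line panel by default, which means pooled Wahlund
heterozygote deficits can legitimately fail HWE — running QC per line is
possible by applying it to each `split_by_line` part. Non-autosomal
markers (Z/W/X/Y/MT = sex chromosomes; any other non-numeric label = an
unassigned linkage group) are excluded after the statistical filters and
counted separately. The avian macro/intermediate/micro chromosome split
defaults to 1–5 / 6–10 / 11–28 and is configurable, since size-class
conventions vary.

## LD estimation

Two-locus haplotype frequencies are maximum-likelihood estimates from
unphased genotypes via EM. Every genotype class except the double
heterozygote contributes determinate haplotype counts; double
heterozygotes are split between coupling and repulsion in ratio
p₁₁p₂₂ : p₁₂p₂₁ at the current iterate. Initialisation is the
linkage-equilibrium product of observed allele frequencies; convergence
when the largest frequency change < 1e-8, cap 1000 iterations (the last
iterate is returned flagged if the cap is hit). Tables with no double
heterozygotes are closed-form (0 iterations). The all-double-heterozygote
table keeps the equilibrium stationary point (r² = 0) by a 50:50 split
when both phase products vanish. The EM log-likelihood is non-decreasing
by construction and is property-tested against a 101³ simplex grid
search. A composite (genotype-dosage correlation) r² is available for
sensitivity checks but is never the default.

The genome scan pairs markers on the same chromosome within 1 Mb
(distances from 1-based bp positions; chromosome boundaries never
crossed), builds all 3×3 genotype-pair tables by indicator-matrix
products over pairwise-complete samples, and runs the EM vectorised over
pairs in blocks. Pairs with either locus monomorphic on the
pairwise-complete subset are emitted with undefined r² and excluded from
aggregation — skipped and counted, never imputed.

Window means default to cumulative windows (all pairs with distance ≤ W
for W in 20..1000 kb) because a decay table's "window size" reads most
naturally as an upper bound; a disjoint mode ((W_prev, W] bins) is
provided, and the two coincide on the first window. The "Average" column
is the unweighted mean of per-window means. The decay model is ordinary
least squares of r² on bp distance. Between-line LD-profile correlation
is the Pearson correlation of two lines' binned mean-r² profiles on a
shared grid (default disjoint 50-kb bins to 1 Mb) — one reasonable
reading of "LD correlation between populations", which is not a uniquely
defined quantity in the field.

## Ne from LD

Sved's drift–recombination equilibrium E(r²) = 1/(4Nec+1) is inverted
per window, Ne = (1/4c)(1/r²−1), dated t = 1/(2c) generations ago (raw t
always reported alongside the rounded integer). Genetic distance comes
from a per-chromosome map as dist_bp · (map_cM / physical_bp)/100, or
from a preset window→cM table ({20 kb: 0.01 cM, 50: 0.03, 100: 0.07,
200: 0.15, 600: 0.4, 800: 0.7, 1000: 0.9}) shipped for replication-style
trajectory tables; an explicit map takes precedence, and windows with no
mapped distance are omitted rather than guessed (note the preset has a
600-kb entry where the binner's default grid has 500 — a deliberate
mismatch inherited from common usage; the trajectory simply skips the
unmapped window).

The single-parameter NLS fit minimises Σ(r²_obs − 1/(4Nec+1) − 1/(2n))²
over Ne ≥ 0 by bounded scalar minimisation on log Ne (the profile is
unimodal in practice; verified against a golden-section oracle). The
1/(2n) sampling-inflation correction is **off** by default — uncorrected
trajectories match the classical usage of the equation — and **on** in
all parameter-recovery validation, where it is known to matter at n ≤ 50.

When fitting Ne to simulated panels, pairs are restricted to
c ≥ 1/n_generations (epochs t ≤ n_generations/2): LD at distance c
equilibrates with time constant ≈ 1/(2c + 1/(2Ne)), so shorter-range
pairs still carry the founder generation's linkage equilibrium and would
bias Ne upward. Even so, recovered medians run a little above truth at
larger Ne (≈ +10–20% at Ne 200) because Sved's hyperbola is itself an
approximation to the Wright–Fisher equilibrium σ²_d; the validation
band (median within 30% of truth) absorbs this known model error.

## Diversity

1 − IBS distance: per-locus shared-allele fraction (1, 0.5, 0 for
identical, one-step, opposite genotypes), averaged over
pairwise-complete loci (missingness handled per pair, no imputation).
Classical MDS: eigendecomposition of −½·J·D²·J; coordinates are top-k
eigenvectors scaled by √eigenvalue; negative eigenvalues (non-Euclidean
residual of the IBS distance) are truncated to zero and their count
reported. Coordinates are defined up to rotation/reflection, so tests
compare embedded distance matrices, never raw axes.

## The synthetic-data generator

Forward-in-time Wright–Fisher, chosen over a coalescent because true Ne
is then an explicit knob equal to the quantity the pipeline estimates.
Discrete non-overlapping generations; each offspring draws two parents
uniformly with replacement; gametes recombine with Poisson(map length)
crossovers at uniform positions. Parent choices are drawn once per
generation and shared across chromosomes (a real pedigree), while
recombination uses fixed-order per-chromosome substreams, so panels are
bit-reproducible and adding chromosomes does not perturb earlier ones.
No mutation: markers are founder standing variation with frequencies ~
Uniform(0.05, 0.5), an array-ascertainment-like spectrum; sites may fix
during the run and are retained for QC to remove, as on a real array.

Reference conditions: 100 diploids, 200 generations, 5 chromosomes of
10 Mb at 3 cM/Mb (the chicken genome-wide average recombination rate),
200 SNPs per chromosome, 50 sampled diploids. Multi-line panels drift
each line independently from a common base; the reference 14-line panel
uses line sizes 6–23 (six small conserved lines at Ne 40–60, eight
larger lines at Ne 80–250), emulating the institute-plus-commercial
structure of real conservation panels.

What the generator does **not** emulate: mutation, selection, migration
or admixture between lines after divergence, overlapping generations,
variable recombination along chromosomes (micro vs macro chromosome
rates), genotyping error, and array ascertainment beyond the founder
frequency window. Passing tests therefore demonstrate correctness of the
estimators under the idealised model the Sved equation assumes, not
robustness to those real-data complications.

## Validation problem sizes

The acceptance checks run: QC-defect accounting on a 60-sample × ~460-SNP
panel with 9/13/7 planted defects plus 15 sex-chromosome and 9
linkage-group markers; the two-line LD contrast (Ne 300 base, lines Ne
300/n=23 vs Ne 50/n=6, 3×2 Mb chromosomes at 10-kb marker spacing);
Ne recovery at true Ne ∈ {50, 100, 200} with 20 replicates (tests) or 8
(acceptance script) under the reference conditions; sample-size
inflation with 6-vs-23 subsamples over 10 (tests) or 6 (script)
replicates; and MDS separation of two lines diverged 60 generations.

## Known limitations

* Ne point estimates at a window mix epochs; no deconvolution of
  time-varying Ne beyond the per-window interpretation, and no
  confidence intervals (no jackknife).
* The EM r² assumes random mating within the analysed group; within-line
  use is appropriate, pooled-panel r² is not a pipeline output.
* Exact HWE p-values are float (≈1e-13 relative accuracy), adequate for
  thresholding at 1e-4.
* `fit_ne_nls` fits a single constant Ne; it is a summary, not a
  demographic reconstruction.
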