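# Methods

## Data model and quality control

Genotypes are unordered diploid allele pairs at L microsatellite loci,
with allele labels treated as opaque positive integers (no stepwise/size
model anywhere in the package; all distances and diversity measures are
allele-identity based). Missing calls are a single sentinel (0 in GenAlEx
files, −9 in STRUCTURE files, −1 in memory). A genotype with exactly one
scored allele cannot be scored for heterozygosity, so it is normalised to
fully missing on construction — a conservative QC choice, made once and
applied uniformly.

Individuals carry a two-level spatial hierarchy (plot nested within block)
plus a timepoint tag. Nesting is validated on construction; plot labels are
qualified by their block internally so reused bare plot names cannot merge
across blocks.

Per-individual missing-data filtering is strict: an individual is removed
when its untyped fraction *exceeds* the threshold (default 0.5), so a
sample exactly at 50 % missing is retained.

## Heterozygosity indices

Five per-individual indices are computed against a frequency reference
(per-locus allele frequencies plus per-locus population H_O and H_E):

* PHt = heterozygous / typed loci.
* Hs_obs = PHt / mean(reference H_O over the individual's typed loci);
  Hs_exp analogously with H_E. This is the GENHET-style standardization:
  an individual's heterozygosity relative to what its typed loci would
  show in the reference population.
* IR = (2H − Σf)/(2N − Σf), with N typed loci, H homozygous loci, and Σf
  summed over **all 2N carried allele copies** (not only homozygous loci).
  Summing over all copies is what makes IR negative for heterozygotes
  carrying rare alleles, the behaviour the index was designed for; it also
  yields the strict monotonicity under het→hom substitution that the
  property tests assert. A carried allele unseen in the reference
  contributes frequency 0. The degenerate 0/0 case (every carried allele
  fixed and fully homozygous) returns 1.
* HL = Σ E(hom loci) / (Σ E(hom) + Σ E(het)), E being the reference H_E
  of each typed locus; undefined when all typed loci have E = 0.

For progeny analyses the reference defaults to the **maternal plants
only**: seed genotypes are non-independent draws from the mothers, and
including them would bias the frequencies toward the maternal alleles. A
pooled mothers+seeds reference is available behind a flag.

## Progeny-array inference

QC removes a seed if, at any locus typed in both mother and seed, the seed
carries no maternal allele (Mendelian-impossible; attributed to genotyping
error), and separately flags seeds with no co-typed locus at all
(genotyping failure). The two removal reasons are reported separately.

The non-maternal allele count uses a minimal-assignment rule per locus:
one seed copy matching a maternal allele is set aside as the maternal
contribution (choosing the assignment that minimizes the count), and
remaining copies absent from the maternal genotype are counted. This
undercounts rather than overcounts paternal alleles. Categories:
0 (maternal only), 1 (single — cross with a close relative, or error),
≥2 (multi — likely outcrossed).

The pure-selfing null simulates, per replicate, a full selfed-seed dataset
whose per-mother seed counts match the observed post-QC counts (so the
null mirrors the analysed dataset's structure; a uniform count option
reproduces a fixed-design experiment), computes the dataset-mean of each
index with the frequency reference held fixed, and bands each index by its
central 95 % empirical quantiles. The band is two-sided; the direction of
any exceedance is reported, so a one-sided reading remains possible.
Outcrossing is indicated by PHt/Hs above the band and IR/HL below it.

The null simulator is vectorised across replicates (one gamete-pick array
per run) and is equal in law — and, given the same generator state, equal
in value — to repeated single-dataset simulation followed by per-individual
scoring; a test asserts that equivalence replicate by replicate.

### Calibration and its limits

When the observed dataset is itself generated under pure selfing, the
banded IR test rejects at the nominal 5 % rate, provided the mothers carry
enough heterozygous loci for the null to be effectively continuous (the
acceptance suite measures the type-I error at 500 experiments × 1000-
replicate nulls). In the fully inbred default regime (equilibrium F = 0.8)
mothers are nearly fully homozygous, the IR null concentrates on a few
atoms, and the quantile test becomes **conservative** — it rejects less
often than nominal, never more. A separate test asserts that conservatism.
Practically: with near-homozygous mothers the test loses power but does
not produce spurious outcrossing signals.

## Diversity statistics

* A: mean distinct alleles per locus; a locus with no typed data in a
  group contributes 0 (matching the convention of the spreadsheet tooling
  this report format mirrors). For H_O/H_E/F such loci are instead
  excluded from the group mean; both conventions are deliberate and noted
  in the output schema.
* H_E is the uncorrected Nei gene diversity 1 − Σp² by default; the
  unbiased 2N/(2N−1) variant is behind a flag.
* F is reported two ways — the mean of per-locus (H_E − H_O)/H_E over loci
  with H_E > 0, and F recomputed from the group's mean H_O and H_E —
  because tools differ in which they print; the two can disagree by a few
  hundredths on real data.
* Rarefied allelic richness uses the hypergeometric estimator
  A_R = Σ_i [1 − C(N−N_i, g)/C(N, g)] over alleles with N_i of N typed
  copies, at standard gene count g. The default g is the smallest
  per-group, per-locus typed copy count in the dataset, so every cell is
  computable; a fixed number of individuals (g = 2n) can be supplied.
  Cells with fewer than g typed copies are flagged NaN and excluded from
  group means. The estimator equals the exhaustive-subsample mean (tested
  by enumeration) and is monotone in g.

## Hierarchical AMOVA

Units are allele copies (two per individual). The distance between two
copies is the count, over loci typed in both individuals, of allele-identity
mismatches (pair deletion for missing data). Sums of squares follow the
distance identity SS(cluster) = Σ_{i<j} d²/n with n the cluster's full
copy count; the four-level decomposition is obtained by differencing
within-total, within-block, within-plot and within-individual SS. Degrees
of freedom come from the design (B−1, P−B, N−P, N), not from typed loci.

Variance components are solved top-down from expected mean squares with
unequal-sample-size coefficients computed from the actual design matrix
(the individual-level coefficient is exactly 2 because every individual
contributes two copies). F-statistics: F_RT = σ²_a/σ²_tot,
F_SR = σ²_b/(σ²_b+σ²_c+σ²_d), F_ST = (σ²_a+σ²_b)/σ²_tot,
F_IS = σ²_c/(σ²_c+σ²_d), F_IT = (σ²_a+σ²_b+σ²_c)/σ²_tot.

Negative variance components are reported raw and retained in F-statistic
arithmetic; an optional flag clamps them to zero for the percent column
(the convention of some desktop tools). Percent variation always sums to
100 within rounding.

With the within-individual level switched off, the among-individual and
within-individual components are pooled into a single "within plots" level
(components and SS summed, df merged); the upper levels are unchanged.
This is a presentation collapse of the four-level fit, not an independent
three-level estimator — the two would differ whenever within-plot variance
is nonzero.

Permutation tests shuffle units at the stratum appropriate to each
statistic: whole plots among blocks (F_RT), individuals among plots within
blocks (F_SR), individuals among all plots (F_ST), and allele copies among
individuals — within plots for F_IS, globally for F_IT — per locus.
Exchanging the two copies *within* an individual is a no-op for an
unordered genotype, so the F_IS null is generated by exchanging copies
between plot-mates, the standard random-union-of-gametes null.
p = (1 + #{perm ≥ obs})/(n_perm + 1).

## Cluster-membership summaries

The predominant cluster of a plot is the modal argmax cluster of its
individuals (the two-step rule: assign each individual to its largest
membership, then take the most common assignment); ties are broken by
higher mean membership, then lower cluster index. Reported per plot: % of
individuals whose argmax is the predominant cluster, and the unweighted
mean membership in it (average admixture proportion). Pre/post deltas
assume both matrices come from one joint clustering run, so no
cluster-matching is applied by default; a greedy column-correlation
matcher is available for separate runs. Both summaries are invariant to
consistent cluster relabelling. Note the mean admixture proportion of the
predominant cluster has no useful lower bound when K > 2; only [0, 1] is
guaranteed.

## Synthetic-data generator

Ancestral allele frequencies per locus are symmetric Dirichlet(0.2) draws
over 6 alleles — sparse, giving one or two common alleles plus rares, the
typical microsatellite profile in a strong selfer. Block frequencies are
Balding–Nichols daughters of the ancestral vector at θ_block = 0.22, and
plot frequencies daughters of their block at θ_plot = 0.42. Genotypes are
drawn either at selfing equilibrium — with probability F = s/(2−s) the two
copies are identical by descent, one plot-frequency draw duplicated — or
by iterating discrete generations of partial selfing within plots from
HWE founders. Defaults (3 blocks of 8/4/8 plots, 9 individuals per plot,
11 loci, s = 8/9 so F = 0.8, 2 % missingness, 5 % null-allele frequency,
1 % genotyping error) reproduce the target regime of the motivating
system: block-level H_E ≈ 0.31, H_O ≈ 0.04, F̂ ≈ 0.8, A ≈ 2.7, and a
variance partition of roughly 24 % among blocks / 30 % among plots / 10 %
within individuals. θ_plot and the Dirichlet concentration were set by
matching those targets; all other defaults are the design quantities
themselves.

Observed genotypes are corrupted in a fixed order — null-allele masking
(a heterozygote carrying one null appears homozygous for the visible
allele; a double null is missing), then single-copy genotyping error
(replacement by a uniform random allele), then missingness — because the
order affects H_O. Latent truth (pre-corruption genotypes, all frequency
vectors, per-seed selfing flags and father identities) is retained for
parameter-recovery tests.

Progeny arrays draw mothers from the population's true genotypes; each
seed is selfed with probability 1−t or sired by a uniform random plot-mate
with probability t. Seeds are corrupted with the genotyping-error and
missingness settings (null alleles are not re-applied to seeds, so
mother/seed comparisons are not confounded by differential nulls unless
requested explicitly).

The generator emulates the statistical structure the analyses assume —
hierarchical drift, partial selfing, progeny arrays, simple corruption —
and not demographic realism: no spatial dispersal kernels, seed-bank age
structure, mutation, or linkage. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every failure mode of real microsatellite data (allele binning artefacts,
locus-specific null-allele rates, scoring drift between plates).

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
populations of 180–500 individuals, 11–20 loci, 1000-replicate Monte-Carlo
nulls, 500-experiment calibration runs, permutation tests at a few hundred
permutations, and brute-force oracle comparisons at ≤ 30 individuals —
sizes at which the exhaustive oracles are exact and the stochastic
assertions have known binomial/MC error, with tolerances set from those
errors (±2 MC s.e., 3σ binomial bands, ±0.05 on equilibrium-F recovery).
Rarefaction uses exact binomial coefficients; AMOVA SS use exact counting
identities rather than O(n²) distance loops; empirical quantile bands use
linear interpolation (numpy default). All stochastic outputs are bit-exact
reproducible given a generator seed, which is recorded in report metadata.
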