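# Methods

This note documents the statistical models behind `germdiv`, the
conventions chosen where several are in circulation, what the synthetic
data do and do not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## Census diversity

For a site census with landrace shares `p_i` the package reports
richness `S`, the Gini–Simpson complement `1 − Σ p_i²`, Shannon entropy
`H = −Σ p_i ln p_i` (natural log), and Pielou evenness `J = H / ln S`.
Two conventions are fixed deliberately: "Simpson index" always means
the *complement* (the probability that two random individuals differ),
because that is the form consistent with dominance-heavy censuses
producing values like 0.6–0.8; and `J` is defined as 1 when `S = 1`,
where both `H` and `ln S` vanish. Zero-count entries are dropped before
normalising. Shares that arrive as percentages are treated as counts —
the indices are scale-invariant, so this is exact.

## Randomized-block quantitative genetics

The trial model is the textbook RBD: `y_gb = μ + G_g + B_b + e_gb` with
genotypes and blocks complete and crossed. Sums of squares come from the
standard closed forms; the package refuses incomplete designs rather
than imputing. Variance components follow the expected mean squares:
`σ̂²_e = MS_e`, `σ̂²_g = (MS_g − MS_e)/r` with a negative estimate
truncated to zero and flagged (`σ²_p = σ²_g + σ²_e`). From these:

* `GCV = 100·σ_g/μ`, `PCV = 100·σ_p/μ` (so `GCV ≤ PCV` always),
* broad-sense heritability `h² = 100·σ²_g/σ²_p`,
* genetic advance `GA = k·(h²/100)·σ_p` with selection intensity
  `k = 2.06` (5% selected) by default, configurable, and
  `GAM = 100·GA/μ`.

Genotypic and phenotypic correlations use the analogous mean
cross-product decomposition per trait pair: `cov_g = (MP_g − MP_e)/r`,
`cov_p = cov_g + MP_e`. A pair involving a trait with `σ̂²_g = 0` has an
undefined genotypic correlation and is reported as missing (NaN), never
as zero. Component-based correlation estimates can exceed |1|; they are
clamped with a flag rather than rejected. Significance stars use the
two-sided t approximation with `n_genotypes − 2` degrees of freedom —
an approximation, since the genotypic correlation's exact sampling
distribution is awkward; the stars are descriptive, as in the tables
this layout mirrors.

Path analysis solves `R·p = r` for the standardized direct effects,
reports `indirect(i via j) = r_ij·p_j`, and the residual
`√(1 − Σ p_i r_i)`. The decomposition identity
`p_i + Σ_{j≠i} r_ij p_j = r_iy` then holds to rounding. A
condition-number guard (default 1e8) rejects near-singular `R` and names
the most collinear predictor pair.

Trait clustering standardizes genotype means to zero mean / unit
variance per trait (constant traits are dropped with a warning), uses
Ward linkage on Euclidean distance, and reports cluster means on the
original scale; the dendrogram exports to Newick. Ward was chosen
because it produces the compact, interpretable clusters germplasm
reports tabulate; the cluster count for a report defaults to the
caller's choice, with 4 used in the worked examples. PCA operates on
the trait correlation matrix (so eigenvalues sum to the number of
traits); each component's sign is fixed so its largest-magnitude
loading is positive, making outputs reproducible across BLAS builds.

## SSR population genetics

Allele frequencies are gene-copy counts: each scored diploid individual
contributes two copies and missing calls leave the denominator. A call
is missing only as a whole pair; half-missing input is an error by
design (silently repairing gel data hides scoring problems). Per-locus
summaries use the uncorrected gene diversity `He = 1 − Σ p²` rather
than the `2n/(2n−1)` unbiased version, so the identity `He = 1 − 1/NE`
with `NE = 1/Σ p²` holds exactly — the convention of the summary tables
this package reproduces. PIC is Botstein's codominant form
`1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`, which satisfies `PIC ≤ He` always.

Nei's (1972) standard distance aggregates over loci by arithmetic means
of the three sums: `I = J̄_xy / √(J̄_x J̄_y)`, `D = −ln I`. Identity
zero (disjoint allele sets) would give infinite distance; it is capped
at a configurable ceiling (default 10) and flagged. UPGMA trees are
built on sorted labels for deterministic tie-breaking; node height is
half the merge distance, making the output ultrametric and exact on
ultrametric input. Neighbor-joining is available as an alternative for
an unrooted-style tree. PCoA is classical metric scaling (double-center
`−D²/2`, eigendecompose); negative eigenvalues of non-Euclidean inputs
are reported but excluded from the percent-variance denominator.

### AMOVA

The three-level AMOVA (among populations / among individuals within
populations / within individuals) operates on gene copies. Distances
between two copies count the loci at which they carry different
alleles, skipping loci missing in either individual — summation over
loci is what makes the result the multi-locus average the Φ statistics
assume. Sums of squares within any group of `m` copies are
`Σ_{i<j} d_ij / m`. Degrees of freedom are `P − 1`, `N − P`, `N`.
Components solve the expected mean squares with the unbalanced-design
coefficient `n_c = (M − Σ m_p²/M)/(P − 1)` in copy units; negatives are
truncated to zero and flagged. `Φ_ST = σ²_AP/σ²_tot`,
`Φ_IS = σ²_AI/(σ²_AI + σ²_WI)`, `Φ_IT = (σ²_AP + σ²_AI)/σ²_tot`.

Permutation tests shuffle individuals among populations (Φ_ST) and gene
copies among individuals within populations (Φ_IS), with
`p = (hits + 1)/(n + 1)`. The permutation *statistic* uses the
untruncated components: truncation piles both observed and permuted
values onto Φ = 0 under weak structure, and the resulting ties destroy
the uniformity of null p-values. With the untruncated statistic the
null distribution of p is uniform (verified by a KS test in the
acceptance suite).

### F_ST

Pairwise F_ST is Weir & Cockerham's θ, accumulated as a ratio of sums
of the a / (a+b+c) components over all alleles and loci shared by the
pair. Small negative estimates are reported as computed — they mean "no
detectable differentiation", and truncating them would bias averages
upward. A labelling utility maps θ to the conventional qualitative
bands (little < 0.05 ≤ moderate < 0.15 ≤ great < 0.25 ≤ very great).

## Structure inference

`admixture_em` maximizes the admixture likelihood
`Π_i Π_l Π_copies Σ_k q_ik p_kl(a)` by EM: the E-step computes the
posterior cluster responsibility of each gene copy, the M-step
re-estimates `Q` and the cluster allele frequencies. This deliberately
replaces a STRUCTURE-style MCMC sampler — the likelihood is the same,
the output is a maximum-likelihood point estimate rather than a
posterior. The trace is asserted non-decreasing every iteration;
restarts (default 5) with seeds spawned from one master seed keep the
best likelihood; convergence is a log-likelihood gain below `tol`
(default 1e-6), and non-convergence within `max_iter` is flagged, not
raised. Individuals are classified to a cluster when their ancestry
reaches a threshold (default 0.8, the common convention) and "admixed"
otherwise.

Identifiability caveat: a panel consisting *only* of identically
admixed individuals does not anchor the cluster frequencies (the
likelihood is flat along a family of reparameterizations), so recovery
tests plant pure individuals from each source population alongside the
admixed ones. Cluster labels are arbitrary; tests compare under the
best label permutation.

`evanno_delta_k` computes, per K, the replicate mean and SD of the
log-likelihood, `L'(K) = L̄(K) − L̄(K−1)`, the absolute second
difference `|L(K+1) − 2L(K) + L(K−1)|` evaluated per replicate and then
averaged, and `ΔK = mean|L''| / sd(L(K))`. Replicates are paired by
rank of replicate id within each K and must be equally many. ΔK is
undefined at the endpoints of the K range and is invariant to adding a
constant to all log-likelihoods.

## Synthetic data

Generators are pure functions of their spec (seed included).

* **Phenotypes** — `y = μ_t + G_gt + B_bt + e_gbt` with genetic effects
  multivariate normal across traits under the requested correlation
  matrix, block variance fixed at 10% of the error variance unless
  overridden (field block effects are usually modest and rarely
  reported), and i.i.d. normal error. Default problem sizes in tests
  mirror a characterisation trial: ~50 genotypes × 3 blocks.
* **Markers** — per locus an ancestral frequency vector is drawn
  Dirichlet-uniform over 3–8 alleles; population frequencies follow the
  Balding–Nichols construction `Dirichlet(p·(1−F)/F)` at the requested
  divergence `F`, chosen because it provides a single interpretable
  F_ST knob. Each individual samples two copies from its (possibly
  admixed) mixture frequencies; with probability `selfing_rate` the
  second copy duplicates the first, which generates exactly the excess
  homozygosity that clonal propagation produces in real SSR panels
  (test regimes use selfing_rate ≈ 0.6, reproducing the observed-vs-
  expected heterozygosity gap of ~0.24 vs ~0.69). Loci are independent,
  as every implemented statistic assumes; linkage, mutation models, and
  null alleles are *not* emulated, so passing tests say nothing about
  those complications in real data.
* **Censuses** — shares Dirichlet(dominance), counts multinomial; a
  small concentration yields the one-dominant-landrace pattern.
* **Log-likelihood tables** — mean curve piecewise linear with a steep
  gain (60/K) up to the true K and a shallow gain (2/K) beyond, plus
  Gaussian replicate noise (SD 2 by default). The kink is the unique
  curvature maximum, so ΔK recovers the true K by construction; these
  tables emulate the *shape* of replicate runs, not any sampler.

## Problem sizes and tolerances

The test and acceptance suites run on one CPU with deliberately chosen
scales: 200 replicate trials of 100 genotypes for variance-component
recovery (bias bounded by 3 Monte-Carlo SEs), 2×50 individuals × 30
loci for F_ST recovery (±0.08 covers sampling error at that size), 200
null datasets × 99 permutations for p-value uniformity (KS at α=0.01),
and 40 individuals × 30 loci at F_ST 0.5 for ancestry recovery (mean
absolute error < 0.1). Floating-point identities (PCoA reconstruction,
path decomposition, ultrametricity) are asserted at 1e-8–1e-10.

## Known limitations

Strictly diploid: triploid or mixed-ploidy material must be excluded or
down-coded before import. No REML/mixed models, no G×E, no rarefaction
or Hill profiles, no LD, no null-allele correction, no bootstrap
support on trees. The EM admixture fit gives no credible intervals. The
published summary tables shipped in `reference_tables` are printed
two-decimal values — internal-consistency checks against them inherit
that rounding.
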