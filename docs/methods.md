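# Methods

## Data model and scope

The package analyses hybrid trials of the following shape: two pools of
fully inbred parents (females/maintainers, males/restorers), an incomplete
but connected factorial of crosses, one adjusted phenotype per hybrid per
environment, and biallelic SNP genotypes of the parents only (hybrids are
deduced).  Parents are assumed homozygous at every locus; heterozygous or
missing parental calls are hard errors, because imputation and phasing are
upstream concerns.  Coordinates are 1-based inclusive internally; BED input
is converted on read.

## Marker processing

*Polymorphism filter.*  A locus is kept iff it segregates in at least one
parental pool ("discard loci monomorphic in both"); the stricter
both-pools rule is available via `mode="both"`.  The defensible readings of
the filter differ only for loci segregating in a single pool, which still
carry female- or male-side information, hence the default.

*Redundancy collapse.*  Loci whose pooled 0/1 columns are identical or
exact complements (|r| = 1 across all parents) form one group; the referent
is the smallest (chromosome, position), ties broken by id.  Collapse is
idempotent and the grouping is an equivalence relation.

*Pathway subsets.*  A locus belongs to a gene set iff its position lies
within `window` bases (default 1 000) of any annotated gene interval.

## Kernels

Transmitted-allele matrices are centered per locus within each pool, so
each parental kernel measures within-pool relatedness.  Kernels default to
a 1/L scale (L = locus count) so variance components are comparable across
SNP subsets of different sizes; all predictions are provably invariant to
the scale choice (tested to 1e-6), so plain cross-product components are
recovered with `scale=1`.

The interaction (SCA) kernel over hybrid combinations is the Gram matrix of
the row-wise Khatri–Rao product of the parental matrices, computed
entrywise as K_fm[(f,m),(f′,m′)] = K_f[f,f′]·K_m[m,m′].  This is the
standard specific-combining-ability kernel; the exact factorization is the
property the tests verify against an explicit L²-column oracle.  Its entity
set is the union of design crosses, not the full grid, to bound memory.
Epistasis kernels are element-wise squares (Schur products, hence PSD).
VanRaden's relationship matrix (method 1, inbred 0/1 coding:
MM′/Σp(1−p)) is provided for ordering parents in design displays only.

## Phenotype adjustment

Raw plots are reduced to one value per hybrid and environment by
oil = μ + row + column + repetition + status + g + e, with row/column/
repetition as unordered fixed factors (sum-to-zero coding), status a fixed
check-vs-hybrid contrast, and g an independent random genotype effect
estimated by REML (the same engine, identity kernel).  The adjusted
phenotype is μ̂ + status(hybrid) + BLUP(g).  This is an explicit
approximation of dedicated spatial models: no autoregressive or spline
correlation, factors not smooths.  Factor levels observed on a single plot
are aliased with that plot's genotype and dropped with a warning; any
remaining linear dependencies among fixed columns (e.g. repetition blocks
spanned by row indicators) are pruned by rank checks.

Two statistical caveats are intentional.  With a single replicate and no
replicated checks the genotype/residual split is unidentifiable (their
observation-level covariances coincide), and the BLUP in the adjusted value
shrinks all genotype contrasts by λ = σ²_g/(σ²_g + σ²_e/r).  Parameter-
recovery tests therefore run on the generator's hybrid-level phenotypes
(drawn exactly from the prediction model); the adjustment is validated by
its own oracles — closed-form shrinkage with two replicates, and
lower error than raw plot means under planted field gradients.

## REML engine

The engine maximizes the restricted likelihood of
y = Xβ + Σ_k Z_k u_k + ε, u_k ~ N(0, σ²_k K_k), profiling the fixed
effects (intercept only in the hybrid models).  Implementation:
average-information updates with an EM-like damped first step, step-halving
line search, and a gradient fallback; all solves via dense Cholesky (n ≤
~500 per environment).  Convergence requires ΔlogL < 1e-8 and relative
Δσ² < 1e-6 (maximum 200 iterations).  Components are floored at
1e-10 × var(y); estimates at the floor are reported as exactly 0 with a
boundary flag, their BLUPs zeroed, and they are excluded from the AI
matrix.  Wald z-ratios use standard errors from the inverse AI matrix at
convergence and are undefined (NaN + warning) for boundary components.

BLUPs are computed for **all** kernel levels: û_k = σ²_k K_k Z_k′ P y,
which predicts unobserved parents and crosses through their kinship
covariance with observed levels — the mechanism behind untested-parent
prediction.  Correctness is anchored to independent oracles: closed-form
balanced one-way ANOVA REML, dense likelihood grids on small toys, the
explicit σ²K_{*,obs}V⁻¹(y−μ̂) prediction formula, and the exact
GBLUP ≡ RR-BLUP equivalence (1e-8).

## Cross-validation

Two schemes, both with round-half-up test-set sizing and per-set RNG
substreams derived from (seed, set index) so earlier sets never reshuffle:

* `random_hybrids`: 10% of observed hybrids per set.
* `by_parents`: 10% of the pooled parent lines (7 of 72 at full size,
  unstratified by default; a flag enables per-pool stratification); the
  test set is every observed descendant of a sampled parent, labeled T0
  (both parents sampled) or T1.  Draws that would empty the training side
  are redrawn and logged.

All models are refit per training set (variance components included) and
scored on the same sets, so model contrasts are paired; a REML failure
skips the set for every model.  Abilities are averaged per environment and
as an unweighted MET mean; the variance over sets is reported but no
significance test is attached, because overlapping test sets are not
independent.

## Stability

Wricke's ecovalence is computed on a complete hybrids × environments matrix
of predicted performances (μ̂ + FM BLUP per environment).  Σ_i W_i equals
the interaction sum of squares of the double-centered matrix.  The default
stability threshold of 5 (squared oil %) is scale-dependent and exposed as
a parameter; the MET mean is the unweighted row mean.

## Synthetic study generator

The generator's defaults encode the study conditions: 36×36 parents, 2 000
loci on 17 chromosomes, 490 crosses with 12–15 descendants per parent,
connected and near-balanced (greedy least-used assignment), 9 environments,
~1% of cross×environment cells unobserved, oil grand mean ≈45% with
environment means varying by ±2.5 sd.

*Parents* are founder mosaics: each pool descends from a few founder
haplotypes (10 female, 6 male), every parent a Markov mosaic (switch
probability 0.02/locus) with 1% private mutations.  This produces the
within-pool relatedness of an elite breeding pool — without it, genomic
kinship has no information to transfer to untested parents and the central
untested-parent contrast would vanish.  Male founders form two diverged
subgroups (Balding–Nichols F_st 0.05), making males more structured than
females.  A configurable fraction of loci (default 5%) is duplicated or
complemented to exercise redundancy collapse; the mosaic process itself
also creates genuinely linked loci in complete LD, as real genomes do.

*Phenotypes.*  Per-locus transmitted-allele effects use a common-factor
construction, effect_e = √ρ_e·shared + √(1−ρ_e)·specific_e with
ρ_e ~ U(0.47, 0.77), so pairwise genetic correlations between environments
land in that range (≈ √(ρ_e ρ_e′)).  Effects are scaled so the *realized*
parental variances hit the per-environment targets — female σ²_f ~
U(1.2, 3.5), male σ²_f/1.5 (the ~3:2 maternal ratio), residual ~U(1.0, 2.0)
in squared oil % — and the equivalent components on the 1/L-kernel scale
(σ²·L/Σ_l var_l) are stored in the truth table, since that is what REML on
the kernel estimates.  One designated environment (the fourth by default)
carries a female×male interaction (σ²_fm = 0.7) drawn exactly from the
interaction kernel via a random L×L coefficient matrix.  Hybrid-level
phenotypes (μ + F + M (+I) + ε) are retained as truth; field plots add
row/column factor effects, randomized check plots and plot noise on top.
An optional pathway share concentrates genetic variance in pathway loci for
pathway-model contrasts.

All randomness flows from one seed through fixed substreams; outputs are
bitwise reproducible.  What the generator does **not** emulate: linkage
disequilibrium decay with genetic distance (mosaic blocks are the only LD
structure), dominance at the locus level (the interaction term is drawn at
the kernel level), selection or pedigree loops, spatially autocorrelated
field error, and multi-trait genetics.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated generative model,
not calibration to any real panel.

## Test problem sizes

The heavy suites run at the study's full design size (2 000 loci, 490
crosses): parameter recovery uses 25 studies × 8 interaction-free
environments (200 replicate environments), comparing per-study mean REML
estimates with the generative kernel-scale truth via a cluster-level 95%
Monte-Carlo interval; the directional cross-validation surface uses 10
replicate studies, each scored as a 3-environment MET average over 20
paired test sets per scheme.  The acceptance script uses 10 test sets over
3 environments.  A note on null interaction components: when the true
interaction variance is zero, its REML estimate lands exactly on the zero
boundary only about half the time (the unconstrained estimate is negative
with probability ≈ 1/2), so roughly half of interaction-free fits report a
small positive interaction variance — visible in published per-environment
tables as a mix of printed zeros and small values.

## Known limitations

Dense algebra bounds environments to a few thousand observations.  The
adjustment model is a deliberate simplification of spatial best practice.
The AI-based standard errors are asymptotic and unreliable near boundaries.
The generator's effect model is purely additive within parents; epistasis
kernels are fit but never simulated as truth.
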