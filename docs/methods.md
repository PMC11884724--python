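# Methods

## Data model

Codominant SSR genotypes are diploid pairs of allele labels (fragment
sizes in bp).  A single observed band is scored as a homozygote — the
standard convention for agarose-resolved SSRs — so every non-missing call
is a pair, canonicalized (min, max).  A call is missing as a whole: a
locus either contributes two gene copies for an individual or none, and
per-locus sample sizes N count only genotyped individuals.  The default
missing code is `0` (configurable).

Raw gel-scored sizes rarely fall exactly on allele classes, so three
binning rules are offered: `exact` (identity), `tolerance-cluster`
(single-linkage clustering of distinct sizes per locus, cutting links
larger than a bp tolerance; bin representative = rounded bin mean) and
`ladder-round` (snapping onto `offset + repeat·round((size−offset)/repeat)`).
All rounding is round-half-to-even, so binning is deterministic across
platforms.  Binning can only merge classes, never split them; tolerance 0
reduces to `exact`.

## Diversity statistics

Two frequency scopes are kept explicit because they answer different
questions: pooled-sample frequencies (all individuals as one sample) feed
the per-marker summary (MAF, Na, GD, PIC, Ho), while per-population
frequencies feed allelic patterns and F-statistics.  The slight
discrepancy between a pooled gene-diversity column and a total
heterozygosity (Ht) column in typical reports traces to exactly this
difference: Ht uses the unweighted mean of population frequencies, not
the pooled count.

PIC uses Botstein's formula (as in PowerMarker),
`PIC = 1 − Σp² − ((Σp²)² − Σp⁴)`; it satisfies `PIC ≤ GD ≤ 1 − 1/Na`
with equality only for equifrequent alleles, which the property tests
assert on random frequency vectors.  The informativeness grades are
(0.5, 1] highly, [0.25, 0.5] moderately, [0, 0.25) slightly informative —
the boundary 0.25 and 0.5 values are graded into the middle class, and
0.5 itself is *not* "highly" because the convention is strictly
"greater than 0.5".

Per-population patterns follow the GenAlEx definitions: Ne = 1/Σp²,
I = −Σp ln p (with 0·ln 0 = 0), uHe = (2N/(2N−1))·He, F = 1 − Ho/He
averaged only over loci with He > 0.  "Locally common" alleles
(freq ≥ 5%) exclude alleles found in a single population (those are
private); with five populations the "≤ 25% of populations" threshold
admits only single-population alleles, so that column is structurally
zero — matching the reference report.

## F-statistics and distances

Per locus: `Fis = (He̅ − Ho̅)/He̅`, `Fit = (Ht − Ho̅)/Ht`,
`Fst = (Ht − He̅)/Ht`, `Nm = ((1/Fst) − 1)/4`, where He̅ and Ho̅ are
unweighted arithmetic means over populations in which the locus is typed
and Ht is computed from the unweighted mean frequencies (a pooled-count
variant is available behind `total="pooled"`).  These are definitional
ratios, asserted directly in tests; the multiplicative identity
`Fit = Fis + Fst − Fis·Fst` does **not** hold for these estimators and is
not asserted.  Column means are arithmetic averages over loci, excluding
undefined cells; `Fst = 0` maps to an infinite Nm sentinel, excluded from
means.

Pairwise Fst applies the same estimator to each population pair and
averages over loci.  Because the "total" is the average of the *pair*,
a Balding–Nichols drift parameter F is recovered in expectation as
roughly `F(1−1/k)/(1−F/k)`: close to F for the five-population design,
but about `F/(2−F)` for a single pair.  The two-population recovery test
therefore checks the estimator against that analytic expectation rather
than the nominal F; the five-population recovery tests check against
nominal F with a 0.04 band that covers the small residual bias.

Pairwise gene flow applies `Nm = ((1/Fst) − 1)/4` to the pairwise Fst
matrix.  Published pairwise Nm tables are not always consistent with
their own pairwise Fst tables under this formula; this package
implements the formula and does not attempt to reverse-engineer any
other convention.

Nei distance accumulates gene identities over loci,
`D = −ln(ΣJxy / √(ΣJx·ΣJy))`; the 1978-unbiased variant replaces within-
population identities with `(2NΣp² − 1)/(2N − 1)`.  Disjoint allele sets
give an infinite sentinel.

## AMOVA

The squared genotypic distance between two diploid single-locus
genotypes is half the squared Euclidean distance between their
allele-count vectors (Smouse–Peakall), i.e. 0/1/2/3/4 for the five
possible configurations, summed over co-genotyped loci.  Sums of squares
follow the standard distance-based decomposition; the among-population
variance component uses `n0 = (N − Σn_p²/N)/(k−1)` and negative
components are truncated to zero before percentages.  The permutation
test shuffles individuals across populations and includes the observed
statistic in the count, `p = (1 + hits)/(1 + permutations)`; default 999
permutations.  A fully degenerate (all-zero distance) input reports
0% among / 100% within and p = 1.

## Ordination and clustering

PCoA Gower-centers `−d²/2` and eigendecomposes; coordinates exist only
for positive eigenvalues and axis percentages are shares of the positive
eigenvalue total (negative eigenvalues from non-Euclidean inputs are
retained in `eigenvalues` but carry no variance share).  For Euclidean
inputs the embedding reproduces the input distances to numerical
precision, which the tests use as a reconstruction oracle; an external
implementation (scikit-bio) serves as a second, independent cross-check.

UPGMA is implemented directly so that tie-breaking is fully specified
(lexicographically smallest pair of sorted leaf-label tuples), making
trees reproducible across platforms; it is validated against SciPy's
average-linkage cophenetic distances on random tie-free inputs.  Node
height is half the merge distance, so Newick root-to-leaf path lengths
equal d/2 and the tree is ultrametric by construction.

Individual-level distances for trees use the shared-allele distance
`d = 1 − shared/2` averaged over co-genotyped loci (a common default for
SSR accession trees); the squared genotypic distance used for AMOVA and
PCoA is also exposed, since reports rarely state which metric fed the
tree.

## Admixture model

The sampler targets the admixture model with correlated allele
frequencies: Z | P,Q and Q | Z (Dirichlet(α + counts)) and P | Z
(Dirichlet(prior + counts)) are conjugate Gibbs updates; the ancestral
frequencies PA move by pairwise mass-transfer Metropolis proposals; each
cluster's drift F_k by a logit random walk under a uniform(0,1) prior;
and α by a Gaussian random walk (sd 0.025) under a uniform(0,10) prior.
Initial values: α = 1, F_k = 0.01, PA at pooled empirical frequencies,
λ = 1.  Missing calls are simply absent from the likelihood.  lnP(D) is
the mean-minus-half-variance estimator over recorded sweeps.  Default
chain lengths (burn-in 30 000, 15 000 recorded sweeps) mirror the study
protocol this package emulates; a burn-in longer than the recorded phase
is unusual but honoured, with a log notice.  Validation uses shorter
chains (2 000 + 2 000), which on well-separated synthetic clusters
already give stable lnP(D) and > 90% correct assignment.

Evanno's ΔK = |L″(K)|/sd(L(K)) is computed over replicate runs per K;
it needs at least three consecutive K and two runs per K, is undefined at
boundary K and where sd = 0, and an all-linear L(K) profile yields an
inconclusive selection (None) rather than an arbitrary pick.  Label
switching across runs is resolved by greedy matching of Q columns to the
first run — adequate for the small K regimes targeted here; a full
CLUMPP-style optimisation is out of scope.

## Synthetic data generator

Populations drift from ancestral frequencies (symmetric Dirichlet(1)
per locus) under Balding–Nichols: `p_pop ~ Dirichlet(p_anc(1−F)/F)` with
F the nominal Fst — chosen precisely because it makes nominal Fst a
direct simulator input for parameter-recovery tests.  Selfing is modelled
as an instantaneous autozygosity probability Fis (draw one allele and
duplicate it, with its source cluster); this reproduces the heterozygote
deficit statistics measure without simulating generations of selfing.
The default spec emulates the study design the package was validated
against: 91 individuals in 5 populations (18/18/18/18/19 — the survey
did not print per-population sizes, so near-equal sizes are used), 13
loci with the panel's allele counts (6–15), Fst 0.19, Fis 0.79, allele
sizes on a 2-bp ladder from 100 bp.  Optional two-cluster admixture draws
each individual's ancestry from Dirichlet(α_admix) and each allele copy's
source cluster from it.

What the generator does **not** emulate: stepwise mutation dynamics,
linkage between loci, genotyping artefacts (null alleles, allele
dropout, stutter mis-binning) and unequal locus-specific drift.  Passing
recovery tests therefore shows estimator correctness under the stated
model, not robustness to those artefacts.

## Problem sizes and numerics

Validation runs use 100 replicate datasets per nominal Fst for estimator
recovery, 10 replicates per point for AMOVA monotonicity, and a
100-individual two-cluster panel with K = 1..4 × 4 runs × (2 000 + 2 000)
sweeps for admixture recovery — sizes chosen to keep Monte-Carlo error
well inside the asserted tolerances.  Dirichlet draws are floored at
1e-9 before normalisation to avoid log(0) in likelihoods; frequencies are
validated to sum to 1 within 1e-9; AMOVA's SS identity is asserted to
1e-6.  All randomness flows from explicit seeds (NumPy `default_rng`);
the pipeline splits one root seed per stage.

## Known limitations

* Fst here is the heterozygosity-ratio (Gst-type) estimator matching the
  reference software, not Weir–Cockerham θ; no jackknife CIs.
* No rarefaction correction for allelic richness with unequal N.
* No Hardy–Weinberg exact tests or linkage disequilibrium statistics.
* The admixture sampler omits LOCPRIOR, linkage and popflag features.
* XLSX input is accepted, but all outputs are plain CSV/Newick/JSON.
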