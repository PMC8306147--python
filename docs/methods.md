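# Methods

## The TGS model

A marker panel is an ordered list of M tri-genotype markers; an
individual's polygenic profile is one genotype per marker. Two scoring
conventions coexist in the package:

* **Williams–Folland (WF).** Each genotype carries G ∈ {2, 1, 0}
  (favourable / medium / neutral for the trait, assigned from literature
  evidence) and `TGS = (100/2n) Σ G_i` on a 0–100 scale.
* **Weighted signed scores.** Each genotype carries a signed real score
  (direction: endurance +, power −, mixed 0; magnitude: strength of
  association), and the raw TGS is the plain sum over markers.

Both raw scales are mapped affinely onto [−1, 1] so profiles are
comparable across panels and conventions: `t = 2(raw − min)/(max − min) − 1`.
By default the bounds are the *theoretical* per-marker extremes of the
score table (the most power-leaning and most endurance-leaning profile the
table allows); empirical cohort min/max bounds are selectable instead. The
theoretical default was chosen because it is data-independent and keeps
the endpoints meaningful (±1 = the extreme achievable profile);
under empirical bounds a new individual can fall outside the interval,
which raises unless clamping is explicitly requested.

## Committee derivation of genotype scores

Genotypes are one-hot encoded (all three indicator columns per marker are
kept — no reference level is dropped, matching the 12-dimensional encoding
of a 4-marker panel; the resulting collinearity is tolerated because the
L2 penalty makes the fit unique). Three pairwise logistic classifiers are
fitted: E(1) vs P(0), E(1) vs M(0), P(1) vs M(0). For binary indicator
features, a coefficient b alone determines the genotype's pull:
`sigmoid(b)` above/below ½ backs class 1/class 0, so each classifier casts
a vote for one trait per genotype (b = 0 abstains).

The committee rule: the trait voted by a majority (≥ 2 of 3, or a single
cast vote when the others abstain) wins. An endurance (power) winner is
scored +(−) the mean of the absolute coefficients of the supporting
classifiers. A mixed winner scores 0, because mixed is the midpoint of the
endurance(+1)/power(−1) axis. A three-way split is a tie: score 0, a
`tie` flag on the decision, and a warning — the committee has no majority
and the rule is deliberately conservative there.

An optional `mixed_mode="signed_mean"` scores a mixed-majority genotype as
the signed mean of the mixed-supporting coefficients instead of 0. This
exists because the bundled reference score table contains one entry
(*ACE* ID, −0.1470) that can only be obtained this way; the default mode
follows the stated rule. Replaying the committee rule on the bundled
printed coefficients reproduces 10 of the 12 reference scores exactly; the
two deviations (*MB* AA: rule gives 0.1025, table prints 0.1325; *ACE* ID
as above) are asserted as deviations in the test suite rather than
silently matched.

Fitting uses L2-regularized maximum likelihood (lbfgs). `penalty_strength`
is the regularization weight λ (the solver receives C = 1/λ); the default
λ = 1 with intercept fitting matches the common library default. Derived
magnitudes — and hence weighted TGS values — depend on λ, which is why it
is exposed rather than hidden. Cross-validation is stratified k-fold
(default k = 10) with a fixed shuffle seed; stratification keeps both
classes present in every fold at sports-genetics sample sizes (classes of
~40–80). The pooled confusion table defaults to the final all-data
classifier evaluated on the same data (resubstitution), which is how the
reference accuracy tables were built; a pooled held-out variant is
available (`confusion_mode="pooled_cv"`).

Weighted scores are documented as typically lying in [−1, 1] but are not
hard-validated against that range: committee magnitudes are means of
absolute logistic coefficients, which are unbounded, and strong planted
effects in simulation legitimately exceed 1. Normalization is unaffected
because bounds are recomputed from the table.

## Combination enrichment

Markers are assumed independent in the population (no linkage-
disequilibrium correction — the reference panel's markers sit on different
chromosomes, but this is an assumption, not a guarantee, for other
panels). p(M) is the product of per-marker genotype frequencies; the
binomial point probability `P_p(k|n)` (evaluated through scipy's
log-space pmf) measures how likely exactly k carriers among n random
individuals would be. The point mass is used deliberately, not a tail
probability, and no multiple-testing correction is applied across the
3^M combinations; the ranking is exploratory.

Two precision modes exist because published tables are often computed from
printed (rounded) intermediate values: the default carries count-derived
frequencies at full precision, while `freq_decimals=3` / `p_decimals=4`
round the per-marker frequencies and the product before the binomial. The
bundled reference combination table is reproduced exactly (to ±1 in the
last printed digit) only under the printed-precision chain, so
`reproduce-tables` and the acceptance checks use it; new analyses should
prefer full precision.

## Cohort statistics

Genotype (2×3) and allele (2×2) case–control tables are tested with the
Pearson χ² test of independence without continuity correction (the
variant that approaches the reference p-values; Fisher's exact test is
available behind a flag for sparse 2×2 tables). Allele counts derive from
genotype counts as allele1 = 2·hom1 + het.

TGS group comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney U)
test for independent samples. (Reference material names both a
"signed-rank" and a "rank-sum" test for these comparisons; the rank-sum
test is the statistically appropriate one for independent groups, and is
what is implemented.) Mid-ranks handle ties. `method="auto"` uses the
exact null distribution for small tie-free samples and the normal
approximation with continuity correction otherwise; both extremes are
selectable. Sidedness is two-sided throughout.

## Synthetic cohorts and experiments

The generator draws genotypes independently per marker per individual from
per-group trinomial distributions (mirroring the independence assumption
above — LD, pedigree and admixture structure are out of scope), assigns
sex deterministically by the group's sex ratio, and is fully reproducible
from one seed. Hardy–Weinberg helpers convert an allele frequency p to
(p², 2p(1−p), (1−p)²). `simulate_study_cohort` emulates the bundled
reference design exactly: (sex, group) cell sizes 27/6/17 females and
54/38/38 males across endurance/power/mixed, each cell drawing from its
own empirical genotype distribution in the bundled per-sex per-group
counts. Because cells are drawn separately, between-sex genotype–trait
differences present in the reference counts are preserved, which a single
per-group distribution could not represent.

What the simulations do *not* emulate: genotyping error, population
stratification, relatedness, and marker dependence. Tests passing on
simulated cohorts therefore validate the pipeline's statistical machinery
and bookkeeping, not the biological claims about any particular marker.

`recovery_experiment` plants a Δ shift on one genotype's frequency in one
group (other genotypes rescaled proportionally; invalid probabilities
raise) and, per seeded replicate, (1) simulates a training cohort,
(2) derives committee scores, (3) checks the planted genotype's score sign
against the planted direction, and (4) scores an *independently simulated*
evaluation cohort of the same design and runs the TGS rank-sum comparison.
The evaluation cohort is independent by design: derived scores are
optimized to separate the training groups, so testing on the training
cohort would inflate the type-I error and a Δ = 0 design would not
calibrate to α. Replicate seeds are drawn from one generator seeded by the
experiment seed, so runs are reproducible and replicates independent. A
replicate whose derived table is all-zero (every genotype mixed or tied —
possible under a null design) yields a constant TGS, carries no
information, and is counted as a non-rejection.

## Problem sizes and numerical choices

Default experiment sizes used by the test suite: recovery experiments run
100 replicates at 1000 individuals per group for planted-effect recovery
and 500 replicates at 150 per group for null calibration; the rank-sum
type-I calibration uses 2000 replicates of 25-vs-25 samples. Frequency
tables must sum to 1 within 1e-9 per marker; TGS contribution sums are
exact to 1e-12; binomial pmf agrees with exact rational arithmetic to
1e-12 for n ≤ 20. Tie-breaking in enrichment output is lexicographic on
the combination key so the ordering is total and deterministic.

## Known limitations

* Marker independence is assumed both for p(M) and in simulation.
* The committee magnitude depends on the regularization strength; scores
  derived under different λ are not directly comparable.
* Resubstitution confusion tables are optimistic by construction; use
  `pooled_cv` for honest error estimates.
* The binomial enrichment model treats the cohort as a random population
  sample of fixed size n; it does not model ascertainment.
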