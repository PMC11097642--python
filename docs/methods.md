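# Methods

This note records the statistical procedures implemented in `virosurvey`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions a user should
know before trusting or extending the results.

## The data model

A virome survey is a samples × viral-families matrix of non-negative
integer read counts together with per-sample labels (species, phylum,
habitat) and a per-family host-domain annotation
(eukaryote / prokaryote+archaea / uncertain). Counts are treated as
compositional: sequencing depth is a nuisance, and only relative
information between families is interpreted. All multivariate analysis
runs on centred log-ratio (clr) coordinates, where Euclidean geometry
equals the Aitchison geometry of the simplex.

## Sample selection

Eligibility is three printed rules: library strategy RNA-Seq, average
read length ≥ 75 bases (inclusive), total bases > 3 × 10⁹ (strict). The
two boundary conventions differ deliberately, following the two different
phrasings of the rules. Selection keeps one run per harmonized species
and at most a configurable number of species per phylum (default 20, with
per-phylum overrides such as Mollusca → 39). Runs below 30 Gbases are
exhausted before larger runs both within a species and when filling a
phylum's cap; the tie-breaks inside each tier are uniform draws from a
seeded generator. Species harmonization keeps the first two rank-bearing
tokens of a name and falls back to "Genus sp." when the epithet is absent
or not a lowercase latinate word; the function is idempotent. Habitat
labels live in a closed five-category set (brackish, freshwater,
intertidal zone, marine, terrestrial) supplied by the user as an ecology
table; anything else is a validation error, and missing species are
labelled `missing` with a warning rather than guessed.

## Diversity

Richness is the number of families with positive counts; Shannon
diversity is H′ = −Σⱼ pⱼ ln pⱼ over the within-sample family proportions.
Natural logarithms are used throughout (the base is configurable only by
post-scaling; ln keeps H′ ≤ ln F exact). Accumulation curves subsample
n samples without replacement (default 50 iterations per size), pool the
counts, and report mean pooled richness with an OLS fit against ln(size).

Group comparisons fit OLS ANOVA models over the phylum and habitat
factors, dropping factor levels with fewer than 5 observations. The
candidate set is every non-empty factor combination (the two one-way
models and the additive model; the interaction model is optional), and
the reported model minimizes AIC computed as n·ln(RSS/n) + 2k with
k = mean parameters + 1. Only AIC differences matter, so the constant
convention is harmless; it is fixed and documented here. A degenerate
(zero-RSS) fit gets AIC −∞ and, for constant responses, F = 0 and p = 1
by convention: a 0/0 statistic is no evidence.

Homoscedasticity is checked with Levene's test, median-centred
(Brown–Forsythe) by default as in the standard implementation; mean
centring is a flag. When H′ is heteroscedastic across phyla the pipeline
refits on the inverse Box-Cox transform with λ = 2.5,
z → (λz + 1)^(1/λ). Both transform directions are provided because the
source description ("the inverse of the Box-Cox transformation") is
ambiguous between the inverse function and an unusual description of the
forward transform; the pipeline default applies the inverse function to
raw H′, and the choice is a constructor argument.

Tukey HSD uses the Tukey–Kramer studentized-range adjustment for
unbalanced groups. The compact letter display assigns one letter per
maximal clique of the non-significance graph, so two groups share a
letter exactly when their comparison was not rejected; groups are ordered
by mean and ties resolve by that order.

## Compositional pipeline

The order is fixed: relative abundances → family filter → zero
replacement → clr. The filter drops families whose column-mean relative
abundance is below 0.01% and renormalizes rows (renormalization is
required for simplex semantics; the source wording does not state it).
The boundary is inclusive (≥) because the two printed phrasings ("did not
reach", "higher than") conflict at exact equality; ≥ was chosen once and
is a parameter. Zero replacement is count-zero multiplicative (CZM): zero
parts become δᵢ = 0.65/(depthᵢ+1), nonzero parts shrink by
(1 − zᵢ·δᵢ), preserving all nonzero ratios exactly and the unit sum to
1e-12. The 0.65 label and the 1/(depth+1) detection limit follow the
standard count-zero convention; depth is the sample's total count before
filtering, since that is the depth at which the zeros were observed. An
imputed value exceeding the smallest observed part triggers a warning.

Group centroids (for distance-to-centroid analyses) are arithmetic means
of clr rows; phylum-level profiles average each sample's
relative-abundance vector with equal weight before the clr transform, so
deep samples do not dominate. Dendrograms use the Ward.D2 criterion on
Euclidean distances of the profiles (scipy's `ward`), for phyla and for
families on the transposed matrix.

## PERMANOVA and PERMDISP

PERMANOVA decomposes the Gower-centred squared-distance matrix
G = −½ J D² J with sequential (type I) sums of squares: terms enter in
formula order through cumulative projection (hat) matrices, pseudo-F is
(SS_term/df_term)/(SS_res/df_res), and R² = SS_term/SS_total. p-values
permute sample labels with the unbiased (1+b)/(1+m) convention, which can
never return 0; exhaustive enumeration over all n! relabellings is
available for n ≤ 9 and returns the exact fraction. For Euclidean
distances of coordinates the decomposition equals the classical MANOVA
between/within split, which the tests verify against scikit-bio and
direct coordinate algebra. A fast vectorised one-way path evaluates
permutation batches from within-group blocks of D²; it computes the same
statistic and is used inside simulations and the bootstrap loop.

Model comparison uses a pseudo-AIC, n·ln(SS_res/n) + 2(model df + 1).
PERMANOVA has no likelihood, so this is the package's own definition: it
is comparable only across models fitted to the same distance matrix, and
is flagged as such wherever it is printed.

PERMDISP embeds the distance matrix by principal coordinates keeping
negative eigenvalues: squared distances to the group centre subtract the
negative-axis contributions and clip at zero, reproducing the original
metric exactly for Euclidean-embeddable input (tested to 1e-8). The
default centre is the centroid; a Weiszfeld spatial median is provided
for parity with the reference implementation's default. The F statistic
is a one-way ANOVA on distances-to-centre and its p-value permutes those
distances among samples.

## Bootstrap equivalence network

Unbalanced groups distort PERMANOVA, so pairwise phylum comparisons run
on balanced bootstrap resamples (default 15 per phylum, 1500 iterations;
the tests and examples use reduced iteration counts). Each iteration:
draw 15 observations per phylum with replacement; relabel one randomly
chosen observation (and all its duplicates) with a uniformly drawn other
phylum; trim the receiving phylum back to 15 keeping the shuffled rows;
refill the donor phylum without redrawing the shuffled observation;
recompute relative abundances, the family filter, CZM and clr on the
resampled count matrix; test every phylum pair with PERMANOVA and
PERMDISP; and adjust all of the iteration's p-values jointly by
Benjamini–Hochberg (reading "the total number of tests per iteration" as
one pooled family of both test types — a per-family alternative is a
flag). A pair is "significantly different" only under the LOC_DIFF code
(PERMANOVA rejects, PERMDISP accepts): simultaneous rejection cannot
attribute the difference to location. Support is the fraction of
iterations with any other code, and the network keeps edges with support
strictly above 0.2.

Two properties of this procedure matter for interpretation. First, the
deliberate label shuffle injects a known false signal each iteration, so
supports are conservative by design. Second, sampling *with* replacement
duplicates observations inside groups, which deflates within-group sums
of squares under the observed labelling and makes the pairwise PERMANOVA
anti-conservative when the per-phylum pool is small: in our simulations
the null rejection rate at α = 0.05 was ≈ 0.49, 0.24, 0.14 and 0.07 for
pools of 20, 40, 60 and 100 samples per phylum. Supports between phyla
with few available samples are therefore biased downward (toward
"different"), and the recovery examples in the test suite use 100-sample
pools where the duplicate artifact is negligible. The per-iteration
permutation count (default 199) is the main runtime knob.

## Bipartite network structure

The interaction matrix is host taxa × viral families with relative
abundances (or presence fractions per group) as weights. Quantitative
linkage density is the marginal-weighted mean effective partner count,
LD = ½ Σ (marginal share) · exp(H of the node's weights), summed over
both margins. H2′ standardises the two-dimensional interaction entropy
between its extremes under fixed marginals: the maximum is the
independence table (row entropy + column entropy); the minimum comes from
the standard greedy marginal-packing heuristic (the exact minimum is a
transportation problem; the heuristic is verified against intuition on
small fixtures and clipped into [0, 1]). d′ for a node is
KL(p ‖ q) / d_max, with p the node's profile, q partner availability,
d_min = 0 (the proportional table is always feasible for continuous
weights) and d_max from packing the node's total onto the rarest partners
with cells capped by partner totals. NODF binarizes at weight > 0, sorts
rows and columns by decreasing fill (the NODF2 variant), and averages
paired overlap percentages over all row pairs and column pairs, a pair
contributing zero unless the richer node's fill strictly exceeds the
poorer's. Barber modularity Q = (1/F) Σ (A − k d/F) δ(g_row, g_col) is
maximised by synchronous label-propagation sweeps (exact given the other
side's labels) with seeded random restarts (default 10); the one-module
partition (Q = 0) is the admissible floor, so reported Q is never
negative. The optimizer is a heuristic: it matches closed-form fixtures
(two equal blocks → 0.5) but is not guaranteed globally optimal.

Null models use the Patefield algorithm — uniform integer tables with the
observed marginals — via scipy's `random_table`. Continuous weight
matrices are scaled by 10⁴, rounded, sampled and rescaled, so nulls
preserve the integer-rounded marginals exactly. Observed indices are
z-tested against the null ensemble (two-sided normal); a warning fires
when the observed value or null mean sits within two null SDs of a closed
range boundary, where the normal approximation is doubtful. At desk scale
the null ensemble of binary NODF can be degenerate (dense draws binarize
to near-complete fill); the analysis wrapper then reports NaN for that
z-test rather than a fabricated number.

## Synthetic surveys

The generator emulates grouped compositional count data, not sequencing.
A shared family centre is drawn from Dirichlet(concentration = 5 over 30
families); each phylum perturbs the centre's logs by
Normal(0, phylum_effect) (a logistic-normal dial: 0 = exchangeable phyla,
≈2 = strong separation); habitat effects add a fixed log-ratio shift to a
random half of the families with magnitude scaled per habitat; each
sample zeroes families independently with probability 0.15 (structural
absence), renormalizes, and draws a multinomial at a log-normal depth
(ln-mean 10 ≈ 22k classified reads, ln-sd 0.5 — skewed like real
classified-read totals; exact values are free parameters). Row sums equal
the drawn depths exactly. All randomness descends from one integer seed
through `numpy.random.SeedSequence` spawning; the pipeline splits its
master seed per stage the same way.

What the generator does **not** emulate: phylogenetic correlation between
species within a phylum (samples are exchangeable within groups),
classifier error and reference-database bias, per-read quality, and the
heavy cross-sample overdispersion of real archives. Passing
parameter-recovery tests therefore shows the estimators are correct under
the stated model, not that real viromes satisfy that model.

## Numerical conventions and degenerate inputs

Tolerances: clr rows sum to 0 within 1e-10; CZM preserves the simplex and
nonzero ratios within 1e-12; PERMANOVA's decomposition must close within
1e-8 or it raises. Permutation p-values use (1+b)/(1+m) everywhere.
Tie-breaks are deterministic: lowest index for greedy packings and
module ids, stable sorts for fills, group order for letter assignment.
Degenerate cases are explicit errors (all-zero Shannon input, singleton
PERMDISP groups, saturated PERMANOVA models, zero-SD null ensembles in
`null_ztest`) or documented conventions (constant-response ANOVA,
single-cell H2′ = 0 with a warning).

## Problem sizes

Test-suite simulations use 4 phyla × 15–20 samples × 30 families, 199 or
fewer permutations per test, 100–500 replicate surveys for calibration
and power, 200 bootstrap iterations and 100–1000 null matrices. These
sizes give binomial standard errors of about 0.01 on the reported rates
while keeping the whole suite and the acceptance script fast on a single
CPU; all of them are constructor or CLI parameters.
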