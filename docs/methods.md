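# Methods

## Genetic distances

Distances between per-sample consensus strains are Kimura 2-parameter
(K2P) estimates. For a pair of aligned sequences, sites where either
sequence carries `N` or `-` are excluded pair-by-pair (pairwise
deletion); `N` and `-` are treated identically as "no information".
Mismatches at the remaining `n` sites are split into transitions
(A↔G, C↔T; fraction `P`) and transversions (fraction `Q`), and

    d = −1/2 · ln[(1 − 2P − Q)·√(1 − 2Q)].

Two situations make the estimate undefined and are reported with a
SATURATED marker rather than a number: a non-positive logarithm argument
(sequences beyond the model's resolvable divergence) and an overlap of
fewer than `min_sites` comparable sites. `min_sites` defaults to 100:
distances feed medians downstream, and the handful of pairs with tiny
overlaps would otherwise contribute wildly unstable estimates.
Ambiguity codes other than `N` are rejected at read time instead of
being resolved; consensus strains rarely contain them and silent
resolution would bias `P` and `Q`.

Internally SATURATED is NaN, which serializes as `NA` in distance-matrix
TSVs; writers accept a `scale` of 100 to emit distances per 100 bases in
the style of EMBOSS distmat, and the reader mirrors triangular matrices
into the canonical square form. The exact gap handling of other distance
tools is not asserted to match bit-for-bit; the pairwise-deletion choice
here is the documented behavior.

## Coherence (niche-association) score

For each host *h* with ≥ 5 strains, `W` collects finite distances among
strains of *h* and `B` finite distances from *h*'s strains to all other
strains. The host score is `max(0, (median B − median W)/median B)`,
with 0 when `median B = 0` and UNDEFINED when more than half of `W ∪ B`
is saturated (the >50% cutoff prevents a few saturated pairs from
silently collapsing a score, while refusing to report a median computed
mostly from leftovers). The SGB's score `C` is the unweighted mean of
the defined host scores. Medians rather than means make the contrast
robust to outlier and near-saturated pairs, and the ratio form makes
every score invariant to rescaling the distances (per-site vs per-100
bases). Hosts below the 5-strain floor receive no score of their own —
a median over fewer than 5 strains' pairs is dominated by single pairs —
but their strains still widen other hosts' between-host pools.

Eligibility to be scored at all: shared by ≥ 2 hosts, ≥ 20 samples
total, ≥ 5 samples in each of ≥ 2 hosts. These floors are survey
conventions for when a between-host contrast is estimable at all, and
are exposed as constants.

The mean aggregation was chosen over sample-size weighting because the
reference host-score triplets it must reproduce (e.g. 0.763/0.876/0.909
→ 0.850) agree with the unweighted mean to within their printed
rounding.

## Ordination and PERMANOVA

Bray–Curtis dissimilarity `1 − 2Σmin(x,y)/(Σx+Σy)` is computed with
scipy's pairwise-distance machinery. PCoA is the classical
eigendecomposition of the Gower-centered matrix `−½ J D² J`; axes with
non-positive eigenvalues are dropped without Lingoes/Cailliez correction
(the ordination is used for display and for the frequency-corrected
scores, both of which rely only on the positive axes), and scores are
eigenvectors scaled by √λ. Requesting more axes than exist positive
eigenvalues returns fewer with a warning.

The frequency correction divides every sample's scores by its group's
sample size (a 367-strong cohort's scores shrink 367-fold), compensating
for very unequal cohort sizes in displays; it refuses to run twice and
records the divisor per sample. Weighted-average taxon positions use
whichever scores (raw or corrected) the caller passes, mirroring how an
annotated ordination is actually drawn.

One-factor PERMANOVA partitions squared-distance sums:
`SS_total = Σ_{i<j} d²/n`, `SS_within = Σ_g Σ_{i<j∈g} d²/n_g`,
`R² = 1 − SS_within/SS_total`, pseudo-F with `(g−1, n−g)` degrees of
freedom, and `p = (#{F_perm ≥ F_obs} + 1)/(B + 1)` over seeded label
permutations (seed mandatory; ≥ 99 permutations enforced). Multi-factor
marginal designs are out of scope; the one-factor statistic is the one
validated against a brute-force oracle and scikit-bio.

## Screening rules

MAG quality: high iff completeness > 90 and contamination < 5; else
medium iff completeness > 50 and contamination < 10; else low. The
"low" grade is defined as the complement so the three grades partition
the plane (a literal `<50% and >10%` reading would leave gaps).
Genome-bin assignment takes the minimum-Mash-distance bin (ties to the
lexicographically smallest id) at species/genus/family level for
d < 0.05/0.15/0.30, else novel. Presence of an SGB in a host requires
relative abundance ≥ 1e-5 in ≥ 3 of that host's samples ("at least"
makes the boundary inclusive; both threshold values are parameters), and
the sharing category is the exact set of hosts with presence. Novel SGBs
enter a marker database only with ≥ 5 genomes. All comparisons are
strict/inclusive exactly as stated above and every boundary is
unit-tested.

## ARG profiles

Alignment hits are retained at identity ≥ 90% and *mutual* coverage
≥ 80% — both query and subject coverage must clear the threshold, the
only reading that makes "mutual" meaningful. Retained gene families are
de-duplicated. ARG presence is counted per host: abundance > 0 in ≥ 3
samples of at least one host. Class aggregation sums each ARG's full
abundance into every drug class it maps to; with a single-class map the
per-sample class totals equal the ARG totals exactly, and with
overlapping classes (e.g. multidrug efflux systems) the multiplicity is
deliberate — resistance classes are not a partition. Unmapped ARGs land
in an `unclassified` bucket so no mass disappears.

## Synthetic data

The strain simulator uses a star-within-star genealogy: a uniform random
root sequence, one ancestor per host at branch length `t_b`, each strain
at `t_w` from its host ancestor, all branches evolved site-independently
under the K80 model (closed-form transition probabilities; rate matrix
normalized so branch length is expected substitutions per site; default
transition/transversion rate ratio κ = 2, a typical bacterial value).
No coalescent is simulated: the coherence score depends only on the
within/between divergence contrast, and the star genealogy gives the
closed-form expectations E[d_within] = 2·t_w, E[d_between] = 2(t_w+t_b),
hence expected coherence `t_b/(t_w + t_b)`. A `mixing` fraction of
strains has labels re-drawn uniformly to model transmission;
ground-truth ancestry and pre-shuffle labels are returned alongside.
Defaults (3 hosts × 20 strains, 5 000 sites, `t_w = 0.01`,
`t_b = 0.09`) put the expected score at 0.9 — a strongly host-coherent
species — with standard errors small enough that 20 replicates resolve
it to ±0.05.

Abundance tables are log-normal (per-taxon log-mean N(0,1), per-sample
noise σ = 1) with disjoint host-signature taxa multiplied by `1 + δ`
and rows renormalized; δ = 5 with 20 samples per host is reliably
detected by PERMANOVA, δ = 0 is a calibrated null. Screening fixtures
are hand-planted boundary records (e.g. completeness exactly 90, a Mash
tie, a 90/80/80 hit) plus seeded random records with independently
derived expected outcomes.

What the generators deliberately do not emulate: recombination and
horizontal transfer, unequal base composition, rate variation across
sites, coalescent genealogies within hosts, read-level noise,
compositional zero-inflation, and study-level batch structure. Passing
tests therefore demonstrate correctness of the statistics under their
own model assumptions, not robustness of the biological conclusions to
real-data messiness.

## Problem sizes and numerics

The validation suite runs at the scales the statistics were designed
for: coherence recovery with 20 replicates of 60 strains × 5 kb; the
PERMANOVA null with 200 simulations of 12 samples at 199 permutations
(the discrete permutation p-grid is fine enough for a Kolmogorov–Smirnov
uniformity check at α = 0.01); power at 100 simulations of 60 samples.
Degenerate inputs are defined rather than crashed on: identical
sequences give distance 0, an all-equal distance matrix gives PERMANOVA
p = 1, an all-zero ordination gives zero axes, a zero-abundance taxon
has undefined position. Distance round-trips through TSV are exact to
1e-6 (six printed decimals).
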