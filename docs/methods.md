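# Methods

This note documents the models, estimators and design choices behind
`thermofungi`, and what the synthetic-data generators do and do not
emulate.

## Pangenome partitioning and rarefaction

An orthogroup is treated as present in a genome when its count is ≥ 1; no
soft-core threshold is offered. For a genome set G, *core* = present in
all of G, *unique* = present in exactly one genome, *shell* = present in
at least two but not all. When |G| = 1 the definitions coincide and core
takes precedence (every present orthogroup is core, none unique); this
precedence is a deliberate reading of the standard definitions, which do
not pin down the single-genome boundary case.

Rarefaction draws, for each subsample size n < |G|, R subsets (default
R = 100) uniformly without replacement, applies the partition to each and
reports the mean and population SD of each category size. n = |G| is
short-circuited to the exact partition with SD 0. When R exceeds the
number of distinct subsets of a given size, subsets simply repeat — the
estimate remains the "R random subsamples" statistic rather than an
exhaustive enumeration. One RNG stream per `rarefy` call, seeded
explicitly; a missing seed is an error rather than a silent
irreproducibility.

## Codon usage

Wright's effective number of codons is computed per gene or on pooled
counts. For each amino acid with n ≥ 2 observed codons the family
homozygosity is F̂ = (n·Σp² − 1)/(n − 1); class means F̄_s average F̂ over
the amino acids of degeneracy s ∈ {2, 3, 4, 6} that yielded a value; and
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Conventions follow common ENC
implementations: a missing three-fold mean (Ile unobserved) is replaced by
(F̄₂ + F̄₄)/2; a missing or non-positive two-, four- or six-fold mean makes
ENC undefined (reported as missing, with the skipped-gene tally); finite-
sample estimates above 61 are clamped to 61 with the raw value retained in
the per-gene record. Note the estimator is only asymptotically
scale-invariant: the 1/n correction means scaling all counts changes ENC
by O(1/n), which the property tests assert at large counts.

GC3 is the G+C fraction at third positions over all sense codons; GC3s
restricts to synonymous families (excluding Met, Trp and stops). Both are
reported because conventions differ between tools and the headline value
is ambiguous in practice. Genes whose length is not a multiple of three,
or which contain an internal stop, are excluded with a logged warning and
counted in the report; codons containing N are skipped individually. Only
the standard genetic code is supported.

Group comparisons: the Wilcoxon rank-sum p-value is exact when both
groups have ≤ 20 observations and no ties (verified against full
enumeration in the tests), otherwise a tie-corrected normal approximation
without continuity correction. Mood's median test drops values equal to
the grand median, then uses Fisher's exact test when any expected cell
count is below 5 and otherwise a chi-square without continuity
correction. The GC3–ENC scatter is summarised by Pearson's r (r² is also
reported; the anticorrelation makes the signed r the interpretable
number) and by quadrants split at the grand means: Q1 = GC3 above, ENC
below (the thermophile-enriched corner), proceeding Q2–Q4
counter-clockwise; points on a mean are labelled `boundary`.

## Ancestral states

Parsimony uses unit-cost Sankoff dynamic programming with both a
downward and an upward pass, which generalises Fitch to multifurcating
trees and yields, per node, the exact set of states attainable in some
globally minimal labeling, plus one concrete optimal labeling
(smallest-index tie-break, resolved root-down).

The Mk1 model has a single symmetric rate α between each ordered state
pair, giving the closed-form branch transition probabilities
P_same(t) = 1/k + (k−1)/k·e^(−kαt) and P_diff(t) = 1/k − 1/k·e^(−kαt).
The root prior is uniform 1/k — the model's stationary distribution.
Likelihood is computed by Felsenstein's pruning recursion with per-node
rescaling; marginal posteriors combine the pruning pass with an upward
(outside) pass and are normalised per node. Both are verified against
brute-force enumeration over all ancestral assignments on small trees to
1e-10. The rate is fitted by bounded scalar minimisation on
[1e-8, 100/tree height] with xatol 1e-8; monomorphic tip data drive α̂ to
the lower bound and are flagged as boundary fits rather than treated as
estimates.

Lifestyles map to characters either ternary
(mesophilic/thermophilic/thermotolerant) or binary, where thermotolerant
merges into mesophilic — the same treatment the classifier applies.

## Lifestyle classifier

The screen follows the staged procedure: population-variance filter at
0.1 on raw counts (a `binarize` flag covers presence/absence); five fixed
training subsets of exactly 20 thermophiles and 30 mesophiles (when a
class is smaller, both counts scale down proportionally with one genome
per class reserved for validation, floored, with a logged warning);
per-feature ranking by mean validation accuracy of a single-feature SVC;
a point-biserial correlation gate at 0.75 capped at the top 10 by rank;
and an exhaustive search over all non-empty combinations of the selected
features, ties broken toward fewer features then lexicographic ids.

The classifier primitive is `sklearn.svm.SVC` with default
regularisation and a **linear** kernel. The kernel choice is deliberate:
on near-binary orthogroup profiles a linear maximum-margin classifier
acts as a weighted vote, so adding informative features monotonically
repairs the genomes that any single feature gets wrong — the behaviour
the combination search is meant to exploit. The RBF kernel, by contrast,
is local: a genome a few flips away from its class profile falls into the
wrong kernel neighbourhood regardless of how many clean features are
added, combination accuracy saturates at small sizes, and the search
degenerates to picking single features. An RBF kernel remains available
via the `kernel` argument of the internal constructor.

Per-genome probabilities come from a Platt-style logistic calibration fit
on the decision values of the final model (trained on all labeled genomes
with the best combination); thermotolerant genomes are scored as held-out
test items only. The z-score matrix standardises each selected feature to
mean 0 / SD 1 (population SD) over the labeled genomes.

## Enrichment

One two-tailed Fisher's exact test (probability method: sum of tables no
more probable than the observed one, margins fixed) per GO term that
annotates at least one universe member, followed by Benjamini–Hochberg
step-up adjustment across terms. The default universe is the reference
clade's core orthogroup set and the lost set is reference core minus
reduced core; an all-orthogroups universe is a caller choice, since the
appropriate background is study-specific. GO-graph propagation
(annotating ancestors) is not performed; annotations are taken literally.

## Structure network

Pairwise structural scores are merged per unordered pair by taking the
maximum of each score over the two alignment directions, then thresholded
strictly: an edge requires fident > 0.7 and TM-score > 0.8. Clusters are
connected components — the minimal faithful reading of threshold-based
cluster separation; note components can chain through intermediate
structures, so a cluster does not certify that all its members exceed the
thresholds pairwise. Two- and three-member components are flagged duplet
and triplet. Disulfide bonds are counted from cysteine SG–SG Euclidean
distances at ≤ 2.5 Å (true bonds sit near 2.05 Å; the slack absorbs
model error) with greedy matching by ascending distance so each cysteine
joins at most one bond. The per-cluster summary reports size, lifestyle
composition, the disulfide-count values with a constant-within-cluster
flag, and membership of the closed 55–60 °C optimal-temperature band,
plus the global fraction of band members that fall in their modal
cluster and the percentage of structures carrying any temperature
annotation.

## Synthetic data: what is emulated, and what is not

Generator defaults are the study conditions the pipeline targets: 29
thermophiles, 8 thermotolerant, 42 mesophiles; nested lifestyle cores of
120 (thermophile) / 180 (thermotolerant) / 200 (mesophile) orthogroups;
500 accessory orthogroups that are unique with probability 0.4 and
otherwise shell; eight discriminative orthogroups; coding sequences of
200 codons at a mesophile GC3 target of 0.52 and bias 0.30, with
thermophiles shifted by +0.08 / +0.15; Mk1 rate 0.5 with exponential
branch lengths of mean 0.3; six structural clusters of sizes
10/6/4/2/1/1 with c − 1 disulfide bonds in cluster c.

Core structure. Lifestyle cores are nested prefixes of one backbone:
orthogroups in the mesophile core but not the thermophile core (the
planted loss) appear in about half of each thermophile's genomes. That
rate makes the loss a *core-membership* loss rather than a clean
presence/absence split — deliberately, so the lost-core block separates
the classes only weakly (point-biserial ≈ 0.5) and does not displace the
planted discriminative features from the classifier's correlation-gated
selection. A guard knocks one genome out of any accessory or
discriminative orthogroup that would otherwise cover an entire lifestyle
group, so planted core sizes are recovered exactly by the partition.

Discriminative features. The eight planted orthogroups are single-copy
(0/1) with clean class profiles except in 20 "exception" genomes, each
flipping a 3-feature subset to the opposite pole. The twenty flip sets
form a fixed double pair-covering design: every feature pair is jointly
flipped in at least two genomes (so no 1–5-feature combination classifies
perfectly), while three flips stay a strict minority vote in 7–8-feature
combinations (so large combinations do win). Each feature ends up flipped
in 7–8 of 71 labeled genomes, keeping its point-biserial correlation near
0.8 — above the 0.75 selection gate. This is the concrete sense in which
the planted signal is *complementary*: features cover one another's
exceptions. Thermotolerant genomes carry a mesophile-like profile with 5%
noise, so the trained classifier scores them mesophilic.

Codon model. Within each synonymous family, codon probabilities
interpolate linearly between uniform (bias 0, ENC → 61) and a point mass
on one preferred codon (bias 1, ENC = 20 exactly). Preferred codons are
assigned greedily to GC- or AT-ending choices so the expected GC3s tracks
the target as closely as the bias level permits; the achievable GC3s
range is the interval around ≈ 0.49 (the uniform-usage value) of
half-width equal to the bias, so extreme targets at low bias are
approached, not hit. Amino acids are sampled uniformly; genes are
ATG + sense codons + TAA with no internal stops.

Trees and states. Topologies come from uniform random sequential joins —
not a birth–death process — with i.i.d. exponential branch lengths.
States evolve by drawing each child state from the closed-form Mk1
transition row (exact, no waiting-time simulation); rate 0 propagates the
root state unchanged.

Structures. Toy PDBs are single-chain CA traces with cysteine SG pairs
placed exactly 2.05 Å apart and all other SG–SG distances above 4 Å;
they exercise coordinate parsing and distance logic only — there is no
fold, no side-chain geometry, no prediction noise. Pairwise score tables
draw intra-cluster scores strictly above the thresholds and inter-cluster
scores strictly below (both alignment directions emitted, the reverse
slightly lower, plus self-pairs for the reader to drop), so the planted
clustering is recovered exactly; real score distributions straddle the
thresholds and can chain components.

Determinism: each generator derives an independent RNG stream from
(seed, stage-tag); a full `simulate` run is byte-identical for the same
spec and seed, which the tests check file by file.

What passing on these data does **not** show: robustness to annotation
noise and missing orthology calls, to gene trees conflicting with the
species tree, to structural-score distributions near the thresholds, or
to codon-usage variation driven by amino-acid composition — none of which
the generators model.

## Problem sizes

The test suite runs the study-scale classifier experiment (79 genomes,
~700 orthogroups, 20 seeds), the Mk1 recovery at 100 tips × 20
replicates, and brute-force oracle comparisons on trees of up to 6 tips
and contingency margins up to 15 — sizes chosen so the full suite
completes in a few minutes on one CPU while every oracle comparison stays
exhaustive.

## Known limitations

* Single chain, first model, blank/'A' altlocs only for PDB input; no
  mmCIF.
* Strict-core definition only; no gene-level (as opposed to
  orthogroup-level) rarefaction.
* Mk1 only — no asymmetric-rate (all-rates-different) models, no
  stochastic character mapping.
* The exception design fixes n_discriminative = 8 to a hand-built
  covering; other values fall back to random flip sets without the
  covering guarantees.
* Mood's median test and the Wilcoxon wrapper handle two groups;
  multi-group contrasts must be decomposed by the caller.
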