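# Methods

## The model

A community is a vector of relative abundances *a* over *N* taxa with
non-zero abundance. Its functional profile is the linear map
*F_j = Σ_i a_i c_ij*, with *c_ij* the copy number of gene family *j* in
taxon *i*'s genome. When abundances derive from 16S amplicon counts they
are first divided by each taxon's 16S rRNA copy number (taxa with many
marker copies are over-counted); the corrected vector is renormalised to
sum 1. Because every downstream robustness quantity uses cosine
dissimilarity, which is invariant to global rescaling, the renormalisation
is a presentational choice with no effect on the fitted coefficients — it
is exposed as a flag. Gene-family profiles are optionally summarised to
pathways by splitting each family's abundance evenly across the pathways
that contain it (mass-conserving for mapped families; unmapped families
are dropped or routed to an `unmapped` bin, per configuration). No
inter-sample abundance recalibration is applied; a configurable
post-normalisation (none, sum-to-1, or median over a user-supplied list of
universal single-copy families) is available, and again cannot affect
cosine-based results.

## Perturbation model

A perturbation of maximum magnitude M > 1 draws, independently per taxon,
a multiplier *m_i* uniform on (0, M] (realised as M·(1 − U), U ∈ [0, 1))
and a fair-coin direction *d_i* ∈ {−1, +1}; the perturbed composition is
*p_i ∝ a_i m_i^{d_i}*, renormalised. The expected magnitude of change is
proportional to the taxon's abundance, and support is preserved — no
migration or extinction. Note that *d_i = −1* with *m_i < 1* inflates an
abundance (m⁻¹ > 1), so the "direction" label is not a guaranteed sign of
change. The default experiment perturbs each community at 45 maximum
magnitudes evenly spaced on [1.2, 10] inclusive (spacing 0.2), 100 draws
per magnitude: 4500 perturbed compositions. Sub-seeds per perturbation are
spawned from the master seed (`numpy.random.SeedSequence`), so the set is
reproducible independent of iteration order.

## Distances

Taxonomic perturbation magnitude is weighted UniFrac: Σ over branches of
branch length × |A_b − B_b|, with A_b, B_b the community fractions
descending through the branch. The normalised variant divides by the
abundance-weighted sum of root-to-leaf distances, bounding values in
[0, 1]; both variants are exposed and the normalised one is the default
(bounded, comparable across trees). The implementation pre-computes a
branch × leaf incidence matrix per tree so one-to-many distances (one
original vs thousands of perturbations) are a single matrix product; it is
verified against an explicit per-branch oracle on every rooted binary
topology of ≤ 5 leaves and against scikit-bio on random instances.

Functional shift is cosine dissimilarity, 1 − ⟨a, b⟩/(‖a‖‖b‖), aligned on
the union of function identifiers with implicit zeros. The shift of a
*single* function is the direction-free relative change
|f′ − f|/f — the absolute value is required because single-function curves
are fitted on a log scale; records with zero original abundance are
excluded and counted.

## Response curve and fitting

The taxa-function response curve is f = t^b/e^a, fitted as the OLS
regression of ln f on ln t (intercept −a, slope b). Because small-t
perturbations dominate the raw sample and the variance of f grows with t,
records are first re-sampled uniformly across taxonomic distances: the
observed [min ln t, max ln t] range is split into 50 equal windows and
each window is capped at 50 records (seeded sampling without replacement;
windows with fewer records keep all). Records with t = 0 or f = 0 are
dropped before the log transform, with counts reported — exact zeros carry
no information for a power law and their treatment is otherwise undefined.
A community whose perturbations produce no functional shift at all (all
cosine shifts below 1e−12, e.g. identical member genomes) is flagged
unfittable rather than fitted.

Attenuation/buffering distributions are asymmetric, so locations are
summarised by the Hodges-Lehmann pseudomedian (median of all Walsh
averages (x_i + x_j)/2, i ≤ j) with the classical Tukey 95% CI: the k-th
extreme Walsh averages with k from the normal approximation of the null
signed-rank statistic. For very small n the computed k is clamped at the
extreme order statistics (the CI is then the Walsh-average range).

Environment comparisons use Wilcoxon rank-sum tests with
Benjamini-Hochberg control across pairs. The "most robust environment" of
a function is decided with pairwise Mood's median tests (counts above the
pooled grand median, ties counted as "not above", chi-square with
continuity correction): environments are ranked by median attenuation and
prefixes of increasing size are tested; a prefix qualifies when every
member differs significantly (p < α, default 0.05) from every non-member
and from no other member. The first qualifying prefix is returned, the
empty set if none. The prefix search is a deliberate design choice: the
qualifying condition is monotone in the ranking, so if any qualifying set
exists a ranked prefix does.

## Community mixing

Given paired communities with measured (e.g. shotgun metagenome-derived)
functional profiles, a perturbation of the first at a chosen taxonomic
distance is built by convex mixing: taxon abundances a_i(1 − m) + b_i m
and function abundances c_j(1 − m) + d_j m. Mixing preserves the sum of a
taxonomic profile, so no renormalisation is applied. The weighted UniFrac
distance from the original is non-decreasing in m (the raw distance is
exactly linear in m; the normalised one is a monotone rational function),
which justifies a binary search on m to hit target distances within 1e−9;
a fine grid search is the guarded fallback if the bracket ever fails.
Records over the default target grid 0.01–0.10 (step 0.01) are fitted with
the same window/log-log machinery; unreachable targets (beyond the m = 1
distance) are dropped with a warning.

## Synthetic data

The generator emulates the statistical shape of real inputs, not any real
taxon inventory: lognormal relative abundances (default σ = 1, long-tailed
like 16S surveys; σ = 0 gives a uniform community), random rooted
bifurcating trees built by uniformly joining subtrees with Exp(1) branch
lengths, and genome content governed by a single redundancy knob
ρ ∈ [0, 1]: ⌊ρ·n_functions⌋ core families shared (with identical copy
number) by all genomes, the rest private to single taxa, dealt
round-robin, plus one universal single-copy marker so no genome is empty.
Copy numbers are drawn from {1, 2, 3} and 16S copy numbers from
{1, …, 5} to exercise the correction code; the exact ranges are arbitrary.
Default problem sizes are 30 taxa × 150 gene families per community —
large enough for stable curve fits and non-trivial GDF spread, small
enough that a full 4500-perturbation fit takes well under a second.

What the generator does *not* emulate: phylogenetic correlation of genome
content (private families are assigned independently of the tree), realistic
pathway structure (memberships are random), compositional sequencing noise,
or between-sample taxon turnover. Passing tests therefore demonstrate the
internal correctness and the qualitative redundancy-robustness relationship,
not quantitative agreement with any real survey's coefficients.

## Gene-distribution features

Per-function redundancy is the Shannon entropy of per-species
contributions s_i·c_i. The contributions are normalised to proportions per
function before the entropy — the unnormalised sum −Σ s_i c_i ln(s_i c_i)
is not a valid Shannon index and can go negative; a `literal` mode
computes it anyway for comparability. No division by ln N is applied
(entropy, not Pielou evenness). Community-average redundancy weights each
function by its share of the functional profile. Average functional
similarity is the unweighted mean cosine similarity over unordered pairs
of present species (self-pairs excluded). Genome size is the total copy
number of a genome; its variability is the population-SD coefficient of
variation, and the average is unweighted by abundance. Unique-function
abundance is the functional-profile share of families encoded by exactly
one present species. "Present" means non-zero abundance in the (possibly
rarefied) profile. GDFs are computed at the gene-family level of the
content matrix; redundancy weighting uses the same functional level as the
fitted profiles when a hierarchy is supplied. The PCA of GDF tables
z-scores columns, drops constant ones with a warning, and reports scores,
loadings and explained-variance fractions.

## Sample processing

Chloroplast reads are removed by case-insensitive substring match on a
configurable lineage label (default "chloroplast"). Samples with fewer
than 10 non-zero taxa or fewer than 5000 reads are dropped; the rest are
rarefied to exactly 5000 reads in a single draw by multivariate
hypergeometric sampling (sampling without replacement — standard
rarefaction semantics; the alternative of repeated rarefaction averaging
is not implemented). Abundance-proportional OTU subsampling (the diversity
control) uses successive weighted draws without replacement with
renormalised weights. Bilateral subsite pooling is a metadata relabeling
utility driven by an explicit mapping. Every stochastic operation takes an
explicit seed; there is no global random state.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data at
the sizes above; the redundancy sweep uses 3 × 10 communities at
ρ ∈ {0.2, 0.5, 0.9} with the full default 4500-perturbation protocol per
community. Pipelines spawn per-community sub-seeds from one master seed,
making outputs byte-identical across reruns with the same seed.

## Known limitations

* The linear taxa-function map ignores regulation, expression, and
  ecological interactions; it describes genomic potential only.
* Weighted UniFrac normalisation variant used by any particular published
  analysis may differ; both variants are exposed (`normalized=` flag).
* The multiplier perturbation model is not a population-dynamic model;
  it samples compositional neighbourhoods, not trajectories.
* Mood's test with small groups is conservative (continuity-corrected
  chi-square); the most-robust-environment procedure applies no
  multiple-testing correction beyond the configurable α.
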