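# Methods

This note documents the statistical procedures, the synthetic-data model
and the numerical conventions used by `myxogeo`, and records the design
choices made where several defensible options existed.

## The nested design and representative distances

Isolates carry hierarchical addresses `SITE t.c.f X`: kilometre-scale site,
metre-scale transect, centimetre-scale soil core, millimetre-separated
fruiting body, and clone letter. A pair of distinct isolates is assigned to
the spatial-scale category of the deepest level at which the two addresses
differ. Each category is summarised by one representative metric distance:

| scale      | default | origin                                        |
|------------|---------|-----------------------------------------------|
| micrometre | 3.3e-5 m| fruiting-body diameter (100 µm) / 3            |
| millimetre | 0.003 m | soil-core diameter (0.9 cm) / 3                |
| centimetre | 0.036 m | field-averaged constant (configurable)         |
| metre      | 18 m    | field-averaged constant (configurable)         |
| kilometre  | 11 000 m| field-averaged constant (configurable)         |

The one-third-of-diameter rule encodes the assumption that two cells inside
a unit are on average maximally separated by a third of that unit's
diameter. The three larger constants cannot be derived from the nominal
grid spacings alone (2 cm between cores, 10 m between transects), so they
are treated as configuration with the conventional defaults, not
re-derived. Display rounding is two significant figures (0.000033), while
internal arithmetic keeps full precision.

## Genotypes

Concatemers are the fixed-order concatenation of per-locus alignments
(default order Mxan_0128, Mxan_0533, Mxan_1277, Mxan_4405, Mxan_5783;
default lengths sum to 1445 sites including gaps). Sequence types are exact
string-equality classes of concatemers — gaps and `N` compare literally,
because the types are defined over the gapped alignment. Isolates missing
any locus are excluded when loading FASTA input.

Nucleotide diversity π is the mean over all unordered pairs of (mismatches
/ comparable sites); a site is comparable for a pair when both bases are
unambiguous A/C/G/T. Pairwise deletion is the default, complete deletion is
available by flag; the choice matters only for gapped data and is recorded
in the result object. Pairwise distances offer p-distance (default), JC69
(d = −(3/4)·ln(1 − 4p/3)) and K2P (transition/transversion-corrected).
The composite-likelihood distance of legacy desktop software is *not*
reimplemented: all scale-resolved conclusions the package supports are
categorical over five scales and insensitive to the exact distance variant,
and the model tag is carried in the output metadata so analyses are
explicit about what they used. JC69/K2P saturation (log of a non-positive
argument) follows a configurable policy: raise (default) or return +inf.

## Independent pair sampling

The identity-decay analysis needs R replicates × k pairs per scale (default
3 × 4 × 5 scales = 60 pairs over 120 isolates) with **global
disjointness**: no isolate may appear in more than one pair across all
replicates and scales, so that every pair is statistically independent.
"Without replacement" is interpreted globally, not per replicate — this is
the stronger reading and the one that makes all pairs independent.

The sampler fills scales from most constrained to least (micrometre pairs
need two clones of one fruiting body; kilometre pairs are abundant). Within
a scale it tries a randomised greedy sweep of the eligible-pair list and
falls back to maximum-cardinality matching (networkx blossom) on the
eligible graph restricted to still-free isolates; if any later scale cannot
be filled the whole construction restarts with fresh randomisation (cap:
1000 restarts, then an error naming the first unfillable scale — never a
silent relaxation). The sampler guarantees validity and seeded
reproducibility, not uniformity over the space of all valid pair sets, and
it does not stratify kilometre pairs by site. `feasibility_report` gives
the per-scale maximum-matching capacity, an upper bound since scales
compete for isolates.

## Kin-discrimination scoring

Observer panels are odd-sized (default 3); each call is 1 when the colony
interface is visibly altered relative to self–self controls. The strict
majority is adopted, with a unanimity flag; social identity of a pair is
1 − majority. Self–self control records must score majority 0 — a KD
majority on a control is an error because alteration is defined relative to
those very interfaces. With per-call error ε and three observers, the
majority call is wrong with probability 3ε²(1−ε) + ε³, which the tests
verify by simulation.

## Identity curves, ANOVA and Tukey HSD

The unit of analysis is the replicate-level identity proportion (k pairs
each), not the pair-level binary: scales are compared by one-way ANOVA on
the R proportions per scale, followed by Tukey HSD using the
studentized-range distribution with k = 5 groups and N − k error degrees of
freedom (equal-n Tukey for the balanced design; Tukey–Kramer standard error
automatically when replicate sizes differ). No arcsine or logit transform
is applied by default. Degenerate cases are handled explicitly: if all
groups have zero variance and equal means, F = 0 and all p = 1; if all
groups have zero variance but means differ, the F ratio is undefined and an
`exact_separation` flag is reported instead of a number.

The genetic and social decay curves (five pooled proportions each) are
compared by Pearson correlation, with an optional exact permutation p-value
from all 5! = 120 orderings of one curve (two-sided, counting
|r_perm| ≥ |r_obs|). Zero variance in either curve leaves r undefined and
flagged, never silently zero. As a reference point, the reported per-scale
proportions (12,7,2,0,0)/12 vs (11,5,5,0,0)/12 give r = 0.9356 ≈ 0.94 and
permutation p = 4/120.

## Spatial statistics

**Mantel test.** r is the Pearson correlation of the upper-triangle entries
of the geographic and genetic distance matrices; the null is generated by
simultaneous row/column permutation of one matrix. The two-sided p uses the
add-one estimator (count of |r_perm| ≥ |r_obs| + 1)/(n_perm + 1), default
9999 permutations; for n ≤ 8 an exact enumeration of all n! permutations is
available. The "two-sided" qualifier is a property of the tail counting,
not a parametric approximation; a parametric t-test variant exists behind a
flag for comparison only, since pair distances are not independent.

**Mean distance by scale.** For each category the mean is taken over *all*
qualifying isolate pairs (the exhaustive set, not the independent
subsample), optionally restricted to pairs within one clade; a linear or
second-order polynomial is least-squares fitted against log10 representative
distance. Scales with no qualifying pair are omitted from the fit and
flagged.

**Clade distribution.** Clade labels are consumed as input (tree inference
is out of scope; the simulator emits exact truth labels). The absence test
is the exact binomial lower tail P(X ≤ observed) at the clade's pooled
frequency; the two-clade frequency test is a two-sided exact binomial test
of a site's split against the pooled proportion.

**Nearest-ST concordance.** Every ST is paired with its genetically nearest
distinct ST, ties broken uniformly at random under the recorded seed. The
no-structure expectation is computed analytically as the fraction of all
unordered distinct ST pairs that share a site; an exact binomial test
(one-sided "greater" by default) compares the observed concordant fraction
with it, and a label-permutation alternative (shuffling the ST-to-site
assignment) is reported alongside, since "no spatial structure" admits more
than one formalisation.

**Within- vs among-site distances.** Distances are resampled at the ST-pair
level (consistent with comparing types, not redundant clones), n draws per
group without reuse of any ST pair, then compared by a two-sided Wilcoxon
rank-sum test — exact null for small untied samples, normal approximation
with tie correction otherwise.

## The synthetic landscape model

The simulator exists so that every stage of the pipeline can be exercised
and validated end to end, with known ground truth, on data that has the
same statistical *shape* as real nested-design samples.

Colonisation is a hierarchical **stay-or-escalate** lineage draw rather
than a coalescent: lineage pools are materialised top-down (regional pool →
site → transect → core → fruiting-body founders → clones), and each draw
takes a parent-pool member with probability 1 − migration, otherwise it
recursively escalates one level up. Every materialised copy gains a Poisson
number of substitutions (per-level means) and, at 0.26 recombination events
per mutation event, receives homologous tracts of geometric length (mean
12 nt) copied from a donor lineage of the same site — matching the
observation that recombination acts within local populations and
contributes several-fold more variation per event than point mutation.
Clade structure is imposed by seeding three deeply divergent founder
haplotypes (40 substitutions each from a common ancestor over 1445 sites),
so clade labels are exact truth; per-site Dirichlet clade weights create
the clustered, non-random clade-by-site pattern the binomial tests detect.
A fruiting body is single-founder with probability 0.82 (the observed
fraction of genetically homogeneous multi-clone fruiting bodies); otherwise
two distinct founders are drawn.

Paper-stated quantities are defaults verbatim: founder clonality 0.82,
recombination/mutation ratio 0.26, tract mean 12 nt, observer error 0.02
(three disagreements in 150 assays), the 3⁵ design truncated to 147
isolates (random clone dropout, never emptying a fruiting body), five loci
summing to 1445 bp. Migration probabilities, pool sizes and per-level
mutation means are stated nowhere; they were fixed once from closed-form
sharing algebra so that expected ST-identity decays roughly as 1 → 0.6 →
0.2 → ~0 → 0 across the five scales, and are documented in
`LandscapeConfig`/`EvolutionConfig`. With all migration probabilities at 1
every clone draws i.i.d. from the regional pool and the decay curve is flat
(panmixia control); with migrations at 0 and mutation off the landscape is
monomorphic.

The kin-discrimination layer draws the true phenotype from a logistic
dose-response in genetic distance, P(KD) = logistic(−3.5 + 350·d) — near
zero at d = 0, saturating within the observed range of between-clade
distances — then flips each of three observer calls independently with
probability ε. The logistic parameters are free defaults chosen for the
qualitative decay shape; no quantitative dose-response exists to estimate
them from. Control plates are emitted with clean zero scores (observers
define alteration relative to those interfaces).

What the simulator does **not** emulate: indel evolution (no gaps are
generated), selection, a true recombination graph or coalescent
genealogies, continuous geography, or the exact missing-data pattern of a
real field campaign. Passing tests on simulated data therefore demonstrate
correctness of the analysis machinery and qualitative recovery of the
generating parameters — not that any particular real dataset will show the
same numbers.

## Validation problem sizes

The test battery runs entirely on generated data and small closed forms:
brute-force π/distance oracles on toys of up to 20 sequences; exact 4!
Mantel enumeration; Mantel type-I calibration with 1000 null 12×12 matrices
at 99 permutations each (rejection rate must sit within the binomial 95%
interval around 0.05); Tukey HSD frozen against a hand-computed 3-group
dataset and cross-checked against an independent implementation; pair
samplers replayed under fixed seeds and audited by an O(P²) disjointness
scan; and simulator parameter recovery (founder clonality within its
binomial interval over ≥50 fruiting bodies, monotone decay under dispersal
limitation, flat decay under panmixia with 18 pairs per scale). These sizes
were chosen to make each check statistically meaningful while keeping the
default suite fast.

## Known limitations

- The pair sampler guarantees a valid independent pair set, not a uniform
  draw over all valid sets; inclusion frequencies are approximately but not
  exactly uniform across equally eligible isolates.
- Tukey HSD assumes homoscedastic groups; proportions near 0 or 1 violate
  this mildly, and no variance-stabilising transform is applied by default
  (a deliberate mirroring of common practice for this analysis).
- The nearest-ST expectation conditions on the observed site ST-counts; the
  permutation alternative is reported because the analytic expectation is
  one of several reasonable nulls.
- π on gapped alignments depends on the deletion mode; reproducing
  third-party values may require toggling `site_handling`.
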