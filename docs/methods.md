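# Methods

This note documents the models and numerical choices behind `magicmap`,
what the synthetic-data generator does and does not emulate, and the
design decisions taken where the problem left room.

## Crossing design and pedigree

A funnel is the balanced 3-generation crossing tree over the eight
founders. Equivalence classes under the 128-element tree-symmetry group
(swapping the parents of any cross) are enumerated exhaustively from the
8! orderings; there are 315. The pedigree generator realizes each funnel
with a uniformly random maternal/paternal orientation at every internal
node: the historical cross directions are not part of the design, and a
fixed canonical orientation would make parental roles degenerate (some
founders would never be an all-maternal contribution, emptying the
sex-effect scan's subsets). `reciprocal_fraction` is the probability that
an individual G3 cross is performed in the reciprocal direction relative
to its funnel's orientation.

Each RIL lineage receives its own G2 individuals. A G1 plant's genome is
determined by its inbred parents, so G1 individuals are shared; a G2
plant's genome is one realized pair of gametes, and sharing it across a
funnel's lines would collapse the funnel to roughly four founders. With
fresh G2 individuals the forward simulation matches the exact two-locus
dynamic program cell by cell (checked against 20,000 simulated lines).

Advanced-intercross (AIC) generations pair lines from different funnels
uniformly at random, preferring pairs with disjoint funnel ancestry; the
mating scheme beyond "different funnels" is our abstraction, as is
`lines_per_funnel`.

## Meiosis and heterozygosity

Meiosis is Haldane: crossover counts Poisson(length/100), positions
uniform, no interference, starting haplotype fair. This matches the
Haldane map function used for every distance conversion downstream; no
interference model is imposed anywhere else, so the simulator and the
estimators are mutually consistent.

Expected residual IBD heterozygosity is h0 * 2^-s after s selfing
generations. Funnel offspring are heterozygous everywhere (their gametes
come from founder-disjoint 4-way parents), so h0 = 1 for MP8RIL and
5 selfings give 2^-5 = 0.03125. An intercrossed line's two gametes each
carry an approximately independent uniform founder, so h0 = 7/8 and the
expectation is 0.02734 — the generator reproduces both within Monte-Carlo
error, and the Viterbi-imputed value sits *below* the expectation on
biallelic panels because heterozygous stretches between founders that
share marker alleles are invisible.

## Exact two-locus distributions

The joint distribution of ordered founder-labelled gametes at two loci
separated by meiotic recombination fraction r is propagated generation by
generation: a gamete is one of 64 (founder at locus 1, founder at
locus 2) pairs, a diploid is an ordered gamete pair, and each meiosis
applies the 4-outcome recombination kernel. Crossing takes the outer
product of two parents' gamete distributions; selfing couples the two
offspring gametes through the same parent. No Monte Carlo is involved.

Two conditioning modes exist. *Funnel-conditional* distributions take the
canonical funnel (founder k in role k); any actual funnel follows by
relabelling. The *funnel-averaged* (exchangeable) distribution marginalizes
over a uniformly random funnel, which reduces to averaging over the 15
equality patterns of the label 4-tuple. Since the generator assigns
funnels uniformly, the funnel-averaged likelihood is the exact marginal
likelihood of a random line, and it is the package default: it admits a
vectorized estimation path whose per-pair cost is a 3x3 count table.
Funnel-conditional estimation is available (`funnels=` argument) and
agrees on recovery tests. One visible consequence of averaging: at r = 0.5
the joint factorizes *conditionally* on the funnel but not marginally — a
heterozygous state retains a trace of funnel information — so unlinked
transition rows for heterozygous states differ from the stationary
distribution by O(10^-3).

Recombination fractions are estimated by grid maximum likelihood over 61
equally spaced values on [0, 0.5] (step 1/120; the grid size is fixed, the
spacing is our choice), ties broken toward smaller r, missing calls
contributing nothing, heterozygote calls forming their own observable
class. For all-biallelic panels the class table depends on the two
founder-allele maps only through (k1, k2, overlap), so tables are cached
per signature and the matrix path reduces to nine matrix products for the
count tables. Memory for an m-marker matrix is O(m^2); desk scale is
~2,000 markers.

Distortion weights: carriers of an over-transmitted allele are
down-weighted by (target(1-q)) / ((1-target) q) within each subpopulation
(q = observed carrier frequency, target = 1/8), normalized to mean weight
1, which restores the weighted carrier frequency exactly and reduces RF
bias across a drive locus.

## Genotype calling

Intensities are converted to theta = (2/pi) atan2(y, x) and r = x + y.
The mixture caller is a MAP-EM fit of three truncated Gaussians on theta
(two homozygote components and one heterozygote component between them)
with a Dirichlet prior that inflates the heterozygote weight — the
deliberately aggressive heterozygote calling the pipeline wants — plus a
per-marker null filter (r below 0.3x the median). Flags: non-convergence
(iteration cap), heterozygote rate above 0.06, monomorphic (minor
homozygote weight below 0.02 or centers closer than 0.2), and
multiallelic (four or more gap-separated theta clusters), the latter
re-called with DBSCAN on (theta, scaled r), which recovers any number of
marker alleles but no heterozygotes. The two-pass panel procedure drops
monomorphic markers and lines whose mean posterior uncertainty
(1 - assigned-class posterior, averaged over non-missing calls) exceeds
0.05, then re-fits. We deliberately do not define line error as
disagreement with a per-marker consensus: in a segregating population the
minor genotype class disagrees with any consensus, and such a rule would
remove most lines.

The duplicated-marker model mixes the allele-1 dosages of two genomic
locations with unequal hybridization weight (2/3 : 1/3), producing four or
more visible theta clusters when both locations segregate — the signature
by which multi-locus markers are flagged and diverted to DBSCAN.

## Map construction

Linkage groups: average-linkage hierarchical clustering of the RF matrix
(missing entries treated as unlinked, 0.5), cut into many initial groups
(ties at equal merge heights are split deterministically so the requested
count is honoured), then automatic aggregation merging group pairs whose
median inter-group RF is below 0.35 — an automated replacement for what is
otherwise a manual curation step. Markers whose median RF to a *different*
group is below the threshold while their group's is not are flagged as
probable duplicated-marker artifacts.

Ordering: the anti-Robinson criterion — entries of the reordered matrix
should increase moving away from the diagonal. The loss sums the
magnitude of violated comparisons between positions up to `band` apart on
the same side of the diagonal. We measured the adjacent-comparison-only
variant and found it noise-dominated on estimated RF matrices: the local
search *worsened* a good coarse order (Kendall tau 0.953 -> 0.928),
because comparisons between effectively unlinked markers are pure noise
while true local signal is small in magnitude. Pooling comparisons over
gaps up to 15 positions makes real misorderings count across many rows,
and the same search then improves the order (tau 0.96-0.97 across seeds);
the full-band loss is worse again (0.94). Band 15 is therefore the
default. The coarse stage seriates ~30 hierarchical subgroups on their
mean-RF matrix (full band; spectral initialization, local search to a
local optimum, orientation canonicalized to the lexicographically smaller
sequence); the fine stage makes only windowed local moves (segment
reversals and single-marker relocations within 12 positions), accepted on
strict loss decrease — deterministic throughout.

Distances: each pair with estimated r <= 0.4 contributes the equation
"sum of spanned gaps = Haldane distance"; gaps are solved by non-negative
least squares (negative gaps are physically meaningless; the 3-marker
worked example, whose solution is interior, is unaffected) and positions
are cumulative sums from 0. Gaps covered by no informative pair fall back
to the adjacent-pair distance with a warning. At moderate sample size the
length is biased *downward* (weakly informative long pairs resolve grid
ties toward smaller r); genotyping error biases it upward. At 1,000 lines
and 100 markers the recovered length is within a few percent of truth.

## IBD imputation

The per-line HMM has 36 states (8 homozygous + 28 heterozygous founder
pairs). Transitions between adjacent loci at distance d are the exact
two-locus genotype joint at r(d), conditioned on the first-locus state —
the standard HMM approximation to full multipoint probabilities, accurate
at moderate marker spacing. The funnel-averaged model is shared by all
lines, which lets forward-backward and Viterbi run batched over lines;
heterozygous-state priors carry the design's expected residual
heterozygosity. The error parameter (default 0.1) acts on emissions only:
the call expected under a state's founder alleles receives 1 - e, the
remainder spread uniformly over the other observable classes; missing
calls emit 1 everywhere. Viterbi ties break toward the lowest state
index; a brute-force enumeration over all 36^4 paths on 4-marker instances
confirms path optimality.

On fully informative (founder-unique) markers Viterbi recovers ~99.9% of
marker-locus states; on biallelic panels the ceiling is ~94-95%, set not
by the HMM but by founder ambiguity — two founders sharing alleles at all
nearby markers are indistinguishable there. Haplotype blocks are delimited
at inter-marker midpoints; a state change counts 1 or 2 recombination
events according to how many haplotypes changed founder.

## Distortion scans

All four scans consume per-line IBD probabilities on a 1 cM grid
(linearly interpolated between flanking markers and renormalized).
Heterozygotes are ignored by renormalizing each line's 8 homozygous-state
probabilities; lines with no homozygous mass drop out of that position,
and n_effective is the count of contributing lines. The tables have
non-integer entries (sums of probabilities); the chi-squared reference is
justified by the central limit theorem. Expected cells below 0.5 are
pooled (smallest categories merged per axis, df reduced, with a warning);
zero-margin categories are dropped. Line weights are not applied in scans.

The scans are agnostic to where the probabilities come from; the
calibration and injection studies in the test suite run them on
probabilities derived from the simulator's true mosaics (the crisp limit
of the HMM posteriors), while the neutral-composition benchmark runs the
full intensity -> calling -> HMM path.

## The distortion generator

* `drive` — gametic: when a parent is heterozygous carrier/non-carrier at
  the locus, carrier gametes are transmitted with probability `strength`
  (0.5 = Mendelian), implemented by rejection sampling of whole gametes so
  linkage is preserved. Drive acts in every meiosis, so its effect
  compounds across generations: transmission 0.75 yields final carrier
  excesses far above the single-generation bias, and transmission 1.0
  fixes the founder.
* `sex` — the same bias restricted to maternal (or paternal) meioses.
  During selfing the same plant is both parents, so the biased germline
  still acts in every line; the maternal-only and paternal-only subsets
  differ by the bias accumulated during the mixing generations.
* `funnel` — the bias restricted to meioses of the G1 individual from one
  founder pair, depleting that founder's alleles specifically in the
  corresponding G1-partner group.
* `interaction` — zygotic viability on offspring carrying a specific
  two-locus founder combination. With `stage="all"` the weight applies at
  every cross, with offspring re-drawn from the same parents (as when a
  breeder replaces a failed plant); note that per-generation selection
  compounds into *margin* distortions that an independence test cannot
  see, and that within an inbred lineage already fixed for the combination
  re-drawing is no selection at all. With `stage="final"` carrying lines
  are culled outright — viability selection on the finished inbred lines —
  which is the regime that produces genuine interaction signal. A
  depletion of a single 8x8 cell bounds the df-49 Pearson statistic near
  n/64 regardless of severity, so a detectable incompatibility must
  involve several cells; penalizing one founder's combinations with every
  non-self partner at a second locus (the "rescued by self" pattern,
  matching the empirically observed excess of self-pair combinations)
  reaches p far below 10^-9.5 at ~3,000 lines.

## What the generator does not emulate

Founder marker alleles are i.i.d. Bernoulli(1/2) given polymorphism — no
linkage disequilibrium or ascertainment structure among founders; default
chromosome counts and lengths are small (tests run 1-3 chromosomes of
50-100 cM, 10-200 markers, 300-10,000 lines, sizes chosen as reasonable
desk-scale study conditions); intensity clusters are well-separated
Gaussians, so calling benchmarks bound the pipeline's behaviour on clean
assays, not on the hard tail of real array data; and there is no
genotyping batch structure. Passing tests therefore demonstrate
correctness of the machinery and its statistical calibration under the
stated models, not robustness to every artifact of real intensity data.

## Numerical conventions

Coordinates are cM from 0 at each chromosome start; blocks are closed
intervals; genotype CSVs use NA for missing; all randomness derives from
one root seed through named substreams (identical config + seed =>
byte-identical outputs). Likelihood floors are 1e-300; EM sigma floor
0.015; posteriors renormalized per locus with a floor-and-warn path for
zero-probability observation sequences.
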