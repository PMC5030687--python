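# Methods

This note records the models behind each module, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical conventions. Nothing here states a result the tests or
`scripts/acceptance.py` do not themselves compute.

## The simulator

`simdata` is a forward simulator of two closely related clades, built to
reproduce the *statistical structure* the analyses consume rather than a
mechanistic evolutionary history.

**Genealogy.** Deterministic and ultrametric. Clades split at
`clade_split_depth` (default 0.76 time units). Within a clade,
populations radiate near the clade crown: population joins are placed in
the deepest 40% of the span between the deepest population split and the
crown, so every population keeps a long private stem — the geometry of
populations diverging contemporaneously, and the source of
population-informative variation. Within a population, leaves join in a
caterpillar at evenly spaced depths. Internal nodes carry stable labels
used by the event logs.

**Core sequences.** A single-parameter uniform-exchange substitution
model (all states equally likely as targets): the downstream methods use
counts, not model-based likelihoods, so rate-matrix realism buys
nothing. Per branch the substitution count is Poisson with mean
mu·t·L, with sites inside the hotspot interval multiplied by
`rate_multiplier`. Recombination is applied *post hoc* between leaf
sequences: per donor/recipient category (same population, same clade
different population, different clade) a Poisson number of events, each
copying a geometric-length tract (mean `tract_mean`, uniform start) from
the donor's current sequence, applied in a randomised order that the log
preserves. This suffices to create the mosaic and homoplasy signals the
methods detect; an ancestral-recombination-graph simulator would add
realism none of the analyses can see. Every substitution and tract is
logged, and `replay_core` rebuilds all leaf sequences from the log alone
— the replay oracle used in tests.

**Gene content.** Infinitely-many-genes: gains draw never-before-used
families at copy 1 (Poisson, `gain_rate` per genome per time), losses
zero a family (probability 1−e^(−loss_rate·t) per present family),
duplications increment copy number (Poisson per present family). A
designated block of "region" families, placed inside the hotspot
interval, is then overwritten by per-CT signature vectors (explicit in
the config, not evolved — the observed one-to-one CT correspondence is
the structure to emulate, its mechanism unknown) with a per-gene
presence-flip noise, and an optional `region_transfer` finally replaces
one genome's region content with another CT's exact signature,
reproducing the natural isolate whose region groups with a CT its core
phylogeny contradicts. `replay_gene_content` is the corresponding oracle.

**Default study configuration** (`study_config`): 22 genomes; clade I
(12 genomes, populations p5–p7, crown at 0.076) ten-fold more diverse
than clade V (10 genomes, populations p1–p4, crown at 0.0076);
mu = 0.0038 with a 10-kb hotspot at 4×, so the genome-wide expected
between-clade divergence is 2·0.76·0.0038·1.3 ≈ 0.75%; recombination
200 within-population and 40 between-population events expected, none
between clades; tract mean 1000 sites; 3000 root families, gain 1000,
loss 0.35, duplication 0.05 per time unit, which puts accessory turnover
several-fold above the core substitution rate and reproduces the
declining content/core ratio with distance (loss saturation on deep
branches); 40 region families, signature noise 0.02, 12 phage-tagged
region families versus 8 elsewhere. The recombination counts were
calibrated once so per-pair co-ancestry lands in the observed bands
(roughly 12–25% same population, 5–12% same clade, <0.01% cross-clade).

**Two painting regimes.** A 100-kb core at the natural isolates'
per-site within-clade diversities would carry only a handful of
within-clade SNPs — orders of magnitude less information than the
multi-megabase alignment population inference is designed for, and too
little for any method to resolve seven populations. Analyses therefore
use two regimes of the same structure: the default **barrier regime**
above (low within-clade diversity, under which the painter's
different-clade copying is exactly zero), and a **well-separated regime**
(`well_separated_config`) for population recovery, with within-clade
diversities scaled up five-fold (clade V crown 0.04, the 10-fold I:V
ratio preserved), short population caterpillars (5% of the crown), and
intense short-tract within-population recombination (3200 events, tract
mean 250, twenty-fold the between-population rate). In the well-separated
regime a little cross-clade copying weight (< 1%) appears even with zero
between-clade events: in SNP-sparse windows that happen to contain no
clade-informative site, the nearest-donor rule ties across the clade
boundary. This is an artifact of the simplified painter, not simulated
gene flow, and it is why the barrier quantity is measured in the barrier
regime.

Two further dedicated regimes exist for calibration experiments:
`equal_intensity_config` (no barrier; 12 expected between-clade events
matched to ~12 expected cross-subclade events via the pair-category
geometry, short tracts so each event contributes ≈1 homoplasy, making
the barrier test's proportionality null true by construction) and
`turnover_config` (gain-only gene content at `rate_ratio` times mu·L, so
content differences accumulate exactly linearly; mu and the population
depths put ≥ ~30 differences on even the shallowest independent pair,
keeping the log–log intercept away from low-count leverage points).

## Painting and population inference

Windows are consecutive runs of `window_snps` SNP columns (default 10;
the last window may be smaller and is weighted by its SNP count).
"Proportion of genome" is SNP-weighted throughout: monomorphic stretches
carry no donor information. Ties split window weight equally among
equidistant donors — unbiased, and the reason co-ancestry rows are exactly
row-stochastic. This is deliberately *not* a copying-model HMM with MCMC
population assignment: the nearest-donor rule preserves the quantity the
analyses interpret (who copies how much from whom) while being exactly
checkable against a brute-force oracle.

Clustering: average-linkage on Euclidean distances between co-ancestry
rows, dropping both genomes' own columns for each pair so the structural
zero diagonal cannot inflate distances; K maximises the mean silhouette
over 2..10 (ties to the smaller K); identical rows short-circuit to K=1
with a warning. Confidence: B window bootstraps (resample windows with
replacement, rebuild the matrix from cached per-window donor weights,
recluster with the same K selection); a genome's confidence is the mean
fraction of its point-estimate co-members assigned with it; genomes in
singleton populations have no co-members and score 1 by convention.

## Homoplasy and the barrier test

Sites are biallelic by default; multiallelic sites are excluded (counted
separately on request). A site is homoplasic iff its Fitch length on the
given tree is ≥ 2; the Fitch kernel is vectorised over sites with state
bitmasks. Classification is polarised where ancestral states are known
(the simulator's root sequence; on real data an outgroup reference): a
site is between-clade iff a *derived* allele is carried in both clades,
and within-clade cross-subclade iff a derived allele sits in one clade,
touches both subclades, and is a minority (≤ half) in at least one of
them. The minority guard excludes clade-wide alleles with a single
reversion hole, which span both subclades at near-consensus without
witnessing any cross-subclade transfer. Without ancestral information
the minor-allele convention is used instead, with the caveat that a
transferred clade-consensus allele leaves the minor allele confined to
the untouched clade and is then invisible.

The barrier test is this package's formalisation of a verbal
proportionality argument: under equal recombination intensity across
versus within clades, homoplasy counts scale with the divergence of the
sequences exchanged, so conditional on N = n_between + n_within,
n_between ~ Binomial(N, R/(1+R)) with R the divergence ratio; the
one-sided lower tail is reported. The binomial treats homoplasies as
independent, which tract-induced clumping violates when tracts are long;
with the study-scale tract of ~1000 sites a between-clade event carries
several homoplasic sites at once, so p-values under the null are
conservative-to-noisy rather than exactly uniform. In the pipeline R is
estimated from the data as the ratio of mean between-clade to mean
cross-subclade per-site divergence, with subclades taken from the two
sides of the focal clade's MRCA split on the midpoint-rooted tree.

## Trees

Neighbor joining is the standard Saitou–Nei algorithm; negative branch
estimates are clamped to zero with the deficit moved onto the sibling
branch so the joined pair's path length is conserved. It replaces
maximum-likelihood inference deliberately: downstream analyses need a
reasonable topology, not model-based branch lengths. Parsimony search is
stepwise addition in input order followed by nearest-neighbor-interchange
hill climbing, ties to the first candidate in a fixed edge ordering —
deterministic for a given input, which matters more here than escape
from rare local optima. Bootstrap support resamples characters with
replacement and reports the percentage of replicate trees containing
each internal bipartition of the point tree; branches under 50 can be
collapsed (`collapse_low_support`). Sequential Fitch over polytomous
nodes is an upper bound; search trees are always binary.

## Gene content

Gene-content distance counts families whose copy numbers differ,
including 0 versus ≥ 1. Independent pairs are chosen greedily: the
closest (patristic) unpaired pair whose connecting path is edge-disjoint
from all accepted paths; on the simulator's 22-leaf genealogy this gives
11 pairs, though on inference trees with near-zero internal branches the
greedy order can fall short of a perfect pairing. Zero-count pairs are
excluded from the log–log fit rather than pseudocounted (a `pseudocount`
flag adds 1 everywhere instead); the rate ratio is reported as
10^intercept with its definition attached, since it is literally the
fitted content difference at one core difference. Fluidity uses presence
(copy ≥ 1) only, per its definition. The pan-genome curve enumerates all
genome orders exactly when n! ≤ P, otherwise averages P seeded
permutations; means are non-decreasing by construction.

Under the default study regime fluidity comes out near 0.2 rather than
the few percent typical of very close isolates: half of all genome pairs
in the 22-genome sample span the deep clade split, and the simulator's
turnover rates — chosen to keep accessory change well above core change
— put proportionally many unique families on those paths. The analyses
never consume φ as an input, so this is a presentation difference, not a
calibration error.

## Region scan and CT concordance

Windows of 10 kb at 1 kb step by default (exposed); the final partial
window is normalised by its true width; regions are maximal merges of
windows above mean + 3 SD (zero variance ⇒ no regions). Reports use
1-based inclusive coordinates, BED stays 0-based half-open, and all
internal arithmetic is 0-based half-open.

Concordance partitions genomes by identical copy-number profile over the
region's families and scores it against CT labels with the adjusted Rand
index — exact-profile identity, so signature noise fragments groups and
lowers ARI even when the parsimony tree still recovers every CT as
monophyletic; both views are reported. A genome is flagged incongruent
when its region group (size ≥ 2) has a majority CT different from the CT
of its nearest core-tree neighbours — the signature of a horizontally
acquired region, and the criterion that flags the bundled
region-transfer genome. Enrichment is the one-sided hypergeometric tail
(Fisher's exact for a 2×2), with a Haldane 0.5 correction on zero cells
for the odds ratio only.

## Seeds, determinism, sizes

All randomness flows through numpy Generators seeded from a single
config seed plus fixed per-stage offsets, so any stage can be re-run in
isolation and identical configs give byte-identical outputs (asserted in
tests). Default problem sizes — 100-kb cores, 22 genomes, 100
bootstraps, 20-replicate calibration experiments, 25-kb cores for the
turnover regime — keep any single analysis under a few minutes on one
CPU while leaving every statistic comfortably estimable; they are
deliberate downscalings of a multi-megabase study design, and the
two-regime split above is the one place where the downscaling forced a
methodological accommodation.

## Known limitations

* The painter has no linkage model: window boundaries are SNP-count
  based, donors are chosen per window independently, and sparse windows
  can tie across deep splits (see the regime discussion).
* Post-hoc recombination at the leaves means tracts never accumulate
  subsequent mutations; real tract edges decay with age.
* The homoplasy classifier's minority guard is ambiguous for subclades
  of two members (half the subclade is both "minority" and "hole").
* CT signatures are assigned, not evolved, so the region tree's branch
  lengths carry no temporal meaning; only its groupings are interpreted.
* The pipeline's unpolarised (minor-allele) homoplasy mode undercounts
  between-clade transfers of clade-consensus alleles; supply an
  outgroup-derived ancestral map where possible.
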