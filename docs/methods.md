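# Methods

`assemblage` implements six null-model frameworks used to disentangle
stochastic from deterministic assembly in microbial (16S amplicon)
communities, plus a synthetic community generator that produces datasets
under known assembly regimes so that every inference can be validated by
regime recovery.  This note records the models as implemented, the tunable
parameters and their defaults, the generator's assumptions, and the
numerical choices made where the published descriptions of these methods
leave the details open.

## Data model

All models operate on a samples × ASVs integer count matrix with per-sample
metadata (treatment group, day, replicate), per-ASV taxonomy strings, and a
rooted phylogeny with branch lengths whose tips are the ASVs.  Counts are
integers because every null model populates randomized samples with
*reads*; a non-integer cell is rejected at validation.  Samples with zero
total are dropped with a warning rather than rejected, which keeps
partially failed replicates from invalidating a whole run.  Taxonomy
strings are split on semicolons; the genus is the 6th rank when present,
else the last non-empty rank, else `unclassified`.

Faith PD is root-inclusive everywhere: the PD of a taxon set is the total
branch length of the union of its root-to-tip paths.  The convention only
affects absolute PD values, never the differences and gains the dispersion
model works with.

## The shared randomization scheme

Four of the models (NST, Hill null, beta-null deviation, Raup–Crick) build
null samples the same way, which this package implements once: a null
version of a sample keeps its observed total read count, draws its taxon
identities without replacement with probability proportional to each
taxon's *occurrence frequency* (the fraction of samples in the analysis
pool containing it), and distributes the reads over the drawn taxa
multinomially in proportion to their *regional relative abundances*, with
one read guaranteed per drawn taxon so the richness constraint holds
exactly.  Under the PF (proportional–fixed) constraint the null richness
equals the observed richness; under PP (proportional–proportional) it is
binomial with mean equal to the observed richness — the published
description names the constraint family but not the PP randomization, so
the binomial mean-preserving scheme is this package's definition and is
recorded in output metadata.  Null draws are keyed by sample id, so all
null-based scores are invariant to the order samples appear in the table.

Reads are filled in proportion to regional abundance rather than uniformly
because the NST literature describes abundance-proportional null draws;
uniform filling is available as a flag on the Hill null.

## The six models

**NST.**  For each within-group sample pair, observed similarity C = 1 − d
(Jaccard or Ružička) is compared with the null expectation E (mean over
1,000 randomizations).  The normalized selection strength is
(C − E)/(1 − E) when the pair is more similar than expected and
(E − C)/E when less similar — i.e. the deviation divided by its maximum
attainable magnitude — and the pair's stochasticity ratio is its
complement.  NST is the mean over pairs: 0 is fully deterministic, 1
(100%) fully stochastic.  The exact published normalization is not printed
in the study this package follows; the endpoint semantics above are the
contract.  Groups below 6 replicates trigger a precision warning.  A pair
whose null expectation is exactly 0 or 1 cannot be normalized and is
skipped with a warning.

**Hill-number null.**  The pairwise dissimilarity qd of order q is
beta/alpha − 1 for two equally weighted samples (gamma = Hill diversity of
the pooled mean vector; alpha = Hill alpha over the halved within-sample
proportions), the effective proportion of unshared ASVs, in [0, 1].
Observed mean qd over consecutive-day pairs is compared against 999
randomizations in which both pair members are replaced by null samples;
observed within the null spread reads as stochastic turnover, above as
deterministic divergence, below as deterministic convergence.  The default
q grid is 0 to 2 in steps of 0.1; equal sample weights are used (read-count
weights were not specified in the source and are configurable).

**Beta-null deviation.**  deviation(pair) = observed beta − mean(null beta)
with Bray–Curtis or generalized UniFrac (default α = 0.5; α is not named in
the study, 0.5 is the common "generalized" setting).  The null preserves
per-sample richness and total (the PF constraint family) because the
original individual-based scheme is not printed in the study; the
constraint choice is recorded in output metadata.  Trajectories are means ±
sd over within-(group, day) replicate pairs.  Note that data simulated as
*multinomial draws from a shared pool* score slightly negative (observed
replicates are a little more similar than occurrence-frequency nulls);
data generated by the null process itself score zero, which is the
self-consistency test the suite runs.

**QPE.**  βMNTD is the abundance-weighted mean nearest-taxon patristic
distance between two samples; a taxon present in both has nearest-taxon
distance 0.  βNTI standardizes the observed βMNTD against a taxa-shuffle
null: one tip-label permutation of the whole harmonized tree per replicate,
shared across all pairs of a group.  βNTI > +2 → variable selection,
< −2 → homogeneous selection; remaining pairs go to Raup–Crick on
Bray–Curtis (RC = tie-corrected fraction of null dissimilarities below
observed, scaled to [−1, 1]): RC > +0.95 → dispersal limitation,
RC < −0.95 → homogenizing dispersal, else undominated.  The ±0.95 cutoffs
follow the framework the study cites and are configuration constants
surfaced in output metadata.  A pair with identical taxon supports has
βMNTD = 0 under *every* permutation — its null collapses.  The single-pair
API raises on such degenerate pairs; group-level classification logs them
and lets the Raup–Crick step decide, since a collapsed null is the absence
of phylogenetic evidence, not evidence of selection.

**Competitive lottery.**  ASVs are grouped by genus; groups are dropped
when total reads < 5,000, overall relative abundance < 0.05%, or members
< 3 (each rule independently configurable — the published filter sentence
conflates them).  In each sample where the group occurs, the winner is the
member holding > 90% of the group's reads (unique for any threshold
> 0.5).  Winner prevalence is the fraction of qualifying samples with a
winner; its null is the broken stick (n − 1 uniform cuts of the unit
interval), whose per-sample win probability has the closed form
n(1 − x)^(n−1) for threshold x ≥ ½.  Winner diversity is the Shannon
entropy of the winner-identity distribution, reported both normalized by
ln(group size) and as an effective number exp(H): the two conventions
disagree in the literature this follows (a constant winner is "0" under
one and "1" under the other), so both are emitted rather than silently
reconciling them.

**Phylogenetic dispersion.**  Per group, the detected set at day t is the
union of ASVs seen in any replicate at any day ≤ t; the observed curve is
its cumulative Faith PD.  The forward model recruits candidates one at a
time with probability ∝ logistic(D · z_s), where z_s is the PD gain of
candidate s standardized over the current candidate pool (keeping D
scale-comparable across steps and groups).  D > 0 prefers phylogenetically
novel recruits (overdispersion), D < 0 close relatives (underdispersion),
D = 0 is uniform recruitment — which is exactly the surrogate null (500
surrogates by default, preserving the observed day-0 detected set and the
observed number of new recruits per day).  The published description of
this model states its inputs, the surrogate count, the logistic error
model, and the sign semantics, but not the functional form; the
logistic-weighted PD-gain model above is this package's definition, and
only the sign/ordering semantics are claimed — no equivalence with any
other estimator.

D is fitted by least squares between the observed curve and the model's
mean curve over common-random-number simulations, on a bracketing grid
(−8 to 8, 33 points) with parabolic refinement; simulations are coupled
across candidate D values so the objective is deterministic given the
seed.  The bootstrap is parametric: single trajectories simulated at the
fitted D are refitted the same way.  A day-resampling bootstrap was
considered and rejected — with only four day transitions it ignores the
dominant noise source (the recruitment events themselves) and produces
intervals far too narrow to cover the truth on neutral data.  A flat
objective across the grid clears the convergence flag.

## The synthetic generator

The generator emulates the microcosm design: 7 treatment groups × 5 days
(0, 3, 7, 14, 28) × 3 replicates at 10,000 reads per sample by default, all
configurable.  Its components:

- **Tree**: random ultrametric tree from successive pair merges with
  exponential waiting times at rate k for k lineages (a Yule-like,
  constant-speciation shape).  Node depths are spread evenly through time,
  as in typical 16S phylogenies.  Kingman-coalescent shapes (rate k(k−1)/2)
  were rejected: their patristic distances are dominated by two deep
  branches, which makes the taxa-shuffle βMNTD null so variable
  (CV ≈ 0.5) that no desk-scale selection signal can reach |βNTI| > 2.
- **Regional SAD**: log-normal, σ = 1.5 — uneven enough for a realistic
  rare tail while keeping the effective richness of desk-scale pools
  (50–400 taxa) meaningful.  At σ = 2 a 50-taxon pool collapses to ~10
  effective taxa and occurrence-frequency nulls become uninformative.
- **Selection trait**: Brownian motion along the tree, optionally with
  Pagel's δ depth transform (δ < 1 concentrates divergence near the root =
  niche conservatism).  Regime scenarios that must express phylogenetically
  clustered selection use δ = 0.3.  The homogeneous-selection optimum
  defaults to the regionally dominant taxon's trait — an occupied niche —
  rather than the trait median, which can fall between clade clusters.
- **Drift**: two forms, both off by default so that the *neutral* regime is
  pure multinomial sampling of the regional pool (the notion of
  stochasticity the NST null encodes): log-normal per-sample abundance
  noise (`drift_sigma`) and independent presence thinning (`occupancy`,
  emulating stochastic colonization).
- **Regimes**: neutral (SAD unchanged); homogeneous selection (SAD ×
  Gaussian fitness around one shared optimum); variable selection
  (per-sample optima over a wide gradient, or caller-supplied environment
  values); dispersal limitation (per-sample pools = random subsets of a
  clade partition — singleton clades by default, see below); lottery
  (within designated genus groups, one member boosted to ≥ winner_fraction
  of the group weight, winner redrawn per sample; group weights equalized
  by default so group-level counts are informative at finite depth);
  dispersed recruitment (the time-series generator, sharing the logistic
  PD-gain model with the dispersion fitter).
- **Dispersal pools are phylogenetically unstructured by default.**  Any
  monophyletic pool structure — even two-tip cherries — systematically
  inflates observed nearest-taxon distances relative to the taxa-shuffle
  null (a taxon's missing sister is missing from the same pools), which
  QPE reads as variable selection.  Dispersal limitation in the QPE sense
  (high compositional turnover without phylogenetic turnover) therefore
  requires random taxon pools; the clade size is configurable for users who
  want phylogenetically structured dispersal, with this caveat documented.

What the generator does **not** emulate: sequencing-level artifacts
(chimeras, PCR bias, variable library sizes), taxon interactions,
temporal autocorrelation within regimes other than the recruitment model,
and real taxonomies.  Passing regime-recovery tests therefore shows that
each model detects its target signal under clean conditions at desk scale;
it does not certify behavior on real amplicon data with confounded signals.

## Consensus verdicts

The orchestrator (`assemblage.report.run_all`) reduces each model's numbers
to one qualitative verdict per treatment group, always carrying the
underlying value: NST above/below 0.5; Hill "stochastic" when ≥ 80% of the
q grid lies within two null standard deviations; beta-null "neutral" when
the mean deviation is within ±0.05 (a pragmatic effect-size cutoff — pure
multinomial sampling alone produces small negative deviations); QPE's
modal category; lottery "winners present" only for genera that both exceed
the broken-stick 97.5th percentile *and* have normalized winner diversity
> 0.25 (a constant winner is dominance, not a lottery); dispersion by
whether the parametric-bootstrap central 95% interval covers 0.

## Problem sizes and randomization counts

The validation suite and the acceptance script scale the published
randomization counts to desk-size problems: NST runs at the full 1,000
randomizations (50 taxa × 9 samples); βNTI/RC classification at 99–199
null draws per pair (from 999); dispersion fits at 100 surrogates (from
500) with 10–100 bootstrap refits.  The analysis drivers under `analysis/`
run closer to the published counts (999 randomizations, 500 surrogates) on
the full 105-sample design.  Regime-recovery scenarios and their
parameters (pool sizes 50–400 taxa, depths 500–20,000 reads, niche widths
0.2–0.3 trait units against a tree of height ≈ 1) are fixed in the tests
and stated there; they were chosen so each regime expresses the signature
its model is designed to detect, and are not re-tuned per run.

## Known limitations

- The NST normalization is this package's fixed definition of the cited
  ratio; only the 0%/100% endpoint semantics are guaranteed to match other
  implementations.
- βNTI needs samples to occupy a modest fraction of the regional pool;
  with near-saturated tables the null degenerates (handled, see above) or
  loses power.
- The Raup–Crick null re-estimates occurrence frequencies from the table
  it is given; with very few samples this estimate is noisy and RC
  acquires a small positive bias.
- The dispersion estimator shrinks |D̂| toward zero for large |D| (the PD
  curve saturates); sign and ordering are reliable, magnitudes are not
  calibrated.
- Between-group significance testing (PANOVA, ANOVA/Tukey, t-tests) is
  deliberately out of scope; per-pair tables are exported for external
  statistical routines.
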