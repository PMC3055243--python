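# Methods

`xyconv` detects, delimits, orients and dates ectopic gene conversion
between X- and Y-linked homologous regions (gametologs) from a multi-species
alignment, and ships a forward simulator that makes every stage of the
pipeline testable against known truth. This note records the model, the
parameters that matter, and the design choices made where more than one
reasonable option existed.

## The inference model

A sex-chromosome stratum stops recombining at some time T_s; from then on
the X and Y copies diverge clock-like at chromosome-specific rates r_X and
r_Y (Y faster, male mutation bias). Two observable signatures follow:

1. **Backdrop**: in unconverted sequence the X–Y per-site difference
   (p-distance, uncorrected) is roughly constant across the region —
   ~10% for a stratum that arrested ~47 Myr ago at
   r_X + r_Y ≈ 2.2 × 10⁻⁹/site/yr.
2. **Conversion tracts**: an ectopic conversion copies a donor tract over
   the recipient, resetting local X–Y divergence to zero at the event time.
   In a gene tree built from such a tract, the converted species' (or
   clade's) X and Y sequences become each other's closest relatives
   ("species pairing") instead of joining their own chromosome's clade
   ("reciprocal monophyly").

The pipeline slides windows across the alignment, builds a
neighbor-joining tree per window from complete-deletion p-distances,
bootstraps it by resampling columns, classifies the topology, merges
windows of identical signature into sub-regions, places the minimal set of
conversion events on a time-calibrated species tree, orients each event
with outgroup-polarized diagnostic sites, and converts coalescence depths
into absolute times with fossil-calibrated substitution rates.

## Topology classification

Each window's tree is searched for *conversion clades*: clades whose leaf
set is exactly the union of complete X+Y sets of some species group S.
A single-species clade (a cherry when one allele per chromosome is
sampled) is a terminal-branch event; a multi-species clade that does not
decompose into per-species clades joined by speciation indicates an event
on the stem branch of S. Nested clades each count — a recent
species-specific event sitting inside an older multi-species one yields
two groups (this is how a conversion-on-conversion is represented).
Multi-species clades require a root; the classifier roots at an outgroup
leaf, auto-detected as any taxon whose species lacks one of the two
chromosomes (e.g. a New World monkey KALX with no Y available). Without
an outgroup only cherries — which are rooting-free bipartitions — are
detectable, and the classifier says so only implicitly by finding fewer
groups; analyses of deep multi-species events should always include an
outgroup.

Reciprocal monophyly is judged on *all* X-labelled leaves (the outgroup X
included, since under no conversion it is simply the deepest member of the
X genealogy) versus all Y-labelled leaves.

Every deciding edge must reach the bootstrap support threshold
(default 70%). If any deciding edge falls below it the window is called
UNRESOLVED rather than given a partial signature: segmentation merges on
exact signature identity, and a half-confident window would otherwise
split a sub-region in two and double-count its events. UNRESOLVED runs
are absorbed into the flanking sub-region with which they share more
columns (ties to the left).

## Event mapping

Per sub-region, each detected group S maps onto the species tree: the
candidate branches are those whose descendant sets lie inside S (an event
on a branch implies pairing in *all* its descendants), and because branch
descendant sets are laminar the maximal candidates form the unique
minimum cover. A species inside a multi-species group whose own X–Y
divergence is below `nesting_factor` (default 0.5) times the median of
its co-members' receives an additional terminal-branch event — the
fallback route for a nested recent event whose cherry the bootstrap did
not resolve. Events in adjacent sub-regions on the same branch are not
merged: each sub-region is independent evidence, which is also how the
study system's event count is meant to be read ("at least" so many).

## Direction

At sites where the unconverted reference species' X and Y groups are each
unanimous but differ, and an outgroup sequence matches one of the two
states, the non-matching state is a derived substitution on one
chromosome's lineage. If the converted pair carries the Y-derived state
the site votes Y→X; the X-derived state votes X→Y. A call needs at least
`min_votes` (3) informative sites and a strict majority. Sites where the
pair carries the ancestral state are uninformative (the substitution may
postdate the conversion) and are not counted. Note the inherent limit:
for an event stacked on an older conversion, polarization reads the
deepest donor lineage — the simulator's ten-event scenario plants its
nested event with the direction that is actually recoverable.

## Dating

d_X and d_Y are the mean tree-path lengths from the calibration-split
node to the X and Y tips respectively, computed on the NJ tree of an
unconverted region (the operation refuses a region where the chromosome
clades are not monophyletic). Dividing by the split age (default:
rhesus–hominoid at 30 Myr, configurable) gives absolute rates. An event's
age is bracketed by two clock readings of the same coalescence: t_X =
b_X/r_X and t_Y = b_Y/r_Y, where b_X and b_Y are the mean depths from the
converted clade's X–Y coalescent node to its X and Y tips; the pair
(min, max) is reported rather than pooled, because the two chromosomes
are independent clocks of unequal rate and their disagreement is the
honest uncertainty statement. Estimates are clipped to the carrying
branch's existence interval (clipping logged). All ± values are
site-bootstrap standard errors (columns resampled with replacement,
default 200 replicates, seeded); the underlying study reports errors
without naming a method, and the bootstrap is the defensible default.
Raw p-distances are used throughout (no multiple-hit correction), which
biases deep estimates slightly downward — at 25 Myr of X–Y divergence the
compression is ~4%, well inside the bootstrap error at the alignment
sizes involved.

Whether divergence should be read from tree paths or from averaged
pairwise distances is genuinely open; tree paths are the default because
they share column sets across all pairs (complete deletion), and the
pairwise route is available via `distance_matrix` directly.

## Breakpoint localization

For an interval known to contain at most one reciprocal-monophyly →
species-pairing switch, each candidate column c is scored by the
bootstrap support of the X|Y edge on the columns just left of c plus the
mean support of the pairing clades just right of c. The two sides are
capped at `flank` (600) columns: on full half-segments whichever pattern
dominates the interval saturates both scores and the profile loses its
peak entirely. Near the true boundary both local supports saturate, so
the maximum is a plateau roughly symmetric about the switch; the estimate
is the plateau midpoint (within 5 support points of the maximum), with
exact ties resolved to the smallest column. No-switch inputs are flagged
when the two end flanks classify identically or the interior profile is
flat (range < 5 points).

## Tract finder

A very recent conversion appears as a maximal gap-free run where one X
allele is identical to a Y allele. A run is reported only if it spans
`min_tract` (50) columns and contains at least one diagnostic site —
a column where all other X alleles share one state and all Y alleles
another — at which the focal allele carries the Y state; identity without
polarization is indistinguishable from chance. Gaps break runs (indel
homoplasy is not modelled). The null probability that all n diagnostic
sites converged independently is per_site_match_prob^n, with the match
probability defaulting to the focal-vs-donor p-distance outside the run
divided by 3 (a random substitution hits the donor's base one time in
three). This formalizes the verbal recurrent-substitution argument rather
than a phylogenetic likelihood; the simulator provides the empirical
calibration (FWER at p < 0.01 stays ≤ 5% under realistic allele
diversity, θ = 0.002).

## The simulator

`synthsim` evolves a uniform-random root sequence along a time-calibrated
species tree under exact Jukes–Cantor transition kernels:
P(change over t) = (3/4)(1 − e^(−(4/3)rt)), so the expected X–Y
p-distance at stratum age T is (3/4)(1 − e^(−(4/3)(r_X+r_Y)T)) in closed
form and the simulator can be checked against arithmetic. At
`stratum_age_myr` each lineage's sequence forks into X and Y copies
evolving at r_X and r_Y; a stratum older than the species root forks on
the stem. Conversions are instantaneous whole-tract copies at a stated
time on a stated branch (no mismatch-repair mosaicism — the analysis
reads block-wise signals and gains nothing from within-tract structure);
deletions write gaps that descendants inherit; a conversion whose donor
tract was previously deleted is an error. Within-species allele pairs are
approximated by evolving each sampled allele an extra Exp(θ/2r) years —
deliberately not a coalescent within species, which matters only for the
tract-finder null and is calibrated there empirically. Times are Myr,
rates substitutions/site/year, and the 10⁶ conversion lives in one
constant.

Defaults mirror the study system: catarrhine species tree with tip ages
6/8/18/30 Myr plus a New World monkey at 40 Myr (X sampled only),
stratum age 47 Myr, r_X = 0.78 × 10⁻⁹ and r_Y = 1.45 × 10⁻⁹ /site/yr,
giving the ~0.10 backdrop.

The canned scenarios (`make_paper_fixture`) reproduce the qualitative
structure of the study's figures. The ten-event scenario uses seven 4-kb
sub-regions scanned with 2-kb non-overlapping windows, with event times
chosen so that every deciding edge carries ≥ 10 expected substitutions
per window — a fixture meant to verify the machinery, not to probe its
detection floor (the floor is exercised separately: a 3-kb tract scanned
with the 500/400 overlapping geometry must pair exactly the overlapping
windows ± 1). What passing these tests does *not* show: performance under
alignment error, indel-rich Sanger data, rate variation across sites, or
ancestral polymorphism — none of which the simulator emulates.

## Problem sizes and numerics

Simulated alignments are 2–28 kb; scans use 100-replicate bootstraps and
dating/divergence use 200; the figure-legend values (500/1000 replicates)
remain the CLI defaults. NJ ties on the Q criterion break to the
lexicographically smallest node-id pair; negative limb estimates clamp to
zero. Bootstrap resampling draws multinomial column weights over the
complete-deletion column set. The ultrametricity check on species trees
tolerates 10⁻³ relative depth spread. Windows with fewer complete
columns than `min_valid_sites` (default: half the window) are emitted as
UNRESOLVED so the window grid stays regular; a final partial window is
kept iff it clears the same threshold.

## Known limitations

- Topology-based detection cannot see conversions older than the next
  speciation on the same branch when the donor edge is shorter than a few
  substitutions per window; "at least N events" is the right reading.
- Direction inference reads the deepest donor lineage for stacked events.
- A stem conversion above the basal ingroup split is only detectable with
  two outgroup levels; with one outgroup it is confounded with the
  no-conversion topology.
- p-distances are uncorrected; dates beyond ~30 Myr compress noticeably.
- The tract-finder null is an independence product, not a genealogy-aware
  likelihood.
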