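# Methods

## Data model

The analysis operates on a rooted cladogram whose tips are genera or named
clades, paired with a character census. Branch lengths are accepted on
input but ignored everywhere: the tree conveys relationships only, and no
operation depends on rates or ages. Tips carry a described-species count
(`species_count`), so clade richness is a sum over tips; taxa without a
cladogram position (*incertae sedis*) are stored as `placed=false` rows
that never enter tree-based comparisons but do count in faunal tallies.

Binary traits are tri-state (`true`/`false`/`unknown`); `unknown` maps to
the full state set {0, 1} in parsimony and is rejected by the sister-pair
extractor, which needs fully resolved tips. The branching *pattern*
(`basal`/`distal`) is a separate categorical character because the two
patterns behave differently: basal forks are integrated with the disc and
accompany heavy branching, distal forks sit far out on the arm and
accompany few forks.

### The packaged fixture

The shipped cladogram (34 tips: 1 outgroup, 1 asteronychid, 11 euryalid,
21 gorgonocephalid) is a composite of the published molecular trees for
the order. Within each family, tips not constrained by a published sister
statement are arranged pectinately in census order; every number this
package reports is invariant to that choice because the constrained sister
pairs are exact. The census carries 46 rows (34 placed, 12 unplaced
gorgonocephalids) summing to 196 euryalidan species: Asteronychidae 12,
Euryalidae 84, Gorgonocephalidae 100 (88 placed + 12 unplaced). One known
source inconsistency is left as-is: the family-level literature quotes the
Euryalidae both as 84 and as 86 species; the census column sum (84) is
used throughout. Genus tallies use a `genera_count` column calibrated so
family sums reproduce the published totals (4 + 11 + 33 = 48); the three
census rows that split the genus *Astroceras* across clades count it once.

## Parsimony origin counting

Minimum change counts use the two-state unit-cost dynamic programme over
subtree costs (Fitch counting). On top of the cost table, a second pass
computes the exact range of gains (0→1 changes) across *all* minimum-cost
reconstructions, plus the per-node attainable state sets, without
enumerating reconstructions: for each child and parent state the set of
conditionally optimal child states is recorded, and conditional gain
minima/maxima are combined additively (children are independent given the
parent state, so both endpoints are attained by real MPRs).

Ancestral-state polarisation follows the outgroup: `root_state=0` is
implemented as a phantom stem lineage in state 0 above the root. The root
node may still resolve to the derived state, at the cost of one stem gain.
This convention makes a two-tip tree of derived tips cost one gain (on the
stem) rather than two, which is the biologically sensible reading of "the
ancestral state is 0".

Polytomies are scored as given (hard); soft treatment could only lower
counts, and the packaged tree is fully bifurcating. Costs are unit and
symmetric: the "up to N origins" style of statement refers to counting
gains within equal-cost reconstructions, not to asymmetric penalties.

A subtlety worth stating: the number of maximal derived clades is *not*
bounded by `gains_max`. When ancestral-state tips are rare, a single deep
gain plus several losses can be strictly cheaper than one gain per clade,
so parsimony may report fewer gains than there are derived clades. The
provable relations, which the property tests assert, are
`gains_min ≤ min_changes ≤ #clades` (the one-gain-per-clade assignment is
always feasible) and, for simulated histories, `min_changes ≤` the true
number of transitions on surviving lineages.

## Sister-group comparisons

A *maximal derived clade* is a node all of whose tips carry the derived
state while its parent subtends at least one ancestral-state tip. Its
sister is the union of its parent's other children (flagged when the
parent is a polytomy). Richness is summed over placed tips only, with one
documented exception: when both sides of a comparison are entire families
(the pedicellariae comparison, Gorgonocephalidae vs Euryalidae), the
`include_unplaced_families` option folds unplaced family members into the
sums, matching how family totals are quoted faunistically (100 vs 84
rather than 88 vs 84; the outcome is the same either way). Mixed sisters —
sisters that themselves contain derived tips, as in the *Astracme*-clade
comparison whose sister includes the basketstar *Astrophyton* — are
allowed and flagged rather than triggering nested comparisons.

Comparisons are never pooled across families in the shipped analysis
scopes, because branching and pedicellariae are plausibly non-independent:
every gorgonocephalid basketstar also has pedicellariae, so an order-wide
pool would confound the two characters.

## The sign test

Ties are excluded from *n* (standard practice; the source tables record a
"0" outcome but the accompanying *n* < 5 arithmetic is consistent with
exclusion). The p-value is the exact upper binomial tail computed in
integer arithmetic (`fractions.Fraction`); no approximation is used, since
*n* is tiny by construction. `min_comparisons(α)` returns the smallest *n*
whose unanimous outcome reaches α (5 at α = 0.05, 7 at α = 0.01); results
with fewer informative pairs are *not applicable*, and `significant` is
forced false regardless of the tail. The directional alternative is fixed
as "derived clade more speciose"; a two-tailed variant exists behind a
flag but is off by default.

## Morphology summaries

Fork counts come from literature maxima; a source reporting "at least *n*
forks" is recorded as *n* + 1 with a lower-bound flag. Segment counts to
the first fork are comparable across specimens of any size because arm
segments are added subterminally (Ocular Plate Rule), so the count is
fixed through growth. The basal/distal classifier uses a configurable
threshold, default 10 segments — the bottom of the observed distal range
(10–80); the shipped census uses the explicit per-taxon pattern flags
rather than derived classification. A bimodality validation rule
(basal ⇒ ≥ 8 forks, distal ⇒ ≤ 10 forks, where data exist) can be run
against any species-level table. Per-species fork/segment histograms are
supported as operations and exercised on synthetic cohorts with known
group means; the package does not ship per-species fork data.

## The simulator

A continuous-time binary-state birth–death process: one lineage starts at
t = 0 in the root state; a lineage in state *s* waits Exp(λₛ + μₛ + qₛ)
and then splits, dies, or flips, chosen proportionally to the rates. The
scheme is stated exactly so any implementation drawing the same
exponentials is distribution-identical. Stopping is by elapsed time
(`t_max`) and/or extant-lineage cap (`n_max`); runs are bit-reproducible
from the seed. The returned tree is pruned to surviving lineages with
unary nodes suppressed; transition counts are reported both for the full
history and restricted to lineages with surviving descendants.

`make_richness_table` collapses tips into genus-like records with species
counts drawn from a geometric distribution (support ≥ 1) with
state-dependent means — the simulated analogue of genera aggregating
different numbers of described species. Defaults (mean 2 species per tip,
64–100 tip caps, transition rates 0.15–0.3 per unit time) were chosen to
put replicates in the regime the real data occupy: a handful of
independent origins on a tree of dozens of genus-level tips, so most
replicates yield fewer than the five comparisons the sign test needs. A
500-replicate experiment runs in a few seconds.

What the simulator does *not* emulate: incomplete taxon sampling,
correlated characters (each trait is simulated alone), clade-age
heterogeneity between sisters (sisters are equal-aged by construction, as
the method assumes), or any richness model beyond the geometric. Passing
pipeline tests on synthetic data therefore show internal correctness and
calibration of the procedure, not that the biological conclusions are
robust to those real-data complications.

## Numerical and degenerate-input choices

- Tail probabilities and group means are computed over exact rationals
  and converted to float only for reporting.
- An all-derived scope returns an empty comparison list under a warning
  (no sister exists), and an all-ancestral trait yields cost 0.
- Ties in richness produce outcome `zero`: retained in pair lists and
  table mirrors, excluded from sign-test *n*.
- Extinct simulation replicates return an explicit `extinct` result; the
  pipeline experiment counts them (with monomorphic and all-derived
  trees) as non-significant and tallies them separately.
- JSON reports are deterministic for fixed inputs: sorted keys, no
  timestamps, seeds recorded in provenance.

## Known limitations

- Richness-corrected sister-clade statistics and state-dependent
  diversification models (e.g. likelihood-based trait-dependent
  birth–death inference) are out of scope; the package implements the
  counting procedure faithfully, including its known conservatism.
- The fixed cladogram takes the published conflict resolutions as given;
  ten gorgonocephalid genera remain unplaceable and are excluded from
  comparisons, which is why the within-family origin count is reported as
  a range on this topology (3–4) while broader topological uncertainty
  could widen it (2–4).
- Genus-level tips assume each tip's species are correctly assigned; the
  census records, not the package, carry that risk.
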