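# Methods

`divtime` implements the timing side of diversification analysis on dated
phylogenies: given an ultrametric chronogram (branch lengths in Myr, tips
at age 0) and a classification of its species into biogeographic status
classes — here endemic, non-endemic native, exotic, plus outgroups — it
asks whether a class's splitting events are older or younger than
expected for a random set of species of the same size drawn from the same
tree. The package was designed around the Mediterranean teleost fauna
(a few hundred species, tree height on the order of 100–160 Myr), but
nothing in it is specific to fish.

## Split events and their summaries

The unit of analysis is the *diversification event*: an internal node of
the chronogram induced by a chosen tip set, dated by its node age. The
induced (pruned) tree keeps the original age of every surviving node, so
each event age equals the age of the MRCA, in the full tree, of the
node's descendant kept tips; pruning therefore never invents dates.

A polytomy with k children counts as k−1 events at the same age. This
convention makes the total event weight of any n-tip tree exactly n−1,
whether or not the tree is fully resolved — important because taxonomic
grafting (below) deliberately creates polytomies. Summaries:

* **Median event age** — weighted median with the even-count midpoint
  taken as the mean of the two central values.
* **Histogram** — weights summed in bins [0, w), [w, 2w), … with
  w = 20 Myr by default; the last bin includes its upper edge so the
  root event is never lost and totals are conserved.
* **LTT curve** — lineage count against age, from (root age, root
  degree) down to (0, n tips); nodes sharing an age merge into one step.

Node ages can be read at the point estimate ("mean") or at the lower or
upper bound of each node's credibility interval; the whole analysis is
repeated at the bounds as a sensitivity check on dating uncertainty.

## The randomization test

For a status class with n members the null model draws n tips at random,
without replacement, from the pool (by default all Mediterranean tips,
i.e. outgroups excluded; a pool of all tips is available), computes the
median split age of the induced subtree, and repeats this 1000 times.
The observed class median is compared two-tailed against the central 95%
of the resampled medians: cutoffs are inclusive empirical-CDF quantiles
(the ceil(n·p)-th order statistic at p = α/2 and 1−α/2), and only
values strictly beyond a cutoff are significant — ties count as inside,
which is conservative on the discrete null. Verdicts are
`significant_young`, `significant_old`, or `not_significant`.

Each repetition derives its own generator from (master seed, repetition
index), so results are bit-reproducible and independent of evaluation
order. Rate estimation (birth/death model fitting) is deliberately out
of scope: the question posed is *when* splits happened, not how fast
lineages multiplied, and resampling sidesteps the sampling-fraction
corrections rate estimators need.

## Taxonomic grafting

Species without molecular data are attached to the backbone as
polytomies at the MRCA of increasingly inclusive ranks, in four steps:
(1) ≥2 congeners present → their MRCA; (2) exactly one congener → that
tip's parent (the node joining the congener to its closest relative);
(3) any confamilials → the family's MRCA; (4) any co-ordinals → the
order's MRCA. A single-member rank attaches at that member's parent.
Each species is placed at the first step that succeeds; the grafted tip
gets a branch length equal to the attachment node's age, so the tree
stays ultrametric. Cumulative prefixes of the ladder yield a series of
four chronograms of growing coverage, used to check that timing verdicts
are robust to incomplete sampling.

By default attachment points are computed against the backbone only:
grafted tips never become attachment points, which makes placement
independent of request order. A `sequential` mode, in which each grafted
tip immediately joins the pool, is provided for protocols that escalate
rank by rank over a growing tree; with it, placement depends on request
order by construction. Unplaceable species are reported, not fatal.
Step 1 accepts "at least two" congeners (their joint MRCA); a strict
"exactly two" reading would leave 3+-congener cases to step 2, which is
defined only for a single congener.

## Supermatrix utilities

The block filter classifies each alignment column by the frequency of
its modal non-gap residue over all sequences: > 0.85 highly conserved,
> 0.5 conserved, otherwise nonconserved; columns with more than 50% gaps
('-' or '?') are excluded outright and treated as nonconserved. Runs of
more than 5 consecutive nonconserved columns are excised, surviving
segments are trimmed to begin and end on a highly conserved column, and
segments shorter than 10 columns are dropped. These defaults reproduce
the canonical relaxed filtering setting for multi-locus vertebrate
supermatrices; all five parameters are configurable. Bit-identity with
any particular legacy filtering binary is not claimed — the published
descriptions underdetermine several sub-rules (e.g. iterative flank
re-examination) — but every rule above is enforced exactly and tested.

Concatenation takes the union of taxa across loci, pads absent
taxon-by-locus blocks with '?', records a partition map (0-based
half-open internally; RAxML-style 1-based inclusive on export), and
reports the overall missing-character fraction.

## The synthetic generator

Real chronograms of this kind are not redistributable, so the package
ships a generator for every input it consumes.

* **Trees** — forward Gillespie birth–death simulation with piecewise-
  constant rates (epochs in forward time since the origin), stopping at
  a target extant tip count (the present is placed just before the next
  event would fire) or at a fixed duration. Extinct lineages are pruned;
  the returned root is the survivors' MRCA. Passes that die out are
  retried with fresh randomness. Tip-count conditioning is by simple
  rejection, not generalized sampling; no inference about the simulator
  itself is claimed, and a Monte-Carlo check confirms the pure-birth LTT
  slope recovers the birth rate (mean OLS slope of log count vs time
  ≈ 1.0 at λ = 1 over 500 replicates).
* **Labels** — either i.i.d. from status proportions (exchangeable, the
  calibration case) or *clade-enriched*: every tip descending from a
  node whose age falls in a window receives the target status with
  probability `strength`, everything else follows the renormalized
  proportions. One property worth knowing: on a Yule-like tree a window
  reaching the present makes almost every tip eligible, so enrichment at
  fractional strength is statistically indistinguishable from random
  labelling (marked tips are then scattered singletons whose mutual
  MRCAs are deep). A detectable minority class needs whole clades:
  strength 1.0 with a narrow window around the radiation age of
  interest. The demo fauna in `analysis/01` uses a 9–11 Myr window for
  exactly this reason.
* **Intervals** — each internal node of age a gets (a(1−u), a(1+u)),
  u ~ Uniform(0, h] with relative halfwidth h (default 0.15, roughly the
  relative width of relaxed-clock credibility intervals on trees of this
  size). Parent/child intervals may overlap, as in real posteriors.
* **Alignments** — i.i.d. ACGT columns with whole taxon-by-locus blocks
  replaced by '?' at a given rate, emulating unsequenced loci — the
  dominant missingness mode of mined multi-locus matrices. The fixtures
  carry no phylogenetic signal and none is needed: they exercise
  bookkeeping (lengths, partitions, missingness), not inference.

What passing tests on these fixtures shows: the machinery (pruning,
event accounting, the null, grafting, filtering) is correct and
calibrated. What it does not show: anything about a real fauna — real
chronograms have autocorrelated dating error, non-exchangeable taxon
sampling and phylogenetically clustered statuses beyond the single
clade-enrichment mechanism modelled here.

## Numerical and design choices

* Newick I/O is round-trip exact: ages derive from branch lengths with
  tips pinned at 0; ultrametricity tolerance is 1e-6 relative to tree
  height; floats serialize in shortest round-trip decimal form; age
  intervals travel as `[&age_interval={lo,hi}]` node comments; support
  values and other comments are ignored.
* Problem sizes for the statistical self-checks were chosen for desk-
  scale runs: calibration uses 200 datasets of 200 tips with 200
  resampling draws each; power uses 100 datasets; both finish in well
  under a minute per batch on one core. With 200 draws, the inclusive-
  quantile two-tailed test has an exact exchangeable rejection rate
  slightly below 0.05 (ties inside), which the calibration check
  confirms empirically.
* `RandTestConfig` requires n_draw ≥ 2, so a draw can never produce an
  empty event set; a status equal to the whole pool yields a point-mass
  null and is never significant.
* Degenerate inputs raise early and specifically: non-ultrametric or
  unlabeled trees, unknown statuses (with the offending row named),
  duplicate species, ragged alignments, enrichment windows containing
  no node, certain-extinction simulation settings.

## Known limitations

* The birth–death sampler's tip-count conditioning slightly biases tree
  age relative to the exact conditioned process; immaterial here since
  no simulator-based inference is performed.
* The block filter does not iterate flank re-examination; on pathological
  alignments its block boundaries can differ from legacy implementations
  even though all stated rules hold.
* Grafted polytomies concentrate event weight at the attachment node's
  age, which can sharpen histogram peaks in heavily grafted trees; the
  chronogram-series comparison is the intended control for this.
* The sequential grafting mode is order-dependent by design and is not
  used by the pipeline default.
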