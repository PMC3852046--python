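# Methods

## The model

A gene family evolves inside a fixed, dated species tree `S`.  Both trees are
*planted*: a degree-1 planted root sits above the root, so the root itself has
an incoming edge and events may predate the first speciation.  The joint model
(DLRS: Duplication, Loss, Rates, Sequence evolution) has three layers:

1. **Duplication-loss.**  A single gene lineage enters at the planted root and
   evolves down `S` as a linear birth-death process with duplication rate
   `lambda` and loss rate `mu` (events per time unit).  At every speciation the
   lineage splits into one copy per descendant edge; lineages reaching the
   leaves become extant genes.  Pruning all subtrees with no extant descendants
   yields the observed gene tree `G`.
2. **Relaxed clock.**  Each edge of the pruned gene tree receives an
   independent substitution rate `r ~ Gamma(mean m, variance v)`; the edge's
   length (expected substitutions per site) is `l = r * t`, where `t` is the
   time the edge spans.
3. **Sequences.**  An empirical amino-acid replacement chain (JTT by default;
   any PAML-format matrix plugs in) generates an alignment `D` down `(G, l)`,
   with the stationary distribution at the planted root and one transition per
   edge, the planted edge included.  No among-site rate variation is modeled;
   rate heterogeneity lives on edges, not sites.

The posterior over gene trees, lengths and parameters factorizes as
`p(G, l, theta | D, S) ∝ P(D | G, l) · p(G, l | theta, S) · p(theta)`, with
`theta = (lambda, mu, m, v, M)`.

## The dynamic program

`p(G, l | theta, S)` is computed on a discretized species tree `S'`: every
edge of `S` (planted edge included) carries `k` equidistant interior vertices,
the only places where duplications can be realized.  A *d-realization* maps
each gene vertex to an `S'` vertex (speciations to species vertices,
duplications to interior vertices); projecting interior vertices to their
species edge yields the *reconciliation*.

For each gene vertex `u` the table `s(x, y, u)` is the density that a lineage
at `x` generates the planted subtree `G^u` with its lengths, with `u` realized
at `y`.  Because sound placements of `u` lie on the `S'` path from
`sigma(u)` (the LCA of `u`'s descendant species) to the planted root, each
table is a lower-triangular matrix over path positions.  Local factors:

* per `S'` segment crossed: the birth-death one-to-one probability
  `p11 = (1-p0)(1-q) / (1-qD)^2`, where `(p0, q)` are Kendall's extinction and
  geometric-offspring parameters for the segment and `D` the extinction
  probability below it (all side branches spawned in the segment die out);
* per speciation vertex passed *through*: the sibling-side extinction
  `eps(x, zbar)` — the copy sent into the other descendant edge leaves no
  extant gene.  A gene vertex realized *at* a speciation pays no such factor:
  its two children take the two copies.  (The raw recursion's placement of
  this factor conflates the two situations; the implementation applies it
  exactly once per pass-through, which is what reproduces the clock-limit
  closed form below.)
* per gene edge: a single relaxed-clock density `rho(l / t(x, y))` over the
  edge's *full* realized span — the per-step densities telescope;
* per duplication: `2 * lambda * dt(y)`, with `dt(y) = (edge duration)/(k+1)`
  the time slice owned by interior vertex `y`.  The slice width makes the sum
  over placements a Riemann sum, so the generation probability converges as
  `k` grows and remains comparable across gene trees with different
  duplication counts (a bare `2 lambda` would scale with the grid density).
* the edge-length factor carries no `1/t` Jacobian: in the clock limit
  (`lambda = mu = 0`, congruent family) the generation probability is exactly
  `prod_e rho(l_e / t_e)`, which serves as an analytic anchor in the tests.

Totals: `p(G, l | theta, S) = sum over placements of the gene root strictly
below the planted root`.  Realizations are sampled backwards through the
table (root placement from its normalized marginal, children conditionally);
the MAP d-realization replaces sums by maxima with backpointers, ties broken
towards the leafmost vertex; the probability of a fixed reconciliation
`gamma` restricts every placement sum to `R(gamma(u))` (species vertex, or the
interior vertices of a species edge).  All three paths are validated against
exhaustive enumeration of sound realizations on small instances, where their
identities (sum-conservation, normalization over reconciliations, argmax
agreement) hold to relative 1e-10.

Numerics: tables are kept in linear space (desk-scale families are far from
underflow; a zero total signals a structurally impossible family, e.g. more
stacked duplications on one edge than `k` can host — callers raise or choose
`k` from the MPR's stacked-duplication depth, see
`compare.min_discretization_for_mpr`).  Chain factors depend only on
`(S', lambda, mu)` and the `sigma` path, so they are cached per species
vertex and shared across gene vertices and whole cohorts.

## Comparing reconciliations

The atomary distance between objects `a, b` of `V(S) ∪ E(S)` is
`d(a, b) = L + 1 − |{a,b} ∩ V(S)|/2 − |{a,b} ∩ E(S)|`, where `L` is the edge
length of the minimum path of `S` containing both objects (an edge is
contained when both endpoints are; objects are counted with multiplicity, so
`d(a, a) = 0`).  Two reference values: a vertex versus its parent edge gives
0.5; two stacked edges give 1.  Reconciliation distances take the maximum of
`d(gamma(u), gamma'(u))` over gene vertices, or the sum divided by the number
of internal vertices (leaves pin both reconciliations, so their terms vanish;
the planted root is excluded from the denominator and contributes 0).

The MPR (most parsimonious reconciliation) is the LCA mapping; a vertex is a
duplication iff it shares `sigma` with a child, and duplications sit on the
edge immediately above `sigma(u)`.  Its minimality over all sound
reconciliations is checked exhaustively for every gene-tree shape with up to
five leaves over a three-species tree.

## MCMC

A Metropolis-Hastings chain over `(G, l, theta)` with one move class per
iteration: rooted NNI (swap a vertex's sibling with one of its children) and
rooted SPR (prune and regraft; edge lengths travel with their child vertex) on
the topology, with Hastings corrections from the move counts on both sides;
log-normal multipliers on a random edge length; log-scale Gaussian random
walks on `lambda, mu, m, v`.  Priors are independent Gamma(1, 10) by default
(weakly informative over the positive axis).  The species tree and its times
are fixed throughout.  With a flat target the topology moves visit all 15
rooted 4-leaf topologies uniformly; with data, a topology-only chain on three
leaves reproduces the exactly enumerable 3-topology posterior.

Two estimation modes matter in practice:

* `run_mcmc` - full per-family sampling of `(G, l, theta)` given an alignment;
* `run_mcmc_params` - cohort-level sampling of `theta` with every family's
  `(G, l)` fixed, targeting `prod_i p(G_i, l_i | theta, S) · p(theta)`; this is
  the natural estimator of duplication/loss rates from reconciled trees.

**Conditioning on observability.**  Simulated (and real) cohorts exclude
families with fewer than two surviving genes.  An unconditioned likelihood is
therefore biased (loss looks too rare, duplication too common).  With
`condition_on_observation=True` each family's density is divided by
`1 − P(extinct) − P(exactly one survivor)`, both computed exactly by a
birth-death recursion over `S'` (`BDTables.single`).  With this correction,
95% posterior intervals from 50-family cohorts cover the simulation truth
`(lambda, mu) = (0.3, 0.2)` in 19 of 20 replicates; without it, coverage
visibly fails.  The correction is off by default to keep the plain model
semantics and enabled in cohort analyses.

## The simulator

`simulate_family` implements the generative process exactly (Gillespie
waiting times per lineage; duplication with probability `lambda/(lambda+mu)`,
otherwise loss), prunes lost subtrees, draws per-edge rates, and simulates
sequences.  It records the full ground truth: pre-pruning vertex count, event
times and species positions of every surviving duplication/speciation, and
per-edge true rates.  True realizations are snapped to the nearest
discretization vertex (ties towards the leaf side); ancestor-descendant
duplication chains on one edge reserve distinct vertices, and a chain deeper
than `k` raises rather than silently distorting, so callers can enlarge `k`.

Defaults emulate a small vertebrate-like analysis: `lambda = 0.3`,
`mu = 0.2` per time unit on a species tree of height 2-3 time units (a few
duplications per family, some loss), rate mean 1.0 and variance 0.25
(coefficient of variation 0.5, a moderately relaxed clock), alignments of 100
amino acids.  What the simulator does *not* emulate: orthology-prediction
artifacts, alignment error, gene conversion/transfer, site-rate
heterogeneity, or dataset-specific family filtering.  Passing recovery tests
therefore demonstrates internal consistency of model + inference, not
robustness to real-data violations.

## Heatmaps and MPR summaries

Expected duplication counts per discretization vertex are accumulated over
families (each family's sampled realizations weighted `1/#samples`) and
binned into 11 equal-width levels (0 maps to level 0, the maximum to 10);
normalization is global, global excluding chosen edges (e.g. the common
ancestral edge, which otherwise dominates), or within each edge (a constant
positive edge maps to level 10).  MPR summaries report, per family, the
expected average and maximum distance to MPR over sampled reconciliations and
the fraction identical to MPR, with the MPR recomputed against each sampled
gene tree; at `lambda = 0` every sampled reconciliation equals MPR, and the
non-MPR fraction grows strictly with `lambda` (about 0.5%, 5% and 36% at
`lambda = 0.05, 0.3, 0.8` on the four-species test tree).

## Problem sizes used in the test suite

Enumeration-backed identities run on gene families with up to 4 leaves over
2-3 species and `k <= 3`, where all sound realizations (tens to hundreds) can
be listed.  Calibration uses 20,000 draws per instance; cohort experiments
use 50 families x 20 replicates (rate recovery) and 25 families x 100 samples
per duplication-rate level (MPR disagreement).  These sizes make the whole
suite run in minutes on one core while keeping every statistical check
well-powered.

## Known limitations

* One global `(lambda, mu)` pair; no transfers, no gene conversion.
* Binary, dated species trees only; polytomies and unrooted input are out of
  scope.
* The discretization is uniform per edge; `k` trades accuracy for time and
  must be large enough to host stacked duplications.
* The reconciliation posterior is approximated through d-realizations; two
  MAP notions (projection of the MAP d-realization; most frequent sampled
  reconciliation) can differ, and both are exposed.
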