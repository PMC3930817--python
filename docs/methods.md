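# Methods

## Network model

The integrated network is an undirected multigraph over two node kinds.
Reaction nodes come from a genome-scale metabolic model; a *metabolic* edge
joins two reactions sharing at least one metabolite (as substrate or product
on either side) that is not on the cofactor exclusion list. Metabolite
identity is compartment-qualified (`pyr[c]` and `pyr[m]` are distinct pools);
exclusion-list entries may be compartment-free, matching every compartment.
Protein-protein interaction records add *ppi* edges: a record whose
evidence score is strictly greater than the threshold (default 900) connects
every node pair (u, v) with one gene in u's rule and the other in v's — one
enzyme pair can therefore materialize several edges. Kinase-phosphatase
records carry no evidence score and bypass the filter (provenance tag
`KPI`; score-filtered records are tagged `S`). A gene matching no reaction
becomes a protein-kind node, provided its partner matched something;
records with both genes unmatched are dropped and logged. Self-edges are
never created: an interaction between two enzymes of the same reaction
projects onto a single node and is discarded. A node pair may carry one
edge of each kind; path traversal treats adjacency kind-agnostically and
records the metabolic kind on ties (configurable), since edge-kind tallies
are reported separately.

## Weighting

Transcription weight: per-gene intensities are arithmetic means over
replicates *per condition*; the gene rule is evaluated on those collapsed
intensities (OR → mean, AND → minimum, recursively), and the node weight is
the log2 ratio of the rule values. Averaging before the ratio, and rule
collapse before the ratio, follow from the ratio being defined on condition
intensities. Non-enzymatic reactions have no transcript and score zero.

Flux weight: the log2 ratio of per-reaction mean absolute fluxes.
Magnitudes rather than signed means keep reversible reactions from
cancelling to a spurious zero across sign-fluctuating samples. Both
numerator and denominator are floored at the zero-flux threshold
(10⁻⁷ mmol/(g CDW h), configurable) so the ratio stays defined when a flux
is zeroed; log ratios are computed as differences of logs, which keeps
w(a,b) = −w(b,a) exact in floating point.

Mixing: w_tot = a·w_flux + (1−a)·w_trans on reaction nodes; protein nodes
always use w_trans alone (no flux exists for them). When flux data is
present and scaling is enabled, reaction w_flux values are affinely mapped
onto [min, max] of the observed w_trans values over all scored nodes — the
data-dependent interval keeps either layer from dominating path scores.
Scaling is applied independently of a (including a = 1), which keeps w_tot
exactly affine in a and path scores comparable across the a grid. A
degenerate (constant) transcription range disables scaling with a warning;
a constant flux vector maps to the interval midpoint. Down-regulated
detection inverts both ratios (control/case) rather than negating weights,
so scaling acts on the direction actually searched; with scaling off the
two directions are exact mirrors.

Genes present in the network but absent from the expression matrix raise an
error naming the gene; an opt-in imputation mode substitutes the condition
median and logs the substitution.

## Flux context

Measured extracellular rates rarely satisfy S·v = 0 exactly. Strict rates
(oxygen uptake, P/O-linked constraints) are pinned at their means; rates
flagged free (carbon evolution) are released entirely; the remaining rates
get bounds mean ± m·(0.1·SEM), with one shared integer multiplier m grown
from 0 until the LP {S·v = 0, bounds} is feasible (HiGHS). A single shared
multiplier is the simplest reading of simultaneous gradual expansion;
per-rate multipliers would be underdetermined. If feasibility is not
reached by the time every half-width spans 10 SEMs, an infeasibility error
reports the constraint set.

Sampling restricts the chain to the null space of the equality system
(stoichiometry plus rows pinning fixed variables), so S·v = 0 holds to
machine precision by construction. The LP start point is refined onto the
equality system by least squares before sampling. Warm-up (default 1000
steps) uses uniform random null-space directions; afterwards directions run
from a uniformly chosen previous point through the running center of all
visited points (artificial centering), and each step moves uniformly within
the chord the bounds allow. Directions are re-projected onto the null space
every step: normalizing short centering directions would otherwise amplify
the ~10⁻¹⁶ off-subspace error that bound clipping introduces, a
multiplicative instability we observed before adding the projection. A
zero-dimensional polytope (fully determined model) returns its unique point
replicated, with a warning; chords unbounded along free exchanges are
capped at ±10⁶. Mean absolute fluxes are computed over a seed-fixed random
subset (default 2000 of 10 000 points); means below the zero threshold are
recorded as exactly 0 and flagged.

## Path detection

Color coding: each node draws a uniform color from {1..k}. The greedy walk
starts at the global maximum-weight node and extends to the
maximum-weight neighbor whose color is absent from the path, until k nodes
or a dead end; distinct colors imply distinct nodes, so returned paths are
simple by construction. Ties (start or extension) break uniformly at
random from the run's generator — a lexical tie-break would bias harvests.
A fixed simple k-path is colorful under a random coloring with probability
k!/k^k (0.24% at k = 8), which sets how many recolorings a harvest needs to
surface any particular path.

The permutation null shuffles the multiset of node weights, redraws the
coloring, and reruns one detection; 1000 shuffles by default. Dead-end
shuffles are redrawn and logged. p = (1 + #{null ≥ score}) / (1 + n), so
p > 0 always. One null distribution is computed per detection run and
reused for all its paths. Harvesting identifies a path with its unordered
node set (the network is undirected; a path equals its reversal), keeps
new paths with p ≤ 0.025, and stops after i = 10 consecutive iterations
yielding only known paths; dead-end iterations count as known. Detected
nodes are *not* removed between iterations (re-detection drives the
stopping rule); an exploration flag enables removal. Defaults k = 8,
i = 10 balance combined-network density against interpretability.

Combined networks are unions of significant paths' nodes and traversed
edges, with counts of PPI vs metabolic edges, nodes, and paths, and
percentage columns rounded half-up. Exports (GraphML/SIF/JSON-lines) carry
`tw`/`fw` weight labels, red/blue/neutral sign classes, and edge provenance
tags, and are byte-deterministic given a seed.

## Enrichment

The genes of a combined network (rule leaves plus protein-node genes) are
tested per category with the upper-tail hypergeometric law
P(X ≥ x), X ~ Hypergeom(N, K, n), against a background defaulting to the
full network's gene set — the universe the search actually explored, not
the genome (overridable). Categories with no background overlap are
skipped and do not count toward the Benjamini-Hochberg correction;
reported categories satisfy q ≤ 0.05 by default. Note the standard
monotonicity: enlarging the background with out-of-category genes makes a
fixed overlap *more* surprising (p decreases).

## Synthetic data

The generator emulates a two-condition chemostat comparison. A random
sparse model is built reaction by reaction, each consuming a metabolite an
earlier reaction touched (so the reaction graph is connected) and producing
a fresh one; extra shared metabolites are attached at a Poisson rate
(default mean 1.6) chosen so a ~200-node benchmark matches the average
degree (~15) of published genome-scale metabolic + PPI networks; cofactor
metabolites hit ~half of all reactions to exercise the exclusion list.
Rules mix single genes, ORs, ANDs and nested forms; ~10% of reactions are
non-enzymatic. PPI records combine scored pairs (600–999, so the >900
filter bites) with kinase-phosphatase records introducing protein nodes.

Expression: per-gene baseline log2 intensities ~ N(8, 1), per-gene true
log2 fold changes ~ N(0, 1), four replicates per condition with N(0, 0.1)
replicate noise — fold-change spread of magnitude 1 and four replicates
mirror a typical normalized two-color microarray comparison. Flux ground
truth bypasses sampling: a random feasible point's magnitudes (clipped
away from zero) perturbed per condition, so path-detection tests do not
depend on sampler mixing.

A planted benchmark overrides the fold changes of one induced simple path:
the shift (default +3 log2) is applied with a mild linear taper (±0.5
around the mean along the path). Design notes, found the hard way:
the plant routes only through gene-bearing nodes, because non-enzymatic
reactions score zero by definition and would break the chain; the taper
makes the path's first node the unique global weight maximum, anchoring
the endpoint-oriented greedy walk; and the path is induced (chordless),
because a chord plus noise-inverted taper order makes the planted sequence
unwalkable by the greedy rule under any coloring, leaving "recovery"
ill-posed. The mean shift still equals the nominal value. Annotations are
random gene partitions plus one positive-control category on the planted
genes.

What the benchmarks show — and don't. Planted-path recovery (top
significant path equals the truth in ≈ 85–95% of seeds at +3 log2 against
N(0, 1) background) exercises the full weighting-search-significance stack,
but the failure modes are informative: a background node outdrawing the
planted tail, or a harvest stopping before one of the ≈ 0.24%-probability
colorful colorings arrives. Real data has correlated fold changes along
pathways and noisier rules; synthetic recovery rates are upper bounds, not
forecasts. Calibration of the permutation test is checked on *sparse*
no-signal networks (average degree ≈ 5), where single detections dominated
by the weight assignment match the null construction and the top path is
"significant" in ≈ 3% of runs at a 2.5% nominal level.

## Known limitations

* The permutation p-value is calibrated per detection. On dense networks
  (average degree ≳ 10) the *top* path of a harvest is a maximum over
  thousands of colorings, while each null shuffle contributes one
  detection; the top-path p is then strongly anticonservative (we measure
  ≈ 50% nominal-2.5% exceedance at degree ~11–14 on no-signal data).
  Interpret harvest maxima on dense networks as rankings, not calibrated
  tests, or reduce the coloring multiplicity before comparing to the null.
* Mixing transcription and flux weights (a = 0.5) halves background weight
  variance, which *shrinks* path diversity and can stop the harvest before
  rare colorful colorings arrive — integrative weighting can recover a
  planted path less often than either single layer on synthetic data.
* The greedy extension never backtracks; it can miss high-weight paths a
  dynamic-programming color-coding search would find. Scores are bounded
  by, and usually below, the exhaustive optimum.
* The hit-and-run sampler targets small and mid-sized models; the dense
  null-space basis makes genome-scale sampling memory-heavy. No formal
  mixing diagnostics are run; warm-up length is configuration.
* Reaction directionality is ignored in the graph (all edges undirected),
  and reversible reactions are not split.
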