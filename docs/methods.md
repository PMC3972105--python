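# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
package's known limitations.

## Differential expression (SAM)

The two-class unpaired statistic per miR i is

    d_i = r_i / (s_i + s0),
    r_i = mean(disease) - mean(control),
    s_i = sqrt((1/n1 + 1/n2) * (SS_1 + SS_2) / (n1 + n2 - 2)),

with SS_g the within-group sum of squared deviations.  The description of
r as a regression coefficient reduces, in a two-group design, to the group
mean difference; we use that reading throughout.

**s0 fitting.**  Candidates are percentiles of the s distribution (default
grid 0, 0.05, …, 1).  For each candidate, the probes are partitioned into
up to 100 s-quantile windows; the spread of d inside each window is the
normal-scaled median absolute deviation, and the objective is the
coefficient of variation (sd/mean) of those spreads.  The candidate with
the smallest CV wins; ties go to the smallest candidate, so the degenerate
all-equal case is deterministic.  With fewer than 20 usable probes the
window statistics are meaningless and s0 falls back to median(s) with a
warning.

**Permutation FDR.**  Group labels are permuted (exhaustively enumerated
when the number of distinct assignments is at most `n_permutations`,
otherwise sampled from a seeded stream; exhaustive mode is therefore
seed-independent).  Observed d's are ordered and compared with the
permutation-averaged order statistics d̄; for a symmetric gap threshold Δ
the cuts are cutup = min{d_(i) : d_(i) − d̄_(i) ≥ Δ} and cutlo the
mirrored negative cut, and

    FDR(Δ) = median_b #{permuted d beyond the cuts} / #{observed calls}.

Δ is tuned to the largest call set with FDR(Δ) ≤ the target (default
0.3%); among thresholds tying on call-set size the largest Δ is kept.  No
pi0 (true-null proportion) correction is applied — the estimate without it
is conservative, and with all planted miRs upregulated and strong effects
the difference is negligible.  Per-probe q is the smallest estimated FDR
over thresholds that would call the probe, which is monotone in |d − d̄|.
This construction makes the call set shrink monotonically as the target
tightens.

**Missing data.**  Probes with more than 20% missing values, or fewer than
two usable values in either group, sit out the test entirely (flagged, not
called).  This is the least destructive convention consistent with the
pooled-SE formula.

## Overlap and partition

Overlap significance is P(X ≥ k) for X ~ Hypergeometric(N, K, n) with N
the background universe, K the curated-list size and n the DE-set size.
The background defaults to the number of probes assayed and is
configurable, since a curated list may cite miRs the array does not carry;
such entries still count in K but cannot contribute overlap.  The
partition Group 1 = DE ∩ curated / Group 2 = DE \ curated is exact and
exhaustive by construction.

## Target filtering

Order of operations: consensus (pair predicted by ≥ 3 distinct
predictors) → score (consensus score ≥ 20, boundary inclusive) → per-miR
top-10 by score, ties broken by gene name ascending.  The record kept for
a consensus pair is the designated consensus predictor's (DIANA-style)
record; the other predictors only vote membership.  When that predictor is
absent for a pair that still meets the vote count, the pair's
highest-score record stands in.  Because the score rule is per-record, the
score filter commutes with consensus whenever all of a pair's records
pass.  Published unique-target counts depend on the 2014 states of
external databases and are not reproduction targets; the operations
reproduce the filtering logic.

## Enrichment

One hypergeometric upper-tail test per term after intersecting the term
with the background; the background defaults to all genes seen in the
supplied GMT and target tables.  BH adjustment is computed over all terms
with K ≥ 1 (not only the terms the query hits) so the family is not
conditioned on observed overlap; the default significance filter is the
*unadjusted* p < 0.05, matching the practice of the enrichment web
services this stage replaces offline, with the adjusted mode behind a
flag.  Terms the query misses entirely (k = 0) are suppressed from the
output.  No ontology-graph propagation is performed.

## Tripartite network and IR scoring

Strict three-layer directed graph; a name appearing in two layers of one
network instance is an error, because layer purity is what makes in- and
out-degree interpretable.  Duplicate TF→miR records (different evidence
lines) collapse to one edge, since m counts distinct regulators.  miRs
without any recorded TF stay in the network with m = 0 and IR = 0.
IR = m × n and the hub threshold (default 70) is inclusive.  Regulation
sign (activation/repression) is carried as an edge attribute but does not
enter the score.

## Co-expression network

Pearson correlation over all samples pooled (one network spanning both
conditions), pairwise-complete over missing values with at least three
common observations per pair.  Edges require r > threshold (default 0.9),
strict and signed; an absolute-value mode exists behind a flag.  Isolated
nodes are dropped by default (mirroring hub analyses that consider only
the connected part).  Conventions for the node statistics, chosen to match
the magnitudes of classic network-analysis services and locked by tests
against a brute-force oracle:

- betweenness: sum over unordered pairs {s,t}, endpoints excluded,
  unnormalized, unreachable pairs skipped;
- eccentricity: maximum *finite* shortest-path length, 0 for isolated
  nodes;
- clustering coefficient: 2e/(k(k−1)), defined 0 for degree < 2;
- summaries use the population SD (divide by N).

The degree-hub rule is a strict cutoff at fraction × max degree (default
0.8).  The source analysis glosses this cutoff as holding "80% of total
connectivity", which is arithmetically a different quantity; the package
implements the degree-cutoff reading, which reproduces the published
cutoff value (63.2 from max degree 79).

## Hierarchical clustering

Distance 1 − r (Pearson, centered — consistent with the co-expression
stage), range [0, 2].  UPGMA: inter-cluster distance is the unweighted
mean over all cross leaf pairs, maintained by the Lance–Williams average
update (algebraically identical).  A cluster is identified by its
lexicographically smallest leaf; distance ties are broken by the smallest
sorted id pair, so merge order is deterministic and invariant to leaf
input order up to relabeling.  Cutting at k undoes the last k − 1 merges;
ids are assigned by decreasing size then smallest member.  k is a user
parameter (default 6): no principled cut criterion is claimed, the
published cluster count arose from its data.  The pipeline clamps k to the
number of DE miRs when the call set is small, and skips the stage below
two leaves.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the pipeline assumes:
a probes × samples log2-ratio matrix for 19 disease vs 13 control samples
(defaults), an additive disease-only upregulation of `de_effect` log2
units on `n_de` planted miRs, correlation blocks built from one latent
factor per block (x = sqrt(ρ)f + sqrt(1−ρ)ε, exact expected pairwise
correlation ρ), TF/target tables with three predictors, decoy records
that fail consensus and per-miR sub-threshold scores that fail the score
screen, a 73-entry curated list overlapping the planted set, and GMT sets
with terms loaded with planted-miR targets.  Defaults (300 probes, 30
planted miRs, effect 2.0, noise sd 1.0, one block of 20 at ρ = 0.95) are
chosen as a realistic mid-2000s miR array scale with a clearly detectable
but not trivial effect; blocks are drawn from the planted DE rows first so
the co-expression stage, which runs on the DE set, sees them.  One global
seed feeds independent per-generator streams, so adding a generator never
changes another's output.

Not emulated: dye/array artifacts and normalization (the pipeline starts
from the log-ratio matrix), miR family sequence structure, realistic
annotation ontologies, and dependence between the regulation tables and
expression.  Passing tests therefore demonstrate correctness of the
statistical machinery and recovery under the assumed generative model,
not performance on raw array data.

## Numerical and engineering choices

- All name keys are canonicalized at file boundaries (miRs: lowercase,
  `hsa-` prefix; genes/TFs: uppercase) so cross-source set operations are
  exact.
- Sum-of-squares terms are clipped at zero against floating-point
  cancellation; correlation values are clipped into [−1, 1] implicitly by
  the pandas implementation.
- Problem sizes in the test and acceptance suites (300-probe simulations,
  ≤ 12-node oracle graphs, 8-leaf UPGMA oracles, 20/10-seed averages)
  are chosen so the whole suite verifies every claim in minutes on one
  CPU while keeping the Monte-Carlo bands well inside the asserted
  tolerances.
- The run report is fully sorted and rounded where floats are emitted, so
  fixed-seed runs are byte-identical.

## Known limitations

- The SAM variant is two-class unpaired only (no paired, multiclass or
  survival designs) and reports a single tuned Δ rather than the full
  Δ-table of the original software.
- FDR estimates at very small call sets are coarse (median of integer
  exceedance counts over an integer count).
- The enrichment stage treats terms as flat sets; parent terms do not
  inherit child members.
- Betweenness on weighted graphs is out of scope: co-expression edges
  carry r as an attribute, but shortest paths are unweighted.
- The CLI is a thin veneer; anything beyond the documented flags is meant
  to be driven from Python.
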