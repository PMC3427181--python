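# Methods

This note documents the models, algorithms and numerical choices behind
modevoprof, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Alignment filtering (blocks)

Columns are classified from the count of their most frequent residue
(gaps and `X` never count as residues): below `min_seqs_conserved` —
nonconserved; at or above `min_seqs_flank` — highly conserved; otherwise
conserved. Three gap policies exist: `none` (any gap makes a column
nonconserved), `with_half` (gap fraction >= 0.5 does), `all` (gaps
ignored). Selection then (1) excises runs of more than
`max_contig_nonconserved` consecutive nonconserved columns, (2) trims each
surviving segment to highly conserved flanks, (3) drops segments shorter
than `min_block_len`. The `relaxed` preset (simple-majority thresholds,
`max_contig` 8, `min_block_len` 5, `with_half`) corresponds to the
"less stringent" option family of Gblocks-style filtering; `strict` uses
85% flank conservation, `min_block_len` 10 and no gaps. Which toggles an
individual published analysis used is rarely recoverable, so the presets
make the choice explicit and recordable; byte-compatibility with any
particular Gblocks build is not claimed. Ties for the most frequent
residue are irrelevant because only the count is used.

Selection is idempotent (re-filtering a filtered alignment keeps every
column) and monotone in the conservation threshold; both are enforced by
property tests.

## Distances, neighbor joining, minimum evolution, bootstrap

Pairwise distances use pairwise deletion (a column is compared for a pair
only if both sequences carry residues): `p` is the raw mismatch
proportion, `poisson` is −ln(1−p), and `gamma` is α((1−p)^(−1/α) − 1)
with default α = 1. The gamma correction is the package's stand-in for
"+G"-style among-site rate variation; maximum-likelihood (e.g. JTT)
distances are deliberately not implemented — the tree is an *input* to
the rate profiling, so any documented distance suffices, and the model
tag travels with the matrix. As α → ∞ the gamma distance converges to
the Poisson distance (tested numerically at α = 10⁶). A pair with p = 1
is reported as saturated rather than silently clamped.

`nj_tree` is standard Saitou–Nei agglomeration with the Studier–Keppler
Q criterion; ties take the first minimum in a fixed scan order. Negative
estimated branch lengths are clamped to zero with the deficit moved to
the sibling branch, preserving the pair's total. `me_nni_refine`
hill-climbs over nearest-neighbor interchanges in a canonical edge order
(sorted child leafsets), accepting the swap that most reduces the
ordinary-least-squares total branch length (unweighted OLS over all leaf
pairs, solved by least squares; acceptance threshold 10⁻¹²), and writes
the final OLS lengths (clamped at zero) onto the tree.

The bootstrap resamples columns with replacement, rebuilds each replicate
with the same distance model and NJ (NNI refinement optional), and scores
each internal edge of the point tree by the percentage of usable
replicates containing the same bipartition. A single seeded generator
draws replicates sequentially — reproducibility over parallelism.
Replicates with a saturated pair are skipped; more than 10% skipped
aborts with an error rather than reporting supports from a biased subset.

## Parsimony substitution counting

The count engine is Sankoff dynamic programming over the 20 amino acids
with a symmetric step-cost matrix. Two matrices are provided: unit costs
(Fitch; every replacement = 1 event) and genetic-code step costs, where
two amino acids are adjacent iff some sense codon of one differs from
some sense codon of the other at exactly one nucleotide (standard code;
stop codons excluded as intermediates) and the cost is the BFS
shortest-path length in that 20-node graph (maximum 3). Gaps and `X` are
missing data — zero cost in every state — not a 21st state: counting
them as states would inflate counts at indel-rich margins. With a
symmetric matrix the per-column minimum is independent of root placement
(tested under rerooting).

Branch-level events come from one most-parsimonious reconstruction chosen
top-down: the root takes its minimum-cost state, each child the state
minimizing transition-plus-subtree cost, all ties resolved to the
alphabetically first one-letter code. The tie rule is deliberate and
documented rather than an emulation of any particular program's
internals; averaging over all MPRs is not attempted, but the per-column
*count* (the DP minimum, reconstruction-independent) is exposed
separately and always equals the per-column sum of branch events.
Unrooted user trees are midpoint-rooted first and the rooting is recorded
in the result.

One MPR attributes each event to a specific branch; when two clades are
adjacent, an event can be attributed to the wrong side. Consequently a
branch-subset profile never exceeds the true *total* event count at a
position, but may exceed the subset's own truth at a small fraction of
positions (~6% under the default simulation); tests assert the provable
total bound everywhere and the subset bound as a strong-majority
property.

## Rate profiles

"Substitution rate" here is a dimensionless parsimony event count per
site over a chosen branch set, not a per-unit-time rate. Profiles are
projected onto the ungapped coordinates of one named reference sequence
(position 1 = start-methionine); alignment columns where the reference is
gapped have no coordinate and are excluded. The moving average is
centered, window 20 by default, with windows truncated (not padded) at
the termini so no data is invented; the divisor is the actual window
size, so a constant profile is a fixed point and a full-length window
reproduces the global mean. Per-domain summaries average raw and
smoothed values inside each annotated interval; positions outside every
domain aggregate as `linker`.

## Domain gain/loss

Dollo parsimony is the default model because single-origin modules with
lineage-specific losses is the natural reading of a domain shared by a
clade with scattered absences: the gain node is the LCA of all presence
leaves, and losses are the maximal edges below it whose clades contain a
known leaf but no presence leaf. Unknown presence (unscanned species,
encoded −1) is ignored in the LCA and never asserted as a loss: an edge
whose clade contains only unknown leaves is left unmarked. The
unconstrained binary Fitch count (multifurcation-safe, two-state Sankoff
formulation) is reported alongside for transparency; Dollo losses + 1 ≥
Fitch always.

## Paralogon scanning

Gene positions are ordinal indices, matching the "window of 50–100
genes" unit of synteny-database scans, not base-pair coordinates. A
window pair qualifies when at least `min_pairs` distinct paralog pairs
have one member in each window, with greedy left-to-right one-pair-per-
gene matching so tandem arrays cannot inflate the count. Qualifying
window pairs are merged by 2-D overlap (runs of consecutive window starts
collapse to rectangles first, keeping the merge near-linear), hit ranges
are trimmed to the outermost contributing genes, and each hit reports its
anchor pairs. Monotonicity in window size and `min_pairs` holds for
one-to-one paralogy maps (where the greedy count equals the anchor
count); with many-to-many maps the greedy count is maximal, not maximum,
and small non-monotonicities are possible in principle.

## The simulator

`simulate_family` emulates the study conditions the pipeline targets, and
its defaults are those conditions: 20 taxa (two subfamilies of 10 created
by duplicating one random species topology at the root), total tree
length 2.0 expected substitutions per site for a rate-1 site, a
GASP/WFIKKN-like domain layout of 675 residues (SP, WAP, FS, kazal,
IGc2, two kunitz, NTR separated by linkers), gamma rate variation with
α = 1 discretized into 4 equal-probability mean-rate categories,
invariant-site fraction 0.1, graded per-domain rate multipliers (linkers
1.4 and WAP 1.5 fast; kazal/IGc2/kunitz 0.45–0.8 conserved), and a
subfamily-1 override of ×0.2 on the follistatin-like module — the
family's hallmark asymmetric conservation. Multipliers are graded rather
than uniform because per-domain rate heterogeneity is part of the
emulated system, and a rank-correlation recovery check is uninformative
when the true values are tied.

Branch evolution is an explicit continuous-time jump process, not
transition-matrix sampling, so the true jump count per (branch, site) is
recorded exactly — parsimony-undercount properties need true counts. The
default `flat` exchangeability gives a state-independent exit rate
(jump counts per site are exactly Poisson with mean = branch length ×
site rate, which the closed-form calibration test uses); the `empirical`
option uses a BLOSUM62-derived symmetric exchangeability built at
runtime, simulated by per-site Gillespie. Branch lengths are exponential
draws rescaled so each simulated tree's length is exactly the configured
total. Site rates multiply: category rate × domain multiplier ×
subfamily override (below the duplication node's first child). The mean
category rate is exactly 1, so the expected per-site rate is
(1 − p_inv) × multiplier.

No indels are simulated — the alignment is correct by construction —
so the generator cannot exercise misalignment, alignment uncertainty, or
gap-length distributions of real data; `mask_random_gaps` post-hoc
replaces random stretches with gaps purely to exercise missing-data code
paths. Passing recovery tests therefore demonstrates correctness of the
*computations* under the stated generative model, not robustness to
alignment error, compositional heterogeneity, or rate variation across
lineages (no covarion/heterotachy is simulated).

The planted-scenario generator for gain/loss requires, by rejection
sampling, that each planted configuration be the unique Dollo optimum:
presence on both sides of the gain node, non-nested loss edges, and a
surviving presence leaf in each loss edge's parent clade. Without the
last condition (e.g. two sibling losses covering a whole clade) the
planted scenario is not minimal and exact recovery would be ill-posed.
The paralogon planter retains round(retention × block length) genes of
the block, consecutively at a random offset among shuffled background
genes, and records the exact expected hit.

## Problem sizes and determinism

The acceptance harness uses: all 123 unrooted topologies on 4–6 leaves ×
500 random columns against the Fitch oracle (a 20-column subsample per
topology against full internal-state enumeration); 100 random instances
for branch-sum additivity and NJ recovery (6–8 leaves); 10 simulation
seeds for the rate-heterogeneity recovery; 200 planted gain/loss
scenarios on 10-leaf trees; 100 planted paralogon blocks plus 100 null
permutations (1000-gene chromosomes, 100 scattered pairs, window 50);
and 200 bootstrap replicates on a simulated quartet. Every stochastic
component takes a single integer seed through `numpy.random.default_rng`;
identical configurations are bitwise reproducible.

## Known limitations

* No maximum-likelihood tree search or model selection; trees beyond
  NJ/ME quality should be supplied as user trees.
* One deterministic MPR, not the full MPR set; branch attribution near
  short internal edges is approximate (see above).
* Dollo assumes irreversibility; horizontally re-acquired or convergently
  gained domains violate it by construction.
* The paralogon scanner detects blocks given a paralogy map; it does not
  infer paralogy, orthology, or statistical significance beyond the
  user's window/min-pair thresholds.
* The invariant-sites fraction is a simulator parameter only; it is not
  estimated from data anywhere in the pipeline.
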