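# Methods

## Age model

A protein's age is a property of its family's phylogenetic profile — the
0/1 vector of presence across the leaf species of a rooted, dated species
tree. Copy number is deliberately collapsed: gaining or losing a *family*
is the event of interest, so five paralogs in one species contribute the
same single presence as one. An ancestral reconstruction algorithm labels
every tree node 0 or 1 for each family; the protein's **origin** is then
the most ancestral node N on its leaf-to-root path such that every node
from the leaf up to N is labeled present — the top of the contiguous
present segment containing the leaf. Under Dollo parsimony this is always
the family's MRCA, so all members share one origin. Under Wagner parsimony
with several gains, the segment top is precisely the gain event that
explains *this* protein's presence, so members in different species can
receive different origins; this is the natural reading of "the branch on
the path between the leaf and the root on which the family first appeared"
when gains are multiple.

The numeric age attached to an origin is the divergence-time estimate of
that node, in millions of years (mya). It is a lower bound: the family may
have arisen anywhere along the branch above the node. Means and
correlations use these numeric ages; enrichment strata use the taxon
labels. Choosing the child-node age (rather than, say, the branch
midpoint) shifts every protein in a stratum by the same constant, so
orderings and stratum counts are unaffected; absolute mean ages from other
conventions may differ by a per-stratum offset.

## Reconstruction algorithms

**Dollo.** Exactly one gain, placed at the MRCA of present leaves. Inside
the gain clade a node is present iff its subtree still contains a present
leaf; this puts one loss at the root of each maximal absent subtree — the
minimal-loss labeling with losses placed maximally high. Any minimal-loss
convention would serve; this one is fixed so event sets are canonical.

**Asymmetric Wagner (Sankoff).** Transition costs: gain (0→1) costs
`gain_penalty` (default 1), loss (1→0) costs `loss_penalty` (the fixed
reference, 1); a root in state 1 pays one gain, i.e. presence predating
the root is still a gain on the root branch. The optimum is computed by
dynamic programming: a post-order pass accumulates, for each node and each
state, the optimal subtree cost (leaves clamped to their observations;
polytomies handled by summing over all children, no binarization); a
pre-order traceback fixes states. Wherever both states are optimal the
traceback chooses **absence**. This tie-break is deterministic, biases
ambiguous families toward multiple independent gains (hence younger ages,
reinforcing the expected Wagner-younger-than-Dollo ordering), and is the
main place our convention could differ from other Wagner implementations
on exactly-tied families. With any strictly positive loss penalty no
optimal Wagner labeling is present above the MRCA of the observed species,
which is why the per-protein ordering Wagner age ≤ Dollo age holds
identically, not just on average.

A brute-force enumerator over all 2^(internal nodes) labelings (capped at
20 internal nodes) provides the exact optimum for verification.

**Domain-based ages.** Given per-domain (taxon, age) assignments, a
protein takes the age of its oldest or youngest domain. Age ties resolve
to the taxon closest to the leaf on the species' root path, then
lexicographically for taxa off the path. Proteins with no annotated
domains — like proteins absent from a family database — are treated as
specific to their own species: origin = own leaf, age 0, flagged
(`family = none`) so analyses can exclude them.

## Trees and inputs

Trees are Newick (parsed with dendropy); internal nodes should be labeled
because ages are reported as taxon names, and unlabeled ones are
auto-named `node_<preorder-index>` for stability. Ages come from a
two-column node-age table, or are derived from branch lengths with leaves
at 0 (a node's age = its maximum path length to a descendant leaf). When
both are available the table wins, but a disagreement above 1e-6 mya is an
error rather than a silent override. Dating must nest monotonically
(parent ≥ child); ultrametricity is not required. The tree is used as
rooted, with no rerooting, since ages are defined relative to the given
root. A unary chain at the root (e.g. the degenerate `(A);`) is collapsed;
reconstruction itself requires ≥ 2 leaves. A species present in the family
database but absent from the tree is an error by default — silently
dropping species changes ages — with an explicit `--restrict-to-tree`
opt-out.

## Statistics

* **Mann–Whitney U** (overall age-shift test): U of the first sample
  counts pairs x > y plus half-ties. p is exact (full enumeration of the
  rank-assignment null) when n1+n2 ≤ 12 with no ties; otherwise a normal
  approximation with midrank tie correction and a 0.5 continuity
  correction. Zero tie-corrected variance (all values equal) gives p = 1.
* **Fisher's exact test** (per-stratum 2×2): two-sided p sums the
  hypergeometric probabilities of all same-margin tables whose probability
  does not exceed the observed one — computed in exact integer arithmetic
  for table totals ≤ 500 and in log space with 1e-12 relative slack on the
  comparison above that. The reported odds ratio is the sample value
  ad/bc (inf or nan for zero cells). Raw p values are primary; BH q values
  are available behind `--bh`. Star conventions (0.05/0.01/0.001) are
  reporting sugar only.
* **Set comparisons**: if one list is a subset of the other after ID
  resolution, the background is disjointified (background minus set) so
  Fisher margins stay valid; identical sets therefore produce a
  degenerate-background error. Unmatched IDs are reported, never silently
  dropped. Strata are the observed origin taxa ordered oldest → youngest.
* **Spearman's ρ**: Pearson correlation of midranks; p by exact
  enumeration of all n! permutations for n ≤ 10, else the t approximation
  with n−2 degrees of freedom.
* **Box summaries**: quartiles are Tukey hinges (median-of-halves, median
  included in both halves at odd n), the convention of classic box plots;
  whiskers are the extreme observations within 1.5 IQR of the hinges.
  Quartile definitions differ across software, so cross-tool numeric
  differences in box summaries are expected.
* **Linear trend**: OLS of feature on numeric age (units per mya), with an
  option to exclude the most ancient strata, where tree depth limits age
  resolution.

## Synthetic histories

The fixture generator stands in for the large cross-species family
databases real analyses use. `simulate_tree` builds a random topology by
repeated joins, with each parent dated a uniform(50, 150) mya increment
above its oldest child — ages strictly decrease root → leaf, leaves at 0 —
and can inject one polytomy. `simulate_families` gives each family one
origin node (uniform by default) and loses each branch below it
independently with probability `loss_prob`, pruning whole subtrees, no
regain; extinct families are redrawn. The truth is therefore
Dollo-consistent by construction, which is exactly what makes it a fair
probe: Dollo should recover origins (exactly at `loss_prob` 0, mostly at
small loss rates), while Wagner's gain/loss trade-off is exercised on the
patchy profiles that loss creates. Default benchmark conditions used by the
tests and the acceptance script: 16-leaf trees, 1,000 families, loss rates
0, 0.05, and 0.1 — large enough for stable rates, small enough to run in
seconds on one core.

What the generator does **not** emulate: regain/horizontal transfer (the
reconstruction explicitly targets eukaryotes, where transfer is rare),
family births by duplication, rate variation across branches or lineages,
annotation noise, and incomplete proteomes. Passing tests demonstrate
algorithmic correctness and calibration under the single-gain model, not
robustness to database artifacts in real data.

## Determinism and numerics

Every stochastic component takes an explicit integer seed; CLI analyses
are fully deterministic, output headers echo the complete configuration
plus package version, and repeated runs are byte-identical (serialization
uses full-precision `repr` for ages and branch lengths). Costs are
compared with a 1e-12 absolute slack in the brute-force enumerator;
equality of DP and enumeration costs in tests uses the same tolerance.
IDs match exactly (no case folding) to avoid false merges; GAF 2.0 lists
use column 2 (DB object ID) as the key with column 3 (symbol) as a
fallback alias.

## Known limitations

* Wagner tie-breaking toward absence is a convention; other tools may
  report different (equally optimal) labelings for tied families.
* Ages inherit all uncertainty of the input tree and its dates; the
  package performs no dating or topology inference.
* Family databases are trusted as given — no sequence-level clustering,
  and false positives/negatives in family assignment propagate directly
  into ages (the default gain penalty of 1 mainly guards against false
  positives producing spuriously ancient patchy families).
* Enrichment strata with tiny counts have low power; Fisher p values are
  exact but the U-test normal approximation needs moderate sample sizes
  (the exact path covers only n1+n2 ≤ 12).
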