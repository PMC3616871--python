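# Methods

This note documents the models and procedures `phylomekit` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behavior on real phylomes.

## Tree model and conventions

Trees are `skbio.TreeNode` objects.  Gene-tree leaves are named
`<sequence_id>_<species_code>` (species after the last underscore); an
explicit sequence→species mapping can be supplied anywhere a species
assignment is needed, so the convention is a default, not a requirement.
Branch lengths are expected substitutions per site on gene trees and time
units on simulated species trees.  Polytomies are accepted on input and
resolved deterministically (left-to-right ladder, zero-length branches) only
where an algorithm requires binary trees; the resolution is logged.
Partition intervals and hit coordinates are 1-based inclusive.

Rooting: outgroup rooting places the root at the middle of the edge above
the smallest clade containing all present outgroup leaves; midpoint rooting
is the fallback when no outgroup is given and refuses trees without positive
branch lengths.  Midpoint ties are resolved by scikit-bio's deterministic
traversal order.

## Species-overlap event labeling

For each internal node of a rooted binary gene tree, the species sets of its
two child subtrees are intersected; the overlap score is
|A∩B| / |A∪B| and the node is a duplication iff the score exceeds the
threshold (default 0: any shared species).  The threshold is exposed because
published phylome pipelines vary in it.  With threshold 0, the
speciation-only decomposition (below) is guaranteed single-labeled.

**What recovery means.** On simulated families with no loss and no copy
dropout, labeled duplication nodes coincide *exactly* with planted events
(this is a theorem for the generative process used, and the test suite
asserts it at 200 families).  Loss or dropout can hide one side of a
duplication and flip its label to speciation — so on real transcriptome
data the labels are a lower bound on duplication activity, which is also why
recovered duplication rates under dropout are biased downward (asserted as a
monotonicity property).

## Orthology and decomposition

Orthologs are leaf pairs whose MRCA is a speciation node; the relation type
comes from how many sequences of each partner's species its side of the
mediating node contains (1 vs 1 → one-to-one; 1 vs >1 → one-to-many; >1 vs
>1 → many-to-many).  The catalogue can be restricted to pairs involving the
seed sequence and can include duplication-mediated pairs as `paralog` rows.

The decomposition splits a labeled tree at every duplication node and
returns all implied speciation-only subtrees, relabeled by species.  At a
speciation node the decompositions of the children are combined by cartesian
product; at a duplication they are concatenated.  Duplicate topologies are
retained by default because support counting weights by occurrence; a
deduplication flag exists.

## Duplication dating, merging, rates

Dating assigns each species-overlap duplication to the species-tree branch
ending at the LCA of the union of species below it.  LCA reconciliation
(`reconcile_lca`) is kept separate: it is the gene-tree-parsimony cost used
by the supertree search, and equals the brute-force minimum duplication
reconciliation cost (oracle-checked at ≤ 6 leaves).

Because each homologous gene carries its own tree, one evolutionary event is
reported once per overlapping tree.  Two reports from different trees are
considered redundant when their unordered pairs of descendant leaf-id sets
are identical after restricting both to the intersection of the two trees'
leaf universes, with all four restricted sides non-empty; redundancy groups
are connected components of this relation and one representative (largest
leaf set) survives.  A stricter verbatim-equality rule is available
(`rule="exact"`).  Merging is idempotent.

Rates: rate(b) = merged duplications dated to branch b divided by the number
of *informative* gene trees for b — trees containing at least one species
below b and one outside it (for terminal branches: at least one sequence of
that species).  Dividing by all trees instead is a flag.  Branches with no
informative tree report NaN, never 0.  Both a per-tree and a
per-merged-event version of "fraction of genes with ≥ 1 duplication" are
emitted, since the two denominators answer different questions.

## Supertrees

*Split fit* scores a candidate against single-labeled source topologies:
both are restricted to their shared species; fit = shared non-trivial
splits / max(source splits, candidate splits), averaged over sources with
≥ 4 shared species.  The max-denominator is the package's choice (the
alternative, dividing by source splits only, is a flag; it changes scores
but not optima on congruent collections).  *Duplication parsimony* sums
LCA-reconciliation duplication counts of the raw (multi-copy) gene trees —
decomposed topologies feed SFIT, raw trees feed parsimony, matching the
input conventions of the tools these criteria originate from.

The search climbs over rooted topologies: NNI first-improvement with
deterministic preorder edge ordering, one SPR sweep whenever NNI stalls,
from one greedy taxon-addition start plus (default) 20 random starts,
followed by 5 double-NNI perturbation restarts from the incumbent.  The
default breadth is deliberate: duplication-parsimony landscapes contain
full-SPR local optima far above the global one (observed: cost 293 vs
optimum 182 on a 10-species collection), and random multistart was the
reliable escape.  Scoring is made cheap by preprocessing — source splits
grouped by taxon set for SFIT; gene trees flattened to integer postorder
programs replayed against a per-candidate LCA table for parsimony — plus
memoization on the candidate's clade set.  Everything is deterministic given
the seed.  Exhaustive enumeration over all rooted topologies
((2n−3)!! trees) provides the exact optimum up to ~7 species and is the
oracle in the tests.

Support: a gene topology is eligible for a species-tree split when both
restricted sides keep ≥ 2 species (strict mode requires every species), and
supports it when the restricted split is among its own non-trivial splits;
support is reported as a percentage, NaN when no tree is eligible.

## Likelihood engine

Q is built from symmetric exchangeabilities and stationary frequencies
(q_ij = s_ij π_j), normalized to one expected substitution per site at
stationarity; P(t) = exp(Qt) via the π^{1/2}-symmetrized eigendecomposition.
The six empirical matrices shipped in `src/phylomekit/data/` are the
published JTT, WAG, mtREV24, LG, BLOSUM62 and Dayhoff-DCMut models, exported
as plain text from the model store of the R package phangorn (4.3/2.12) and
cross-checked against published values; the Poisson model (uniform
exchangeabilities and frequencies) exists for closed-form testing.

Rate heterogeneity is the standard discrete gamma with k = 4 mean-of-bin
category rates (mean exactly 1; `alpha=None` or ∞ gives uniform rates) plus
an invariant-sites class: per-column likelihood
p_inv·π(residue) [constant columns] + (1−p_inv)·mean over categories.  Gaps
and ambiguity codes are fully missing (partial likelihood 1).  Columns are
compressed to unique patterns; per-node rescaling guards against underflow.
Per-site log-likelihoods can be exported/read in a plain
"ntopologies nsites" matrix format, with name-prefixed rows accepted.

Branch lengths are optimized coordinate-wise with bounded Brent cycles until
the total log-likelihood improves by < tol (default 1e-6); the two branches
incident to the root are confounded under reversibility, which affects
neither the likelihood nor any downstream quantity.  AIC selection
re-optimizes branch lengths, α (log-space, [0.02, 100]) and p_inv
([0, 0.99]) per candidate by alternating 1-D optimizations (two outer
rounds; a loose 1e-4 line-search tolerance, since AIC differences between
amino-acid models are orders of magnitude larger); AIC = 2(branches + 2) −
2 lnL, ties broken by model-name order.

Distances for NJ: observed p-distance with pairwise gap deletion, or the
Poisson-corrected −(19/20)·ln(1 − (20/19)p) with saturated pairs clamped.

## Topology tests

All tests consume the per-site lnL matrix only (no re-optimization), i.e.
RELL resampling.  KH compares each topology with the observed ML topology
using replicate-mean centering; the p-value is the fraction of centered
replicate differences at least as large as the observed ΔlnL — ties count
as exceedance, so two identical lnL vectors give p = 1 (the convention
matters only for degenerate data).  Note the KH p is calibrated for an a
priori fixed topology; evaluating it at the data-selected worst topology
roughly doubles the nominal level, which is the classical selection effect,
not an implementation artifact (the calibration test fixes the topology).
SH centers every topology at its own replicate mean and compares against the
max, giving SH ≥ KH pointwise by construction.

AU: for each scale r in {0.5, …, 1.4}, n_rep replicates of round(r·S) sites;
BP(r) = fraction of replicates where the topology is best.  The model
1 − Φ(d√r + c/√r) is fitted by weighted least squares (binomial variance
weights, probit-regression start, Levenberg–Marquardt refinement);
p = 1 − Φ(d − c).  All-zero or all-one BP vectors short-circuit to p = 0 / 1
with a degeneracy flag; fewer than two informative scales flags AU
unavailable while KH/SH are still returned.  Per-scale seed streams keep
results stable when scales are added.  Constraint topologies (one focal
split on a star) can be built directly and resolved by clade-level NJ
before scoring.

## Supermatrix and composition

One-to-one selection requires exactly one sequence of every required species
and a speciation MRCA for every cross-species pair.  Trimming keeps a column
iff its non-gap fraction ≥ the gap-score cutoff (default 0.1) and, when an
entropy cutoff is given, its Shannon entropy (bits, non-gap residues) is
≤ the cutoff; trimming is idempotent and refuses to empty an alignment.
The entropy filter is a deliberately simple instrument for compositional
column screening — it is not a reimplementation of window-based trimmers.
Families are grouped into partition blocks by assigned model (blocks ordered
by model name, stable family order within); the number of blocks is
data-dependent.  Outputs: relaxed PHYLIP, FASTA mirror, and
`MODEL, name = start-end` partition lines.

Composition PCA centers per-species amino-acid frequency vectors (non-gap
sites) and eigendecomposes their covariance; explained variances sum to the
total variance by construction.  A per-species chi-square statistic against
the pooled composition (df 19) flags deviant taxa.

## Phylome bookkeeping

Hit filtering keeps hits with e-value ≤ 1e-5 whose single continuous aligned
region is strictly longer than 30% of the query (a 15% preset mirrors the
seed-genome variant), then at most the 200 best per query by ascending
e-value, ties by subject id.  "Continuous" means one HSP interval; intervals
are never chained.

Combination: a target transcript belongs to the primary phylome when it
appears as *any leaf* of any primary tree (a seed-only mode is a flag);
otherwise the first fallback whose seed set contains it contributes its
tree; the rest are listed uncovered.  Combined coverage therefore never
drops below primary coverage.  Coverage reports include mean homologs per
tree and, given reference ortholog lengths, the Pearson correlation between
per-tree homolog count and relative transcript length (flagged unavailable
below 3 points).

## Synthetic phylomes

The generator emulates the data regime of a multi-species transcriptome
phylome.  Species trees: birth–death (default birth 1.0, death 0.2 per
lineage per unit time) conditioned on the species count via the
general-sampling approach, so no branch has length zero; ultrametric, time
units.  Gene families: one lineage enters at the root; along every species
branch each lineage duplicates at λ_d (default 0.3 per lineage per unit
length — chosen so a typical family carries a handful of events, giving the
event-merging and rate machinery something to chew on) and dies at λ_l
(default 0.1); at the tips each surviving copy is retained with
sampling_prob (transcriptome incompleteness); exactly one surviving copy in
the seed species is flagged as seed.  Families with fewer than 3 sampled
leaves or no seed-species copy are resimulated and the count reported.
With probability topology_error_p a tree receives one uniformly chosen NNI,
standing in for gene-tree reconstruction error.  Alignments evolve a root
sequence drawn from the model's stationary frequencies along the gene tree
with continuous gamma(α)+invariant site rates.

Planted `EventRecord`s keep the branch on which each duplication occurred
and the sampled descendant sets of both sides; events with an empty side
are unobservable in principle and are not recorded.  Everything is
reproducible byte-for-byte from (config, seed).

**What the simulations do not model:** incomplete lineage sorting,
horizontal transfer, indels (dropout is whole-sequence), alignment error,
rate variation across lineages, and assembly chimerism.  Passing tests show
the algorithms are correct under their own model; they do not certify
robustness to these real-data pathologies — the NNI-error and dropout knobs
probe the first-order effects only.

## Validation scales

The test suite validates at the following problem sizes, chosen as the
smallest scales at which each property is meaningfully tested: event-label
recovery at 200 families × 8 species; reconciliation against brute force at
100 random trees ≤ 6 leaves; supertree recovery at 8–12 species × 100 trees
× 10 seeds for both criteria plus exhaustive-enumeration agreement at 5
species; support saturation/decay at 40 trees × 10 seeds × NNI error ∈
{0, 0.2, 0.5}; rate recovery at 500 loss-free families (3 Monte-Carlo SEs,
plus the closed-form pure-birth expectation e^{λd}(e^{λt}−1)); likelihood
exactness against vectorized brute-force state sums at ≤ 5 leaves (1e-8);
AIC recovery of WAG at 6 taxa × 2000 columns in ≥ 8/10 seeds; KH type-I
error in [0.03, 0.07] over 500 null datasets of 10,000 sites; AU inverse-fit
recovery to 1e-6.
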