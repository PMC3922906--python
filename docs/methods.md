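# Methods

## The classification model

famclade classifies members of a gene family by reconciling a rooted gene
tree against a fixed, rank-level species hierarchy rather than a full
species tree. The hierarchy (the *rank ladder*) is

```
viridiplantae
├── green_algae
└── embryophyte
    ├── bryophyte
    └── vascular
        ├── lycophyte
        └── angiosperm
            ├── monocot
            └── eudicot
```

Every leaf of the gene tree is assigned a rank through its species
abbreviation; every internal node *v* receives the LCA mapping *M(v)*, the
lowest ladder node containing the ranks of all descendant leaves, computed
in one post-order pass. A node is labelled a **duplication** exactly when
one of its children maps to the same ladder node; otherwise it is a
**speciation**. This rule is the rank-level specialization of standard
gene-tree/species-tree LCA reconciliation, and it applies unchanged at
polytomies.

Groups and supergroups are then maximal clades found by a pre-order
traversal. For groups, the traversal descends while *M(v)* is strictly
above `angiosperm`, or *v* is a duplication mapping exactly to
`angiosperm`; any other node is emitted. Emitted clades containing
angiosperm leaves are groups — each corresponds to one gene lineage present
at the monocot/eudicot split. Emitted clades without angiosperm leaves
(bryophyte-, lycophyte- or algae-only) are reported as *unplaced
lineage-specific clades*. Supergroups use the identical traversal with
`embryophyte` as the boundary, so duplications mapping to `vascular` or
`angiosperm` multiply groups *within* a supergroup, while duplications at
`embryophyte` or `viridiplantae` separate supergroups.

Mapping at rank granularity is deliberate: duplications inside a single
rank (e.g. within eudicots) cannot move a group boundary, so the
classification needs no per-species reconciliation and no loss counting.

**Naming.** Supergroups are lettered and groups numbered deterministically:
descending subtree leaf count, ties broken by the lexicographically
smallest contained leaf id. Figure-layout orders of published trees are not
recoverable, so an optional anchor map (leaf id → letter) can pin letters
to published members. Angiosperm leaves carry an E/M half marker from their
own rank.

## Tree inference

The in-package inference engine is distance-based:

* **p-distance** over columns where both sequences carry a residue;
  `X` is treated as missing for distance purposes.
* **Poisson correction** d = −ln(1 − p).
* **JTT ML distance**: the pairwise likelihood
  ∏ sites π(x) P(x→y | d) under the Jones–Taylor–Thornton rate matrix
  (published exchangeabilities and frequencies, hard-coded; Q normalized to
  one expected substitution per site per unit d, P(d) via eigendecomposition
  of the reversible symmetrization) is maximized by bounded scalar
  optimization on [0, 10] with tolerance 1e-6. Comparisons with mismatch
  proportion ≥ 0.95, or estimates at the bracket ceiling, are capped at
  d = 10 with a warning.
* **Neighbor joining** with the standard Q-criterion and limb-length
  formulas. Two determinism choices that published implementations differ
  on are fixed explicitly: ties in Q are broken by the lexicographically
  smallest pair of cluster tags (a cluster's tag is its smallest leaf
  label), and a negative limb is clamped to zero with the deficit moved to
  its sibling. The Q minimum is taken over the upper triangle only, because
  the two triangles of the vectorized Q matrix can differ by one ulp and a
  full-matrix minimum could otherwise match no pair exactly. The result is
  an unrooted tree anchored at a trailing 3-way multifurcation (for n = 2,
  a root with two half-length children so the leaf-to-leaf path equals the
  input distance).
* **Bootstrap**: each replicate resamples all columns with replacement from
  an RNG stream keyed by (seed, replicate index), rebuilds distances and
  the NJ tree; an internal edge's support is the fraction of replicates
  whose bipartition set contains the edge's canonical split (exact matches
  only — a replicate's merely *compatible* split does not count). Replicates
  in which some pair shares no residue-bearing column are dropped and the
  denominator reduced. Default 1000 replicates; the test suite uses 100 for
  runtime.
* **Collapse**: internal edges with support ≤ 0.75 (strictly greater
  survives) are contracted into polytomies; the contracted edge's length is
  discarded so paths through retained edges are unchanged. When the stored
  root of an unrooted tree has two children, their two edges are one
  physical edge and their supports are unified before collapsing.

Maximum-likelihood or parsimony tree search is out of scope; externally
built trees in Newick are accepted anywhere a tree is consumed, since the
clan test, rooting and classification are inference-agnostic.

## Clans and rooting

A set of leaves is a **clan** iff some single edge of the unrooted tree
separates it from everything else (singletons and the full leaf set are
clans by convention; the complement of a clan is a clan). The monophyly
report evaluates each rank class and the merged plant class; the
vertical-inheritance test passes when the non-plant class is a single clan.
Rooting requires the chosen outgroup to be a clan — there is no silent
fallback — and places the root at a configurable position (default
midpoint) of the separating edge, conserving total branch length.

## Filtering rules and their boundaries

| rule | default | boundary semantics |
|---|---|---|
| hit identity | ≥ 30 % | inclusive ("at least") |
| hit E-value | < 1e-50 | strict ("lower than") |
| hit coverage | ≥ 50 % of query length | inclusive; proxy for the fragment rule |
| row gap fraction | ≤ 30 % of alignment length | strict exceedance excludes |
| column score | ≥ 0.40 | strict `<` drops |

The column score is the fraction of unordered residue pairs in a column
whose entry in a standard log-odds matrix (BLOSUM62 by default) is
positive; columns with fewer than two residues score 0. This is a
transparent, matrix-parameterized stand-in for aligner-internal local
similarity scores, thresholded at the same 40 % level. The coverage number
operationalizes "not a series of small fragments", which has no canonical
constant; it is configurable.

The iterative long-branch workflow (exclude gappy/aberrant rows →
re-align → rebuild) is supported as a recipe via `gap_filter` plus any
external aligner; re-alignment itself is out of scope.

## The simulator

`simulate_family` emulates the evolutionary scenario the classifier
targets, and nothing more:

* A dated species tree with fixed epoch ages — viridiplantae 1.0,
  embryophyte 0.8, vascular 0.6, angiosperm 0.4 (abstract units; only the
  order matters to truth labels) — and a default species set of 3 eudicots,
  2 monocots, 1 lycophyte, 1 bryophyte, 1 green alga: the minimal
  configuration exercising every rank boundary. Within-rank splits default
  to even spacing inside each rank's crown window. Larger sets are a
  constructor argument away.
* One ancestral gene at the root; along each species-tree branch every gene
  lineage duplicates at rate λ (default 0.3) and dies at rate μ (default
  0.1), independent Poisson processes; at each speciation every surviving
  lineage is copied into both daughters. The run conditions on ≥ 1
  surviving leaf by resampling from substream (seed, attempt), at most 1000
  attempts.
* Sequences evolve site-independently under JTT (or a 20-state equal-rates
  model) at `subst_rate` expected substitutions per site per unit time
  (default 0.5, giving a maximum leaf-to-leaf path of 1.0 expected
  substitutions on the default tree), root drawn from the model
  equilibrium. **There is no indel process**: the simulated homologous
  sites are already an alignment, which keeps the truth exact; the gap and
  column filters are therefore tested on hand-built fixtures, not on
  simulator output.
* Truth labels are read off the event history: a surviving angiosperm
  leaf's true group is its ancestral lineage at the angiosperm split, its
  true supergroup the lineage at the embryophyte split. By construction the
  group partition refines the supergroup partition.

What passing simulator-based tests shows — and does not. Exact recovery on
true trees (μ = 0) validates the traversal logic; coarsening-only behavior
under loss (splits = 0) validates the direction of the information loss;
≥ 90 % full-pipeline recovery at 2000 sites validates the distance/NJ/
rooting chain at realistic divergence. None of this exercises alignment
error, indels, rate heterogeneity across sites or lineages, model
misspecification, or incomplete taxon sampling, all of which real families
have.

## Numerical and degenerate-input choices

* Supports are fractions in [0, 1] internally; Newick inputs with values
  > 1 are read as percentages and divided by 100.
* Gap characters `-` and `.` are both accepted and normalized to `-`; `X`
  is a residue for filtering (BLOSUM62 defines its rows) and missing for
  distances.
* Alignment columns are 0-based half-open in the API and 1-based inclusive
  in written reports.
* `mean_rounded` aggregates round half-up (2.5 → 3), matching how integer
  member counts are conventionally printed.
* Classifying a tree whose root is a single angiosperm leaf yields one
  group containing that leaf; all-outgroup trees are an error at the
  pruning step.

## Known limitations

* Collapsing a *group-defining* edge — the angiosperm-speciation edge at a
  group's root, or the edge above the group root itself — redistributes
  that group's members into rank-pure clades of a higher polytomy, which
  the literal group definition then reports as separate monocot-only /
  eudicot-only groups. This is a faithful reading of the definition (pure
  one-rank groups do occur in published nomenclatures) but means support
  collapse is only guaranteed partition-preserving for edges strictly
  inside groups; the corresponding property test is scoped accordingly. A
  duplication node with a pure-rank child is indistinguishable by topology
  from this situation and genuinely is a separate lineage, so no local rule
  can merge one case and split the other.
* Bootstrap counts exact bipartition matches; compatible-but-unequal splits
  of polytomous references contribute nothing.
* The JTT distance assumes stationarity, reversibility and site
  independence; no Gamma rate heterogeneity is fitted.
* Hit filtering takes the E-value column at face value (no
  composition-based rescaling distinction).
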