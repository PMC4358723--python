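# Methods

## The detection model

The pipeline treats horizontal acquisition as a signal in alignment
bitscores. Under vertical descent a transcribed animal gene aligns
better to other metazoan proteins than to non-metazoan ones; a
horizontally acquired gene shows the reverse. The per-gene statistic is
the HGT index h, the best non-metazoan bitscore minus the best metazoan
bitscore, computed per transcript and inherited by the gene from the
transcript whose single best match (over both protein sets) is highest.
Two reductions shape the comparison sets:

* the focal species' own phylum is removed from the metazoan set, so a
  transfer that predates the radiation of the phylum — whose descendants
  all carry the gene — is not masked by those within-phylum homologs;
* viral hits are kept apart: a gene whose foreign signal exists only
  against viruses is labelled class V and excluded from the main
  classes, because the direction of virus-mediated transfer cannot be
  resolved from scores alone.

Absent matches are encoded as bitscore 0 with an explicit no-hit
marker: 0 sits below every threshold, which is the behaviour absence
must have (a class A gene may legitimately have *no* metazoan match at
all). A gene with no non-metazoan cellular hit has no h and is native
by fiat — the class C bitscore gate (≥ 100) makes this consistent.

Classes are nested. C: h ≥ 30 and best non-metazoan ≥ 100 — the 30 is a
large difference on a logarithmic score and is the established
sensitivity/specificity trade-off for this index; the 100 discards
genes whose non-metazoan alignments are all poor. B: the gene's
ortholog group averages h_orth ≥ 30, i.e. the gene looks foreign in
every species of the taxon it appears in. A: additionally no metazoan
match ≥ 100 for the gene or any group member.

## Ortholog groups and Markov clustering

Groups are clusters of the all-vs-all within-taxon blastp graph (edges
for pairs with e-value ≤ 1e-5; weight −log10(e-value) capped at 200,
the common practice when only a cutoff is given — raw-bitscore weights
are available by flag; weights symmetrised as the max of the two
directions). Markov clustering is implemented in-package (no installed
package provides it): add self-loops at each node's maximum incident
weight, column-normalise, then iterate expansion (matrix square),
inflation (entrywise power 15, then renormalise) and pruning of entries
below 1e-5, until the matrix changes by less than 1e-8 (max 200
iterations; non-convergence returns the current clustering with a
warning). Clusters are the connected components of the limit matrix's
support. The graph is processed per connected component — clusters can
never span components, and the dense matrices stay small even for
studies with thousands of genes. Inflation 15 is deliberately high:
within a group of closely related species, tight clusters approximate
ortholog groups.

Members lacking h (no non-metazoan hit) are excluded from the h_orth
mean — only scored genes carry the index — but their metazoan best
still enters the group maximum that vetoes class A; both choices are
configurable.

## Phylogenetic validation

Candidates with a metazoan match ≥ 50 bitscore get a taxon-labelled,
unrooted gene tree (tips `id|TAXON`). Monophyly is unrooted: a tip set
is monophyletic iff some single (possibly newly resolved) edge
separates it from its complement. Multifurcations are soft polytomies —
the test asks whether every component hanging off some vertex lies
wholly inside or outside the set, which equals the edge-bipartition
test on binary trees and is conservative toward validation on
polytomies. Own-phylum tips are ignored on both sides of every
monophyly test: for recent transfers the best own-phylum matches are
not orthologs of the foreign gene and may sit anywhere, including
inside the donor clade.

A tree validates its gene when the focal tips are monophyletic with one
donor kingdom (strictly: all of that kingdom's tips in the tree; a
relaxed mode requiring only that the focal tips nest inside a
kingdom-pure clade is available by flag), or with the union of two or
more kingdoms ("multiple potential donors", donor reported as
ambiguous), while not being monophyletic with the metazoan tips. One
degeneracy needs a rule of its own: on an unrooted tree, when the
focal-plus-donor clade spans every non-metazoan tip, "focal plus
metazoa" is the same bipartition read from the other side. In that
configuration the donor grouping wins — the complement reading carries
no independent evidence. The metazoan grouping blocks validation in
every other configuration, including when focal groups with both
metazoans and donors through genuinely distinct edges.

Contamination rescue: for each metazoan tip whose smallest bipartition
side contains no other metazoan and at least one non-metazoan tip — a
lone metazoan sequence inside another kingdom, the signature of a
contaminated database entry — relabel it to that side's majority
kingdom and re-run validation. A tree counts as rescued if any single
relabelling validates it. Rescue is only evaluated for trees that did
not validate as-is, and the rescued status is reported separately,
never substituted.

Where a validated tree yields an unambiguous donor, it is compared with
the bitscore-based donor (kingdom of the best non-metazoan match; ties
break by the fixed order bacteria, archaea, protists, fungi, plants).
Branch support values are parsed but never used: the rule is purely
topological.

## Genomic context and function

Linkage: a foreign gene sharing a scaffold with at least one native
gene (h < 30, or no h) is linked; contaminant sequences assemble into
scaffolds of their own and stay unlinked. Intron content: a gene has
introns if any transcript has ≥ 2 exons (gene-level, any-transcript
rule); foreign-vs-native intron proportions are compared by plain
Pearson chi-squared on the 2×2 table (no continuity correction by
default, flag available), optionally restricted to one donor kingdom —
bacterial donors are intronless, so recent bacterial transfers should
show an intron deficit while domesticated ancient ones should not.
Tables with a zero margin return chi2 = 0, p = 1 flagged unreliable;
any expected cell < 1 keeps the statistic but flags it.

Enrichment: per GO term annotating at least one foreign gene, the
upper-tail hypergeometric probability of the observed overlap given the
annotated background, BH-corrected across tested terms per species and
class, enriched at adjusted p ≤ 0.05 (raw-p mode by flag). Terms are
tested as annotated, without GO-graph ancestor propagation (no
propagation rule is assumed; a mode exists behind a flag). Enzyme bias
is the 2×2 chi-squared of enriched/un-enriched × enzyme/non-enzyme
flags, reported with the two enzyme percentages; with no enriched terms
the result is flagged "insufficient terms".

The gene-loss control set contains native genes with no match ≥ 100 in
any species of each of six branchpoints between the metazoan root and
the focal phylum — genes whose apparent restriction to the phylum would
require at least six independent losses. Their enrichment against the
remaining natives is the functional control for the loss alternative.

## Event mapping

Each foreign ortholog group is one founding event placed, single-gain
Dollo-style, on the branch above the most recent common ancestor of its
member species; groups spanning all species map to the root branch
(transfer anywhere between the phylum's origin and the taxon's base).
Secondary losses are silently absorbed by the MRCA placement — no
gain/loss optimisation is attempted, matching the one-event-per-group
reading. Input species trees must be rooted (a root trifurcation is
rejected); branches are named by the node below them, with stable
postorder `nodeK` labels where the Newick has none.

## The synthetic-study generator

The pipeline consumes scores, not sequences, so the generator simulates
at the score level — the minimal faithful model; sequence-level
simulation (codon models, database construction) is a non-goal. Per
gene family it plants one of four categories and draws per-gene best
bitscores (normal, common σ = 5 by default, values in bitscore units):

| category | best non-metazoan | best metazoan | placement |
|---|---|---|---|
| native | N(150, σ), absent with p = 0.3 | N(250, σ) | orthologs in all species |
| ancient HGT | N(200, σ) | non-met − Δ (Δ = 60) | all descendants of a random internal branch |
| recent HGT | N(200, σ) | N(60, σ) | one species |
| contaminant | N(250, σ) | none | one species, foreign-only scaffold |

Defaults: 4 species on a caterpillar tree, 500 families, 2% ancient,
2% recent, 1% contaminant. Δ = 60 with σ = 5 puts every planted
foreign gene above h = 30 with probability ≈ 1 − 1e-5; lowering Δ
toward 30 produces the misclassification rates predicted by the normal
tail, which the tests check. Recent transfers get class-A-like metazoan
scores (below 100, mostly above the validation gate of 50); ancient
ones sit around 140 — validatable, class B but not A. Own-phylum hits
are planted above the metazoan best for natives, exercising the
exclusion rule. Gene families carry complete within-family similarity
edges (e-value 1e-50) plus self-hits so singletons enter the graph.
Intron probabilities: 0.95 for natives and ancient transfers, 0.30 for
recent bacterial transfers (the recent-transfer deficit), 0 for
contaminants. GO: 150 background terms (enzyme probability 0.30) and 30
foreign-favoured terms (enzyme probability 0.67, drawn by foreign genes
with probability 0.8); the term universe is sized so that term-level
tests have realistic power — real annotated genomes carry hundreds of
terms. Donor kingdoms are drawn with bacteria and protists dominant
(0.50/0.25), then fungi, plants, archaea. Gene trees are generated
topologically — focal tip grafted inside the donor clade, metazoan and
own-phylum context tips, unit branch lengths — for foreign genes with a
metazoan match.

What the generator does *not* emulate: score noise correlated across
databases, partial assemblies, paralogy within species, HGT between
metazoans, and donor databases that lack the true donor. Passing tests
therefore demonstrate the correctness of the decision rules and the
internal consistency of the pipeline, not its error rates on real
genomes, which depend on database content.

## Numerical and interface choices

* Thresholds live in one dataclass (h ≥ 30, non-metazoan ≥ 100, class A
  gate 100, validation gate 50, e-value 1e-5, inflation 15), loadable
  from YAML; all are independent knobs.
* Ties break deterministically everywhere: lexicographic ids for
  transcripts and subjects, the fixed kingdom order for donors.
* Coordinates are GFF3-native 1-based inclusive throughout; no
  half-open conversion.
* Unmappable subject ids in hit tables are a hard error by default
  (silently dropping hits would bias h); a drop-with-warning policy is
  selectable.
* Hit rows are kept at full multiplicity on read; the single best HSP
  per pair wins at reduction time (HSP bitscores are not summed).
* Class V genes are removed before ortholog grouping.
* Generator runs are fully seeded; identical seeds give byte-identical
  study directories.

## Problem sizes used by the tests

The end-to-end recovery check runs 4 species × 2000 gene families with
5% planted foreign genes (Δ = 60, σ = 5), the oracle-equivalence suites
use 100 random graphs (≤ 10 nodes), 200 random 9-tip trees and all
hypergeometric tables with N ≤ 30 — sizes at which the independent
references (loop-coded dense MCL, edge-bipartition enumeration, exact
factorial sums, the closed-form Pearson statistic) are exhaustive or
near-exhaustive while the whole suite stays fast.

## Known limitations

* The strict donor-monophyly reading can fail genuinely transferred
  genes whose donor kingdom is polyphyletic in the gene tree; the
  relaxed nested-clade mode exists for exactly that case but is not the
  default.
* h_orth averages only scored members; a paper-exact denominator is
  unknowable from the published description and the alternative is one
  flag away.
* Event mapping ignores losses: a group absent from one descendant of
  its true origin branch maps too shallow.
* The enzyme over-representation test counts terms, not genes, so its
  power is bounded by annotation granularity.
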