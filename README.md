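# hgtscan

Detection of horizontally transferred (foreign) genes in animal genomes
from tabular protein-alignment scores: per-gene HGT index, nested
confidence classes via cross-species ortholog groups, phylogenetic
validation by monophyly rules, genomic-context and functional controls,
and mapping of founding transfer events onto a species phylogeny.

## Who this is for

Comparative genomicists asking how much of a transcriptome derives from
horizontal gene transfer (HGT) rather than vertical descent. The
pipeline consumes BLAST-style best-hit tables (a species' transcripts
aligned to a metazoan protein set with the species' own phylum removed,
and to a non-metazoan set partitioned by donor kingdom), gene models
(GFF3), Newick gene trees and a species tree, and GO annotations. It
never runs an aligner itself. A synthetic-study generator with planted
truth labels makes every stage testable without any sequence database.

## The statistic

For each transcribed gene the HGT index is

```
h = bitscore(best non-metazoan match) − bitscore(best metazoan match)
```

with the focal species' own phylum excluded from the metazoan set so
that ancient transfers remain detectable. Bitscores are log-scaled, so
h ≥ 30 means a much better alignment to non-metazoan sequences.

* **Class C** (candidate): `h ≥ 30` and best non-metazoan bitscore ≥ 100.
* **Class B** ⊆ C: the gene's cross-species ortholog group (Markov
  clustering of an all-vs-all blastp graph, e-value cutoff 1e-5,
  inflation I = 15) has group-average index `h_orth ≥ 30`.
* **Class A** ⊆ B: neither the gene nor any member of its group has a
  metazoan match with bitscore ≥ 100.
* **Class V**: genes whose foreign signal is exclusively viral are set
  aside (transfer direction is ambiguous).

Candidates with a metazoan match ≥ 50 are validated on unrooted,
taxon-labelled gene trees: validated when the focal sequences are
monophyletic with one donor kingdom (or a union of kingdoms) and not
with the metazoans; a stray metazoan tip nested alone inside a donor
clade can be flagged as probable database contamination ("rescue").
Scaffold linkage to native genes (h < 30) and intron-content
chi-squared tests control for assembly contamination, GO-term
hypergeometric enrichment with Benjamini–Hochberg correction tests the
enzyme bias expected of operational gene transfer, and each foreign
ortholog group is placed as a single founding event on the branch above
its member species' most recent common ancestor.

## Worked example

The classic case is the *C. elegans* trehalose-6-phosphate phosphatase
gene *gob-1*: best non-metazoan bitscore 135, best metazoan 39.3.

```python
from hgtscan import BestHits, HGTThresholds, compute_h, gene_score, classify_class_c
from hgtscan.orthogroups import OrthologGroup, annotate_groups, classify_class_a

best = BestHits("gob-1.t1", best_met_bitscore=39.3, best_nonmet_bitscore=135.0,
                has_met=True, has_nonmet=True)
print(compute_h(best))          # 95.7  -> foreign signal, well above 30
score = gene_score("gob-1", [best])
print(classify_class_c(score, HGTThresholds()))  # True -> class C
```

Its homologs in three congeners carry h = 102, 97.1 and 86.4, so the
group average is `h_orth = (95.7 + 102 + 97.1 + 86.4) / 4 = 95.3` —
class B — and with every member's best metazoan bitscore below 100
(39.3, 37, 38.9, 36.6) the gene is also class A.

End-to-end on synthetic data:

```python
from hgtscan import SimParams, generate_study, run_study, evaluate_recovery

study = generate_study(SimParams(n_species=4, genes_per_species=500, seed=1))
result = run_study(study)
print(result.class_counts())    # {'C': 45, 'B': 45, 'A': 15, 'V': 0}
metrics = evaluate_recovery(result.scores, study.truth, linkage=result.linkage,
                            event_assignments=result.event_assignments,
                            membership=result.membership)
print(metrics.precision["C"], metrics.recall["C"])   # 1.0 1.0
```

A `hgt` command-line tool wraps the same stages
(`hgt simulate / score / cluster / validate / context / functions /
events`, plus `hgt io validate` for format checking); see
`hgt --help`.

## Scope

The pipeline starts from score tables: building BLAST databases,
running alignments, inferring gene trees and curating GO enzyme flags
are upstream of it. Cross-taxon ortholog groups for distantly related
species are out of scope (the clustering is only reliable within groups
of closely related species).
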