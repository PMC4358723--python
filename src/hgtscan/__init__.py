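"""hgtscan: detection of horizontally transferred genes from alignment bitscores.

The core statistic is the HGT index

    h = bitscore(best non-metazoan match) − bitscore(best metazoan match)

computed per transcribed gene with the focal species' own phylum
excluded from the metazoan comparison set.  Candidate foreign genes
(h >= 30, best non-metazoan bitscore >= 100; class C) are refined via
cross-species ortholog groups (Markov clustering, inflation 15) into
class B (group-average h >= 30) and class A (additionally no metazoan
match >= 100 for the gene or any group member), validated
phylogenetically by monophyly rules on unrooted gene trees, checked
against contamination by scaffold linkage and intron content, and the
founding transfer events are mapped onto the species tree.
"""

from .core import (
    DONOR_KINGDOMS,
    GeneModel,
    GOAnnotation,
    HGTThresholds,
    HitRecord,
    TaxonGroup,
)
from .event_mapping import EventAssignment, SpeciesTree, branch_event_counts, map_group_to_branch
from .function_analysis import (
    EnrichmentTable,
    enzyme_over_representation,
    go_enrichment,
    loss_pattern_native_set,
)
from .genome_context import (
    ContingencyResult,
    LinkageResult,
    chi2_2x2,
    intron_contingency,
    linkage_test,
)
from .hgt_index import (
    BestHits,
    GeneScore,
    assign_donor_taxon,
    classify_class_c,
    compute_h,
    flag_viral,
    gene_score,
    reduce_best_hits,
    score_genes,
)
from .orthogroups import (
    MCLParams,
    OrthologGroup,
    SimilarityGraph,
    assign_classes,
    build_similarity_graph,
    classify_class_a,
    classify_class_b,
    compute_h_orth,
    mcl_cluster,
)
from .pipeline import StudyResult, run_study
from .synthetic import (
    RecoveryMetrics,
    SimParams,
    SyntheticStudy,
    TruthLabels,
    evaluate_recovery,
    generate_study,
)
from .tree_validation import (
    ValidationOutcome,
    contamination_rescue,
    is_monophyletic,
    phylo_origin_agreement,
    validate_gene_tree,
    validation_eligible,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
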