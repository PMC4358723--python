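"""End-to-end driver: scores → groups → classes → validation → controls → events."""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import HGTThresholds, TaxonGroup
from .event_mapping import EventAssignment, SpeciesTree, branch_event_counts, map_group_to_branch
from .genome_context import ContingencyResult, LinkageResult, intron_contingency, linkage_test
from .hgt_index import GeneScore, score_genes
from .io import tree_from_string
from .orthogroups import OrthologGroup, assign_classes, build_similarity_graph, mcl_cluster
from .synthetic import SyntheticStudy
from .tree_validation import (
    ValidationOutcome,
    classify_tips,
    contamination_rescue,
    validate_gene_tree,
    validation_eligible,
)


@dataclass
class StudyResult:
    """Everything the pipeline computed for one study."""

    scores: dict[str, GeneScore]
    groups: list[OrthologGroup]
    membership: dict[str, str]  # gene -> group id
    validations: dict[str, ValidationOutcome] = field(default_factory=dict)
    linkage: list[LinkageResult] = field(default_factory=list)
    intron_test: ContingencyResult | None = None
    event_assignments: list[EventAssignment] = field(default_factory=list)
    event_counts: dict[str, int] = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        """Cumulative class sizes honouring the nesting A ⊆ B ⊆ C."""
        n_a = sum(1 for s in self.scores.values() if s.hgt_class == "A")
        n_b = n_a + sum(1 for s in self.scores.values() if s.hgt_class == "B")
        n_c = n_b + sum(1 for s in self.scores.values() if s.hgt_class == "C")
        n_v = sum(1 for s in self.scores.values() if s.viral_flag)
        return {"C": n_c, "B": n_b, "A": n_a, "V": n_v}

    def h_orth_of(self, gene_id: str) -> float | None:
        gid = self.membership.get(gene_id)
        if gid is None:
            return None
        for g in self.groups:
            if g.group_id == gid:
                return g.h_orth
        return None


def run_study(study: SyntheticStudy, t: HGTThresholds | None = None) -> StudyResult:
    """Run the full pipeline on a synthetic study (all inputs in memory)."""
    t = t or HGTThresholds()
    scores = score_genes(study.hits, study.gene_of_transcript, t)

    graph = build_similarity_graph(study.pairwise_hits, t, species_of=study.species_of)
    groups = mcl_cluster(graph)
    membership = assign_classes(scores, groups, t)

    validations: dict[str, ValidationOutcome] = {}
    for gid, s in scores.items():
        if not s.is_foreign:
            continue
        if not validation_eligible(s, t):
            validations[gid] = ValidationOutcome("not_applicable")
            continue
        nwk = study.gene_trees.get(gid)
        if nwk is None:
            continue
        ltree = tree_from_string(nwk)
        focal, taxa = classify_tips(ltree)
        outcome = validate_gene_tree(ltree, focal, taxa)
        if not outcome.validated:
            outcome.rescue = contamination_rescue(ltree, focal, taxa)
        validations[gid] = outcome

    linkage = linkage_test(study.models, scores, "C", t)
    intron = intron_contingency(study.models, scores, "C", TaxonGroup.BACTERIA, t)

    stree = SpeciesTree(tree_from_string(study.species_tree_newick,
                                         tip_label_parser=None))
    assignments = []
    for g in groups:
        if any(
            scores.get(m) is not None and scores[m].is_foreign for m in g.members
        ):
            assignments.append(map_group_to_branch(g, stree, study.species_of))
    counts = branch_event_counts(assignments, stree)

    return StudyResult(
        scores=scores,
        groups=groups,
        membership=membership,
        validations=validations,
        linkage=linkage,
        intron_test=intron,
        event_assignments=assignments,
        event_counts=counts,
    )
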