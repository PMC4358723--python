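"""Mapping founding HGT events onto branches of the species tree.

Each foreign ortholog group is treated as one founding transfer event.
Under single-gain (Dollo-style) parsimony the event is placed on the
branch above the most recent common ancestor of the species that carry
member genes; groups present in every studied species map to the root
branch — the transfer happened anywhere between the origin of the
phylum and the taxon's base.  Counting the groups mapped to each branch
shows whether transfer is ancient (root-heavy) or ongoing (spread over
internal and terminal branches).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .io import LabelledTree
from .orthogroups import OrthologGroup


@dataclass
class EventAssignment:
    """One founding event: the group and the species-tree branch (named by
    the child node below the branch) above the members' MRCA."""

    group_id: str
    branch: str
    species_present: frozenset[str]


class SpeciesTree:
    """A rooted species tree with deterministically named branches.

    Every branch is identified by the node below it: tips keep their
    species name, unlabelled internal nodes get stable ``nodeK`` labels
    in postorder, and the root branch carries the root node's label.
    Trees whose root is an unresolved trifurcation are rejected — branch
    placement needs a rooted topology.
    """

    def __init__(self, ltree: LabelledTree):
        tree = ltree.tree
        seed = tree.seed_node
        n_children = len(seed.child_nodes())
        if n_children > 2:
            raise ValueError(
                "species tree appears unrooted (root has "
                f"{n_children} children); provide a rooted tree"
            )
        self.ltree = ltree
        self.tree = tree
        # a bifurcating root is the rooted reading of the topology; make it
        # explicit so MRCA queries respect it
        tree.is_rooted = True
        k = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node._branch_id = node.taxon.label
            elif node.label:
                node._branch_id = node.label
            else:
                node._branch_id = f"node{k}"
                k += 1
        self.species: set[str] = {lf.taxon.label for lf in tree.leaf_node_iter()}
        self.root_branch: str = seed._branch_id

    def branch_ids(self) -> list[str]:
        return [n._branch_id for n in self.tree.postorder_node_iter()]

    def mrca_branch(self, species: set[str]) -> str:
        missing = species - self.species
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        if len(species) == 1:
            return next(iter(species))
        taxa = [
            lf.taxon
            for lf in self.tree.leaf_node_iter()
            if lf.taxon.label in species
        ]
        mrca = self.tree.mrca(taxa=taxa)
        return mrca._branch_id


def read_species_tree(path) -> SpeciesTree:
    from .io import read_tree

    return SpeciesTree(read_tree(path, tip_label_parser=None))


def map_group_to_branch(
    group: OrthologGroup,
    stree: SpeciesTree,
    species_of: dict[str, str],
) -> EventAssignment:
    """Place one foreign group on the branch above its members' MRCA."""
    present = {species_of[m] for m in group.members if m in species_of}
    unknown = {m for m in group.members if m not in species_of}
    if unknown:
        raise ValueError(
            f"group {group.group_id}: members without species: {sorted(unknown)[:5]}"
        )
    if not present:
        raise ValueError(f"group {group.group_id} has no members with species")
    return EventAssignment(
        group_id=group.group_id,
        branch=stree.mrca_branch(present),
        species_present=frozenset(present),
    )


def branch_event_counts(
    assignments: list[EventAssignment], stree: SpeciesTree
) -> dict[str, int]:
    """Number of founding events per branch; branches with none count 0.

    The counts sum to the number of assignments (each group maps to
    exactly one branch).
    """
    counts = {b: 0 for b in stree.branch_ids()}
    for a in assignments:
        if a.branch not in counts:
            raise ValueError(f"assignment to unknown branch {a.branch!r}")
        counts[a.branch] += 1
    return counts
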