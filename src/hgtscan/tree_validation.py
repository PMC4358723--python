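"""Phylogenetic validation of candidate foreign genes by monophyly rules.

Candidate foreign genes with a metazoan match of bitscore >= 50 get a
taxon-labelled, unrooted gene tree.  A tree validates the candidate when
the focal (foreign) sequences are monophyletic with a single donor
kingdom, or with the union of several potential donor kingdoms, while
NOT being monophyletic with the metazoan sequences.  The focal species'
own phylum is set aside from the metazoan test set: for recent transfers
the best own-phylum matches are not orthologs of the foreign gene, so
its monophyly is not required.

Monophyly is taken in the unrooted sense: a tip set is monophyletic iff
it forms one side of the bipartition induced by removing a single edge.
Multifurcations are treated as soft polytomies — a tip set counts as
monophyletic if some resolution of the polytomy makes it so.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DONOR_KINGDOMS, TaxonGroup
from .hgt_index import GeneScore, HGTThresholds
from .io import LabelledTree

_KINGDOM_RANK = {k: i for i, k in enumerate(DONOR_KINGDOMS)}
_KINGDOM_RANK[TaxonGroup.VIRUSES] = len(DONOR_KINGDOMS)

#: tag spellings accepted when classifying tips from ``id|TAXON`` labels
TAG_ALIASES = {
    "metazoa": TaxonGroup.METAZOA,
    "metazoan": TaxonGroup.METAZOA,
    "metaz": TaxonGroup.METAZOA,
    "met": TaxonGroup.METAZOA,
    "own_phylum": TaxonGroup.OWN_PHYLUM,
    "bacteria": TaxonGroup.BACTERIA,
    "eubacteria": TaxonGroup.BACTERIA,
    "bact": TaxonGroup.BACTERIA,
    "archaea": TaxonGroup.ARCHAEA,
    "arch": TaxonGroup.ARCHAEA,
    "fungi": TaxonGroup.FUNGI,
    "fung": TaxonGroup.FUNGI,
    "plants": TaxonGroup.PLANTS,
    "plant": TaxonGroup.PLANTS,
    "viridiplantae": TaxonGroup.PLANTS,
    "protists": TaxonGroup.PROTISTS,
    "protist": TaxonGroup.PROTISTS,
    "prot": TaxonGroup.PROTISTS,
    "viruses": TaxonGroup.VIRUSES,
    "virus": TaxonGroup.VIRUSES,
    "vir": TaxonGroup.VIRUSES,
}


@dataclass
class ValidationOutcome:
    """Result of the monophyly-based validation of one gene tree.

    ``rescue`` marks trees that were not validated as-is but become
    validated when one stray metazoan tip is treated as non-metazoan
    contamination.  ``not_applicable`` marks genes that never entered
    validation (best metazoan bitscore below the eligibility gate).
    """

    status: str  # validated_single_donor | validated_multiple_donors | not_validated | not_applicable
    donor_inferred: TaxonGroup | None = None
    rescue: bool = False
    reason: str | None = None

    @property
    def validated(self) -> bool:
        return self.status in ("validated_single_donor", "validated_multiple_donors")


def validation_eligible(score: GeneScore, t: HGTThresholds) -> bool:
    """Eligible for phylogenetic validation: any metazoan match >= the gate.

    Without such a match there are no metazoan sequences to build a
    meaningful tree against; the gene cannot (and need not) be validated
    this way.
    """
    return score.has_met and score.best_met_bitscore >= t.validation_met_bitscore_min


# ---------------------------------------------------------------------------
# unrooted monophyly


def _adjacency(ltree: LabelledTree):
    """(adjacency over node indices, node index → tip label for leaves)."""
    nodes = list(ltree.tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    leaf_label: dict[int, str] = {}
    for n in nodes:
        i = index[id(n)]
        if n.parent_node is not None:
            j = index[id(n.parent_node)]
            adj[i].add(j)
            adj[j].add(i)
        if n.is_leaf():
            leaf_label[i] = n.taxon.label
    return adj, leaf_label


def _component_leafsets(adj, leaf_label, v: int) -> list[frozenset[str]]:
    """Leaf sets of the components of the tree with vertex v removed."""
    out = []
    seen = {v}
    for start in adj[v]:
        if start in seen:
            continue
        stack, leaves = [start], set()
        seen.add(start)
        while stack:
            n = stack.pop()
            if n in leaf_label:
                leaves.add(leaf_label[n])
            for m in adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        out.append(frozenset(leaves))
    return out


def _is_monophyletic_impl(
    adj, leaf_label, tipset: set[str], ignore: frozenset[str] = frozenset()
) -> bool:
    all_tips = set(leaf_label.values()) - ignore
    if len(tipset) == 1 or tipset >= all_tips:
        return True
    for v in adj:
        if v in leaf_label:
            continue
        comps = _component_leafsets(adj, leaf_label, v)
        if all(
            (c - ignore) <= tipset or not ((c - ignore) & tipset)
            for c in comps
        ):
            return True
    return False


def is_monophyletic(
    ltree: LabelledTree, tipset: set[str], *, ignore: set[str] | None = None
) -> bool:
    """Unrooted monophyly of ``tipset``, with soft polytomies.

    True iff some vertex v exists such that every component of the tree
    minus v lies entirely inside or entirely outside the tip set — i.e.
    a single (possibly newly resolved) edge would separate the set from
    its complement.  Singletons and the full tip set are trivially
    monophyletic.  Tips in ``ignore`` are disregarded on both sides of
    the test (used to set the own-phylum tips aside).
    """
    if not tipset:
        raise ValueError("tipset must be non-empty")
    adj, leaf_label = _adjacency(ltree)
    all_tips = set(leaf_label.values())
    missing = tipset - all_tips
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    return _is_monophyletic_impl(adj, leaf_label, tipset, frozenset(ignore or ()))


def _bipartition_sides(ltree: LabelledTree) -> list[frozenset[str]]:
    """All edge-bipartition sides (both orientations) of the tree."""
    adj, leaf_label = _adjacency(ltree)
    all_tips = frozenset(leaf_label.values())
    sides: set[frozenset[str]] = set()
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            # side of edge (u, v) on v's side
            stack, seen, leaves = [v], {u, v}, set()
            while stack:
                n = stack.pop()
                if n in leaf_label:
                    leaves.add(leaf_label[n])
                for m in adj[n]:
                    if m not in seen:
                        seen.add(m)
                        stack.append(m)
            side = frozenset(leaves)
            if side and side != all_tips:
                sides.add(side)
                sides.add(all_tips - side)
    return sorted(sides, key=lambda s: (len(s), sorted(s)))


# ---------------------------------------------------------------------------
# tip classification


def classify_tips(
    ltree: LabelledTree,
    *,
    own_phylum_tag: str | None = None,
    focal_tags: tuple[str, ...] = ("focal",),
) -> tuple[set[str], dict[str, TaxonGroup]]:
    """Split tips into focal sequences and taxon-labelled context tips.

    Tags matching a taxon-group name (or a common alias) classify the
    tip; ``own_phylum_tag`` (e.g. ``"Nematoda"``) maps that phylum to the
    own-phylum group; tags in ``focal_tags`` — and any unrecognised tag —
    mark the focal species' own sequences.
    """
    focal: set[str] = set()
    taxa: dict[str, TaxonGroup] = {}
    own = own_phylum_tag.lower() if own_phylum_tag else None
    for label, (_seq, tag) in ltree.tip_meta.items():
        low = tag.lower()
        if low in focal_tags:
            focal.add(label)
        elif own is not None and low == own:
            taxa[label] = TaxonGroup.OWN_PHYLUM
        elif low in TAG_ALIASES:
            taxa[label] = TAG_ALIASES[low]
        else:
            focal.add(label)
    return focal, taxa


# ---------------------------------------------------------------------------
# the validation rule


def validate_gene_tree(
    ltree: LabelledTree,
    focal_tips: set[str],
    tip_taxa: dict[str, TaxonGroup],
    *,
    strict_donor: bool = True,
) -> ValidationOutcome:
    """Apply the monophyly validation rule to one gene tree.

    With the own-phylum tips set aside from the metazoan test set:

    * ``validated_single_donor`` — focal tips plus ALL tips of one donor
      kingdom form a clade, and focal plus the metazoan tips do not;
    * ``validated_multiple_donors`` — same but only the union of two or
      more kingdoms' tips forms the clade with the focal sequences;
    * ``not_validated`` — the focal tips group with the metazoans (alone
      or together with donors), or with no kingdom at all.

    ``strict_donor=False`` relaxes "monophyletic with a donor kingdom" to
    "focal tips nested inside a clade containing only that kingdom" —
    the kingdom itself need not be complete in the clade.

    On an unrooted tree, when the focal-plus-donor clade and the
    focal-plus-metazoa grouping are two readings of the *same*
    bipartition (the donor grouping's complement is exactly the metazoan
    set), the donor grouping wins: the signal that the foreign gene sits
    inside the donor kingdom is direct, and the "grouping with metazoa"
    is only the trivial complement.  The metazoan grouping blocks
    validation whenever it holds in any other configuration.
    """
    if not focal_tips:
        raise ValueError("focal_tips must be non-empty")
    met_tips = {x for x, t in tip_taxa.items() if t is TaxonGroup.METAZOA}
    own_tips = frozenset(
        x for x, t in tip_taxa.items() if t is TaxonGroup.OWN_PHYLUM
    )
    kingdoms: dict[TaxonGroup, set[str]] = {}
    for x, t in tip_taxa.items():
        if t not in (TaxonGroup.METAZOA, TaxonGroup.OWN_PHYLUM):
            kingdoms.setdefault(t, set()).add(x)

    if not kingdoms:
        return ValidationOutcome("not_validated", reason="no_nonmetazoan_tips")

    all_kingdom_tips = set().union(*kingdoms.values())
    mono_with_met = bool(met_tips) and is_monophyletic(
        ltree, focal_tips | met_tips, ignore=own_tips
    )

    def acceptable(donor_used: set[str]) -> bool:
        # a metazoan grouping blocks unless it is merely the complement of
        # this donor grouping (possible only when the grouping spans every
        # non-metazoan tip in the tree)
        return not mono_with_met or donor_used == all_kingdom_tips

    single: list[TaxonGroup] = []
    if strict_donor:
        for k, tips in kingdoms.items():
            if is_monophyletic(ltree, focal_tips | tips, ignore=own_tips) and acceptable(tips):
                single.append(k)
    else:
        sides = _bipartition_sides(ltree)
        for k, tips in kingdoms.items():
            for side in sides:
                rest = side - focal_tips - own_tips
                if focal_tips <= side and rest and rest <= tips and acceptable(rest):
                    single.append(k)
                    break

    multi = False
    if not single and len(kingdoms) >= 2:
        # union of >= 2 kingdoms; 6 kingdoms max so enumeration is cheap
        from itertools import combinations

        names = sorted(kingdoms, key=lambda k: _KINGDOM_RANK[k])
        for r in range(2, len(names) + 1):
            for combo in combinations(names, r):
                tips = set().union(*(kingdoms[k] for k in combo))
                if is_monophyletic(
                    ltree, focal_tips | tips, ignore=own_tips
                ) and acceptable(tips):
                    multi = True
                    break
            if multi:
                break

    if single:
        donor = min(single, key=lambda k: _KINGDOM_RANK[k])
        return ValidationOutcome("validated_single_donor", donor_inferred=donor)
    if multi:
        return ValidationOutcome("validated_multiple_donors", donor_inferred=None)
    if mono_with_met:
        return ValidationOutcome("not_validated", reason="monophyletic_with_metazoa")
    return ValidationOutcome("not_validated", reason="no_donor_clade")


def contamination_rescue(
    ltree: LabelledTree,
    focal_tips: set[str],
    tip_taxa: dict[str, TaxonGroup],
    *,
    strict_donor: bool = True,
) -> bool:
    """Would one stray metazoan tip, treated as contamination, validate the tree?

    Candidate tips are metazoan tips m whose smallest bipartition side
    containing m holds no other metazoan tip and at least one
    non-metazoan tip — i.e. a lone metazoan sequence grouping inside
    another taxon, the signature of a contaminated database entry.  Each
    candidate is relabelled to the majority non-metazoan kingdom of that
    side and validation re-run; True iff any single relabelling yields a
    validated status.

    Only callable for trees that did not validate as-is.
    """
    base = validate_gene_tree(ltree, focal_tips, tip_taxa, strict_donor=strict_donor)
    if base.validated:
        raise ValueError("contamination_rescue requires a not-validated tree")

    met_tips = {x for x, t in tip_taxa.items() if t is TaxonGroup.METAZOA}
    sides = _bipartition_sides(ltree)
    for m in sorted(met_tips):
        candidate_sides = [
            s
            for s in sides
            if m in s
            and not ((s & met_tips) - {m})
            and any(
                x in tip_taxa
                and tip_taxa[x] not in (TaxonGroup.METAZOA, TaxonGroup.OWN_PHYLUM)
                for x in s
            )
            and not (s & focal_tips)
        ]
        if not candidate_sides:
            continue
        side = min(candidate_sides, key=len)
        counts: dict[TaxonGroup, int] = {}
        for x in side:
            t = tip_taxa.get(x)
            if t is not None and t not in (TaxonGroup.METAZOA, TaxonGroup.OWN_PHYLUM):
                counts[t] = counts.get(t, 0) + 1
        majority = min(counts.items(), key=lambda kv: (-kv[1], _KINGDOM_RANK[kv[0]]))[0]
        relabelled = dict(tip_taxa)
        relabelled[m] = majority
        if validate_gene_tree(
            ltree, focal_tips, relabelled, strict_donor=strict_donor
        ).validated:
            return True
    return False


def phylo_origin_agreement(
    outcome: ValidationOutcome, score: GeneScore
) -> bool | None:
    """Does the phylogenetically inferred donor match the best-hit donor?

    None when the comparison is undefined (tree not validated, donor
    ambiguous, or the gene carries no best-hit donor).
    """
    if not outcome.validated or outcome.donor_inferred is None:
        return None
    if score.donor is None:
        return None
    return outcome.donor_inferred is score.donor
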