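"""Ortholog groups by Markov clustering, h_orth, and classes B and A.

Per-species candidate calls are combined across the closely related
species of a taxon by clustering the all-vs-all protein similarity graph
(blastp-style pairwise hits, e-value cutoff 1e-5) with Markov clustering
at inflation 15.  A class C gene whose group-average HGT index (h_orth)
is >= 30 is class B — foreign on average across every species it is
found in.  Class A additionally requires that neither the gene nor any
member of its group has a metazoan match with bitscore >= 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import HGTThresholds, HitRecord
from .hgt_index import GeneScore

#: cap on the -log10(e-value) edge weight (e-value 0 would be infinite)
_WEIGHT_CAP = 200.0


@dataclass
class SimilarityGraph:
    """Undirected weighted protein-similarity graph across a taxon's species."""

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)

    def neighbors(self, node: str):
        for (a, b) in self.edges:
            if a == node:
                yield b
            elif b == node:
                yield a

    def connected_components(self) -> list[list[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        seen: set[str] = set()
        comps: list[list[str]] = []
        for start in self.nodes:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                n = stack.pop()
                comp.append(n)
                for m in adj[n]:
                    if m not in seen:
                        seen.add(m)
                        stack.append(m)
            comps.append(sorted(comp))
        return comps


@dataclass
class MCLParams:
    """Markov-clustering controls.

    inflation
        Entrywise power applied after each expansion; higher values give
        finer clusters.  The pipeline default (15) is deliberately high:
        with closely related species, tight clusters approximate
        ortholog groups.
    """

    inflation: float = 15.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class OrthologGroup:
    group_id: str
    members: set[str] = field(default_factory=set)
    h_orth: float | None = None
    group_max_met_bitscore: float = 0.0


def evalue_weight(evalue: float) -> float:
    """Edge weight −log10(e-value), capped so e-value 0 stays finite."""
    if evalue <= 0:
        return _WEIGHT_CAP
    return min(-np.log10(evalue), _WEIGHT_CAP)


def build_similarity_graph(
    pairwise_hits: list[HitRecord],
    t: HGTThresholds | None = None,
    *,
    species_of: dict[str, str] | None = None,
    use_bitscore_weights: bool = False,
) -> SimilarityGraph:
    """Build the within-taxon similarity graph from all-vs-all hits.

    Edges exist for pairs with e-value <= the cutoff; the weight is the
    capped −log10(e-value) (or the raw bitscore when
    ``use_bitscore_weights``), symmetrised as the max over the two
    alignment directions.  Self-hits are ignored.
    """
    t = t or HGTThresholds()
    nodes: set[str] = set()
    edges: dict[tuple[str, str], float] = {}
    for hit in pairwise_hits:
        nodes.add(hit.query_id)
        nodes.add(hit.subject_id)
        if hit.query_id == hit.subject_id:
            continue
        if hit.evalue > t.orthograph_evalue_max:
            continue
        w = hit.bitscore if use_bitscore_weights else evalue_weight(hit.evalue)
        key = (min(hit.query_id, hit.subject_id), max(hit.query_id, hit.subject_id))
        if w > edges.get(key, 0.0):
            edges[key] = w
    return SimilarityGraph(
        nodes=sorted(nodes), edges=edges, species_of=dict(species_of or {})
    )


def _mcl_component(
    nodes: list[str],
    edges: dict[tuple[str, str], float],
    p: MCLParams,
) -> tuple[list[set[str]], bool]:
    """Run dense MCL on one connected component; returns (clusters, converged)."""
    n = len(nodes)
    if n == 1:
        return [set(nodes)], True
    idx = {node: i for i, node in enumerate(nodes)}
    m = np.zeros((n, n))
    for (a, b), w in edges.items():
        i, j = idx[a], idx[b]
        m[i, j] = m[j, i] = w
    # self-loops: each node's max incident weight keeps the walk sticky
    # enough that singleton attractors do not depend on weight scale
    loops = m.max(axis=1)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(p.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, p.expansion)
        m = np.power(m, p.inflation)
        colsums = m.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        m /= colsums
        m[m < p.prune_threshold] = 0.0
        colsums = m.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        m /= colsums
        if prev.shape == m.shape and np.max(np.abs(m - prev)) < p.tolerance:
            converged = True
            break

    # clusters = connected components of the limit matrix's support
    support = (m + m.T) > p.prune_threshold
    seen = np.zeros(n, dtype=bool)
    clusters: list[set[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(support[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        clusters.append({nodes[i] for i in comp})
    return clusters, converged


def mcl_cluster(g: SimilarityGraph, p: MCLParams | None = None) -> list[OrthologGroup]:
    """Markov clustering of the similarity graph into ortholog groups.

    The graph is processed per connected component (clusters can never
    span components, and dense matrices stay small).  The output always
    partitions the node set; singletons are allowed.  Non-convergence
    within ``max_iterations`` returns the current clustering with a
    warning.
    """
    if not g.nodes:
        raise ValueError("cannot cluster an empty graph")
    p = p or MCLParams()
    comp_edges: dict[int, dict[tuple[str, str], float]] = {}
    comps = g.connected_components()
    node_comp = {n: ci for ci, comp in enumerate(comps) for n in comp}
    for (a, b), w in g.edges.items():
        comp_edges.setdefault(node_comp[a], {})[(a, b)] = w

    all_clusters: list[set[str]] = []
    any_unconverged = False
    for ci, comp in enumerate(comps):
        clusters, converged = _mcl_component(comp, comp_edges.get(ci, {}), p)
        any_unconverged |= not converged
        all_clusters.extend(clusters)
    if any_unconverged:
        warnings.warn("MCL did not converge within max_iterations; returning current clustering")

    all_clusters.sort(key=lambda c: min(c))
    return [
        OrthologGroup(group_id=f"OG{i:05d}", members=c)
        for i, c in enumerate(all_clusters)
    ]


def compute_h_orth(
    group: OrthologGroup, scores: dict[str, GeneScore]
) -> float | None:
    """Arithmetic mean of the members' h values.

    Members without an h (no non-metazoan hit) are excluded from the
    mean; a group where no member carries h has h_orth undefined and can
    never be class B.
    """
    hs = [
        scores[m].h
        for m in group.members
        if m in scores and scores[m].h is not None
    ]
    if not hs:
        return None
    return float(np.mean(hs))


def annotate_groups(
    groups: list[OrthologGroup], scores: dict[str, GeneScore]
) -> None:
    """Fill h_orth and the group-level max metazoan bitscore in place.

    Unscored members contribute nothing to h_orth but their metazoan
    best (0 when absent) still enters the class-A veto maximum.
    """
    for g in groups:
        g.h_orth = compute_h_orth(g, scores)
        mets = [
            scores[m].best_met_bitscore for m in g.members if m in scores
        ]
        g.group_max_met_bitscore = max(mets, default=0.0)


def classify_class_b(
    gene: GeneScore, group: OrthologGroup, t: HGTThresholds
) -> bool:
    """Class B: a class C gene whose group-average h is >= h_min."""
    if gene.hgt_class not in ("C", "B", "A"):
        return False
    return group.h_orth is not None and group.h_orth >= t.h_min


def classify_class_a(
    gene: GeneScore, group: OrthologGroup, t: HGTThresholds
) -> bool:
    """Class A: class B, and no metazoan match >= the gate for the gene
    or any member of its ortholog group."""
    if not classify_class_b(gene, group, t):
        return False
    return (
        gene.best_met_bitscore < t.classA_met_bitscore_max
        and group.group_max_met_bitscore < t.classA_met_bitscore_max
    )


def assign_classes(
    scores: dict[str, GeneScore],
    groups: list[OrthologGroup],
    t: HGTThresholds | None = None,
) -> dict[str, str]:
    """Upgrade class C genes to B/A using their ortholog groups.

    Genes absent from the similarity graph stay in their per-gene class
    (a class C singleton with no blastp hits cannot gain group support).
    Returns gene id → group id for grouped genes; GeneScore.hgt_class is
    updated in place.
    """
    t = t or HGTThresholds()
    annotate_groups(groups, scores)
    membership: dict[str, str] = {}
    for g in groups:
        for m in g.members:
            membership[m] = g.group_id
        for m in g.members:
            s = scores.get(m)
            if s is None or s.hgt_class != "C":
                continue
            if classify_class_a(s, g, t):
                s.hgt_class = "A"
            elif classify_class_b(s, g, t):
                s.hgt_class = "B"
    return membership
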