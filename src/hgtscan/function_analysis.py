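"""Functional characterisation: GO enrichment, enzyme bias, gene-loss control.

Horizontally acquired genes in other systems are biased toward
operational functions, typically enzymes.  This module tests that
pattern: per-term upper-tail hypergeometric enrichment of foreign genes
against the annotated background with Benjamini–Hochberg correction,
then a 2x2 chi-squared asking whether enzyme-activity terms are
over-represented among the enriched terms.

The gene-loss control builds the comparison set for the alternative
hypothesis — native genes whose apparent absence outside the focal
phylum would require independent losses at each of six branchpoints of
the metazoan tree.  If apparent foreignness were really serial loss,
these genes should look functionally like the foreign set; in practice
their enzyme bias runs the opposite way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GOAnnotation, HGTThresholds
from .genome_context import ContingencyResult, chi2_2x2


@dataclass
class EnrichmentTable:
    """Per-term enrichment results (one row per tested GO term)."""

    table: pd.DataFrame  # term, foreign_count, background_count, p, p_adj, enriched, enzyme
    n_foreign: int
    n_background: int

    @property
    def enriched_terms(self) -> set[str]:
        return set(self.table.loc[self.table["enriched"], "term"])


@dataclass
class LossPatternSet:
    """Native genes absent (bitscore < gate) at every required branchpoint."""

    members: set[str]
    loss_flags: dict[str, list[bool]] = field(default_factory=dict)


def hypergeom_enrichment_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric: P(X >= k) for overlap X of a size-n draw
    with a size-K term set from a size-N background."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def go_enrichment(
    foreign: set[str],
    background: set[str],
    ann: GOAnnotation,
    *,
    alpha: float = 0.05,
    adjusted: bool = True,
) -> EnrichmentTable:
    """Per-term hypergeometric enrichment of the foreign set.

    Only terms annotating at least one foreign gene are tested (a term
    absent from the foreign set can never be enriched there).  BH
    correction runs across the tested terms; a term is *enriched* when
    its BH-adjusted p (raw p when ``adjusted=False``) is <= alpha.
    Terms are tested as annotated, without GO-graph ancestor
    propagation.
    """
    if not foreign <= background:
        raise ValueError("foreign gene set must be a subset of the background")
    bg_annotated = {g for g in background if ann.gene_to_terms.get(g)}
    fg_annotated = foreign & bg_annotated
    N = len(bg_annotated)
    n = len(fg_annotated)

    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for g in bg_annotated:
        for t in ann.gene_to_terms[g]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in fg_annotated:
                term_fg[t] = term_fg.get(t, 0) + 1

    terms = sorted(t for t, c in term_fg.items() if c > 0)
    if not terms:
        empty = pd.DataFrame(
            columns=["term", "foreign_count", "background_count", "p", "p_adj", "enriched", "enzyme"]
        )
        return EnrichmentTable(table=empty, n_foreign=n, n_background=N)

    pvals = np.array(
        [hypergeom_enrichment_p(N, term_bg[t], n, term_fg[t]) for t in terms]
    )
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    crit = p_adj if adjusted else pvals
    df = pd.DataFrame(
        {
            "term": terms,
            "foreign_count": [term_fg[t] for t in terms],
            "background_count": [term_bg[t] for t in terms],
            "p": pvals,
            "p_adj": p_adj,
            "enriched": crit <= alpha,
            "enzyme": [ann.enzyme_flag[t] for t in terms],
        }
    )
    return EnrichmentTable(table=df, n_foreign=n, n_background=N)


def enzyme_over_representation(tab: EnrichmentTable) -> tuple[ContingencyResult, float | None, float | None]:
    """Are enzyme terms over-represented among enriched vs un-enriched terms?

    Returns the 2x2 chi-squared result plus the enzyme percentages of
    the enriched and un-enriched term sets.  With no enriched terms the
    comparison is flagged as having insufficient terms (chi2 undefined).
    """
    df = tab.table
    enr = df[df["enriched"]]
    unr = df[~df["enriched"]]
    pct_enr = 100.0 * enr["enzyme"].mean() if len(enr) else None
    pct_unr = 100.0 * unr["enzyme"].mean() if len(unr) else None
    table = np.array(
        [
            [int(enr["enzyme"].sum()), int((~enr["enzyme"]).sum())],
            [int(unr["enzyme"].sum()), int((~unr["enzyme"]).sum())],
        ]
    )
    if len(enr) == 0 or len(unr) == 0:
        res = ContingencyResult(
            table=table, chi2=0.0, p=1.0, significant=False,
            reliable=False, note="insufficient terms",
        )
    else:
        res = chi2_2x2(table)
    return res, pct_enr, pct_unr


def loss_pattern_native_set(
    native: set[str],
    best_bitscore_by_species: dict[str, dict[str, float]],
    branchpoints: list[set[str]],
    t: HGTThresholds | None = None,
) -> LossPatternSet:
    """Native genes whose distribution implies a loss at every branchpoint.

    For each branchpoint (a set of species splitting off between the
    metazoan root and the focal phylum — six in the default metazoan
    tree), a loss is inferred when the gene has no match with bitscore
    >= the class-A gate (100) in any species of that branchpoint.  Genes
    lost at all branchpoints form the control set for the gene-loss
    alternative hypothesis.
    """
    t = t or HGTThresholds()
    if not branchpoints or any(not bp for bp in branchpoints):
        raise ValueError("branchpoints must be non-empty species sets")
    members: set[str] = set()
    loss_flags: dict[str, list[bool]] = {}
    for g in sorted(native):
        per_species = best_bitscore_by_species.get(g, {})
        flags = []
        for bp in branchpoints:
            best = max((per_species.get(sp, 0.0) for sp in bp), default=0.0)
            flags.append(best < t.classA_met_bitscore_max)
        loss_flags[g] = flags
        if all(flags):
            members.add(g)
    return LossPatternSet(members=members, loss_flags=loss_flags)
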