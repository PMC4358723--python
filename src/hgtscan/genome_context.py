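"""Genomic sanity controls for candidate foreign genes.

Two checks guard against assembly contamination and implausible calls:

* scaffold linkage — a genuine foreign gene should share its scaffold
  with at least one native gene (h < 30); a contaminant scaffold holds
  foreign calls only;
* intron content — foreign genes of bacterial origin started intronless,
  so comparing intron proportions between foreign and native genes (2x2
  Pearson chi-squared) flags either recent transfer or contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GeneModel, HGTThresholds, TaxonGroup
from .hgt_index import GeneScore

_CLASS_ORDER = {"C": 0, "B": 1, "A": 2}


def _in_class(score: GeneScore, hgt_class: str) -> bool:
    """Class membership honouring the nesting A ⊆ B ⊆ C."""
    if score.hgt_class not in _CLASS_ORDER:
        return False
    return _CLASS_ORDER[score.hgt_class] >= _CLASS_ORDER[hgt_class]


def is_native(score: GeneScore | None, t: HGTThresholds) -> bool:
    """Native gene: h < h_min, or no h at all (no non-metazoan match)."""
    if score is None or score.h is None:
        return True
    return score.h < t.h_min


@dataclass
class LinkageResult:
    gene_id: str
    scaffold: str
    linked: bool
    n_native_on_scaffold: int


@dataclass
class ContingencyResult:
    """2x2 chi-squared comparison with the counts that produced it."""

    table: np.ndarray
    chi2: float
    p: float
    significant: bool
    reliable: bool = True
    note: str | None = None


def linkage_test(
    models: list[GeneModel],
    scores: dict[str, GeneScore],
    hgt_class: str = "C",
    t: HGTThresholds | None = None,
) -> list[LinkageResult]:
    """Scaffold co-occurrence of foreign genes with native genes.

    A foreign gene (of the requested class or better) is *linked* when
    at least one native gene sits on the same scaffold.  Foreign genes
    with no gene model are reported via a warning and excluded.
    """
    t = t or HGTThresholds()
    model_of = {m.gene_id: m for m in models}
    native_per_scaffold: dict[str, int] = {}
    for m in models:
        if is_native(scores.get(m.gene_id), t):
            native_per_scaffold[m.scaffold] = native_per_scaffold.get(m.scaffold, 0) + 1

    results: list[LinkageResult] = []
    unplaced: list[str] = []
    for gid in sorted(scores):
        if not _in_class(scores[gid], hgt_class):
            continue
        m = model_of.get(gid)
        if m is None:
            unplaced.append(gid)
            continue
        n_native = native_per_scaffold.get(m.scaffold, 0)
        results.append(
            LinkageResult(
                gene_id=gid,
                scaffold=m.scaffold,
                linked=n_native >= 1,
                n_native_on_scaffold=n_native,
            )
        )
    if unplaced:
        warnings.warn(
            f"{len(unplaced)} foreign genes without a gene model excluded "
            f"from the linkage test (e.g. {unplaced[:5]})"
        )
    return results


def chi2_2x2(table: np.ndarray, *, continuity_correction: bool = False) -> ContingencyResult:
    """Pearson chi-squared on a 2x2 table (no continuity correction by default).

    Degenerate tables (a zero margin) are returned with chi2 = 0, p = 1
    and flagged unreliable; tables with any expected cell < 1 keep their
    statistic but are flagged unreliable too.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return ContingencyResult(
            table=table, chi2=0.0, p=1.0, significant=False,
            reliable=False, note="degenerate margin",
        )
    chi2, p, _, expected = stats.chi2_contingency(
        table, correction=continuity_correction
    )
    reliable = bool((expected >= 1).all())
    return ContingencyResult(
        table=table,
        chi2=float(chi2),
        p=float(p),
        significant=bool(p <= 0.05),
        reliable=reliable,
        note=None if reliable else "expected cell < 1",
    )


def intron_contingency(
    models: list[GeneModel],
    scores: dict[str, GeneScore],
    hgt_class: str = "C",
    origin_filter: TaxonGroup | None = None,
    t: HGTThresholds | None = None,
    *,
    continuity_correction: bool = False,
) -> ContingencyResult:
    """Foreign vs native intron proportions (2x2 Pearson chi-squared).

    A gene "has introns" when any of its transcripts has >= 2 exons.
    ``origin_filter`` restricts the foreign set to one donor kingdom
    (e.g. bacteria, the kingdom whose donors are intronless).
    """
    t = t or HGTThresholds()
    fw = fwo = nw = nwo = 0
    for m in models:
        s = scores.get(m.gene_id)
        if s is not None and _in_class(s, hgt_class):
            if origin_filter is not None and s.donor is not origin_filter:
                continue
            if m.has_introns:
                fw += 1
            else:
                fwo += 1
        elif is_native(s, t):
            if m.has_introns:
                nw += 1
            else:
                nwo += 1
    table = np.array([[fw, fwo], [nw, nwo]])
    return chi2_2x2(table, continuity_correction=continuity_correction)


def export_positions(
    models: list[GeneModel],
    scores: dict[str, GeneScore],
    path,
    hgt_class: str = "C",
) -> int:
    """Write foreign-gene positions (scaffold, start, end, strand, class)
    as a TSV sorted by (scaffold, start); returns the row count."""
    model_of = {m.gene_id: m for m in models}
    rows = []
    for gid, s in scores.items():
        if not _in_class(s, hgt_class):
            continue
        m = model_of.get(gid)
        if m is None:
            continue
        rows.append((m.scaffold, m.start, m.end, m.strand, gid, s.hgt_class))
    rows.sort(key=lambda r: (r[0], r[1], r[4]))
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tstrand\tgene_id\thgt_class\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return len(rows)
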