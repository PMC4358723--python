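"""Readers and writers for the standard formats the pipeline touches.

TSV best-hit tables use the BLAST outfmt-6 column order
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore); gene models come from GFF3; trees are Newick with
``proteinid|TAXON`` tip labels by default; GO annotations and the
subject→taxon map are plain two-column TSVs.  Coordinates stay 1-based
inclusive (GFF3-native) throughout — there is no internal conversion to
half-open intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import dendropy
import yaml

from .core import GeneModel, GOAnnotation, HGTThresholds, HitRecord, TaxonGroup

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# best-hit tables


def read_taxon_map(path: str | Path) -> dict[str, TaxonGroup]:
    """Read a two-column TSV mapping subject protein id → taxon group."""
    out: dict[str, TaxonGroup] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, taxon = parts
            try:
                out[sid] = TaxonGroup(taxon)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unknown taxon {taxon!r}") from exc
    return out


def read_hits(
    path: str | Path,
    taxon_map: dict[str, TaxonGroup],
    *,
    on_unmapped: str = "error",
) -> list[HitRecord]:
    """Read a 12-column outfmt-6-like TSV into hit records.

    Duplicate (query, subject) rows — separate HSPs — are preserved; the
    max-bitscore reduction happens downstream.  Subjects absent from
    ``taxon_map`` are a hard error by default (silently dropping hits
    would bias the HGT index); pass ``on_unmapped="drop"`` to skip them
    with a warning instead.

    An empty file yields an empty list.
    """
    if on_unmapped not in ("error", "drop"):
        raise ValueError(f"on_unmapped must be 'error' or 'drop', got {on_unmapped!r}")
    records: list[HitRecord] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns (outfmt 6), got {len(parts)}"
                )
            qid, sid = parts[0], parts[1]
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric evalue/bitscore") from exc
            taxon = taxon_map.get(sid)
            if taxon is None:
                if on_unmapped == "error":
                    raise ParseError(
                        f"{path}:{lineno}: subject {sid!r} absent from taxon map"
                    )
                n_dropped += 1
                continue
            records.append(HitRecord(qid, sid, taxon, bitscore, evalue))
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} hits with unmapped subjects")
    return records


def write_hits(records: Iterable[HitRecord], path: str | Path) -> None:
    """Write hit records back to outfmt-6 TSV (placeholder alignment columns)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{r.evalue:g}\t{r.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.rstrip(";").split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a three-level (gene / mRNA / exon) GFF3 file into gene models.

    Exons with no resolvable parent are skipped with a warning; a gene
    with zero transcripts is an error.  Gene span falls back to the
    min/max over its transcripts' exon spans when the gene line's own
    coordinates are absent or narrower.
    """
    genes: dict[str, dict] = {}
    transcript_parent: dict[str, str] = {}
    exon_counts: dict[str, int] = {}
    exon_spans: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {
                    "scaffold": seqid,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "transcripts": [],
                }
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise ParseError(f"{path}:{lineno}: mRNA without ID/Parent")
                transcript_parent[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in transcript_parent:
                    warnings.warn(f"{path}:{lineno}: exon with unresolvable parent; skipped")
                    continue
                exon_counts[parent] = exon_counts.get(parent, 0) + 1
                exon_spans.setdefault(parent, []).append((start, end))

    for tid, gid in transcript_parent.items():
        if gid not in genes:
            warnings.warn(f"{path}: transcript {tid} references unknown gene {gid}; skipped")
            continue
        genes[gid]["transcripts"].append(tid)

    models: list[GeneModel] = []
    for gid, info in genes.items():
        tids = sorted(info["transcripts"])
        if not tids:
            raise ParseError(f"{path}: gene {gid} has zero transcripts")
        spans = [s for t in tids for s in exon_spans.get(t, [])]
        start, end = info["start"], info["end"]
        if spans:
            start = min(start, min(s for s, _ in spans))
            end = max(end, max(e for _, e in spans))
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_ids=tids,
                scaffold=info["scaffold"],
                start=start,
                end=end,
                strand=info["strand"],
                exon_count_per_transcript={t: exon_counts.get(t, 1) for t in tids},
            )
        )
    models.sort(key=lambda m: m.gene_id)
    return models


# ---------------------------------------------------------------------------
# trees


@dataclass
class LabelledTree:
    """A dendropy tree plus parsed per-tip metadata.

    ``tip_meta`` maps the raw tip label to ``(sequence id, label)`` where
    the label is a taxon-group name (gene trees) or species id (species
    trees).  ``degenerate`` flags trees with fewer than two tips.
    """

    tree: dendropy.Tree
    tip_meta: dict[str, tuple[str, str]]
    is_rooted: bool
    degenerate: bool = False
    path: str | None = None

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def parse_tip_label(label: str, delimiter: str = "|") -> tuple[str, str]:
    """Split ``proteinid|TAXON`` into its components."""
    if delimiter not in label:
        raise ParseError(f"tip label {label!r} lacks delimiter {delimiter!r}")
    seq_id, _, tag = label.rpartition(delimiter)
    if not seq_id or not tag:
        raise ParseError(f"tip label {label!r} is not 'id{delimiter}TAXON'")
    return seq_id, tag


def read_tree(
    path: str | Path,
    tip_label_parser: Callable[[str], tuple[str, str]] | None = parse_tip_label,
) -> LabelledTree:
    """Read a Newick tree, preserving topology and branch lengths.

    Tip labels are parsed into (id, taxon/species) with the pluggable
    parser; pass ``tip_label_parser=None`` to keep labels opaque (species
    trees whose tips are bare species names).
    """
    if hasattr(path, "read"):
        tree = dendropy.Tree.get(file=path, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tip_meta: dict[str, tuple[str, str]] = {}
    bad: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if tip_label_parser is None:
            tip_meta[label] = (label, label)
            continue
        try:
            tip_meta[label] = tip_label_parser(label)
        except ParseError:
            bad.append(label)
    if bad:
        raise ParseError("unparseable tip labels: " + ", ".join(sorted(bad)))
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    return LabelledTree(
        tree=tree,
        tip_meta=tip_meta,
        is_rooted=tree.is_rooted,
        degenerate=n_tips < 2,
        path=None if hasattr(path, "read") else str(path),
    )


def tree_from_string(
    newick: str,
    tip_label_parser: Callable[[str], tuple[str, str]] | None = parse_tip_label,
) -> LabelledTree:
    """Parse a Newick string directly (same contract as read_tree)."""
    import io as _io

    return read_tree(_io.StringIO(newick), tip_label_parser)


def write_tree(ltree: LabelledTree, path: str | Path) -> None:
    ltree.tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# GO annotations


def read_go(gene_terms_path: str | Path, enzyme_flags_path: str | Path) -> GOAnnotation:
    """Read gene→terms and term→enzyme-flag TSVs into a GOAnnotation.

    The gene table has one ``gene<TAB>term`` row per annotation; the flag
    table has ``term<TAB>{0,1|true,false}`` rows.  A term referenced by a
    gene but absent from the flag table is an error naming the terms.
    """
    gene_to_terms: dict[str, set[str]] = {}
    with open(gene_terms_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{gene_terms_path}:{lineno}: expected 2 columns")
            gene_to_terms.setdefault(parts[0], set()).add(parts[1])

    enzyme_flag: dict[str, bool] = {}
    truthy = {"1", "true", "True", "TRUE", "yes"}
    falsy = {"0", "false", "False", "FALSE", "no"}
    with open(enzyme_flags_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{enzyme_flags_path}:{lineno}: expected 2 columns")
            term, flag = parts
            if flag in truthy:
                enzyme_flag[term] = True
            elif flag in falsy:
                enzyme_flag[term] = False
            else:
                raise ParseError(f"{enzyme_flags_path}:{lineno}: bad flag {flag!r}")

    return GOAnnotation(gene_to_terms=gene_to_terms, enzyme_flag=enzyme_flag)


def write_go(ann: GOAnnotation, gene_terms_path: str | Path, enzyme_flags_path: str | Path) -> None:
    with open(gene_terms_path, "w") as fh:
        for gene in sorted(ann.gene_to_terms):
            for term in sorted(ann.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(enzyme_flags_path, "w") as fh:
        for term in sorted(ann.enzyme_flag):
            fh.write(f"{term}\t{int(ann.enzyme_flag[term])}\n")


# ---------------------------------------------------------------------------
# thresholds config


def read_thresholds(path: str | Path) -> HGTThresholds:
    """Load HGTThresholds from a YAML mapping; absent keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a YAML mapping of threshold names")
    valid = set(HGTThresholds.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ParseError(f"{path}: unknown threshold keys {sorted(unknown)}")
    return HGTThresholds(**data)


# ---------------------------------------------------------------------------
# gene report

REPORT_COLUMNS = [
    "gene_id",
    "source_transcript",
    "best_met_bitscore",
    "best_nonmet_bitscore",
    "h",
    "hgt_class",
    "viral_flag",
    "donor",
    "group_id",
    "h_orth",
    "validation",
    "linked",
]


def write_gene_report(
    scores: dict,
    path: str | Path,
    *,
    groups: dict | None = None,
    h_orth: dict | None = None,
    validations: dict | None = None,
    linkage: dict | None = None,
) -> None:
    """Write the per-gene summary TSV (one row per gene, sorted by id).

    ``scores`` maps gene id → GeneScore; the optional maps attach group
    id, group-average h, validation status and scaffold-linkage flags.
    Re-running on identical input produces a byte-identical file.
    """
    groups = groups or {}
    h_orth = h_orth or {}
    validations = validations or {}
    linkage = linkage or {}

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, bool):
            return str(int(x))
        if isinstance(x, float):
            return f"{x:g}"
        return str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for gid in sorted(scores):
            s = scores[gid]
            row = [
                gid,
                s.source_transcript,
                s.best_met_bitscore if s.has_met else None,
                s.best_nonmet_bitscore if s.has_nonmet else None,
                s.h,
                s.hgt_class,
                s.viral_flag,
                s.donor.value if s.donor is not None else None,
                groups.get(gid),
                h_orth.get(gid),
                getattr(validations.get(gid), "status", validations.get(gid)),
                linkage.get(gid),
            ]
            fh.write("\t".join(fmt(x) for x in row) + "\n")


def read_gene_report(path: str | Path):
    """Read a gene report back as a pandas DataFrame (NA-aware)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
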