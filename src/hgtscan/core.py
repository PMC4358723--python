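"""Domain types shared by every stage of the HGT-detection pipeline.

The pipeline consumes tabular best-hit alignment records (BLAST outfmt-6
style) of a study species' transcripts against two protein sets — metazoan
proteins (with the species' own phylum removed) and non-metazoan proteins
partitioned by donor kingdom — plus gene models, gene trees, a species tree
and GO annotations.  Everything downstream works on the small value types
defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class TaxonGroup(str, enum.Enum):
    """Taxonomic label attached to every subject protein.

    ``OWN_PHYLUM`` is conceptually a subset of Metazoa but is kept as its
    own label so that it can be excluded from the "best metazoan match"
    reduction: ancient transfers would otherwise be masked by recent
    paralogs inside the focal species' phylum.
    """

    METAZOA = "metazoa"
    OWN_PHYLUM = "own_phylum"
    BACTERIA = "bacteria"
    ARCHAEA = "archaea"
    FUNGI = "fungi"
    PLANTS = "plants"
    PROTISTS = "protists"
    VIRUSES = "viruses"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Cellular (non-viral) donor kingdoms, in the fixed tie-break order used
#: whenever two kingdoms reach the same bitscore.
DONOR_KINGDOMS: tuple[TaxonGroup, ...] = (
    TaxonGroup.BACTERIA,
    TaxonGroup.ARCHAEA,
    TaxonGroup.PROTISTS,
    TaxonGroup.FUNGI,
    TaxonGroup.PLANTS,
)

#: Groups counted as "non-metazoan cellular" in the h reduction.
NONMETAZOAN_CELLULAR: frozenset[TaxonGroup] = frozenset(DONOR_KINGDOMS)

#: Groups counted as "metazoan" once the own phylum has been split off.
METAZOAN: frozenset[TaxonGroup] = frozenset({TaxonGroup.METAZOA})


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit of a transcript against a subject protein.

    ``(query_id, subject_id)`` pairs may repeat (multiple HSPs); all rows
    are kept at read time and the max-bitscore reduction happens later so
    provenance is preserved.
    """

    query_id: str
    subject_id: str
    taxon: TaxonGroup
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise ValueError(
                f"bitscore must be > 0, got {self.bitscore!r} for "
                f"({self.query_id}, {self.subject_id})"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue!r}")


@dataclass
class HGTThresholds:
    """Tunable thresholds of the classification pipeline.

    h_min
        Minimum HGT index for a candidate (class C) foreign gene.
    nonmet_bitscore_min
        Minimum bitscore of the best non-metazoan match for class C;
        excludes genes whose non-metazoan alignments are all poor.
    classA_met_bitscore_max
        Exclusive upper bound on the best metazoan bitscore (for the gene
        and every member of its ortholog group) for class A.
    validation_met_bitscore_min
        Minimum best metazoan bitscore for a foreign gene to enter
        phylogenetic validation — with no metazoan match of at least this
        score there is nothing to build a meaningful tree against.
    orthograph_evalue_max
        E-value cutoff for edges of the all-vs-all protein similarity
        graph used for ortholog grouping.
    mcl_inflation
        Markov-clustering inflation parameter (granularity).
    """

    h_min: float = 30.0
    nonmet_bitscore_min: float = 100.0
    classA_met_bitscore_max: float = 100.0
    validation_met_bitscore_min: float = 50.0
    orthograph_evalue_max: float = 1e-5
    mcl_inflation: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "h_min",
            "nonmet_bitscore_min",
            "classA_met_bitscore_max",
            "validation_met_bitscore_min",
            "orthograph_evalue_max",
            "mcl_inflation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class GeneModel:
    """Genomic placement and exon structure of one gene.

    Coordinates are GFF3-native: 1-based, inclusive.  The intron count of
    a transcript is its exon count minus one.
    """

    gene_id: str
    transcript_ids: list[str]
    scaffold: str
    start: int
    end: int
    strand: str
    exon_count_per_transcript: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        for tid, n in self.exon_count_per_transcript.items():
            if n < 1:
                raise ValueError(f"transcript {tid}: exon count must be >= 1")

    @property
    def has_introns(self) -> bool:
        """True if any transcript has at least one intron (>= 2 exons)."""
        return any(n >= 2 for n in self.exon_count_per_transcript.values())

    def intron_count(self, transcript_id: str) -> int:
        return self.exon_count_per_transcript[transcript_id] - 1


@dataclass
class GOAnnotation:
    """Gene → GO-term map plus a per-term enzymatic-activity flag.

    Every term referenced by any gene must carry an enzyme flag; the
    constructor enforces this so downstream enrichment never encounters a
    term of unknown enzymatic status.
    """

    gene_to_terms: dict[str, set[str]]
    enzyme_flag: dict[str, bool]

    def __post_init__(self) -> None:
        missing = sorted(
            {t for terms in self.gene_to_terms.values() for t in terms}
            - set(self.enzyme_flag)
        )
        if missing:
            raise ValueError(
                "GO terms referenced by genes but missing an enzyme flag: "
                + ", ".join(missing)
            )

    @property
    def terms(self) -> set[str]:
        return {t for terms in self.gene_to_terms.values() for t in terms}
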