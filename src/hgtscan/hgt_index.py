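"""The HGT index h and the per-gene candidate (class C) classification.

For each transcript the hits are reduced to the best (maximum-bitscore)
match in two subsets: metazoan proteins with the focal species' own
phylum removed, and non-metazoan cellular proteins.  The HGT index is

    h = bitscore(best non-metazoan match) − bitscore(best metazoan match)

so h > 0 means the gene aligns better to non-metazoan sequences than to
metazoan ones — the signature of horizontal acquisition.  A gene is a
candidate foreign gene (class C) when h >= 30 and its best non-metazoan
bitscore is >= 100; the donor kingdom is that of the best non-metazoan
match.  Genes whose foreign signal is exclusively viral are flagged as
class V and excluded from the A/B/C classes because the direction of
virus-mediated transfer is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    DONOR_KINGDOMS,
    NONMETAZOAN_CELLULAR,
    HGTThresholds,
    HitRecord,
    TaxonGroup,
)

_KINGDOM_RANK = {k: i for i, k in enumerate(DONOR_KINGDOMS)}


@dataclass
class BestHits:
    """Per-transcript maxima over the relevant hit subsets.

    Absence of a hit in a subset is encoded as bitscore 0 with the
    corresponding ``has_*`` marker False; 0 sits below every threshold,
    which is exactly the behaviour absence must have.
    """

    transcript_id: str
    best_met_bitscore: float = 0.0
    best_nonmet_bitscore: float = 0.0
    best_viral_bitscore: float = 0.0
    has_met: bool = False
    has_nonmet: bool = False
    has_viral: bool = False
    best_per_kingdom: dict[TaxonGroup, tuple[str, float]] = field(default_factory=dict)

    @property
    def overall_max(self) -> float:
        """Highest bitscore over both databases (viral included)."""
        return max(self.best_met_bitscore, self.best_nonmet_bitscore, self.best_viral_bitscore)


@dataclass
class GeneScore:
    """Per-gene score: h inherited from the best-matching transcript."""

    gene_id: str
    source_transcript: str
    best_met_bitscore: float
    best_nonmet_bitscore: float
    has_met: bool
    has_nonmet: bool
    h: float | None
    donor: TaxonGroup | None = None
    hgt_class: str = "native"  # native | C | B | A
    viral_flag: bool = False
    best_hits: BestHits | None = None

    @property
    def is_foreign(self) -> bool:
        return self.hgt_class in ("C", "B", "A")


def reduce_best_hits(
    hits: list[HitRecord], *, own_phylum_excluded: bool = True
) -> dict[str, BestHits]:
    """Reduce raw hits to per-transcript best scores.

    The metazoan best excludes own-phylum hits (when ``own_phylum_excluded``,
    the default) so that ancient transfers — which still have close
    homologs inside the focal phylum — remain detectable.  Viral hits are
    kept apart from the cellular non-metazoan best.  Multiple HSPs per
    (query, subject) pair collapse to the single best one here.
    """
    out: dict[str, BestHits] = {}
    for hit in hits:
        best = out.get(hit.query_id)
        if best is None:
            best = out[hit.query_id] = BestHits(transcript_id=hit.query_id)
        t = hit.taxon
        if t is TaxonGroup.METAZOA or (
            t is TaxonGroup.OWN_PHYLUM and not own_phylum_excluded
        ):
            if hit.bitscore > best.best_met_bitscore:
                best.best_met_bitscore = hit.bitscore
            best.has_met = True
        elif t is TaxonGroup.VIRUSES:
            if hit.bitscore > best.best_viral_bitscore:
                best.best_viral_bitscore = hit.bitscore
            best.has_viral = True
            _update_kingdom(best, t, hit)
        elif t in NONMETAZOAN_CELLULAR:
            if hit.bitscore > best.best_nonmet_bitscore:
                best.best_nonmet_bitscore = hit.bitscore
            best.has_nonmet = True
            _update_kingdom(best, t, hit)
        # own-phylum hits under the default policy fall through: excluded
        # from the metazoan best and never a donor.
    return out


def _update_kingdom(best: BestHits, taxon: TaxonGroup, hit: HitRecord) -> None:
    cur = best.best_per_kingdom.get(taxon)
    # ties broken toward the lexicographically smaller subject id
    if (
        cur is None
        or hit.bitscore > cur[1]
        or (hit.bitscore == cur[1] and hit.subject_id < cur[0])
    ):
        best.best_per_kingdom[taxon] = (hit.subject_id, hit.bitscore)


def compute_h(best: BestHits) -> float | None:
    """HGT index: best non-metazoan bitscore minus best metazoan bitscore.

    A transcript with no non-metazoan (cellular) hit has no defined h —
    it is native by fiat.  A missing metazoan match contributes 0, which
    maps absence below every threshold.
    """
    if not best.has_nonmet:
        return None
    return best.best_nonmet_bitscore - best.best_met_bitscore


def gene_score(gene_id: str, transcript_bests: list[BestHits]) -> GeneScore:
    """Inherit the gene's h from the transcript with the highest-scoring match.

    The source transcript is the one whose single highest bitscore over
    both databases is maximal; ties break toward the lexicographically
    smaller transcript id for reproducibility.
    """
    if not transcript_bests:
        raise ValueError(f"gene {gene_id}: no transcripts to score")
    source = min(transcript_bests, key=lambda b: (-b.overall_max, b.transcript_id))
    return GeneScore(
        gene_id=gene_id,
        source_transcript=source.transcript_id,
        best_met_bitscore=source.best_met_bitscore,
        best_nonmet_bitscore=source.best_nonmet_bitscore,
        has_met=source.has_met,
        has_nonmet=source.has_nonmet,
        h=compute_h(source),
        best_hits=source,
    )


def classify_class_c(score: GeneScore, t: HGTThresholds) -> bool:
    """Candidate foreign gene: h >= h_min and best non-metazoan >= the gate.

    Genes flagged class V (viral-only signal) are excluded.
    """
    if score.viral_flag or score.h is None:
        return False
    return (
        score.h >= t.h_min
        and score.best_nonmet_bitscore >= t.nonmet_bitscore_min
    )


def assign_donor_taxon(best: BestHits) -> TaxonGroup | None:
    """Donor kingdom = taxon of the best non-metazoan cellular match.

    Bitscore ties between kingdoms break by the fixed order bacteria,
    archaea, protists, fungi, plants.
    """
    candidates = [
        (kingdom, sb[1])
        for kingdom, sb in best.best_per_kingdom.items()
        if kingdom in NONMETAZOAN_CELLULAR
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda kb: (-kb[1], _KINGDOM_RANK[kb[0]]))[0]


def flag_viral(best: BestHits, t: HGTThresholds) -> bool:
    """Class V: foreign signal carried only by viral matches.

    True iff the gene would pass the class C gates were the viral best
    used as its non-metazoan score, while its best cellular non-metazoan
    hit fails those gates.  Such genes are excluded from classes C/B/A
    (transfer direction is ambiguous) and reported separately.
    """
    if not best.has_viral:
        return False
    viral_as_c = (
        best.best_viral_bitscore - best.best_met_bitscore >= t.h_min
        and best.best_viral_bitscore >= t.nonmet_bitscore_min
    )
    cellular_c = (
        best.has_nonmet
        and best.best_nonmet_bitscore - best.best_met_bitscore >= t.h_min
        and best.best_nonmet_bitscore >= t.nonmet_bitscore_min
    )
    return viral_as_c and not cellular_c


def score_genes(
    hits: list[HitRecord],
    gene_of_transcript: dict[str, str],
    t: HGTThresholds | None = None,
) -> dict[str, GeneScore]:
    """Full per-gene scoring: reduce, inherit, flag V, classify C, donor.

    ``gene_of_transcript`` maps transcript id → gene id; transcripts with
    hits but no gene mapping are an error (they would silently vanish
    from the analysis otherwise).
    """
    t = t or HGTThresholds()
    bests = reduce_best_hits(hits)
    missing = sorted(set(bests) - set(gene_of_transcript))
    if missing:
        raise ValueError(
            "transcripts with hits but no gene mapping: " + ", ".join(missing[:10])
        )
    by_gene: dict[str, list[BestHits]] = {}
    for tid, best in bests.items():
        by_gene.setdefault(gene_of_transcript[tid], []).append(best)

    scores: dict[str, GeneScore] = {}
    for gid, tb in by_gene.items():
        s = gene_score(gid, tb)
        s.viral_flag = flag_viral(s.best_hits, t)
        if classify_class_c(s, t):
            s.hgt_class = "C"
            s.donor = assign_donor_taxon(s.best_hits)
        scores[gid] = s
    return scores
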