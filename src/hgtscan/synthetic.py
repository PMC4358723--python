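"""Synthetic multi-species studies with planted truth for every gene.

The pipeline consumes alignment *scores*, not sequences, so the
generator simulates directly at the score level: per-gene best-hit
bitscores for the metazoan and non-metazoan protein sets, an all-vs-all
within-taxon similarity table encoding the planted ortholog families,
gene models on scaffolds, GO annotations with an enzyme bias for
foreign genes, taxon-labelled gene trees consistent with the planted
donor, and a rooted species tree.

Planted categories per gene family:

* ``native`` — vertical descent: metazoan best well above non-metazoan
  best (h strongly negative), orthologs in every species.
* ``ancient_HGT`` — transferred on an internal branch of the species
  tree: orthologs in every descendant species, non-metazoan best above
  metazoan best by at least the signal Δ.
* ``recent_HGT`` — species-specific transfer: single species, weak
  metazoan similarity (class-A-like signal).
* ``contaminant`` — assembly contamination: strong bacterial score, no
  metazoan match, intronless, and placed on a foreign-only scaffold.

The same seed always yields a byte-identical study directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import DONOR_KINGDOMS, GeneModel, GOAnnotation, HitRecord, TaxonGroup
from .io import write_go, write_hits

#: donor-kingdom sampling weights — bacteria and protists dominate,
#: mirroring the relative abundance of potential donors
_DONOR_WEIGHTS = {
    TaxonGroup.BACTERIA: 0.50,
    TaxonGroup.PROTISTS: 0.25,
    TaxonGroup.FUNGI: 0.12,
    TaxonGroup.PLANTS: 0.08,
    TaxonGroup.ARCHAEA: 0.05,
}

NATIVE = "native"
ANCIENT = "ancient_HGT"
RECENT = "recent_HGT"
CONTAMINANT = "contaminant"


@dataclass
class SimParams:
    """Study-generation controls.

    The bitscore model draws per-gene best scores from normal
    distributions (bitscore units): natives have metazoan mean
    ``mu_met_native`` above non-metazoan mean ``mu_nonmet_native``;
    foreign genes have non-metazoan mean ``mu_nonmet_foreign`` with the
    metazoan best ``delta`` below it (ancient) or down at
    ``mu_met_recent`` (recent, class-A-like).  ``sigma`` is the common
    spread.  Intron probabilities encode that recently transferred
    bacterial genes have had no time to gain introns.
    """

    n_species: int = 4
    genes_per_species: int = 500
    frac_ancient: float = 0.02
    frac_recent: float = 0.02
    frac_contaminant: float = 0.01
    delta: float = 60.0
    sigma: float = 5.0
    mu_met_native: float = 250.0
    mu_nonmet_native: float = 150.0
    mu_nonmet_foreign: float = 200.0
    mu_met_recent: float = 60.0
    mu_nonmet_contaminant: float = 250.0
    p_native_no_nonmet: float = 0.3
    p_intron_native: float = 0.95
    p_intron_recent_bacterial: float = 0.30
    p_intron_ancient: float = 0.95
    p_second_transcript: float = 0.1
    genes_per_scaffold: int = 10
    n_go_terms_background: int = 150
    n_go_terms_foreign_pool: int = 30
    p_enzyme_background: float = 0.30
    p_enzyme_foreign_pool: float = 0.67
    p_foreign_pool_draw: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_ancient + self.frac_recent + self.frac_contaminant
        if total > 1:
            raise ValueError(f"foreign fractions sum to {total} > 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        for name in (
            "frac_ancient", "frac_recent", "frac_contaminant",
            "p_native_no_nonmet", "p_intron_native",
            "p_intron_recent_bacterial", "p_intron_ancient",
            "p_second_transcript", "p_foreign_pool_draw",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")


@dataclass
class TruthLabels:
    """Planted ground truth, keyed by gene id."""

    label: dict[str, str]  # native | ancient_HGT | recent_HGT | contaminant
    donor: dict[str, TaxonGroup]
    family_of: dict[str, str]
    event_branch: dict[str, str]  # family id -> planted branch (foreign families)
    family_members: dict[str, set[str]]

    def foreign_genes(self) -> set[str]:
        return {g for g, lab in self.label.items() if lab != NATIVE}

    def contaminants(self) -> set[str]:
        return {g for g, lab in self.label.items() if lab == CONTAMINANT}

    def ancient_families(self) -> dict[str, str]:
        return {
            f: b
            for f, b in self.event_branch.items()
            if any(self.label[m] == ANCIENT for m in self.family_members[f])
        }


@dataclass
class SyntheticStudy:
    """A generated study: every input the pipeline reads, plus the truth."""

    params: SimParams
    species: list[str]
    species_tree_newick: str
    hits: list[HitRecord]
    taxon_map: dict[str, TaxonGroup]
    gene_of_transcript: dict[str, str]
    pairwise_hits: list[HitRecord]
    models: list[GeneModel]
    go: GOAnnotation
    gene_trees: dict[str, str]  # gene id -> newick with id|TAXON tips
    species_of: dict[str, str]
    truth: TruthLabels
    branches: dict[str, list[str]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write the study in the standard formats (deterministic bytes)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_hits(sorted(self.hits, key=lambda h: (h.query_id, h.subject_id, -h.bitscore)),
                   out / "hits.tsv")
        write_hits(
            sorted(self.pairwise_hits, key=lambda h: (h.query_id, h.subject_id)),
            out / "pairwise.tsv",
        )
        with open(out / "taxon_map.tsv", "w") as fh:
            for sid in sorted(self.taxon_map):
                fh.write(f"{sid}\t{self.taxon_map[sid].value}\n")
        with open(out / "transcript_map.tsv", "w") as fh:
            for tid in sorted(self.gene_of_transcript):
                fh.write(f"{tid}\t{self.gene_of_transcript[tid]}\n")
        with open(out / "species_map.tsv", "w") as fh:
            for gid in sorted(self.species_of):
                fh.write(f"{gid}\t{self.species_of[gid]}\n")
        _write_gff3(self.models, out / "genes.gff3")
        write_go(self.go, out / "go_gene_terms.tsv", out / "go_enzyme_flags.tsv")
        with open(out / "species_tree.nwk", "w") as fh:
            fh.write(self.species_tree_newick + "\n")
        trees = out / "trees"
        trees.mkdir(exist_ok=True)
        for gid in sorted(self.gene_trees):
            with open(trees / f"{gid}.nwk", "w") as fh:
                fh.write(self.gene_trees[gid] + "\n")
        with open(out / "truth_labels.tsv", "w") as fh:
            fh.write("gene_id\tlabel\tdonor\tfamily\tevent_branch\n")
            for gid in sorted(self.truth.label):
                fam = self.truth.family_of[gid]
                fh.write(
                    f"{gid}\t{self.truth.label[gid]}\t"
                    f"{self.truth.donor.get(gid, TaxonGroup.METAZOA).value}\t"
                    f"{fam}\t{self.truth.event_branch.get(fam, 'NA')}\n"
                )


def _write_gff3(models: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.scaffold, m.start, m.gene_id)):
            fh.write(
                f"{m.scaffold}\t.\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for tid in m.transcript_ids:
                fh.write(
                    f"{m.scaffold}\t.\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                    f"ID={tid};Parent={m.gene_id}\n"
                )
                n_exons = m.exon_count_per_transcript[tid]
                span = m.end - m.start + 1
                step = max(span // n_exons, 2)
                for e in range(n_exons):
                    es = m.start + e * step
                    ee = min(es + step - 2, m.end) if e < n_exons - 1 else m.end
                    fh.write(
                        f"{m.scaffold}\t.\texon\t{es}\t{ee}\t.\t{m.strand}\t.\t"
                        f"ID={tid}.e{e + 1};Parent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# species tree


def pectinate_tree(species: list[str]) -> tuple[str, dict[str, list[str]]]:
    """Caterpillar species tree with labelled internal nodes.

    Returns the newick string and a map branch id → descendant species.
    Internal branches are ``anc1 .. ancK`` from shallowest to deepest,
    the root branch is ``root``.
    """
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    nwk = f"({species[0]},{species[1]})"
    descendants = {sp: [sp] for sp in species}
    clade = [species[0], species[1]]
    k = 0
    for sp in species[2:]:
        k += 1
        nwk = f"({nwk}anc{k},{sp})"
        descendants[f"anc{k}"] = list(clade)
        clade.append(sp)
    nwk += "root;"
    descendants["root"] = list(species)
    # branch above the first cherry
    if len(species) > 2:
        descendants["anc1"] = species[:2]
    else:
        descendants["root"] = list(species)
    return nwk, descendants


def _evalue_for(bitscore: float) -> float:
    return max(10.0 ** (-bitscore / 5.0), 1e-180)


# ---------------------------------------------------------------------------
# the generator


def generate_study(p: SimParams) -> SyntheticStudy:
    """Generate a fully consistent study with planted truth labels."""
    rng = np.random.default_rng(p.seed)
    species = [f"sp{i + 1}" for i in range(p.n_species)]
    tree_nwk, descendants = pectinate_tree(species)
    internal_branches = [b for b in descendants if b not in species]

    donors = list(_DONOR_WEIGHTS)
    donor_p = np.array([_DONOR_WEIGHTS[d] for d in donors])
    donor_p = donor_p / donor_p.sum()

    n_fam = p.genes_per_species
    n_anc = int(round(p.frac_ancient * n_fam))
    n_rec = int(round(p.frac_recent * n_fam))
    n_con = int(round(p.frac_contaminant * n_fam))

    categories = (
        [ANCIENT] * n_anc + [RECENT] * n_rec + [CONTAMINANT] * n_con
        + [NATIVE] * (n_fam - n_anc - n_rec - n_con)
    )
    # scatter foreign families among native ones so scaffolds mix the two,
    # the way real foreign genes sit amid native neighbours
    rng.shuffle(categories)

    hits: list[HitRecord] = []
    taxon_map: dict[str, TaxonGroup] = {}
    gene_of_transcript: dict[str, str] = {}
    pairwise: list[HitRecord] = []
    species_of: dict[str, str] = {}
    gene_trees: dict[str, str] = {}
    label: dict[str, str] = {}
    donor_truth: dict[str, TaxonGroup] = {}
    family_of: dict[str, str] = {}
    event_branch: dict[str, str] = {}
    family_members: dict[str, set[str]] = {}
    intron_flag: dict[str, bool] = {}

    def add_hit(tid: str, sid: str, taxon: TaxonGroup, bitscore: float) -> None:
        bitscore = max(round(float(bitscore), 1), 1.0)
        taxon_map[sid] = taxon
        hits.append(HitRecord(tid, sid, taxon, bitscore, _evalue_for(bitscore)))

    for fam_idx, category in enumerate(categories):
        fam_id = f"fam{fam_idx:05d}"
        if category == NATIVE:
            members = list(species)
            donor = TaxonGroup(rng.choice([d.value for d in donors], p=donor_p))
        elif category == ANCIENT:
            branch = internal_branches[int(rng.integers(len(internal_branches)))]
            members = descendants[branch]
            donor = TaxonGroup(rng.choice([d.value for d in donors], p=donor_p))
            event_branch[fam_id] = branch
        elif category == RECENT:
            sp = species[int(rng.integers(len(species)))]
            members = [sp]
            donor = TaxonGroup(rng.choice([d.value for d in donors], p=donor_p))
            event_branch[fam_id] = sp
        else:  # contaminant
            sp = species[int(rng.integers(len(species)))]
            members = [sp]
            donor = TaxonGroup.BACTERIA
            event_branch[fam_id] = sp

        fam_genes: list[str] = []
        for sp in members:
            gid = f"{sp}_g{fam_idx:05d}"
            fam_genes.append(gid)
            species_of[gid] = sp
            label[gid] = category
            family_of[gid] = fam_id
            if category != NATIVE:
                donor_truth[gid] = donor

            # --- bitscores for the primary transcript
            if category == NATIVE:
                met = rng.normal(p.mu_met_native, p.sigma)
                nonmet = (
                    None
                    if rng.random() < p.p_native_no_nonmet
                    else rng.normal(p.mu_nonmet_native, p.sigma)
                )
                own = rng.normal(p.mu_met_native + 100, p.sigma)
            elif category == ANCIENT:
                nonmet = rng.normal(p.mu_nonmet_foreign, p.sigma)
                met = nonmet - p.delta + rng.normal(0, p.sigma)
                own = rng.normal(p.mu_nonmet_foreign + 50, p.sigma)
            elif category == RECENT:
                nonmet = rng.normal(p.mu_nonmet_foreign, p.sigma)
                met = rng.normal(p.mu_met_recent, p.sigma)
                own = rng.normal(p.mu_met_recent + 20, p.sigma)
            else:  # contaminant: no metazoan or own-phylum signal at all
                nonmet = rng.normal(p.mu_nonmet_contaminant, p.sigma)
                met = None
                own = None

            tids = [f"{gid}.t1"]
            if category == NATIVE and rng.random() < p.p_second_transcript:
                tids.append(f"{gid}.t2")
            for k, tid in enumerate(tids):
                gene_of_transcript[tid] = gid
                drop = 15.0 * k  # secondary transcript scores strictly lower
                if met is not None:
                    add_hit(tid, f"met_{gid}", TaxonGroup.METAZOA, met - drop)
                    add_hit(tid, f"met2_{gid}", TaxonGroup.METAZOA, met - drop - 20)
                if own is not None:
                    add_hit(tid, f"ophy_{gid}", TaxonGroup.OWN_PHYLUM, own - drop)
                if nonmet is not None:
                    add_hit(tid, f"{donor.value}_{gid}", donor, nonmet - drop)
                    other = donors[(donors.index(donor) + 1) % len(donors)]
                    add_hit(tid, f"{other.value}_{gid}", other, nonmet - drop - 30)

            # --- gene tree for foreign genes with a metazoan match
            if category in (ANCIENT, RECENT) and met is not None:
                d = donor.value
                gene_trees[gid] = (
                    f"(({gid}|focal,(d1_{gid}|{d},d2_{gid}|{d})),"
                    f"(m1_{gid}|metazoa,m2_{gid}|metazoa),p1_{gid}|own_phylum);"
                )

            # --- intron status
            if category == NATIVE:
                p_int = p.p_intron_native
            elif category == ANCIENT:
                p_int = p.p_intron_ancient
            elif category == RECENT:
                p_int = (
                    p.p_intron_recent_bacterial
                    if donor is TaxonGroup.BACTERIA
                    else p.p_intron_ancient
                )
            else:
                p_int = 0.0
            intron_flag[gid] = bool(rng.random() < p_int)

        # --- within-family all-vs-all similarity edges; the self-hit puts
        # singleton genes into the graph so they can form singleton groups
        for i, a in enumerate(fam_genes):
            pairwise.append(HitRecord(a, a, TaxonGroup.OWN_PHYLUM, 500.0, 1e-180))
            for b in fam_genes[i + 1:]:
                bs = max(float(rng.normal(300, 10)), 50.0)
                pairwise.append(HitRecord(a, b, TaxonGroup.OWN_PHYLUM, bs, 1e-50))
                pairwise.append(HitRecord(b, a, TaxonGroup.OWN_PHYLUM, bs, 1e-50))

        family_members[fam_id] = set(fam_genes)

    # --- gene models on scaffolds
    transcripts_of: dict[str, list[str]] = {}
    for tid, gid in gene_of_transcript.items():
        transcripts_of.setdefault(gid, []).append(tid)
    models: list[GeneModel] = []
    for sp in species:
        normal_genes = sorted(
            g for g, s in species_of.items() if s == sp and label[g] != CONTAMINANT
        )
        contam_genes = sorted(
            g for g, s in species_of.items() if s == sp and label[g] == CONTAMINANT
        )
        for pos, gid in enumerate(normal_genes):
            scaf = f"{sp}_scaf{pos // p.genes_per_scaffold:04d}"
            models.append(_make_model(gid, scaf, pos % p.genes_per_scaffold,
                                      intron_flag[gid], sorted(transcripts_of[gid]), rng))
        for pos, gid in enumerate(contam_genes):
            scaf = f"{sp}_contig_c{pos // 2:04d}"
            models.append(_make_model(gid, scaf, pos % 2,
                                      intron_flag[gid], sorted(transcripts_of[gid]), rng))

    # --- GO annotations
    go = _generate_go(p, sorted(label), label, rng)

    truth = TruthLabels(
        label=label,
        donor=donor_truth,
        family_of=family_of,
        event_branch=event_branch,
        family_members=family_members,
    )
    return SyntheticStudy(
        params=p,
        species=species,
        species_tree_newick=tree_nwk,
        hits=hits,
        taxon_map=taxon_map,
        gene_of_transcript=gene_of_transcript,
        pairwise_hits=pairwise,
        models=models,
        go=go,
        gene_trees=gene_trees,
        species_of=species_of,
        truth=truth,
        branches=descendants,
    )


def _make_model(
    gid: str,
    scaffold: str,
    slot: int,
    has_intron: bool,
    tids: list[str],
    rng: np.random.Generator,
) -> GeneModel:
    start = 1 + slot * 5000
    end = start + 999 + int(rng.integers(0, 3000))
    strand = "+" if rng.random() < 0.5 else "-"
    exon_counts = {
        t: (2 + int(rng.poisson(3)) if has_intron else 1) for t in tids
    }
    return GeneModel(
        gene_id=gid,
        transcript_ids=tids,
        scaffold=scaffold,
        start=start,
        end=end,
        strand=strand,
        exon_count_per_transcript=exon_counts,
    )


def _generate_go(
    p: SimParams,
    genes: list[str],
    label: dict[str, str],
    rng: np.random.Generator,
) -> GOAnnotation:
    n_bg, n_fp = p.n_go_terms_background, p.n_go_terms_foreign_pool
    terms = [f"GO:{i + 1:07d}" for i in range(n_bg + n_fp)]
    bg_terms, fp_terms = terms[:n_bg], terms[n_bg:]
    enzyme_flag = {t: bool(rng.random() < p.p_enzyme_background) for t in bg_terms}
    enzyme_flag.update(
        {t: bool(rng.random() < p.p_enzyme_foreign_pool) for t in fp_terms}
    )
    gene_to_terms: dict[str, set[str]] = {}
    for g in genes:
        k = 1 + int(rng.integers(0, 3))
        chosen: set[str] = set()
        for _ in range(k):
            if label[g] != NATIVE and rng.random() < p.p_foreign_pool_draw:
                chosen.add(fp_terms[int(rng.integers(n_fp))])
            else:
                chosen.add(bg_terms[int(rng.integers(n_bg))])
        gene_to_terms[g] = chosen
    return GOAnnotation(gene_to_terms=gene_to_terms, enzyme_flag=enzyme_flag)


# ---------------------------------------------------------------------------
# recovery metrics


@dataclass
class RecoveryMetrics:
    """End-to-end pipeline accuracy against the planted truth."""

    precision: dict[str, float]
    recall: dict[str, float]
    contaminant_unlinked_rate: float | None
    event_branch_accuracy: float | None
    n_foreign_truth: int
    n_predicted: dict[str, int]


def _prf(predicted: set[str], truth: set[str]) -> tuple[float, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall


def evaluate_recovery(
    scores: dict,
    truth: TruthLabels,
    *,
    linkage: list | None = None,
    event_assignments: list | None = None,
    membership: dict[str, str] | None = None,
) -> RecoveryMetrics:
    """Precision/recall per class, contaminant detection, event accuracy.

    Class-level sets are cumulative (class B includes A, class C includes
    B and A), matching the nesting of the classifier.  Contaminant
    detection = fraction of planted contaminants whose linkage flag is
    False.  Event accuracy = fraction of planted ancient events whose
    predicted group maps to the planted branch.
    """
    unknown = set(scores) - set(truth.label)
    if unknown:
        raise ValueError(f"predicted genes missing from truth: {sorted(unknown)[:5]}")
    foreign_truth = truth.foreign_genes()
    cum = {"C": ("C", "B", "A"), "B": ("B", "A"), "A": ("A",)}
    precision, recall, n_pred = {}, {}, {}
    for cls, accepted in cum.items():
        predicted = {g for g, s in scores.items() if s.hgt_class in accepted}
        p_, r_ = _prf(predicted, foreign_truth)
        precision[cls], recall[cls] = p_, r_
        n_pred[cls] = len(predicted)

    contaminant_rate = None
    if linkage is not None:
        planted = truth.contaminants()
        flags = [not r.linked for r in linkage if r.gene_id in planted]
        contaminant_rate = float(np.mean(flags)) if flags else None

    event_acc = None
    if event_assignments is not None and membership is not None:
        branch_of_group = {a.group_id: a.branch for a in event_assignments}
        correct = total = 0
        for fam, planted_branch in truth.ancient_families().items():
            total += 1
            member = min(truth.family_members[fam])
            gid = membership.get(member)
            if gid is not None and branch_of_group.get(gid) == planted_branch:
                correct += 1
        event_acc = correct / total if total else None

    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        contaminant_unlinked_rate=contaminant_rate,
        event_branch_accuracy=event_acc,
        n_foreign_truth=len(foreign_truth),
        n_predicted=n_pred,
    )
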