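"""The three gene-annotation strategies and the confident-species machinery.

* **MD1** — classify the predicted genes directly; each gene keeps its own
  call, lifted to species rank.
* **MD2** — classify the contigs; every gene inherits the species label of
  the contig it sits on.
* **MD3 (ConDiGA)** — classify the contigs, compute a per-species profile
  (relative sequence abundance and genome coverage), keep only the "most
  confident" species passing both thresholds, then assign each gene by its
  best alignment against the selected species' reference genomes.

All strategies label at species rank: calls below species (strains) are
lifted, calls above species become ``unknown``.  Every strategy conserves
genes — labeled plus unknown equals the number of predicted genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .formats import AlignmentRecord, AssemblyMeta, BlastHit, GeneRecord, TaxAssignment
from .sixframe import UNKNOWN
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

#: Threshold presets: (min relative sequence abundance %, min genome coverage %).
#: "synthetic-community" is the stringent preset for defined mixtures;
#: "fecal" is the permissive preset for complex real samples.
PRESETS: dict[str, tuple[float, float]] = {
    "synthetic-community": (0.5, 0.1),
    "fecal": (0.01, 0.1),
}

_LEVEL_PRIORITY = {"Complete Genome": 0, "Chromosome": 1, "Scaffold": 2, "Contig": 3}
_CATEGORY_PRIORITY = {"reference genome": 0, "representative genome": 1}


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# annotation map


@dataclass
class GeneAnnotationMap:
    """gene id → species taxid or ``"unknown"``, with provenance."""

    labels: dict[str, int | str]
    strategy: str
    evidence: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> int | str:
        return self.labels[gene_id]

    def __len__(self) -> int:
        return len(self.labels)

    def species_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for label in self.labels.values():
            if label != UNKNOWN:
                counts[label] = counts.get(label, 0) + 1
        return counts

    def distinct_species(self) -> set[int]:
        return {l for l in self.labels.values() if l != UNKNOWN}

    @property
    def n_labeled(self) -> int:
        return sum(1 for l in self.labels.values() if l != UNKNOWN)

    @property
    def n_unknown(self) -> int:
        return sum(1 for l in self.labels.values() if l == UNKNOWN)


def _species_label(tree: TaxonomyTree, taxid: int | None) -> int | str:
    """Lift a raw classifier call to species rank, or unknown."""
    if taxid is None or taxid not in tree:
        return UNKNOWN
    sp = tree.resolve_to_rank(taxid, "species")
    return sp if sp is not None else UNKNOWN


# ---------------------------------------------------------------------------
# classifier-output reduction (BLAST)


def blast_assignments(hits: Sequence[BlastHit], tree: TaxonomyTree) -> list[TaxAssignment]:
    """Reduce tabular BLAST rows to one assignment per query.

    Several rows per query can survive ``-max_target_seqs 1`` (multiple
    HSPs/subject versions); the max-bitscore row wins, and exact bitscore
    ties collapse to the LCA of all tied taxids.  Unknown taxids in a row
    are dropped; a row with no usable taxid yields an unclassified call.
    """
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.qseqid, []).append(h)
    out: list[TaxAssignment] = []
    for query, qhits in by_query.items():
        best_score = max(h.bitscore for h in qhits)
        tied_taxids: set[int] = set()
        for h in qhits:
            if h.bitscore == best_score:
                tied_taxids.update(t for t in h.staxids if t in tree)
        if not tied_taxids:
            out.append(TaxAssignment(query, None, "blast", best_score))
        else:
            taxid = tied_taxids.pop() if len(tied_taxids) == 1 else tree.lca(tied_taxids)
            out.append(TaxAssignment(query, taxid, "blast", best_score))
    return out


# ---------------------------------------------------------------------------
# MD1 / MD2


def _check_unique(assignments: Sequence[TaxAssignment], what: str) -> dict[str, TaxAssignment]:
    by_id: dict[str, TaxAssignment] = {}
    for a in assignments:
        prev = by_id.get(a.seq_id)
        if prev is not None and (prev.taxid, prev.classifier) != (a.taxid, a.classifier):
            raise PipelineError(
                f"conflicting duplicate assignments for {what} {a.seq_id!r}: "
                f"{prev.classifier}:{prev.taxid} vs {a.classifier}:{a.taxid}"
            )
        by_id[a.seq_id] = a
    return by_id


def md1_annotate(
    gene_assignments: Sequence[TaxAssignment],
    tree: TaxonomyTree,
    all_genes: Iterable[str] | None = None,
) -> GeneAnnotationMap:
    """Direct per-gene annotation: each gene's own call, lifted to species.

    ``all_genes``, when given, supplies the full gene universe; genes with
    no assignment row (BLAST emits nothing for a no-hit query) become
    unknown so conservation holds.
    """
    by_id = _check_unique(gene_assignments, "gene")
    labels: dict[str, int | str] = {}
    evidence: dict[str, str] = {}
    for gid, a in by_id.items():
        labels[gid] = _species_label(tree, a.taxid)
        evidence[gid] = f"{a.classifier}:{a.taxid}"
    if all_genes is not None:
        for gid in all_genes:
            if gid not in labels:
                labels[gid] = UNKNOWN
                evidence[gid] = "no-assignment"
    return GeneAnnotationMap(labels=labels, strategy="md1", evidence=evidence)


def md2_annotate(
    contig_assignments: Sequence[TaxAssignment],
    genes: Sequence[GeneRecord],
    tree: TaxonomyTree,
    all_contigs: Iterable[str] | None = None,
) -> GeneAnnotationMap:
    """Contig-label propagation: a gene inherits its contig's species call.

    ``all_contigs``, when given, names the full contig universe; contigs in
    it without an assignment row (the BLAST no-hit case) count as
    unclassified.  A gene referencing a contig outside both sets is an
    input error.
    """
    by_contig = _check_unique(contig_assignments, "contig")
    contig_labels = {cid: _species_label(tree, a.taxid) for cid, a in by_contig.items()}
    if all_contigs is not None:
        for cid in all_contigs:
            contig_labels.setdefault(cid, UNKNOWN)
    labels: dict[str, int | str] = {}
    evidence: dict[str, str] = {}
    for gene in genes:
        if gene.contig_id not in contig_labels:
            raise PipelineError(
                f"gene {gene.gene_id} references contig {gene.contig_id!r} "
                "absent from the contig assignment set"
            )
        labels[gene.gene_id] = contig_labels[gene.contig_id]
        evidence[gene.gene_id] = f"contig:{gene.contig_id}"
    return GeneAnnotationMap(labels=labels, strategy="md2", evidence=evidence)


# ---------------------------------------------------------------------------
# species profile + selection (MD3 stage 1)


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species aggregate over species-resolved contigs."""

    species_taxid: int
    assigned_bases: int
    n_contigs: int
    abundance_pct: float  # % of species-resolved contig bases (or counts)
    coverage_pct: float | None  # 100 * assigned_bases / genome size
    selected: bool = False


def species_profile(
    contig_assignments: Sequence[TaxAssignment],
    contig_lengths: Mapping[str, int],
    genome_sizes: Mapping[int, int],
    tree: TaxonomyTree,
    weighting: str = "bases",
) -> list[SpeciesProfile]:
    """Aggregate contig calls into per-species abundance and coverage.

    Relative sequence abundance is base-weighted by default (``weighting=
    "bases"``): a species' share of all contig bases resolved at species
    rank.  ``weighting="count"`` uses contig counts instead.  Coverage is
    assigned contig bases over the species' genome size, as a percent; it is
    None (and the species unselectable) when no genome size is known.
    Unclassified and above-species calls are excluded from both numerator
    and denominator.  Output is sorted by abundance, descending.
    """
    if weighting not in ("bases", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    bases: dict[int, int] = {}
    counts: dict[int, int] = {}
    for a in contig_assignments:
        label = _species_label(tree, a.taxid)
        if label == UNKNOWN:
            continue
        if a.seq_id not in contig_lengths:
            raise PipelineError(f"no length for assigned contig {a.seq_id!r}")
        length = contig_lengths[a.seq_id]
        if length < 0:
            raise PipelineError(f"negative length for contig {a.seq_id!r}")
        bases[label] = bases.get(label, 0) + length
        counts[label] = counts.get(label, 0) + 1
    weights = bases if weighting == "bases" else counts
    total = sum(weights.values())
    profiles: list[SpeciesProfile] = []
    for sp in bases:
        size = genome_sizes.get(sp)
        profiles.append(
            SpeciesProfile(
                species_taxid=sp,
                assigned_bases=bases[sp],
                n_contigs=counts[sp],
                abundance_pct=100.0 * weights[sp] / total,
                coverage_pct=100.0 * bases[sp] / size if size else None,
            )
        )
    profiles.sort(key=lambda p: (-p.abundance_pct, str(p.species_taxid)))
    return profiles


def select_confident_species(
    profiles: Sequence[SpeciesProfile],
    abundance_min_pct: float,
    coverage_min_pct: float,
    inclusive: bool = True,
) -> tuple[list[SpeciesProfile], set[int]]:
    """Flag species passing both thresholds as "most confident".

    Comparisons are inclusive (≥) by default; ``inclusive=False`` switches
    both to strict (>).  Species with unknown coverage are never selected.
    Returns the re-flagged profiles and the selected taxid set.
    """
    if abundance_min_pct < 0 or coverage_min_pct < 0:
        raise ValueError("thresholds must be non-negative")

    def passes(value: float, cut: float) -> bool:
        return value >= cut if inclusive else value > cut

    flagged: list[SpeciesProfile] = []
    selected: set[int] = set()
    for p in profiles:
        ok = (
            p.coverage_pct is not None
            and passes(p.abundance_pct, abundance_min_pct)
            and passes(p.coverage_pct, coverage_min_pct)
        )
        flagged.append(replace(p, selected=ok))
        if ok:
            selected.add(p.species_taxid)
    return flagged, selected


def choose_reference_assembly(
    species_taxid: int, assemblies: Sequence[AssemblyMeta]
) -> AssemblyMeta:
    """Pick the reference assembly for a species from assembly_summary rows.

    Priority: RefSeq category (reference > representative > other), then
    assembly level (Complete Genome > Chromosome > Scaffold > Contig), then
    latest release date, then lexicographically smallest accession.
    """
    rows = [a for a in assemblies if a.species_taxid == species_taxid]
    if not rows:
        raise PipelineError(f"no assembly row for species taxid {species_taxid}")
    return min(
        rows,
        key=lambda a: (
            _CATEGORY_PRIORITY.get(a.refseq_category, 2),
            _LEVEL_PRIORITY.get(a.assembly_level, 4),
            # newest first: invert by sorting the date string descending
            tuple(-ord(c) for c in a.release_date),
            a.assembly_accession,
        ),
    )


# ---------------------------------------------------------------------------
# best-alignment gene assignment (MD3 stage 2)


def assign_genes_by_best_alignment(
    alignments: Sequence[AlignmentRecord],
    target_to_species: Mapping[str, int],
    genes: Iterable[str],
) -> GeneAnnotationMap:
    """Label each gene with the species of its best primary alignment.

    "Best" = maximum residue matches; ties break by maximum block length,
    then maximum mapq, then lexicographically smallest species taxid, making
    the ordering total and the output deterministic.  Genes with no primary
    alignment become unknown.
    """
    best: dict[str, tuple[AlignmentRecord, int]] = {}
    for aln in alignments:
        if aln.target_id not in target_to_species:
            raise PipelineError(
                f"alignment target {aln.target_id!r} maps to no selected species"
            )
        if not aln.primary:
            continue
        sp = target_to_species[aln.target_id]
        key = (-aln.matches, -aln.block_length, -aln.mapq, str(sp))
        cur = best.get(aln.query_id)
        if cur is None or key < (-cur[0].matches, -cur[0].block_length, -cur[0].mapq, str(cur[1])):
            best[aln.query_id] = (aln, sp)
    labels: dict[str, int | str] = {}
    evidence: dict[str, str] = {}
    for gid in genes:
        if gid in best:
            aln, sp = best[gid]
            labels[gid] = sp
            evidence[gid] = f"paf:{aln.target_id}:m{aln.matches}"
        else:
            labels[gid] = UNKNOWN
            evidence[gid] = "no-primary-alignment"
    return GeneAnnotationMap(labels=labels, strategy="md3", evidence=evidence)


# ---------------------------------------------------------------------------
# MD3 end-to-end


def md3_annotate(
    contig_assignments: Sequence[TaxAssignment],
    contig_lengths: Mapping[str, int],
    genes: Iterable[str],
    genome_sizes: Mapping[int, int],
    alignments: Sequence[AlignmentRecord],
    target_to_species: Mapping[str, int],
    tree: TaxonomyTree,
    abundance_min_pct: float = 0.01,
    coverage_min_pct: float = 0.1,
    weighting: str = "bases",
    inclusive: bool = True,
) -> tuple[GeneAnnotationMap, list[SpeciesProfile]]:
    """ConDiGA: contig profile → confident-species selection → best alignment.

    Only alignments whose target genome belongs to a selected species take
    part in gene assignment, so the label set is always a subset of the
    selected set; every other gene is unknown.
    """
    profiles = species_profile(
        contig_assignments, contig_lengths, genome_sizes, tree, weighting=weighting
    )
    profiles, selected = select_confident_species(
        profiles, abundance_min_pct, coverage_min_pct, inclusive=inclusive
    )
    logger.debug("md3: %d species selected of %d profiled", len(selected), len(profiles))
    kept = [a for a in alignments if target_to_species.get(a.target_id) in selected]
    kept_map = {t: s for t, s in target_to_species.items() if s in selected}
    annotation = assign_genes_by_best_alignment(kept, kept_map, genes)
    return annotation, profiles


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class AnnotationSummary:
    total_genes: int
    labeled: int
    unknown: int
    annotation_rate: float
    species_count: int
    species_gene_counts: dict[int, int]
    precision: float | None = None
    recall: float | None = None


def tabulate_annotation(
    annotation: GeneAnnotationMap, truth: Mapping[str, int] | None = None
) -> AnnotationSummary:
    """Per-species gene counts, annotation rate, and optional accuracy.

    With a truth map (gene → true species taxid), precision is the fraction
    of labeled genes whose label matches truth, and recall the fraction of
    truth-bearing genes recovered with the correct label.
    """
    counts = annotation.species_counts()
    total = len(annotation)
    labeled = annotation.n_labeled
    precision = recall = None
    if truth is not None:
        correct = sum(
            1
            for gid, label in annotation.labels.items()
            if label != UNKNOWN and truth.get(gid) == label
        )
        precision = correct / labeled if labeled else 0.0
        n_truth = sum(1 for gid in annotation.labels if gid in truth)
        recall = correct / n_truth if n_truth else 0.0
    return AnnotationSummary(
        total_genes=total,
        labeled=labeled,
        unknown=annotation.n_unknown,
        annotation_rate=labeled / total if total else 0.0,
        species_count=len(counts),
        species_gene_counts=counts,
        precision=precision,
        recall=recall,
    )


def write_profile_tsv(profiles: Sequence[SpeciesProfile], names: Mapping[int, str] | None = None) -> str:
    names = names or {}
    rows = ["species_taxid\tname\tassigned_bases\tn_contigs\tabundance_pct\tcoverage_pct\tselected"]
    for p in profiles:
        cov = f"{p.coverage_pct:.6f}" if p.coverage_pct is not None else "NA"
        rows.append(
            f"{p.species_taxid}\t{names.get(p.species_taxid, '')}\t{p.assigned_bases}\t"
            f"{p.n_contigs}\t{p.abundance_pct:.6f}\t{cov}\t{int(p.selected)}"
        )
    return "\n".join(rows) + "\n"


def write_annotation_tsv(annotation: GeneAnnotationMap) -> str:
    rows = ["gene_id\tlabel\tstrategy\tevidence"]
    for gid in sorted(annotation.labels):
        rows.append(
            f"{gid}\t{annotation.labels[gid]}\t{annotation.strategy}\t"
            f"{annotation.evidence.get(gid, '')}"
        )
    return "\n".join(rows) + "\n"


def read_annotation_tsv(source) -> GeneAnnotationMap:
    from .formats import _lines

    labels: dict[str, int | str] = {}
    evidence: dict[str, str] = {}
    strategy = "unknown"
    for ln in _lines(source):
        if not ln.strip() or ln.startswith("gene_id\t"):
            continue
        fields = ln.split("\t")
        gid, label, strategy = fields[0], fields[1], fields[2]
        labels[gid] = label if label == UNKNOWN else int(label)
        evidence[gid] = fields[3] if len(fields) > 3 else ""
    return GeneAnnotationMap(labels=labels, strategy=strategy, evidence=evidence)
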