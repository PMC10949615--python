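"""Seeded synthetic-community fixtures for exercising the whole pipeline.

The generator emulates the intermediates a real metagenomic run would
produce — genomes, assembled contigs, predicted genes, classifier outputs
in the Kaiju/Kraken2/BLAST dialects, minimap2 PAF alignments, and a
quantified peptide table — without any sequencing-data download.

Per-species relative sequence abundance is realized *by construction*: each
species contributes exactly ``round(fraction * total_assembly_bases)``
contig bases (a prefix partition of its genome), so threshold behaviour in
the confident-species selection is sharp, not sampled.  Chimeric contigs
swap the tail of a host contig for another species' sequence, leaving
contig lengths (hence realized abundances) untouched while still exercising
the contig-label-propagation failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .abundance import PeptideQuant, write_peptide_tsv
from .dbbuild import translate_cds
from .formats import (
    AssemblyMeta,
    ContigRecord,
    GeneRecord,
    revcomp,
    write_assembly_summary,
    write_fasta,
    write_paf,
    AlignmentRecord,
)
from .taxonomy import TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

CLASSIFIER_STYLES = ("kaiju", "kraken2", "blast")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class SpeciesDesign:
    """One community member: its taxonomy slot, genome, and target share."""

    name: str
    taxid: int
    genome_size: int
    fraction: float  # of total_assembly_bases
    decoy: bool = False
    intensity_scale: float = 1.0


@dataclass
class CommunityDesign:
    """Full study design for one synthetic community.

    ``fraction`` values are shares of ``total_assembly_bases``; they must
    sum to at most 1 and each species' share may not exceed its genome size
    (contigs are non-overlapping genome fragments).
    """

    species: list[SpeciesDesign]
    total_assembly_bases: int = 500_000
    # contig length model: lognormal, clipped below
    contig_log_mean: float = 7.6  # median ~2 kb
    contig_log_sigma: float = 0.5
    min_contig_length: int = 500
    chimera_rate: float = 0.0
    chimera_tail_fraction: float = 0.3
    # gene model
    gene_codons: tuple[int, int] = (80, 300)  # internal codons, excl. start/stop
    gene_gap: tuple[int, int] = (20, 150)
    # classifier noise
    error_rate: float = 0.0
    above_species_rate: float = 0.05
    unclassified_rate: float = 0.05
    strain_rate: float = 0.10
    # peptide model
    shared_peptide_fraction: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        total_frac = sum(s.fraction for s in self.species)
        if total_frac > 1 + 1e-9:
            raise ValueError(f"species fractions sum to {total_frac:.4f} > 1")
        for s in self.species:
            if s.fraction * self.total_assembly_bases > s.genome_size:
                raise ValueError(
                    f"{s.name}: assigned bases exceed genome size {s.genome_size}"
                )
        rates = self.error_rate + self.above_species_rate + self.unclassified_rate + self.strain_rate
        if rates > 1:
            raise ValueError("classifier rate parameters sum above 1")

    @property
    def targets(self) -> list[SpeciesDesign]:
        return [s for s in self.species if not s.decoy]

    @property
    def decoys(self) -> list[SpeciesDesign]:
        return [s for s in self.species if s.decoy]


#: Target-species shares of the default community (sum 0.925 with decoys
#: adding 0.04); the ordering
#: spans 1%–30% so the least abundant member still clears a 0.5% abundance
#: cut with headroom while staying realistically skewed.
_DEFAULT_FRACTIONS = (0.28, 0.14, 0.11, 0.09, 0.08, 0.06, 0.05, 0.04, 0.03, 0.02, 0.015, 0.01)
_DEFAULT_SIZES = (
    200_000, 160_000, 150_000, 120_000, 110_000, 100_000,
    90_000, 80_000, 70_000, 60_000, 55_000, 50_000,
)


def default_design(
    n_decoys: int = 40,
    seed: int = 42,
    chimera_rate: float = 0.02,
    decoy_fraction: float = 0.001,
) -> CommunityDesign:
    """The stock 12-member community plus sub-threshold decoy species.

    Decoys each get 0.1% of assembly bases — five-fold below the stringent
    0.5% abundance cut yet large enough to yield at least one minimum-length
    contig, so decoy presence is real but never selectable.
    """
    species = [
        SpeciesDesign(
            name=f"Synthetica target{i + 1:02d}",
            taxid=1001 + i,
            genome_size=_DEFAULT_SIZES[i],
            fraction=_DEFAULT_FRACTIONS[i],
            intensity_scale=1.0,
        )
        for i in range(12)
    ]
    species += [
        SpeciesDesign(
            name=f"Decoya species{j + 1:02d}",
            taxid=2001 + j,
            genome_size=50_000,
            fraction=decoy_fraction,
            decoy=True,
        )
        for j in range(n_decoys)
    ]
    return CommunityDesign(species=species, seed=seed, chimera_rate=chimera_rate)


# ---------------------------------------------------------------------------
# genomes + taxonomy + assembly metadata


def build_taxonomy(design: CommunityDesign) -> TaxonomyTree:
    """A tree placing each species in its own genus, grouped 4 genera per
    family, 4 families per order, under one class/phylum/superkingdom.
    Every species also carries one strain child to exercise rank lifting."""
    nodes: dict[int, tuple[int, str, str]] = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        10: (2, "phylum", "Synthphyla"),
        20: (10, "class", "Synthclassia"),
    }
    for i, sp in enumerate(design.species):
        order_id = 400 + i // 16
        family_id = 300 + i // 4
        genus_id = 50_000 + sp.taxid
        strain_id = 60_000 + sp.taxid
        nodes.setdefault(order_id, (20, "order", f"Synthorder {i // 16 + 1}"))
        nodes.setdefault(family_id, (order_id, "family", f"Synthfam {i // 4 + 1}"))
        nodes[genus_id] = (family_id, "genus", sp.name.split()[0] + f" g{sp.taxid}")
        nodes[sp.taxid] = (genus_id, "species", sp.name)
        nodes[strain_id] = (sp.taxid, "strain", f"{sp.name} strain X1")
    return TaxonomyTree(nodes=nodes, root_id=1)


def generate_genomes(
    design: CommunityDesign, seed
) -> tuple[dict[int, str], TaxonomyTree, list[AssemblyMeta]]:
    """I.i.d. uniform-base genomes plus matching taxonomy and assembly rows."""
    rng = _rng(seed)
    genomes: dict[int, str] = {}
    assemblies: list[AssemblyMeta] = []
    for sp in design.species:
        arr = rng.integers(0, 4, size=sp.genome_size)
        genomes[sp.taxid] = _BASES[arr].tobytes().decode()
        assemblies.append(
            AssemblyMeta(
                species_taxid=sp.taxid,
                assembly_accession=f"GCF_{sp.taxid:09d}.1",
                refseq_category="representative genome",
                assembly_level="Complete Genome",
                release_date="2022/01/01",
                genome_size=sp.genome_size,
                organism_name=sp.name,
            )
        )
    return genomes, build_taxonomy(design), assemblies


# ---------------------------------------------------------------------------
# contigs


def fragment_to_contigs(
    genomes: Mapping[int, str], design: CommunityDesign, seed
) -> tuple[list[ContigRecord], dict[str, int], dict[str, list[tuple[int, int, int]]]]:
    """Cut each genome's allotted prefix into lognormal-length contigs.

    Returns ``(contigs, truth, regions)`` where ``truth`` maps contig id to
    its (host) species taxid and ``regions`` lists ``(start, end, taxid)``
    ownership spans per contig — a chimeric contig has a second span owned
    by the donor species.
    """
    rng = _rng(seed)
    contigs: list[ContigRecord] = []
    truth: dict[str, int] = {}
    regions: dict[str, list[tuple[int, int, int]]] = {}

    for sp in design.species:
        target_bases = int(round(sp.fraction * design.total_assembly_bases))
        if target_bases <= 0:
            continue
        genome = genomes[sp.taxid]
        pos = 0
        k = 0
        while pos < target_bases:
            remaining = target_bases - pos
            if remaining <= design.min_contig_length * 2:
                length = remaining
            else:
                length = int(rng.lognormal(design.contig_log_mean, design.contig_log_sigma))
                length = max(design.min_contig_length, min(length, remaining))
                if remaining - length < design.min_contig_length:
                    length = remaining
            cid = f"ctg_{sp.taxid}_{k}"
            contigs.append(ContigRecord(cid, genome[pos : pos + length]))
            truth[cid] = sp.taxid
            regions[cid] = [(1, length, sp.taxid)]
            pos += length
            k += 1

    # chimeras: replace host tails with donor-species sequence; lengths fixed
    if design.chimera_rate > 0 and len(contigs) > 1:
        n_chim = int(round(design.chimera_rate * len(contigs)))
        order = rng.permutation(len(contigs))
        made = 0
        for idx in order:
            if made >= n_chim:
                break
            host = contigs[idx]
            if host.length < 2 * design.min_contig_length:
                continue
            donor_sp = design.species[int(rng.integers(len(design.species)))]
            if donor_sp.taxid == truth[host.id]:
                continue
            tail_len = max(1, int(host.length * design.chimera_tail_fraction))
            donor_genome = genomes[donor_sp.taxid]
            start = int(rng.integers(0, len(donor_genome) - tail_len))
            seq = host.sequence[: host.length - tail_len] + donor_genome[start : start + tail_len]
            contigs[idx] = ContigRecord(host.id, seq)
            split = host.length - tail_len
            regions[host.id] = [
                (1, split, truth[host.id]),
                (split + 1, host.length, donor_sp.taxid),
            ]
            made += 1
    return contigs, truth, regions


# ---------------------------------------------------------------------------
# genes


def plant_genes(
    contigs: Sequence[ContigRecord],
    regions: Mapping[str, list[tuple[int, int, int]]],
    design: CommunityDesign,
    seed,
) -> tuple[list[ContigRecord], list[GeneRecord], dict[str, int]]:
    """Write ORF-like genes (start codon, stop-free body, stop codon) into
    the contigs on both strands; genes never straddle a chimera junction, so
    each has an unambiguous true species.

    Returns the rewritten contigs, the gene records, and gene-id → true
    species taxid.
    """
    rng = _rng(seed)
    lo, hi = design.gene_codons
    gap_lo, gap_hi = design.gene_gap
    out_contigs: list[ContigRecord] = []
    genes: list[GeneRecord] = []
    gene_truth: dict[str, int] = {}
    counter = 0

    for contig in contigs:
        buf = bytearray(contig.sequence, "ascii")
        for (rstart, rend, owner) in regions[contig.id]:
            pos = rstart
            while True:
                gap = int(rng.integers(gap_lo, gap_hi + 1))
                start = pos + gap
                avail = rend - start + 1
                max_codons = avail // 3 - 2
                if max_codons < lo:
                    break
                n = int(rng.integers(lo, min(hi, max_codons) + 1))
                body = "".join(
                    _NONSTOP_CODONS[i]
                    for i in rng.integers(0, len(_NONSTOP_CODONS), size=n)
                )
                cds = "ATG" + body + _STOPS[int(rng.integers(3))]
                strand = "+" if rng.random() < 0.5 else "-"
                end = start + len(cds) - 1
                written = cds if strand == "+" else revcomp(cds)
                buf[start - 1 : end] = written.encode()
                counter += 1
                gid = f"gene_{counter:05d}"
                genes.append(
                    GeneRecord(
                        gene_id=gid,
                        contig_id=contig.id,
                        start=start,
                        end=end,
                        strand=strand,
                        nt_sequence=cds,
                    )
                )
                gene_truth[gid] = owner
                pos = end + 1
        out_contigs.append(ContigRecord(contig.id, buf.decode()))
    return out_contigs, genes, gene_truth


def genes_to_gff(genes: Sequence[GeneRecord]) -> str:
    rows = ["##gff-version 3"]
    for g in genes:
        rows.append(
            f"{g.contig_id}\tsynth\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.gene_id}"
        )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# classifier emulation


def emulate_classifier(
    truth: Mapping[str, int],
    style: str,
    tree: TaxonomyTree,
    design: CommunityDesign,
    seed,
    seq_lengths: Mapping[str, int] | None = None,
    error_rate: float | None = None,
    above_species_rate: float | None = None,
    unclassified_rate: float | None = None,
    strain_rate: float | None = None,
) -> str:
    """Serialize noisy taxonomic calls in a real classifier dialect.

    Per sequence (in sorted id order, so output is deterministic): with
    ``unclassified_rate`` emit an unclassified row; with
    ``above_species_rate`` emit the genus; with ``error_rate`` relabel to a
    random decoy species; with ``strain_rate`` emit the strain node (which
    rank-lifts back to the true species); otherwise emit the true species.
    BLAST, which writes nothing for a no-hit query, simply omits
    unclassified sequences.
    """
    if style not in CLASSIFIER_STYLES:
        raise ValueError(f"unknown classifier style {style!r}")
    rng = _rng(seed)
    e = design.error_rate if error_rate is None else error_rate
    a = design.above_species_rate if above_species_rate is None else above_species_rate
    u = design.unclassified_rate if unclassified_rate is None else unclassified_rate
    s = design.strain_rate if strain_rate is None else strain_rate
    decoy_taxids = [sp.taxid for sp in design.decoys] or [sp.taxid for sp in design.species]

    lines: list[str] = []
    for sid in sorted(truth):
        true_sp = truth[sid]
        length = (seq_lengths or {}).get(sid, 1000)
        x = rng.random()
        if x < u:
            call: int | None = None
        elif x < u + a:
            call = tree.parent(true_sp)  # the genus
        elif x < u + a + e:
            call = int(decoy_taxids[int(rng.integers(len(decoy_taxids)))])
        elif x < u + a + e + s:
            call = 60_000 + true_sp  # the strain child
        else:
            call = true_sp

        if style == "kaiju":
            lines.append(f"U\t{sid}\t0" if call is None else f"C\t{sid}\t{call}")
        elif style == "kraken2":
            if call is None:
                lines.append(f"U\t{sid}\tunclassified (taxid 0)\t{length}\t")
            else:
                lines.append(
                    f"C\t{sid}\t{tree.name(call)} (taxid {call})\t{length}\t{call}:1"
                )
        else:  # blast: one 22-field row; no row when unclassified
            if call is None:
                continue
            alen = max(50, int(length * 0.9))
            pident = round(float(rng.uniform(92.0, 100.0)), 3)
            bitscore = round(alen * 1.8, 1)
            lines.append(
                "\t".join(
                    str(v)
                    for v in (
                        sid,
                        f"ref|NC_{call:06d}.1|",
                        call,
                        tree.name(call),
                        tree.name(call),
                        "Bacteria",
                        pident,
                        alen,
                        length,
                        max(length, 10_000),
                        int(alen * (100 - pident) / 100),
                        0,
                        0,
                        1,
                        alen,
                        1,
                        alen,
                        f"{tree.name(call)} chromosome, complete genome",
                        1e-50,
                        bitscore,
                        90.0,
                        90.0,
                    )
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# PAF + peptides


def emulate_paf(
    genes: Sequence[GeneRecord],
    gene_truth: Mapping[str, int],
    references: Mapping[int, tuple[str, int]],
    seed,
    decoy_hit_rate: float = 0.3,
) -> str:
    """One primary alignment per gene to its true species' reference, plus
    optional secondary alignments to other references with strictly fewer
    matches — so best-primary assignment recovers truth by construction."""
    rng = _rng(seed)
    records: list[AlignmentRecord] = []
    other_species = sorted(references)
    for g in sorted(genes, key=lambda g: g.gene_id):
        sp = gene_truth[g.gene_id]
        if sp not in references:
            continue
        acc, reflen = references[sp]
        qlen = len(g.nt_sequence)
        matches = int(qlen * rng.uniform(0.92, 0.99))
        tstart = int(rng.integers(0, max(1, reflen - qlen)))
        records.append(
            AlignmentRecord(
                query_id=g.gene_id,
                query_length=qlen,
                query_start=1,
                query_end=qlen,
                strand="+" if rng.random() < 0.5 else "-",
                target_id=acc,
                target_length=reflen,
                target_start=tstart + 1,
                target_end=tstart + qlen,
                matches=matches,
                block_length=qlen,
                mapq=60,
                primary=True,
            )
        )
        if rng.random() < decoy_hit_rate and len(other_species) > 1:
            alt = sp
            while alt == sp:
                alt = other_species[int(rng.integers(len(other_species)))]
            alt_acc, alt_len = references[alt]
            alt_matches = max(1, int(matches * rng.uniform(0.4, 0.8)))
            records.append(
                AlignmentRecord(
                    query_id=g.gene_id,
                    query_length=qlen,
                    query_start=1,
                    query_end=qlen,
                    strand="+",
                    target_id=alt_acc,
                    target_length=alt_len,
                    target_start=1,
                    target_end=qlen,
                    matches=alt_matches,
                    block_length=qlen,
                    mapq=0,
                    primary=False,
                )
            )
    return write_paf(records)


def emulate_peptides(
    genes: Sequence[GeneRecord],
    gene_species: Mapping[str, int],
    design: CommunityDesign,
    seed,
    min_len: int = 6,
    max_len: int = 40,
) -> list[PeptideQuant]:
    """Tryptic-like peptides (cut after K/R) with lognormal intensities
    scaled per species; a configurable fraction is marked as shared between
    two species."""
    rng = _rng(seed)
    scale = {sp.taxid: sp.intensity_scale for sp in design.species}
    target_taxids = [sp.taxid for sp in design.targets]
    peptides: list[PeptideQuant] = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        sp = gene_species.get(g.gene_id)
        if sp is None:
            continue
        aa = translate_cds(g.nt_sequence)
        start = 0
        pieces: list[str] = []
        for i, res in enumerate(aa):
            if res in "KR":
                pieces.append(aa[start : i + 1])
                start = i + 1
        if start < len(aa):
            pieces.append(aa[start:])
        for pep in pieces:
            if not (min_len <= len(pep) <= max_len):
                continue
            intensity = float(rng.lognormal(15.0, 1.0)) * scale.get(sp, 1.0)
            labels = {sp}
            if rng.random() < design.shared_peptide_fraction and len(target_taxids) > 1:
                other = sp
                while other == sp:
                    other = target_taxids[int(rng.integers(len(target_taxids)))]
                labels.add(other)
            peptides.append(PeptideQuant(pep, intensity, frozenset(labels)))
    return peptides


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticCommunity:
    """All fixture artifacts for one simulated community."""

    design: CommunityDesign
    tree: TaxonomyTree
    genomes: dict[int, str]
    assemblies: list[AssemblyMeta]
    contigs: list[ContigRecord]
    contig_truth: dict[str, int]
    regions: dict[str, list[tuple[int, int, int]]]
    genes: list[GeneRecord]
    gene_truth: dict[str, int]
    _seed_base: int = field(default=0, repr=False)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.contigs}

    @property
    def genome_sizes(self) -> dict[int, int]:
        return {sp.taxid: sp.genome_size for sp in self.design.species}

    @property
    def names(self) -> dict[int, str]:
        return {t: self.tree.name(t) for t in self.tree.nodes}

    @property
    def references(self) -> dict[int, tuple[str, int]]:
        return {
            a.species_taxid: (a.assembly_accession, a.genome_size or 0)
            for a in self.assemblies
        }

    @property
    def target_to_species(self) -> dict[str, int]:
        return {a.assembly_accession: a.species_taxid for a in self.assemblies}

    def _stage_seed(self, k: int) -> int:
        return (self._seed_base * 1_000_003 + k) % (2**31)

    def classifier_text(self, style: str, level: str = "contig") -> str:
        """Classifier output for contigs (MD2/MD3) or genes (MD1)."""
        if level == "contig":
            truth = self.contig_truth
            lengths = self.contig_lengths
        elif level == "gene":
            truth = self.gene_truth
            lengths = {g.gene_id: len(g.nt_sequence) for g in self.genes}
        else:
            raise ValueError(f"unknown level {level!r}")
        offset = {"kaiju": 10, "kraken2": 11, "blast": 12}[style]
        if level == "gene":
            offset += 10
        return emulate_classifier(
            truth, style, self.tree, self.design, self._stage_seed(offset), lengths
        )

    def paf_text(self, decoy_hit_rate: float = 0.3) -> str:
        return emulate_paf(
            self.genes, self.gene_truth, self.references, self._stage_seed(7), decoy_hit_rate
        )

    def peptides(self) -> list[PeptideQuant]:
        return emulate_peptides(self.genes, self.gene_truth, self.design, self._stage_seed(8))


def simulate_community(design: CommunityDesign) -> SyntheticCommunity:
    """Run every generator stage under seeds derived from ``design.seed``."""
    base = design.seed % (2**31)
    genomes, tree, assemblies = generate_genomes(design, (base * 1_000_003 + 1) % (2**31))
    contigs, contig_truth, regions = fragment_to_contigs(
        genomes, design, (base * 1_000_003 + 2) % (2**31)
    )
    contigs, genes, gene_truth = plant_genes(
        contigs, regions, design, (base * 1_000_003 + 3) % (2**31)
    )
    return SyntheticCommunity(
        design=design,
        tree=tree,
        genomes=genomes,
        assemblies=assemblies,
        contigs=contigs,
        contig_truth=contig_truth,
        regions=regions,
        genes=genes,
        gene_truth=gene_truth,
        _seed_base=base,
    )


def write_fixture(community: SyntheticCommunity, outdir) -> dict[str, str]:
    """Write every fixture file in its real dialect; returns name → path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def put(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        paths[name] = str(p)

    put("contigs.fna", write_fasta(community.contigs))
    put("genes.gff", genes_to_gff(community.genes))
    put(
        "genes.fna",
        write_fasta([(g.gene_id, g.nt_sequence, f"contig={g.contig_id}") for g in community.genes]),
    )
    put(
        "taxonomy.tsv",
        "".join(
            f"{t}\t{p}\t{r}\t{n}\n"
            for t, (p, r, n) in sorted(community.tree.nodes.items())
        ),
    )
    put("assembly_summary.txt", write_assembly_summary(community.assemblies))
    for style in CLASSIFIER_STYLES:
        put(f"contigs.{style}.txt", community.classifier_text(style, "contig"))
        put(f"genes.{style}.txt", community.classifier_text(style, "gene"))
    put("genes.paf", community.paf_text())
    put("peptides.tsv", write_peptide_tsv(community.peptides()))
    put(
        "contig_truth.tsv",
        "".join(f"{c}\t{t}\n" for c, t in sorted(community.contig_truth.items())),
    )
    put(
        "gene_truth.tsv",
        "".join(f"{g}\t{t}\n" for g, t in sorted(community.gene_truth.items())),
    )
    return paths
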