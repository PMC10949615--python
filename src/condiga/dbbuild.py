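"""Translate annotated genes into the final protein sequence database.

Every predicted gene — annotated or not — becomes one database entry; genes
without a species-level annotation are labeled ``unknown`` so the database
keeps full sequence content regardless of annotation strategy.  Headers use
a UniProt-like ``OS=<species> OX=<taxid>`` dialect so downstream search
engines pick up taxonomy without custom parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats import GeneRecord
from .sixframe import START_CODONS, UNKNOWN, _CODON_TO_AA

logger = logging.getLogger(__name__)


class TranslationError(ValueError):
    pass


def translate_cds(nt: str, genetic_code: int = 11) -> str:
    """Translate a complete CDS under the bacterial code (table 11).

    The initial codon becomes 'M' when it is a valid table-11 start codon;
    a trailing stop codon is dropped; an internal stop is an error naming
    its nucleotide position.  Ambiguous codons translate to 'X'.
    """
    if genetic_code != 11:
        raise ValueError("only genetic code table 11 is supported")
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise TranslationError(f"CDS length {len(nt)} not divisible by 3")
    if not nt:
        return ""
    aa: list[str] = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        res = _CODON_TO_AA.get(codon, "X")
        if res == "*":
            if i == n_codons - 1:
                break  # trailing stop dropped
            raise TranslationError(
                f"internal stop codon {codon} at nucleotide position {3 * i + 1}"
            )
        if i == 0 and codon in START_CODONS:
            res = "M"
        aa.append(res)
    return "".join(aa)


@dataclass(frozen=True)
class ProteinDBEntry:
    """One protein database record (protein id = gene id)."""

    protein_id: str
    aa_sequence: str
    species_label: str  # "<name>" or "unknown"
    species_taxid: int  # 0 for unknown
    contig_id: str
    strategy: str

    def __post_init__(self) -> None:
        if not self.aa_sequence or "*" in self.aa_sequence:
            raise ValueError(f"{self.protein_id}: empty or stop-containing protein")

    @property
    def header(self) -> str:
        return (
            f"{self.protein_id} OS={self.species_label} OX={self.species_taxid} "
            f"strategy={self.strategy}"
        )


def build_protein_db(
    genes: Sequence[GeneRecord],
    annotation: Mapping[str, int | str],
    names: Mapping[int, str] | None = None,
    strategy: str = "md3",
    deduplicate: bool = False,
) -> tuple[list[ProteinDBEntry], int]:
    """Translate genes and attach their species labels.

    Returns ``(entries, skipped)`` where ``skipped`` counts genes that could
    not be translated (internal stops, bad length, fully ambiguous); each
    skip is logged.  ``entries + skipped == len(genes)`` always holds (when
    ``deduplicate`` is off, the default).

    The annotation map gives each gene id either a species taxid or the
    string ``"unknown"``; genes absent from the map raise, since identical
    sequence content across strategies is only meaningful over a common
    gene universe.
    """
    names = names or {}
    entries: list[ProteinDBEntry] = []
    skipped = 0
    seen_seqs: set[str] = set()
    for gene in genes:
        if gene.gene_id not in annotation:
            raise KeyError(f"gene {gene.gene_id} missing from annotation map")
        label = annotation[gene.gene_id]
        try:
            aa = translate_cds(gene.nt_sequence)
        except TranslationError as exc:
            logger.warning("skipping gene %s: %s", gene.gene_id, exc)
            skipped += 1
            continue
        if not aa or set(aa) == {"X"}:
            logger.warning("skipping gene %s: empty or fully ambiguous protein", gene.gene_id)
            skipped += 1
            continue
        if deduplicate:
            if aa in seen_seqs:
                skipped += 1
                continue
            seen_seqs.add(aa)
        if label == UNKNOWN or label is None:
            species_label, taxid = UNKNOWN, 0
        else:
            taxid = int(label)
            species_label = names.get(taxid, str(taxid))
        entries.append(
            ProteinDBEntry(
                protein_id=gene.gene_id,
                aa_sequence=aa,
                species_label=species_label,
                species_taxid=taxid,
                contig_id=gene.contig_id,
                strategy=strategy,
            )
        )
    return entries, skipped


def write_protein_fasta(entries: Sequence[ProteinDBEntry], line_width: int = 60) -> str:
    out: list[str] = []
    for e in entries:
        out.append(f">{e.header}")
        for i in range(0, len(e.aa_sequence), line_width):
            out.append(e.aa_sequence[i : i + line_width])
    return "\n".join(out) + ("\n" if out else "")


def write_db_sidecar(entries: Sequence[ProteinDBEntry]) -> str:
    """TSV sidecar: gene id → species label/taxid → strategy."""
    rows = ["protein_id\tspecies_label\tspecies_taxid\tcontig_id\tstrategy"]
    for e in entries:
        rows.append(
            f"{e.protein_id}\t{e.species_label}\t{e.species_taxid}\t{e.contig_id}\t{e.strategy}"
        )
    return "\n".join(rows) + "\n"
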