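"""Readers and writers for every file dialect the annotation pipelines touch.

Covered dialects: FASTA, GFF3-like gene predictions, minimap2 PAF, Kaiju
classified output, Kraken2 ``--use-names`` output and report, the 22-field
BLAST tabular layout (``-outfmt 6`` with taxonomy columns), NCBI
``assembly_summary.txt``, and plain TSV sidecars for assignments and peptide
quantities.

Coordinates are 1-based inclusive everywhere inside the package; the PAF
parser converts from PAF's 0-based half-open convention at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


class ParseError(ValueError):
    """Malformed input; the message carries the offending line number."""


def _lines(source) -> list[str]:
    """Accept a path, literal text, open file, or iterable of lines."""
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str):
        if source and "\n" not in source and Path(source).is_file():
            return Path(source).read_text().splitlines()
        return source.splitlines()
    if isinstance(source, io.IOBase):
        return source.read().splitlines()
    return [str(ln).rstrip("\n") for ln in source]


def revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig: uppercase DNA over {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A predicted gene, strand-oriented, coordinates 1-based inclusive."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_sequence: str
    complete: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.complete and len(self.nt_sequence) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: complete CDS length not divisible by 3")


@dataclass(frozen=True)
class TaxAssignment:
    """One sequence's taxonomic call; ``taxid`` is None when unclassified."""

    seq_id: str
    taxid: int | None
    classifier: str
    score: float | None = None

    @property
    def classified(self) -> bool:
        return self.taxid is not None


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF row (coordinates already converted to 1-based inclusive)."""

    query_id: str
    query_length: int
    target_id: str
    target_length: int
    matches: int
    block_length: int
    strand: str
    mapq: int
    primary: bool = True
    query_start: int = 1
    query_end: int = 0
    target_start: int = 1
    target_end: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.block_length):
            raise ValueError(
                f"alignment {self.query_id}->{self.target_id}: "
                f"matches {self.matches} outside [0, block {self.block_length}]"
            )
        if self.query_length <= 0:
            raise ValueError(f"alignment {self.query_id}: non-positive query length")


_BLAST_COLUMNS = (
    "qseqid sseqid staxids sscinames scomnames sskingdoms pident length qlen slen "
    "mismatch gapopen gaps qstart qend sstart send stitle evalue bitscore qcovs qcovhsp"
).split()


@dataclass(frozen=True)
class BlastHit:
    """One row of the 22-field tabular BLAST layout with taxonomy columns."""

    qseqid: str
    sseqid: str
    staxids: tuple[int, ...]
    sscinames: str
    scomnames: str
    sskingdoms: str
    pident: float
    length: int
    qlen: int
    slen: int
    mismatch: int
    gapopen: int
    gaps: int
    qstart: int
    qend: int
    sstart: int
    send: int
    stitle: str
    evalue: float
    bitscore: float
    qcovs: float
    qcovhsp: float


@dataclass(frozen=True)
class AssemblyMeta:
    """One NCBI assembly_summary.txt row (the columns the pipeline uses)."""

    species_taxid: int
    assembly_accession: str
    refseq_category: str = "na"
    assembly_level: str = "na"
    release_date: str = ""
    genome_size: int | None = None
    organism_name: str = ""

    def __post_init__(self) -> None:
        if self.genome_size is not None and self.genome_size <= 0:
            raise ValueError(f"{self.assembly_accession}: non-positive genome size")


@dataclass(frozen=True)
class Kraken2ReportRow:
    percent: float
    clade_reads: int
    direct_reads: int
    rank_code: str
    taxid: int
    name: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source, validate: bool = True) -> list[ContigRecord]:
    """Parse FASTA into records, validating residues against IUPAC DNA codes."""
    records: list[ContigRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        records.append(ContigRecord(header, "".join(chunks), desc))

    for lineno, ln in enumerate(_lines(source), 1):
        if ln.startswith(">"):
            flush()
            head = ln[1:].strip()
            if not head:
                raise ParseError(f"FASTA line {lineno}: empty sequence id")
            parts = head.split(None, 1)
            header, desc = parts[0], parts[1] if len(parts) > 1 else ""
            chunks = []
            header_line = lineno
        elif ln.strip():
            if header is None:
                raise ParseError(f"FASTA line {lineno}: sequence before first header")
            seq = ln.strip().upper()
            if validate and not set(seq) <= _IUPAC_DNA:
                bad = sorted(set(seq) - _IUPAC_DNA)
                raise ParseError(
                    f"FASTA line {lineno}: non-IUPAC residue(s) {bad} in record "
                    f"starting at line {header_line}"
                )
            chunks.append(seq)
    flush()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"duplicate FASTA ids: {dup}")
    return records


def write_fasta(records: Iterable, line_width: int = 60) -> str:
    """Serialize (id, sequence[, description]) records to FASTA text."""
    out: list[str] = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec[0], rec[1]
            desc = rec[2] if len(rec) > 2 else ""
        else:
            rid, seq = rec.id, rec.sequence
            desc = getattr(rec, "description", "")
        out.append(f">{rid} {desc}".rstrip())
        for i in range(0, len(seq), line_width):
            out.append(seq[i : i + line_width])
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# classifier outputs


def parse_kaiju(source) -> list[TaxAssignment]:
    """Kaiju classified output: ``C/U <tab> seqid <tab> taxid [...]``."""
    out: list[TaxAssignment] = []
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ParseError(f"kaiju line {lineno}: expected >=3 columns")
        status, seqid, taxid_s = fields[0], fields[1], fields[2]
        if status == "U":
            out.append(TaxAssignment(seqid, None, "kaiju"))
        elif status == "C":
            try:
                taxid = int(taxid_s)
            except ValueError:
                raise ParseError(
                    f"kaiju line {lineno}: non-integer taxid {taxid_s!r}"
                ) from None
            out.append(TaxAssignment(seqid, taxid if taxid > 0 else None, "kaiju"))
        else:
            raise ParseError(f"kaiju line {lineno}: unknown status {status!r}")
    return out


def _kraken_taxid(field: str, lineno: int) -> int:
    field = field.strip()
    if field.isdigit() or (field.startswith("-") and field[1:].isdigit()):
        return int(field)
    # --use-names dialect: "Escherichia coli (taxid 562)"
    marker = "(taxid "
    idx = field.rfind(marker)
    if idx >= 0 and field.endswith(")"):
        inner = field[idx + len(marker) : -1].strip()
        if inner.lstrip("-").isdigit():
            return int(inner)
    raise ParseError(
        f"kraken2 line {lineno}: column 3 {field!r} is neither an integer "
        "taxid nor a '(taxid N)' name"
    )


def parse_kraken2_output(source) -> list[TaxAssignment]:
    """Kraken2 standard 5-column output, with or without ``--use-names``."""
    out: list[TaxAssignment] = []
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ParseError(f"kraken2 line {lineno}: expected >=3 columns")
        status, seqid = fields[0], fields[1]
        if status == "U":
            out.append(TaxAssignment(seqid, None, "kraken2"))
            continue
        taxid = _kraken_taxid(fields[2], lineno)
        out.append(TaxAssignment(seqid, taxid if taxid > 0 else None, "kraken2"))
    return out


def parse_kraken2_report(source) -> list[Kraken2ReportRow]:
    """Kraken2 ``--report`` table (read-only; not used by the MD pipelines)."""
    rows: list[Kraken2ReportRow] = []
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 6:
            raise ParseError(f"kraken2 report line {lineno}: expected 6 columns")
        rows.append(
            Kraken2ReportRow(
                percent=float(fields[0]),
                clade_reads=int(fields[1]),
                direct_reads=int(fields[2]),
                rank_code=fields[3],
                taxid=int(fields[4]),
                name=fields[5].strip(),
            )
        )
    return rows


def parse_blast_tab(source) -> list[BlastHit]:
    """22-field tabular BLAST rows; multi-valued ``staxids`` split on ';'."""
    hits: list[BlastHit] = []
    n = len(_BLAST_COLUMNS)
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != n:
            raise ParseError(
                f"blast line {lineno}: expected {n} tab-separated fields, got {len(fields)}"
            )
        try:
            staxids = tuple(
                int(t) for t in fields[2].split(";") if t.strip() and t.strip() != "N/A"
            )
            hits.append(
                BlastHit(
                    qseqid=fields[0],
                    sseqid=fields[1],
                    staxids=staxids,
                    sscinames=fields[3],
                    scomnames=fields[4],
                    sskingdoms=fields[5],
                    pident=float(fields[6]),
                    length=int(fields[7]),
                    qlen=int(fields[8]),
                    slen=int(fields[9]),
                    mismatch=int(fields[10]),
                    gapopen=int(fields[11]),
                    gaps=int(fields[12]),
                    qstart=int(fields[13]),
                    qend=int(fields[14]),
                    sstart=int(fields[15]),
                    send=int(fields[16]),
                    stitle=fields[17],
                    evalue=float(fields[18]),
                    bitscore=float(fields[19]),
                    qcovs=float(fields[20]),
                    qcovhsp=float(fields[21]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"blast line {lineno}: {exc}") from None
    return hits


# ---------------------------------------------------------------------------
# PAF


def parse_paf(source) -> list[AlignmentRecord]:
    """minimap2 PAF: 12 mandatory columns plus SAM-style tags.

    ``matches`` is column 10 (residue matches), ``block_length`` column 11.
    Primary/secondary status comes from the ``tp:A:`` tag; rows without the
    tag count as primary.  PAF's 0-based half-open coordinates are converted
    to 1-based inclusive.
    """
    out: list[AlignmentRecord] = []
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 12:
            raise ParseError(f"PAF line {lineno}: expected >=12 columns, got {len(fields)}")
        primary = True
        for tag in fields[12:]:
            if tag.startswith("tp:A:"):
                primary = tag[5] == "P"
        try:
            out.append(
                AlignmentRecord(
                    query_id=fields[0],
                    query_length=int(fields[1]),
                    query_start=int(fields[2]) + 1,
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_id=fields[5],
                    target_length=int(fields[6]),
                    target_start=int(fields[7]) + 1,
                    target_end=int(fields[8]),
                    matches=int(fields[9]),
                    block_length=int(fields[10]),
                    mapq=int(fields[11]),
                    primary=primary,
                )
            )
        except ValueError as exc:
            raise ParseError(f"PAF line {lineno}: {exc}") from None
    return out


def write_paf(records: Iterable[AlignmentRecord]) -> str:
    rows = []
    for r in records:
        rows.append(
            "\t".join(
                str(x)
                for x in (
                    r.query_id,
                    r.query_length,
                    r.query_start - 1,
                    r.query_end,
                    r.strand,
                    r.target_id,
                    r.target_length,
                    r.target_start - 1,
                    r.target_end,
                    r.matches,
                    r.block_length,
                    r.mapq,
                    f"tp:A:{'P' if r.primary else 'S'}",
                )
            )
        )
    return "\n".join(rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# GFF gene predictions


def _gff_attr(attrs: str, keys: Sequence[str]) -> str | None:
    for chunk in attrs.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
        elif " " in chunk:
            k, v = chunk.split(None, 1)
        else:
            continue
        if k.strip() in keys:
            return v.strip().strip('"')
    return None


def parse_gff_genes(source, contig_seqs: Mapping[str, str]) -> list[GeneRecord]:
    """Extract genes from GFF3-like CDS/gene rows against in-memory contigs.

    The nucleotide sequence is sliced from the contig (1-based inclusive
    coordinates) and reverse-complemented for minus-strand features.
    """
    genes: list[GeneRecord] = []
    counter = 0
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) < 9:
            raise ParseError(f"GFF line {lineno}: expected 9 columns, got {len(fields)}")
        seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
        if ftype not in ("CDS", "gene"):
            continue
        if seqid not in contig_seqs:
            raise ParseError(f"GFF line {lineno}: unknown contig {seqid!r}")
        start, end = int(start_s), int(end_s)
        contig = contig_seqs[seqid]
        if not (1 <= start <= end <= len(contig)):
            raise ParseError(
                f"GFF line {lineno}: feature {start}..{end} outside contig "
                f"{seqid} (length {len(contig)})"
            )
        counter += 1
        gene_id = _gff_attr(attrs, ("ID", "gene_id")) or f"gene_{counter}"
        nt = contig[start - 1 : end]
        if strand == "-":
            nt = revcomp(nt)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=seqid,
                start=start,
                end=end,
                strand=strand,
                nt_sequence=nt,
                complete=len(nt) % 3 == 0,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# assembly_summary


def parse_assembly_summary(source) -> list[AssemblyMeta]:
    """NCBI assembly_summary.txt: '#'-prefixed header, tab-separated rows.

    The header row (the last comment line) names the columns; ``genome_size``
    is optional — the 2021-era layout lacked it — and records carry None when
    the column is absent.
    """
    lines = _lines(source)
    header: list[str] | None = None
    rows: list[AssemblyMeta] = []
    for ln in lines:
        if ln.startswith("#"):
            stripped = ln.lstrip("#").strip()
            if "\t" in stripped:
                header = [c.strip() for c in stripped.split("\t")]
            continue
        if not ln.strip():
            continue
        if header is None:
            raise ParseError("assembly_summary: no '#' header row found before data")
        if "species_taxid" not in header:
            raise ParseError("assembly_summary: header lacks species_taxid column")
        fields = ln.split("\t")
        col = {name: (fields[i] if i < len(fields) else "") for i, name in enumerate(header)}
        size_s = col.get("genome_size", "").strip()
        rows.append(
            AssemblyMeta(
                species_taxid=int(col["species_taxid"]),
                assembly_accession=col.get("assembly_accession", "").strip(),
                refseq_category=col.get("refseq_category", "na").strip() or "na",
                assembly_level=col.get("assembly_level", "na").strip() or "na",
                release_date=col.get("seq_rel_date", "").strip(),
                genome_size=int(size_s) if size_s and size_s != "na" else None,
                organism_name=col.get("organism_name", "").strip(),
            )
        )
    if header is None and not rows:
        raise ParseError("assembly_summary: empty input with no header")
    if "species_taxid" not in (header or []):
        raise ParseError("assembly_summary: header lacks species_taxid column")
    return rows


def write_assembly_summary(rows: Iterable[AssemblyMeta]) -> str:
    header = (
        "# assembly_accession\tspecies_taxid\torganism_name\trefseq_category\t"
        "assembly_level\tseq_rel_date\tgenome_size"
    )
    out = [header]
    for r in rows:
        out.append(
            "\t".join(
                [
                    r.assembly_accession,
                    str(r.species_taxid),
                    r.organism_name,
                    r.refseq_category,
                    r.assembly_level,
                    r.release_date,
                    str(r.genome_size) if r.genome_size is not None else "na",
                ]
            )
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# genome sizes


def resolve_genome_sizes(
    assemblies: Sequence[AssemblyMeta] | None = None,
    size_table: Mapping[int, int] | None = None,
    reference_fasta=None,
    species_of_reference: Mapping[str, int] | None = None,
) -> dict[int, int]:
    """Species-taxid → genome size, trying sources in a fixed priority order.

    1. ``genome_size`` column of assembly_summary rows;
    2. an explicit species-taxid → size table;
    3. summed sequence lengths of a reference FASTA (one species per record,
       mapped through ``species_of_reference``).
    """
    sizes: dict[int, int] = {}
    if reference_fasta is not None and species_of_reference:
        totals: dict[int, int] = {}
        for rec in read_fasta(reference_fasta):
            sp = species_of_reference.get(rec.id)
            if sp is not None:
                totals[sp] = totals.get(sp, 0) + rec.length
        sizes.update(totals)
    if size_table:
        sizes.update(size_table)
    if assemblies:
        for a in assemblies:
            if a.genome_size is not None:
                sizes[a.species_taxid] = a.genome_size
    return sizes


def read_size_table(source) -> dict[int, int]:
    """Two-column TSV: species taxid, genome size in bases."""
    table: dict[int, int] = {}
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ParseError(f"size table line {lineno}: expected 2 columns")
        table[int(fields[0])] = int(fields[1])
    return table


# ---------------------------------------------------------------------------
# assignment / peptide TSV sidecars


def write_assignments(assignments: Iterable[TaxAssignment]) -> str:
    rows = ["seq_id\ttaxid\tclassifier\tscore"]
    for a in assignments:
        rows.append(
            f"{a.seq_id}\t{a.taxid if a.taxid is not None else 'NA'}\t"
            f"{a.classifier}\t{a.score if a.score is not None else 'NA'}"
        )
    return "\n".join(rows) + "\n"


def read_assignments(source) -> list[TaxAssignment]:
    out: list[TaxAssignment] = []
    lines = _lines(source)
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip() or ln.startswith("seq_id\t"):
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ParseError(f"assignments line {lineno}: expected >=3 columns")
        taxid = None if fields[1] in ("NA", "") else int(fields[1])
        score = None
        if len(fields) > 3 and fields[3] not in ("NA", ""):
            score = float(fields[3])
        out.append(TaxAssignment(fields[0], taxid, fields[2], score))
    return out
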