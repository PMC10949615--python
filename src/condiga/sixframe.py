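"""Naive six-frame translation of contigs and the longest-alignment
annotation rule used for six-frame-translated ("6FT") databases.

A contig is translated in frames +1/+2/+3 of the forward strand and
−1/−2/−3 of the reverse complement; stop codons are written as ``*`` and
the stop-free fragments between them are available for database building.
Queries are then annotated with the species holding the *longest* alignment
among those passing strict >10% alignment-fraction and >10% identity
filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .formats import ParseError, _lines, revcomp

UNKNOWN = "unknown"

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    _CODON_TO_AA[_stop] = "*"
START_CODONS: frozenset[str] = frozenset(_TABLE11.start_codons)

FRAMES = (1, 2, 3, -1, -2, -3)


def translate_frame(seq: str, offset: int) -> str:
    """Translate one reading frame; ambiguous codons (N etc.) become 'X'."""
    seq = seq.upper()
    aa: list[str] = []
    for i in range(offset, len(seq) - 2, 3):
        aa.append(_CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(aa)


@dataclass(frozen=True)
class FrameTranslation:
    """One contig frame: the full '*'-marked protein and its stop-free pieces."""

    contig_id: str
    frame: int  # +1..+3, -1..-3
    aa_sequence: str

    @property
    def fragments(self) -> list[tuple[int, str]]:
        """Stop-free substrings with 0-based frame-local AA start positions.

        Joining the fragment strings with ``*`` reconstructs ``aa_sequence``
        exactly (empty fragments between adjacent stops included).
        """
        frags: list[tuple[int, str]] = []
        pos = 0
        for piece in self.aa_sequence.split("*"):
            frags.append((pos, piece))
            pos += len(piece) + 1
        return frags


def six_frame_translate(contig_id: str, seq: str) -> list[FrameTranslation]:
    """All six frame translations of a DNA sequence.

    Frames +k use the forward strand starting at offset k−1; frames −k use
    the reverse complement at offset k−1.  The standard/bacterial code is
    used (start-codon differences are irrelevant without ORF calling).
    """
    seq = seq.upper()
    rc = revcomp(seq)
    out: list[FrameTranslation] = []
    for frame in FRAMES:
        src = seq if frame > 0 else rc
        out.append(FrameTranslation(contig_id, frame, translate_frame(src, abs(frame) - 1)))
    return out


def write_sixframe_fasta(
    translations: Iterable[FrameTranslation],
    mode: str = "full",
    min_fragment_aa: int = 20,
    line_width: int = 60,
) -> str:
    """FASTA of frame translations, headers ``<contig>|frame=<f>``.

    ``mode="full"`` writes the whole '*'-marked frame string; ``"fragments"``
    writes each stop-free fragment of at least ``min_fragment_aa`` residues
    with a ``|frag=<start>`` suffix.
    """
    if mode not in ("full", "fragments"):
        raise ValueError(f"unknown six-frame output mode {mode!r}")
    out: list[str] = []

    def emit(header: str, seq: str) -> None:
        out.append(f">{header}")
        for i in range(0, len(seq), line_width):
            out.append(seq[i : i + line_width])

    for t in translations:
        base = f"{t.contig_id}|frame={t.frame:+d}"
        if mode == "full":
            if t.aa_sequence:
                emit(base, t.aa_sequence)
        else:
            for start, frag in t.fragments:
                if len(frag) >= min_fragment_aa:
                    emit(f"{base}|frag={start}", frag)
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# annotation rule


@dataclass(frozen=True)
class Tab6FTHit:
    """One alignment of a six-frame query against a reference protein."""

    query_id: str
    species_taxid: int
    alignment_length: int
    query_length: int
    identity_fraction: float

    def __post_init__(self) -> None:
        if self.alignment_length > self.query_length:
            raise ValueError(
                f"hit {self.query_id}: alignment length {self.alignment_length} "
                f"exceeds query length {self.query_length}"
            )

    @property
    def alignment_fraction(self) -> float:
        return self.alignment_length / self.query_length


def meta6ft_annotate(
    hits: Sequence[Tab6FTHit] | Mapping[str, Sequence[Tab6FTHit]],
    min_fraction: float = 0.10,
    min_identity: float = 0.10,
) -> dict[str, int | str]:
    """Per query: longest alignment among hits passing both strict filters.

    A hit survives when identity_fraction > ``min_identity`` AND
    alignment_length/query_length > ``min_fraction`` (both strictly greater,
    so a hit sitting exactly at 10% is rejected).  Among survivors the
    maximum alignment length wins; ties break to the lexicographically
    smallest species taxid.  Queries with no surviving hit map to
    ``"unknown"``.
    """
    if isinstance(hits, Mapping):
        grouped: dict[str, list[Tab6FTHit]] = {q: list(h) for q, h in hits.items()}
    else:
        grouped = {}
        for h in hits:
            grouped.setdefault(h.query_id, []).append(h)

    result: dict[str, int | str] = {}
    for query, qhits in grouped.items():
        survivors = [
            h
            for h in qhits
            if h.identity_fraction > min_identity and h.alignment_fraction > min_fraction
        ]
        if not survivors:
            result[query] = UNKNOWN
            continue
        best = min(survivors, key=lambda h: (-h.alignment_length, str(h.species_taxid)))
        result[query] = best.species_taxid
    return result


def read_tab6ft(source) -> list[Tab6FTHit]:
    """TSV of six-frame alignment hits.

    Columns: query id, species taxid, alignment length (residues), query
    length (residues), identity fraction in [0,1].
    """
    hits: list[Tab6FTHit] = []
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip() or ln.startswith("#") or ln.startswith("query"):
            continue
        fields = ln.split("\t")
        if len(fields) < 5:
            raise ParseError(f"6FT hits line {lineno}: expected 5 columns")
        try:
            hits.append(
                Tab6FTHit(
                    query_id=fields[0],
                    species_taxid=int(fields[1]),
                    alignment_length=int(fields[2]),
                    query_length=int(fields[3]),
                    identity_fraction=float(fields[4]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"6FT hits line {lineno}: {exc}") from None
    return hits
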