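"""Metagenome (MG) vs metaproteome (MP) taxonomic abundance comparison.

MG abundance of a species is its share of species-labeled genes; MP
abundance is its share of summed identified-peptide intensity.  Species
fractions are rolled up the taxonomy to any requested rank and compared as
log2(MG/MP) per taxon — the per-taxon quantity a cladogram of multi-omic
agreement is colored by.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats import ParseError, _lines
from .pipelines import GeneAnnotationMap
from .sixframe import UNKNOWN
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class PeptideQuant:
    """One quantified peptide and the species its protein groups belong to."""

    peptide: str
    intensity: float
    species_taxids: frozenset[int]

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"peptide {self.peptide}: negative intensity")


@dataclass(frozen=True)
class TaxonRatio:
    """Relative MG and MP abundance of one taxon at one rank."""

    taxid: int
    rank: str
    rel_mg: float
    rel_mp: float
    log2_ratio: float | None  # None when either side is zero


def mg_abundance(annotation: GeneAnnotationMap) -> dict[int, float]:
    """Species → fraction of species-labeled genes (unknown genes excluded)."""
    counts = annotation.species_counts()
    total = sum(counts.values())
    if total == 0:
        return {}
    return {sp: n / total for sp, n in counts.items()}


def mp_abundance(
    peptides: Sequence[PeptideQuant], shared: str = "exclude"
) -> dict[int, float]:
    """Species → fraction of summed peptide intensity.

    ``shared="exclude"`` (default): only species-unique peptides contribute,
    each giving its full intensity to its single species.  ``shared="split"``
    divides a shared peptide's intensity equally among its species.
    Peptides matching no species (unknown-only) never contribute.
    """
    if shared not in ("exclude", "split"):
        raise ValueError(f"unknown shared-peptide mode {shared!r}")
    totals: dict[int, float] = {}
    for p in peptides:
        if not p.species_taxids:
            continue
        if len(p.species_taxids) == 1:
            (sp,) = p.species_taxids
            totals[sp] = totals.get(sp, 0.0) + p.intensity
        elif shared == "split":
            share = p.intensity / len(p.species_taxids)
            for sp in p.species_taxids:
                totals[sp] = totals.get(sp, 0.0) + share
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {sp: v / grand for sp, v in totals.items()}


def rollup_to_rank(
    fractions: Mapping[int, float], tree: TaxonomyTree, rank: str
) -> dict[int, float]:
    """Sum species fractions up each lineage to ``rank`` and renormalize.

    Species whose lineage never reaches the rank are dropped before
    renormalization, so the returned fractions sum to 1 whenever any
    species resolves.
    """
    sums: dict[int, float] = {}
    for sp, frac in fractions.items():
        if sp not in tree:
            raise KeyError(f"species taxid {sp} absent from taxonomy")
        anc = tree.resolve_to_rank(sp, rank)
        if anc is None:
            continue
        sums[anc] = sums.get(anc, 0.0) + frac
    total = sum(sums.values())
    if total == 0:
        return {}
    return {t: v / total for t, v in sums.items()}


def rank_rollup_ratio(
    mg: Mapping[int, float],
    mp: Mapping[int, float],
    tree: TaxonomyTree,
    ranks: Iterable[str],
) -> list[TaxonRatio]:
    """Per rank, roll both sides up, renormalize, and take log2(MG/MP).

    A taxon present on only one side gets ratio None (not ±inf), keeping
    the output serializable.
    """
    out: list[TaxonRatio] = []
    for rank in ranks:
        mg_r = rollup_to_rank(mg, tree, rank)
        mp_r = rollup_to_rank(mp, tree, rank)
        for taxid in sorted(set(mg_r) | set(mp_r), key=str):
            g = mg_r.get(taxid, 0.0)
            p = mp_r.get(taxid, 0.0)
            ratio = math.log2(g / p) if g > 0 and p > 0 else None
            out.append(TaxonRatio(taxid=taxid, rank=rank, rel_mg=g, rel_mp=p, log2_ratio=ratio))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_peptide_tsv(source) -> list[PeptideQuant]:
    """Peptide table: peptide, intensity, semicolon-joined species taxids.

    An empty third column means the peptide matched only unknown-labeled
    proteins.
    """
    out: list[PeptideQuant] = []
    for lineno, ln in enumerate(_lines(source), 1):
        if not ln.strip() or ln.startswith("peptide\t") or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ParseError(f"peptide TSV line {lineno}: expected >=2 columns")
        species = frozenset(
            int(t) for t in (fields[2] if len(fields) > 2 else "").split(";") if t.strip()
        )
        try:
            out.append(PeptideQuant(fields[0], float(fields[1]), species))
        except ValueError as exc:
            raise ParseError(f"peptide TSV line {lineno}: {exc}") from None
    return out


def write_peptide_tsv(peptides: Sequence[PeptideQuant]) -> str:
    rows = ["peptide\tintensity\tspecies_taxids"]
    for p in peptides:
        rows.append(
            f"{p.peptide}\t{p.intensity:.6g}\t"
            + ";".join(str(t) for t in sorted(p.species_taxids))
        )
    return "\n".join(rows) + "\n"


def write_ratio_tsv(ratios: Sequence[TaxonRatio], names: Mapping[int, str] | None = None) -> str:
    """Long-format export (taxon, rank, rel_mg, rel_mp, log2_ratio)."""
    names = names or {}
    rows = ["taxid\tname\trank\trel_mg\trel_mp\tlog2_ratio"]
    for r in ratios:
        ratio = f"{r.log2_ratio:.6f}" if r.log2_ratio is not None else "NA"
        rows.append(
            f"{r.taxid}\t{names.get(r.taxid, '')}\t{r.rank}\t"
            f"{r.rel_mg:.6f}\t{r.rel_mp:.6f}\t{ratio}"
        )
    return "\n".join(rows) + "\n"
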