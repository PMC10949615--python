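"""NCBI-style taxonomy: lineage queries, rank lifting, lowest common ancestor.

The tree is a flat ``taxid -> (parent, rank, name)`` table in the shape of
the NCBI taxdump (``nodes.dmp``/``names.dmp``), which is the taxonomy all of
the contig/gene classifiers consumed here (Kaiju, Kraken2, BLAST ``staxids``)
report against.  A 4-column TSV dialect (taxid, parent, rank, name) is
accepted as a lightweight alternative for synthetic fixtures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

#: Canonical rank order, root-most first.  "strain" and "no rank" sit below
#: species for lifting purposes.
RANK_ORDER: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
    "no rank",
)


class TaxonomyError(ValueError):
    """Structural or lookup problem in a taxonomy table."""


@dataclass
class TaxonomyTree:
    """Validated taxonomy with parent pointers and named ranks.

    Parameters
    ----------
    nodes
        ``taxid -> (parent_taxid, rank, name)``.  The root points to itself.
    root_id
        Taxid of the root node.
    """

    nodes: dict[int, tuple[int, str, str]]
    root_id: int = 1
    _lineage_cache: dict[int, tuple[int, ...]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -------------------------------------------------------
    def validate(self) -> None:
        """Check parent closure and acyclicity; raise TaxonomyError if broken."""
        if self.root_id not in self.nodes:
            raise TaxonomyError(f"root id {self.root_id} not in node table")
        for taxid, (parent, _rank, _name) in self.nodes.items():
            if parent not in self.nodes:
                raise TaxonomyError(
                    f"node {taxid} has orphan parent id {parent}"
                )
        # cycle check: follow parents with a visited set per walk
        for taxid in self.nodes:
            seen: set[int] = set()
            cur = taxid
            while cur != self.root_id:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at taxid {cur}")
                seen.add(cur)
                cur = self.nodes[cur][0]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def parent(self, taxid: int) -> int:
        return self._node(taxid)[0]

    def rank(self, taxid: int) -> str:
        return self._node(taxid)[1]

    def name(self, taxid: int) -> str:
        return self._node(taxid)[2]

    def _node(self, taxid: int) -> tuple[int, str, str]:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    # -- queries ---------------------------------------------------------
    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Path from ``taxid`` (inclusive) up to the root (inclusive)."""
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        path = [taxid]
        cur = taxid
        self._node(cur)
        while cur != self.root_id:
            cur = self.nodes[cur][0]
            path.append(cur)
        result = tuple(path)
        self._lineage_cache[taxid] = result
        return result

    def resolve_to_rank(self, taxid: int, rank: str) -> int | None:
        """First ancestor-or-self of ``taxid`` whose rank equals ``rank``.

        Returns None when the lineage never carries that rank, i.e. the call
        sits above the requested rank (a genus-level call cannot be resolved
        to species).  Strain and other below-species nodes are thereby
        lifted to their species.
        """
        for node in self.lineage(taxid):
            if self.nodes[node][1] == rank:
                return node
        return None

    def lca(self, taxids: Iterable[int]) -> int:
        """Deepest node ancestral to (or equal to) every input taxid."""
        ids = list(taxids)
        if not ids:
            raise TaxonomyError("lca of an empty taxid set")
        common: list[int] | None = None
        for taxid in ids:
            lin = list(reversed(self.lineage(taxid)))  # root first
            if common is None:
                common = lin
            else:
                n = min(len(common), len(lin))
                i = 0
                while i < n and common[i] == lin[i]:
                    i += 1
                common = common[:i]
        assert common  # root is always shared
        return common[-1]


# ---------------------------------------------------------------------------
# loading


def _read_lines(source) -> list[str]:
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str) and source and "\n" not in source and Path(source).is_file():
        return Path(source).read_text().splitlines()
    if isinstance(source, str):
        return source.splitlines()
    if isinstance(source, io.IOBase):
        return source.read().splitlines()
    return list(source)


def _parse_dmp_row(line: str) -> list[str]:
    # taxdump rows are "<f>\t|\t<f>\t|\t...<f>\t|" ; tolerate plain "|" too
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")] if "\t|\t" in line else [
        f.strip() for f in line.strip().strip("|").split("|")
    ]


def load_taxonomy(
    nodes_source,
    names_source=None,
    merged_source=None,
) -> TaxonomyTree:
    """Load a taxonomy from taxdump ``nodes.dmp``/``names.dmp`` or a 4-column TSV.

    The TSV dialect carries ``taxid<TAB>parent<TAB>rank<TAB>name`` per row and
    needs no separate names source.  For taxdump input, names use the
    "scientific name" class when several name classes are present.
    ``merged_source`` (taxdump ``merged.dmp``) is an optional old→new taxid
    remap applied to nothing at load time but stored for assignment remapping
    via :func:`remap_taxid`.
    """
    lines = [ln for ln in _read_lines(nodes_source) if ln.strip()]
    nodes: dict[int, tuple[int, str, str]] = {}
    names: dict[int, str] = {}

    is_dmp = any("\t|" in ln or ln.rstrip().endswith("|") for ln in lines[:5])
    if is_dmp:
        for ln in lines:
            fields = _parse_dmp_row(ln)
            if len(fields) < 3:
                raise TaxonomyError(f"malformed nodes.dmp row: {ln!r}")
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            nodes[taxid] = (parent, rank, "")
        if names_source is not None:
            for ln in _read_lines(names_source):
                if not ln.strip():
                    continue
                fields = _parse_dmp_row(ln)
                if len(fields) < 4:
                    raise TaxonomyError(f"malformed names.dmp row: {ln!r}")
                taxid, name, _uniq, cls = int(fields[0]), fields[1], fields[2], fields[3]
                if cls == "scientific name" or taxid not in names:
                    names[taxid] = name
    else:
        for i, ln in enumerate(lines, 1):
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise TaxonomyError(
                    f"taxonomy TSV line {i}: expected 4 columns, got {len(fields)}"
                )
            taxid, parent, rank, name = int(fields[0]), int(fields[1]), fields[2], fields[3]
            nodes[taxid] = (parent, rank, name)

    if names:
        nodes = {t: (p, r, names.get(t, "")) for t, (p, r, _n) in nodes.items()}

    roots = [t for t, (p, _r, _n) in nodes.items() if p == t]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one self-parented root, found {roots}")
    tree = TaxonomyTree(nodes=nodes, root_id=roots[0])

    if merged_source is not None:
        tree.merged = load_merged(merged_source)  # type: ignore[attr-defined]
    return tree


def load_merged(source) -> dict[int, int]:
    """Parse a taxdump ``merged.dmp`` old→new taxid remap table."""
    remap: dict[int, int] = {}
    for ln in _read_lines(source):
        if not ln.strip():
            continue
        fields = _parse_dmp_row(ln)
        remap[int(fields[0])] = int(fields[1])
    return remap


def remap_taxid(taxid: int, tree: TaxonomyTree, merged: Mapping[int, int] | None = None) -> int:
    """Apply a merged-taxid remap; unknown, unmapped ids fail fast."""
    if taxid in tree:
        return taxid
    if merged and taxid in merged and merged[taxid] in tree:
        return merged[taxid]
    raise TaxonomyError(f"taxid {taxid} not in taxonomy and not remappable")
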