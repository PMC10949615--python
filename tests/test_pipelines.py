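import numpy as np
import pytest

from condiga.formats import AlignmentRecord, AssemblyMeta, BlastHit, GeneRecord, TaxAssignment
from condiga.pipelines import (
    PipelineError,
    assign_genes_by_best_alignment,
    blast_assignments,
    choose_reference_assembly,
    md1_annotate,
    md2_annotate,
    select_confident_species,
    species_profile,
    tabulate_annotation,
)
from condiga.sixframe import UNKNOWN
from condiga.taxonomy import TaxonomyTree


def _aln(query, target, matches, block=None, mapq=60, primary=True, qlen=1000):
    return AlignmentRecord(
        query_id=query, query_length=qlen, target_id=target, target_length=10**6,
        matches=matches, block_length=block if block is not None else matches,
        strand="+", mapq=mapq, primary=primary,
    )


class TestMd1:
    def test_strain_call_lifted_to_species(self, small_tree):
        ann = md1_annotate([TaxAssignment("g1", 1011, "kaiju")], small_tree)
        assert ann["g1"] == 101

    def test_genus_call_is_unknown(self, small_tree):
        ann = md1_annotate([TaxAssignment("g2", 11, "kaiju")], small_tree)
        assert ann["g2"] == UNKNOWN

    def test_conservation_with_unclassified(self, small_tree):
        ann = md1_annotate(
            [
                TaxAssignment("g1", 101, "kaiju"),
                TaxAssignment("g2", 102, "kaiju"),
                TaxAssignment("g3", None, "kaiju"),
            ],
            small_tree,
        )
        assert ann.n_labeled == 2 and ann.n_unknown == 1 and len(ann) == 3

    def test_missing_genes_become_unknown(self, small_tree):
        ann = md1_annotate(
            [TaxAssignment("g1", 101, "blast")], small_tree, all_genes=["g1", "g2"]
        )
        assert ann["g2"] == UNKNOWN and len(ann) == 2

    def test_conflicting_duplicates_rejected(self, small_tree):
        with pytest.raises(PipelineError, match="conflicting"):
            md1_annotate(
                [TaxAssignment("g1", 101, "kaiju"), TaxAssignment("g1", 102, "kaiju")],
                small_tree,
            )


class TestMd2:
    @staticmethod
    def _gene(gid, contig):
        return GeneRecord(gid, contig, 1, 3, "+", "ATG")

    def test_propagation(self, small_tree):
        ann = md2_annotate(
            [TaxAssignment("c1", 101, "kaiju")],
            [self._gene("g1", "c1"), self._gene("g2", "c1")],
            small_tree,
        )
        assert ann["g1"] == ann["g2"] == 101

    def test_unclassified_contig_gives_unknown(self, small_tree):
        ann = md2_annotate(
            [TaxAssignment("c2", None, "kaiju")], [self._gene("g3", "c2")], small_tree
        )
        assert ann["g3"] == UNKNOWN

    def test_two_contigs_two_labels(self, small_tree):
        ann = md2_annotate(
            [TaxAssignment("c1", 101, "kaiju"), TaxAssignment("c2", 103, "kaiju")],
            [self._gene("g1", "c1"), self._gene("g2", "c2")],
            small_tree,
        )
        assert ann.distinct_species() == {101, 103}

    def test_unknown_contig_rejected(self, small_tree):
        with pytest.raises(PipelineError, match="absent"):
            md2_annotate([], [self._gene("g1", "cX")], small_tree)


class TestSpeciesProfile:
    def test_two_species_arithmetic(self, small_tree):
        profiles = species_profile(
            [
                TaxAssignment("c1", 101, "kaiju"),
                TaxAssignment("c2", 101, "kaiju"),
                TaxAssignment("c3", 102, "kaiju"),
            ],
            {"c1": 6000, "c2": 3000, "c3": 1000},
            {101: 1_000_000, 102: 2_000_000},
            small_tree,
        )
        by_sp = {p.species_taxid: p for p in profiles}
        assert by_sp[101].abundance_pct == pytest.approx(90.0)
        assert by_sp[101].coverage_pct == pytest.approx(0.9)
        assert by_sp[102].abundance_pct == pytest.approx(10.0)
        assert by_sp[102].coverage_pct == pytest.approx(0.05)

    def test_single_species_is_100pct(self, small_tree):
        (p,) = species_profile(
            [TaxAssignment("c1", 101, "kaiju")], {"c1": 500}, {101: 1000}, small_tree
        )
        assert p.abundance_pct == pytest.approx(100.0)

    def test_no_resolved_contigs_empty(self, small_tree):
        assert species_profile(
            [TaxAssignment("c1", None, "kaiju")], {"c1": 500}, {}, small_tree
        ) == []

    def test_abundances_sum_to_100(self, small_tree):
        profiles = species_profile(
            [TaxAssignment(f"c{i}", sp, "kaiju") for i, sp in enumerate([101, 102, 103, 101])],
            {f"c{i}": 100 * (i + 1) for i in range(4)},
            {},
            small_tree,
        )
        assert sum(p.abundance_pct for p in profiles) == pytest.approx(100.0, abs=1e-9)

    def test_missing_length_rejected(self, small_tree):
        with pytest.raises(PipelineError, match="length"):
            species_profile([TaxAssignment("c1", 101, "kaiju")], {}, {}, small_tree)


class TestSelect:
    def _profiles(self, small_tree):
        return species_profile(
            [
                TaxAssignment("c1", 101, "kaiju"),
                TaxAssignment("c2", 101, "kaiju"),
                TaxAssignment("c3", 102, "kaiju"),
            ],
            {"c1": 6000, "c2": 3000, "c3": 1000},
            {101: 1_000_000, 102: 2_000_000},
            small_tree,
        )

    def test_coverage_filters(self, small_tree):
        _, selected = select_confident_species(self._profiles(small_tree), 0.5, 0.1)
        assert selected == {101}  # SpB fails coverage at 0.05%

    def test_inclusive_boundary(self, small_tree):
        profiles = self._profiles(small_tree)
        # abundance exactly at the threshold is selected (inclusive >=)
        _, selected = select_confident_species(profiles, 10.0, 0.05)
        assert 102 in selected
        _, strict = select_confident_species(profiles, 10.0, 0.05, inclusive=False)
        assert 102 not in strict

    def test_empty_profile(self):
        flagged, selected = select_confident_species([], 0.5, 0.1)
        assert flagged == [] and selected == set()

    def test_unknown_coverage_never_selected(self, small_tree):
        profiles = species_profile(
            [TaxAssignment("c1", 101, "kaiju")], {"c1": 100}, {}, small_tree
        )
        _, selected = select_confident_species(profiles, 0.0, 0.0)
        assert selected == set()


class TestChooseReference:
    def test_reference_beats_representative(self):
        rows = [
            AssemblyMeta(1, "GCF_B", "representative genome", "Complete Genome", "2019/01/01", 100),
            AssemblyMeta(1, "GCF_A", "reference genome", "Contig", "2015/01/01", 100),
        ]
        assert choose_reference_assembly(1, rows).assembly_accession == "GCF_A"

    def test_newer_date_wins_among_na(self):
        rows = [
            AssemblyMeta(1, "GCF_A", "na", "Contig", "2015/01/01", 100),
            AssemblyMeta(1, "GCF_B", "na", "Contig", "2019/06/01", 100),
        ]
        assert choose_reference_assembly(1, rows).assembly_accession == "GCF_B"

    def test_single_row(self):
        rows = [AssemblyMeta(1, "GCF_A", "na", "na", "", 100)]
        assert choose_reference_assembly(1, rows).assembly_accession == "GCF_A"

    def test_missing_species_errors(self):
        with pytest.raises(PipelineError):
            choose_reference_assembly(2, [AssemblyMeta(1, "GCF_A", genome_size=1)])


class TestBestAlignment:
    T2S = {"refA": 101, "refB": 102}

    def test_max_matches_wins(self):
        ann = assign_genes_by_best_alignment(
            [_aln("g1", "refA", 850), _aln("g1", "refB", 820)], self.T2S, ["g1"]
        )
        assert ann["g1"] == 101

    def test_unaligned_gene_unknown(self):
        ann = assign_genes_by_best_alignment([], self.T2S, ["g2"])
        assert ann["g2"] == UNKNOWN

    def test_block_length_tiebreak(self):
        ann = assign_genes_by_best_alignment(
            [_aln("g3", "refA", 500, block=550), _aln("g3", "refB", 500, block=600)],
            self.T2S,
            ["g3"],
        )
        assert ann["g3"] == 102

    def test_secondary_alignments_ignored(self):
        ann = assign_genes_by_best_alignment(
            [_aln("g1", "refB", 990, primary=False), _aln("g1", "refA", 500)],
            self.T2S,
            ["g1"],
        )
        assert ann["g1"] == 101

    def test_full_tie_falls_to_smallest_taxid_string(self):
        ann = assign_genes_by_best_alignment(
            [_aln("g1", "refB", 500, mapq=60), _aln("g1", "refA", 500, mapq=60)],
            self.T2S,
            ["g1"],
        )
        assert ann["g1"] == 101  # "101" < "102"

    def test_unmapped_target_rejected(self):
        with pytest.raises(PipelineError, match="selected"):
            assign_genes_by_best_alignment([_aln("g1", "refZ", 10)], self.T2S, ["g1"])


class TestBlastReduction:
    def _hit(self, q, taxids, bitscore):
        return BlastHit(
            qseqid=q, sseqid="s", staxids=tuple(taxids), sscinames="", scomnames="",
            sskingdoms="", pident=99.0, length=100, qlen=100, slen=100, mismatch=0,
            gapopen=0, gaps=0, qstart=1, qend=100, sstart=1, send=100, stitle="",
            evalue=0.0, bitscore=bitscore, qcovs=100.0, qcovhsp=100.0,
        )

    def test_max_bitscore_wins(self, small_tree):
        (a,) = blast_assignments(
            [self._hit("c1", (101,), 200.0), self._hit("c1", (103,), 150.0)], small_tree
        )
        assert a.taxid == 101

    def test_bitscore_tie_collapses_to_lca(self, small_tree):
        (a,) = blast_assignments(
            [self._hit("c1", (101,), 200.0), self._hit("c1", (102,), 200.0)], small_tree
        )
        assert a.taxid == 11  # shared genus


class TestTabulate:
    def test_annotation_rate(self, small_tree):
        ann = md1_annotate(
            [TaxAssignment(f"g{i}", 101 if i < 7 else None, "kaiju") for i in range(10)],
            small_tree,
        )
        s = tabulate_annotation(ann)
        assert s.annotation_rate == pytest.approx(0.7)
        assert s.labeled + s.unknown == s.total_genes == 10

    def test_truth_identity_gives_perfect_scores(self, small_tree):
        ann = md1_annotate(
            [TaxAssignment("g1", 101, "kaiju"), TaxAssignment("g2", 103, "kaiju")], small_tree
        )
        s = tabulate_annotation(ann, truth={"g1": 101, "g2": 103})
        assert s.precision == 1.0 and s.recall == 1.0

    def test_species_counts(self, small_tree):
        ann = md1_annotate(
            [
                TaxAssignment("g1", 101, "kaiju"),
                TaxAssignment("g2", 101, "kaiju"),
                TaxAssignment("g3", 103, "kaiju"),
                TaxAssignment("g4", None, "kaiju"),
            ],
            small_tree,
        )
        s = tabulate_annotation(ann)
        assert s.species_gene_counts == {101: 2, 103: 1}
        assert s.species_count == 2


# ---------------------------------------------------------------------------
# brute-force oracle agreement on random small communities


def _brute_profile_select(assignments, lengths, sizes, tree, ab_min, cov_min):
    """Naive reimplementation: explicit loops, no shared code path."""
    per_species = {}
    for a in assignments:
        if a.taxid is None or a.taxid not in tree:
            continue
        sp = None
        node = a.taxid
        while True:
            if tree.nodes[node][1] == "species":
                sp = node
                break
            if node == tree.root_id:
                break
            node = tree.nodes[node][0]
        if sp is None:
            continue
        per_species.setdefault(sp, []).append(lengths[a.seq_id])
    total = sum(sum(v) for v in per_species.values())
    out = {}
    for sp, ls in per_species.items():
        ab = 100.0 * sum(ls) / total
        cov = 100.0 * sum(ls) / sizes[sp] if sp in sizes else None
        out[sp] = (sum(ls), ab, cov)
    selected = {
        sp for sp, (_b, ab, cov) in out.items()
        if cov is not None and ab >= ab_min and cov >= cov_min
    }
    return out, selected


def _random_community(rng):
    n_species = int(rng.integers(1, 8))
    nodes = {1: (1, "no rank", "root"), 2: (1, "genus", "G")}
    species = []
    for i in range(n_species):
        taxid = 100 + i
        nodes[taxid] = (2, "species", f"sp{i}")
        species.append(taxid)
    tree = TaxonomyTree(nodes=nodes, root_id=1)
    n_contigs = int(rng.integers(1, 51))
    assignments, lengths = [], {}
    for c in range(n_contigs):
        cid = f"c{c}"
        u = rng.random()
        taxid = None if u < 0.15 else (2 if u < 0.25 else int(rng.choice(species)))
        assignments.append(TaxAssignment(cid, taxid, "synthetic"))
        lengths[cid] = int(rng.integers(200, 20_000))
    sizes = {sp: int(rng.integers(10**5, 10**7)) for sp in species if rng.random() > 0.1}
    return tree, assignments, lengths, sizes


def test_profile_and_selection_match_bruteforce():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        tree, assignments, lengths, sizes = _random_community(rng)
        ab_min = float(rng.uniform(0, 40))
        cov_min = float(rng.uniform(0, 2))
        profiles = species_profile(assignments, lengths, sizes, tree)
        flagged, selected = select_confident_species(profiles, ab_min, cov_min)
        brute, brute_selected = _brute_profile_select(
            assignments, lengths, sizes, tree, ab_min, cov_min
        )
        assert {p.species_taxid for p in profiles} == set(brute)
        for p in profiles:
            b_bases, b_ab, b_cov = brute[p.species_taxid]
            assert p.assigned_bases == b_bases
            assert p.abundance_pct == pytest.approx(b_ab)
            if b_cov is None:
                assert p.coverage_pct is None
            else:
                assert p.coverage_pct == pytest.approx(b_cov)
        assert selected == brute_selected


def test_selection_monotone_in_thresholds(small_tree):
    rng = np.random.default_rng(77)
    tree, assignments, lengths, sizes = _random_community(rng)
    profiles = species_profile(assignments, lengths, sizes, tree)
    grid = [0.0, 0.5, 1.0, 5.0, 20.0]
    prev_rows = None
    for ab in grid:
        row = []
        for cov in [0.0, 0.05, 0.1, 0.5, 1.0]:
            _, sel = select_confident_species(profiles, ab, cov)
            if row:
                assert sel <= row[-1][1]
            row.append((cov, sel))
        if prev_rows:
            for (c, s), (_pc, ps) in zip(row, prev_rows):
                assert s <= ps
        prev_rows = row
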