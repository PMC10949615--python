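# Methods

## The annotation problem

A metaproteomic search is only as good as its protein sequence database.
When the database is derived from the sample's own metagenome, every
predicted gene must carry a species label, and the labeling strategy
determines both how many proteins can be attributed to a species and how
many spurious species enter the database. `condiga` implements three
strategies over one shared set of gene predictions:

* **MD1** classifies each predicted gene directly. Short genes carry weak
  taxonomic signal, so MD1 tends to scatter labels across many species that
  are not in the sample.
* **MD2** classifies the (longer, better-resolved) contigs and propagates
  each contig's species label to its genes. Its failure mode is chimeric
  assembly: when reads from two species co-assemble into one contig, every
  gene on it inherits a single label.
* **MD3 (ConDiGA)** uses the contig classifications only to decide *which
  species are confidently present*, then assigns genes by alignment against
  those species' reference genomes. Misassemblies and sporadic
  misclassifications are absorbed at the selection stage rather than
  propagated to genes.

All three lift classifier calls to species rank before accounting: a call
below species (a strain) resolves upward to its species; a call above
species (genus or higher) cannot be resolved and counts as `unknown`.

## Species profile and confident-species selection

For contig set *C* with per-contig species calls, the profile of species
*s* is

* relative sequence abundance: `100 · Σ_{c→s} len(c) / Σ_{c→species} len(c)`
  (percent of *species-resolved* contig bases; unclassified and
  above-species contigs are excluded from the denominator — a configurable
  choice, `weighting="count"` switches to contig counts);
* genome coverage: `100 · Σ_{c→s} len(c) / G_s`, with `G_s` the species'
  reference genome size.

Coverage here is an approximation: it uses the total assigned contig bases
rather than alignment-derived covered positions (contig classifiers emit no
coordinates), so it can exceed 100 % for deeply assembled species. A
species with no known genome size has undefined coverage and can never be
selected.

Selection keeps species with `abundance ≥ a_min` **and** `coverage ≥
c_min`. Both comparisons are inclusive by default (`inclusive=False` gives
strict `>`); the two shipped presets are `synthetic-community`
(0.5 %, 0.1 %) — appropriate for defined mixtures where every true member
is abundant — and `fecal` (0.01 %, 0.1 %) for complex communities with a
long low-abundance tail.

## Gene assignment

MD3 assigns genes from minimap2 PAF alignments against the selected
species' genomes. Secondary alignments (`tp:A:S`) are discarded; among a
gene's primary alignments the maximum residue-match count (PAF column 10)
wins, with a total tie-break chain — block length (column 11), then mapq,
then lexicographically smallest species taxid — so identical inputs always
produce byte-identical annotation maps. Genes with no primary alignment to
a selected species are `unknown`. Because alignments to unselected species
are filtered before assignment, the label set is a subset of the selected
set by construction.

Reference assemblies are chosen from `assembly_summary.txt` rows by RefSeq
category (reference > representative > other), then assembly level
(Complete Genome > Chromosome > Scaffold > Contig), then latest release
date, then smallest accession.

BLAST tabular input (the 22-field layout with taxonomy columns) is reduced
to one call per query before any of this: maximum bitscore wins, exact ties
collapse to the LCA of the tied taxids, and queries without any BLAST row
(BLAST writes nothing for a no-hit query) are treated as unclassified via
the optional gene/contig universe arguments of `md1_annotate`/`md2_annotate`.

## Translation and database construction

CDS translation uses NCBI genetic code 11. The initial codon is rendered
as `M` whenever it is one of the table's start codons (TTG, CTG, ATT, ATC,
ATA, ATG, GTG); a trailing stop is dropped; an internal stop is an error
(such genes are skipped with a logged warning and counted, so entries +
skipped = genes). Ambiguous codons translate to `X`; fully ambiguous
proteins are skipped. Headers follow a UniProt-like dialect
(`OS=<species name> OX=<taxid> strategy=<tag>`, `OS=unknown OX=0` for
unannotated genes) so search engines parse taxonomy without custom code.
Deduplication of identical protein sequences is off by default (a flag
enables it). Because MD1/MD2/MD3 share gene predictions, their databases
differ only in headers — the sequence multisets are identical, which the
test suite asserts literally.

Six-frame databases translate frames +1..+3 of each contig and −1..−3 of
its reverse complement, with `*` at stops; the writer emits either the full
frame strings or stop-free fragments of ≥ 20 aa (both modes exist because
downstream tools differ in what they expect). The 6FT annotation rule is:
among hits with alignment fraction > 10 % **and** identity > 10 % (both
strict, matching the rule's "over 10%" phrasing), the longest alignment
wins; ties break to the smallest species taxid. Alignment fraction is
relative to the query length (configurable).

## MG/MP abundance comparison

MG abundance of a species is its share of species-labeled genes (unknowns
excluded). MP abundance is its share of summed peptide intensity; shared
peptides (matching protein groups of more than one species) are excluded
by default, since razor-peptide conventions vary — `shared="split"` divides
them equally instead. Species fractions are rolled up the taxonomy to any
requested rank by lineage summation and renormalized within the rank;
species whose lineage lacks the rank are dropped before renormalization.
The per-taxon statistic is `log2(MG/MP)`; a taxon present on only one side
reports `None` rather than ±inf so the long-format TSV stays serializable.

## The synthetic community generator

The generator emulates the *intermediates* of a metagenomic workflow, not
the sequencing itself: no read simulation, no error models, no real
assembly — fragmentation with optional chimeras stands in for assembly
output. Its purpose is to give every pipeline stage realistic inputs in
the exact file dialects of the real tools, under one integer seed.

Key design points:

* **Abundance by construction.** Each species contributes exactly
  `round(fraction · total_assembly_bases)` contig bases, cut as a prefix
  partition of its genome into lognormal-length fragments (median ≈ 2 kb,
  σ = 0.5, minimum 500 bp). Realized abundances therefore sit exactly at
  their designed values, making threshold behaviour sharp rather than
  sampled.
* **The stock design** has 12 target species at 1–28 % of 500 kb assembly
  bases with genome sizes 50–200 kb (chosen so assigned bases never exceed
  the genome), and 40 decoys at 0.1 % each — five-fold below the stringent
  0.5 % abundance cut yet one full minimum-length contig each. Genome
  sizes are scaled down from bacterial scale so the whole fixture stays in
  the megabase range; every statistic exercised is a ratio, so the scale
  cancels.
* **Chimeras as tail replacement.** A chimeric contig keeps its length but
  has its tail (30 %) replaced by another species' sequence. Per-species
  base counts — and with them the realized abundances — are untouched by
  the chimera rate, while genes planted in the donor tail genuinely belong
  to the donor species, exercising the MD2 failure mode.
* **Genes** are ORF-like: a start codon, a random stop-free codon body
  (80–300 codons), and a stop, written into the contig on either strand and
  never straddling a chimera junction, so each gene has one true species
  and always translates cleanly.
* **Classifier emulation** draws, per sequence: unclassified (5 %),
  above-species/genus call (5 %), strain-level call (10 %, which lifts back
  to the true species), otherwise the true species; mislabeling to decoys
  is off by default because planted-recovery experiments require decoy
  abundance to be controlled by design. Output is serialized in the real
  Kaiju / Kraken2 `--use-names` / 22-field BLAST dialects so the parsers
  are exercised end to end (BLAST omits unclassified rows, as the real tool
  does).
* **Alignments**: each gene gets one primary PAF record to its true
  species' reference (92–99 % matches) and, with probability 0.3, a
  secondary record elsewhere with strictly fewer matches — so
  best-primary-alignment assignment recovers truth by construction, and any
  deviation observed in tests is a real pipeline defect.
* **Peptides** are tryptic-like (cut after K/R, length 6–40) with lognormal
  intensities scaled per species; 5 % are marked shared between two target
  species.

What passing tests on this fixture do **not** show: robustness to real
assembly artifacts (fragmented/partial genes, repeats, strain mixtures),
realistic classifier error structure (errors here are parameterized, not
homology-driven), or protein inference effects on the MP side. The fixture
demonstrates the pipeline logic — selection sharpness, conservation,
determinism, recovery under controlled noise — not classifier accuracy on
real sequences.

## Numerical and degenerate-input choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; stage seeds are derived arithmetically from
  the design seed and stay below 2³¹. Same seed ⇒ byte-identical fixtures.
* Abundance percentages over a profile sum to 100 within 1e-9; empty
  profiles (no species-resolved contigs) are legal and select nothing.
* Parsers fail fast with line numbers; they never drop malformed rows.
  Taxonomy loading rejects cycles and orphan parents at construction.
* Ties everywhere break through total, documented chains ending in a
  string comparison of taxids, so every output is deterministic.
* Problem sizes in the test suite and acceptance script (500 kb assembly,
  ~770 genes, 200-replicate oracle sweeps) were chosen to exercise every
  code path at comfortably interactive runtimes.

## Known limitations

* Coverage-from-assigned-bases can exceed 100 % and is only a proxy for
  breadth of coverage.
* The MD2 implementation trusts the single contig-level call; it does not
  re-vote contigs with conflicting per-gene evidence.
* Merged-taxid remapping is supported at the assignment level, but ids
  absent from both the taxonomy and the remap table fail fast rather than
  being dropped.
* The 6FT path consumes alignment tables; it does not run a search engine.
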