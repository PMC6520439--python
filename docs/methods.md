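# Methods

## Scope and data model

`metacaz` starts where assembly, gene prediction, read mapping and database
searches end: its inputs are the tabular artifacts those tools emit (a
12-column alignment report with a subject-taxon column, a taxonomy
nodes/names dump, a per-contig read-count table, HMM per-domain tables or a
simplified 6-column equivalent, peptide-hit tables, and per-gene EC
evidence from up to three channels). Gene identifiers encode their contig
as `<contig>_<n>`. All profiles are relative abundances — compositions —
and are treated as such throughout.

## Contig taxonomy: gene-vote-filtered LCA

Alignment hits are filtered with *strict* removal semantics: a hit is
removed when E > 10⁻⁵ or identity < 30%, so boundary values survive. Each
gene takes the taxon of its top surviving hit (maximal bit score; ties
broken by smaller E-value, then lexicographic taxon id, making assignment
independent of input order). For each contig, the support of a taxon is
the fraction of classified genes assigned *exactly* that taxon — votes for
a descendant do not count toward an ancestor. Taxa with support < 10%
(again strict, so a 1-in-10 minority survives while 1-in-11 does not) are
discarded and the contig receives the LCA of the survivors. Contigs with
no classified genes, or whose every taxon is discarded, are reported as
`UNCLASSIFIED` rather than assigned to the root: a root assignment carries
no information and would silently inflate "classified" totals.

One consequence worth knowing: the consensus is not strictly monotone at
the support boundary. Adding votes for the assigned taxon dilutes a
minority sitting at exactly 10% below the cutoff, which can sharpen the
call from the LCA to one of its descendants. The call never leaves the
assigned taxon's subtree; the test suite pins down exactly this behaviour.

Rank vocabulary is fixed (`root`, `superkingdom`, `phylum`, `class`,
`order`, `family`, `genus`, `species`). Dump files may carry other rank
labels (`no rank`, `tribe`, ...); these are mapped to the nearest coarser
recognised rank on the lineage, with a warning, so roll-ups stay well
defined.

## Abundance normalization

Counts are scaled to a common sequencing effort (default 10 Gb):
`scaled = reads · 10¹⁰ / total_clean_bases`. Coverage is
`scaled · L_read / len` with `L_read` defaulting to 150 bp. The scale
factor cancels in relative abundances but is kept explicit because
absolute coverages are exportable. Contigs with zero mapped reads are
retained at abundance 0 so matrix shapes are stable across samples.
Whether the original coverage estimator used per-base depth rather than
`reads · L / len` cannot be decided from the published numbers; the
formula above is fixed here and configurable only through `L_read`.

## Dual-evidence CAZyme calls

The HMM channel is filtered at E ≤ 10⁻⁵ (inclusive). Domains overlapping
by ≥ 1 residue on the protein are resolved by keeping the longest aligned
interval (ties: smaller E-value, then family label), repeated until the
kept intervals are pairwise disjoint. "Longest" is deliberately the
aligned interval on the protein, not the profile length, because overlap
is defined on the protein.

The peptide channel is a compact reimplementation of peptide-pattern
classification: a family model is the set of 6-mers occurring in at least
`min_count = 2` training sequences (top 200 by count, ties lexicographic,
counts retained as weights); a protein is assigned a family when at least
`min_hits = 2` distinct model peptides occur as substrings. These four
parameters (k, min_count, top_n, min_hits) are exposed; bit-for-bit
fidelity to any particular external implementation is a non-goal.

A family is *called* only when both channels agree; a gene may carry
several families. EC numbers are assigned per gene when ≥ 2 distinct
channels report a compatible EC, where a partial `x.y.z.-` is compatible
with any full `x.y.z.w`. The most specific agreed form is reported, and
conflicting fully-specified ECs with sufficient support are all reported
rather than adjudicated.

## Profile matrices and statistics

A sample's enzyme profile sums, per EC, the relative abundance of the
contig carrying each qualifying gene — a contig with g qualifying genes
contributes g times, which is the gene-level reading of published
cross-species tables. Cells are displayed ×10⁶. The taxon × enzyme matrix
routes each contribution to the carrier contig's taxon at a chosen rank
(default `order`), pooling unassignable mass under `UNCLASSIFIED`; its
column sums equal the enzyme profile exactly.

Fold change divides each cell by its column mean across samples;
all-zero columns are dropped with a warning, zero cells over a positive
mean give ratio 0 and log₂ = −∞, kept as a sentinel in numeric output and
floored (default −10) only for display.

CLR closes each row to proportions, replaces zeros multiplicatively
(default δ = half the smallest positive value of the closed matrix;
strategy pluggable), and centers log values per row. PCA is column-centered
SVD with a deterministic sign convention (largest-magnitude loading per
component made positive); explained-variance fractions are relative to the
total variance of the centered data. Hierarchical clustering defaults to
Euclidean distance with average linkage via scipy; both are configurable.

## Synthetic data: what it emulates, and what it does not

The generator draws a balanced ranked taxonomy (deterministic given the
size configuration, so samples of a study share one tree), a Dirichlet
community over genera (with optional diet presets biasing particular
orders, mimicking fungus-grower-like vs wood-feeder-like compositions),
contigs assigned to genera proportionally to abundance with log-normal
lengths and Poisson gene counts, noisy top hits (misassignment rate ε,
a configured fraction violating the E-value/identity filters, decoy
lower-scoring hits), multinomial read counts proportional to
abundance × length, and three-channel annotation evidence in which each
channel reports the planted label with sensitivity *s* and a random wrong
label with false-positive rate *f*, independently. All randomness flows
through one seeded generator; regeneration is byte-identical.

Default study conditions: 60 genera over 10 orders, 500 contigs, ε = 0.05,
10% filter-violating hits, 2×10⁵ reads of 150 bp, s = 0.9, f = 0.05, 30%
of genes annotated from a 10-family/EC inventory. Contigs default to ~33 kb
with ~40 genes (~36 classified): that places the typical contig firmly in
the regime the vote-filtered consensus is designed for, where single *and*
double wrong-genus votes fall below the 10% support cutoff. This is a
deliberate idealisation — real gut-metagenome assemblies have N50 near
1 kb, i.e. mostly short contigs with a handful of genes, whose
classification is intrinsically noisier. Passing recovery tests therefore
demonstrate that the machinery is correct in its operating regime, not
that short-contig field data would classify this well. Ground truth for
composition recovery is the *realized* catalogue composition (community
renormalized over genera that received at least one contig), since genera
without contigs are invisible to every downstream table. No sequence
realism is attempted except random proteins with planted peptides where
the peptide classifier needs them.

## Numerical and design choices

- Compositions must sum to 1 within 10⁻⁹ (profiles) and CLR rows to 0
  within 10⁻⁹; both are enforced or asserted rather than renormalized
  silently.
- Degenerate inputs fail loudly: all-zero coverage vectors, all-zero CLR
  rows, empty taxon sets for LCA, fold change on a single row.
- The pipeline stages re-use in-memory artifacts when run together and
  read the upstream stage's TSVs otherwise; a missing upstream output is a
  `DependencyError` naming the stage. Reruns are byte-identical; staged
  and joint runs agree to CSV-parser precision.
- The bundled nine-species table is shipped verbatim, including its twelve
  all-zero enzyme rows and its two repeated partial-EC labels (rows are
  keyed by `ec|enzyme-name` for uniqueness).

## Known limitations

- Strict LCA only: no probabilistic lineage models, no weighting of gene
  votes by score.
- The peptide classifier is a minimal reimplementation intended for
  consensus logic, not a drop-in for trained production models.
- Per-base depth, duplicate masking and read-level artifacts are outside
  scope; coverage is a read-count approximation.
- Statistical testing of differential abundance is intentionally absent;
  the fold-change and ordination outputs are descriptive.
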