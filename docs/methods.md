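# Methods

## The comparison problem

A pathway/genome database (PGDB) asserts three kinds of claims about an
organism: which genes encode enzymes (function annotations, here Enzyme
Commission numbers), which reactions those enzymes catalyze, and how
reactions assemble into pathways.  Two resources built on the same gene
model set can be compared on two axes: *accuracy* of the function
annotations against experimentally supported truth, and *content overlap*
per entity class.  This package implements both axes plus the pathway-level
gene–reaction contrast.

## Gold standard construction

Inputs are two annotation source tables — `reviewed` (manually curated
EC assignments) and `experimental` (literature-derived assignments) — a
cross-link table mapping experimental accessions to reviewed ones, and
BLASTP hits of the source proteins against the genome's translated gene
models.

Procedure: (1) re-key cross-linked experimental accessions to their
reviewed accession and take the union over (accession, EC label) pairs,
merging provenance; a single experimental accession linked to two different
reviewed accessions is an error, not a silent choice.  (2) Filter hits at
percent identity ≥ 96 and e-value ≤ 1e-20.  Both bounds are inclusive
("cutoff" read as pass-at-threshold, the conventional BLAST filtering
semantics); the tests pin this.  (3) Keep the top-scoring hit per query:
highest bitscore, ties broken by lowest e-value, then lexicographically
smallest subject identifier.  Bitscore rather than e-value is the primary
key because it is length-normalized; the full tie-break chain makes the
selection reproducible under input permutation.  Queries whose hits all
fail the filters are dropped entirely (no fallback to lower hits).
(4) Attach each accession's labels to the gene of its best-hit subject and
union the labels of all isoforms of a gene.  Only EC labels enter the gold
standard; GO terms never participate in accuracy scoring.

## Scoring rules

Evaluation is restricted to gold-standard genes.  For gold gene *g* with
labels gold(g) and predictions pred(g):

    TP = |pred(g) ∩ gold(g)|    FP = |pred(g) \ gold(g)|    FN = |gold(g) \ pred(g)|

Each prediction set carries its resource's *gene universe*; a gold gene
outside the universe has pred(g) = ∅, so all of its labels are false
negatives (the missing-gene rule, counted per annotation).  True negatives
are not counted — for open-ended function prediction the class of "functions
correctly not predicted" is unbounded — and for the same reason predictions
on genes without gold labels are unscorable and contribute nothing.  FP is
therefore counted only on gold genes; this is the only reading under which
TP + FN equals the gold annotation total for every prediction set, a
conservation law the package asserts (`check_conservation`) and surfaces as
a diagnostic when violated rather than ignoring.

EC labels are compared by exact four-field string equality after
normalization (strip `EC-`/`EC ` prefix, pad to four fields with `-`).  A
partial label such as `2.7.7.-` matches only an identical partial label; no
hierarchical credit is given.  Translocases (class 7) are accepted
throughout even though older resources predate the class.

precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R); empty
denominators score 0.  Metrics are kept at full precision internally and
rounded to two decimals for display only.

Merging two prediction sets takes the per-gene label union over the union
of the universes.  Merging can only add true positives (TP_merged ≥
max(TP_a, TP_b)), only remove false negatives, and accumulates at most the
sum of the false positives — properties the tests verify against brute-force
enumeration.

## Overlap statistics

Entities are matched across resources by exact identifier (MetaCyc-style
frame IDs), justified when both resources import reactions, compounds and
pathways from the same reference encyclopedia.  Structure-based compound
reconciliation (stereochemistry, protonation) is out of scope.  Per class:

* genes — restricted to *annotated* genes: ≥ 1 GO term, or associated with
  a protein catalyzing ≥ 1 reaction;
* proteins — restricted to reaction-mapped proteins (≥ 1 catalyzed
  reaction; spontaneous reactions map no protein);
* compounds — small molecules only, excluding macromolecules and elements
  (an explicit `KIND` slot in `compounds.dat` supplies the category, since
  the artifact does not ship an ontology to infer it from);
* reactions, pathways — all.

Each Venn partition satisfies unique_a + shared = |A| and
unique_b + shared = |B|.  Reactions are further tallied by top-level EC
class within each partition; the three partition totals sum to the size of
the reaction union.

## Pathway pairing matrix

For one pathway, the reaction columns are the union of the pathway's
reaction lists in the two resources (this generalizes the case where both
agree on membership), rows are genes with at least one pairing, and each
cell records which resource asserts the gene–reaction link (isoform links
collapsed to the gene).  Swapping the resources swaps the two single-sided
codes and fixes the rest.

## Flat-file dialect

One `SLOT - VALUE` pair per line; records end with `//`; repeated slots
accumulate into sets; a line starting with `/` continues the previous
value.  Recognized slots: genes.dat `UNIQUE-ID, PRODUCT, GO-TERMS`;
proteins.dat `UNIQUE-ID, GENE, CATALYZES`; reactions.dat
`UNIQUE-ID, EC-NUMBER, LEFT, RIGHT`; compounds.dat `UNIQUE-ID, KIND`;
pathways.dat `UNIQUE-ID, REACTION-LIST`.  UTF-8, Unix or Windows line
endings.  A record without `UNIQUE-ID`, or a duplicate `UNIQUE-ID` within a
file, is a parse error naming the file and record; unknown slots are
ignored with a logged warning; unresolved cross-references are collected as
diagnostics on the returned object, never silently dropped.  Writing is
deterministic (sorted records and slots), so equal databases produce
byte-identical files.

## Synthetic data: what it emulates and what it does not

The generator (`pgdbcompare.synthetic`) builds a paired-resource scenario
on one gene namespace.  Defaults are the study conditions of the maize
benchmark:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 5,000 | union gene count (scaled down from the ~40k-gene genome; large enough that every partition is well populated) |
| `mean_isoforms_per_gene` | 1.6 | resource A's transcripts per gene; resource B is canonical-transcript only, matching the real pair's splicing asymmetry |
| `go_fraction_a/b` | 0.001 / 0.531 | fraction of each resource's genes with GO terms |
| `reaction_map_fraction_a/b` | 0.991 / 0.198 | fraction of genes mapped to ≥ 1 reaction |
| `entity_overlap` | gene 0.5, reaction 0.525, compound 0.5, pathway 0.56 | shared fraction of each identifier union; reaction and pathway values follow the published resource pair |
| `n_gold_genes` / `n_gold_annotations` | 1,450 / 1,475 | gold standard size |
| `missing_gold_genes_a/b` | 86 / 2 | gold genes absent from each resource's universe |
| `planted_precision/recall` per resource | ratios of TP 1326 / FP 213 / FN 149 and TP 1235 / FP 436 / FN 240 | confusion plant |
| `ec_class_weights` | published shared-column class mix | EC top-level class distribution of generated reactions |
| `n_reactions` / `n_compounds` / `n_pathways` | 800 / 600 / 120 | union entity counts, scaled down proportionally |

Isoform counts are drawn as a geometric variable with mean
`mean_isoforms_per_gene` (support ≥ 1); the generated mean converges to the
target as `n_genes` grows and a test checks it within three standard
errors.

Counts are *planted by construction*, not sampled: the generator chooses
which gold labels each resource copies (TP), which it omits (FN, with the
missing-gene share forced by placing those gold genes in the other
resource's unique partition), and how many disjoint noise labels it adds to
gold genes (FP, drawn from an EC field range disjoint from the gold pool so
no accidental matches occur).  Venn partitions are likewise assigned, and
the generator bookkeeps every expected count with plain set arithmetic into
an `ExpectedLedger`.  End-to-end recovery of the ledger is therefore an
exact check, which is the primary test harness; an infeasible plant (e.g.
a recall implying fewer false negatives than the missing genes force) is a
config error.  Alignment hits are generated in all four pass/fail quadrants
of the identity/e-value filter, including one hit exactly on both cutoffs.

What the generator does **not** emulate: real sequences and chemistry, the
reference ontology's compound classes, name-based entity matching noise,
hierarchically related EC labels, or curation artifacts.  Passing tests
show the pipeline's bookkeeping is exact under the planted statistical
shape; they do not certify accuracy numbers for any real database pair.

## Numerical and design choices

* All randomness flows from one integer seed through numpy's `default_rng`;
  same config and seed give byte-identical flat-file output.
* Degenerate inputs: empty hit sets, empty PGDB directories and all-zero
  confusion counts are legal and score/parse to the obvious identities.
* The published merged-resource confusion row violates TP + FN conservation
  (1365 + 62 = 1427 against a 1,475-annotation gold standard) while the two
  single-resource rows conserve exactly; the package enforces conservation
  and reports such a violation as a diagnostic instead of reproducing it.
* Reported problem sizes: the test suite runs the planted scenario at
  n_genes = 400–600 for unit tests and 5,000 for the end-to-end recovery
  check; the acceptance script uses the 5,000-gene defaults.

## Known limitations

* Identifier-based matching understates overlap between resources that do
  not share a reference namespace.
* Exact EC matching gives no credit for near-miss predictions (correct to
  three fields); a hierarchical scorer is a deliberate non-goal.
* The gold-standard builder drops queries whose top hit fails the filters
  rather than re-examining lower-ranked hits.
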