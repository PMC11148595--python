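# Methods

This note documents the models, rules and parameter choices behind
`virannot`, in the order data flows through the engine.

## Host masking

Host-read removal deletes any read that maps to the host reference; if
the reference contains virus-like sequence, genuine viral reads vanish
with it. The masking recipe therefore shreds a viral reference
collection into fixed 85-base windows starting every 55 bases (i.e. a
30-base overlap), with the final window truncated at the sequence end —
"average length 85" arises from those truncated tails. Fragments are
located on the host on both strands by exact 13-mer seeding plus infix
alignment (edlib), and an alignment is accepted at ≥90% identity over
its aligned columns with at most 2 insertion/deletion *events* (gap
runs, not gap columns — the cap is on events because a single biological
indel of several bases should count once; both the cap and its unit are
configurable). Accepted intervals are unioned and hard-masked with `N`
rather than soft-masked, so downstream mapping hard-fails on them.
Masking is idempotent and length-conserving; externally produced
mappings can be supplied as 3-column BED (0-based half-open) instead of
using the built-in mapper.

Identity is gated on the aligned region (the whole fragment is always
consumed by the infix alignment); gating on full-fragment identity would
be marginally stricter for end-trimmed alignments.

## Dereplication and the seqtable

Reads are clustered per sample with a deterministic greedy centroid
algorithm: longest-first (ties by read id), each read joins the first
centroid it matches at ≥97% identity — matches divided by alignment
columns, gaps counting against — over an alignment covering ≥80% of the
centroid; otherwise it founds a new cluster. These thresholds mirror
standard linear-time clustering practice for read dereplication. An
exact 15-mer prefilter restricts which centroids are aligned; by the
pigeonhole principle any gap-free join candidate at the default
thresholds shares a 15-mer for reads up to ~480 bases, so at fixture
scales the prefiltered result is identical to the all-pairs scan (and a
test asserts this). Production clusterings can be ingested as a
2-column (read, representative) table instead — the bookkeeping, not
the clustering heuristic, is the load-bearing contract.

Headers pack `sample:cluster_index:member_count:percent_of_sample` with
the percentage at one decimal; `decode(encode(x)) = x` at that
precision. The percentage denominator is the post-host-removal read
count when host removal ran, else the raw read count. The count table
reports raw counts and CPM (`raw × 1e6 / sample_total`); per sample the
CPM column sums to 1e6 by construction.

## Tiered classification

The routing is: viral amino-acid hits → multikingdom amino-acid
cross-check; no aa evidence but viral nucleotide hits → polymicrobial
nucleotide cross-check; neither → `unclassified` (retained, with
sentinel taxonomy, so counts are conserved). Amino-acid-tier verdicts
are final and never re-routed to the nucleotide tier.

Hit ranking is (bitscore desc, e-value asc, target id asc) —
deterministic under permutation of input order. The cross-check rule:
with no secondary hits the primary viral call stands; otherwise the
verdict flips to `nonviral` only when the best non-viral secondary hit
*strictly* outscores every viral secondary hit by bitscore. Strict
dominance was chosen because bitscores are length- and
composition-normalized and the rule is monotone-safe: adding a worse
non-viral hit can never flip a viral verdict. Surviving viral calls are
assigned by LCA over the viral-consistent secondary hits whose e-value
is within a factor 10 of the top hit's (the conventional window for
dual-search LCA schemes; configurable). Hits with e-value above 1e-3
are discarded at parse time (configurable) so a visible ceiling always
exists.

## LCA with top-hit reversion

Plain LCA is computed by pairwise depth-lifting over the parent links.
An LCA over a mixed hit set degenerates in exactly two ways: to the
global root (evidence spans viruses and cellular organisms) or to the
virus root, taxid 10239 (evidence spans distinct viral realms). In both
cases, when the hit set has ≥2 distinct taxids, the assignment reverts
to the top hit and the row is flagged (`augmented=true`), preserving
information that a bare "root" assignment would discard. No-rank nodes
between root and the superkingdoms do **not** trigger reversion: the
trigger set is exactly {root, virus root}, the two degenerate cases with
a clear biological reading; extending it to intermediate no-rank nodes
would make the flag depend on dump-specific tree cosmetics.

Lineages are reported at the 7 canonical ranks (kingdom…species) with
the nearest ancestor-or-self per rank; the NCBI `superkingdom` rank
fills the kingdom slot when no kingdom node exists, matching how real
dumps are organized. Absent ranks carry the sentinel `unclassified`;
merged taxids are honored via `merged.dmp`; taxids unknown to the tree
classify to the sentinel lineage with a warning rather than aborting.

The Baltimore join (family → one of groups I–VII plus nucleic-acid
type) is data, not algorithm: a packaged ~100-family TSV compiled from
public ICTV/Baltimore definitions, matched case-sensitively, sentinel
`NA` on a miss.

## Contig tables

Per (contig, sample): `RPKM = r·1e9/(R·l)`; `FPKM` analogous over
fragments, where a read pair (mate suffixes `/1,/2,_R1,_R2`) counts once
when both mates map to the same contig, else each mate is its own
fragment; `SPM = 1e6·(r/l)/Σ(r/l)`, a TPM-style rate share that sums to
1e6 per sample whenever any read maps. Only primary alignments are
counted (secondary/supplementary SAM records are skipped) so every read
contributes at most once. GC is computed over A/C/G/T only; coverage is
the union of mapping intervals. Unmapped reads are pooled across
samples with provenance retained; a read appearing both mapped and
unmapped is a hard integrity error.

## Quadrant QC

Hits are triaged by percent identity versus alignment length with
cutoffs 70% (translated), 90% (untranslated) and 150 aligned bases —
deliberately user-adjustable study conventions, not fitted values.
Boundary values classify to the high/long side (Q1 high/short, Q2
high/long, Q3 low/short, Q4 low/long); the rule had to be pinned one way
and boundary-inclusive keeps "at the cutoff" hits in the
higher-confidence class.

## Synthetic data and the naive aligner

The fixture generator emits: taxdump-dialect toy taxonomies (each viral
family on its own 7-rank path under taxid 10239, so cross-family hits
exercise the virus-root reversion); uniform-random genomes; reads
sampled uniformly from both strands with i.i.d. substitutions (default
rate 1%, the scale of platform error; an indel knob exists but defaults
to 0 so read–source identity stays analytically simple); and per-read
truth labels. Toy protein databases are the frame-1 translation of each
genome, which makes one of a read's six frames a near-exact substring of
its source protein.

The naive aligner (exact k-mer seeds, edlib infix extension, nt k=13 /
aa k=5) emits 13-column BLAST tabular. Its bitscore is a documented
Karlin–Altschul-style proxy (nt +2/−3, gaps −5/−2, λ=0.625, K=0.41; aa
+4/−2 unit-cost, gaps −6/−1, λ=0.267, K=0.041; `E = m·n·2^−bits`) and is
not comparable to a production aligner's; amino-acid alignment is
unit-cost edit distance, not BLOSUM-weighted, which is the correct
signal here because fixtures are built from the same genomes as the toy
databases. Thresholds on these scores are fixture-calibrated.

What the fixtures do *not* emulate: real error models (quality-dependent
substitutions, homopolymer indels), compositional bias, repeats, shared
genes between genomes, database incompleteness, or chimeric reads.
Passing the end-to-end benchmark therefore demonstrates routing,
bookkeeping and count-conservation correctness — not production recall
on real viromes.

## Benchmark problem sizes

The standard end-to-end benchmark uses 4 viral (4 kb) + 2 bacterial
(8 kb) genomes, 200 reads of 150 bases per genome, 1% substitutions,
seed 42 — a deliberately desk-scale design whose expected outcome
(family-rank sensitivity ≥0.95, FPR ≤0.05) mirrors, qualitatively, the
near-perfect recovery such engines show on in-silico communities at
full scale. Oracle suites use 1,000 random LCA queries on ~75-node
trees, 200-read clustering fixtures and 200 randomized routing fixtures.
Runs are bit-reproducible given a seed.

## Known limitations

* The greedy clusterer is quadratic in the worst case and intended for
  desk scale; large runs should ingest external clusterings.
* The built-in fragment mapper and aligner index every k-mer position
  in memory; they are reference implementations, not production tools.
* The confirmatory cross-check accepts whole-read secondary hit tables;
  a region-restricted variant (re-querying only the aligned region)
  would be slightly more conservative and is not implemented.
* Baltimore assignment is family-table-driven; families absent from the
  packaged table yield `NA` rather than being inferred.
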