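# Methods

This note documents the models, conventions and numerical choices behind
`trapmeta`, and what the synthetic fixtures do and do not establish about
real data.

## Study design and containers

All stages assume the eight-library design: two *Genlisea* species (NIG,
HIS) × two seasons (SS summer, WS winter) × trap and leaf organs, with the
trap and leaf samples of one species/season forming a pair
(`trapmeta.design`). Community abundances live in an `AbundanceTable`
(genus × sample integer counts plus a category label per genus over the
five community categories: Bacteria, SAR protists, Chlorophyta, Metazoa,
other eukaryotes). Host expression lives in an `ExpressionMatrix` (total
and unique mapped read counts plus exon lengths).

## Read trimming and classification

**Trimming** is the modified-Mott rule: with per-base error probability
`p_i` (from Phred+33 qualities), keep the contiguous segment maximizing
`sum(limit − p_i)` with `limit = 0.05`; reads retaining fewer than 80
bases are dropped. Among equal-score segments we keep the longest, then
the leftmost — this tie-break makes trimming idempotent, which the suite
checks as a property.

**Classification** is defined purely by thresholds over a standard local
alignment: a read is assigned to every reference for which some local
alignment covers ≥ 90% of the read at ≥ 80% identity (97% in the strict
rRNA tier). The scoring scheme (match +1, mismatch −2, gap open −3, gap
extend −1) is configurable and documented because different schemes pick
different optimal alignments near the thresholds; only the thresholds are
normative. `N` bases never match, and the identity denominator is
alignment columns excluding end gaps. Candidate references come from an
exact 15-mer index supplemented by a banded edit-distance screen
(`edlib`), so divergent-but-in-threshold targets are not lost to seeding;
a read shorter than the seed size is unassignable.

**Binning** follows priority rRNA > host > non-host: a read matching both
an rRNA and a host reference counts as rRNA, and the remainder after both
reference sets is the non-host mRNA bin. rRNA is evaluated at both 97%
and 80% identity; the strict tier defines the bin by default (a flag
switches this), and the composition summary reports both counts. Percents
are rounded half-up to 2 decimals, the convention of published
library-summary tables.

## Ribotag profiling

A reference sequence contributes to its genus only when at least one read
maps uniquely to it; it then contributes its *total* mapped reads (unique
plus shared). A read shared by k qualifying references therefore counts k
times by default — this multi-counting matches how per-reference mapping
totals are summarized by taxonomy tools; a fractional 1/k mode is
available but off. Organellar (mitochondrial/plastid) rRNA references are
excluded from community profiling. Genus is the first ancestor of rank
"genus"; references whose lineage stops above genus are aggregated at
their deepest named ancestor and logged. Richness is genera with ≥ 1
qualifying read.

Two normalizations: reads per million of the per-sample rRNA total, and
percent within the genus's category in that sample (undefined, emitted as
missing, where a category has no reads). Rarefaction draws uniform
subsamples without replacement, one permutation per replicate (100
replicates by default, seeded), which makes each replicate's curve
monotone by construction; the suite checks the mean against the
hypergeometric closed form.

## The active-microbiome classifier

A genus is called *preferentially entrapped* when all three criteria
hold:

1. **Abundance** — within-category percent ≥ 0.1 in at least one trap
   sample. A strict mode requiring it in every occupied trap sample
   exists; the permissive reading is the default because it reproduces
   the "≥ 0.1% and found in ≥ 2 trap samples" style of census.
2. **Occurrence** — present (≥ 1 read by default; configurable to
   ≥ 0.1%) in at least two of the four trap samples, regardless of
   species or season.
3. **Enrichment** — trap/leaf fold change ≥ 2 in at least one
   species/season pair, where both abundances are within-category
   percents. A trap-present/leaf-absent genus is *trap-exclusive*
   (reported as infinity) and passes; absent from both is undefined. A
   mean-over-pairs mode exists.

Raising any threshold can only shrink the called set (checked as a
property). Per-genus paired t-tests are reported unadjusted, as is usual
for this design; Benjamini–Hochberg columns are added for information
only and do not drive the classifier. Both the trap-vs-leaf contrast (per
species, n = 2 pairs, 1 df — flagged low-power) and the winter-vs-summer
contrast (per organ) are emitted, since with two species and two seasons
either pairing is defensible.

Sample clustering uses Bray–Curtis dissimilarity
(`sum|u−v| / sum(u+v)`; two empty samples defined as identical) and
UPGMA. UPGMA is implemented directly (~50 lines) rather than through a
linkage library because the output contract — deterministic
lexicographic tie-breaking and an ultrametric Newick tree whose branch
lengths are height differences — is part of the interface; scipy's
average linkage is the oracle for merge heights in the tests.

Phenotype profiles are abundance-weighted: a trait's proportion in a
genus set is the abundance share of members carrying it, so multi-label
genera contribute to every trait they carry (proportions within a
phenotype category can exceed 100% in sum) and unannotated mass is
reported as `unknown`.

## Contig cascade and functional summaries

The subtraction order is fixed as: length ≥ 500 → remove host matches →
remove rRNA matches → cluster at 80% identity keeping representatives →
remove leaf-assembly matches → keep ≥ 1000 bp; cluster-then-leaf order is
configurable since either is defensible. Match evidence is either a
supplied tabular hit set (removal at e-value ≤ 1e-9) or the module's own
search (best infix alignment at ≥ 80% identity over ≥ 100 columns). Every
removal carries its stage tag and `removed + survivors = input` is
checked on every run.

Clustering is greedy and incremental: contigs visited by decreasing
length (ties lexicographic), joining the first representative at ≥ 80%
global identity. Identity is matches / alignment columns with terminal
gaps free (the convention of greedy clustering tools, under which a
contained substring has identity 1), computed from edlib extended CIGARs.

Taxonomic assignment takes the best protein hit (bit score, then
e-value, then subject id), requires bit score ≥ 50, and buckets hits
whose lineage passes through Chordata into the Metazoa category. Because
"LCA over one best hit" degenerates to best-hit assignment, a true-LCA
mode over hits within 10% of the best score is provided; neither mode
claims to reproduce any external tool exactly. The annotation window is
the closed interval 1500–8000 bp.

EC tallies count a transcript once per top-level class it carries;
hydrolases are EC 3.-, with phosphatase (EC 3.1.3) and peptidase (EC 3.4)
sub-tallies, and the hydrolase fraction is hydrolase transcripts over
EC-assigned transcripts (percent, one decimal). GO enrichment runs a
two-sided Fisher's exact test per term on the subset × has-term table
with annotations propagated to ancestor terms (flat mode available for
toy ontologies), Benjamini–Hochberg across terms, significance at
q < 0.05. The full annotation-score weighting of GO annotation pipelines
is out of scope; GO terms are taken from hits at e-value ≤ 1e-6.

## Host differential expression

RPKM = 1e9 · count / (exon length · library total). Quantile
normalization is the classical algorithm: replace each value by the mean
over samples of the values at its rank, ties receiving the mean of their
tied ranks' reference values; afterwards all columns share one multiset
and within-column order is preserved (both checked). Genes are tested
only if they pass the expressed rule — more than one unique read and
more than five total reads — in at least one sample by default (an
all-samples mode exists; the rule's scope is genuinely underdetermined,
so it is a flag). Per-pair log2 ratios use a pseudo-offset of 1
normalized-RPKM unit against zeros (configurable, recorded in output).

DEG selection: paired t-test across the trap/leaf pairs, DEG at
p < 0.05. The additional fold-change condition is exposed as `log2_cut`
with default 0 (p-only), because a strict |log2 ratio| > 2 reading is
inconsistent with published DEG sets that contain two-fold changes; the
"strongly changed" subset uses `log2_cut = 1` (≥ two-fold). Counts are
reported as percents of the whole catalog and of expressed genes, one
decimal.

## The synthetic-data generator

The generator is the package's study-conditions contract, not a tuning
surface. Defaults: 36 genera over the five categories, 8 planted active
genera (one trap-exclusive), enrichment fold 4, decoy fold 1.5, 40% rare
background genera (0.1–1%), 100,000 rRNA-table reads per sample, 400
simulated 100-bp reads per library at 0.5% substitution error, 200 host
genes with 10 planted DEGs at |log2FC| = 3 and lognormal noise of 0.25
(log2 scale). Seeds fully determine every output (per-operation rng
streams), and the same configuration reproduces byte-identical files.

Planted margins are at least twofold on every classifier threshold:
actives sit at 0.8% within-category (vs the 0.1% cutoff), occur in all
four trap samples (vs two), and are enriched fourfold (vs two); each
decoy violates exactly one criterion (0.05% abundance; single-trap
occurrence; 1.5-fold enrichment). Background genera are jittered within
±10% per sample, so their pairwise ratios stay below ~1.5 and they can
never pass criterion (iii); one background genus per category is forced
dominant (> 10%). Category totals are equal across samples up to
rounding, so count ratios and percent ratios agree to a few percent.

Planted DEGs start from a mid-range baseline and the *elevated* organ
stays inside the null value envelope (up-regulated genes elevated in
traps, down-regulated genes elevated in leaves). This matters: quantile
normalization equalizes the per-sample value distributions including
their extremes, so planted effects that protrude beyond the null range
are compressed and can push adjacent null genes across the fold
threshold. Keeping planted values inside the envelope bounds the
normalization distortion by the local rank spacing (~0.03 log2 units at
the default density).

What the fixtures do **not** emulate: realistic sequence evolution or
conserved rRNA domains (references are i.i.d. random, so cross-mapping
between genera is essentially absent and the unique-read rule is easier
than on real SILVA references); paired-end fragment structure; abundance
overdispersion between biological replicates; real ontology or trait
databases. Passing recovery suites therefore demonstrates correctness of
the decision logic under the planted margins, not field performance on
real libraries.

## Problem sizes

Default test and acceptance runs use 400 reads × 8 libraries for the
read-level stages, 36-genus count tables, ~25-contig cascade fixtures
and 150–200-gene expression matrices; recovery suites run 10–20 seeds
and the null type-I estimate 200 simulations (~30,000 tests). These
sizes give exact planted-set recovery and a type-I estimate with a
standard error near 0.1 percentage points while keeping the full suite
under a minute of CPU.
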