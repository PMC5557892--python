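# Methods

This note documents the models, rules and numerical choices behind
`chimeramap`, and what the bundled synthetic studies do and do not
establish about real data.

## Coordinates and alphabets

All genomic coordinates are 0-based half-open internally; GTF input is
read as 1-based inclusive and converted, BED output is written 0-based
half-open. RNA sequences are normalized to the DNA alphabet (U→T) at
ingest; all matching, complementation and wobble evaluation (G:U written
G:T) happens in DNA space.

## Chimera calling

A chimeric read is `barcode + miRNA + target` (miRfirst) or
`barcode + target + miRNA` (miRlast). Mature miRNAs are located inside
reads under the tolerance of a short-read aligner configured for
reverse-matching: at most one mismatch within the first 18 nt of the
(possibly truncated) mature sequence, at most two mismatches in total,
and an optional single-nucleotide truncation at either end. The scan is
implemented by pigeonhole seeding — the first 18 nt are split into two
halves, one of which must occur exactly — so the per-read cost is a
handful of dictionary lookups rather than a full alignment.

When two miRNAs match within 4 nt of each other only the first in
case-insensitive alphanumeric name order is kept, so each locus in a
read yields one event; matches more than 4 nt apart coexist (pre-miRNA
or miRNA–miRNA chimeras). Target segments shorter than 19 nt are
discarded. Segments map to the genome by exact substring search on both
strands, falling back to a 6-mer pigeonhole index for up to two
mismatches; only unique best hits are kept, multi-mappers are dropped
(the multi-mapper policy is this package's choice). PCR duplicates
collapse on (target coordinates, strand, miRNA, barcode) within each
replicate library — duplication is a within-library artifact, and
collapsing across biological replicates would corrupt the biological
complexity (BC) statistic. Targets mapping into annotated miRNA
precursor loci are removed. The operation is idempotent and invariant
to read order.

A note on boundary precision: when a sequencing error falls on the
terminal nucleotide of the miRNA insert, the matcher may prefer the
1-nt-truncated variant, shifting the inferred ligation point — and
hence the target interval — by one nucleotide. Recovery statistics
therefore match calls to planted events with a ±2 nt tolerance.

## Peaks

Peak calling is deliberately simple: deduplicated read starts are
extended by a fixed fragment length (53 nt, the mean AGO-CLIP fragment
size), peaks are maximal regions with coverage at or above a height
threshold, and summits closer than 75 nt merge. The default threshold
is max(2, the 0.1% upper tail of a Poisson at the library's mean
coverage). This is a height threshold, not an enrichment model;
normalized height is peak height per million uniquely mapped reads in
the library (the upstream normalization is not specified by the
protocols this emulates, so per-million scaling was chosen for
interpretability).

## Seed sites and duplex structures

Canonical site strings for a miRNA m (positions 1-based) are, written
5′→3′ on the target: 8mer = rc(m[2..8])+A, 7mer-m8 = rc(m[2..8]),
7mer-A1 = rc(m[2..7])+A, 6mer = rc(m[2..7]), 5mer = rc(m[2..6]); the A
opposite position 1 is target-encoded. Variants allow exactly one
substitution (mismatch; a G:U wobble is a mismatch, not canonical — the
canonical categories are defined by Watson–Crick identity) inside the
8/7/6mer span, or one inserted target nucleotide strictly inside the
8/7mer span (bulge). Priority is canonical > mismatch > bulge, longer
spans first, leftmost site on ties. A consequence worth knowing: for
seeds with self-similar runs (e.g. UUU), bulged sites often contain a
higher-priority mismatch or 5mer window and are classified as such;
the brute-force variant scanner in the test suite encodes the same
taxonomy independently and agrees exactly.

Duplex prediction is a maximum-score intermolecular co-fold: the miRNA
pairs antiparallel with the target, pairs may not cross, there is no
intramolecular structure, and consecutive pairs may be separated by at
most 15 unpaired nt per side (internal loop) or at most 5 nt on one
side (bulge); dangling ends are free. Pair scores are GC=3, AU=2,
GU=1. This replaces free-energy minimization because downstream
analyses consume only the binary pairing vector per miRNA position.
Perfect canonical sites force the matched seed positions to pair
(implemented as a large per-pair bonus; if the forced positions cannot
all pair under the caps the unconstrained optimum is returned,
flagged). Mismatch/bulge sites trigger two runs forcing miRNA positions
{3,4} and {5,6}; the run with more pairs in positions 2–8 wins (ties:
more total pairs, then the {3,4} run). Optima are tie-broken totally:
maximize (score, number of pairs), then take the lexicographically
smallest pair list in (miRNA index, reversed-target index) coordinates.
The DP is O(n·m·c²) with c = 16 via windowed suffix maxima; the test
suite verifies exact equality — scores and tie-broken structures —
against exhaustive enumeration on small instances.

Target windows for duplex prediction are fixed at 75 nt: cluster spans
≤75 nt extend symmetrically from the genome (extra nucleotide on the
right), spans of 76–100 nt trim symmetrically, spans >100 nt are
omitted as unreliable; windows clipped at chromosome ends are flagged.
Pairing-vector matrices are right-padded with zeros to the longest
miRNA and clustered with k-means (default k=8, 50 starts, seed 1234),
with a within-cluster sum-of-squares curve over k=3..12 for elbow
support. Per-miRNA enrichment in structure groups uses the two-sided
Fisher exact test of each miRNA's distribution against all
interactions.

## Motif discovery

For each miRNA with ≥50 chimeras in ≥40 clusters, foreground = its
75-nt target windows (one per chimera) and background = 5× as many
windows sampled without replacement from other miRNAs' chimeras,
excluding every miRNA with the same seed family (sampling with
replacement, flagged, when the pool is too small); backgrounds are
drawn in triplicate with seeds (seed, seed+1, seed+2). Every 7mer is
scored by the hypergeometric upper tail of its foreground
presence/absence count given the pooled presence count. Motifs enriched
at p ≤ 1e-3 are carried forward — mirroring a discovery tool that
reports only its top enriched motifs — and receive a match score s
(best gapless identity against the reverse complement of the mature
miRNA over all full-overlap offsets; the reported miRNA position is the
one aligned with the motif's 3′ end, ties toward the 5′ end), the
combined confidence c = (−log10(p) − 10)/10 + (s − 0.35)·6.7 (p = 0 is
clamped to the smallest positive double, flagged), and — when c is in
range — a PWM over all ≤1-mismatch occurrences in the foreground with
information content (1/7)·Σ(2 − H_j) bits against a uniform background.
Motifs pass at s ≥ 0.35, IC ≥ 1.75 bits/bp and c ≥ 1. The positional
heatmap reports, per miRNA position, the percentage of foreground
windows containing a passing motif mapped there, rows ordered by
average-linkage hierarchical clustering.

Note on the IC threshold: the ≤1-mismatch PWM is diluted by systematic
near-miss occurrences. In synthetic data where one miRNA's sites are a
mix of canonical and single-defect variants, the exact seed-complement
motif can fall marginally below 1.75 bits/bp; with canonical-only
planting it passes comfortably. The thresholds are kept exactly as
stated; heatmap validation plants canonical sites.

## Expression, ASC and cooperativity

CPM = count/library × 10⁶ and RPKM = CPM/(mature length in kb), both
averaged over replicate columns; genes with fewer than 100 summed tags
are flagged not expressed and excluded from regulation analyses. For
each miRNA family with ≥500 3′UTR-bound chimeras (the 3′UTR definition
includes the 10-kb downstream extension),

    ASC(r, f) = log2( (chimeras_f(r) / chimeras_f(total)) / RPKM(r) )

with a per-gene lower level of quantification evaluated at count 1.
Genes with zero family chimeras carry a non-targeted sentinel and never
enter family means; GO gene sets are the genes with ASC strictly above
the family mean.

Cooperativity: the gene × family ASC matrix (non-targeted cells imputed
to min − 1) is k-means-clustered in three iterations (default k = 45 at
full scale; desk-scale analyses use smaller k) with 1,000 restarts by
default (100,000 via `--full`). A cluster's signature is the set of
families whose within-cluster mean exceeds their global mean by ≥1.0
ASC units; clusters with fewer than 6 genes carry no signature, because
a handful of coincidentally co-extreme genes otherwise produces stable
pure-noise signatures (at the default margin, pure-noise matrices with
unit-SD columns yielded recurrent signatures in ~11% of runs without
the floor and ~4% with it, while a planted 12-gene co-targeted group is
always recovered with support 3/3; the floor is trivially permissive at
the ~100-genes-per-cluster scale of a full study). Signatures with ≥2
families recurring in ≥3 iterations (2 supported) populate the
symmetric cooperativity matrix.

ceRNA candidates are maximal per-strand genomic regions in which some
window of ≤3000 bp anchored at a qualifying cluster start contains ≥3
interaction clusters that each hold ≥5 unique chimeras; overlapping
qualifying windows merge.

## Regulation analyses

Per-gene log2 fold change is log2((CPM_t + 0.5)/(CPM_c + 0.5)) with
CPM averaged over replicates — an ordering-faithful statistic, not a
count-model fit. Plain CPM normalization carries a composition bias
when a large fraction of genes shift (treated library size inflates);
group contrasts (targeted-group median minus reference-group median)
cancel it, and the recovery analyses report that contrast. Grouped
comparisons use the asymptotic two-sided two-sample KS test against the
no-site/no-chimera reference; groups with n < 2 report an undefined p.
Targetome overlap between two datasets tests, per miRNA present in ≥1%
of chimeras in both, the upper hypergeometric tail of the shared-target
count in the universe of genes with ≥1 chimera in both. Chimera support
of peaks is binned by deciles of normalized height and fitted with the
3-parameter logistic y = A/(1 + exp(−(x − x0)/w)) by least squares
(bounds A ∈ [0,1]); A estimates the saturation ceiling and is reported
with a Wald 95% CI.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume:
two chromosomes with 50 genes (5′UTR 200 / CDS 600 / 3′UTR 1500 nt,
alternating strands, >10 kb intergenic spacing so the
downstream-extension rule is exercised), four miRNA hairpins with one
annotated and one unannotated arm, 20 mature miRNAs in 16 seed families
(so some families hold two members), and 60 planted interactions drawn
by a lognormal miRNA abundance profile. Sites follow a configurable
seed-type mix (default 35% 8mer, 25% 7mer, 15% 6mer, 10% mismatch, 5%
bulge, 10% noncanonical) written into 3′UTRs (10% into CDS) with guard
bases preventing accidental upgrades to higher categories. Libraries
default to 10⁵ reads per study — 2% chimeric (within the observed 0.5–5%
range for such experiments), 20% AGO-loaded small RNAs (including ~300
copies of each unannotated hairpin arm), the rest background fragments
concentrated at planted sites (peak structure) plus a uniform
transcript component — across three replicates, with a 5-nt degenerate
barcode, 5% miRNA mismatch and 5% truncation rates in chimeric inserts,
and PCR duplicates re-emitting existing reads at rate 0.3. Expression
tables are gamma-Poisson (dispersion 0.1, lognormal means) in two
conditions × three replicates, with targeted genes de-repressed by a
planted log2 shift of 0.11.

What passing tests show: the calling rules, statistics and recovery
behavior are correct under the generator's assumptions — exact
substring-level ligation structure, uniform random genome background,
error-free target fragments, independent gamma-Poisson counts. What
they do not show: robustness to real-data features the generator omits
— sequencing quality gradients, adapter artifacts, repeat-driven
multi-mapping at genome scale, transcript isoform ambiguity,
crosslinking-induced deletions, and library-specific biases. Genome-
scale alignment is delegated to external aligners via SAM ingest.

## Problem sizes

Default test and acceptance runs use the 10⁵-read study (≈130,000 reads
after duplication), 2,000 planted chimeric events, 10,000 random
miRNA–target pairs for the seed-classifier oracle, 150–250 small
instances for the duplex enumeration oracle, 100 simulated saturation
curves, 20 expression simulations of 1,000 genes, and 500–1,000 null KS
replicates. A full study plus all downstream stages completes in well
under five minutes on one CPU.
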