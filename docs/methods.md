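# Methods

This note documents the models, parameter choices and numerical decisions
behind tssmapper, and what the simulation-based tests do and do not
establish.

## Salience peak calling

The salience function convolves the per-position read signal f with an
asymmetric kernel: weight +1/m over the m+1 positions from j to m bp
downstream (transcription direction), −1/m over the m positions upstream.
The printed kernel is implemented literally, so the two windows have
different sizes and constant signal c leaves a residual c/m instead of 0;
an ideal step of height h attains its maximum h·(m+1)/m exactly at the
step. Both facts are asserted in the tests. The default m = 10 bp matches
the scale of a TSS jump against local noise; m = 30 reappears as two of the
classifier features, probing a broader scale.

**What f is.** Salience is computed on the per-nucleotide *coverage* track
(reads overlapping each position), not on read-start counts. The reason is
a degeneracy, not a preference: if every read 5' end maps to one base — the
canonical dRNA-seq TSS signal — the salience of the read-start track is
exactly constant over m+1 positions, so the location of the "local maximum"
is decided by background noise, and the 5 bp magnitude pruning can then
discard the true peak in favour of a one-read neighbour. A coverage step
has a unique salience maximum at the jump. Peak *heights* and the
height-derived features remain read-start counts, which is the quantity a
TSS's strength is read from. Tracks loaded without coverage fall back to
read starts.

**Plateaus and edges.** Exact salience plateaus are resolved to the
position with the largest read-start count (ties toward 5'): within an
equal-salience run, the jump is where the reads pile up. Runs touching the
array boundary are never maxima — a jump cannot be established without
signal on both sides — but positions within m of the boundary use truncated
windows and are flagged as edge peaks rather than dropped. Pruning is
greedy by descending salience magnitude with ties toward 5'; pairing of
(+) and (−) peaks (0–2 nt apart) is greedy nearest-first with distance ties
toward 3', and each (−) peak supports at most one candidate.

## Classification and merging

The ten features standardize to z-scores before an RBF-kernel SVM;
hyperparameters are chosen by stratified 5-fold cross-validated grid search
over C ∈ {0.1, 1, 10, 100} and γ ∈ {0.1, 1, 10}/n_features, seeded and
deterministic. The (+)/(−) ratio feature uses a pseudocount of 1 read in
numerator and denominator so an empty (−) library yields a finite, large
ratio. "30 bp interval" is the centred window [−15, +14] in transcription
direction; "4 bp radius" means 9 positions. The published score is the raw
SVM decision value; 0.4 is the high/low-confidence boundary, applied to
the best score across conditions.

Merging of Free and Nod candidates (< 3 bp apart) takes the rounded mean
coordinate; a half-integer mean is equally close to both inputs and the
3' one is chosen. Records are retained when at least one condition scores
positive; the score in an unobserved condition is NA (an empty TSV field,
an omitted GFF3 attribute), never a numeric sentinel.

The internal-TSS filter compares, per condition in which both are scored,
the iTSS's ratio against the maximum gTSS ratio of its gene, falling back
to the best available ratios when the two were scored in different
conditions. Only failing iTSS *assignments* are removed; a record is
dropped only when nothing else supports it, so a TSS that is also a gTSS,
antisense or orphan TSS is never lost to this filter. iTSSs in genes
without a mapped gTSS pass unchanged — there is nothing to compare against,
and such iTSSs are a real and common class.

## Categorization

Categories are pure interval tests (1-based, inclusive) against the
annotation: leader windows of utr5_max = 200 nt (riboswitch-preceded genes:
500 nt — regulatory leaders are known to exceed the ordinary cap, the exact
extension is configurable), gene bodies, and antisense windows using the
same 5' cap and utr3_max = 100 nt. Leaderless means the minimal gTSS
distance is ≤ 10 nt, distance 0 being a TSS on the first base of the start
codon. Overlapping windows produce multiple simultaneous assignments;
orphan (oTSS) appears only when nothing else applies. The implementation is
tested for exact agreement with an independent brute-force oracle over
randomized annotations, and for monotonicity (growing a UTR cap never
removes a gene-linked assignment). Operon propagation counts every member
downstream of a gTSS-bearing member and every member strictly downstream of
an iTSS-bearing one as expressed.

## Promoter discovery

Patterns are pairs of hexamers at fixed negative offsets within the 50 bp
upstream window (box starts ≥ −50, spacer 3–25 bp), matched with ≤ 1
mismatch per box and ± 1 bp shift. Exact occurrences seed the candidate
set — a pattern that never occurs exactly in ≥ max(3, 1% n) windows cannot
be meaningfully overrepresented, and seeding keeps enumeration linear —
then fuzzy counts are computed for every seed.

The null expectation of a pattern is n · q_up · q_down, where q is the
box's match probability within its shift band under the GC background
model (computed as the uniform-model probability times the GC/uniform
probability ratio, i.e. the factor that makes GC-rich hexamers in a
GC = 0.64 genome as unremarkable as they are). Scores are
log2((obs + 1)/(expected + 1)); retention requires score ≥ 3 (eight-fold
enrichment) *and* observed support in ≥ 5% of windows, so a tiny
expectation cannot promote a handful of chance co-occurrences. Both
thresholds were fixed by Monte-Carlo calibration on GC-background nulls
(per-pattern false discovery ≤ 1%); the test suite re-checks that nulls
yield zero retained patterns and zero motifs.

Retained patterns are embedded by painting their box letters one-hot into
a 4 × window frame at their absolute offsets: a one-mismatch neighbour or a
1 bp shifted variant of the same genomic motif differs in two cells
(distance √2), while sequence-disjoint families share no cells. PCA keeps
the components explaining ≥ 90% of variance and single-linkage clustering
cuts at distance 2.5, letting neighbour variants chain into one motif while
families stay apart. Per cluster, each window's best member-pattern match
contributes its actual (possibly mismatched) subsequences to the two PWMs
(pseudocount 0.5 per cell), and its matched offsets to the spacer and
location distributions.

Mapping scores each motif in each upstream window as the maximum over
observed locations (± 1 shift) of log-odds(up box) + log-odds(down box) +
log2(empirical spacer frequency), against the GC background; hits ≥ 8 bits
are reported, a threshold at which dinucleotide-shuffled windows score hits
at ≤ 1%. A TSS can receive hits from several motifs at once. These scores
are on a bits scale specific to this implementation; tests assert rank and
architecture properties, not any external absolute score. Labels are
assigned from consensus content and modal box locations: GG/GC boxes near
−24/−12 → RpoN-like; TGnTA in the downstream consensus → leaderless-like;
TTG…TA boxes near −35/−10 → RpoD-like; otherwise other.

## Proteogenomic database

Start codons are ATG/GTG/TTG (configurable), all rendered as initiator M
as proteomics N-termini are observed. Shorter variants require a
same-strand TSS 0–200 nt upstream of the internal start; longer variants
require an upstream in-frame start with no intervening stop, supported by
the alternate annotation or a TSS. iTSS translations start at every start
codon whose first base lies within 200 nt downstream of the internal TSS,
in any reading frame, and run to the next stop; translations shorter than
10 aa are suppressed as un-observable. Identical sequences are collapsed
with all provenances kept in the FASTA header. Every emitted entry
re-translates from its stated coordinates (checked against Biopython's
translator in the tests).

## The simulator

The simulator emulates the dRNA-seq measurement design, not transcription
biology: an i.i.d. GC = 0.64 genome into which clean ORFs (start codon,
stop-free body, terminal stop) are written with 250–450 bp intergenic gaps;
consecutive same-strand genes grouped into operons; 100 planted TSSs per
condition (40% gene TSSs 20–40 nt upstream of starts, 15% internal, the
rest orphan) in three expression tiers with mean (+)-library read-start
counts 200/50/8; TEX enrichment 5× (the (−) library draws Poisson(mean/5));
processed 5'-end sites inside genes with the inverted ratio; Poisson(0.02)
per-position background; and in-transcript 5'-end background (0.3/bp in
the (−) library, TEX-depleted in (+)) over 300 bp downstream of each TSS,
which is what places the TSS spike on a small step as in real libraries.
Coverage extends each read 100 bp downstream. The Nod condition reuses 30%
of the Free TSSs and adds Nod-specific TSSs carrying the planted RpoN-like
motif (GG/GC at −24/−12); Free TSSs carry the RpoD-like motif (−35/−10,
17 bp spacer) in 70% of cases, both written into the upstream sequence
with 10% per-base mutation. Planted internal and orphan TSSs are kept out
of every gene's leader window so planted categories coincide with inferred
ones. Everything derives from one seeded generator; identical seeds give
byte-identical outputs.

Training labels imitate the study's expert curation: candidates in the
first 30% of the genome are labeled by proximity (≤ 2 bp) to planted truth.

**What passing means.** The simulator plants single-base 5' ends with
Poisson noise and clean separations (≥ 60 bp between signals); real dRNA-seq
has ragged 5' ends, replicate structure, mapping artifacts and rRNA
carry-over that it does not model. Recovery of ≥ 90% of high-tier planted
TSSs at ≥ 90% precision therefore validates the machinery (peak calling,
features, classifier wiring, merging, filtering), not field performance on
any real library; likewise motif recovery shows the discovery chain is
correct, not that every real promoter family would be found.

## Problem sizes and runtime

Default scenario: 100 kb genome, 90 genes, 100 TSSs per condition, 20
processed sites — the catalogue-scale behaviour of the method at a size
where the full pipeline, the 1000-track salience oracle comparison and the
1000-annotation categorizer oracle all run in well under a minute each.
Promoter scenarios use 500 windows of 50 bp, the scale at which a motif in
30% of windows is unambiguous against the calibrated null. The acceptance
script derives every random stream from its `--seed` argument.

## Known limitations

- Replicates are not modeled (libraries are treated as pooled); there is no
  multi-replicon joint normalization.
- Circular replicons are supported in categorization via modular wrapping
  only if enabled; the simulator emits linear replicons.
- The promoter score scale is implementation-specific; absolute scores are
  not comparable across tools.
- GenBank export is not implemented (GFF3 only).
- The heuristic nominator for expert labeling (ratio ≥ 2, height ≥ 5) is a
  convenience for building label lists, not part of the classifier.
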