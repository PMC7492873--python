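# Methods

This note documents the models and procedures behind `plastcomp`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical corner cases.

## Coordinate and sequence model

All coordinates are 1-based inclusive, both genomic and alignment columns.
Plastomes are treated as circular but stored linearised exactly as read; no
rotation to a canonical start is applied, since deposited plastome records
conventionally begin at the LSC origin. An interval whose end precedes its
start wraps across the origin. `N` is a legal base; every statistic defines
its own N handling (GC excludes N from the denominator; variant calling skips
and tallies N columns; diversity excludes them per pair).

## Quadripartite structure

The inverted repeat is defined as the longest pair of disjoint intervals on
the circle such that one is the reverse complement of the other, found by
seed-and-extend over the doubled sequence (12-mer seeds by default). Defaults
are `min_len = 1000` and `max_mismatch = 0`: plastome IRs are tens of
kilobases and near-identical, so exact matching is both adequate and easy to
verify; both knobs are configurable for degenerate genomes. A small mismatch
budget, when given, is spent greedily during extension (no optimal mismatch
placement is attempted). When a maximal match's two intervals overlap on the
circle (palindrome-like configurations), the largest disjoint sub-match is
recovered by trimming from either end. Absence of an IR at `min_len` is a
structured result (a single-copy genome), not an error.

The two single-copy gaps between the IR copies are labelled LSC (longer) and
SSC (shorter); on a tie the segment earlier in linear order becomes the LSC
and the structure is flagged. IRb is the copy immediately following the LSC
in circular order. Region lengths always sum exactly to the genome length —
this is asserted, not assumed. (Published plastome reports occasionally carry
inconsistent region arithmetic — *A. thaliana* region tables, for example,
have given both 85,164 and 84,170 bp for the same accession's LSC, and
per-region lengths summing to one less than the stated genome length; this
package enforces exact summation rather than emulating any such
inconsistency.)

A junction's coordinate is the last base of its upstream region (so LSC/IRb
is the LSC end). The junction report lists genes spanning each junction
(gene span contains the junction base and the next) and the nearest gene on
each side with a non-negative distance; two genomes are "junction-identical"
when the same genes span/flank all four junctions.

## SSR detection and classification

A locus is a maximal tandem run of ≥ 2 complete copies of a primitive unit
of 1–10 bp. Runs are found per unit length from the sequence's
self-comparison at lag k (`s[i] == s[i+k]`): a maximal periodic stretch of
total length T yields `copies = T // k`, so partial trailing units never
count. The unit is reported in the phase of the leftmost start, and
non-primitive units (themselves repeats of a shorter unit) are discarded —
standard repeat-finder practice that prevents AT×6 also being reported as
ATAT×3. When two accepted loci cover the identical interval, the shorter
unit wins.

Classification thresholds: normal SSRs are units of 1–6 bp with total span
≥ 10 bp inclusive, i.e. minimum copies mono 10, di 5, tri 4, tetra 3,
penta 3, hexa 3; penta/hexa runs of exactly 2 copies are "potential" SSRs;
units of 7–10 bp with ≥ 2 copies are "extended" SSRs. Span 10 is accepted
(not strictly exceeded): the convention's own worked example — a TA×5 locus
of exactly 10 bp grouped across genomes — forces the inclusive reading.

Region is assigned by locus midpoint (a locus straddling a region boundary
is flagged); genic context is exon if the midpoint falls in an exon interval,
intron if inside a gene span otherwise, else intergenic. Loci inside the IR
are genuine tandem repeats in both copies and are reported twice, matching
the convention of listing IR-duplicated variants at both coordinates.

Runs are detected on the linearised sequence; a run straddling the origin of
the circle would be truncated. Deposited plastomes start inside the LSC, so
this does not arise in practice, and the generator never plants loci there.

## Cross-genome SSR grouping

Orthologous SSRs sit in homologous neighbourhoods, so loci are linked by
flank similarity: up to 60 bp upstream and downstream (excluding the repeat
itself; wrapping on circles, truncating on linear sequences, and capped so a
flank never wraps into its own repeat). Left and right flanks are
concatenated and compared by the best gapless local alignment score with
match +1 / mismatch −2 — the simplest scheme consistent with comparing
flanking sequences; per-side scoring would only differ for rearranged flanks,
which are outside this package's scope. Significance uses the Karlin–Altschul
ungapped statistic E = K·m·n·e^(−λS): λ solves
¼·e^λ + ¾·e^(−2λ) = 1 under uniform base composition (λ ≈ 1.33), and
K = 0.621, the published parameter for this nucleotide scheme; both the
scores and K are configurable. The default cutoff is E ≤ 1e−10. The null
behaviour is calibrated by Monte Carlo in the test suite: over 10⁴
independent random 120 bp flank pairs, the observed rate of E ≤ 1e−10 is
below 10⁻³.

Groups are single-linkage connected components of the similarity graph with
edges only between loci of *different* genomes, so the two IR copies of one
locus in one genome cannot merge otherwise unrelated groups (both copies can
still join the same group through cross-genome edges). A group's type is the
number of genomes represented; the spectrum (groups and member loci per
type) conserves the total input locus count, which is asserted on every run.

## Variant extraction and coding effects

From a two-row alignment, each column yields at most one record: a SNP when
both bases are unambiguous and differ; an INDEL when exactly one row has a
gap. INDELs are counted per gap column, not per contiguous event — a 6 bp
deletion is six records — which makes the INDEL count equal the ungapped
length difference when all indels lie on one side; a merged per-event view
is also available for human reading. Columns with N on either row are
skipped and tallied; both-gap columns (projection artifacts of a multiple
alignment) are skipped silently.

Effects are computed per affected codon under the bacterial/plastid genetic
code (translation table 11), strand-aware and honouring `codon_start` phase
for joined CDS features. A coding SNP is synonymous iff the amino acid is
unchanged. A contiguous run of gap columns inside a CDS is an in-frame indel
when its length is divisible by 3, else a frameshift; the removed residues
are rendered (e.g. "DN to -") when the deletion is codon-aligned, otherwise
the amino-acid rendering is left empty because it is ambiguous. Insertions
relative to the annotated genome are anchored at the last preceding
reference coordinate for context lookup; their inserted residues are not
rendered, since the annotation lives on the reference.

Variation levels bin a genome pair by its counts: low (SNPs < 80 and
INDELs < 100), medium (SNPs < 80, 100 ≤ INDELs ≤ 200), high (SNPs ≥ 80 or
INDELs > 200) — thresholds observed to separate intraspecific plastome
comparisons into three clusters.

## Nucleotide diversity

Per window, π is the mean over all C(n,2) row pairs of the difference
proportion over columns where both bases are unambiguous (pairwise deletion);
pairs with no comparable column are excluded from the mean. Pairwise rather
than complete deletion is deliberate: one isolate carrying a large insertion
would otherwise erase those columns for every pair and suppress exactly the
peaks of interest. No n/(n−1) sample-size correction is applied — π is the
plain mean of pairwise proportions. Note one consequence: duplicating every
row does *not* leave the pair-mean unchanged (the duplicate pairs contribute
zeros); what is invariant is every cross-copy pairwise proportion, and that
is what the tests assert.

Windows are laid out on alignment coordinates (default 500 columns, step
200); a trailing partial window is kept only if it covers at least half the
window length, and an alignment shorter than one window becomes a single
flagged window. The headline average is the unweighted mean of window π
values; a per-site weighted mean (total differences over total comparable
sites) is emitted alongside, since the two differ whenever coverage varies.
Peaks are maximal runs of consecutive windows with π at or above
mean + 5·sd (configurable), each reported at its maximum window; the
default only behaves sensibly when windows number in the hundreds, as on
full-length plastome alignments.

## Synthetic data

The generator builds LSC + IRb + SSC + IRa with IRa the exact reverse
complement of IRb. Defaults (6 kb LSC, 2 kb IR, 1.2 kb SSC — a 1:14 scale
model of a real plastome; one SSR of every class across the three regions;
~8 CDS features including a two-exon gene, an IR-duplicated gene and a
minus-strand gene) keep the whole suite fast while exercising every code
path. Background sequence is kept repeat-free by rejection against the SSR
classifier itself, so "no false positives on background" is a meaningful
assertion rather than luck; planted runs get guard bases so they are exactly
maximal, and the bases flanking each IR copy are guarded so the planted IR
is exactly the longest inverted repeat. All randomness flows from an
explicit integer seed and outputs are deterministic given it.

Derived genomes carry chosen numbers of substitutions and deletions. Sites
are drawn from the single-copy regions (keeping the derived IR copies
identical), avoid planted SSR spans with a 12 bp buffer, and the whole
placement is redrawn if any mutation creates or destroys a classified SSR.
In-CDS deletions are placed codon-aligned near the middle of a plus-strand
CDS. The true alignment is ancestor vs derived with deleted bases as gap
columns — deletions only, so alignment columns equal ancestor coordinates.

The MSA generator starts from one random row copied n times and plants
single-column substitutions to hit per-window π targets (each planted column
changes one row, contributing 2/(n·w) to that window's π); the realised π is
recomputed directly and returned as truth. Acceptance runs use a 150 kb
six-row alignment with a sparse background difference density and two
planted hotspots of π 0.0147 and 0.00441 — the shape of an intraspecific
plastome comparison in which one isolate carries a large insertion and a
second region clusters substitutions.

What the generator does **not** emulate: realistic substitution models
(HKY/GTR), indel length distributions fit to data, recombination,
rearrangements, imperfect or compound microsatellites, sequencing error, or
annotation error. Passing tests therefore demonstrate correctness of the
algorithms on clean inputs with known truth, not robustness to assembly or
alignment artifacts in real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run on an 11.2 kb synthetic
plastome (scaled-down regions in real proportion), six derived isolates, and
a 150 kb × 6 alignment — sizes chosen so the full suite completes in seconds
while every algorithm sees the same structure it would on full-size data
(all algorithms are linear or near-linear in genome length except the
brute-force test oracles, which are quadratic and run on ≤ 2 kb inputs).
Window π values match an exhaustive all-pairs oracle to 1e−12 (they are
ratios of small integer counts). Oracle comparisons for IR detection use
exact equality of lengths and intervals, with ties broken identically
(smaller first-interval start) on both paths.
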