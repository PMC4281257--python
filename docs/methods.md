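# Methods

This note documents the models, conventions and numerical choices behind
`methclone`, and what the synthetic test bed does and does not show about
real data.

## Read placement model

Reads are matched under a substitution-only (Hamming) model: a read of
length L is reported at every genomic window, on either strand, whose
distance is at most `⌊mismatch_fraction · L⌋` (default fraction 0.04,
accepted range [0, 0.1]). There is no best-hit selection, no mapping
quality, and no indel handling: enrichment-based methylome quantification
counts *where fragments can come from*, and repeat-derived multi-mapping
reads are themselves informative (the multiplicity spectrum), so all hits
are kept everywhere downstream.

The implementation is a seed-and-verify index: the genome's 12-mers are
kept in a sorted table; a query allowed k mismatches is split into k+1
disjoint segments, and by pigeonhole at least one segment of any true hit
matches exactly, so looking up each segment's leading 12-mer and verifying
every candidate diagonal is *exhaustive*, not heuristic. Queries too short
to carry k+1 seeds of 12 bases fall back to a full sliding scan. N bases
never match anything; reads with more than 10% N are skipped with a
warning. Coordinates are 0-based half-open internally; GFF3's 1-based
inclusive convention exists only at file boundaries.

Two read-level statistics deliberately use different weights: distinct
sequence statistics (multiplicity spectrum, occurrence classes) count each
distinct read sequence once, whereas per-scaffold and per-region "hits"
weight every placement by the read's pyrosequencing copy count.
Occurrence classes at threshold t use `count ≥ t` by default; the strict
reading `count > t` is available because "represented more than t times"
is genuinely ambiguous in this field's usage.

## Region stratification

Eight interval classes are built from the gene models and transposon
annotations: gene body, exon, intron (gene span minus exons), promoter
windows 0–2 kb and 2–3 kb upstream of the transcription start
(strand-aware), transposon body, its 1 kb borders, and a distal 49–51 kb
upstream window that serves as background control. Transposons in BED
rarely carry a strand, so the distal window defaults to the left of the
leftmost coordinate. All windows are clipped at scaffold edges.

A placement increments a class once per owning feature it overlaps by at
least 1 bp, and classes are independent — a read straddling an
exon/intron junction counts in exon, intron and gene body. Class totals
are defined as the sum of the per-feature breakdown, so overlapping
features of the same class (e.g. adjacent genes' promoters) can both
count one placement. Counts are not CpG-density normalized by default
(the quantity of interest is captured-fragment enrichment);
`cpg_normalized_hits` provides hits-per-CpG for sensitivity analysis.

Per-gene methylation change uses a boundary-inclusive two-fold rule:
green ≥ fold × orange is `up2x_green`, the mirror `down2x_green`,
`insufficient` when neither variant reaches `min_hits` (default 5). A
zero denominator takes the direction of the non-zero side when it reaches
`min_hits` — mirroring the transcriptome convention of "≥ t reads in one
sample and none in the other".

Scaffolds are ranked by methylation density: the arithmetic mean of the
two variants' hit totals divided by scaffold length, descending, ties
broken by scaffold id.

## SSH calibration and expression classes

SSH contigs are assigned to genes by gapless full-length placement of the
contig (both orientations) under the same Hamming machinery; the score is
the number of matching bases of the best locus, and the default
`min_score = 50` plays the role of a stringent e-value cutoff (a 100 bp
exact match passes comfortably; a 60%-identity stretch cannot, since at
4% mismatches it is never reported at all). A contig whose equal-best
loci resolve to more than one gene is left unassigned — unambiguous
assignment is a requirement, not a preference. When a locus overlaps both
a gene body and another gene's promoter, the body wins; ties among bodies
(or among promoters) are ambiguous.

Internal-control pairs are reciprocal best matches between the two
libraries by a gapless shared-k-mer diagonal aligner, requiring
similarity ≥ 0.9 and both read counts ≤ `max_count` (default 15), one
pair per contig. Score ties prefer the smaller length difference, which
resolves contigs cut from overlapping regions of the same transcript.
The library scale factor is the ratio of summed orange to summed green
control counts (a ratio estimator, robust to zero-inflated small counts;
a median per-pair estimator is available via `method="median_ratio"`).
Green counts are multiplied by the factor; calibrated counts stay
real-valued until reporting. Zero recovered pairs is an error instructing
the caller to supply a factor — calibration is never silently skipped.

Gene-level counts are the sum over assigned contigs. Classes, evaluated
on calibrated counts: *strong* = ≥ 20 in one variant and exactly 0 in the
other; *slight* = ≥ 5 vs 0 (not strong); *moderate* = both non-zero,
ratio ≥ 2, larger count ≥ 5 (the slight threshold doubles as the moderate
minimum, an assumption worth revisiting on real data); otherwise
unchanged. Requiring both counts non-zero keeps moderate disjoint from
the vs-zero classes.

## GO enrichment

Annotations are closed under is_a ancestry (true-path rule) before
counting; other relationship types are ignored with a warning. For a list
of n genes from an N-gene background (genes with ≥1 annotation after
propagation — unannotated genes are excluded and logged), a term carried
by m background and k list genes gets the one-sided upper tail
`p = P(X ≥ k)` with `X ~ Hypergeom(N, m, n)`, computed through scipy's
log-space survival function (stable to N ~ 10⁶). Terms with k = 0 are
untestable for enrichment and not reported. Raw p < α (default 0.05) is
the primary flag, matching how such screens are conventionally reported;
Benjamini–Hochberg q-values are computed alongside and never silently
substituted. Because the statistic is discrete, the attainable rejection
level of any single term lies below the nominal α and depends on m — the
type-I simulation in the acceptance suite therefore measures a term whose
attainable level is analytically closest to the nominal 0.05.

The cross-list family is {up, down expression} × {no methylation filter,
methylation up, methylation down} × {gene body, promoter} at a chosen
expression stringency; stringency is cumulative (slight includes strong,
moderate includes both), since "at least t vs none" screens nest.

## Integration

Per scaffold, the methylation direction is the variant with more hits and
the expression direction is the sign of Σ(calibrated green − orange) over
genes located on the scaffold — one of several defensible definitions of
scaffold-level expression direction, chosen for its simplicity and
documented as an interpretation. A scaffold is concordant when the two
directions are inverse. Concordance over the top-k methylation-ranked
scaffolds excludes expression-silent scaffolds from the denominator by
default and reports them separately (`include_silent=True` gives the
other convention). Exported tracks (BED per variant with copy-count
scores, expression GFF3, summary TSV) are written in fixed (scaffold,
start, id) order so reruns are byte-identical and diffs meaningful.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study *design*, not the organism: AT-rich
random scaffolds (GC 0.30) whose lengths vary uniformly around the
configured mean (±60%), with non-overlapping gene models (≥2 exons,
random strand) and transposon intervals at densities scaled to scaffold
length; repeat units overwritten at exact planted copy numbers (verified
against the finished sequence, and placed outside genes so contig
assignment stays unambiguous); MseI fragments as the exact T^TAA cut
intervals, fragments <30 bp dropped (pyrosequencing read-length realism);
capture modelled as one multinomial draw with weight 1 per fragment,
multiplied by `fragment_capture_bias` (default 10) when the fragment
overlaps a hot spot of that variant.

Hot spots come in a shared component (identical coordinates in both
variants; default 70% of spots) and per-variant specific components drawn
with independent Poisson counts and fresh positions. Each scaffold
carries a latent methylation direction; `hotspot_direction_bias` is the
probability a specific hot spot sides with it (default 1.0; 0.5 makes
the variants' specific methylation fully independent, which is how the
correlation null is constructed). Hot-spot lengths vary ±50% around
`hotspot_length` so coverage imbalances are rarely exact ties.

SSH libraries contain identical-sequence control pairs from non-DE genes
with low, nearly equal counts (a shared base count with ±1 jitter), a
global green library-size multiplier (default 1.2, the kind of modest
imbalance real library pairs show), and one high-count contig per
planted DE gene in exactly one library. Planted strong genes start at
1.25× the strong threshold: planting exactly at a decision boundary
makes the truth ill-posed under calibration rounding. Similarly, a gene
enters the planted methylation-shift truth only when its hot-spot
coverage implies an expected fold ≥ 3 (a 1.5× margin over the two-fold
call threshold). The default DE fraction (0.2 of genes) is a power
choice: with ~4 DE genes per scaffold the planted coupling of 0.9 is
measurable on 50 scaffolds; sparser planting leaves the concordance
estimator noise-bound. Enriched GO terms are planted by annotating 80%
of one DE direction's genes (vs 5% background) with a leaf term.

Not modelled: sequencing errors and quality scores, adapter/barcode
artifacts, assembly (contigs are cut directly from gene sequence), CpG
landscape structure, fragment-size selection, and biological replication.
Passing tests therefore demonstrate the *analysis* recovers what the
design plants — they say nothing about wet-lab biases such as incomplete
MBD capture or SSH subtraction chemistry.

## Problem sizes and numerical choices

The default synthetic study is 50 scaffolds × ~100 kb with 2×10⁵ reads
per variant — small enough for the full pipeline to run in well under a
minute on one core while leaving every recovery statistic comfortably
powered. The correlation behavior checks use 1,000 equal-length 5 kb
scaffolds (equal lengths isolate the hot-spot-driven component). The
top-level seed feeds deterministic per-stage child generators, so
identical (config, seed) reproduces byte-identical bundles and reports.

Known limitations: the gapless aligner will not assign contigs spanning
real indels or splice junctions relative to the assembly (real SSH
contigs cross introns; synthetic ones are genomic substrings by
construction); integer library counts quantize the calibration at
sub-unity multipliers (recovered factors at a planted 0.5 multiplier are
biased high by several percent); the moderate-class minimum count and
the raw-p default are conventions, not fitted values; and depletion
(under-representation) testing is out of scope.
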