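# Methods

## Coordinates and orientation

All coordinates are 0-based half-open; GFF3 input (1-based closed) is
converted on read. On the '−' strand, the 5′ end of a half-open interval
is its `end` coordinate and the 3′ end its `start`; this convention is
defined once in `annotation_io` and used everywhere. A gene model is an
ORF plus 5′/3′ UTR extensions; UTR lengths default to 100 bp per side
when no measured estimate exists, and the UTR-extended transcript span
is clipped silently at chromosome bounds (published UTR estimates can
overrun contig ends). Overlapping genes are permitted; UTRs are not
clipped against neighboring genes.

## Segmentation

A fragment contributes a single count at the center of its outer span
(lower median for even lengths — deterministic and documented rather
than randomized). Signal positions have center count ≥ `min_cov`
(default 2: "coverage greater than 1" read literally, exposed as a
parameter), and units are maximal signal runs whose internal non-signal
gaps are each ≤ `max_gap` (default 20 nt). Gaps count non-signal
positions strictly between two signal positions. Unit boundaries are
defined by signal positions only — no extension by fragment length — so
a called unit under-reaches the true transcript by about half a
fragment length per end; downstream tolerances account for this. A
dense position-scan reference implementation
(`call_units_reference`) is kept in the package purely as a test
oracle for the sparse implementation.

## Antisense catalog

Overlap fractions are computed with exact integer arithmetic
(`fractions.Fraction` over bp counts) before any float conversion, so
the closed tier bounds ("75% or more") are exact: frac_ORF = 0 →
`UTR_ONLY`, = 1 → `FULL`, ≥ 3/4 → `GE75`, ≥ 1/2 → `GE50`, else `GE25`.
The antisense-call threshold (≥ 25%) applies to the UTR-extended
transcript span while tiers follow the bare ORF, because the two
criteria serve different questions (is this locus antisense-transcribed
at all vs how much of the coding unit it shadows). A unit antisense to
several genes yields one call per gene; no uniqueness is forced.

Curation replaces by-eye merging of over-segmented antisense units with
a deterministic rule: same-strand units opposite the same gene are
chained while consecutive gaps are ≤ 200 bp (an order of magnitude
above the segmentation gap, well below typical yeast gene length), and
fractions are recomputed on the merged span. Members must overlap the
gene's opposite strand by ≥ 30 bp: isolated strand-flip noise produces
1–2 bp signal blips (and, through max_gap-chaining, spurious units up
to ~21 bp wide) densely enough in deep libraries that the literal rule
would chain them into curated spans; 30 bp is the smallest floor
strictly above that chaining scale. Chains whose merged span still
covers < 25% of the transcript are dropped.

Expressed-gene detection measures same-strand unit coverage against the
UTR-extended transcript span (≥ 80% by default); a `use_orf` flag
measures against the ORF instead, since "length of each gene" is
ambiguous. Catalog comparison normalizes the overlap by *our* unit's
length, picks the external unit maximizing it (ties: longer external
unit, then smaller id), and reports matched (≥ 50%) and covered80
(≥ 80%) states.

The strand-specificity QC statistic counts fragments whose center lies
inside exactly one gene's transcript span (centers in regions annotated
on both strands are ambiguous and excluded) and reports the fraction
antisense to that gene. On a library without genuine antisense
transcription this estimates the strand-flip leak of the protocol; with
antisense present it reports total antisense signal.

## Origin classification

Classification walks a strict precedence ladder (3′-UTR extension,
5′-UTR extension, divergent promoter, adjacent-3′-NFR, unexplained) —
the order of successive exclusion — with a 400 bp margin on
boundary-to-boundary distances. For the same-strand rules an
overlapping gene counts as distance 0. The divergent rule requires the
neighbor to read away from the unit (5′-to-5′); head-on proximity never
qualifies, and no overlap shortcut applies. The NFR rule accepts either
strand of the adjacent gene and uses pure boundary distance: every
antisense unit overlaps its sense gene's transcript, so an overlap
shortcut here would make the NFR class absorb all units and leave the
unexplained class unreachable. Margins anchor on the unit's 5′ end (the
presumed initiation side). The runthrough flag fires when the unit's 3′
end is < 200 bp from a convergent gene's transcript 3′ end.

The Wilcoxon rank-sum test uses midranks for ties, exact enumeration of
all C(n, n_a) assignments up to combined n = 12, and above that a
normal approximation with tie correction and 0.5 continuity correction;
two-sided p doubles the smaller tail (capped at 1). The exact/approx
switch and continuity correction keep small flagged-gene sets
reproducible while matching standard large-sample behavior; the default
is two-sided with a one-sided flag available.

## Expression statistics

qPCR log2 ratios are computed per (primer set, replicate) stratum after
division by the control gene (PDA1 by default) measured in the same
stratum, then summarized as mean ± sample sd across strata — pooling
primer and replicate variation rather than decomposing it. Conversion
from raw Cq values is out of scope; inputs are relative quantities.

nCounter-style normalization is two-step against a reference sample
(the first by default): every probe is scaled so positive-spike sums
match the reference, then mRNA probes (targets and controls, not the
spikes, which carry no mRNA content) are scaled so the control-gene
geometric mean matches the reference. The geometric mean is robust to a
single dominant control; spike *sums* are used (sum vs mean are
proportional and give identical results). The operation is idempotent
and leaves the reference sample unchanged.

Regulation calls default to |log2 ratio| ≥ 1 (2-fold); the threshold is
configurable and recorded in output metadata since published
heat-map colorings rarely print their cut-off. Discordance counting
reports sense-induced/antisense-repressed (and mirror) counts per
condition plus union ("either") and intersection ("both") across
conditions. Correlations are Pearson on log2 ratios by default with a
Spearman option.

## Conservation

Unit endpoints become fractional offsets along the sense ORF from its
5′ end (values outside [0, 1] encode UTR overhangs) and are laid out
along the ortholog ORF from its 5′ end; the projected strand is the
opposite of the ortholog's. Fractional endpoints round to the nearest
base with ties toward the unit interior, preserving start < end. UTR
overhangs project linearly beyond the ortholog ORF by default; a
`restrict_to_orf` flag clamps them. Projection round-trips to within
1 bp per endpoint when ortholog and source ORF lengths are within about
±33% of each other — the realistic regime for orthologous coding
genes; more extreme length ratios amplify the 0.5 bp rounding error of
the forward map. Synteny verification is out of scope; `synteny_ok` is
consumed as input truth.

## Synthetic data

The generator is a pure function of (config, seed); random streams are
partitioned per purpose (placement, fragment lengths, strand flips,
expression noise) so changing one parameter does not perturb unrelated
draws.

**Annotation.** Target loci are built in a '+'-strand frame and
mirrored at random, so planted units occur on both strands. Regular
genes draw ORF lengths ~N(1100, 250) clipped to [600, 2000] bp and UTRs
~N(100, 20); antisense-target ORFs are 1200–1600 bp so tier geometry
has ≥ 100 bp slack from every tier threshold. Inter-locus gaps of
1200–1800 bp keep unrelated gene boundaries > 1150 bp from any planted
unit end, so origin labels are decided solely by the planted
neighbor (placed 50–350 bp inside the 400 bp margin, with ≥ 50 bp
slack) or by engineered clearance (> 450 bp) for unexplained units.
Origin-defining neighbors may overlap the target gene on the opposite
strand — as real divergent/embedded yeast genes do — and are placed
> 200 bp (the curation gap) plus half a fragment length away from the
planted unit's footprint so curation cannot chain them.

**Planted spans are center footprints.** A planted unit's span is the
expected fragment-center footprint; the simulated antisense transcript
extends half a fragment length beyond it per side. This mirrors the
segmentation's known half-fragment shrinkage, so recovered boundaries
estimate the planted span directly.

**Fragments.** `depth` is the mean fragment-center coverage per
transcribed base: each transcript receives exactly
`round(depth × length)` fragments (deterministic, not Poisson), with
lengths ~N(250, 30) truncated at [100, transcript length] — echoing a
180–480 bp size-selected library — placed uniformly, and strands
flipped independently with probability `leak_rate` (default 0.0062).
Planted antisense transcripts are sampled at 10% of the sense depth,
matching the low antisense coverage of real libraries.

**Expression.** Per-pair sense/antisense log2 fold changes are drawn
bivariate-normal with sd 2.0 (strong stress-response regulation) and
correlation −0.8 across 67 pairs. Counts are baseline × 2^fc × a
per-sample processing scale (seen by all probes) × an mRNA-content
scale (not seen by spikes) × multiplicative log-normal noise (sd 0.3 in
log2). Counts are kept continuous — no integer rounding or Poisson
sampling — so the zero-noise limit recovers planted fold changes
exactly. qPCR quantities add per-primer offsets and per-reaction scales
shared with the PDA1 control of the same stratum, which the
control-normalized ratio cancels.

**What the generator does not emulate.** No sequence content, mapping
error, duplicate fragments, GC or position bias, expression-level
heterogeneity between genes' fragment depth, overlapping same-strand
transcription, or condition-dependent antisense unit presence. Passing
tests therefore demonstrate correctness of the interval arithmetic,
segmentation, classification and normalization logic under realistic
geometry and noise — not robustness to mapping artifacts or biological
heterogeneity.

## Problem sizes

The validation suite uses 200 genes with 50 planted antisense units on
a 1-Mbp chromosome at 20× center coverage (~6M fragments) for recovery,
a ~500k-fragment sense-only library for the leak estimate, 100 planted
origin geometries, 1000-case oracle sweeps for segmentation and overlap
arithmetic, and 100-seed replication for the anticorrelation estimate —
sizes chosen so the full suite completes in a few minutes on one core
while keeping every estimate's sampling error far below its tolerance.
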