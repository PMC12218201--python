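# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Coordinates and formats

All in-memory coordinates are 0-based, half-open. Conversions happen only
at file boundaries: samtools-depth positions (1-based) and GFF3 records
(1-based, inclusive) are shifted on read and shifted back on write;
BedGraph and BED are passed through. Positions absent from a samtools-depth
file are depth 0, matching that tool's default of omitting zero rows.
Megabase values in reports are rounded half-up to 2 decimals; the
underlying tables always carry full-precision base pairs, because a span
printed as 29.71 Mb can legitimately disagree with the difference of its
printed endpoints by one rounding unit.

## Depth model and SLR calling

The signal is copy number. With a pooled per-base sequencing depth λ on
diploid sequence, a hemizygous (Y-specific) segment yields λ/2 in the male
pool and ≈ 0 in the female pool; an X-linked segment yields λ/2 in males
and λ in females; PARs yield λ in both.

Windows of `window` bp (default 50,000) advance by `step` bp (default
5,000); the trailing partial window is dropped, so a chromosome of length
L ≥ window yields ⌊(L − window)/step⌋ + 1 windows. Window means are
computed exactly from the run-length-encoded track via prefix sums.

**Normalization.** Each pool's window depths are divided by that pool's
genome-wide normalizer. The default is the median over windows outside any
excluded interval, applied in two passes: a provisional call with the
all-window median, then a recall with the normalizer recomputed excluding
provisional SLR windows. The median is robust to the SLR itself (which
depresses a mean normalizer when the region is a large chromosome
fraction); the two-pass scheme removes the residual bias.

**Classification bands.** Defaults: half-coverage band [0.3, 0.7],
balanced band [0.75, 1.25], "negligible" ceiling 0.10. The study design
states only "approximately 50 %" and "negligible", so the bands are wide,
configurable, and recorded in the output metadata. Every window gets
exactly one class; the four-way rule is evaluated in the order Y-linked,
X-linked, balanced, ambiguous.

**Region merging.** Maximal same-class runs are merged, bridging interior
gaps (ambiguous or opposite windows) up to `max_gap` (default 50 kb = 10
steps); merged regions shorter than `min_region` (default 500 kb) are
dropped. These two defaults suppress isolated misclassified windows
without hiding Mb-scale regions. A region's interval is the union of its
member windows — outermost edges, not centers — so reported base-pair
statistics never double-count overlapping windows. The chromosome
complement of all calls is reported as PARs.

**Attainable boundary precision.** For a Y region the binding constraint
is female absence: a boundary window with more than ~8–10 % of its length
outside the region picks up enough female coverage to fail the negligible
ceiling, so called edges land within about one step (5 kb) of truth. An
X region has no such sharp constraint — an edge window ≥ 60 % inside
still reads male_rel ≤ 0.7 — so X boundaries are only good to roughly
0.4 × window (20 kb) with the default bands. Tests assert the two
precisions separately.

**Repeat content** of a called interval is |union(repeats) ∩ interval| /
|interval|, with overlapping repeat records unioned first.

## Gene-origin classification

Precedence per SLR gene: (1) a synteny hit to a putative ancestral
chromosome → *ancestral*; a BLAST hit to an ancestral chromosome is
accepted as ancestral evidence too, ranked after collinearity (collinearity
is assessed first; BLAST only mops up the remainder); (2) otherwise any
hit to a non-ancestral chromosome → *acquired*; (3) no hit anywhere →
*specific*; (4) last, within each connected component of within-SLR
paralog pairs, the member with the smallest start coordinate keeps its
step-1–3 category and every other member becomes *duplicated*, whatever
its prior label. The positional rule makes the one-of-each-pair
re-labelling deterministic and order-invariant; chains (a↔b, b↔c) collapse
to a single keeper. BLAST hits below 70 % identity are ignored by default
(configurable). The caller supplies the ancestral chromosome set;
"autosome" is simply its complement.

## NG86 Ks/Ka

Implemented in full rather than delegated, so the estimator is
self-contained and testable at the codon level:

* per-codon synonymous site count = Σ over positions of (synonymous
  single-base changes)/3, with changes to stop codons counted as
  nonsynonymous; site totals are averaged between the two sequences;
* codons differing at k positions are resolved over all k! orderings of
  the single-base steps with equal weight; orderings passing through a
  stop codon are excluded (if every ordering is blocked, all are used);
* distances are Jukes–Cantor corrected, d = −¾ ln(1 − 4p/3), flagged
  undefined when the log argument is ≤ 0 (p ≥ 3/4) instead of crashing;
* codons containing ambiguity codes are skipped and counted; internal
  stops are skipped with a warning; gap columns are stripped pairwise
  before analysis (no aligner is embedded).

Equal-pathway NG86 with JC69 is fully adequate at the divergence scale of
young strata (Ks ≤ 0.13, far from saturation); likelihood models (GY94,
YN00) would add machinery without moving the estimates.

Block mean Ks is the arithmetic mean over member pairs with defined Ks
(pairs assigned by Y-position containment; overlapping blocks are an
error). Stratum mean Ks is the pair-weighted mean over member blocks, so
Σ stratum pair counts equals Σ block pair counts.

## Strata segmentation

Ordered blocks are partitioned into m contiguous segments by dynamic
programming minimizing within-segment sum of squares of block mean Ks
(verified against exhaustive enumeration for ≤ 10 blocks). Segment means
are then collapsed into `k_levels` divergence levels by cutting the sorted
means at the k−1 largest gaps; levels are labelled "1" (highest Ks =
oldest) downward, with positional suffixes ("2-1", "2-2") when one level
holds several segments.

`anchors` names a contiguous block run forced to be its own segment and
assigned to the oldest level regardless of its mean — the explicit version
of the manual structural-variation / fusion-point override, since
inversions can inflate or depress local Ks. A per-block Ks offset table is
likewise applied openly and recorded in the output; there is no silent
adjustment. When anchors are given, m defaults to the flank|anchor|flank
structure; otherwise m is chosen at the elbow of the DP cost curve (and is
1 when the blocks are already homogeneous).

## Gene-tree patterns

A set of leaves is a clade iff some edge-induced split of the tree
separates it exactly — this handles polytomies and paralog duplicates
uniformly (leaf-set monophyly, not pair siblinghood). With an outgroup
leaf the tree is read as rooted on it, which reduces to testing the same
split with the outgroup constrained to the far side; without one,
bipartitions of the unrooted tree are used. *Ancestral* requires the X
leaf set and the Y leaf set each to be clades; *recent* requires every
species' {X, Y} set to be a clade; *chaotic* is strictly neither;
*unclassifiable* covers trees where some species lacks a copy or only one
species is present. For ≥ 2 complete species the two named patterns are
mutually exclusive (asserted, not assumed). Support values are ignored by
default — the source protocol states no threshold — but `min_support`
optionally collapses weak branches before judging. Note that for two
species the third unrooted 4-leaf topology (X and Y copies crossed between
species) satisfies neither named pattern and is therefore a valid chaotic
outcome.

## Candidate screen

The specificity rule uses flower-bud samples only: male-specific means
TPM ≥ `tau_on` (default 1) in *every* male bud sample and ≤ `tau_off`
(default 0.5) in *every* female bud sample. The thresholds are
conventional detection floors — the source protocol states none — and are
configurable and logged; a high-expression flag additionally marks
max male-bud TPM > 100. Stem/leaf samples are reported descriptively, not
filtered on.

The cascade then drops genes without a congener homolog; among survivors a
gene passes if it either has no X-SLR homolog but an autosomal one (the
duplication-origin route) or has an X-SLR homolog whose gametolog tree
shows the ancestral pattern; survivors are *selected*, and those inside
the oldest stratum (gene midpoint within the stratum-1 interval) are
*final candidates*. Every stage's survivor set is nested in the previous
one. A gene failing stage 2 by lacking homologs everywhere is reported
under the same `excluded_topology` stage as a topology failure, since the
stage is one filter with two acceptance routes.

## Synthetic data: what it does and does not emulate

**Depth** is drawn one Poisson value per fixed tile (default 1 kb, i.e.
the variance equals the mean at the tile scale) with mean
copy/2 × λ + ε·λ, where the mismapping leak ε (default 0.02) applies where
the pool has no true copy — so "negligible" female coverage is small but
nonzero, as in real data. Poisson is the simplest model consistent with
the qualitative 1 : 0.5 : 0 signature; real pooled data are overdispersed
(GC bias, mapping artifacts, repeats), so passing recovery tests here
shows correctness of the inversion, not robustness to every real-world
artifact. Defaults: λ = 30, a 4.5 Mb region planted on a 12 Mb chromosome
(2,391 window positions).

**Gametolog pairs** start from a stop-free ancestral CDS built from
fourfold-degenerate codon families (TCN, CCN, ACN, GCN, GTN, GGN), so
every codon carries exactly one synonymous site and third-position changes
are always synonymous. Third positions are substituted per site with
probability p = ¾(1 − e^(−4Ks/3)) — the JC69 expectation inverted — which
makes the realized NG86 estimate unbiased for the target Ks (verified:
|bias| < 0.005 at 500 codons × 100 pairs). Multiple hits per site are not
simulated; the targets sit far below saturation. First/second positions
are optionally substituted at a configured Ka (default 0.01, a
purifying-selection-scale rate); substitutions that would create stops are
resampled. Per-stratum defaults are the published means (0.0574, 0.1041,
0.0418) with 19/43/48 pairs of 500 codons. No indels, no rate
heterogeneity, no codon-usage structure.

**Gene trees** are built constructively for the ancestral and recent
patterns and by rejection sampling for chaotic (an explicit error is
raised only if rejection cannot succeed). Branch lengths are uniform
decorations; only topology matters downstream.

**Expression** draws background TPM log-normally (floored at 1, centred
so a column sums near 10^6 before exact renormalization); planted
male-specific genes sit above 30 TPM in male buds and below 0.1 in female
samples. Defaults: 300 genes, 11 planted, 3 + 3 bud samples.

**Whole-study simulation** wires these together with noiseless homology
tables (so origin recovery is exact by construction) and a screen
narrative in which, of the male-specific genes, five lack a congener
homolog, two fail on a species-pairing topology, three are autosomal
duplicates and one passes via the ancestral tree pattern, with one
selected gene placed outside the oldest stratum.

## Problem sizes

Default simulations run on a 12 Mb chromosome, 110 gametolog pairs of 500
codons, and a 300 × 6 expression matrix; the whole test suite plus the
acceptance script completes in well under a minute on one core. These
sizes were chosen because every recovery statistic stabilizes well below
them (e.g. a stratum mean over 43 pairs has a standard error of ≈ 0.0026,
a quarter of the ±0.01 assertion band).

## Known limitations

* Poisson depth understates real pooled-depth dispersion; band defaults
  may need widening on noisy data.
* X-SLR boundary precision is inherently ~0.4 × window with the default
  bands (see above); shrink the window for sharper X edges.
* The NG86 estimator is appropriate for Ks ≲ 0.5; beyond that the JC69
  correction degrades and a likelihood method should be used instead.
* Strata labels depend on the block table supplied; the package does not
  detect synteny blocks itself.
* The screen's acceptance routes encode presence/absence homology calls;
  borderline homologs (fragmented or diverged copies) must be resolved
  upstream.
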