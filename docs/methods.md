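# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `cohloop`.

## Contact matrices and normalization

Read pairs (4-column TSV: chrom1, pos1, chrom2, pos2; 0-based bp) are
binned at a fixed resolution into per-chromosome upper-triangular sparse
matrices: an intra-chromosomal pair increments exactly one pixel
(⌊pos1/res⌋, ⌊pos2/res⌋), ordered i ≤ j. Inter-chromosomal pairs are
counted into the total depth but not stored, since all downstream analyses
here are cis. Same-bin pairs sit on the main diagonal; loop calling never
tests them (minimum distance ≥ 2 bins by default), and fragment-level
artifacts such as self-ligations are assumed filtered upstream.

CPM of a pixel is count × 10⁶ / total_depth, with total_depth = all input
pairs of the sample (intra + inter). The same denominator is used for loop
CPM and virtual-4C CPM, so the two report on one scale. No matrix balancing
(ICE/KR) is applied: the loop test conditions on the diagonal, which
absorbs the dominant (distance) bias, and balancing would break the simple
count model the NB test needs.

Internally all coordinates are 0-based half-open (BED convention); 1-based
positions are accepted only at the CLI (e.g. `--viewpoint chr3:133,544,706`)
and converted on entry.

## Loop calling: negative binomial per diagonal

For each bin distance d in [min_dist, max_dist] (defaults 2 and 100 bins,
i.e. 40 kb – 2 Mb at 20 kb), the counts of *all* pixels at that distance —
including zeros, which are genuine observations — are pooled across
chromosomes and fitted by the method of moments:

- μ_d = mean, s²_d = population variance;
- if s²_d > μ_d: negative binomial with size r_d = μ_d² / (s²_d − μ_d) and
  p = r_d / (r_d + μ_d);
- otherwise Poisson(μ_d) (flagged as the fallback; forced, e.g., by
  constant counts).

Method of moments is used because it is deterministic, closed-form and
directly testable; maximum likelihood would change estimates by little at
the pixel counts involved and would add an iterative failure mode.
Diagonals with fewer than `min_pixels` (default 10) pixels are skipped with
a warning.

Each pixel gets the inclusive upper-tail p-value P(X ≥ x). Benjamini–
Hochberg runs once across **all** tested pixels genome-wide (zero-count
pixels enter the family with p = 1), which is the more conservative and the
standard choice; a per-diagonal family is available via `bh_scope=
"diagonal"`. Ties are broken by a stable sort on (p-value, chrom, anchors)
for bit-reproducibility, and adjusted values are floored at the raw
p-value. Loops are pixels with FDR < 0.1 **and** CPM > 30 (both
configurable).

Note one structural property of these thresholds: the expected CPM of a
pixel is depth-invariant (count and depth scale together), so whether a
planted loop can clear CPM > 30 depends only on its distance, the decay
exponent and its enrichment — increasing depth adds power against the FDR
cut but cannot rescue a pixel whose expected CPM sits below the CPM cut.

### Differential loops

The union of significant loops called in either sample is keyed by exact
pixel coordinates; each union entry records its source ("a", "b", "both").
For every union loop, CPM is looked up in both matrices (also where a
sample did not call it) and scored as log₂(CPM_a + c) − log₂(CPM_b + c)
with pseudocount c = 1 CPM. The difference-of-logs form makes
swap-antisymmetry exact in floating point, which the tests assert.

### Aggregate peak analysis

For each loop at distance d, the (2w+1)² window (w = 5 bins) of
distance-normalized values — pixel count divided by the mean of its own
diagonal — is extracted and averaged across loops. Loops closer than w bins
to a matrix edge, or whose window would cross the minimum tested distance
(d − 2w < min_dist), are excluded. The enrichment score is the center value
over the mean of the w×w lower-left corner (the short-distance background),
the conventional APA normalization.

## Virtual 4C

A pair qualifies iff **exactly one** mate lies in the viewpoint interval
[position − flank, position + flank] (inclusive; flank default 10 kb).
Pairs with both mates inside carry no distal information and are excluded.
For each qualifying pair, +1 is added to every 20 kb window containing the
distal mate; windows start at coordinate 0 of the viewpoint chromosome and
step every 1 kb (95% overlap), with the final partial windows clipped at
the chromosome end. An interior point therefore lies in exactly
⌈20000/1000⌉ = 20 windows — an arithmetic identity the acceptance suite
checks against a brute-force per-window recount. Counts are CPM-normalized
by the sample's total depth. Only the viewpoint chromosome is profiled
(cis). Per-window log₂ fold-changes between conditions use the same
pseudocount convention as differential loops.

## Compartment c-scores

Per chromosome at 100 kb: bins with zero marginal counts are masked; the
masked submatrix is transformed to observed/expected by per-diagonal means;
a light boxcar smoothing (half-width 1 bin) is applied to the O/E matrix;
the Pearson correlation matrix is computed and then correlated once more
(correlation-of-correlation, which sharpens megabase block structure
against sampling noise in shallow matrices); the compartment eigenvector is
selected among the 3 leading eigenvectors of that matrix as the one most
correlated in absolute value with the reference activity track (leading
eigenvectors can capture decay residuals instead of compartments); a 3-bin
boxcar is applied to the eigenvector; the result is rescaled by its maximum
absolute entry into [−1, 1]. Smoothing and double-correlation are
parameters (`oe_smooth`, `double_correlation`, `score_smooth`) and can be
switched off for deep matrices.

The eigenvector sign is arbitrary, so tracks are oriented by the sign of
the correlation with the reference (H3K27ac-like peak counts per bin): the
active-chromatin-rich side scores positive and is labeled A, negative is B,
masked bins are NA. Orientation by correlation sign is used rather than a
top-quartile mean rule because quartile thresholds degenerate when most
bins carry zero reference signal. This scorer is a deliberate surrogate for
likelihood-based c-score estimation: everything downstream (delta c-score,
cross-sample correlations, A/B calls) depends only on a signed per-bin
score, and the tests validate it by recovery of planted truth, not by
matching any external tool numerically.

Delta c-score is the per-bin difference a − b on jointly unmasked bins;
track correlation is plain Pearson over jointly finite bins (also usable
between two delta tracks).

## Consensus somatic-variant filters

Per-caller tables are merged on (sample, chrom, pos, ref, alt); one record
per alt allele. Only keys reported by ≥ 2 callers survive; annotation and
numeric fields come from the first reporting caller in a declared priority
order (default alphabetical). Hard filters then retain a variant iff
tumor_depth ≥ 30, tumor_alt ≥ 5, tumor VAF ≥ 0.10, germline VAF ≤ 0.01,
not dbSNP, and consequence ∈ {missense, synonymous, stop-gained,
frameshift, splice-region, NMD-transcript} — the exclusion thresholds are
phrased strictly (< 30, < 5, < 10%, > 1%), so boundary values are
retained. "Truncating" is expanded to the four classes above; the set is
configurable. Rules are evaluated in a fixed order (callers, depth, alt
reads, tumor VAF, germline VAF, dbSNP, consequence) and each dropped
variant is charged to the first rule it fails, so the report partitions the
input; zero depth makes the VAF undefined and drops at the depth rule.

Percent genome altered: gain% = 100 × Σ length(segments with log₂ ratio >
0.1) / genome size, loss% analogously with < −0.1; overlapping segments
within a sample are rejected, and the measure is invariant to splitting a
segment at the same log₂ value. Gene tallies count a gene as mutated in a
sample iff ≥ 1 retained variant (set semantics), reported as per-group
frequencies over the declared group sizes, with explicit zeros.

## The synthetic-data generator

The generator emulates the post-alignment products of an in situ Hi-C
experiment and a tumor/germline exome workflow; it does **not** emulate
reads, alignment artifacts, duplicates, self-ligation, or restriction-
fragment structure (those are upstream of this package's inputs).

Contacts: every intra-chromosomal pixel at bin distance d ≥ 1 carries
weight d^(−α) (α = 1 by default, the canonical contact-decay slope)
× `checkerboard_strength` if its two bins share a compartment label
× the planted-loop enrichment factor for the current condition. Exactly
`depth` pairs are drawn multinomially over pixels and scattered uniformly
within bins, giving closed-form expected pixel means that the truth object
records per diagonal. Overdispersion enters as per-pixel gamma rate
multipliers with mean 1 and variance `dispersion` (default 0.05, a small
positive value so the caller's NB branch is genuinely exercised;
`dispersion = 0` gives Poisson-like counts, which the tests verify via
variance/mean ≈ 1). Conditions draw from independent sub-streams of one
seed, so a two-condition experiment from a single config is reproducible
end to end.

The default toy genome is 2 chromosomes × 20 Mb (1,000 bins at 20 kb, 200
at 100 kb): large enough for ~190,000 tested pixels per library, small
enough that the full acceptance battery — including 20 null libraries —
runs in tens of seconds. Test conditions used throughout: null libraries at
2×10⁵ pairs; loop-recovery libraries at 2×10⁶ pairs with 50 planted loops
(enrichment 4 at 2–6 bins distance, enrichment 8 at 7–12 bins — the
distance split keeps each group's expected CPM above the retention cut, cf.
the depth-invariance note above, and keeps the strong group's outliers from
inflating the weak group's diagonal variance estimates); checkerboards of
2 Mb alternating blocks at 1.5× same-label boost and 5×10⁵ pairs.

Annotations: a chosen fraction of planted loops receives a 2 kb promoter
interval (with a gene name) inside anchor 1 and a 1 kb enhancer inside
anchor 2; remaining intervals are placed uniformly at random. The H3K27ac-
like reference track places ~2 one-kb peaks per A-compartment bin —
a realistic density for active chromatin — and none in B blocks.

Variant tables are stratified so that every filter dimension is exercised
at, below and above its threshold (caller count 1/2/3, depth around 30, alt
reads around 5, tumor VAF around 10%, germline VAF around 1%, dbSNP flags,
retained and non-retained consequence classes), and each variant carries
the label the filters should assign, computed independently by the
generator.

What passing these tests does and does not show: the generator's decay,
checkerboard and focal-loop structure make the background models and
eigenvector analysis well-specified by construction, so the tests establish
correctness and calibration of the implementations, not robustness to real-
data pathologies (copy-number-driven coverage waves, unmappable regions,
translocations, fragment-level biases).

## Numerical choices and degenerate inputs

- NB tails use the inclusive survival function P(X ≥ x) = sf(x − 1); the
  acceptance suite verifies agreement with explicit PMF summation to 1e−9
  across an r × μ grid for all counts ≤ 500.
- BH with structural zeros: the family size counts all tested pixels; the
  zero-count block enters as p = 1 and can never be called.
- Empty matrices or distance ranges yield empty loop sets with a warning;
  zero total depth is an error wherever CPM is required.
- Eigen-decomposition uses `numpy.linalg.eigh` (deterministic); repeated
  fits are bit-identical, which a test asserts.
- Chromosomes with fewer than 10 usable bins are masked entirely from
  compartment scoring.
- Loop sets and tracks are plain pandas DataFrames with a `resolution`
  attribute; resolution mismatches between operands raise.

## Limitations

- The NB background is fitted per diagonal from the same matrix being
  tested; a dense cluster of very strong loops on one sparse diagonal
  inflates that diagonal's variance estimate and costs power (visible in
  the generator experiments; mitigated in practice by the genome-wide
  pixel pool at each distance).
- The compartment scorer is an eigenvector surrogate, not a likelihood
  c-score; absolute score magnitudes are not comparable across tools, only
  signs, ranks and differences.
- The CPM retention threshold is depth-invariant in expectation (see
  above), so very distal loops cannot pass it at any depth under a pure
  power-law background — consistent with its role as an intensity floor.
- Virtual 4C profiles are cis-only and dominated near the viewpoint by
  distance decay; distal peaks, not the proximal shoulder, are the
  interpretable signal.
- The variant module consumes caller outputs and VEP-style consequence
  strings as given; it does not call variants, realign, or re-annotate.
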