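# Methods

This note documents the models and procedures implemented in `sgfound`,
the choices made where the underlying experimental descriptions leave the
design open, and what the synthetic-data validations do and do not show.

## Stress-granule quantification (`sgfound.imaging`)

**Segmentation.** Nuclei are thresholded in the Hoechst channel with
Otsu's method, hole-filled, and filtered by a minimum area
(`nucleus_min_area_px`, default 40 px; components strictly below the
minimum are discarded). Cytoplasm is assigned by nearest-nucleus label
expansion out to `cytoplasm_radius_px` (default 20 px), with the nucleus
pixel set excluded from the cytoplasm. Cells whose cytoplasm touches the
image border are discarded entirely, since partial cytoplasm biases both
the granule counts and the donut statistic. Pixel coordinates are
0-based (row, col).

**Transfection calling.** Each cell's mean cytoplasmic V5 is compared to
a threshold. Two methods are provided: a global Otsu split of the
per-cell means (fails with an explicit message when all means are equal),
and the default k-sigma rule — positive when the mean exceeds
`mean + k·sd` of an untransfected reference (k = 4), estimated from the
image's non-cell background unless reference statistics from a control
well are supplied. The k-sigma margin has a relative floor
(`v5_min_contrast`, 10% of the reference mean) so the call remains
meaningful in the noiseless limit where the reference sd collapses to
zero. The method and threshold used are returned in a log.

**Spot detection.** Candidate pixels must lie in cytoplasm, have a
positive difference-of-Gaussians response at `spot_detection_sigma_px`
(default 2 px; high sigma at the scikit-image default 1.6× ratio), and
exceed `spot_threshold_k` (default 1.3) times the cell's median
cytoplasmic TIAL1. Connected components outside the area band
[`spot_min_area_px`, `spot_max_area_px`] = [5, 250] px are discarded;
each granule is assigned to the cell containing its centroid (majority
vote over component pixels when the centroid falls off-cytoplasm).
Every step is either scale-covariant (Otsu, median-relative threshold)
or scale-invariant (DoG sign), so quantification is invariant to
multiplying the channels by a positive constant, and translation
invariant up to border-cell exclusion; both properties are tested.

**Donut-ratio enrichment.** For each granule the donut is the
morphological dilation of the spot by a disk of `donut_width_px`
(default 5 px, optional gap 0 px) minus the spot, minus every other
granule's pixels, intersected with the owning cell's cytoplasm — the
exclusions keep neighbouring spot signal and foreign cells out of the
local background. The enrichment ratio is median(spot V5)/median(donut
V5) and the granule is V5-enriched when the ratio strictly exceeds 1.2.
A granule whose donut is empty keeps an undefined ratio and is excluded
from enrichment tallies while still counting toward total SG numbers; a
zero donut median yields +inf with a warning. The published description
("the surrounding donut of 5 pixels") does not specify the exclusions or
whether 5 is a radius or a width; the implementation uses a 5-px-wide
annulus immediately surrounding the spot and exposes both width and gap
as parameters, without asserting that this reproduces the original
geometry exactly.

## Replicate-level inference (`sgfound.sgstats`)

Per-image summaries (proportion of SG-containing cells, mean SGs per
cell, enriched/non-enriched SGs per cell — computed separately for
transfected and untransfected cells) are collapsed to one value per
construct × treatment × replicate by cell-weighted averaging across the
images of a condition.

`RepeatedMeasuresAnova` fits the fully within-subject one- or two-way
decomposition on a complete balanced design, with the independent
experiment as the subject. Incomplete designs fail with the list of
offending subjects rather than silently switching to a mixed model (a
deliberate choice: the complete-data ANOVA is deterministic and
oracle-checkable; mixed-effects estimation is out of scope). The
Greenhouse–Geisser epsilon for each effect is the Box epsilon
tr(Σ)²/(q·tr(Σ²)) of the covariance of orthonormalized within-subject
contrast scores (Kronecker products of the factor contrasts for the
interaction), clamped to [1/q, 1]; corrected p-values use epsilon-scaled
numerator and denominator df. A two-level factor forces epsilon = 1.
Note the common claim that the corrected p never falls below the
uncorrected p holds for F ≥ 1 but can reverse for F < 1 — shrinking both
df can shrink the upper tail area below an F smaller than its mean.

`DunnettComparison` performs many-to-one comparisons against the control
construct on per-replicate paired contrasts. The error term is the
construct × subject interaction mean square with (k−1)(n−1) df; the
contrasts share the control and are therefore equicorrelated at ρ = 0.5,
and the reference distribution of max|T| (shared studentizing
denominator) is sampled by seeded Monte-Carlo with 10⁵ draws, giving
adjusted p-values with a tolerance of about ±0.002 and simultaneous 95%
confidence intervals `mean_diff ± c·SE`. A single comparison is
special-cased to the exact paired two-sided t-test, which the Monte-Carlo
construction reduces to. Monte-Carlo reference samples are cached per
(m, df, draws, seed), so repeated fits (e.g. simulation studies) pay the
sampling cost once. Calibration is verified in the test suite: the
GG-corrected main-effect type-I error over 2000 null simulations must lie
in [0.04, 0.06] at α = 0.05, and the familywise error of three null
mutants over 5000 simulations must not exceed 0.05 plus two Monte-Carlo
standard errors.

## Founder-haplotype dating (`sgfound.haplotype`)

All carriers are hemizygous males, so identity-by-descent sharing on
chromosome X reduces to allele concordance. `find_shared_segment`
returns the maximal run of consecutive markers, containing the mutation
position, at which all carriers carry identical alleles; the reported
interval endpoints are the outermost concordant markers (1-based
inclusive), and the physical span is (end − start)/10⁶ rounded to two
decimals — the convention that reproduces published haplotype sizes of
5.35 Mb (chrX:17499443–22849591) and 19.79 Mb (chrX:12750254–32544555).
Genetic length is cM(end) − cM(start) by piecewise-linear interpolation
of a (bp, cM) map, with linear extrapolation plus a warning outside the
map range. The core finder tolerates no genotyping mismatches by
default (hemizygous array calls are high-confidence); an optional
`max_mismatch` budget exists.

The age rule is g = 200/L(cM), rounded to the nearest generation, with
years = g × 25. This is a calibration: it is the unique simple
length-based rule consistent with both published anchor pairs
(8.07 cM ↔ 25 generations and 625 years; 25.5 cM ↔ 8 generations and
200 years), with the 25-year generation time implied by the printed
years. It matches the familiar order-of-magnitude argument that an
ancestral segment erodes by recombination at about 1% per cM per
meiosis, but it is a point approximation with no confidence interval and
should be read as such.

## Variant prioritization (`sgfound.variants`)

A variant passes the frequency filter iff its allele frequency is
strictly below 0.001 in every population database field it is annotated
with (gnomAD/ExAC-style INFO fields, configurable); an absent annotation
counts as frequency zero ("absent from aggregation databases"), and a
malformed value fails the variant with a message rather than passing it.
Gene-list restriction passes variants whose (case-normalized) gene symbol
is on a user-supplied muscle-expressed gene list; the bundled defaults
are demonstration lists only, with no claim of equivalence to any
published transcriptome. The two filters commute on the pass set, which
is tested. External predictor scores (CADD, PrimateAI, SIFT, PolyPhen2,
SpliceAI) are pass-through annotations; no thresholds are applied.
HGVS helpers cover single-nucleotide coding substitutions
(`c.<pos><ref>><alt>`, whitespace-tolerant) and the codon arithmetic
codon = ⌈pos/3⌉; anything else (indels, splice offsets) raises an
explicit unsupported-syntax error. VCF input/output goes through pysam;
hemizygous male ALT calls are counted once and no zygosity filter is
applied.

## Solubility fractionation (`sgfound.solubility`)

Band densitometry is first divided by total protein loading, then by the
mean of the wild-type construct within the same experiment and fraction,
so WT maps to 1 per experiment and the statistic is invariant to
per-experiment scaling (tested). Mutants are compared to WT per fraction
on replicates pooled across experiments (three triplicate experiments
give n = 9 per group) with a two-tailed Mann–Whitney U test: the exact
permutation null (conditioning on the pooled values, midrank ties,
p = min(1, 2·min(tails))) for groups up to 12+12, and the normal
approximation with tie correction above that. Bonferroni correction
uses m = the number of mutant constructs by default, treating
supernatant and pellet as separate families (the published figure
annotates the fractions independently; m is configurable and reported in
the output). Stars follow the adjusted p: * < 0.05, ** < 0.01.

## Synthetic data (`sgfound.synthetic`)

**Scenes.** Nuclei are non-overlapping ellipses (semi-axes 7–11 px)
placed with a margin so no cell touches the border; cytoplasm is an
irregular lobed region around each nucleus (radius ~14 px modulated by
2–4 angular lobes), with overlapping claims resolved by nearest nucleus.
Granules are 2-D Gaussian bumps (radius 3–5 px, σ = r/2, amplitude 150
over a cytoplasmic TIAL1 level of 60 on background 100) planted wholly
inside the owner's cytoplasm, with per-cell counts Poisson at the
transfection-dependent rate and same-cell spots kept separated whenever
space allows. V5 enrichment exists only in transfected cells (V5 is the
transfection tag) and is a co-located V5 bump whose amplitude is
calibrated so the median V5 over the spot is about `enrichment_factor`
(default 1.5) times the local cytoplasmic V5 — the median of a Gaussian
over the half-max disk is e⁻¹ of its peak. Noise is additive Gaussian
(sd 4), clipped at zero; intensities are unitless floats, scaled to
16 bit on TIFF export. Defaults represent a moderately confluent 20×
field: 25 analyzable cells, half transfected, ~2 SGs per cell under
stress; cell counts per field and images per replicate are not published
quantities, so they are config-exposed defaults, not assertions.
The generator does **not** model 3-D structure, PSF blur, shot noise,
photobleaching, uneven illumination or cell-to-cell expression
variability, so passing tests demonstrate correctness of the measurement
pipeline on its stated model, not robustness to every real-microscopy
artifact.

**Genotype panels.** Hemizygous single-allele genotypes (all patients
are male); markers sampled over chrX:12–33 Mb with markers forced at the
planted interval's endpoints, carriers identical across the planted
segment, at least two carriers forced discordant at the first marker
outside each end (so the segment is exactly recoverable), and
non-carriers drawn independently at minor-allele frequency 0.35. The
default genetic map is piecewise linear at ~1.5 cM/Mb, anchored so the
default planted interval spans 8.07 cM. Diploid genotypes and phasing
are out of scope.

**Densitometry.** A construct's `solubility_shift` moves that fraction
of the wild-type supernatant signal into the pellet, conserving total
signal; multiplicative Gaussian noise with coefficient of variation 0.1
models blot variability, and `noise_cv = 0` returns exact expected
means. Defaults mirror the three-triplicate design (n = 9) with strong
shifts for the N-terminal mutants (0.6, 0.5) and mild shifts (0.15) for
the C-terminal ones.

## Numerical conventions

Thresholds printed as strict inequalities are implemented strictly
(enrichment ratio > 1.2; AF < 0.001); area minima are inclusive (≥).
Rounding: physical spans to 2 decimals, allele frequencies reported at 3
significant figures, generations to the nearest integer before
converting to years. All generators and Monte-Carlo procedures are
deterministic given their seeds; identical configs give bit-identical
outputs. Simulation sizes in the test suite (2000 ANOVA nulls, 5000
Dunnett nulls, ≥500 planted granules, 20–40 synthetic tables) were
chosen to keep Monte-Carlo standard errors small relative to the
tolerances being checked while the whole suite runs in a few minutes.

## Known limitations

- The dating rule is a two-point calibration with no uncertainty
  quantification; genuine founder-age estimators model recombination and
  genealogy explicitly.
- The RM-ANOVA requires complete balanced designs; unbalanced data must
  be completed or subjects dropped.
- The spot detector assumes roughly isotropic granules within a fixed
  area band; elongated or out-of-focus granules would need different
  band-pass parameters.
- The Mann–Whitney exact branch enumerates up to C(24,12) ≈ 2.7M splits;
  beyond 12 per group it switches to the tie-corrected normal
  approximation.
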