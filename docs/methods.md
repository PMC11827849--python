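# Methods

This note documents the models, default parameters, and numerical choices
behind each pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## MPRA quantification

Counts are modeled per construct × replicate, where the replicate axis is
a grid of independent plasmid libraries (default 3) each transfected into
several wells (default 4).  Construct-level counts are sums over the
construct's barcodes; barcode sets must be pairwise disjoint and unmatched
barcodes are tallied, never dropped.  Normalization is counts per million
within each replicate, so per-replicate normalized totals equal 10⁶
exactly; a zero-total replicate cannot be normalized and is excluded with
a reason code.

Activity is the per-cell RNA-CPM/DNA-CPM ratio.  No pseudocount is used:
a zero-DNA cell carries no abundance information and is marked undefined
rather than imputed.  Note that CPM ratios are normalized to the pool, not
to the wild-type construct: when many constructs in the pool have reduced
activity, all ratios shift by a common factor (ratios of ratios, and all
rank statistics, are unaffected).

QC applies two exclusions, both config-exposed:

* representation: cells with normalized DNA < `min_norm_count` (default
  100 CPM) are excluded.  The threshold is strict (`< 100` excluded,
  `= 100` retained) and applies to the DNA assay by default (abundance is
  the standard MPRA representation filter); RNA-side filtering is a flag.
* replicate consistency: a technical replicate is dropped entirely when
  the wild-type element's activity in it deviates from the within-library
  replicate mean by ≥ `wt_sd_k` (default 1.0) sample standard deviations.
  When the within-library SD is zero no replicate is dropped.

The mutagenesis effect map assigns each element position (1-based
inclusive genomic intervals) the mean activity over all included
(construct, replicate) values of constructs whose mutated interval covers
it; binding-site/end deletions and point mutations are reported as
separate tracks.  Uncovered positions are gaps, not zeros.  Group
comparisons against the wild-type element use Welch's unpaired two-tailed
t test; BH adjustment spans exactly the family of groups tested in one
call and families are never pooled across calls.

## Allele-specific expression

The pooled estimator `Σ mut / Σ wt` is depth-weighted and is the default;
`mean_of_snps` (unweighted mean of per-SNP ratios over SNPs with both
alleles observed) is available since plots of per-SNP counts do not fix an
aggregator.  The two coincide exactly when all SNPs share depth and ratio.
Undefined ratios (all wild-type-linked counts zero) propagate as missing,
never 0 or ∞.  The ratio is a convex function of the allele fraction, so
it carries a small positive Jensen bias of order var(p̂)·2/(1−p)³; at the
study depths (10⁴/SNP, 10 SNPs) this is ≈ +0.01 under overdispersion 0.05
and negligible under pure binomial sampling.

The cis/trans call compares per-sample ratios between wild-type and
heterozygous groups with Welch's t: a significant depression in
heterozygotes with the wild-type group within 0.1 of 1 is labeled
cis-consistent (a trans effect would shift both alleles equally, leaving
both groups at 1).

ΔΔCt: ΔCt = Ct(target) − Ct(housekeeping) per sample, ΔΔCt subtracts the
reference group's mean ΔCt per gene, fold = 2^(−ΔΔCt).  Folds are
invariant to any constant added to all of a sample's Ct values.  Mendelian
tests use the asymptotic χ² goodness of fit (df = k − 1), matching
standard practice for litter genotype counts.

## Micropillar tracking and force

Templates are cut from the first frame around iteratively refined
intensity-weighted centroids (background = window median).  Each frame is
matched independently against the frame-0 template — no template updating,
so tracking errors cannot accumulate.  Stage 1 is the integer argmax of
the normalized cross-correlation over a ±`search_radius` window
(default 10 px); stage 2 fits a 3-point parabola per axis to the
correlation surface around the peak, clipped to ±0.5 px.  Peaks on the
window boundary flag the frame; flagged frames carry no deflection.  On
synthetic caps the combined error is ~0.001 px.

Deflection is the displacement projected on the inter-pillar axis
(positive toward the opposite pillar, i.e. contraction); the full 2-D
magnitude is recoverable from the stored positions.  The resting position
is re-estimated as the median deflection over the lowest decile of
per-frame |deflection| ("robust", default) or taken from frame 0
("first_frame").  With a waveform that has no diastolic plateau the robust
baseline sits slightly above true rest (≈ 1% of amplitude for a pure
raised cosine at 30 frames/period); recordings with a resting phase are
unaffected.  Force(t) = k·deflection(t) with k defaulting to 2.68 μN/μm;
stress = force/area with the tissue cross-sectional area a user input
echoed to outputs.  Fractional shortening is computed directly from
LVEDD/LVESD and rejects LVESD > LVEDD rather than clamping.

## Sarcomere metrology

Segmentation: a large-kernel Gaussian background estimate (default σ = 25
px, ≫ filament width) is subtracted for illumination correction; a light
denoising blur (default σ = 1 px, set 0 to disable) suppresses shot noise
below the filament scale; the global threshold is Otsu by default or a
fixed value; components smaller than `min_area_px` (default 5) are
discarded.

Metrics follow the equivalent-ellipse convention: λ = 4·√(eigenvalue) of
the pixel-coordinate second central moments, giving full axis lengths that
are exact for solid ellipses.  Angles are measured clockwise from the
image vertical axis in [−90°, 90°); near-isotropic components report an
undefined (NaN) angle.  Single-pixel components floor the minor eigenvalue
at one pixel.  For few-pixel components the orientation estimate is
discretization-limited: at the default scale (λ1 = 1.2 μm ≈ 7 px at
0.1625 μm/px, ~16 px per filament) individual angles scatter several
degrees even without noise, while the per-image mean is accurate to
fractions of a degree; tests therefore check single-shape angles on larger
objects and population means on generated fields.

Spacing d pairs each filament with its nearest neighbor lying along its
own major-axis direction (offset within `max_angle_diff_deg`, default 15°,
of the axis; similar orientation; within `max_gap_um`, default 3 μm); each
unordered pair is recorded once.

MEFL calibration is an ordinary least-squares affine fit of reference MEFL
against measured AU over ≥ 2 bead peaks; upstream flow gating is out of
scope and the module consumes exported intensity tables only.

## Statistics

Welch's t (with Welch–Satterthwaite df), χ² goodness of fit, exact
one-sided binomial enrichment (upper tail; two-sided by doubling, capped
at 1), and BH step-up adjustment (monotone, capped, order-preserving).
Identical constant samples compare as t = 0, p = 1.  All primitives are
validated wrappers over scipy/statsmodels, cross-checked in the test
suite against hand-evaluated formulas and brute-force enumeration.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` and return a
`SimTruth` with every argument and per-item latent truth; identical
arguments and seed reproduce identical outputs.

* **MPRA**: construct × library plasmid abundances are log-normal around
  `mean_depth` (σ = 0.25 on the log scale, emulating library-prep
  variation) and shared across a library's wells; counts are
  negative-binomial with variance μ + αμ² (α = `dispersion`, 0 → Poisson;
  the count model is an assumption, standard for sequencing counts).  RNA
  expected counts are abundance × activity.
* **ASE**: mutant-linked counts are binomial with p = r/(1+r), optionally
  beta-binomial with intraclass correlation ρ = `dispersion` emulating
  SNP-to-SNP capture variability; wild-type samples use r = 1; zero-depth
  SNPs are emitted and flagged.
* **Pillar stacks**: two logistic-edged caps, one translating along the
  inter-pillar axis by amplitude × raised-cosine(t) with a 30-frame period
  (1 Hz at 30 fps); Gaussian read noise; uint16.  Defaults place the peak
  exactly on a sampled frame.
* **Sarcomere fields**: strings of solid ellipses (full axes λ1 × λ2)
  laid end-to-end along the string direction at center-to-center spacing
  d, rendered with 4× supersampled partial-volume edges; rejection-sampled
  placement keeps strings ≥ 3.5 μm apart; generation fails rather than
  render overlapping geometry.  Defaults λ1 = 1.2 μm, λ2 = 0.45 μm,
  d = 1.8 μm, 0.1625 μm/px (6.5 μm camera pixel at 40×).
* **Beads**: log-spaced AU peaks over several decades with an affine MEFL
  map plus AU-axis noise.

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: sequencing-read structure and barcode
errors (counts are generated directly), mapping or phasing artifacts in
allele assignment, focus drift, photobleaching and non-rigid tissue motion
in the videos, out-of-focus light and filament curvature or branching in
the images, and autofluorescence or spectral spillover in cytometry.
Parameter-recovery results bound algorithmic error under the stated noise
models, not instrument systematics.

## Problem sizes

Test-suite simulations use the study-scale conditions stated above at
modest replication (20–200 seeds per property; ~15 s total).  The
acceptance script uses 50 replicate simulations per allelic-ratio
condition (250 heterozygous samples each) and a 60-frame noise-free
twitch; it completes in seconds.

## Known limitations

* The MPRA activity scale is pool-relative (see above); absolute
  activities require a spike-in or wild-type renormalization, available
  downstream of the returned tables.
* The WT-replicate QC rule interprets an ambiguous protocol sentence
  (deviation ≥ k·SD from the within-library mean, k = 1); scope and k are
  config-exposed.
* The stress denominator is a user-supplied cross-sectional area; no
  geometry is inferred from the images.
* Segmentation assumes well-separated filaments; touching strings merge
  into single components and bias λ1 upward.
* The χ² and Welch tests are asymptotic; for very small litters an exact
  multinomial test would be preferable but is not what the reported
  analyses used.
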