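# titinreg

Quantitative analysis pipelines for characterizing a cardiac enhancer —
the kind of noncoding element that controls expression of the giant
sarcomere protein titin (TTN), whose haploinsufficiency is the most common
genetic cause of dilated cardiomyopathy.  The package implements the
desk-side quantification for four experimental readouts, the statistics
applied to each, and seeded synthetic-data generators with exact ground
truth for every stage.

## What it computes

**MPRA activity and mutagenesis scanning** (`titinreg.mpra`).  In a
massively parallel reporter assay, each construct's transcriptional
activity is the ratio of normalized RNA to normalized plasmid DNA barcode
abundance,

```
activity(c, r) = RNA_CPM(c, r) / DNA_CPM(c, r),    CPM = count / replicate_total × 10⁶
```

over a libraries × wells replicate grid.  QC excludes cells with
normalized DNA counts < 100 CPM and whole technical replicates whose
wild-type activity deviates from the within-library mean by ≥ 1 SD.  A
per-position effect map averages activities of all constructs whose
mutated interval covers each element position (deletion and
point-mutation tracks kept separate), and every construct (or motif
group) is compared against the wild-type element by Welch's unpaired
two-tailed t test with Benjamini–Hochberg correction.

**Allele-specific expression** (`titinreg.ase`).  In heterozygous-deletion
animals on a hybrid strain background, transcribed strain-distinguishing
SNPs split reads by allele; the per-sample mutant/WT ratio is
`Σ mut_counts / Σ wt_counts` (pooled, depth-weighted) or a mean of per-SNP
ratios.  A depressed ratio confined to heterozygotes, with the wild-type
group at 1, is the *cis*-regulation signature (tested by Welch's t).
Also: ΔΔCt relative expression (fold = 2^(−ΔΔCt), HPRT housekeeping) and
χ² goodness-of-fit tests of offspring genotype counts against Mendelian
ratios.

**Micropillar contractility** (`titinreg.contractility`).  Cardiac
microtissues suspended between two elastic pillars are imaged at 30 fps
under 1 Hz pacing; pillar deflection is tracked in two stages (pixel-scale
normalized cross-correlation, then per-axis parabolic subpixel refinement
of the correlation surface, accurate to ~0.001 px on synthetic data).
Twitch force = spring constant k × deflection (k = 2.68 μN/μm by default);
stress = force / tissue cross-sectional area.  Fractional shortening
(LVEDD − LVESD)/LVEDD × 100% is included for echocardiographic data.

**Sarcomere metrology** (`titinreg.sarcomere`).  GFP-titin filaments are
segmented by illumination-corrected global thresholding; each filament's
primary/secondary axis lengths λ1, λ2 are the equivalent-ellipse axes
4·√(eigenvalue) of its pixel second central moments, with area,
orientation from the image vertical axis, and center-to-center neighbor
spacing d along the filament string.  Rainbow-bead tables calibrate the
affine AU → MEFL fluorescence conversion.

**Synthetic data** (`titinreg.synthetic`).  Every stage has a seeded
generator emulating its noise structure — negative-binomial barcode counts
(variance μ + αμ²), beta-binomial allele counts, rendered pillar twitch
stacks with exact subpixel truth, striated filament fields, bead tables —
returning a `SimTruth` record of all parameters and per-item latent values
for parameter-recovery testing.

## Worked example

```
$ titinreg demo --seed 1 --out demo_out
[mpra] 19 constructs tested vs WT, 2 significant after BH
[ase] wt ratio 1.094, het ratio 0.514, p = 3.52e-05 (cis_consistent)
[pillar] max force 2.657 uN, max stress 2.657 Pa
[sarcomere] 24 filaments (true 24), mean d = 1.779 um
[beads] MEFL slope 10.001, intercept 6.806
demo complete
```

Reading the output: the mutagenesis scan flags exactly the two binding
sites simulated with reduced activity (0.4× wild type); the allelic-ratio
estimator recovers the programmed half-rate transcription of the deleted
allele (0.514 vs true 0.5) while the wild-type group stays at 1, so the
Welch test calls the effect *cis*-consistent; the pillar tracker converts
a programmed 1.0 μm twitch into k × 1.0 ≈ 2.68 μN of force (2.657 after
robust resting-position estimation); all 24 rendered filaments are
segmented with their 1.8 μm string spacing recovered; and the bead fit
returns the programmed MEFL slope of 10.

Each subcommand (`simulate`, `mpra`, `ase`, `ddct`, `mendel`, `pillar`,
`sarc`, `stats`) runs one stage on files; see `titinreg COMMAND --help`.

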