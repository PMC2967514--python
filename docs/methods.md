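# Methods

`nucleoscape` quantifies how cell scattering remodels nuclear architecture,
and validates every read-out on synthetic data with exact ground truth.  The
biological setting it emulates: hepatic progenitor cells dissociate from
their colonies when the fibronectin receptor α5β1 integrin is blocked with a
function-perturbing antibody, or when they are stimulated with HGF/SF1.
Scattering leaves the nuclear volume unchanged (~250 µm³) but disaggregates
pericentromeric heterochromatin: chromocenters become more numerous and
individually smaller (mean volumes around 8 µm³ per chromocenter in
untreated cells, ~6 µm³ under antibody blockade, ~4 µm³ under HGF/SF1),
while gene loci such as *Itgb1*/*Itgb3* keep their peripheral radial
position (80–100% of the nuclear radius).  On the transcriptional side, the
three-condition expression design is summarized per gene set with a
permutation statistic drawn on a single [0, 1] color scale.

## Synthetic microscopy

**Model.** A nucleus is an axis-aligned ellipsoid; the default semiaxes
(4.2, 4.0, 3.55) µm give a 250 µm³ volume, and per-nucleus volumes are
jittered with a 10% coefficient of variation.  Chromocenters are solid
spheres with lognormal volumes (sd = 30% of the mean); H3K9me3 foci are the
same spheres displaced by a small Gaussian offset (sd 0.1 µm), reflecting
their co-localization with pericentromeric heterochromatin; locus spots are
0.3 µm-radius spheres placed at a radial fraction drawn from a configurable
law, with directions uniform on the sphere.  Rendering: binary masks at
0.2 × 0.2 × 0.25 µm voxels (250 nm optical sectioning), a separable
Gaussian PSF (σ = 0.15 µm lateral, 0.3 µm axial), amplitude 200 over
background 5, then Poisson noise — an SNR comfortably above 5.

**Condition presets.** Counts per nucleus are Poisson with means 5 / 6.67 /
10 for control / antibody / HGF-SF1.  These conserve ~40 µm³ of total
chromocenter material per nucleus across conditions — the disaggregation
signature (more, smaller objects at constant nuclear volume) — and yield
500–1000 measured elements per condition for 100 nuclei, the scale at which
such experiments report.

**Placement.** Chromocenters are placed largest-first by rejection sampling
inside the eroded ellipsoid, followed by a pairwise repulsion relaxation.
The required surface-to-surface gap is direction-dependent — 0.5 µm for
lateral separations, 0.9 µm axial — because the elongated axial PSF bridges
small z-gaps at the detection threshold long before equivalent xy-gaps.  A
volume complement that cannot be packed is redrawn a bounded number of
times (the drawn count is kept, so count laws are honored exactly); any
residual overlap is flagged per object, and a dataset-level warning fires
when the overlapping fraction exceeds a configurable cap (default 5%).
This matters because merged objects are a real failure mode of 3D object
counting, and the truth table must make them attributable.

**What the phantom does not model.** No spherical aberration, photobleaching,
chromatic shift, depth-dependent attenuation, cell-cycle heterogeneity,
non-ellipsoidal nuclear shapes, or textured chromatin background.  Passing
the round-trip tests therefore shows the pipeline is correct for
well-resolved, blob-like objects at realistic noise; it does not certify
absolute volume accuracy on real acquisitions, where threshold choice and
PSF calibration dominate.

## Object quantification

Nuclei: global Otsu threshold on the DAPI channel, 3D hole filling,
26-connected labelling, minimum nuclear volume 50 µm³.  Objects: per-nucleus
Otsu threshold computed from voxels inside the nuclear mask (fixed-value
override available), 26-connected components of at least 8 voxels (a guard
against shot-noise singletons), clipped to the mask.  Volume is voxel count
times voxel volume; centres of mass are intensity-weighted and reported at
voxel centres, i.e. voxel (i, j, k) maps to ((i+0.5)dx, (j+0.5)dy,
(k+0.5)dz).  26-connectivity merges diagonal touches, the behaviour of
interactive 3D object pickers this module replaces; merged chromocenters
are reported, not watershed-split.

Measured volumes run 1–5% above truth, because per-nucleus Otsu settles
slightly below the blurred objects' half-maximum; the acceptance gate of
10% relative error absorbs this by design.

## Radial positioning

A signal's radial position is ‖s − c‖ / ‖b − c‖, where c is the nucleus
centre of mass and b the mask boundary along the ray from c through the
signal s.  The boundary is found by marching the linearly interpolated
binary mask in quarter-voxel steps and refining the 0.5-crossing linearly —
sub-voxel accuracy without a surface mesh.  Fractions are clamped to [0, 1];
a signal whose centre falls outside the mask (blur can push a peripheral
spot's centroid out) is rejected rather than clamped, so the outermost
shell is never silently inflated.  Shells are [0, 0.2), [0.2, 0.4),
[0.4, 0.6), [0.6, 0.8), [0.8, 1.0], with fraction 1.0 in shell 5.

Distribution comparisons use the two-sample Kolmogorov–Smirnov test: D is
the exact supremum over pooled sample points; the p-value is asymptotic
with effective size n_a·n_b/(n_a+n_b) — at the 50–70 nuclei per condition
this analysis targets, the measured type-I rate is ~4.7% at α = 0.05.
Counts per nucleus are compared with a pooled-rate z test (the classical
"proportions test" applied to objects-per-nucleus; whether the original
analyses pooled totals or compared per-nucleus counts is not recorded, and
a per-nucleus Poisson regression would be the natural alternative).  Mean
volumes and intensities use Welch's t test, which coincides with the pooled
t when variances are equal.

## Synthetic expression and gene-set statistics

The generator emits log2-scale matrices shaped like an RMA-normalized
three-condition microarray: 3 classes × 3 replicates, baseline per-gene
means N(7, 1.5²), i.i.d. Gaussian noise (sd 0.25), uniform chromosome
assignment over the mouse karyotype (chr1–chr19, X; configurable weights).
Planted sets shift their member genes by ±δ in one class; regulated sets
are planted on disjoint genes so no gene carries conflicting directions.
Probe-level effects, normalization artifacts, inter-gene correlation and
missing values are not modelled — so null calibrations here certify the
statistics under exchangeability, not robustness to array artifacts.

**Per-gene DE stand-in.** The original moderated array fit is out of scope;
differential expression between two classes uses the pooled two-sample t
test with uncorrected p < 0.05.  Pooled rather than unequal-variance t is
deliberate: with three replicates per class the Welch approximation is
conservative (measured ~3.7% type-I at nominal 5%), while the pooled test
holds its nominal size under the generator's homoscedastic noise (measured
~5.0–5.4%).  Genes with zero within-class variance are flagged and assigned
p = 1.

**Permutation heat value.** For gene set G and class c, the observed score
is mean_{g∈G} (mean expression in c − mean expression in the other
classes), equal to the class-versus-rest contrast of per-sample set means.
The class-membership indicator is permuted uniformly over samples; with S
samples and k in the class, all C(S, k) distinct splits are enumerated when
C(S, k) ≤ N (for the 3×3 design, 84 splits), otherwise N = 10000 splits are
sampled.  n_up counts permuted scores ≥ observed and n_down those ≤
observed — ties deliberately fall in both tails.  The reported value is
1 − n_up/N for non-negative observed scores and n_down/N otherwise, so
up-regulation approaches 1, down-regulation approaches 0, and both co-plot
on one scale; cells with 0.05 < p < 0.95 are flagged not significant.  The
per-set mean (rather than sum) keeps scores comparable across set sizes on
a shared color scale, and permuting sample labels (rather than genes)
preserves inter-gene correlation.

**Chromosome density and GO.** The per-chromosome ratio is (DE genes on the
chromosome) / (genes mapped to the chromosome); DE genes missing from the
map are returned explicitly, never dropped.  GO over-representation is the
upper-tail hypergeometric probability with Holm step-down correction across
categories; genes without annotation are excluded from both universe and DE
list.

## Numerical choices

Permutation tie comparisons use a relative tolerance of 1e-9 so that the
observed split's own score registers as a tie in both tails.  Sub-voxel ray
marching steps at one quarter of the smallest voxel edge.  A signal exactly
at the nucleus centre has undefined direction and returns fraction 0.  KS
p-values are clipped to [0, 1].  Seeds flow from one root through named
CRC32 substreams (`pipeline.stage_seed`), so adding a stage never perturbs
another stage's draws.

## Problem sizes

Round-trip acceptance checks run 100 nuclei per condition (≈500–1000
chromocenters each), 20 replicate datasets of 60 nuclei for the radial
modal-shell check, 1000 replicates for KS calibration, and 10000 genes for
DE calibration — sizes chosen to put Monte-Carlo error well inside each
stated tolerance while keeping a full run in minutes on one core.

## Known limitations

Absolute volume agreement with interactively thresholded commercial
software is calibration-dependent; only relative condition differences are
claimed.  Merged chromocenters are counted as one object.  The permutation
statistic's null is exchangeability of samples across classes; with only 84
distinct splits, attainable p-values are quantized at 1/84.  Table-level GO
results depend on the annotation map supplied; no ontology propagation is
performed.
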