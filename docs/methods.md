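# Methods

This note records the models, conventions and numerical choices behind
`canopygp`, and what the synthetic testbeds do and do not establish.

## Height extraction

**Grids and windows.** Rasters are north-up, row 0 at the top; the origin
is the field coordinate of the north-west corner of pixel (0, 0).  A plot
rectangle (north-west corner, width east, height south) maps to the pixel
window anchored at the pixel containing its origin corner and spanning
`floor(extent / resolution)` pixels per axis.  This floor convention is
what makes a 0.72 m x 1.8 m plot at 13 mm/px exactly 55 x 138 px and its
0.24 m x 0.6 m central block 18 x 46 px.  For the 3 x 3 partition of a
length not divisible by 3, the centre cell gets `floor(L/3)` pixels and
the remainder goes to the discarded margins — biasing the *kept* region
small, since the margins exist precisely to be thrown away.

**Differencing and percentiles.** The height raster is canopy minus
ground, masked wherever either input is masked; negative values are kept
(they are ground-model noise, and clamping would bias low percentiles).
Percentiles use linear interpolation between order statistics (rank
h = (n-1)p/100), the convention of mainstream statistical environments.  A
central block with fewer than 50% valid pixels (configurable) yields a
missing value, never a silent zero.  The two DSMs are required to be on an
identical grid; resampling is deliberately out of scope and left to the
caller.

## Replicate selection and diagnostics

Plot-level PH_R is the mean of the sampled plants (2 of 5 by default).
Replicate selection works per accession x treatment on exactly two
complete replications; ties select replication 1 for reproducibility.  The
adjacency diagnostic uses the 8-neighbourhood on the plot grid; border
plots use the neighbours they have (N < 8) rather than being dropped.  The
comparison of the dependent correlations r(lower, PH_R) vs r(mean, PH_R)
uses a paired bootstrap over accessions (default 10,000 seeded resamples,
degenerate resamples redrawn, ties counted half) — the two correlations
share the PH_R vector, so independent-sample tests do not apply, and the
bootstrap avoids committing to a parametric null.

## G-BLUP

GRM: VanRaden method 1 on mean-imputed dosages, markers below 1% minor
allele frequency dropped.  A ridge of 1e-6 x mean(diag G) is added before
any inversion or eigendecomposition.  REML profiles the restricted
log-likelihood over delta = sigma_e^2/sigma_g^2 after one
eigendecomposition; the 1-D bounded search runs on log delta in [-10, 10]
with tolerance 1e-8, and solutions within 1e-3 of a bound are flagged
(`boundary=True`, h^2 ~ 0 or ~ 1) rather than raised.  Prediction of
held-out accessions is the conditional mean; it is algebraically identical
to ridge-regression BLUP of marker effects with penalty
`denominator x delta`, an identity the test suite verifies to 1e-8 as an
independent oracle, alongside a 41-point grid-search oracle for the REML
optimum.

**A cross-validation caveat.** Under a (near-)zero-heritability phenotype,
REML lands on the sigma_g^2 = 0 boundary and every LOOCV fold predicts its
training mean; the prediction vector is then near-constant and its only
dependence on the held-out value is the O(1/n) leave-one-out mean shift,
so the Pearson correlation degenerates towards -1 while carrying no usable
information.  This is a property of cross-validation with per-fold
refitting, not of this implementation.  Where a no-skill check is needed,
the stable measures are the regression slope cov(pred, y)/var(y) and the
collapse of prediction variance; accuracy r is meaningful whenever
predictions have real variance (any appreciable h^2).

## The synthetic campaign

The generator emulates a replicated two-treatment trial: 172 accessions
(151 genotyped), 2 fertilization levels x 2 replications = 688 plots of 5
plants at 0.3 m spacing in 0.72 m x 1.8 m plots, 13 mm/px rasters, ruler
measurement of 2 plants per plot (1,376 plants).  All randomness flows
through named child streams of one seed, so every artefact is a pure
function of (config, seed).

**Genomes.** Ancestral allele frequencies uniform on (0.05, 0.5);
accessions belong to one of 8 Balding-Nichols subpopulations with
divergence Fst = 0.3, and dosages are binomial(2, p) per accession.  The
structure is essential, not cosmetic: germplasm core collections are
strongly structured, and an unrelated panel (Fst = 0) caps LOOCV accuracy
near 0.15 at n = 151, too low for any of the prediction phenomena to show.
Fst = 0.3 places simulated LOOCV accuracy around 0.6, in the range field
studies of this design report.  100 of the 2,000 markers are causal with
normal effects, rescaled so genetic values have the configured sd (0.5 m).

**Phenotypes.** Plant height = mean height (2.0 m) x treatment factor
(0.8 under low fertilization) + accession genetic value + plot effect +
per-plant noise (sd 0.08 m), truncated at 0.2 m.  The plot-effect variance
is set so plot-mean heritability equals the configured h^2 (0.5) within a
treatment.

**Scenes.** Ground is a tilted plane (~0.2 m drop across the field) plus
per-pixel noise; the canopy and ground dates get independent noise draws
(presets: 0.05 m for the near-infrared camera profile, 0.09 m for RGB).
Each plant is a flat-topped cone: full height out to 60% of its footprint
radius, linear decay to zero at `base_radius + spill x height`.  The
height-dependent radius is the contamination mechanism — taller plants
overhang farther into neighbours.  Sparseness is modelled as per-pixel
canopy dropout: a fraction 1 - cover of pixels fall through to bare
ground, emulating photogrammetric failure on sparse canopies.  Defaults
cover = 0.75 and spill = 0.35 m/m make overhang contamination the dominant
(one-sided, upward) error; at much lower cover the dropout noise dominates
instead and, being one-sided *downward*, it inverts the lower-replicate
rule — a regime the field data contradicts.  The crown shape itself is a
modelling convenience; only its consequences (sparse returns, spill-over)
carry meaning.

**What passing tests show.** The simulator reproduces the *mechanisms* —
contaminated plots have elevated r2, lower-replicate selection beats the
mean, prediction vectors agree more than raw phenotypes — not any field
campaign's numeric values.  It omits real-world features including spatial
fertility gradients beyond a plane, lodging, structure-from-motion
artefacts with spatial correlation, linkage disequilibrium, and
genotype-by-environment interaction; conclusions about those require real
data.

## Problem sizes

Default analyses run the full 688-plot design.  The test-suite and the
reproduction script use 5 cm rasters and panels of 40-151 accessions with
a few hundred markers — sizes chosen so the whole suite runs in under a
minute while keeping every statistical check well-powered; the geometry
worked examples are resolution-exact regardless.
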