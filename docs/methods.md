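# Methods

`epibind` packages the quantitative procedures used to characterise a
receptor-ligand interaction discovered in a cell-conjugation screen
(B7-1 binding the neurotrophin receptor p75^NTR^) and its downstream
effects on neuronal morphology: flow-cytometry conjugation quantification,
Hill-model titration and competition fitting, mutagenesis epitope mapping
on structures, and fluorescence-image scoring of dendrites and synapses.
Because no raw flow or image data accompany such studies, the package
includes first-class synthetic generators for every input class, each
carrying ground truth sufficient to score the estimators.

## Binding quantification

**Quadrant gating.** Events are (green, red) intensity pairs in arbitrary
fluorescence units. An event is positive in a channel iff its intensity is
*strictly* greater than that channel's threshold; the four quadrants
partition the events. Percent bound is `100 · n_double_positive / n_total`
(double positives are cell-cell conjugates). Default thresholds come from
the 99.5th percentile of a negative-control table per channel; fixed
thresholds are accepted as an override. The denominator counts *events*;
whether conjugates should instead be resolved into constituent cells is
ambiguous in practice and events were chosen for determinism.

**Relative binding and loss classification.** A mutant's relative binding
is `R = 100 · P_mut / P_wt` per partner; loss is `L = 100 − R`. A
mutant × partner pair is assigned the highest of the thresholds
{25, 50, 70} that `L` *strictly* exceeds ("greater than"), so `L = 25`
is `none`. A loss call is flagged partner-specific when it is the mutant's
only partner with any loss call — the signature used to separate true
interface residues (e.g. a p75-specific loss with retained CTLA-4/CD28
binding) from folding defects.

**Hill fitting.** The model is `Y = Bmax · X^h / (Kd^h + X^h)`, with
`Y(0) = 0` and the fitted curve passing through `Bmax/2` at `X = Kd` by
construction; `Kd` is reported as EC50 (the two names denote the same
fitted parameter here). Fitting is nonlinear least squares with
multi-start: `Kd` starts on an 8-point log-spaced grid spanning the
nonzero concentration range, `h ∈ {0.5, 1, 2, 4}` (apparent coefficients
above 5 occur with dimeric Fc reagents, and single starts are fragile at
high cooperativity), `Bmax = max(Y)`. Bounds: `Bmax ∈ (0, 10·max Y]`,
`Kd ∈ (0, max(10⁴ nM, 100·max X)]`, `h ∈ (0.1, 10]`. The best candidate
by residual sum of squares wins; if no start converges the best candidate
is returned with `converged=False`. The fitted `h` is reported without
mechanistic interpretation: with dimeric fusion proteins it reflects
avidity as much as cooperativity.

**Competition profiles.** Signals are normalised so the zero-competitor
bin is exactly 100%. Inhibition is declared only when the Spearman rank
correlation between competitor concentration and signal is significantly
negative (one-sided, α = 0.05); only then is a descending four-parameter
logistic fitted and an IC50 reported. A flat profile (isotype control)
yields "no inhibition" with IC50 undefined. The IC50 is an optional
summary, not a binding constant.

**Suppressor rescue.** In a receptor-mutant × ligand-mutant matrix
normalised to the WT:WT pair = 100, a pair is a rescue when its cell
exceeds the rescue threshold (default 50% of WT:WT) *and* the ligand
mutant alone (vs the WT receptor) has lost binding. Charge-reversal
rescues imply spatial proximity of the mutated residues across the
interface.

## Epitope mapping on structures

**Solvent accessibility.** Shrake–Rupley quadrature with a 1.4 Å water
probe and 960 golden-spiral points per atom (two-sphere benchmark error
< 2% at this density); per-atom exposed areas are summed per residue and
divided by Gly-X-Gly theoretical maxima (Tien et al. 2013) to give
relative SASA. Coordinates are first rotated into a deterministic
principal-axis frame (third-moment sign convention), which makes the
quadrature result exactly invariant under rigid transforms of the input.
Exactly coincident equal-radius atoms are resolved by letting the
lower-index atom keep the sphere, so duplicated atoms do not double-count
area. Surface residues for scanning mutagenesis default to relative
SASA > 0.2. Whether accessibility should be computed on a monomer or a
physiological dimer is left to the caller (pass the assembly you mean).

**Annotation.** Per-residue loss values are written into the
temperature-factor column of a PDB file for visualisation; round-trips are
lossless at that column's two decimals. Residue-numbering offsets between
expression construct and crystal numbering are an explicit argument,
never guessed.

**Clustering test.** The statistic is the mean pairwise Cα distance among
flagged residues (Cα only, for robustness to side-chain disorder); the
null re-draws equally many residues from the background set. When
C(|background|, |flagged|) ≤ 10⁵ the null is enumerated exhaustively and
p is the exact fraction of subsets at least as tight as observed;
otherwise 10,000 seeded draws give the standard permutation estimate
`p = (1 + #{null ≤ obs}) / (1 + n)`. Small p supports spatial clustering
of loss residues into a coherent binding face.

## Image quantification

All scoring operates on 8-bit images; other bit depths are min-max
rescaled with a warning (the continuity formula divides by 255).
Coordinates are 0-based, x right, y down; dendrite paths are open
polylines supplied by the user (tracing is manual, as in practice).

**MAP2 continuity.** The MAP2 channel is background-subtracted
(rolling-ball, default radius 50 px, the common ImageJ setting) and
thresholded to {0, 255} (Otsu by default, fixed value as override; pixels
strictly above threshold are on). The profile along a path is sampled at
1-pixel spacing with nearest-pixel lookup — chosen over interpolation so
profiles of binary images stay binary — giving `round(arc length) + 1`
samples. The continuity score is

    C = 100 · Σ profile / (255 · n_samples)

i.e. the percent of the traced path carrying signal; the denominator uses
the sample count (pixel metric), with physical µm lengths reserved for
densities. A fragmented (punctate) MAP2 profile scores low; `1 − C/100`
estimates the generator's gap fraction with |bias| < 0.05 across the
sweep g ∈ {0, …, 1}.

**Puncta densities.** Puncta are 8-connected components of the
thresholded marker channel with area in [2, 200] px²; a punctum belongs
to a path when its centroid is within 1 µm of the polyline (inclusive).
Density is count per µm of path. Connected-component counting cannot
split two puncta that land within a blob-merge distance of each other, so
it is only unbiased when puncta are resolvable — which is also the
physical situation it measures (synapses are discrete, non-overlapping
objects). The generator therefore enforces a minimum punctum separation
(see below), and flags datasets where that constraint could not be
honoured.

**Contact paths.** A path is in contact with a (ligand-presenting) cell
mask when any 1-px-spaced sample lies within the dilation radius of the
mask, boundary inclusive, evaluated on a Euclidean distance transform.

**Spine densities.** Golgi-style tables (group, neuron, count, segment
length) give per-neuron densities `count / length` and per-group
mean ± SEM.

## Group statistics

`group_compare` is classical fixed-effects one-way ANOVA with pairwise
two-sample t-tests Bonferroni-multiplied by the number of comparisons
(capped at 1). Observations are treated as independent within groups;
hierarchical structure (dendrites within neurons within cultures) is not
modelled — a deliberate simplification matching common practice, and a
known limitation. Effect sizes are reported as
`Δ = 100 · (1 − treated/control)` on group means.

## Synthetic generators

All generators take one explicit seed and are bit-reproducible; no global
RNG state is used. Ground truth (event labels, per-pixel masks, puncta
centroids, true densities) always suffices to compute the estimand
without re-running the generator.

- **Flow events**: two-component log-normal mixtures per channel
  (standard cytometry intensity model). A latent fraction `p` of events
  is double-positive; the rest are single-positive, split evenly between
  colours. Defaults: positive median 5000 AFU, negative 50 AFU,
  log-sigma 0.5.
- **Titrations**: exact Hill curves with multiplicative Gaussian noise
  (CV), matching fluorescence-bead readouts; `cv = 0` is exact.
- **Dendrite images**: unit-step random-walk paths (60 µm at 0.1 µm/px in
  288² frames) drawn at 220 ADU over N(10, 3) background, clipped to
  [0, 255]. MAP2 gaps are removed as contiguous segments (default 4)
  totalling a fraction `g` of the path — fragmentation, not per-pixel
  dropout, mimicking the punctate degeneration phenotype. Each puncta
  channel draws a Poisson(λ·L) number of puncta (λ per µm of path) and
  places them uniformly along the path as 1 px-radius disks under a
  minimum centre separation of `2·radius + 2` px — just beyond the
  8-connectivity merge window — because synaptic puncta are discrete
  objects that do not superimpose; a pure position-Poisson placement
  would merge ~15% of puncta at 0.5/µm into single blobs and bias any
  component-counting detector. When the constraint cannot be satisfied
  (λ far above the packing limit) puncta are placed unconstrained and a
  warning flag is set once more than half of placements collide. Not
  modelled: PSF blur, chromatic shift, uneven
  illumination, crossing dendrites from other cells — so passing tests
  demonstrate estimator correctness on clean geometry, not robustness to
  real microscopy artefacts.
- **Spine counts**: per-neuron Poisson counts with mean
  `length × multiplier × base density`. Base density defaults to
  1.0 spines/µm (a typical pyramidal apical value; configurable — no
  baseline is implied by the effect sizes studied), segments 100 µm,
  72 neurons/group (4 animals × 18 neurons).
- **Mutant screens**: true relative binding per mutant × partner with a
  WT row pinned at 100 before multiplicative CV noise; observations are
  floored at 0.

## Problem sizes and tolerances

The shipped checks use sizes that resolve the effects they test: Hill
round-trips use 13 concentrations (noiseless recovery to 1e-4 relative);
the puncta-decline comparison uses 30 images per arm (~30 puncta each),
judged within 3 standard errors of the group-mean ratio; spine tables use
72 neurons per group; the continuity sweep uses 4 images per gap
fraction. Optimiser tolerances are scipy defaults; the multi-start grid,
not the tolerance, is what protects against local minima at high `h`.

## Known limitations

- Otsu thresholding misbehaves on images with no true signal (it then
  splits noise); use a fixed threshold for near-empty channels.
- Connected-component puncta counting cannot split merged puncta; on
  real images with densely packed or overlapping synapses, counts are
  conservative.
- The competition IC50 is a descriptive 4PL parameter, not a Ki.
- No compensation/spillover correction and no doublet discrimination
  beyond two-channel quadrants.
- SASA reference maxima cover the 20 standard residues; nonstandard
  residues get absolute SASA only (relative = NaN).
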