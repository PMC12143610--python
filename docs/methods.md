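# Methods

This note documents the models, conventions and numerical choices the
package implements, what the synthetic-data generators do and do not
emulate, and the simulation sizes the test suite and the acceptance
script use.

## Compartment-restricted focus calling

**Rule.** A connected component of above-threshold dsDNA signal is
accepted as a cytoplasmic focus iff (i) area ≥ `min_area` (default
5 px, inclusive — "area" is the pixel count of the component, not a
diameter), (ii) no pixel of the component lies on a nucleus label, and
(iii) its centroid and at least 50 % of its pixels lie inside one cell
territory. Rejection reasons are assigned with the precedence
`in_nucleus` > `too_small` > `outside_cytoplasm`: nucleus contact
dominates because the nuclear dsDNA signal is rendered/recorded at or
near sensor saturation and must never leak into cytoplasmic counts.
`unassigned` marks the rare component that satisfies the pixel-majority
rule for some territory while its centroid falls outside every
territory.

**Segmentation.** Nuclei: global Otsu on the DNA counterstain,
8-connected components, minimum area 50 px, no declumping (touching
nuclei merge; the generator keeps nuclei separated, and declumping real
clumps would need a dedicated step that is out of scope). Cell
territories: the F-actin stain is Otsu-thresholded, merged with the
nucleus pixels for contiguity, and flooded from the nuclei by a
watershed on the distance-from-nucleus map (a nearest-seed partition);
stained regions not connected to any nucleus stay unlabelled, and
nucleus pixels are removed from the returned cytoplasm mask. Cells
whose territory touches the image border are flagged and excluded from
per-cell statistics by default (their cytoplasm is truncated).

**dsDNA detection threshold.** median + 5·MAD (MAD scaled by 1.4826 to
be a normal-consistent σ estimate), computed over the whole channel.
Otsu is deliberately not used here: the saturated nuclei put a large
mass at the top of the histogram while genuine foci occupy a tiny pixel
fraction, so a robust location/scale rule anchored on the background is
the stable choice. On a noise-free background the MAD is 0 and the
threshold degenerates to the background median, which recovers planted
pixel sets exactly.

**Conventions.** 8-connectivity everywhere; 0-based (row, col)
coordinates; integer pixel areas; label 0 = background; deterministic
labelling in raster-scan order of each component's first pixel.
Background correction (subtracting the 0 Gy group mean of the same
radiation quality) may produce negative corrected means; they are
reported as computed, not clipped.

## Synthetic fields

Cells are elliptical nuclei (semi-axes 9×6 px) inside larger elliptical
territories (margin 14 px), placed by rejection sampling without
overlap; geometry is deliberately simple because the generator's job is
to be an exact oracle for the counting rules, not to mimic 4T1
morphology. Per cell, cytoplasmic foci are planted Poisson with mean
`b + s_q·D` (defaults b = 1 focus/cell at 0 Gy — the unirradiated
background rate is a free model parameter with no canonical value —
and s_q per simulated quality). Planted focus pixel sets are digital
disks of exact requested area (5–9 px by default, configurable down to
3 px to exercise the size cutoff from below), kept ≥ 4 px away from
nuclei, ≥ 2 px from the cell edge and ≥ 2 px (Chebyshev) from each
other so that blur never merges plants or bleeds them across
compartment boundaries. The dsDNA channel renders the nuclear area at
3000 of a 4095 sensor maximum (saturation is exercised explicitly by
setting it to 4095), foci at +150 over a background of 10; optional
Gaussian PSF blur (σ = 0.7 px) and additive Gaussian read noise
(σ = 8) follow, then clipping to the sensor range. An optional
per-cell rate of nucleus-straddling plants stress-tests the
nucleus-exclusion rule.

Not emulated: realistic optics (no confocal PSF), shot noise,
autofluorescence gradients, cell-to-cell intensity variation, touching
or overlapping cells, micronuclei, or 3-D stacks. Passing the imaging
tests therefore demonstrates correctness of the counting *rules* and
robustness to saturation/noise at the stated SNR — not segmentation
performance on real micrographs.

One integer seed plus the field index feeds a numpy `SeedSequence`, so
every generator output is bit-reproducible and fields are independent
substreams.

## Dose–response fitting

Fit observations are per-dose group means weighted by 1/SE² (matching
how mean ± SD dose–response data are presented); the slope/intercept
covariance uses the standard WLS estimate with estimated residual
scale. A free intercept is kept even after background subtraction
(through-origin is available via argument). Slopes are compared with
`t = Δslope / √(SE₁² + SE₂²)` and Welch–Satterthwaite df from the two
slope variances and residual dfs; because the SEs carry estimated
scale at small df, "within 3 SE of truth" is a ~96 % event per fit
(t₄), which is how the recovery tests assert it (coverage in
aggregate, not per replicate).

The saturating model `y(D) = P − (P−1)·exp(−kD)` is anchored at
`y(0) = 1` because the fold change of the unirradiated control is 1 by
definition. Starting values: P from the mean response at the largest
dose, rate from a small grid `{0.5, 2, 8}/D_max`; best converged start
wins; non-convergence from every start raises with diagnostics. A flat
series at 1 is returned as P = 1 with the rate flagged unidentifiable
rather than erroring. Curve families are compared with the
extra-sum-of-squares F-test (shared (P, k) vs per-group), which assumes
iid additive errors — under multiplicative (signal-proportional) noise
its type-I error is inflated, so calibration checks use the additive
model. RSS values below 1e−12 of the response's sum of squares are
treated as exact fits (F = 0) to avoid forming a noise-over-noise
ratio.

`compare_groups` is an unpaired two-tailed Welch t-test; degenerate
variances are handled by convention (identical constant samples →
p = 1; constant samples with different means → p = 0). Factorial
layouts get a two-way type-II ANOVA with interaction plus Tukey HSD
over the crossed cell means.

## Survival and RBE

Plating efficiency is computed per replicate (each replicate is an
experiment with its own 0 Gy flask) and each replicate's doses are
normalised to its own PE before pooling across replicates. The LQ fit
is (weighted) least squares of `ln SF = −(αD + βD²)`, linear in (α, β),
solved by non-negative least squares — the non-negativity constraint is
common radiobiology practice and keeps pure-exponential data at the
β = 0 boundary instead of going negative. The 0 Gy point (SF ≡ 1)
carries no information and is dropped; non-positive SF values (e.g.
zero-colony flasks at high dose) cannot enter the log and are excluded
with a warning. Parameter SEs come from the weighted normal-equations
covariance scaled by residual variance; when a parameter sits on the
boundary its SE should be read with care. Iso-survival doses are the
positive root of `βD² + αD + ln(level) = 0` (linear fallback at β = 0)
and RBE is the ratio of reference to test dose at that level, computed
from fitted curves (not interpolation between measured points).

## Expression analytics

**ΔΔCt.** Technical replicates are averaged to one Cq per (sample,
gene) first, then samples averaged per condition. The reference value
is the geometric mean of the two reference genes' mean Cq values —
following the usual phrasing of the method literally on the Cq scale;
the arithmetic mean of Cq (equivalent to a geometric mean on the
expression scale) is available via `ref_combine="arithmetic"`. A
consequence worth knowing: with the geometric-mean-of-Cq convention, a
global Cq shift cancels exactly only when the reference genes are
stable across conditions (the √(R₁R₂) term is nonlinear); in
arithmetic mode the cancellation is unconditional. Reference-gene
stability is reported descriptively (SD of mean Cq across conditions,
flag above 0.5 cycles) — not a geNorm/NormFinder ranking.

**DE screen.** Fold change is the ratio of raw group means (0/0 → 1,
x/0 → ∞), so boundary semantics are exact: FC = 1.5 passes. The
pseudocount (0.1) enters only the log2 transform for the t-test
(pooled-variance, unpaired, two-tailed). No multiple-testing correction
enters the DE flag — the flag mirrors the classic printed criteria —
but a Benjamini–Hochberg FDR column is emitted for transparency.
Z-scores standardise each gene row by its sample SD (ddof = 1, the
`scale` convention); constant rows are zeroed and flagged.

## Pipeline

One global seed is expanded into per-stage, per-quality substreams.
The demo experiment runs two qualities with foci slopes 0.1 vs 0.3
foci·cell⁻¹·Gy⁻¹ over 0–12 Gy (5 dose levels × 5 fields × 8 cells per
field), LQ parameter sets (α = 0.2 Gy⁻¹, β = 0.02 Gy⁻²) vs (0.55,
0.03) — chosen to give an RBE near 2 at 10 % survival — with 3
replicate flasks of 1000 seeded cells, and a 200-gene expression matrix
with a 10 % DE fraction. All artifacts are plain CSV/TSV/JSON written
deterministically; running the same config and seed twice produces
byte-identical files.

## Simulation sizes used by tests and the acceptance script

Clean-field exactness: 20 fields × 10 cells, planted areas 3–12 px,
0.5 nucleus-straddling plants per cell. Detection performance: 20
fields at the default SNR (≈ 650 planted foci). Slope inference: 6
dose levels × 200 cells per dose; power over 200 replicates, type-I
error over 1000. LQ/RBE: 3 flasks × 1000 cells at 6 dose levels per
quality; RBE distribution over 200 replicates. DE screen: 50–500 genes,
3 + 3 samples. These sizes make the Monte-Carlo bounds in the tests
sharp at interactive runtimes.

## Known limitations

* No declumping of touching nuclei and no handling of overlapping
  cells; the generator avoids creating them.
* The robust dsDNA threshold assumes foci + nuclei occupy a small pixel
  fraction; fields dominated by signal would shift the median.
* LQ SEs at the α = 0 or β = 0 boundary are approximate.
* The plateau-model F-test inherits the iid-error assumption; use
  weighted fits or transform if errors scale with signal.
* ΔΔCt assumes perfect primer efficiency (no Pfaffl correction).
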