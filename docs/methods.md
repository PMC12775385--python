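# Methods

`spasquant` simulates dynamic-ventilation CT (DVCT) of a compressible
sponge phantom and quantifies the simulated peripheral air spaces
(SPAS) it contains, so that the relative merits of an
ultra-high-resolution (UHR, 0.25 mm pixel) and a normal-resolution
(NR, 0.5 mm pixel) acquisition mode can be studied end to end without
any physical data. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic results do and do
not show about real acquisitions.

## Phantom model (`spasquant.phantom`)

A cross-section is a 60 x 35 mm rectangle of homogeneous sponge matrix
containing `n_spas` non-overlapping, axis-aligned elliptical air
spaces. Defaults (chosen once, as the package's standing study
conditions):

| parameter | default | rationale |
|---|---|---|
| `n_spas` | 110 | dense porous section; in-gate (0.5-7 mm^2) count ~65 at 0% |
| `area_range_mm2` | 0.2-15, log-uniform | spans below and above the counting gate; log-uniform mirrors the broad pore-size spectrum of cellulose sponge |
| `aspect_range` | 1-3, long axis transverse | reference measurements of real sponges show transverse > longitudinal diameters |
| `min_gap_mm` | 0.4 | thick walls between lumens |
| `air_hu` | -1000 | air |
| `target_mean_hu` | -776 | measured mean density of the real sections |

The matrix CT number is not set directly: it is solved from the
air-area fraction so that the two-level section mean equals
`target_mean_hu` (one scalar equation). With the default geometry the
air fraction is ~0.15 and the calibrated matrix lands near -737 HU.
Two consequences are intentional. First, the rendered uncompressed
section mean falls inside the measured range (-816.5 to -729.9 HU) by
construction. Second, the air/matrix contrast stays large enough
(~260 HU) that the automatic threshold sits many noise standard
deviations away from the matrix gray level; a sparse-hole phantom
(air fraction ~5%) would calibrate its matrix to ~-765 HU and the
threshold would then slice into the matrix noise tail, flooding the NR
counts with speckle — unlike anything in the real data. The large
never-closing pores above the 7 mm^2 gate serve the same purpose at
high compression: they keep the gray-level histogram bimodal at every
phase so the threshold stays pinned in the air/matrix gap.

Placement is rejection sampling, largest ellipse first, with a
conservative bounding-circle criterion guaranteeing `min_gap_mm` of
wall between any two lumen boundaries; generation fails loudly after
`10 * n_spas` rejections. Everything is deterministic given the seed.

### Compression law

Uniaxial compression by `c` percent scales the section length and all
longitudinal center coordinates by `1 - c/100`. Air spaces close
faster than the bulk: each longitudinal diameter scales by
`1 - kappa*c/100` with `kappa = 1.5`; transverse diameters are
unchanged; areas are recomputed. A lumen whose longitudinal diameter
falls below `closure_mm = 0.75` is flagged closed — retained in the
truth, removed from the rendered air set.

No deformation law for individual pores is available from
measurements, so `kappa` and `closure_mm` are free parameters of the
generator. The closure threshold is deliberately thick-walled: with
log-uniform areas, pure shrinkage leaves the in-gate count almost
unchanged (the size distribution is scale-invariant inside the range),
so lumen closure is the mechanism that makes counts fall with
compression. At 0.75 mm most in-gate lumens close by ~40% compression,
matching the observation that SPAS become unrecognizable near maximal
compression; at the originally considered 0.3 mm almost nothing
in-gate ever closed and count-versus-compression slopes were flat.

## Imaging chains (`render_image`)

Rendering is: (1) area-weighted rasterization of the two-level HU
field at >= 4x supersampling per axis; (2) isotropic Gaussian PSF with
sigma fixed by the 5% MTF frequency via
`MTF(f) = exp(-2 pi^2 sigma^2 f^2) = 0.05`, i.e. sigma = 0.309 mm for
UHR (1.26 cyc/mm) and 0.639 mm for NR (0.61 cyc/mm); (3) a 1-D box
kernel along the longitudinal axis of length equal to the per-image
motion blur (1.3125 mm at the 4-s cycle, 1.05 mm at 5 s, both derived
from the 15-mm stroke, half-cycle travel, 0.35-s rotation and half
reconstruction); (4) additive white Gaussian noise with sd equal to
the 20-mA noise magnitudes (UHR 14.6 HU, NR 17.8 HU). The 10% MTF
values are not used: they are printed in a different unit than the 5%
values and cannot be reconciled. The noise-power-spectrum shape is not
modeled; see Limitations.

The REFERENCE chain stands in for the optical (smartphone) gold
standard: a 0.05 mm grid, noiseless, with a PSF narrower than one
pixel (applied as identity below a quarter pixel). Perspective,
lighting and lens distortion are not modeled.

## Windowing and moments binarization (`physics`, `particles`)

CT images are converted to 8 bits under a lung window (level -650,
width 1500 HU; a linear map with half-up rounding and clipping — the
window is stated elsewhere as "width -1500 / level 650", which is read
as a sign/order typo for the conventional lung window). Air maps to
gray level 68 at -1000 HU.

The automatic threshold is moment-preserving (Tsai) thresholding in
discrete form. A threshold `t` splits levels into `g <= t` and
`g > t`; replacing each class by one representative level while
matching the histogram mean and variance exactly leaves the third
moment as the selection criterion, and the returned `t` is its
mismatch minimizer (ties to the smaller `t`). This discrete argmin is
preferred over the textbook `p0`-fraction lookup because on discrete
histograms the lookup and the actual moment-preservation objective
disagree on ~2% of random histograms; the analytic route survives as
an independent oracle in the tests. Degenerate (zero-variance)
histograms fall back to the mean level. Binarization takes air (dark)
as the white foreground phase; particle counting uses 8-connectivity,
physical areas are `pixel count * pixel_mm^2`, holes are not filled,
border-touching particles are kept, and the counting gate is
half-open: total in `[0.5, 7)` mm^2 with sub-bins
`[0.5,1), [1,2), [2,4), [4,7)`.

## Betti-number sweep (`homology`)

For a binary image, `b0` is the number of 8-connected foreground
components and `b1` the number of 4-connected background components
not touching the border. The complementary (8, 4) pair is required
for a consistent digital topology, verified in the tests against
flood-fill and Euler-characteristic (V - E + F on the closed-pixel
complex) oracles on all 512 3x3 images and random larger ones.
"Continuous binarization" is an exhaustive sweep of all 256 integer
thresholds of the windowed image (foreground `gray < t`, so the sweep
is a filtration); `peak_b0` is the maximum of `b0`, tie-broken to the
smallest threshold. By default no component-size floor is applied to
`b0` (the statistic is described as counting isolated pixels), so on
noisy images `peak_b0` is dominated by noise speckle at some threshold
inside the matrix peak — this reproduces the known noise sensitivity
of the statistic and still orders UHR above NR; an optional
`min_area_mm2` floor (e.g. the 0.5 mm^2 gate) is available and is what
makes noiseless per-phase `peak_b0` series cleanly non-increasing.

## FWHM sizing (`sizing`)

Diameters are measured as the full width at half maximum of the
intensity trough along longitudinal and transverse profiles through
the (ground-truth) SPAS center, sampled bilinearly at a quarter pixel.
Profile half-length is twice the true diameter, capped at 6 mm and
clipped to the image. The trough minimum is searched within half the
true diameter of the center so a deeper neighbouring lumen cannot
hijack the measurement. The baseline is the wall level both flanks
actually reach — the smaller of the two per-side maxima of a
median-of-5-smoothed profile. (A quantile-based baseline was tried
first and fails systematically in densely packed sections, where the
outer quartiles of the window often lie inside neighbouring lumens.)
The half level is midway between baseline and minimum; crossings are
located by linear interpolation walking outward from the minimum. A
measurement is "not measurable" when the trough depth is below 50 HU
or a crossing is missing — mirroring the unmeasurable cases footnoted
in the original tables. Elliptical area is `pi/4 * d_long * d_trans`.

Deviations are CT-minus-REFERENCE, paired per (SPAS, phase), with the
compression-percentage mismatch carried as a covariate. Trackable
SPAS for trajectories are ground-truth-selected (open at every phase,
in-gate at 0%), standing in for the radiologists' visual selection;
the same FWHM operator measures both CT and REFERENCE, which isolates
resolution effects (the original study measured its reference on
binarized optical images instead).

## Mixed model (`stats`)

Counts, peak-b0 values and sizes from one cross-section are
correlated; the model is a random intercept per cluster — equivalent
to compound symmetry for non-negative intra-class correlation
(negative ICC is out of scope). REML is profiled to a 1-D bounded
search over `log(sigma_b^2/sigma_e^2)`; at each candidate the fixed
effects are solved by GLS using the closed-form Woodbury inverse of
`I + lambda J`. Inference on fixed effects uses the empirical
(cluster-robust sandwich) covariance with a single `G/(G-1)`
correction and a standard-normal reference; no Satterthwaite or
Kenward-Roger degrees-of-freedom correction is applied, a known
small-sample difference from SAS-style t-type inference that the
simulations bound: at 14 clusters the interaction CI covers a true
-2.1 slope difference in ~95% of 200 replicates and the null Wald
test rejects at ~6.5% for nominal 5%. Estimation is validated against
OLS (boundary case), closed-form balanced ANOVA estimators, and
`statsmodels` MixedLM. No multiplicity adjustment is applied.

## Experiment driver (`experiment`)

The default design mirrors the study bookkeeping: 14 cross-sections
x 4 phases (0, 12, 24, 35% — the 0-35% range is measured, the interior
values are a modeling choice) x 2 CT modes x 2 cycle durations = 224
CT images, plus one REFERENCE render per (section, phase). Cycles
differ only through the motion-blur length, so any cycle effect in
the outputs emerges from blur rather than from a hard-coded offset.
Per-cell noise seeds are spawned from `(master_seed, section, phase,
mode, cycle)`, so extending the design never perturbs existing cells.
Images are written as 16-bit TIFF (HU + 32768) with JSON sidecars;
tables as CSV; a summary JSON carries ensemble slopes, contrasts and
ordering checks.

## Problem sizes used by the test and acceptance runs

The test suite uses the full 14-section default design once, 20-seed
ensembles for the ordering properties, 200-replicate simulations for
the mixed-model checks, 1000 random histograms and 712 binary images
for the operator oracles. `scripts/acceptance.py` re-runs the full
default design and the model simulations from scratch at the given
seed.

## What the synthetic results show — and what they cannot

The generator reproduces the *mechanisms* by which resolution matters:
partial-volume loss of small lumens at the NR pixel/PSF scale, noise
gating of the counting threshold, blur-floored FWHM measurements. The
headline orderings are reproduced robustly across seeds: more counted
SPAS and higher peak b0 on UHR at every phase, a steeper (more
negative) count-versus-compression slope on UHR, and smaller
longitudinal-diameter deviations from the reference on UHR.

They are *orderings*, not the study's empirical coefficients: real
Table-level values depend on the physical sponges and are not
recoverable from a synthetic ensemble. One directional result is
deliberately not reproduced: with ground-truth centers and an
automated FWHM operator, the NR trajectory slope of tracked lumens
remains statistically distinguishable from zero (the blur kernel still
transmits ~60% of the true shrinkage), whereas the original analysis
— ten lumens, manual reader measurements near the NR resolution limit
— found none. The corresponding acceptance test states the original
property and is expected to fail; an idealized measurement is simply
more sensitive than the reader-limited one, and we chose not to add an
ad-hoc reader-noise parameter to force the null.

## Known limitations

- 2-D cross-sections only; no volumetric rendering or z-axis partial
  volume.
- White noise in HU; the NPS shape (and hence noise texture) is not
  modeled, which mildly exaggerates single-pixel speckle relative to a
  reconstruction-kernel-correlated field.
- Homogeneous matrix: real sponge walls have texture that broadens the
  gray-level histogram.
- The deformation law (uniform `kappa`, hard closure threshold) is a
  stand-in for unknown pore mechanics.
- The REFERENCE chain ignores optics (perspective, lighting, lens
  distortion) and measures with the same FWHM operator as CT rather
  than on binarized images.
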