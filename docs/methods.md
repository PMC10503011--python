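# Methods

`nmjquant` quantifies the spatial organisation of synaptic vesicles in
*Drosophila* larval NMJ type-Ib boutons from calibrated fluorescence
Z-stacks. This note records the models, conventions and numerical
choices behind each stage, what the synthetic generator does and does
not emulate, and the problem sizes the test suite and the acceptance
script run at.

## Coordinate and calibration conventions

All volumes are indexed `(z, y, x)`, 0-based. A pixel's physical
extent is `pixel_size_nm × pixel_size_nm`; the area of any mask is its
pixel count times `(pixel_size_nm / 1000)²` µm², exactly. Two
calibration presets are built in: STED (27.5 nm XY, 0.1145 µm Z) and
confocal (60 nm XY, 0.2 µm Z). Distances for the peripheral band are
measured between pixel centers and scaled by the XY pixel size, so the
200 nm band is ≈ 7.27 px deep at STED calibration.

## Bouton segmentation

Anti-HRP staining labels the neuronal membrane, so a bouton appears as
a bright rim around a darker interior. Segmentation operates on the
maximum-intensity projection: threshold (Otsu by default, or a fixed
value), morphological closing (3×3 element iterated twice) to seal rim
gaps, hole filling, a fixed 1-px erosion, and 8-connected labelling
with a minimum-area filter. The 1-px erosion compensates a systematic
bias: the superlevel set of a PSF-blurred rim lies slightly outside
the membrane midline, so the filled region over-reaches by roughly the
blur half-width. With the generator's default blur (60 nm) the
correction leaves a residual edge error under 1 px (mean Jaccard
against planted footprints ≈ 0.97).

How the original workflow delimited boutons from HRP is not
algorithmically specified (ROIs were effectively manual); the
automatic path above is this package's reproducible default, and
`mask_from_roi_polygon` accepts ImageJ-style polygon ROIs as the
escape hatch that mimics hand-drawn ROIs.

The *center slice* of a bouton is the Z index maximising the
membrane-enclosed area inside its footprint, ties broken toward the
middle of the stack. Masks live on the projection; the center slice
feeds the slice-based intensity rule below.

Type-Ib boutons are selected by an inclusive area filter, default
[2.5, 12] µm². Inclusivity is declared so the filter is deterministic
at the bounds.

## Bouton-size model

`fit_size_model` fits Gaussian mixtures with k = 1..K components
(maximum likelihood, 5 restarts at a fixed seed, EM tolerance 1e-6,
up to 500 iterations) and selects k by minimum BIC, ties toward
smaller k. The derived size window is reported as the dominant
component's mean ± 2 s.d., clipped to positive values — a convention
this package declares; only the resulting range, not its derivation,
is fixed by the original analysis. At n = 500 the selection is
essentially always correct for a single Gaussian and for
well-separated two-component mixtures.

## CSP particle detection (peripheral vs central zones)

A *particle* is a local maximum of the vesicle channel inside a bouton
footprint: a pixel ≥ all 8 neighbours with at least one strictly
smaller pixel adjacent to its (possibly multi-pixel) equal-valued
plateau. Each plateau yields one particle at its centroid, rounded to
the nearest pixel with ties toward the top-left, snapped to the
nearest plateau pixel if rounding leaves it. A constant region is not
a maximum. Maxima are computed on the full frame so the mask boundary
cannot manufacture detections; the mask only selects which maxima
count.

The intensity floor defaults to background mean + 2 background s.d.
estimated outside all masks; any absolute value may be passed instead.
`smooth_sigma_px` optionally smooths the detection frame first: on raw
(non-deconvolved) images, pixel noise on a punctum's flanks creates
several spurious 3×3 maxima per physical spot, and a ~1 px Gaussian
smooth restores one maximum per punctum. The original analysis ran on
deconvolved STED data, for which the default of no smoothing is
appropriate; the recovery tests, which render raw noisy images, use
1 px smoothing with a floor of background + 5 noise s.d.

Zones: the peripheral zone is every footprint pixel whose Euclidean
distance transform to the exterior is ≤ 200 nm (configurable); the
central zone is the remainder. The two zones partition the footprint
pixel-exactly. Zone density is the particle count divided by the zone
area; a zero-area central zone (bouton thinner than twice the band)
reports NaN — undefined, not zero.

## Radial profiles (erosion shells)

The footprint is repeatedly eroded with the full 3×3 element; the
pixels removed at each step form shells, outermost first, which are
disjoint and union to the footprint. Shells are grouped whole (no
pixel splitting) into n bands of nominally equal area fraction — a
shell spanning cumulative fractions [c0, c1] joins band
`floor(n·(c0+c1)/2)`. Quartile profiles are rebuilt from the shells at
n = 4, not by averaging decile values, so the exact-partition property
survives re-binning. Band densities are particle counts per µm² or
background-subtracted intensity per µm² (negative residuals clipped at
0 and flagged); both semantics are offered because the source
measurements alternate between particle-count and intensity density.

The mobilization ratio divides the stimulated density by the
unstimulated density per zone or band; a zero denominator is flagged
NaN rather than raised.

## Intensity and FM1-43

The raw bouton mean is the equal-weight mean of per-slice ROI means
over the center slice ± 2 flanking slices (window clipped at stack
bounds, with the clipping recorded). The source text says the
flanking-slice intensities were "calculated and added"; a literal sum
would scale with slice count and break comparability across stacks, so
the mean reading is the default and `slice_agg="sum"` is available.
The corrected mean subtracts a background estimate and floors at 0
(raw value retained).

Backgrounds: *remote* is the mean of the dimmest 5% of off-structure
tiles (a deterministic stand-in for a hand-chosen remote region, with
an explicit ROI override); *local* is the mean of a ring 3–10 px
outside each bouton, excluding other masks; *combined* averages the
two, following the original FM protocol. Adding a constant to every
voxel and to the background estimate leaves corrected means unchanged
(exact, pre-clipping).

Normalization divides corrected means by the control group's mean,
independently per experiment; the control group then averages exactly
1 and normalization is idempotent.

FM1-43: per bouton, load and unload means are measured on the
maximum-area slice of the paired frames (assumed registered) with
combined background subtraction, and the unload fraction is
1 − unload/load, clipped to [0, 1] with the raw value kept. The
per-preparation summary is the unweighted mean over that preparation's
size-filtered boutons, matching one-point-per-larva plotting.

## Manders colocalization

Channels are segmented inside the bouton footprint replicated along
the whole Z axis (Otsu within the mask by default, or fixed
thresholds). With A the vesicle channel and B the endosome channel:

    M1 = Σ A over (A⁺ ∧ B⁺) / Σ A over A⁺
    M2 = Σ B over (A⁺ ∧ B⁺) / Σ B over B⁺

Raw intensities enter the sums; segmentation only selects voxels. This
thresholded-Manders convention (the JACoP family's) is adopted
deliberately: the alternative denominator "all intensity in the mask"
would make identical channels score below 1 whenever sub-threshold
signal exists, breaking the identity and swap-symmetry properties the
coefficients are expected to satisfy (identical channels → (1, 1);
disjoint signals → (0, 0); M1(A,B) = M2(B,A) exactly; scale
invariance when a channel and its fixed threshold are scaled
together).

## Synthetic scenes and what recovery tests show

Geometry: boutons are star-shaped blobs — a base radius modulated by
four low-order Fourier modes of the polar angle — rasterized so the
realized pixel count lands within 0.5% of a target drawn uniformly
from the area range (default 2.5–12 µm², the type-Ib window). Without
an explicit canvas, placement uses a jittered grid that guarantees a
≥ 2 px gap and cannot fail; on a fixed canvas, rejection sampling
raises after bounded retries.

Puncta: per zone, a Poisson count with mean density × zone area,
positions uniform over the zone's pixels, minimum pairwise spacing
2 px enforced by thinning; the truth records *realized* counts, which
is what recovery is compared against. A density so high that fewer
than 75% of the drawn count can be placed raises a saturation error.

Rendering: each punctum is an isotropic 2D Gaussian per slice whose
amplitude is its *integrated* intensity (blur kernels are normalized,
so the noiseless, background-free channel integrates exactly to the
sum of planted amplitudes). The membrane channel is a 2-px rim of the
footprint, eroded per slice away from the widest slice in multi-slice
stacks. Noise is additive Gaussian (default s.d. 3 on a background of
20) with optional Poisson shot noise. Defaults were chosen as
plausible for deconvolved STED data and are configuration, not claims:
the source reports no SNR or amplitude figures. All outputs are pure
functions of (parameters, seed).

FM pairs share geometry; the unload frame's bouton signal is the load
signal times (1 − unload fraction) before noise, with background
planes at stated remote/local levels. Colocalization scenes plant
equal-amplitude endosome spots, `round(f·n)` of them exactly on
vesicle puncta and the rest ≥ 10 px from every punctum, so the planted
intensity fraction equals the recorded count fraction.

Not emulated: spectral bleed-through, drift, bleaching beyond the
planted unload, depth-dependent PSFs, structured muscle background,
and real biological clustering of vesicles. Passing recovery tests
therefore demonstrates correctness of the measurement algorithms under
a known forward model, not robustness to every artefact of real
microscopy.

## Problem sizes and tolerances

Monte-Carlo sizes are chosen so each check runs in minutes on one CPU
while keeping the standard error well below the effect being checked:
zone-density recovery and the uniform-flatness check use 200 scenes
(3-s.e. criterion), the mobilization ratio 200 scene pairs with 4
boutons each (ratio of grand means, delta-method s.e.), FM recovery
50 seeds per planted fraction (tolerance 0.02), the Manders ladder 6
seeds per overlap level (tolerance 0.05), detection recovery 20 scenes
of ~50 puncta (≥ 96% matched within 1 px, ≤ 1 false positive per
scene), and BIC selection 50 seeds at n = 500 (≥ 90% correct).
`scripts/acceptance.py` recomputes the same quantities at half-sized
replications (100 scenes / 100 pairs / 25 seeds) to stay fast while
the standard errors remain a few percent. Exact checks (partitions,
shell unions, the worked intensity example, Manders identities,
byte-level determinism) carry no tolerance at all.

## Known limitations

- The zone-density and mobilization recoveries measure detection on
  the ground-truth footprints, isolating the detector and the zone
  partition from segmentation; segmentation accuracy is covered
  separately (Jaccard ≥ 0.9 against planted footprints). On segmented
  masks a sub-pixel edge bias shifts the narrow 200 nm band slightly
  and mixes a few percent of peripheral counts into the central zone.
- Local-maxima counting undercounts when puncta sit closer than about
  twice the PSF sigma; at the default densities this costs a few
  percent, well inside the 3-s.e. recovery bands, but dense real
  preparations would need spot-fitting methods that are out of scope.
- The FM path assumes load and unload frames are registered; a
  misalignment check is limited to the shared-mask assumption.
- Otsu thresholds inside small masks are noisy for sparse signals;
  fixed thresholds are recommended for the colocalization of sparse
  spot patterns (the recovery tests use them).
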