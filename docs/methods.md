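# Methods

This note records the models implemented, the defaults chosen where the
underlying experimental practice leaves the choice open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Raman forward model and band registry

A hyperspectral cube is modelled per pixel as a sum of Gaussian bands,

    S(ν, y, x) = Σ_b A_b(y, x) · exp(−(ν − ν_b)² / 2σ_b²) + ε,

where each substance b has a characteristic wavenumber ν_b and width
σ_b, and A_b is its spatial amplitude map. The registry defaults are
literature-standard assignments — amide I 1655, C–H stretch 2935,
O–H/ice 3125, cytochrome C 750, glycerol 850, DMSO 670, sucrose
1120 cm⁻¹ — held in one editable mapping (`cryoraman.bands`) and passed
into every operation, never hard-coded. They are stand-ins for whichever
integration windows a given instrument protocol prescribes; any user
with calibrated windows should supply their own registry. Widths are
chosen so the ±3σ integration windows of neighbouring bands are
disjoint; `validate_separability` enforces centre spacing > 4× the
wider σ.

Detector noise is additive Gaussian with standard deviation
`noise_level · sqrt(intensity)` — a shot-noise surrogate that matches a
CCD's variance scaling without integer-count bookkeeping. The default
`noise_level = 1` puts the per-sample SNR at band peaks near 10,
typical of 0.2-s-dwell confocal Raman mapping.

## Band integration

Heat maps are pixel-wise trapezoidal integrals over the discrete
wavenumber grid — exact for the linear-baseline model, which is also why
the default baseline is the straight line through the window's endpoint
samples (standard single-band practice; switchable to `none` per
window). Negative integrals, which can only arise from noise under the
baseline, are clamped to zero so heat maps are valid non-negative
intensity fields.

## Point spread function and deconvolution

The theoretical PSF is Gaussian with FWHM = 0.61 λ/NA; for the 532-nm /
NA 0.90 configuration that is ≈ 361 nm, i.e. ~1.1 pixels at the 333-nm
pitch. Restoration is Richardson–Lucy with this kernel, 10 iterations by
default — RL preserves non-negativity and is the standard choice for
confocal restoration when no measured PSF exists. The implementation
uses periodic boundary handling so each multiplicative update conserves
total intensity exactly (the test tolerance of 1 % is a ceiling, not the
typical error, which is at machine precision); objects are assumed to
sit away from the field edge, as they do in single-cell fields. A
requested FWHM below one pixel is under-sampled and ill-posed, so the
map passes through unchanged with a logged notice. `iterations=0` is the
identity.

Deconvolution always precedes segmentation and the per-pixel metrics.
Whether a particular historical analysis thresholded raw or restored
maps is usually undocumented; running everything on restored maps is a
single consistent convention, and every metric function also accepts raw
maps for the comparison.

## Segmentation

Substance masks are Otsu-thresholded, cleared of components smaller
than `min_object_px` (default 20 px), and hole-filled. The cell is the
largest connected component of the filled union of the amide I and C–H
masks; ties in component size break to the smallest centroid in (y, x)
order. Coordinates are 0-based, row-major, y before x. One caveat worth
knowing: when the two histogram modes of a map are separated by an
empty gap, Otsu's between-class variance is flat across the gap and the
implementation returns the first tied bin, so the threshold sits just
above the low mode; with heavy noise this admits tail pixels, which the
small-object filter then removes.

Intracellular ice is the O-H-bright Otsu class intersected with the
cell mask eroded by 1 px. The erosion drops partial-volume pixels that
straddle the cell boundary (the frozen extracellular matrix is also
O-H-bright); without it, the boundary ring alone would inflate the ice
fraction of a ~40-px-diameter cell by several percent.

## Frozen-cell metrics

- **Ice.** `ice_area_fraction = |ice ∩ cell| / |cell|`; *chunky* iff the
  largest 8-connected ice component covers ≥ 75 % of the cell
  (configurable; "nearly the entire cytoplasm" is a qualitative notion
  and 0.75 is its operational cut here).
- **Partitioning.** Extracellular reference = 3-px-wide annulus starting
  2 px outside the cell boundary — clear of boundary blur but in the
  same field; intracellular mean excludes ice pixels (ice displaces
  solution; toggleable). Intensity is assumed proportional to
  concentration with zero intercept; no calibration curve is applied.
- **Moran's I.** Row-standardized k-NN weights (k = 8), Euclidean
  distance with exact integer squared-distance arithmetic and
  lexicographic (y, x) tie-breaking; row standardization makes S₀ = n so
  I reduces to the ratio of the weighted cross-product to the variance.
  Binary (un-standardized) weighting and the raw-map option are exposed
  through `knn_weights`/`morans_I` arguments since field practice
  varies. The implementation is verified against an exhaustive
  double-sum oracle to 10⁻¹⁰ relative error and its permutation-null
  mean against −1/(n−1). Note that on a strict checkerboard the 8-NN
  statistic is slightly *positive* (+0.0625 on an 8×8 field): the four
  anticorrelated rook neighbours cancel against the four correlated
  diagonal ones; the familiar strong negative value belongs to k = 4
  rook weights.
- **Diameter.** D = 2·sqrt(A/π) from the mask pixel count; the frozen
  fraction divides by the fresh-cell mean supplied by the caller.
- **Hydration.** Ratio of intracellular mean C–H to O–H band integrals,
  ice pixels excluded; invariant to global gain by construction.
- Cytochrome C release is reported only as the band's Moran's I (plus
  group statistics); no per-cell release boolean is invented, since any
  cut-off would be arbitrary without a calibration experiment.

## Synthetic phantoms and what they show

The phantom is a disk cell (default 13.3 µm — the intermediate of the
three fresh-cell sizes the assays target, 10.6/13.3/19.8 µm) at 333-nm
pitch in a 96-px field. Chunky ice is a single concentric blob of
exactly the requested area fraction; dispersed ice is a stratified grid
of tile blobs separated by 1-px gap lines, dithered so the expected
density matches the request. Disjoint components with 1-px gaps cannot
exceed a density of (t/(t+1))² for tile size t, so dispersed fractions
above 0.79 are geometrically impossible and rejected — which is also why
the chunky-vs-dispersed discrimination test runs its dispersed arm at
0.78 against chunky at 0.80, and on the emitted ground-truth masks: at
those densities the optical blur necessarily bridges the 1-px gaps in
the imaged cube, so the map-derived ice route is instead validated at a
0.3 dispersed fraction.

The protein-clustering knob maps to a Gaussian-random-field correlation
length (0.75 + 3.25·knob px) *and* amplitude (2·knob of the mean), so
the expected amide I Moran's I rises monotonically from ≈ 0 (uniform
field, detector noise only) to ≈ 0.95; the knob→I curve is established
empirically per seed batch and only its monotonicity (rank correlation)
is asserted, not assumed values. Cytochrome C is mitochondria-like
puncta at `cytc_release = 0`, linearly exchanged for a mass-conserving
uniform level at 1.

What passing phantom tests shows: the measurement chain (integration,
restoration, thresholding, mask arithmetic) is unbiased to within the
stated tolerances under shot-like noise, optical blur at the theoretical
PSF, and the stated geometries. What it does not show: robustness to
fluorescence baselines, cosmic rays, cell-shape irregularity, spectral
overlap beyond the registry's separability guarantee, or focus drift —
none of which the generator emulates.

## Calcium pipeline

Movies default to the study acquisition geometry: 185 s at 4 frames/s
(740 frames), stimulus at 10 s. Somata are soft-edged disks with a
resting brightness of 1.0 ΔF/F0 over background (real indicator-loaded
somata are visible at rest; this is also what makes nonresponders
detectable); responders add a rising-exponential transient
`A·(1 − e^{−(t−t₀)/τ})` with τ = 0.5 s — the fast rise of a
depolarization-evoked somatic transient. Noise is per-pixel Gaussian in
ΔF/F0 units.

Detection: local maxima of the Gaussian-smoothed temporal maximum
projection above its Otsu threshold, minimum separation 8 px, ROI = 4-px
disk. ΔF/F0 uses F0 = time-averaged mean over the background region,
and the transient amplitude is read as the post-stimulus plateau minus
the pre-stimulus baseline of the trace (the resting pedestal cancels).

The responder rule is `max forward-difference of ΔF/F0 × frame rate >
threshold`, with the threshold derived from the background trace. Two
background conventions exist in practice — a soma-sized ROI or the whole
non-soma field — and both are available; the default is a soma-sized ROI
in the dimmest soma-free region, because it gives the background trace
the *same noise scale* as the soma traces and therefore makes its
maximum derivative a meaningful reference. The default
`threshold_factor` is 3.0: the maximum of n iid noise derivatives
concentrates tightly around its extreme-value location, so a threshold
equal to *one observed* background maximum would be exceeded by a
matched-noise nonresponder trace about half the time; a 3× guard band
places the threshold far into the tail of the matched-noise extreme
distribution while remaining ~2× below the discrete derivative of a
default transient (≈ 1.57·A/s at τ = 0.5 s, Δt = 0.25 s). At the
default amplitude-to-noise ratio of 10 this yields errorless
classification in practice; the acceptance bar is ≥ 99 % accuracy and
≤ 5 % false positives over 20 movies.

## Cytometry and viability

Fresh-cell diameters: Otsu + connected components with a 20-px minimum
size (debris rejection), D = 2·sqrt(A/π). Survival fractions carry
Wilson 95 % intervals — well-behaved at 0 and 1, where the Wald interval
degenerates. Recovery ( %) = 100 × post-thaw viable / pre-CPA viable,
reported unclamped above 100 with a logged notice; attachment ( %) and
the PDA excimer/monomer (460 nm / 400 nm) fluidity ratio are plain
ratios with positivity guards. The 460 → excimer assignment follows the
kit convention; the wavelength pair alone does not fix it.

## Freeze schedule generator

`make_freeze_log` samples the controlled-rate-freezer profile
piecewise-linearly: 20 °C → −10 °C/min to `t_nuc` → 15-min hold
(nucleation is induced during the hold) → `B` °C/min to −60 °C →
−10 °C/min to −100 °C, for any (T_NUC, B) — in particular the six-point
study grid T_NUC ∈ {−4, −8} °C × B ∈ {−1, −3, −5} °C/min. The trace is
an idealized set-point log; real sample thermocouples additionally show
the recalescence spike at nucleation, which is deliberately not
modelled.

## Statistics layer

Two groups: two-tailed Student's t (equal variances, per the classical
convention). Three or more: Shapiro–Wilk at α = 0.05 per group; any
failure routes the whole family to Kruskal–Wallis with pairwise
two-sided rank-sum follow-ups, otherwise one-way ANOVA with pairwise
t-tests. All pairwise p-values receive Bonferroni `min(1, m·p)` with
m = all pairs (pre-planned-contrast counting would need information a
metrics table does not carry). Significance is α = 0.05 on the adjusted
value. Family-wise type-I error of both paths is verified ≤ 0.05 within
Monte-Carlo error on a simulated three-group null at n = 10 per group,
2,000 replicates.

## Numerical conventions and problem sizes

All randomness flows from `numpy.random.default_rng(seed)`; every
generator records its seed in the output sidecar, and identical specs
and seeds reproduce outputs bit-for-bit (movie and cube assembly is
float32 with a fixed operation order). CSVs are written with a fixed
`%.12g` float format so repeated seeded runs are byte-identical.

Test problem sizes — 96-px cubes with a 4-cm⁻¹ spectral grid, 50 seeds
per recovery setting, 20 movies, 2,000 statistical replicates — were
chosen as the smallest batches at which the Monte-Carlo error of each
check is comfortably below its tolerance; the acceptance script uses
somewhat smaller batches (reported in its `n` fields) since it reports
measured values rather than pass/fail margins.

## Known limitations

- Disk-shaped phantoms only; no irregular morphology, no multiple cells
  per field (the pipeline keeps the largest component by design).
- Intensity–concentration linearity is assumed for partitioning; no
  spectral unmixing (MCR-ALS/NMF), despiking, or baseline modelling.
- The amide I amplitude is kept uniform across ice in chunky phantoms so
  cell delineation stays testable; in reality proteins are excluded from
  the ice mass.
- The responder threshold constant is a convention, not a calibration;
  `threshold_factor` and the background definition must be fixed per
  study and held constant across conditions.
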