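# Methods

This note records the models, conventions and numerical choices behind
`myddo`, and what the synthetic-data tests do and do not demonstrate about
real microscope data.

## The measurement model

A Myddosome punctum is a diffraction-limited spot whose integrated
fluorescence is proportional to its MyD88-GFP copy number. The pipeline
estimates copy number in units of the single-GFP intensity, measured from
purified GFP adsorbed to glass and processed through the identical chain:
dark-frame subtraction, disk-median background subtraction, LoG detection,
and a 3×3-pixel intensity **sum** at the rounded spot center. Using a sum
(not a mean), and the same window for calibration and cells, means the
finite capture fraction of the window — erf(1.5/(σ√2))² ≈ 0.68 of the PSF
for σ = 1.1 px — cancels exactly in normalized units. No temporal
smoothing is applied to intensity traces; the classification statistic is
the raw per-frame maximum.

The N-mer intensity model is Gaussian with mean *and variance* scaling
linearly in N: X_N ~ Normal(N·μ, N·σ²). This is the distribution of a sum
of N independent fluorophores with unit distribution Normal(μ, σ²). At the
4.5× threshold the model gives a hexamer capture of
1 − Φ((4.5 − 6)·μ/(√6·σ)); at CV = σ/μ = 0.25 this is 99.3 %, and it stays
above 98 % for every CV up to 0.29. Dimers are essentially never
misclassified (tail ≈ 8·10⁻¹³ at CV 0.25). The threshold is inclusive
(≥ 4.5×). The calibration statistic is a robust mean: samples outside
median ± 5×MAD are discarded before the mean/SD are taken (the screen only
exists to reject rare aggregates and hot pixels; it removes <0.1 % of
Gaussian data).

## Conventions fixed by the analysis

* **Coordinates** — pixel indices are 0-based; physical position =
  (index + 0.5) × pixel size (pixel-center convention). Distances for
  colocalization are computed in µm on sub-pixel centers.
* **Lifetime** — observed frame count × frame interval (not span−1), so
  the minimum observable lifetime with the 3-frame filter at 1 s intervals
  is 3 s. Short < 50 s, long ≥ 50 s. Tracks alive in the final frame are
  flagged right-censored and included.
* **Growth** — Δ = (max − initial)/μ, with "initial" the first observed
  frame. Tracks starting at ≥ 2.5× GFP are excluded (strict <): they are
  likely buds or splits of pre-existing assemblies whose nucleation time
  is unknown. This is also why the linker carries no merge/split model —
  fusion and fission appear as track ends/starts and are screened here.
* **Colocalization** — ≤ 0.25 µm (inclusive) for ≥ 2 consecutive frames;
  a gap in *either* channel breaks the run (strictest reading of
  consecutive). Assignment is one-to-one; the longest run wins a contested
  partner track, ties going to the earlier-nucleating reference track.
  Recruitment time = (first partner frame − first reference frame) × Δt;
  negative delays are flagged and excluded from distributions.
* **FRAP** — normalized as (I(t) − I(0))/(I(pre) − I(0)) with I(0) the
  single first post-bleach sample and I(pre) the mean of the prebleach
  window. Negative normalized values are kept; traces with zero bleach
  depth are rejected. No correction for observational photobleaching is
  applied.
* **Fixed cells** — "radius" is the equivalent-circle radius √(area/π);
  eccentricity is the major/minor axis ratio of the second-moment ellipse
  (≥ 1). Filters: nucleus radius 5.5–10 µm (inclusive), cytoplasm radius
  < 15 µm (strict), nucleus ecc ≤ 1.66, cytoplasm ecc ≤ 2.25, border
  exclusion by cell-mask bounding box, and crowding: at most 5 nuclear
  centroids within a 16 µm radius, counted over all segmented cells
  pre-filter and *including the cell itself* (only this reading makes a
  cluster of six mutually-near nuclei fail as a group). Each rule can be
  toggled independently; the pass flag is their conjunction.

## Preprocessing numerics

Median filters use a disk footprint of the stated pixel radius (25 px for
background, 100 px for illumination) with edge-repeating reflective
padding, implemented as a histogram-based sliding median on a 12-bit
affine quantization of the frame. The quantization step (range/4095) is
far below camera noise, and any residual bias is shared between
calibration and cellular frames, cancelling in normalized units.
Illumination is estimated once from the mean of all frames, rescaled to
unit mean before division so intensities stay on the camera scale; the
correction is reliable away from the filter-radius border band. All
corrected stacks stay in floating point and are never clipped at zero —
clipping would bias the dim end of the intensity distribution that
calibration depends on.

Detection is Laplacian-of-Gaussian at the PSF scale (σ²-normalized),
thresholded at a quality expressed as a multiple (default 5×) of the
robust SD of the per-frame LoG response, so it tracks camera noise without
retuning; sub-pixel centers come from a 1-D quadratic fit per axis,
clamped to ±0.5 px. Linking is greedy mutual-nearest per frame pair
(candidates sorted by distance, ties broken on coordinates so the result
is invariant to detection order), default search radius 0.5 µm and gap
closing of 1 frame — appropriate for mostly stationary puncta at 1 s
intervals; both are configuration keys.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
150 nm pixels, 1 s frames, puncta nucleating as a Poisson process
(configurable rate) at uniform positions, starting at 1–3 monomers.
Copy-number kinetics are a two-phase birth–death walk: in the unstable
phase a punctum gains a monomer with probability `p_grow` (default 0.22)
or loses one with `p_shrink` (0.38) per frame, dying at zero — so most
nascent oligomers dissolve within seconds; on reaching
`stable_size_threshold` (6) it stabilizes, growing slowly
(`stable_p_grow` 0.05) and disappearing wholesale at a small rate
(`stable_p_death` 0.01, mean stable lifetime ≈ 100 s). With these
defaults roughly 10–20 % of puncta ever become large, the transient
population has 3–10 s lifetimes, and lifetime couples to intensity growth
— the qualitative two-population regime the analysis is designed to
resolve. An unbounded `max_size` emulates unchecked oligomerization (the
kinase-knockout regime); setting it caps growth.

Punctum brightness is the sum of per-monomer unit intensities, each drawn
once at recruitment from Normal(μ, (CV·μ)²) with μ = 500 ADU and CV = 0.25
by default. The total is therefore N·μ·(1+ε) with ε ~ Normal(0, CV/√N) —
exactly the Gaussian N-mer model — and is *constant in time* for a
constant-size punctum: fluorophore brightness is a static property, and
frame-to-frame fluctuation comes from the camera model alone. (Redrawing ε
every frame would make the max-over-frames statistic systematically
overshoot by ~20 % for monomers, which is a property of that incorrect
noise model, not of the estimator.) Rendering integrates an isotropic
Gaussian PSF (σ = 1.1 px) exactly over each pixel via error functions,
truncated at 5σ; the camera adds Poisson shot noise on the signal, a
constant offset (100 ADU) and Gaussian read noise (1.6 ADU rms),
approximating an sCMOS. Positions are continuous with optional Gaussian
per-frame diffusion, default stationary — puncta mobility is not
quantified by the assay this emulates, so the stationary default is a
stand-in, not a claim. Each simulation call consumes one seeded NumPy
generator with a documented draw order, making outputs bit-reproducible.

Partner-channel (kinase) recruitment: puncta reaching
`partner_size_threshold` receive a partner whose appearance is delayed
from *nucleation* by Normal(15, 5²) s truncated at zero (defaults chosen
on the scale of measured kinase recruitment); the partner renders at the
reference position until the punctum dies.

Calibration stacks are sparse immobile single emitters with single-step
photobleaching (geometric survival); the generator refuses densities at
which the expected nearest-neighbour spacing falls below 4σ. FRAP traces
are a plateau, an instantaneous drop, and a single-exponential recovery
toward a mobile fraction. Fixed-cell fields are disk nuclei (with a small
central intensity bump so seeded watershed finds one maximum per nucleus)
inside larger cytoplasm disks at 0.2833 µm/px (a 20× camera geometry);
optional constructions — a cluster of six nuclei with mutually-near
centroids, border-straddling cells, elongated debris — exist solely to
exercise the quality filters.

### What the synthetic tests do not show

The generator reproduces the *statistical* structure (intensity scaling,
noise model, kinetic two-population mixture, recruitment delays), not the
*biological* one: no cell boundaries or heterogeneous cytosolic
background in live movies, no punctum fusion/fission, no blinking or
maturation dark fraction, no 3-D PSF or defocus, idealized disk-shaped
cells in fixed fields. Passing tests therefore demonstrate that the
estimators are correct under the stated model assumptions and robust to
the modelled noise — not that those assumptions hold for any particular
microscope. Headline percentages from the original assay (colocalization
rates, per-cell proportions, FRAP recovery values) are properties of the
deposited imaging data and are not reproduced here; the pipeline
recovers the corresponding quantities from ground truth instead.

## Problem sizes and tolerances in the test suite

Stochastic checks run at sizes where their analytic error bounds are
sharp: kinetic laws on ≥10⁴ simulated puncta (χ² at α = 0.01), the
classification benchmark on 500 hexamers + 500 dimers rendered as
jittered 64-spot grids (≥95 % / ≥99 % correct; mean size within 15 % of N
for N ∈ {1, 2, 4, 6, 8, 12}), recruitment on ~500 rendered two-channel
events (mean within 1 s of realized truth), and the lifetime–growth
coupling on >1,000 growth-eligible tracks (R > 0.4 coupled, |R| < 0.05
decoupled). The decoupled arm is a constructed track set with growth drawn
independently of lifetime: with per-frame measurement noise, max-minus-
initial necessarily grows with track length, so a rendered movie cannot
realize exact decoupling. Exact identities (normalization, arithmetic,
boundary inclusivity, the colocalization run-length scan against a
brute-force oracle) are asserted without tolerance.

## Known limitations

* The linker is greedy mutual-nearest without motion prediction or
  merge/split costs; dense fields with fast motion would need a LAP-style
  tracker.
* Sub-pixel localization is a quadratic interpolation of the LoG response,
  adequate at the assay's SNR (RMSE ≈ 0.1 px on defaults) but inferior to
  Gaussian MLE fitting near the detection limit.
* Watershed segmentation parameters are validated on synthetic geometry
  only; real fixed-cell data would need threshold/seed tuning.
* Censored lifetimes are flagged but not modelled (no survival analysis);
  movie-length truncation biases long-lifetime statistics accordingly.
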