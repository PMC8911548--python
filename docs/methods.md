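# Methods

## Acquisition model

A decay map is a regular (row, col) grid of TCSPC histograms sharing one
`AcquisitionConfig`. Defaults mirror the fibre-based instrument the package
is modelled on: repetition rate f = 20 MHz, 256 bins of Δt = 195 ps, so the
histogram spans 49.92 ns of the 50 ns excitation period; the configuration
is rejected if the window exceeds the period. Counts are non-negative
integers; float counts are refused on input so that file round-trips are
bit-exact. Real freehand scans do not document how acquisition points map
onto a 2-D raster, so the package simply treats maps as dense regular
grids.

Times use the bin-centre convention `t_k = (k + ½)Δt`: left-edge sampling
would inject an O(ωΔt) phase offset into the phasor projections, whereas
bin centres leave only the second-order bias analysed below.

The instrument-geometry helper models the excitation cone diverging at the
fibre's acceptance half-angle: `spot = 2·d·tan(arcsin NA)`. With NA = 0.22
this reproduces both documented spot-diameter endpoints (0.9 mm at 2 mm,
4.5 mm at 10 mm) after rounding to 0.1 mm; the small-angle approximation
`2·d·NA` misses the upper endpoint (4.4 mm), which is why the arcsin form
is used.

## Synthetic decays

The generator emulates steady-state periodic excitation by an ideal delta
pulse. For a population with amplitude fractions `f_i` and lifetimes `τ_i`,
the expected counts in bin k are

    λ_k = A · Σ_i f_i · exp(−t_k/τ_i) / (1 − exp(−T/τ_i)),   T = 1/f,

with A scaled so `max_k λ_k` equals the target peak count. The wrap factor
`1/(1 − e^{−T/τ})` is the geometric sum over all previous pulses; at the
lifetimes of interest it is a near-unity constant (for τ = 4.5 ns,
e^{−T/τ} ≈ 1.5·10⁻⁵) but it re-weights components of multi-exponential
mixtures, so it is kept on by default and merely exposed as a flag.
Poisson noise draws independent counts per bin; the noiseless mode rounds
λ_k to the nearest integer. Per-pixel random streams are derived from
`SeedSequence(seed, spawn_key=(row, col))`, so a map is reproducible pixel
by pixel regardless of traversal order.

Defaults are the study conditions the pipeline is validated under: target
peak 500 counts (comfortably above the 100-count filter; actual peak
levels of the original measurements are unreported), interface maps of
50×60 = 3000 pixels matching the 3000 acquisition points of a measurement
session, and ground-truth lifetimes taken from the measured mixture table
(e.g. 3.7 ns vs 1.7 ns for cerulean blue in rabbit-skin glue vs linseed
oil).

What the generator deliberately omits: instrument response function
(excitation is ps-scale against ns lifetimes; an optional Gaussian IRF
convolution exists for robustness checks but is off by default),
background/dark counts, detector afterpulsing, dead time and pile-up, and
any spatial correlation of noise. Passing tests therefore demonstrate the
*algorithmic* correctness of the pipeline under ideal counting statistics,
not robustness to every instrumental artefact of real data.

## Phasor transform and its discretization bias

`phasor_transform` evaluates the two projection sums exactly as written —
no calibration, no background subtraction (hooks for a reference-phasor
calibration and a constant-background subtraction exist but default to
identity/off, since the analysis this package reproduces used neither).
The transform is linear: the phasor of a bin-wise sum of decays is the
total-count-weighted convex combination of the phasors, an exact identity
the property tests assert at 1e−12.

Because the transform is a midpoint-sampled Riemann sum rather than a
continuous Fourier integral, the τ-phase of a sampled mono-exponential
carries a deterministic discretization bias. Writing u = Δt/τ, the
estimate obeys (to ~5·10⁻⁵ relative, the residual being O((ωΔt)²) and
window-truncation terms)

    τ_est = τ · (u/2)·coth(u/2) ≈ τ · (1 + Δt²/(12 τ²)).

At the default 195 ps binning this is +0.11% at τ = 1.7 ns, +0.03% at
3.7 ns — negligible against counting noise — but grows to +1.27% at
τ = 0.5 ns. The bias is a property of the estimator, not of the
simulation: bin-integrated counts give the identical phasor for a single
exponential. No correction is applied, because any correction would either
break the exact linearity of the transform or redefine the τ-phase
formula; the property suite instead asserts the bias law itself and 0.5%
recovery for τ ≥ 0.8 ns, where the law permits it.

Pixels with g ≤ 0 (possible only for pathological or ultra-long decays)
keep their phasor for clustering but are assigned a missing (NaN) τ-phase
and are excluded from lifetime statistics; exported masks encode missing
as 0.

## Mixture model and EM

The (g, s) cloud is fitted with a full-covariance bivariate Gaussian
mixture by EM. Choices, and why:

- **K fixed, default 2.** The intended use measures the interface of two
  known mixtures; one component per population. Automatic K selection is
  out of scope.
- **Initialization**: seeded farthest-point start (random first centre,
  each next centre the point farthest from those chosen), shared spherical
  covariance from the global spread, uniform fractions; `n_starts = 5`
  independent starts, best final log-likelihood kept. Deterministic given
  the seed.
- **Convergence**: relative log-likelihood change below `tol = 1e−8`,
  `max_iter = 500`.
- **Regularization**: the M-step covariance receives a 1e−10 diagonal
  ridge only when its smallest eigenvalue falls below 1e−10. The floor
  prevents singular collapse on numerically identical (noiseless)
  clusters, while leaving the M-step untouched on healthy data — an
  unconditional ridge would destroy the exact monotonicity of the
  likelihood trace, which the test suite asserts to 1e−9.
- **Hard assignment** takes the argmax responsibility; exact ties go to
  the lower cluster index.
- **Canonical ordering** renumbers components by descending τ-phase of the
  component mean (ties: descending fraction, then mean g), so "cluster 1"
  is always the longer-lived population regardless of seed.
- **Summaries** report mean ± SD of the finite τ-phases of member pixels,
  with the population (n-denominator) SD; at the n ≈ 1500 cluster sizes of
  the standard experiment the distinction from the sample SD is
  irrelevant, and nothing in the reproduced analysis specifies one.

scikit-learn's `GaussianMixture` is used in the test suite as an
independent implementation that must reach the same optimum on a
well-separated cloud; it is never used in the pipeline itself.

## Rendering and scoring

τ-phase maps are coloured by a linear HSV hue sweep from blue (240°) at
the range minimum to red (0°) at the maximum — the documented colour-scale
endpoints are 2.0 ns (blue) and 4.5 ns (red) — with out-of-range values
clipped and missing pixels neutral grey. Cluster maps use red for cluster
1 and green for cluster 2 (palette extension: blue, magenta, cyan, yellow).
Probability blends mix the palette channel-wise by the GMM
responsibilities, so a responsibility-1 pixel matches its hard colour
exactly. All renderers are pure functions; identical inputs give
bit-identical 8-bit RGB images.

`segmentation_accuracy` scores a segmentation against simulation ground
truth over retained pixels under the best label permutation (exhaustive,
K ≤ 3).

## Problem sizes and numerical checks

The standard end-to-end experiment — and the one `scripts/acceptance.py`
reruns — uses a 50×60 map (1500 pixels per population), Poisson noise at
peak 500 and K = 2; it completes in well under a second, and the recovered
cluster means land within a few thousandths of a nanosecond of the 3.7 and
1.7 ns ground truth with segmentation accuracy 1.0 at the tested seeds.
Property tests run on 10×10 to 20×20 maps for speed; the statistics they
assert (Poisson bin means within 5 SE over 200 replicates, EM parameter
recovery within 3 SE) are scale-aware rather than size-dependent.

## Known limitations

- Mono-exponential τ-phase equals the true lifetime only for
  mono-exponential decays; for mixtures it is an intensity-weighted
  apparent lifetime, as in any single-harmonic phasor analysis.
- The discretization bias above makes sub-nanosecond lifetimes slightly
  overestimated at 195 ps binning.
- The GMM assumes roughly Gaussian phasor clusters; populations with
  nearly identical lifetimes produce overlapping clouds that K = 2 cannot
  reliably split (soft responsibilities near ½ and unstable hard edges) —
  the probability-blend rendering is the honest output in that regime.
- No IRF deconvolution or reference calibration: absolute phasor
  coordinates from real instruments with a non-negligible IRF will be
  rotated/demodulated relative to the ideal semicircle and should be
  calibrated upstream (the inert calibration hook marks the seam).
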