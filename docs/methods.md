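# Methods

## Problem and scope

At the invasive front of bone-invading oral squamous cell carcinoma
(OSCC), a laminar stromal band 100–200 μm thick lies between the tumor
nests and the resorbing jawbone surface. Cancer-associated fibroblasts
(CAFs, FAP+/α-SMA+) populate this band; RANKL+ OSCC cells occupy the
nests and cathepsin-K+ osteoclasts line the bone surface. `cafprox`
quantifies how CAFs are positioned relative to the two reference
populations from cell-coordinate exports of a digital-pathology platform
(or from its own simulator): quadrat (ROI) counts with pooled
CAF-per-reference ratios, cross-type nearest-neighbor (NN) distance
profiles in 10 μm increments, truncated within-distance fractions, and a
thin- versus thick-stroma comparison.

The package consumes or simulates *coordinates*; cell detection,
staining, serial-section registration and any clinical interpretation are
upstream or out of scope.

## Spatial statistics

For source set $S$ (default: CAFs) and target set $T$ (a reference type),
the NN distance of $s \in S$ is $d(s) = \min_{t \in T} \lVert s - t
\rVert$ in the section plane. Distances are computed with a k-d tree and
the reported value is recomputed from the matched pair with `hypot`, so
it equals the brute-force pairwise minimum bit-for-bit — a property the
test suite asserts on random instances.

The radial profile counts sources in half-open annuli $[kw, (k+1)w)$,
$w = 10$ μm by default, up to an outer radius of 100 μm; $d \ge 100$ μm
is excluded. A secondary per-area density divides each count by the area
of the union of the per-target annuli (optionally clipped to tissue) per
100 μm²; raw counts are the normative output because the exact
normalization of published density axes is under-specified. No edge
correction is applied — sources near the tissue border are biased toward
longer distances; this mirrors the analysis being reproduced and is a
known limitation.

The headline statistic is the truncated within-fraction

$$\hat F = \frac{\#\{d < r_\text{in}\}}{\#\{d < r_\text{out}\}},
\qquad r_\text{in}=50,\; r_\text{out}=100\ \mu m,$$

flagged undefined when the denominator is zero. The measurement
direction is switchable; the default takes CAFs as sources because the
published histograms count CAFs by distance to the reference type.

ROI quantification places 100 × 100 μm² quadrats, 15 anchored to the
bone surface (each must intersect a 20 μm buffer of the interface
polyline) and 15 over tumor nests away from that buffer. Membership is
half-open in both axes, so abutting quadrats never double-count. The
pooled ratio (total CAFs / total reference cells over a stratum's ROIs)
is used rather than a mean of per-ROI ratios: it is defined even when
individual ROIs lack reference cells, and it reproduces the worked
example 890 CAFs / 78 OSCC cells = 11.4 exactly. (Note 745/32 = 23.28
rounds to 23.3; the conventional printed value 23.2 is matched within
±0.1.) Since manual, blinded ROI selection is not reproducible in code,
placement is seeded-random: surface quadrats occupy randomly chosen
non-overlapping x-slots with a random vertical offset within the window
that guarantees interface contact (free sequential rejection at 15
quadrats per 2 mm frame sits near the random-sequential-adsorption
jamming density and can fail stochastically; slot placement cannot),
and deep quadrats use bounded rejection sampling.

## The synthetic invasive front

Because the underlying tissue data are not public, the simulator is a
first-class component generating patterns with the statistical structure
the analysis assumes:

* **Geometry** — image-convention frame (origin top-left, y downward,
  μm); a tumor zone with disc-shaped nests, a stromal band of prescribed
  mean thickness, and bone below a (optionally wavy) interface polyline.
  Waviness is a mean-zero sum of two sinusoids, preserving band area.
* **Reference cells** — OSCC uniform in nests with Poisson counts at an
  areal density; osteoclasts uniform along the interface with ≤ 5 μm
  normal jitter.
* **CAFs** — a two-component mixture. With probability
  `clustered_fraction` a CAF is the offspring of a uniformly chosen
  reference cell, displaced by an isotropic 2-D Gaussian of scale σ
  (Thomas-process-like); otherwise it is uniform in the band. Offspring
  landing outside valid tissue (band ∪ nests) are rejection-resampled,
  capped at 1000 rounds. The parent is recorded for provenance.
* **Background** — `spindle_fraction` (default 0.70, the observed share
  of spindle-shaped stromal cells) controls a complementary population of
  untyped OTHER cells, uniform in the band, which all analyses ignore.

The Gaussian-offspring choice is an emulation device, not a biological
claim: its radial displacement has the closed-form Rayleigh CDF
$1 - e^{-r^2/2\sigma^2}$, which makes the truncated within-fraction
analytically invertible:

$$F(\sigma) = \frac{1 - e^{-r_\text{in}^2/2\sigma^2}}
{1 - e^{-r_\text{out}^2/2\sigma^2}},$$

strictly decreasing from 1 (σ→0) to $r_\text{in}^2/r_\text{out}^2$
(σ→∞). `solve_displacement_scale` inverts F by bracketed Brent root
finding to a residual below 1e−9 and refuses targets at or below the
uniform limit (0.25 for 50/100 μm). Calibrated scales: F⁻¹(0.81) ≈ 27.5
μm, F⁻¹(0.74) ≈ 30.6 μm, F⁻¹(0.89) ≈ 23.8 μm, F⁻¹(0.62) ≈ 36.7 μm.

In the *sparse-reference regime* (pairwise reference separation > 400 μm,
references ≥ 150 μm from tissue borders, pure offspring), a CAF's nearest
reference is its own parent and boundary rejection is negligible, so the
pipeline's empirical fraction estimates F(σ) directly; the test suite and
the acceptance script exploit this to validate the whole chain
(simulation → NN search → binning → fraction) against the closed form at
n = 5000, where the binomial standard error of the fraction is ≈ 0.6
percentage points.

### Default parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| band_thickness | 150 | μm | middle of the observed 100–200 μm range |
| osc_density | 5.2e−4 | μm⁻² | ≈ 5.2 OSCC per 100×100 μm² nest ROI (78/15) |
| oc_linear_density | 2.13e−2 | μm⁻¹ | ≈ 2.1 osteoclasts per 100 μm of interface (32/15) |
| caf_density | 5.93e−3 | μm⁻² | ≈ 59.3 CAFs per 100×100 μm² band ROI (890/15) |
| clustered_fraction | 0.75 | — | strong clustering with a visible uniform background |
| displacement_scale_sigma | 27.5 | μm | F⁻¹(0.81) at 50/100 μm |
| spindle_fraction | 0.70 | — | observed spindle share of stromal cells |

CAF counts are exact (⌈density × band area⌉, or the `n_cafs` override);
reference counts are Poisson. All randomness flows from one
`numpy.random.default_rng(rng_seed)` per operation, so outputs are
bit-identical per seed.

### What the simulator does not emulate

No pixel-level image synthesis or stain modelling; no cell shapes or
osteoclast multinucleation; no serial-section misregistration (all
coordinates live in one plane); no CAF subtype heterogeneity; reference
cells are placed independently rather than in cords or files. Passing
tests therefore demonstrate that the *measurement chain* is correct under
the assumed point-process structure — not that real tissue follows that
structure.

## Numerical choices

* Half-open bins and ROI membership everywhere; a distance of exactly
  10 μm falls in [10, 20), a cell on a shared quadrat edge is counted
  once.
* NN ties are resolved by value: the distance is identical whichever
  target attains it.
* Degenerate inputs fail loudly: empty target sets, zero pooled
  reference counts, non-divisible bin widths, calibration targets outside
  the attainable interval, infeasible ROI packings (reporting achieved
  counts).
* Reported ratios are rounded to one decimal at the reporting layer
  only; full precision is carried alongside.
* Problem sizes in the test and acceptance protocols: 5000 CAFs per
  simulated field, 20 reference cells, 20-seed Monte-Carlo averages for
  histogram-shape expectations — large enough that stochastic assertions
  sit several standard errors inside their tolerances.

## Known limitations

Uncorrected border bias in NN distances; the pooled-versus-per-ROI
ambiguity of published ratio definitions (pooled adopted, see above); the
per-area density normalization is a labelled secondary output; the
simulator's mixture model is one of many point processes consistent with
the reported summary statistics.
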