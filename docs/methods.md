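# Methods

This note records the models, parameter choices, and numerical decisions
behind `oculims`, and what the synthetic phantoms do and do not establish
about real data.

## Mass arithmetic

Monoisotopic masses come from a table frozen in `oculims.masses`
(IUPAC values, 7 decimal places: H 1.0078250, C 12, N 14.0030740,
O 15.9949146, Na 22.9897693, plus S, P, K, Cl, F), so results are
reproducible with no network access. Adduct m/z values are
electron-corrected cation additions: [M+H]⁺ adds 1.0072764 Da and [M+Na]⁺
adds 22.9892207 Da. With this table, atropine C₁₇H₂₃NO₃ gives
[M+H]⁺ = 290.17507 and CHCA C₁₀H₇NO₃ gives [M+H]⁺ = 190.05 and
[M+Na]⁺ = 212.03 (2 dp), the three anchors everything else is referenced
to. The Na⁺/H⁺ cation difference is consequently 21.9819443 Da for every
formula.

The extraction window's stated width, 0.0009 Da, is interpreted as a *full*
width (membership |m/z − center| ≤ 0.00045 Da): "window" in imaging
software conventionally denotes the total width, and the half-open
alternative would double the effective tolerance. It is configurable.

Lock-mass correction is a single-point *additive* shift per spectrum: the
most intense peak inside a search window (default full width 0.1 Da) around
the CHCA sodium adduct is moved exactly onto its theoretical m/z and the
whole axis shifted with it. One anchor peak supports exactly one free
parameter, and over a 110-Da acquisition range an additive model captures
the drift adequately; a multiplicative model would need a second anchor to
be distinguishable. The anchor's corrected m/z is pinned bit-exactly to the
reference, which makes the operation idempotent. Spectra without an anchor
peak are passed through unchanged and flagged, never dropped.

## Ion images and normalization

An ion image is the per-pixel **sum** of centroid intensities inside the
mass window — not the maximum — because centroided FT-ICR data contain at
most one true peak per 0.0009 Da and a sum is robust to split centroids.
TIC normalization divides by the pixel's total intensity over the full
acquisition range (m/z 200–310 by default, configurable); pixels with zero
TIC get value 0 with a logged flag, since off-tissue matrix pixels are an
expected condition, not an error. The "full-intensity threshold" display
operation clips at the threshold and rescales to [0, 1]; it is monotone, so
lowering the threshold never darkens a pixel — this reproduces the
anterior-contrast vs posterior-contrast renderings used to visualize weak
posterior signal.

## Boundary tracing and ROI placement

The tissue outline is the marching-squares contour (0.5 level) of the
largest connected component of the mask, simplified with Douglas-Peucker at
a 1-pixel tolerance. Simplification is what keeps arc length honest: the
raw staircase contour inflates a smooth outline's perimeter by 5–7%,
whereas a moving average that fixes smooth shapes erodes genuine corners;
Douglas-Peucker straightens staircases while preserving corners and lands
within ~3% on rectangles and well under 1% on ellipses. An optional
circular moving average remains available for display. Empty masks and
ties for the largest component are errors (the caller must disambiguate).

The corneal apex is projected onto the contour (error if farther than
2 pixels) and inserted as the arc-length origin; the traversal direction
whose half-perimeter contains the user-supplied superior-side hint is
labeled superior. ROI centers sit at arc positions 0, ±400, ±800, … μm
(the apex ROI is shared between branches), each ROI being the disk of
diameter 200 μm around its center. The stated "outer perimeter of each ROI
… 200 μm" is read as a **diameter**: a 200-μm-circumference disk (⌀≈64 μm)
could contain zero laser spots at common pitches, while a 200-μm diameter
with 400-μm spacing yields non-overlapping ROIs holding a handful of spots,
matching reported practice. A spot belongs to an ROI iff its pixel center
lies inside the disk — partial-overlap weighting is rejected as
underdetermined. ROIs with no spots (unscanned regions) are dropped with a
warning.

## Statistics

The Mann-Whitney U statistic counts pairs with x > y plus half the ties
(midranks). For pooled n ≤ 16 the two-sided p-value is exact: all
C(n₁+n₂, n₁) labelings of the observed pooled values are enumerated, which
handles ties correctly and covers the 2–11 spots per ROI typical of
perimeter line scans. Above that, a normal approximation with tie
correction and a 0.5 continuity correction is used; at n₁ = n₂ = 30 it
agrees with a 10⁵-resample permutation estimate to within 0.01. The test
is two-sided; the reported direction (superior- or inferior-higher) comes
from the sample means. Per-position significance is reported uncorrected at
α = 0.05 / 0.01 — matching the per-position markers such line-scan figures
carry — and a Holm-adjusted column is emitted alongside for readers who
want family-wise control. Positions present on only one branch are listed
without a test.

## The eye phantom

The generator emulates a sagittal whole-eye cryosection on a regular laser
grid and returns the ground truth alongside the imzML-compatible dataset.

**Geometry** (defaults, all configurable): an ellipse with semi-axes
8.5 × 7.8 mm (a rabbit-scale eyeball), apex on the +x side, superior = −y.
The outer 500-μm shell is cornea within 3.5 mm of arc from the apex
(epithelium 100 μm, stroma 300 μm, endothelium 100 μm, by depth from the
surface) and sclera elsewhere; inside sit a lens (3.0 × 2.8 mm, offset
2.5 mm toward the apex), an anterior chamber (interior region anterior of
the lens midline), and vitreous. Laser pitch is 50 μm — one of the
acquisition pitches used in practice, chosen over 100 μm because a 200-μm
ROI then holds ~5–8 boundary spots: enough for the exact Mann-Whitney test
to resolve p < 0.05 at all (at 100 μm most matched positions would hold 3
spots each, where the smallest attainable two-sided exact p is 2/20 = 0.1,
and no per-position significance could ever be declared). Only tissue
pixels are scanned; the rest of the grid is absent, like pixels outside a
drawn measurement region.

**Drug field** (arbitrary units): at arc distance *s* from the apex the
surface concentration is A₀·e^(−s/λ) with A₀ = 1000 and λ = 6 mm, switching
continuously to λ₂ = 2 mm beyond a changepoint at s = 10 mm — the sharp
posterior decline where the globe re-enters the orbit and stops touching
instilled solution. Branch-specific Gaussian hotspots model the drug
reservoirs: inferior tear meniscus (center 2 mm, amplitude 2500, σ 0.4 mm —
the largest, as gravity pools the drop in the lower meniscus), superior
tear meniscus (4.5 mm, 1200, σ 0.6 mm), inferior conjunctival sac
(10.5 mm, 500, σ 0.7 mm), superior conjunctival sac (13 mm, 350, σ 0.6 mm).
Corneal layers multiply the surface value by 1.0 / 0.8 / 0.15
(epithelium / stroma / endothelium — the lipoidal endothelium carries
little), sclera by 0.6; the anterior chamber holds a uniform 3% of A₀; the
lens and vitreous are structurally zero, which is the defining negative
control of the whole analysis.

**Spectra and noise**: each scanned pixel's spectrum holds the drug peak at
290.17507 plus five matrix/background peaks inside m/z 200–310 (the
212.0318 CHCA sodium adduct at amplitude 800 serving as the lock-mass
anchor; background TIC 1460 per pixel). One seeded generator draws, in
fixed order: (1) a per-pixel mass drift ~ N(0, 0.0005 Da) clipped at ±4σ,
applied additively to every peak of that pixel, as calibration drift is;
(2) per-peak multiplicative log-normal noise with σ_log = 0.3; (3) a
per-peak additive exponential floor (scale 1). The same seed reproduces the
dataset bit-exactly (m/z as float64, intensities as float32, matching the
file encoding).

`expected_profile` is the closed-form oracle: ROI centers are placed on the
*analytic* ellipse by inverting the arc-length integral (cumulative
quadrature on 4097 parameter nodes), and the noiseless, TIC-normalized
field is averaged over scanned pixel centers inside each disk. It shares
the field definition with the generator but nothing with the pipeline
(no contour tracing, no KD-tree assignment, no spectra), which is what
makes pipeline-vs-oracle agreement informative.

## What the phantom tests do and do not show

Passing tests establish that the pipeline recovers a known spatial
structure through the full imzML → recalibration → normalization → line
scan → statistics chain, at realistic noise (σ_log = 0.3, drift comparable
to the extraction window) and with the ROI spot counts real line scans
have. They do not validate: ionization suppression beyond what a
multiplicative model captures, isotope envelopes and harmonics of real
FT-ICR spectra, histology-to-MSI registration (apex and superior hint are
user inputs here as in practice), 3-D section-to-section variation, or the
absolute intensity scale (phantom units are arbitrary).

## Problem sizes and tolerances used in the checks

The default phantom is ~83,000 pixels and runs through the pipeline in a
couple of seconds, so the replicate-based checks use it directly:
pipeline-vs-oracle agreement is asserted at 2% per position on a noise-free,
hotspot-free, uniform-shell phantom (with hotspots, a 2% per-position match
would require the traced contour and the analytic ellipse to agree in arc
position to a few μm on the steep Gaussian flanks, which no contour tracer
guarantees; hotspot configs are instead checked against brute-force
ground-truth averaging); decay-length recovery is asserted within 10% as
the median over 20 seeds, fitting log-linear regressions to the inverted
TIC normalization f = B·y/(1−y); and the hotspot-asymmetry recovery is
asserted in ≥80 of 100 seeded replicates. Exact-test correctness is
exhaustive for all sample sizes n₁, n₂ ≤ 6 against an independent
enumeration oracle. Round-trip and idempotence properties run 100
randomized cases each.

## Known limitations

- Compartment labels are defined on the pixel grid (Euclidean distance
  transform for depth, angular parameter for arc), so layer boundaries are
  quantized at the pixel pitch.
- The anterior-chamber region is a coarse half-space cut anterior of the
  lens; it is a placeholder compartment, adequate because no line-scan ROI
  reaches it.
- `set_origin` requires a closed contour; open paths (used in tests for
  straight-line geometry) take their origin via `origin_arc_um` directly.
- The exact Mann-Whitney enumerator is O(C(n₁+n₂, n₁)) and is capped by the
  auto rule at pooled n = 16; forcing `method="exact"` on much larger
  samples is possible but slow.
- Writing imzML delegates to pyimzml; the writer emits processed- or
  continuous-mode files with 64-bit m/z and 32-bit intensities only.
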