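# Methods

## The measurement model

A seedling carrying a systemic fluorescent marker sits on the bed of a dark
imaging chamber. A downward-looking camera sees the bed directly in the
central part of the frame; four planar mirrors, inclined at angle `θ` to the
direction of travel and with their bottom edges at distance `d` (cm) from the
chamber center, add four side views in the frame corners. Because a band-pass
filter passes only the dye's emission band, frames are 8-bit single-channel
images in which the background sits near zero and only the crop signal is
bright.

Along the axis of a mirror pair, a fluorescent point at lateral position `a`
and height `b` above the bed projects to the mirror-view coordinate

    x = (b + d)(c + d) / (−a + b + c + 2d)

with `c` the camera height; the opposing mirror of the pair sees

    x1 = (b + d)(c + d) / (b − a − c).

For a single mirror observed in two frames separated by camera travel `l`,

    x1 = N / (−a1 + b + c + 2d),  x2 = N / (−a2 + b + c + 2d),
    a2 = a1 + l sin θ,            N = (b + d)(c + d).

Both systems invert in closed form. The printed opposing-view denominators
differ by exactly `2(c + d)`, so `b = 2·x·x1/(x1 − x) − d`; the two-frame
denominators differ by `l sin θ`, so `N = l sin θ · x1 x2 / (x2 − x1)`.
Each solver rejects observations whose coordinate separation falls below a
parallax epsilon (default 1e−6 cm) instead of returning an ill-conditioned
inverse.

### The asymmetric opposing-view equation

The opposing-view denominator `b − a − c` is *not* the mirror image of the
single-view denominator `−a + b + c + 2d`; a physically symmetric pair would
use `a + b + c + 2d`. The package implements the equations exactly as given
and makes the renderer use the same forward maps the solvers invert, so
generator and solver are self-consistent under either convention. The
`eq4_variant` configuration key (`printed` | `symmetric`) selects the
convention; `printed` is the default. One observable consequence: under the
printed variant, opposite-pair scenes are not equivariant under a 180°
rotation of the scene (the symmetric variant is, and the test suite checks
equivariance for that variant).

### From 1-D solver output to a 2-D pixel center

The projection equations are one-dimensional along the pair axis. The second
in-plane coordinate is taken from the blob-centroid component parallel to the
mirror edge, which a planar reflection preserves; for an opposing pair the
mean of the two blobs' along-edge components is used. The solver's `a` is
placed along the pair axis through the frame center at `a · pixel_scale`.
The pair axis points toward the *top* mirror of each pair, which supplies the
first (single-view-form) coordinate. For the one-mirror case the travel
formula `a2 = a1 + l sin θ` is applied in each mirror's own outward frame,
and the along-edge apparent shift between the two frames is not modeled;
cross-frame blob matching is therefore nearest-centroid within the region.

## Case dispatch

Which informative regions (MC, TL, TR, BL, BR) contain at least one blob maps
to one of 16 cases; MC occupancy always wins (Case 1), four mirrors give the
diagonal cross (Case 2), three mirrors a diagonal plus a perpendicular
(Cases 3–6), two non-opposite mirrors two perpendiculars (Cases 7–10), two
opposite mirrors the pair solver (Cases 11–12), one mirror the two-frame
solver (Cases 13–16), and nothing `NOT_FOUND`. "Perpendicular" is read as
perpendicular to the mirror's bottom edge — i.e. along the corner diagonal —
not image-vertical; image-vertical lines would not intersect the diagonals
meaningfully for all four corners. The mapping is total over the 32 occupancy
patterns and is verified exhaustively, including its behavior under the
180° relabeling TL↔BR, TR↔BL (which exchanges Cases 3↔4, 5↔6, 7↔8, 9↔10,
13↔16 and 14↔15).

## Image pipeline

* Smoothing: 3×3 uniform mean with edge replication, re-quantized
  round-half-up — the smallest kernel that suppresses single-pixel shot
  noise, applied before thresholding.
* Threshold: global, strict `>`, default 4. Intensity 4 is the measured
  background ceiling of untreated plants, so it is excluded from foreground.
* Components: 8-connected; blobs below `min_area` are discarded.
  `min_area` defaults to 12 px: smoothing correlates noise over a 3×3
  footprint, so noise-induced exceedance clusters span up to ~9 px, while
  real blobs at the default photometry cover ~200 px. The floor must sit
  between those scales.
* Centroids are intensity-weighted for sub-pixel precision.

## The synthetic scene generator

The generator emulates the statistical structure the algorithm assumes, not
plant morphology:

* Frame: 1024×1024 px at 12 px/cm (a desk-scale stand-in for the
  4656×3520 sensor at 87 px/cm; the full-resolution scale remains the
  `RigGeometry` default and is used for the 43.5 px = 0.5 cm success-radius
  conversion).
* Rig defaults: `c` = 150 cm (a 50 mm lens framing a ~53 cm bed at that
  height), `d` = 18 cm, `θ` = 45°, `l` = 10 cm (≈0.9 m/s travel at a
  ~0.11 s frame interval).
* Layout: MC is the central 30% rectangle; each mirror area is a frame
  quadrant minus its MC overlap; BG is an 8 px border ring. Mirror views
  occupy most of the frame in the physical rig, and small corner patches
  could not contain the reflected images, whose offset from the frame center
  grows like `(b + 2d) · pixel_scale`.
* Photometry: isotropic Gaussian blobs, peak 200, σ = 3 px, over background
  offset 2, plus i.i.d. Gaussian sensor noise (σ = 2 by default), clipped
  and quantized to 8 bits.
* Plant pose: uniform in a disc of radius 10.5 cm about the bed center
  (seedlings sit near the row line), height `b` uniform in [1, 10] cm
  (cotyledon scale). Draws whose mirror images would leave their regions or
  the frame are rejected and resampled — such scenes would not carry the
  scenario label they were drawn for.
* Mirror-view positions come from the forward equations above: per-mirror
  single-view projection for the construction scenarios, the paired
  equations for opposite-pair scenes, the two-frame equations for
  single-mirror scenes. Consequently noise-free renders are invertible by
  construction, and a passing benchmark demonstrates the *internal*
  consistency of segmentation, dispatch and solvers — not robustness to
  lens distortion, perspective within mirror views, non-Gaussian blob
  shapes, multiple plants, or fluorescent weeds, none of which the
  generator produces.
* Determinism: a benchmark is seeded once; every scene's sampling and
  rendering derive from spawned child streams, so identical seeds give
  bit-identical frames.

## Evaluation

A localization succeeds when the estimated center lies within the success
radius (default 43.5 px, boundary inclusive) of the truth. Absent estimates,
out-of-frame intersections and degenerate solves count as failures with a
typed reason; out-of-frame centers are reported, never clipped. The
benchmark case mix is 32/67/54/65/44/38 scenes (total 300) for the central,
four-, three-, two-non-opposite-, two-opposite- and one-mirror scenarios.

## Numerical behavior and limitations

* Construction cases (1–10) are exact up to centroiding error; noise-free
  rendered scenes localize well within 1 px.
* The opposite-pair solve is well conditioned (the denominators differ by
  the large constant `2(c+d)`).
* The two-frame solve divides by `x2 − x1 ≈ x·l sinθ / (c + 2d)`, so
  centroid error is amplified by roughly `x/(x2 − x1)` (~30× at the default
  geometry). 8-bit quantization alone leaves a few pixels of error;
  sensor noise at σ = 2 typically stays well inside the success radius, but
  this is the least robust path — consistent with it being the weakest case
  on the physical rig.
* Success rates are monotone non-increasing in sensor noise; at σ ≥ 5 the
  smoothed noise field crosses the threshold often enough to create spurious
  blobs and misclassified cases.
* One plant per frame is assumed throughout; multi-plant frames and tracking
  across long frame sequences are out of scope.

## Problem sizes used in the checked runs

The shipped acceptance runs use the full 300-scene mix at 1024×1024 for the
noisy benchmark, the per-scenario counts (32, 44, 38) for the noise-free
scenario checks, 1000 random draws for solver round-trips, 100 instances for
the brute-force oracle comparison, 200 rendered blobs for centroid recovery,
and 100 scenes per noise level for the noise sweep.
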