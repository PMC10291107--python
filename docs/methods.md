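# Methods

## Measurement model

A dual-mobility liner surface is modelled as a sphere of nominal radius R
(internal 14 mm, external 31.5 mm by default — the largest commercial DM
size) sampled along meridional traces about the polar axis (+z). Each trace
starts at the pole and is sampled at a fixed arc pitch until the surface
terminus: the retentive bore at polar angle `bore_polar_angle` (default
100°) on the internal surface, or `external_overrun` (default 3 mm,
interpreted as arc length along the surface, not axial drop) past the
equator on the external surface. With the default 2.5° azimuthal spacing
and 0.3 mm pitch this yields 144 traces and roughly 11.8k internal / 25.2k
external points per surface, matching the scale of a real CMM programme for
this component size. Pitch and bore angle are not dictated by any standard;
both are configurable and the defaults are stated assumptions.

## Virtual CMM

The simulator perturbs each sampled point radially:

    r_measured = R + s · (D(θ, φ) + ε) / 1000

where D is the summed defect displacement in µm (penetration positive),
ε ~ N(0, σ²) is isotropic radial measurement noise in µm (default σ = 0;
the repeatability studies use σ = 1 µm, a realistic noise floor for a
bridge CMM probing polyethylene), and s = +1 for the internal concave
surface, −1 for the external convex one. Material lies outside the internal
sphere and inside the external sphere, so this sign makes a penetrating
defect remove material on both sides. Refixturing between repeats is
modelled as a rigid-body rotation/translation of the whole cloud —
clamping distortion, stylus-tip compensation, probing deflection and
thermal drift are deliberately not modelled. Every simulated point carries
its noise-free D as ground truth, and scans record their seed, so the whole
pipeline is testable without physical implants.

Defect primitives (all magnitudes in µm, penetration positive):

| kind | shape | extent parameter |
|---|---|---|
| wear_patch / circular_mark / polar_protrusion | rotationally symmetric cap, cosine (`m·cos(πγ/2γ₀)`, zero at rim) or Gaussian profile in great-circle distance γ | cap radius γ₀ (deg) |
| gouge | profile in angular distance δ to a great-circle path segment, Gaussian `m·exp(−(δ/w)²)` by default | half-width w (deg) |
| machining_ripple | `m·sin(2πθ/λ)` over the whole surface | wavelength λ (deg) |

Defects superpose additively and order-independently.

What the simulator does **not** emulate — and hence what green tests do not
demonstrate about real retrievals: spatially correlated form error, probe
dynamics, surface compliance, genuinely aspheric as-manufactured form, and
the wear-vs-creep ambiguity (a geometric method cannot separate the two).
Passing recovery tests show the *analysis* is correct, not that a physical
measurement would achieve the same uncertainty.

## Reference-sphere fit

The unworn reference is fitted per surface rather than taken from CAD or
pristine parts, so manufacturing variation between components is absorbed.
The objective is orthogonal-distance least squares, Σ(‖p−c‖−r)², the
metrology standard. Implementation: closed-form algebraic initialisation
(linear least squares on ‖p‖² = 2p·c + ρ, degenerate/coplanar clouds
rejected by rank), then Gauss–Newton with step-halving damping, which
guarantees the residual sum never increases relative to the initialiser.
Convergence: centre and radius updates both < 1e−6 mm within 100
iterations; non-convergence is flagged, not raised. Tests verify agreement
with an independent Nelder–Mead minimiser of the same objective to
< 1e−4 mm on partial, noisy caps.

Because it is unknown whether damaged regions should be excluded from the
reference, both behaviours are provided: the plain fit uses all points; the
robust variant iteratively drops points with |residual| > k·1.4826·MAD
(k = 3) until the inlier set is stable (≤ 10 rounds). Robust fitting is the
sensible default when visible damage covers a non-trivial surface fraction;
for mildly worn or pristine parts the two agree to well under 0.1 µm. A
`rim_exclusion` band (arc mm, default 0 for synthetic data since the
simulator has no rim artefacts) drops points near the external trace ends
before fitting, mirroring the practical inaccessibility of the rim.

## Deviation mapping and regions

Geometric variance per point: d = s·(‖p−c‖−r)·1000 µm, with spherical
coordinates taken about the fitted centre and the scan's polar axis. The
summaries are the arithmetic mean, median (mean of the middle two for even
counts), minimum and maximum over all points, computed on the raw field
with no outlier handling. Repeatability across n repeated measurements is
the sample standard deviation (n−1 denominator; with n = 5 the choice is
material) of the fitted radius and of each summary.

Region labelling automates what is otherwise a visual read of the heatmap:
points beyond ±threshold (default 20 µm, the scale below which only
manufacturing artefacts are expected) are grouped by 4-connectivity on the
(trace × point-index) grid with azimuthal wrap-around between the first and
last trace; components smaller than `min_points` (default 5) are dropped.
Each region reports polarity, the extreme member deviation as its peak, a
point count, and a solid-angle estimate (Σ sin θ·Δθ·Δφ over members). Under
noise the single-point peak is biased by the sample extreme (~2.5σ for a
few hundred members), so when *sizing* a small feature the recommended
estimator is the extreme cell mean of the rasterised map, which averages
co-located samples (the 144 duplicated pole points make this especially
effective for polar features); the sensitivity checks use that estimator
and recover a seeded 15 µm polar protrusion to well within 3 µm under 1 µm
noise.

## Exploded projection and rendering

For polar angle θ ≤ 90°: ρ = r·sin θ (true top-down view); for θ > 90°:
ρ = r·(1 + (θ−90°) in radians). The mapping is continuous at the equator
(sin 90° = 1), azimuth-preserving, and strictly increasing in θ along a
meridian, so supra-hemispheric points never fold onto sub-equatorial ones.
A pure azimuthal-equidistant mapping (ρ = r·θ) is available behind a flag;
it avoids the slope discontinuity at the equator at the cost of distorting
the familiar top-down view of the lower hemisphere. Rasterisation bins
points into a polar grid (default 144 azimuth × 100 radial cells — one
azimuth bin per trace) of per-cell mean deviation; empty cells are masked,
never zero-filled. Colour limits are symmetric, ±max|d| rounded up to the
next 10 µm (minimum ±10 µm), on a diverging map with penetration warm and
protrusion cool; the equator is drawn as a black circle at ρ = r. All of
map, limits and resolution are style, not contract, and are overridable.

## Numerical and design notes

- Lengths are mm internally; deviations and noise are µm at the API
  surface. Angles are degrees at the API surface, radians internally.
- The CSV scan format stores coordinates as shortest round-trip decimals
  and is re-read with correctly-rounded parsing, so write→read is
  bit-lossless.
- All randomness flows through seeded `numpy` generators; a scan records
  its seed, and reports echo every option needed to re-run them.
- Degenerate inputs fail loudly: < 4 or coplanar points, pitch longer than
  a trace, non-orthonormal "rotations", empty fields, < 2 repeats.
- The repeatability and sensitivity studies in `scripts/acceptance.py` use
  the full 144-trace protocol (≈ 12k/25k points per surface); unit tests
  use coarser protocols (36 traces, 1 mm pitch) where only correctness, not
  sampling density, is exercised.

## Known limitations

Retentive-bore and chamfer geometry is outside the assessed surface; wear
and deformation are indistinguishable; the fitted sphere absorbs any
uniform size change (a liner worn perfectly uniformly would read as
pristine with a different radius); and simulated repeatability reflects
only the modelled error sources, so it bounds the analysis contribution,
not a physical instrument's.
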