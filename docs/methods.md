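# Methods

## Scope and assumptions

`memcurv` treats the membrane as a closed plane curve: the bilayer is
assumed strongly curved in the XZ plane and nearly planar along Y, which
holds when the Y box dimension is small against X and Z (ribbon-like
patches, e.g. 111 × 12.4 nm initial geometry). Under this assumption the
membrane shape is fully described by its midline in XZ; no 2D surface
parameterization, curvature tensor or bending-modulus estimate is
attempted. Inputs violating the aspect-ratio assumption are the caller's
responsibility.

All geometry uses one marker bead per lipid (the phosphate headgroup bead
of coarse-grained models; cholesterol's hydroxyl head bead plays the same
role). Coordinates are nm, times ns, energies k_BT (Joules also reported).

## Leaflet assignment

Marker beads at PBC distance strictly below r_p form graph edges; the two
connected components of that graph are the monolayers. The comparison is
strict (`< r_p`) so the contract is reproducible; the boundary has measure
zero for real data. Exactly-two components is enforced as a hard error —
one component means the cutoff exceeds the inter-leaflet gap (or the
leaflets touch), more than two means a fragmented leaflet — both are data
errors worth surfacing rather than repairing silently.

- **r_p = 2.0 nm (default).** Between typical in-leaflet marker spacing
  (~0.8 nm at ~0.65 nm² area per lipid) and the headgroup–headgroup
  bilayer thickness (~4 nm).
- **Orientation.** "upper" is the component with larger PBC-safe mean Z.
  For every membrane that is a (possibly overhanging) graph over X this
  agrees with the local-normal convention, because the upper leaflet is
  offset +h/2 along upward-pointing normals. When mean Z ties (vesicle
  cross-sections: concentric leaflets), the radially outer component is
  "upper". Assignment is done once on the first frame and propagated by
  molecule identity — lipid flip-flop is far slower than trajectory
  lengths.

## Local bilayer frame

`Local(p)` returns the bilayer centre and unit normal near an arbitrary
point. Markers of each leaflet are selected in a cylinder around `p`:
radius `r_loc` perpendicular to the local normal direction (in XZ; the Y
extent of the ribbon always contributes fully) and half-height
`axial_cut = 4 nm` along it. The per-leaflet weighted centroids give the
centre (their midpoint); the normal is perpendicular (in XZ) to the
principal axis of the pooled, per-leaflet-centred marker scatter, oriented
from the lower to the upper centroid.

Three numerical choices matter and were driven by measured failure modes
on synthetic membranes:

1. **Cylinder, not XZ-ball.** A plain XZ-radius ball of r_loc = 3 nm
   cannot reach the opposite leaflet (4 nm away); the neighborhood must be
   elongated along the normal. The axis starts from the previous trace
   step's normal (or the direction between each leaflet's nearest marker)
   and is refined by one re-selection pass.
2. **Smooth lateral weights.** Markers are weighted with a Gaussian in the
   lateral coordinate (σ = r_loc/3, shifted to vanish exactly at r_loc).
   A hard window makes the centroid jump whenever a marker column crosses
   the edge, imprinting the marker-grid spacing on the midline; with bead
   noise, the edge column flickers independently per leaflet and tilts the
   normal by degrees.
3. **PCA tangent, not inter-centroid normal.** The inter-centroid
   direction reproduces any tilt of the selection axis exactly (the two
   selection windows shift tangentially by ±hθ/2), so iterating it never
   converges. The principal axis of the pooled centred scatter is
   first-order insensitive to axis tilt, making the refinement contract.
   Measured normal errors on noisy sinusoid membranes: ≲2° (was up to 14°
   with the inter-centroid rule).

`r_loc = 3.0 nm (default)`: large enough that each window holds
𝒪(100) markers (noise averaging), small against the smallest radius of
curvature of interest (~10 nm), so the centroid bias toward the concave
side stays ≪0.2 nm.

## Midline tracing

From the marker bead of the lowest-numbered lipid, the trace alternates a
tangential prediction `c + s·t`, `t = n × ĵ` (sign fixed to advance in +X
on the first step, then kept by continuity through vertical segments,
where n × ĵ flips sign), and one local-frame refinement at the predicted
point. Two deliberate deviations from the plain
"next point = Local(prediction)" update:

- the refinement correction is applied **only along the local normal**, so
  the tangential advance stays exactly `s` and the arc-length
  parameterization l_i = i·s remains faithful (the local centre's
  tangential coordinate carries marker-grid granularity);
- after closure (PBC distance to the start < s after >1 step), the closed
  polyline is **resampled to exactly uniform spacing** total/N with
  N = round(total/s) (N+1 if that spacing would reach s). The raw trace
  ends with a seam segment of arbitrary length < s, which would break the
  uniform-spacing assumption of the FFT; the resampling removes it. Every
  segment, including the closing one, is strictly shorter than s.

Together these reduced the pointwise curvature error on noisy sinusoid
membranes from ~8–13% RMS to ~2–3% where the curve is band-limited above
λ_c. `max_steps` defaults to 4·Lx/s — the meander can be several times
longer than the box. The midline Y coordinate is reported at the ribbon
mid-plane; it is carried but unused by the curvature. One refinement per
step (no iteration to convergence) proved sufficient at these noise
levels.

## Spectral curvature

X(l) and Z(l) are unwrapped across the box; a closed trace generally winds
the box once in X, so the linear trend (winding number × box length over
N·s) is separated and stored, leaving periodic residuals for the FFT. The
wavelength of harmonic k is λ_k = N·s/k. The low-pass filter zeroes
components with λ ≤ λ_c (hard cutoff, no taper); the DC term and winding
trend always survive. λ_c = 0 is therefore the exact identity, and the
filter is a projection (idempotent, energy non-increasing).

Derivatives multiply each component by i·2π/λ (and the square for second
derivatives); the trend contributes its constant slope to first
derivatives only. The 2π is required: a closed circle fed through the
pipeline returns |κ| = 1/R to 0.2% with it and is off by (2π)² without.
Mean curvature is reported as ⟨|κ|⟩ — the signed mean of a closed meander
is ≈0 and cannot match radius-of-curvature style summaries (0.06 nm⁻¹ ↔
R = 16.7 nm).

**Choice of λ_c.** The default 15 nm suits membranes whose genuine
features live at radii ≳10 nm. It is a physical resolution limit, not just
denoising: a sinusoid of 30 nm wavelength has real curvature content in
its 3rd arc-length harmonic (λ ≈ 10–12.5 nm), which the filter removes —
pointwise errors of ~9–33% RMS against the unfiltered closed form on such
curves are the information-theoretic floor, not implementation error (the
pipeline matches a truncated-Fourier oracle of the same band to <5% RMS
there). λ_c must be chosen per system, smaller for more sharply featured
membranes.

Degenerate parameterizations (Ẋ² + Ż² < 10⁻¹²) raise an error rather than
returning inf curvatures. Per-frame failures in trajectory sweeps are
skipped with a warning; more than 10% skipped frames aborts the run.

## Curvature statistics and free energies

Distributions are over |κ| with density normalization (Σ P·Δκ = 1);
default bin width 0.0085 nm⁻¹, configurable, with an optional fixed upper
edge so two distributions share binning exactly. Sampling rules follow the
two study conditions: every midline point (each frame), or the nearest
midline point to each cholesterol (nearest by PBC distance, ties to the
lower index). These two rules are *not* re-weighted against each other;
the asymmetry is inherited from the study design.

Boltzmann inversion E = −k_B T ln(P_a/P_b) at T = 320 K uses
k_B = 1.380649×10⁻²³ J/K. Bins where either distribution holds fewer than
n_min = 10 samples are masked (NaN) — no extrapolated "walls" are
invented where there is no data. The profile is antisymmetric under
swapping its inputs by construction.

The cholesterol partition ratio pools counts over frames before dividing
(robust to frames with momentarily empty domains); mean-of-ratios is not
used. The ratio is invariant under frame duplication.

## Flip-flop kinetics

An event requires both the leaflet and the lipid-type of the occupied
domain to change between consecutive, uniformly spaced frames. Requiring
the domain-type change disregards membrane regions where lateral domain
drift has put the same lipid species in both monolayers, where a leaflet
change is not a meaningful transbilayer transition.

The interval histogram (pooled over molecules) is fitted by weighted
nonlinear least squares with A₁e^(−t/t₁) + A₂e^(−t/t₂), Poisson weights
σ = √max(count, 1), multi-started over a log grid of time-constant pairs
spanning [bin width, max interval]; results are ordered t₁ ≤ t₂.
Decaying exponentials are the only form with finite interval statistics.
Alongside the double fit, a single-exponential fit and an AIC comparison
are reported, plus flags for unresolved timescales (t₂/t₁ < 2) and for
t₁ within 25% of the frame spacing — the signature of head groups near
the bilayer centre rattling between monolayers, a detection artifact;
only t₂ should then be read as the physical flip-flop time. Debouncing
(dropping event pairs that cancel within a window) is available but **off
by default**, mirroring the detect-then-discard-t₁ convention. An
interval-level EM maximum-likelihood fit of the exponential mixture is
provided as a cross-check; on 10⁵ synthetic intervals it agrees with the
histogram fit within a few percent (the histogram fit shows a ~4–5%
downward bias on t₂ from weighting by observed counts — inherent to the
histogram method, well inside the recovery tolerance).

Default interval bin width: 2 ns (half the 4 ns frame spacing — resolves
the fast component while keeping tail bins populated).

## Synthetic membranes

The generator emulates the reference study geometry: a ribbon of
prescribed analytic midline (flat / sinusoid / Fourier series / circle),
leaflets offset ±h/2 = ±2.0 nm along the *local analytic normal*
(constant thickness in bent regions — exactly what the local-frame
operator assumes), markers on a regular grid in arc length and Y,
block-wise lipid domains along the arc with the block pattern inverted
between leaflets (an upper DOPC block faces a lower DOPS block), optional
cholesterol heads inset 0.6 nm from their leaflet surface, and isotropic
Gaussian bead noise, σ = 0.1 nm by default (small against r_p and the
leaflet separation; bead-scale thermal disorder). The `paper` preset
carries the reference composition — 4032 lipids (2016 of each species,
144 × 14 grid per leaflet) and 784 cholesterol (chol:lipid ≈ 0.2) in a
12.4 nm-wide box — on a 6 nm-amplitude, 74 nm-wavelength meander-like
sinusoid. Random cholesterol placements avoid lipid-block boundaries by
1.5 nm so planted domain labels are unambiguous.

What the generator does **not** emulate: physical dynamics (shapes are
prescribed, not simulated), thermal undulation spectra, area-per-lipid
adjustment, electrostatics, or genuinely diffusing cholesterol. Passing
tests therefore demonstrate the *measurement chain* is correct on
membranes with known geometry; they do not validate force-field-level
behaviour of real trajectories.

Trajectories share topology across frames (counts fixed by the first
frame while the curve morphs); cholesterol leaflet transitions are
planted via an explicit schedule, giving exact ground-truth event lists
for the detector. `generate_intervals` draws seeded exponential-mixture
waiting times as the fitting oracle.

## Degenerate inputs and tie-breaks

- Equidistant nearest markers: lowest molecule_id wins (deterministic).
- Histogram boundary values: half-open bins, with one bin past the
  maximum so the top edge is never right-inclusive.
- Ambiguous unwrapping (consecutive points half a box apart) is an error,
  not a guess.
- Empty distributions, empty interval records, non-uniform frame times,
  and mixtures with invalid weights all raise typed errors.

## Known limitations

- Membranes curved in more than one plane are out of scope by design.
- λ ≤ λ_c structure is invisible; sharp kinks are reported smoothed.
- The local-frame centroid is slightly biased toward the concave side at
  radii approaching r_loc; midline points are accurate to ~0.1–0.2 nm on
  the synthetic benchmarks.
- Free-energy profiles from finite sampling inherit a global offset equal
  to the log normalization ratio of the two conditions; only differences
  across κ are physical.
- The double-exponential histogram fit is least-squares (not maximum
  likelihood); use the EM cross-check when the tail is sparse.
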