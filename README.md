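# memcurv

Curvature analysis of strongly curved lipid bilayers from coarse-grained
simulation data.

Most membrane-analysis tools assume a planar bilayer with a global normal
along Z. That assumption breaks for strongly bent membranes — meandering
asymmetric patches, budding intermediates, vesicle cross-sections — where
every quantity of interest (leaflet identity, bilayer thickness, lipid and
cholesterol localisation) must be defined relative to a *local* membrane
frame. `memcurv` reconstructs that frame for membranes curved in the XZ
plane and nearly planar along Y, and builds curvature-resolved statistics
on top of it. It is aimed at people post-processing coarse-grained MD
trajectories of curved bilayers (e.g. MARTINI-scale models of mixed
DOPC/DOPS membranes with cholesterol), and works from GRO/PDB + XTC/TRR/DCD
files, or from plain CSV/NPZ bead tables.

## Method

1. **Leaflet assignment.** One headgroup marker bead per lipid (the
   phosphate bead, `PO4`). Markers closer than a cutoff r_p = 2.0 nm
   (periodic boundaries respected) are joined into a graph; its two
   connected components are the monolayers. Anything other than exactly
   two components is reported as an error. Done once per trajectory and
   propagated by molecule identity.
2. **Midline tracing.** A local frame operator returns the bilayer centre
   c and unit normal n around any point, from the two leaflets' marker
   centroids in a cylinder around the local normal. Starting at an
   arbitrary lipid, the trace repeatedly steps a distance s = 1 nm along
   the tangent t = n × ĵ (ĵ ⊥ XZ plane) and re-centres with the local
   frame, until it returns to its starting point. The result is a closed
   curve sampled uniformly in arc length, X(l_i), Z(l_i) with l_i = i·s.
3. **Spectral curvature.** Both coordinate series are unwrapped across the
   periodic box, split into a linear winding trend plus periodic residual,
   and Fourier transformed. Components with wavelength λ ≤ λ_c (default
   15 nm) are discarded — they carry bead-scale noise that second
   derivatives would amplify. Derivatives are computed by multiplying each
   component of wavelength λ by i·2π/λ, and the signed curvature follows
   from the plane-curve formula

       κ(l) = (Ẋ Z̈ − Ż Ẍ) / (Ẋ² + Ż²)^{3/2}   [nm⁻¹]

4. **Curvature-conditioned statistics.** |κ| sampled at midline points or
   at cholesterol positions is binned into normalized distributions; two
   equilibrium distributions are compared by Boltzmann inversion,
   E(κ) = −k_B T ln(P_a/P_b) at T = 320 K, with under-sampled bins masked.
   The cholesterol partition ratio r_DOPC/DOPS is the time-averaged,
   pooled-count occupancy ratio between lipid domains.
5. **Flip-flop kinetics.** A cholesterol flip-flop is counted when its head
   group changes monolayer *and* lipid-domain type between consecutive
   frames (the second condition suppresses regions where lateral domain
   drift puts the same lipid species in both leaflets). Waiting times are
   pooled and their histogram fitted with
   P_flip(t) = A₁e^(−t/t₁) + A₂e^(−t/t₂); a fast t₁ at the frame spacing
   is flagged as a detection artifact, the slow t₂ is the physical
   flip-flop time. An interval-level EM maximum-likelihood fit is
   available as a cross-check.

A synthetic-membrane generator (`memcurv.synthetic`) builds bilayers whose
midline is a prescribed analytic curve (flat, sinusoid, Fourier series,
circle) with leaflets offset ±h/2 along the local normal, block-wise
DOPC/DOPS domains inverted between leaflets, planted cholesterol and
Gaussian bead noise — so every pipeline stage can be tested against closed
forms.

## Worked example

```python
import memcurv as mc

# one period of a sinusoid membrane, amplitude 5 nm, wavelength 50 nm,
# 0.1 nm bead noise — ground truth is known analytically
spec = mc.sinusoid_spec(amplitude=5.0, wavelength=50.0, seed=0)
frame, truth = mc.generate_membrane(spec)

leaflets = mc.assign_leaflets(frame, r_p=2.0)
midline, profile = mc.frame_curvature(frame, leaflets, lambda_c=15.0)
print(f"midline points : {midline.n_points}")
print(f"traced length  : {midline.length():.2f} nm (analytic {truth.arclength:.2f} nm)")
print(f"mean |kappa|   : {mc.mean_curvature(profile):.4f} nm^-1")
```

prints

```
midline points : 55
traced length  : 54.55 nm (analytic 54.62 nm)
mean |kappa|   : 0.0409 nm^-1
```

The traced length matches the analytic arc length to 0.13%, and the crest
curvature (max |κ| = 0.0777 nm⁻¹) agrees with the closed form
A(2π/L)² = 0.0790 nm⁻¹ to under 2%. A mean curvature of 0.06 nm⁻¹
corresponds to a radius of curvature of 16.7 nm (κ = 1/R), which the
spectral pipeline reproduces on a closed circle to 0.2%.

The same pipeline runs from the shell:

```
memcurv synth --preset paper --seed 1 --out membrane.csv
memcurv curvature --input membrane.csv --lambda-c 15 --out curvature.csv
memcurv report --preset paper --seed 1 --frames 12 --out report.json
```

`memcurv report` emits one JSON bundle with the mean-curvature time
series, curvature distributions, both free-energy profiles, the partition
ratio and the flip-flop fit.

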