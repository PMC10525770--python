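# Methods

This note documents the models, numerical choices and defaults behind each
pipeline stage, and what the synthetic data do and do not establish.

## Parametric bifurcation geometry

The vessel is modeled as three variable-radius tubes in a common plane: the
CCA along +x ending at the bifurcation apex (origin), the ICA at
`ica_branch_angle` on the +y side, the ECA at `eca_branch_angle` on the −y
side.  The surface is the zero level set of a smooth-min (log-sum-exp)
union of capsule distance fields, polygonized by marching cubes and wrapped
as a `trimesh` surface.  The smooth-min width (default 0.2 × CCA radius)
acts as the apex fillet: it rounds the branch junction and prevents
self-intersection at large total angles.  Branch ends carry spherical caps
so the mesh is watertight; a lateral-clearance check rejects parameter
combinations whose ICA/ECA tubes would merge downstream of the junction.

Radius profiles:

- CCA: linear taper from the inlet radius to `cca_taper_ratio` × inlet
  radius at the apex (default ratio 0.9 — the taper is anatomically
  attested but its magnitude is not standardized, so it is configurable).
- ICA: a junction blend over one CCA diameter, then a cosine-squared
  spindle bulge (the sinus) of length `sinus_length` peaking at
  `sinus_max_diameter`, then a constant downstream radius
  `ica_cca_diameter_ratio` × inlet radius.  Defaults: sinus max diameter
  1.1 × inlet diameter, sinus length 3 × ICA downstream diameter.  Setting
  the sinus maximum equal to the ICA downstream diameter removes the bulge
  (degenerate, plain tube).
- ECA: junction blend to a constant `eca_diameter` (default 0.7 × inlet).

Entry/exit extensions (defaults 3 inlet diameters / 8 branch diameters)
exist to give downstream analyses an undisturbed tube; tests shorten them.

**Measurement.**  `measure_geometry` recovers parameters from the mesh
alone.  Diameters come from plane/mesh cross sections: segments from
`trimesh.intersections.mesh_plane` are clustered into loops, the loop
nearest the probed centerline station is circle-fitted (Kasa), and a
chord-sagitta correction removes the leading inward bias of an inscribed
triangulation (each section vertex lies on a mesh edge, i.e. on a chord of
the smooth surface; the deficit is s(1−s)·L²/2R per vertex).  With this
correction the measured diameters change by < 0.2% when the grid spacing is
halved, and presets at the default resolution (140 points along the longest
box edge) are recovered to ~0.1%.  The inlet diameter is extrapolated to
the inlet plane from two stations inside the tapered entry; branch angles
come from centerline tangents at the apex and are exact by construction.

**Sinus frame.**  Origin at the apex, first axis along the ICA centerline
over the sinus segment, completed to a right-handed orthonormal basis
(orthonormal to 1e-12); ξ is the axial coordinate in this frame.

## Pulsatile inflow and outlets

The digitized patient-averaged CCA waveform is not part of the package
inputs, so the inflow is a documented surrogate: the truncated Fourier
series (default 8 harmonics) of a periodized von Mises pulse
exp(κ·cos 2π(t−t_peak)/T) with κ = 10 and a systolic peak at t/T = 0.15.
All cosine coefficients about the peak are positive, so the series attains
its maximum exactly at t_peak and its mean is the constant term; the affine
calibration to the target peak/mean Reynolds numbers is therefore
closed-form, idempotent, and exact to machine precision on any phase grid
containing t_peak.  The defaults reproduce peak Re 1530 / mean Re 385 at
D = 6.5 mm, ν = 6.95e-7 m²/s, T = 1 s, with a diastolic plateau near
Re ≈ 210 and no inlet reversal.  A measured waveform can be supplied as a
two-column CSV (`waveform_from_samples`) when exact replication is needed.

Density is needed only to convert ν to μ for WSS; the default is
1050 kg/m³ (whole blood) and every WSS output records the (ρ, ν) used.
Outlets are purely resistive, Δp = R·Q, with the published resistance
values as defaults; the three-element Windkessel is deliberately out of
scope.  The ECA flow is defined by continuity (Q_eca = Q_cca − Q_ica).

## Synthetic flow fields

Each generator is an exact solution or exact construction with ground truth
attached:

- **Poiseuille / Womersley pipe flow.**  The Womersley series matches the
  waveform's cross-sectional mean velocity mode by mode; profiles use
  J₀(i^{3/2}α_k r/a) with α_k = a√(kω/ν), and the analytic wall shear trace
  and per-mode pressure-gradient amplitudes are attached.  Pipe point grids
  are sine-clustered toward the wall and can embed exact wall-sample radii
  so that wall-shear checks isolate the derivative approximation.
- **Vortex tubes.**  Rigid rotation (λ₂ = −ω² off axis), simple shear
  (λ₂ = 0), Lamb–Oseen (pressure from radial-momentum quadrature of
  ρu_θ²/r with p(∞) = 0, splined).
- **Hairpin filament.**  Biot–Savart over a Λ-shaped polyline with
  spherical-Gaussian core smoothing, σ = r_c/√2.  The line integral of a
  spherical Gaussian is a 2-D Gaussian, so a straight filament induces
  exactly the Lamb–Oseen profile with core radius r_c; the quadrature
  refines segment-halving until the maximum velocity change is below an
  absolute tolerance (default 1e-8 m/s) and errors out with a step-size
  report otherwise.
- **Moving pressure minima.**  A Gaussian well of prescribed depth/width
  riding a prescribed trajectory over a uniform background, with the exact
  trajectory and its velocity attached.

What these emulate: the kinematic structure of pulsatile bifurcation CFD
fields (boundary-layer shear, vortex cores with pressure minima, secondary
swirl, favorable/adverse gradient cycles).  What they do not: Navier–Stokes
dynamics, turbulence/transition, geometry-coupled vortex formation, or wall
compliance.  Passing tests therefore certify the *analysis operators* at
their stated tolerances, not the physiological magnitudes of any real flow.

## λ₂ identification and region tracking

Gradients: second-order central differences (second-order one-sided at
boundaries) on structured grids; distance-weighted least squares over
k-nearest neighbors (default 16) on point clouds, exact for affine fields
and rotation-equivariant.  S²+Ω² is symmetrized before `eigvalsh` to absorb
round-off; eigenvalues are sorted descending.

Regions are 26-connected voxel components (edge-connected components with a
user adjacency on point clouds) of {λ₂ < threshold}, discarding components
below `min_size` (default 10) points.  The default automatic threshold is
−5% of the 99th percentile of |λ₂| over the series — scale-free and always
reported in output metadata.  The pipeline instead keys the fraction off
the series maximum (percentile 100), which filters background vortices far
weaker than the structure of interest; because detected existence windows
depend on the iso-value and no universal reference value exists, the
threshold is always explicit configuration, and both comparative runs
share a single value.

Frame-to-frame matching: maximum bounding-box overlap, ties broken by
centroid distance then region id — deterministic.  A track's window is the
first/last phase at which its matched region exists.

## Wall shear stress

τ_w = μ·u_t(y)/y from a wall-adjacent sample at distance y (first order),
or μ·(4u_t(y) − u_t(2y))/(2y) (second order); the wall-normal component is
projected out, so τ_w is tangent to machine precision.  Sample velocities
are exact lookups when the sample points are snapshot points, trilinear
interpolation on structured grids otherwise.  TAWSS is the periodic
trapezoid (= plain mean over uniform phases with the closing endpoint
excluded).  For the pulsatile check the per-phase error is normalized by
the cycle-maximum analytic shear, because instantaneous wall shear crosses
zero during the cycle and a pointwise relative error is undefined there.

Overlap: high-WSS band = faces above the q-quantile of |τ_w| (default
q = 0.8); vortex footprint = faces within distance d (default 2 wall cell
sizes) of any region point; statistic = Szymkiewicz–Simpson
|A∩B|/min(|A|,|B|).  Both knobs are configurable; "high-WSS band" is a
qualitative notion with no standard numeric definition.

## Core tracking and kinematics

The core is the minimum-pressure candidate inside the search window
(optionally restricted to near-wall points), with deterministic tie-breaks:
nearest to the previous position, most upstream at the first frame.  The
window is stationary or advected with the instantaneous bulk axial
velocity.  A minimum pinned to the window's axial boundary (within ~half a
grid cell) is treated as the core having left the field of view; after
`k = 3` consecutive missing frames the trajectory is truncated and the end
phase logged (deterioration).  Core pressure is nondimensionalized by P0,
by default the tracked pressure at reference phase t/T = 0.191.

Velocity/acceleration: optional 3-point moving average (raw available),
then second-order `np.gradient` — exact for quadratic ξ(t).  Events:
stillstand at velocity zero crossings (linearly interpolated phase),
upstream-motion onset at +→− sign changes, deterioration at truncation.

## Secondary flow and the axial gradient

Planes: six stations uniformly spaced in arc length across the sinus
(configurable), square in-plane sample grids with a circular mask; the
decomposition is u·n̂ (axial) plus the in-plane remainder, which preserves
|u|² to round-off.  u/U uses the mean inlet speed at reference phase
t/T = 0.27 by default.  Pair detection: 8-connected blobs of
{|ω_n| > f·max|ω_n|} (f = 0.2), blob circulation by area integral, pairs =
opposite-sign blobs with circulation ratio in [0.5, 2] and separation below
the plane diameter, matched greedily from the strongest blob (nearest
compatible partner) — deterministic and rotation-invariant.

ΔP/Δξ_ICA uses area-averaged pressures at the sinus entry and exit stations
(a point-probe option exists) divided by the sinus length.  Extrema are
classified on the periodically extended trace with a prominence floor of
10% of the trace range: favorable = negative minima, adverse = positive
maxima.  Percent differences pair extrema of equal class by nearest phase,
(a−b)/|b|·100.

## Comparative pipeline

The pipeline generates, per geometry case, a synthetic sinus series in
sinus-frame coordinates (x = ξ) inside a tube bounding the sinus: pulsatile
parabolic axial flow driven by the calibrated waveform; a persistent
counter-rotating axial tube pair (Dean-type secondary flow); a transverse
vortex tube with a smoothstep-plateau circulation envelope over the case's
vortex window; a waveform-driven axial pressure gradient
(−8μU/a² − ρ dU/dt, scaled per case) plus a Gaussian wall well riding the
prescribed core trajectory.  The per-case schedule defaults emulate the
phenomenology documented for these two anatomies in the hemodynamics
literature — healthy window 0.23–0.98
with a slow-and-recover core; pre-disposed onset 0.05 earlier, end 0.42,
stall-and-reverse core, favorable-gradient scale 0.45 — and are ordinary
configuration, not measurements: the comparative numbers in `report.json`
(windows, lifespan ratio, onset shift, percent differences) are computed by
the analysis stages from these synthetic fields.

Default problem sizes (resolution 110; 40 time steps on a 40×27×27 series
grid) keep a full two-case run under a minute on one CPU; the test suite
uses coarser settings.  Every stage is deterministic; the seed feeds only
optional noise injection, and identical configs yield byte-identical
reports (floats rounded to 10 significant decimals in the report).

## Known limitations

- No Navier–Stokes solve: all flow fields are analytic constructions.
- The geometry is planar and idealized; patient-specific anatomy, plaque
  and fluid–structure interaction are out of scope (rigid walls,
  Newtonian fluid).
- Detected existence windows depend on the λ₂ iso-value; no universal
  default exists, so the threshold policy is explicit configuration.
- `measure_geometry` assumes near-circular cross sections; strongly
  non-circular lumens would need an elliptic fit.
- VTK output is write-only ASCII XML (VTU/VTP) for viewing; stages exchange
  in-memory objects or `.npz` archives.
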