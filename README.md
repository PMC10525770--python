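# cabvort

Vortex, wall-shear-stress and pressure-gradient analysis of pulsatile flow
in parametric carotid-artery-bifurcation (CAB) models.

## The problem

Atherosclerotic plaque forms preferentially in the internal-carotid-artery
(ICA) sinus, where wall shear stress (WSS) is low and the flow separates.
Coherent vortical structures — in particular a hairpin-shaped vortex that
forms in the sinus during the cardiac cycle — locally *raise* WSS and are
therefore candidates for an atheroprotective mechanism.  Whether such a
structure forms early, persists, and keeps translating downstream depends on
vessel anatomy: a larger ICA branching angle and a smaller ICA/CCA diameter
ratio (the clinically "pre-disposed" anatomy) weaken the favorable axial
pressure gradient over the sinus, stall the vortex core, and let the
structure deteriorate early.

`cabvort` packages the full analysis chain needed to study this
quantitatively:

- **geometry** — watertight parametric CAB surface meshes with branch
  centerlines and a sinus-anchored coordinate frame.  Two presets:
  *healthy* (symmetric 60° total branch angle, ICA/CCA diameter ratio 0.7)
  and *pre-disposed* (75° total angle with a 45° ICA branch, ratio 0.5).
- **boundary** — a pulsatile CCA inflow waveform calibrated so that
  Re(t) = U(t)·D/ν peaks at 1530 with a period mean of 385 (D = 6.5 mm,
  ν = 6.95·10⁻⁷ m²/s, period T = 1 s); resistive outlets Δp = R·Q
  (R_ICA = 1.5·10⁶, R_ECA = 11·10⁶ Pa·s/m³); CFL utilities.
- **synthetic** — analytic flow fields carrying known ground truth
  (Poiseuille and Womersley pipe flow, Lamb–Oseen tubes, Biot–Savart
  hairpin filaments, advecting pressure minima), standing in for a CFD
  solution so that every analysis stage can be verified exactly.
- **vortex** — the λ₂ criterion: velocity-gradient tensor J, its
  strain/rotation split S = (J+Jᵀ)/2, Ω = (J−Jᵀ)/2, eigenvalues
  λ₁ ≥ λ₂ ≥ λ₃ of S² + Ω², connected-region extraction (λ₂ < threshold)
  and frame-to-frame tracking of each structure's existence window.
- **wall** — instantaneous WSS τ_w = μ(∂u/∂y)|wall, its cycle average
  TAWSS = (1/T)∫|τ_w|dt, and the spatial overlap between the high-WSS wall
  band and the wall footprint of vortex regions.
- **tracking** — the vortex-core wall pressure minimum located inside a
  stationary or advected search window, expressed through the axial sinus
  coordinate ξ(t) and differentiated to core velocity/acceleration with
  stillstand / upstream-motion / deterioration events.
- **secondary** — velocity decomposition on six centerline-perpendicular
  planes (u/U nondimensionalization), counter-rotating (Dean) pair
  detection from in-plane vorticity, and the axial pressure-gradient trace
  ΔP/Δξ_ICA over the sinus with favorable (< 0) / adverse (> 0) extrema.
- **pipeline** — an end-to-end, deterministic comparative run of the two
  presets producing `report.json` plus STL/VTP/CSV artifacts.

## Worked example

Generate the calibrated inflow waveform and verify the Reynolds targets:

```sh
$ cabvort waveform --out wave.csv
{"peak_Re": 1530.0, "mean_Re": 385.0}
```

Build and measure the pre-disposed geometry:

```sh
$ cabvort geometry --preset predisposed --out mesh.stl --resolution 100
{
 "preset": "predisposed",
 "watertight": true,
 "ica_branch_angle_deg": 45.0,
 "eca_branch_angle_deg": 30.0,
 "diameter_ratio": 0.499
}
```

The measured values come from slicing the constructed mesh, not from the
input parameters: the branch angles are read off the centerline tangents at
the apex, and the diameter ratio is the ICA diameter downstream of the
sinus over the inlet diameter (both from cross-section circle fits).

Run the comparative pipeline on coarse settings:

```sh
$ printf 'resolution: 80\nseries:\n  n_steps: 16\n  grid: [30, 21, 21]\n' > cfg.yaml
$ cabvort run cfg.yaml --out run/
report written to run/report.json
{
 "compared_case": "predisposed",
 "favorable_extrema_percent_differences": [
  {
   "class": "favorable",
   "percent_difference": 54.9726184428,
   ...
  }
 ],
 "lifespan_ratio": 4.5,
 "onset_shift_t_over_T": 0.0625,
 "reference_case": "healthy"
}
```

Reading the output: in the synthetic sinus series the pre-disposed vessel's
hairpin stand-in appears `onset_shift` earlier in the cycle, persists
`1/lifespan_ratio` as long as the healthy one, and its first favorable
axial-pressure-gradient peak is ~55% weaker — the comparative quantities
the pipeline is designed to measure.  Per-case details (existence windows,
core-kinematics events, WSS/vortex overlap, per-plane pair counts) are in
`run/report.json`.

## Scope

The package analyzes time-resolved velocity/pressure fields; it does not
solve the Navier–Stokes equations.  Synthetic analytic fields (module
`cabvort.synthetic`) emulate the features of pulsatile bifurcation CFD data
— with exact ground truth attached — and are what the test suite and the
bundled pipeline consume.  See `docs/methods.md` for the models, defaults,
and what the synthetic fields do and do not capture.
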