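# flutterpath

Patient-specific assessment of macro-reentrant tachycardia (atrial flutter)
vulnerability on triangulated cardiac surfaces.

The pipeline:

1. **Eikonal activation maps** — anisotropic multifront fast marching on
   triangle meshes, with rate-dependent conduction-velocity (CV) restitution
   `CV(BCL) = A − B·exp(−BCL/C)` and per-region anisotropy tensors
   (eigenvalues {k, 1, 1} along the fiber direction).
2. **Reentry loop candidates** — wavefront-collision detection (adjacent
   nodes whose unit activation vectors oppose, `‖âᵢ+âⱼ‖ < 0.99`),
   predecessor back-tracing to the stimulus, round-trip-time (RTT)
   fixed-point evaluation under restitution, and the wavelength condition
   `maxᵢ ERPᵢ(RTT) < RTT`.
3. **Geometric-snake constriction** — loops contract like a rubber band to
   locally minimal-RTT cycles on the surface; ablation lesions are hard
   constraints; loops that fall below the wavelength condition are
   disregarded.
4. **Vulnerability maps** — loops aggregated over a thinned stimulus set,
   deduplicated, and rendered as covered mesh elements with a coverage
   fraction.
5. **Phase dynamics** — a vulnerable loop's phase is extrapolated to the
   whole domain (travel-time-corrected circular relaxation anchored on the
   loop) and used to initialize an event-driven dynamic simulation with CV
   and ERP restitution, which grades reentry stability.

A synthetic-geometry module provides all benchmark substrates: planar sheets
with circular slow-conduction zones, annular bands, cylinders, and
sphere-like chamber surrogates with orifices, encircling ablation lesions,
and lesion gaps.

## Command line

```bash
flutterpath generate --preset annulus --out annulus.vtk
flutterpath activation --mesh annulus --substrate clinical_example --out act.vtk
flutterpath map --mesh annulus --min-distance 20 --out summary.json --mesh-out covered.vtk
flutterpath sweep --mesh annulus --parameter cv_scale --values 0.8,1.0,1.3
flutterpath phase --mesh annulus --mesh-out phase.vtk
flutterpath dynamic --mesh annulus --cycles 20
flutterpath experiment slow_zone_critical_ratio
```

Meshes are read/written in plain-text VTK legacy (with `fiber`, `region`,
`conductive` and result arrays as point/cell data), OFF, PLY and STL.
Substrate configurations are YAML:

```yaml
bcl_range: [200, 1000]
regions:
  default: {cv: {A: 700, B: 180, C: 170}, erp: {A: 300, B: 95, C: 190}, k: 3}
  slow:    {cv: {A: 500, B: 0}, erp: {A: 250, B: 0}}
```

Built-in presets: `clinical_example` (CV 650 mm/s, ERP 250 ms, isotropic),
`slow_zone`, `control`, and a multi-region `illustrative` set.  The
illustrative coefficients reproduce plausible regional orderings only and
are **not** fitted to measured data; scientific use requires an explicit
substrate file.

## Units

Lengths in mm, times in ms, CV in mm/s (converted internally to mm/ms).
Wavelength WL = CV·ERP is in mm.
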