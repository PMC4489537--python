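# eiphase

Single-image phase retrieval for edge-illumination (EI) X-ray phase-contrast
imaging.

EI setups record a *mixed* image: refraction (differential-phase) contrast
along the scan direction y, where a misaligned detector aperture converts
beam deflections into count changes through the illumination curve C(y_e),
plus near-field free-space-propagation contrast along x. Classical EI
retrieval needs two images at different aperture positions, and turning the
resulting refraction map into thickness requires a 1D integration that
smears noise into streaks. `eiphase` implements, end to end, the
alternative: a forward model for the mixed image and a one-shot Fourier
inversion that recovers the object's projected thickness t(x, y) — or its
projected electron density ρ_e,p under the weaker constant-δ/β assumption —
from a **single** image.

For a homogeneous object (refractive index n = 1 − δ + iβ, attenuation
μ = 2kβ), with W = exp(−μt), working point (C0, C′) and object–detector
distance z, the normalized signal satisfies

    F{S_n} = MTF_x(ξx) · [ 1 + A ξx² + i A (C′/C0) ξy ] · F{W},   A = zδ/μ,

and the retrieval is `t = −ln(F⁻¹{F{S_n}/D})/μ` with D the bracketed
denominator. D equals 1 at zero frequency and never vanishes (|D| ≥ MTF_x),
so the inversion is stable at all frequencies and suppresses noise as a
low-pass filter while the attenuation signal anchors the low frequencies.

The package is fully self-contained: phantoms (cylindrical wires, slabs,
spheres, wedges, a seeded petal-like textured object), illumination-curve
models, Poisson noise, the two-image + integration baseline and comparison
metrics are all generated in code — no external data.

## Worked example

Recover the diameter of a 500 µm PET wire (δ = 4.09×10⁻⁷, β = 7.83×10⁻¹¹ at
27 keV) from one simulated image at a synchrotron-like geometry — z = 3.85 m,
20 µm/250 µm slits at 50% illumination, 20 µm scan steps, 46 µm pixels:

```python
import eiphase as ei

pet      = ei.get_material("PET")
geometry = ei.BeamGeometry(energy_keV=27.0, z_od=3.85, step_y_um=20.0, step_x_um=46.0)
curve    = ei.AnalyticCurve(a1_um=20.0, a2_um=250.0)
wp       = ei.working_point(curve, 0.5, "lower")   # C0 = 0.5, C' = 0.05/µm

wire  = ei.cylinder_wire(500.0, (256, 128), 20.0, 46.0, material=pet)
mixed = ei.simulate_mixed_image(wire, geometry, curve, wp)
t_ret = ei.retrieve_thickness(mixed, pet, geometry, wp)
peak  = t_ret.values[:, 64].max()
print(f"retrieved peak thickness: {peak:.1f} µm")
```

This prints

```
retrieved peak thickness: 499.6 µm
```

i.e. the wire's nominal 500 µm diameter is recovered to −0.1% from a single
mixed image. The same pipeline is available from the shell:

```bash
eiphase demo --out-dir demo_output
```

which runs both wire phantoms (PET 500 µm, PEEK 200 µm) and prints

```
PET: nominal 500 µm, retrieved peak 499.6 µm (-0.08%)
PEEK: nominal 200 µm, retrieved peak 197.7 µm (-1.16%)
```

writing the mixed images, retrieved maps and profile CSVs alongside a JSON
report. Other subcommands: `phantom`, `simulate`, `retrieve`,
`baseline` (two-image + 1D integration), `compare` (RMSE, streak index,
profiles). Images are 32-bit float TIFF with JSON sidecars; curves and
profiles are CSV; every run echoes its resolved configuration as YAML.

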