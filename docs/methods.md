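# Methods

## The imaging model

Edge illumination (EI) X-ray phase-contrast imaging collimates the beam with
a narrow aperture (width a1) ahead of the sample and partially blocks it with
a second, misaligned aperture at the detector. Refraction by the object
shifts the beam across the detector-aperture edge, so a refraction angle
Δθ_y along y (the direction orthogonal to the slits) modulates the counts
through the *illumination curve* C(y_e) — the fraction of the unperturbed
beam reaching the detector as a function of the beam–aperture offset y_e.
Along x (parallel to the slits) the signal is that of near-field free-space
propagation, described by the transport-of-intensity (TIE) term.

With transmission T = exp(−μt), phase Φ = −kδt, Δθ_y = (1/k)∂yΦ, and a
working point (C0, C′) on one edge of the illumination curve, the normalized
signal of the linearized forward model is

    S_n = [ T + z·(C′/C0)·T·Δθ_y − (z/k)·∂x(T·∂xΦ) ] ⊛x LSF_x .

The `exact-curve` simulator mode replaces the first-order refraction term by
T·C(y_e + z·Δθ_y)/C0, evaluating the curve directly; it is the physical
(bounded) model and is used for all noisy simulations, since the Taylor
term can leave the physical range when z·Δθ_y is comparable to the curve's
ramp width. `taylor_validity_check` reports max|z·Δθ_y| against the curve
FWHM.

Sign conventions: y_e is the *beam-relative* offset (beam centre height
above the aperture's lower edge), so the default "lower" branch has C′ > 0
and an upward refraction adds to y_e. Row index is y, column index is x.

## Single-image retrieval

For a homogeneous object, substituting W = exp(−μt) and regrouping with
T·∂t = −(1/μ)·∂W turns the model into a single convolution equation whose
Fourier transform (kernel e^{−iξ·r}) is

    F{S_n} = MTF_x(ξx) · [ 1 + A·ξx² + i·A·(C′/C0)·ξy ] · F{W} = D·F{W},

with A = zδ/μ = (z/2k)(δ/β). D(0,0) = 1 and |D| ≥ MTF_x > 0 everywhere: the
filter never diverges, and |1/D| ≤ 1 when MTF = 1, so the retrieval

    t = −(1/μ)·ln Re F⁻¹{ F{S_n}/D }

acts as a low-pass filter on noise while leaving the attenuation anchor at
low frequencies untouched. Under the weaker assumption that only δ/β is
constant, the same filter yields the projected electron density
ρ_e,p = −ln(·)/γ with γ = 2k·σ/(δ/β), σ = r_e λ²/2π; for a single material
ρ_e,p ≡ δ·t/σ pixel-wise, which the tests assert to 1e-10.

### Numerical choices

- **Frequency symbols.** The default `spectral` stencil uses the continuous
  symbols (ξx², ξy) and the analytic Gaussian MTF. A `difference` stencil
  uses the DFT symbols of the three-point Laplacian and central first
  difference plus the DFT of the sampled LSF kernel; paired with the
  spectral compact-form simulator on a shared periodic grid it is an exact
  algebraic inverse (round-trip to ~1e-13), which the oracle tests exploit.
  For even grids the odd ξy symbol is zeroed on the Nyquist row to keep the
  filter Hermitian (real output for real input); the residual imaginary RMS
  is logged and is ≲1e-15 of the real part on noiseless data.
- **Padding.** Images are padded to the next power of two with ≥25% margin
  per side before the FFT and cropped afterwards. Retrieval pads by *edge
  replication*: the inverse filter's y kernel is long (decay length
  A·C′/C0, several mm at synchrotron geometries), and reflective padding
  places mirror copies of the object in the pad whose odd refraction term
  carries the wrong sign — measured +7% wire-peak bias, against +0.04% for
  edge replication, which is the exact continuation for objects whose
  signal has flattened at the frame edge. The forward model pads thickness
  maps by odd reflection (point reflection about the border value), exact
  for linear ramps and identical to replication on flat borders.
- **Clipping.** The filtered image is clipped below at 1e-8 before the
  logarithm; counts of clipped pixels are logged and returned in the result
  metadata. Retrieved thickness is additionally floored at zero (the raw
  minimum is kept in the metadata); noise can ring slightly negative.
- **Discretization of the forward model.** Derivatives are central
  differences; the TIE term is discretized in conservative (staggered-flux)
  form so it collapses to the compact Laplacian stencil for slowly varying
  T. With that choice the spatial simulator agrees with the spectral
  compact form to ~1e-7 RMS on band-limited phantoms; on the wire phantom
  the agreement is limited to ~3e-4 RMS because the chord jumps ~140 µm per
  20 µm step at the edge and the discrete chain rule T·Δt ≈ −ΔT/μ is only
  first-order accurate there.

## Baselines and metrics

The two-image baseline acquires symmetric working points on opposite curve
edges (equal C0, opposite C′): T = (S⁺+S⁻)/2 and
Δθ_y = C0(S⁺−S⁻)/(zC′(S⁺+S⁻)), exact for the linearized model when the
object has no x-structure. Thickness follows by cumulative integration of
−Δθ_y/δ along y anchored at zero on the first row. The `streak_index` of a
residual map is Var_x(mean_y)/Var_total — 1 for pure column streaks, 1/N_y
for white noise. By default the baseline splits the photon budget across
its two images, making dose-matched comparisons fair.

## Synthetic data

All inputs are generated: analytic phantoms (cylindrical wire chord, slab,
sphere, wedge) and a seeded petal-like `textured_phantom` (elliptical
pollen-grain-like blobs on a modulated membrane with cell-like thin spots).
The textured map is Gaussian-softened (default 3 µm) so phantoms are slowly
varying at the pixel scale — the regime where the TIE description itself is
valid; without band-limiting, blob edges at sub-µm pixels drive the TIE
term outside the physical range. Poisson noise replaces each pixel S by
Poisson(n̄·S)/n̄ at a stated mean count n̄ per pixel of the *normalized*
image, preserving the expectation; all generators take one explicit integer
seed and hold no global state.

What the generator does not emulate: Fresnel fringes beyond the TIE
regime, detector gain/readout noise, flat-field structure, polychromaticity
and partial-coherence effects beyond the Gaussian source blur folded into
the illumination curve. Passing tests therefore demonstrate correctness of
the stated forward/inverse pair and its noise behaviour, not detector-level
realism.

## Study conditions used by the tests

- **Wire recovery.** 27 keV; z = 3.85 m; 20 µm/250 µm slits at 50%
  illumination (lower edge at the beam centre); 20 µm scan steps, 46 µm
  pixels; 256×128 frames. PET (δ = 4.09e-7, β = 7.83e-11) at 500 µm and
  PEEK (δ = 3.92e-7, β = 6.91e-11) at 200 µm. Retrieved peak thickness
  matches the nominal diameter within 2% (measured −0.1% and −1.2%; about
  half of the PEEK deficit is pixel-centre sampling of the chord apex).
- **Noise robustness.** Water-like material at 9.7 keV (δ = 2.46e-6,
  β = 5.94e-9), z = 0.30 m, 3 µm aperture, 1.6 µm scan steps, 0.8 µm
  pixels, 512×256 textured phantom, Poisson noise at 10 photons/pixel
  (≈32% per-pixel fluctuation). The filtered retrieval's RMSE is ≥5× below
  the attenuation-only log retrieval. Structure visibility is assessed as a
  detection significance: the largest blob's mean elevation over a
  surrounding background ring, with the uncertainty estimated from eight
  ring segments (this respects the long-range noise correlations the filter
  leaves at ξy ≈ 0); the median significance over eight noise realizations
  exceeds 3. A per-pixel 3σ reading of the same question is genuinely
  marginal at this dose and frame size, because y-mean noise passes the
  filter as column offsets of magnitude comparable to the blob contrast.
- **Streak comparison.** The normalized streak index compares artifact
  *structure*, so it is evaluated in the regime where the filter's y kernel
  fits inside the field of view: z = 0.5 m, a1 = 100 µm at 27 keV, textured
  PET phantom, 10 photons/pixel, dose split for the baseline. There the
  single-image index is ≈0.06 against ≈0.6 for integration, in every one of
  20 seeds. At long-kernel geometries (e.g. the wire setup) the single-image
  residual is itself column-structured — smaller in magnitude but not in
  normalized streak fraction — which is why the comparison is defined in
  the well-conditioned regime.

## Known limitations

- Retrieval quality for structure larger than the field of view degrades
  smoothly (no boundary spikes — tested on a frame-spanning wedge), but
  global trends are poorly constrained when the filter kernel A·C′/C0
  approaches the frame height; the attenuation term is then the only anchor
  and is weak for thin, weakly absorbing objects.
- The constant δ/β assumption is exact only for homogeneous objects; for
  mixed materials the maps are qualitative, as usual for phase–attenuation
  duality methods.
- Monochromatic beams only; the 1D edge model does not cover 2D aperture
  masks.
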