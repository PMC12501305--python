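# Methods

This note records the model implemented by `mwisar`, its assumptions, the
conventions that an independent re-implementation would need to match, and
the design choices made where more than one reasonable reading existed.

## Acquisition geometry

The scene is a 2-D polar plane centred on the turntable axis. Azimuth is
measured in degrees from the +y axis toward +x, so a point at radius Ri
and azimuth φ has cartesian coordinates (Ri sin φ, Ri cos φ); φ = 180°
maps to (0, −Ri). The transmit and receive antennas sit on a ring of
radius R₀ just outside the container, each at an angle θ from the +y
axis, boresights pointing at the origin.

Two placements are implemented:

* **adjacent** (default): Tx = (R₀ sin θ, R₀ cos θ),
  Rx = (−R₀ sin θ, R₀ cos θ) — a side-by-side quasi-monostatic pair
  separated by 2w = 2R₀ sin θ. This is the physically meaningful
  arrangement for a turntable rig whose link budget counts *two passes*
  through each tissue layer, and it is the only one of the two for which
  the imaging operator is identifiable (below).
* **opposed**: Rx = −Tx, a pure transmission geometry.

**Identifiability.** The bistatic point response depends on the target
only through the symmetric quantities d₁d₂, d₁+d₂ and G(δ₁)G(δ₂). With
opposed antennas (Rx = −Tx), reflecting a target through the origin
swaps d₁↔d₂ and δ₁↔δ₂ and therefore leaves the response *identical* at
every frequency and every turntable angle. Each pixel and its antipode
produce the same sensitivity-matrix column; the operator loses exactly
half its rank and every reconstruction carries an exact point-symmetric
ghost. The adjacent placement has no such degeneracy (mirror-image pixels
map to angle-reversed, not identical, columns) and its sensitivity matrix
has full effective rank over the in-container pixels. All imaging
defaults therefore use the adjacent placement; the opposed one is kept
for transmission studies.

The default opening angle θ = 20° corresponds to a ≈5.8 cm element
separation on the 8.5 cm ring — the footprint of two planar UWB antenna
housings mounted side by side. It is a geometry parameter, not a tuning
knob: any moderate nonzero θ behaves equivalently.

Turntable rotation is modelled by adding the rotation angle to every
scatterer's azimuth while the antennas stay fixed. The sign of this
convention only permutes sinogram columns; forward model and sensitivity
matrix share one kernel, so they can never disagree.

## Forward model

A point scatterer with RCS σ at distances d₁ (to Rx) and d₂ (to Tx)
contributes

S(ω, φ) = A₀ · √(G(δ₁) G(δ₂) σ) / (d₁ d₂) · exp(+j (ω √εr / c₀)(d₁ + d₂)),

with A₀ = √(Z₀ P_t / 4π) · λ/(4π) the effective receive aperture.
Scatterers superpose linearly (a Born-type single-scattering
approximation); there is no mutual coupling, no container-wall echo and no
medium absorption by default (εr is real; a complex εr is accepted and
produces exponential attenuation through the same √εr phase factor).

Choices the model leaves open and how they are fixed here:

* **Wavelength in A₀** — the in-medium wavelength c₀/(f√εr). The choice
  rescales all rows of sinograms and sensitivity matrix identically, so
  reconstructions are unaffected.
* **Gain pattern** — configurable: isotropic (default, so results carry
  no invented antenna parameters), cos^n, or Gaussian beam by half-power
  beamwidth.
* **Transmit power and impedance** — P_t = 1 W, Z₀ = 376.730 Ω. These
  scale all measurements uniformly and cancel in normalized images.
* **Phase sign** — exp(+jωτ) throughout (`mwisar.constants.PHASE_SIGN`).

Default acquisition (the study conditions): 0.1–4.8 GHz sweep, water
εr = 80, 17 cm diameter container (R₀ = 8.5 cm). The full 200-bin ×
360-angle acquisition is supported; library defaults and tests use a
64-bin × 90-angle desk scale (below).

## Range compression

Per-angle range profiles are the unitary forward-sign DFT of the windowed
spectrum: profile_k = M^(−1/2) Σ_m w_m S_m exp(−j2π f_m τ_k) on the delay
lattice τ_k = k/(M·Δf). The forward sign pairs with the exp(+jωτ)
propagation convention so physical delays land in positive bins; the
unitary normalization makes profile energy equal windowed-spectrum energy.
Windows: rect, hann (default), hamming. The unambiguous delay span is
1/Δf; at the desk scale (Δf ≈ 74.6 MHz) that is ≈13.4 ns, comfortably
above the ≈7 ns maximum water path.

## Sensitivity matrix and inverse model

The sensitivity matrix J stacks the unit-RCS response of every pixel:
rows ordered angle-major with frequency fastest (row = n·M + m), columns
in row-major grid order; one shared vectorizer is used for measurements so
the orderings cannot drift apart. Building J requires at least as many
measurements as pixels (M·N ≥ p·q).

The imaging grid is a cartesian p×p lattice of pixel centres spanning
[−r, +r]² (pitch 2r/p; defaults p = 64, r = 8 cm, with a 10 cm preset),
with a circular support mask at radius r. Pixels whose centre falls
outside the *container* cannot host a scatterer, so their columns are
identically zero; the SVD truncation absorbs the resulting null space and
the mask hides them in images.

Reconstruction solves S = J·P in the least-squares sense via the SVD
pseudo-inverse, P = J⁺S, with singular values below rtol·s_max dropped
(default rtol = max(M·N, p·q)·ε_machine). The Hermitian transpose is used
throughout — on complex data the plain transpose does not define a
meaningful inner product, and only J⁺ = V Σ⁺ Uᴴ satisfies the
Moore–Penrose identities. P is kept complex; images display |P|, either
linear or peak-normalized dB (floor −120 dB), and can be bilinearly
upsampled (2401×2401 by convention) for presentation. Peak localization
uses strict 8-neighbour local maxima with a minimum Chebyshev separation
of 2 pixels.

## Dielectrics

* Loss tangent: tan δ = σ/(2πf ε₀ εr); wavelength in a lossy medium:
  λ = c₀ / (f · Re√(εr(1 − j tan δ))). These standard forms reproduce the
  published 1 GHz head-tissue table (blood, cortical bone, CSF, grey and
  white matter) to its printed precision from (σ, εr) alone.
* Cole-Cole dispersion ε(ω) = ε∞ + (εs−ε∞)/(1+(jωτ)^(1−α)) − jσ_i/(ωε₀),
  with the `tap_water_25C` preset (ε∞ = 5.2, εs = 78.4, τ = 8.27 ps,
  α = 0, σ_i = 0): at 1 GHz it evaluates to ≈78 − j4, the regime that
  makes water a practical matching medium. The ionic-conductivity term is
  exposed for saline media.
* Link budgets are signed-dB sums (losses negative). The default head
  budget at 1 GHz — skull (1 cm × 2 passes × 1 dB/cm), grey matter
  (3 cm × 2 × 2.1 dB/cm), the grey-matter/blood interface return loss,
  coupling losses, the RCS of a 3 cm blood sphere, spreading — totals
  −67.6 dB.
* Range resolution ΔR = c₀/(2B√εr). Cross-range resolution is provided as
  the standard rotational-aperture estimate λ/(4 sin(aperture/2)) with the
  in-medium wavelength; it is an order-of-magnitude figure only, since
  real apertures are tapered by the antenna pattern and windowing, and no
  exact operating definition is pinned to it.

## Phantoms and noise

Phantoms are point-scatterer scenes (RCS in m², unit by default) —
consistent with the constant-RCS linearization of the inverse model, not
dielectric volumes:

* `single_point`: 1 m² at (0, −6 cm), the canonical off-centre target.
* `nine_point`: pairs on the ±x (7 cm) and ±y (6 cm) axes, four
  diagonal targets at 4.5 cm, one at the centre — radii chosen to honour
  the farther-x / nearer-diagonal distance ordering of the standard
  multi-target constellation; they are free parameters.
* `ellipse_with_inserts`: an 8 cm × 12 cm ellipse (vegetable surrogate)
  with two 1 cm cylindrical inserts, discretized as a boundary ring
  (skin, high contrast), interior fill (weak) and insert disks (distinct
  contrast) at a default pitch of λ/4 in water at 4.8 GHz (≈0.87 mm).
  Contrast values are free parameters.
* `rod`: a 5 mm metal rod as a single strong scatterer for calibration.

Noise injection adds circular complex white Gaussian noise scaled to a
target mean SNR, seeded and reproducible.

What the synthetic data does *not* emulate: container-wall reflections,
antenna ringdown and cross-coupling, cable drift, frequency-dispersive
tissue contrast, multiple scattering. Passing round-trip tests therefore
demonstrates the correctness and conditioning of the linear chain, not
performance on measured data; measured sinograms additionally need
reference subtraction and medium calibration (both provided) and will show
clutter the model does not predict.

## Calibration

`calibrate_medium` estimates the coupling liquid's εr from rod sweeps at
two or more known positions: per-angle peak delays of the range-compressed
sinograms are regressed (zero intercept) against the geometric bistatic
path lengths; the slope is √εr/c₀. Peak delays are refined below the
delay-bin quantization by parabolic interpolation of |profile| around each
per-angle maximum — without it the bin width (1/(M·Δf)) is a few percent
of the total delay for low-permittivity media. On synthetic rod data the
estimate is within a fraction of a percent of the true εr.

## Problem sizes and numerics

The package's default test and demonstration scale is 64 frequencies ×
90 angles × 32×32 pixels (J is 5760×1024 complex, ≈90 MB; build ≈1 s,
SVD ≈5 s on one core). The full 200×360×64×64 system is supported — J is
assembled in pixel chunks to bound memory — but a dense SVD at that size
is a workstation job, and all scientific conclusions here are already
visible at the desk scale: single-point and nine-point phantoms
reconstruct with every peak within one pixel of truth, and at 20 dB SNR
the single point still localizes within one pixel in ≥95% of seeded
trials.

Degenerate inputs are handled explicitly: empty scenes give zero
sinograms; all-zero scatterer maps give a floored dB image with a warning;
rank-zero matrices, under-determined grids, out-of-container scatterers,
mismatched vector orderings and malformed measurement files raise typed
errors naming the offending quantity.

## Known limitations

* The inverse model recovers effective backscatter strength (localized
  RCS), not quantitative permittivity; it is a linear back-projection, not
  an iterative nonlinear reconstruction (DBIM-class methods are out of
  scope).
* Extended objects are point-cloud surrogates; inter-scatterer coupling is
  ignored, so bright boundaries dominate reconstructions exactly as they
  do in the linear approximation.
* The opposed antenna placement is retained for transmission studies but
  is not identifiable for imaging (exact antipodal ghost; see
  *Identifiability*).
* Cross-range resolution is reported as an estimate without a calibrated
  operating definition.
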