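# Methods

## Model and assumptions

The measured quantity is a complex scalar wave image `u(x) = φ(x) − iψ(x)`
on a regular pixel grid with known metric spacing `h` (m) and vibration
frequency `f` (Hz), ω = 2πf. φ is the in-phase displacement snapshot and ψ
the 90°-advanced one; a stack of N uniformly phase-offset snapshots
`s_k = Re(u e^{+2πik/N})` is reduced to `u` by its first temporal DFT
coefficient, `u = (2/N) Σ_k s_k e^{−2πik/N}`, which inverts the sampling
exactly for N ≥ 3. The sign of the phase advance is a documented,
configurable convention (`SnapshotStack.advance_sign`).

Locally, `u` is assumed to be a finite sum of attenuated complex plane
waves `a e^{ω(α+iβ)·(x−p)}` (the multiple-wave form). No constitutive
model enters the estimation itself; a nearly incompressible isotropic
viscoelastic medium is assumed only for the final conversion of `(α, β)`
to the complex shear modulus via

    ρ + (G′ + iG″)(α + iβ)·(α + iβ) = 0 .

This holds region-wise with possibly different moduli per region, and
presumes the density ρ (default 1000 kg/m³) is known.

## Windowed spectral estimation

The Gaussian-windowed Fourier transform is discretized as the Riemann sum

    W(ξ) = h² Σ_x e^{−i(x−p)·ξ} u(x) e^{−|x−p|²/2σ²}

over a square patch of half-width 6σ around the probe (Gaussian tail mass
below ~4·10⁻⁹; still below ~4·10⁻⁶ when attenuation shifts the effective
window center by up to σ). The kernel is *centered* at the probe: this
differs from the uncentered convention only by the unimodular factor
`e^{−ip·ξ}` (an exact conversion is provided) and removes the large `p·ξ`
phase ramp, which keeps the spectral phase-gradient fit well conditioned.
The ξ-grid comes from a zero-padded FFT (default 4× padding, spanning
[−π/h, π/h) per axis); the FFT length is chosen from the *unclipped*
patch size so every probe at a given σ shares one ξ-grid. The h²
normalization makes the continuum closed form

    W = 2πaσ² exp[iω²σ²α·β + ω²σ²|α|²/2]
        · exp[−iωσ²α·ξ − σ²|ξ−ωβ|²/2]

the oracle without rescaling; the discrete transform matches it to better
than 10⁻⁴ of the peak for σ ≥ 4h (observed ~10⁻⁸ at the default 6σ
patch).

**Wave vector.** β̂ = ξ̂/ω where ξ̂ is the argmax of |W| over nodes with
|ξ| ≥ one ξ-cell (DC exclusion), refined per axis by log-quadratic
interpolation through the peak node and its neighbours — exact for the
Gaussian peak the model predicts, and necessary because the raw FFT bin
width (~4 % of |ωβ| at default settings) would otherwise floor the
accuracy. Ties break toward the smallest |ξ| (longest wavelength), then
lexicographic node order.

**Attenuation vector.** With the centered kernel the single-wave spectral
phase is `θ(ξ) = −ωσ²α·ξ + θ₀`, so α̂ = −∇θ/(ωσ²) with the gradient from
a weighted least-squares fit (two slopes + intercept) over a square
stencil of ξ-nodes around the peak. Phase differences are computed as
`arg(W(ξ) conj(W(ξ₀)))`, continuous across the ±π/2 branch cuts of the
arctangent form. Weights are Gaussian with width `s = 1/(2σ)` (half the
window's spectral lobe width); the stencil radius defaults to
`max(2, ceil(3s/Δξ))` cells. The weighted RMS misfit is reported per
point. A warning is raised when |ωα̂|σ > 1, where the single-Gaussian peak
model degrades.

**Window size.** σ is best taken between half and one dominant
wavelength; the default policy is σ = 0.75·2π/|ξ∞| with ξ∞ the
whole-field spectral peak. A field whose masked spectral maximum is less
than 10× the median modulus (pure noise, flat spectrum) is rejected as
degenerate rather than returning a meaningless argmax.

## Moduli conversion and masking

`(α̂, β̂) → (G′, G″)` is the exact algebraic link above; G″ may come out
negative where the fitted α points against propagation, and such values
are reported, not clipped, so ROI statistics reflect the true spread. The
inverse map (used by the generator) solves `|α|²−|β|² = −G′ρ/|G*|²`,
`2α·β = G″ρ/|G*|²` for the vector lengths given the β direction and the
α–β angle; for G″ > 0 any angle with cos > 0 is feasible, and the
quadratic root is evaluated in a cancellation-free form. Points with
|β̂| below 0.1× the median |β̂| are masked (`low-beta`): a vanishing wave
vector sends G′ = ρ/|β|² to infinity and typically marks wave shadows or
unwrapping failures; the cutoff makes reproducible what would otherwise
be a hand-drawn exclusion. Boundary-clipped estimates are masked with
reason `boundary`. ROI statistics are the arithmetic mean and
*population* (divide-by-N) standard deviation of unmasked points.

## Spectral denoising

Each tile (default 4 px; 1 px reproduces per-pixel filtering) is replaced
by `[W(ξ̂)/m_p] e^{i(x−p)·ξ̂}`, where ξ̂ is the tile's refined strongest
peak (local mode) or the field-wide peak ξ∞ (global mode), the amplitude
is the direct windowed projection at ξ̂, and `m_p` is the discrete window
mass `h²ΣG` of the possibly clipped patch. This normalization makes the
filter exactly the identity on a noiseless plane wave whose ωβ lies on a
spectral node — including boundary tiles — and equals the continuum
2πσ² away from boundaries. A spectral width γ > 0 replaces the
single-node selection by a normalized Gaussian-weighted bundle of nodes
(γ → 0 recovers the delta filter continuously). Tiles are assembled by
characteristic-function superposition, so seams can appear where
neighbouring tiles lock onto different waves — inherent to the method.

## Synthetic data generator

The generator emulates the bounded-domain simulation study: a 128×128
grid at h = 1.2 mm (micro-MRE pixel pitch), f = 250 Hz, ρ = 1000 kg/m³,
and per-region attenuated plane waves whose (α, β) are derived from the
prescribed (G′, G″) through the viscoelastic link, so the ground truth
satisfies it to < 10⁻⁹ relative by construction. Defaults: one region
with G′ = 14.4 kPa, G″ = 0.69 kPa, β toward the upper right (1,1)/√2, α
at 75° counterclockwise from β (upper-left half-plane); the derived
|α|/|β| ≈ 0.09, i.e. weak attenuation, consistent with gel phantoms.
Named ROIs default to the central-third square ("center") and the
right-third slab ("right").

Noise is i.i.d. complex Gaussian, calibrated by `noise_to_signal`, the
ratio of noise RMS to the RMS of |u| over the field (default 0.095).
Because the attenuated wave's amplitude spans several e-folds across the
domain, this single global ratio produces strongly position-dependent
local signal-to-noise: below 0.1 in the dim corner (where the wave
pattern drowns in noise and recovery fails, as expected) and far above 1
in the bright corner. This reproduces the study's reported behaviour
quantitatively — ROI-mean G′ within a fraction of a percent of truth with
a ~0.1 kPa spread, G″ with a spread comparable to its mean, and ≥ 90 % of
interior probes recovering β within 10 %.

What the generator does *not* emulate: reflections and standing waves
from real boundaries, phase-unwrapping artifacts, spatially correlated
scanner noise, and frequency-dependent rheology. Passing tests therefore
demonstrate correctness of the estimators on the local plane-wave model
with white noise, not robustness to every pathology of scanner data; the
attenuation estimate in particular is known to destabilize near standing-
wave nodes, and no stabilization is attempted.

## Numerical choices and problem sizes

* Probe sampling every 4 px with a margin of 2σ from the field edge
  (boundary effects dominate inside it); margin 0 keeps clipped points
  but flags them. A spectrum counts as boundary-clipped when the edge
  intrudes into the 2σ window core, not its far tail.
* Sub-cell refinement is skipped on non-concave or edge configurations
  (falls back to the node); offsets are clamped to half a cell.
* In map mode, a phase-fit stencil that would leave the ξ-grid yields an
  unavailable (NaN, masked) α rather than aborting the map; the
  single-point function raises instead.
* Default problem sizes — 128² fields for the study replication, 256² for
  the pipeline smoke run, 50 random draws for the oracle comparison, 5
  seeds for the noise-robustness average — keep the full suite and the
  reproduction script to a few minutes on one CPU while leaving all
  statistics stable to well within their tolerances.
* Feasibility guard: an α–β angle whose cosine is below 10⁻¹² in
  magnitude (or of the wrong sign for the requested G″) is rejected with
  the feasible range named.

## Limitations

Strictly 2-D scalar fields; no phase unwrapping of raw scanner phase
maps; single dominant wave per probe (the strongest peak only — secondary
peaks are neither tracked nor reported); moduli are frequency-specific
and not comparable across drive frequencies; G″ estimation inherits the
noise sensitivity of the spectral phase gradient and is reliable only in
ROI aggregate, not per point.
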