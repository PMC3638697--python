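# mrewave

Model-independent analysis of magnetic resonance elastography (MRE) wave
images.

MRE drives a time-harmonic shear vibration (typically 100–250 Hz) into
tissue or a gel phantom and images snapshots of the resulting displacement
field. Stiffer material carries longer shear waves, so mapping the local
wavelength maps stiffness — without committing to a full tissue model.
`mrewave` implements this idea for 2-D complex wave images
`u(x) = φ(x) − iψ(x)` built from quadrature snapshots, for researchers who
want a transparent, model-independent inversion they can test end to end
without scanner data.

## Method

Locally the field is modelled as a *multiple-wave form*, a finite sum of
attenuated complex plane waves

```
u(x) ≈ Σₙ aₙ exp( ω (αₙ + i βₙ) · (x − p) )
```

with angular frequency ω, propagation slowness vectors βₙ (s/m) and
attenuation vectors αₙ (s/m). Around a probe point `p` the package
computes a Gaussian-windowed Fourier (FBI/Gabor) transform

```
W(u; p, σ)(ξ) = ∫ e^{−i(x−p)·ξ} u(x) e^{−|x−p|²/2σ²} dx .
```

For a single wave, |W| is a Gaussian peaking exactly at `ξ = ωβ`, and the
spectral phase is linear with slope `−ωσ²α`. Hence:

* **LWV** (local wave vector): `β̂ = argmax_ξ |W| / ω`, with sub-cell
  log-quadratic peak interpolation (exact for the Gaussian peak shape);
* **LAV** (local attenuation vector): `α̂ = −∇_ξ θ / (ωσ²)`, the
  Gaussian-weighted least-squares phase gradient at the peak;
* **moduli**: the viscoelastic link
  `ρ + (G′ + iG″)(α + iβ)·(α + iβ) = 0` converts `(α̂, β̂)` into storage and
  loss moduli, `(G′, G″) = ρ (|β|²−|α|², 2α·β) / ((|α|²−|β|²)² + 4(α·β)²)`,
  or the lossless shortcut `G′ = ρ/|β|²`;
* **denoising**: each image tile is replaced by the plane wave of its
  strongest spectral peak (or of the field-wide peak ξ∞), which removes
  noise and interfering waves.

A synthetic generator manufactures bounded-domain wave fields from
prescribed `(G′, G″)` per region — inverting the same viscoelastic link —
plus calibrated complex Gaussian noise, and returns the per-pixel ground
truth, so the whole pipeline is testable without acquisition data.

## Worked example

Simulate the default study conditions — a 128×128 field (1.2 mm pixels,
250 Hz) carrying one attenuated plane wave with true G′ = 14.4 kPa,
G″ = 0.69 kPa at density 1000 kg/m³, plus white complex Gaussian noise at
9.5 % of the field RMS — then recover the moduli:

```
$ mrewave simulate --seed 1 --out demo/sim
INFO mrewave: simulated 128x128 field at 250 Hz (seed 1) -> demo/sim
$ mrewave analyze --in demo/sim/field --out demo/analysis
INFO mrewave: ROI center   storage mean   14.359 kPa  std   0.060 kPa  (n=121)
INFO mrewave: ROI center   loss    mean    0.673 kPa  std   0.052 kPa  (n=121)
INFO mrewave: ROI right    storage mean   14.325 kPa  std   0.216 kPa  (n=138)
INFO mrewave: ROI right    loss    mean    0.721 kPa  std   0.384 kPa  (n=138)
```

The storage modulus comes back within 0.5 % of the 14.4 kPa truth in both
ROIs despite the noise; the loss modulus — an order of magnitude smaller
and carried entirely by the noise-sensitive attenuation vector — averages
near its 0.69 kPa truth with a much larger spread, the expected behaviour
for this quantity. `demo/analysis/` also receives the per-point vector and
modulus tables (CSV), quiver overlays of β̂ and α̂ over the wave image, and
grayscale modulus maps.

The same objects are available as a library:

```python
import mrewave as mw

sim = mw.simulate_experiment(mw.SimulationConfig(seed=1))
out = mw.analyze_field(sim.field, rois=tuple(sim.rois))
for s in out.stats:
    print(s.name, s.quantity, s.mean / 1e3, "kPa")
```

`mrewave denoise --in ... --mode global` applies the spectral filter and
writes the filtered field plus before/after spectrum images.

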