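# ssos — single-shot optical sectioning for widefield fluorescence microscopy

Deconvolution of a widefield fluorescence stack cannot restore axial
structure near the optical axis of frequency space: the 3-D optical transfer
function (OTF) has a *missing cone* around k_z, so out-of-focus light and
in-focus axial detail are indistinguishable. Conventional optically
sectioned structured illumination (OS-SIM) fixes this with three
phase-stepped exposures and a non-linear homodyne sum — at three times the
light dose and frame time, and without a definable PSF.

This package implements **single-shot optical sectioning (ssOS)**: a purely
linear reconstruction that fills the missing cone from just **two**
simultaneously acquired images taken under sinusoidal excitation patterns
that are π-phase-shifted and coded in orthogonal polarizations. Because the
two patterns sum to a spatially constant exposure, their average is an
ordinary widefield image i₀ while either frame alone is a structured
illumination image i₁. In Fourier space (capitals denote transforms,
Ψ the OTF support, p the pattern frequency, n its modulation contrast,
φ₀ its phase):

1. Deconvolve: S₀ = W[I₀], S₁ = W[I₁], both truncated to Ψ
   (W is a Wiener or Richardson–Lucy inverse of the OTF H).
2. Unmix: S₁′ = S₁ − S₀ − (n/2)e^{iφ₀} S₀(k−p) − (n/2)e^{−iφ₀} S₀(k+p).
   What survives is sample content that the pattern translated *into*
   Ψ from the missing cone.
3. Restore: shift S₁′ back by ∓p, divide by the pattern weights, average
   the two copies where both shifted supports overlap (Ω), and keep only
   bins outside Ψ.
4. Recombine: S_OS = S₀ |∈Ψ + S̄₁′ |∉Ψ; the sectioned image s_OS is its
   inverse transform.

The pattern parameters (p, φ₀, n) are estimated from the raw data at
frequency-bin precision via cross-correlation of the deconvolved spectra.
The two patterns can be projected simultaneously because fluorescence
anisotropy preserves polarization: with anisotropy r the parallel and
perpendicular arms see the emission in the ratio t = (1 + 2r)/(1 − r)
(3:1 at the one-photon maximum r = 0.4), and the cross-talk reduces a raw
pattern contrast m to an effective contrast **n = m(t − 1)/(t + 1)** —
50% in the best case t = 3, m = 1.

The package contains the full forward simulator needed to validate the
method without external data: a scalar pupil-integral PSF/OTF model, a
tilted frequency-chirp phantom whose stripe frequency rises linearly with
depth (so recovered axial resolution can be read off as a depth
coordinate), anisotropy mixing of the two polarization-coded patterns, and
a seeded Poisson photon-noise model.

## Worked example

```python
from ssos import ReconOptions, make_psf, ssos_reconstruct
from ssos.evaluate import default_scenario, modulation_profile, recovered_fraction
from ssos.simulate import form_raw_pair, make_chirp_sample

scenario = default_scenario(f_max_fraction=1.0)   # chirp up to the confocal cutoff
sample = make_chirp_sample(scenario.chirp)
psf = make_psf(scenario.cfg, scenario.grid)
i_p, i_s = form_raw_pair(sample, scenario.pattern, psf)

result = ssos_reconstruct(i_p, i_s, psf, ReconOptions(wiener_w=1e-6))
print("estimated pattern bin:", result.pattern.freq_px)
print("estimated contrast  :", round(result.pattern.mod_contrast, 3))
print("cone bins filled    :", int(result.diagnostics["cone_fill"]))

profile = modulation_profile(result.s_os, scenario.chirp)
print("recovered axial cutoff (cycles/um):", round(profile.cutoff_frequency, 3))
print("fraction of confocal limit        :", round(recovered_fraction(profile, scenario.cfg), 3))
```

prints

```
estimated pattern bin: 19
estimated contrast  : 0.252
cone bins filled    : 1238
recovered axial cutoff (cycles/um): 3.021
fraction of confocal limit        : 0.819
```

The pattern sat at bin 19 with effective contrast 0.25 (raw contrast 0.5
mixed at t = 3) and was recovered exactly from the raw pair alone. 1238
frequency bins inside the missing cone were filled, and the reconstruction
keeps ≥25% stripe modulation out to 3.02 cycles/µm along the tilted axis —
82% of the confocal axial limit (1/Δz = 3.69 cycles/µm for the 1.49 NA /
oil configuration), where the deconvolved widefield image alone retains
barely 40%.

## Command line

`ssos` exposes the same pipeline as subcommands: `cutoffs` (band limits for
a configuration), `simulate` (phantom + raw pair + noisy pair as TIFF
stacks with a JSON sidecar), `reconstruct` (ssOS on a raw pair, or on a
3-phase SIM stack with `--emulate`), `baseline-ossim` (the homodyne
three-phase baseline), `evaluate` (depth-resolved modulation profile CSV),
and `noise-sweep` (the photon-budget experiment). All commands accept a
YAML/JSON configuration; the effective merged configuration, seeds and a
config hash are echoed next to every output for exact reproducibility.

```bash
ssos cutoffs
ssos simulate --out run1
ssos reconstruct run1/raw_p.tif run1/raw_s.tif --out run1
ssos evaluate run1/s_os.tif --out run1
```

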