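# Methods

## Imaging model

The microscope is modelled as a scalar, aberration-free widefield system.
For each defocus plane z the amplitude PSF is the inverse 2-D transform of
the circular pupil (radius NA/λ_em in frequency space) carrying the
defocus phase exp(2πi·z·k_z) with k_z = √((n/λ_em)² − k_r²); the intensity
PSF h is its squared magnitude, normalized to Σh = 1 so the OTF satisfies
H(0) = 1. Vectorial high-NA depolarization is ignored — the excitation
beams of a polarization-coded pattern pair sit close to the optical axis in
the back focal plane, where those effects are negligible — and no
refractive-index-mismatch or Gibson–Lanni aberration terms are included.
The scalar model reproduces the property the reconstruction depends on: a
3-D OTF whose support Ψ is a torus with a missing cone of axial
frequencies around k_z (verified by a dedicated test at the default
configuration).

Axis order is (z, y, x) with z the optical axis; all frequency lattices are
DC-centred; configurations use nm, reported frequencies cycles/µm.
Convolutions are circular (FFT-based) throughout, and the forward model,
the deconvolution and the spectral shifts all share that convention.

Band limits: lateral cutoff 2·NA/λ; the confocal axial resolution used to
normalize recovered frequency ranges is Δz = 0.64·λ_em/(n − √(n² − NA²)),
axial cutoff 1/Δz. The denominator is deliberately the *difference* form;
the alternative product reading is dimensionally admissible but
inconsistent with the axial-resolution literature the formula comes from,
and it remains a one-line change in `optics.axial_confocal_cutoff`.

## Default optical and pattern configuration

NA = 1.49, oil immersion n = 1.518, λ_exc = 488 nm, λ_em = 520 nm. Grid
128 × 8 × 256 voxels (z, y, x) at 40 nm in all directions — small enough
for an end-to-end run in well under a second, large enough to
Nyquist-sample both lateral cutoffs (≤ 87 nm required) and the confocal
axial cutoff (≤ 135 nm). The illumination pattern has raw contrast
m = 0.5, frequency at 30% of the lateral excitation cutoff (snapped to the
nearest frequency bin: 19 bins on the default grid), and polarization
ratio t = 3 (anisotropy r = 0.4), hence effective contrast
n = m(t − 1)/(t + 1) = 0.25.

## Pattern algebra and conventions

A raw frame is i′ = const · h ⊗ [s(1 + n cos(2π p x/N + φ₀))]. Expanding
the cosine, the sideband S(k − p) carries the complex weight
w = (n/2)e^{iφ₀}; the subtraction and recovery stages use exactly this
weight, with n and φ₀ taken from the data. The reported modulation
contrast is the amplitude/offset ratio n (so the anisotropy-limited best
case is n = 0.5), not the half-amplitude w.

`estimate_pattern` cross-correlates the deconvolved widefield spectrum with
the deconvolved SI spectrum along the pattern axis. The correlation has a
smooth object-autocorrelation shoulder around DC; the genuine illumination
peak is an isolated single bin (patterns are lattice-snapped), so a
candidate must exceed 1.5× its immediate neighbours (the DC bin included)
and 3× the off-DC median, and the implied contrast must exceed 0.01 —
otherwise `PatternNotFoundError`. Frequency is estimated at bin precision
only; sub-bin refinement is deliberately absent, which makes the stripe
artifacts expected of bin-precision estimation reproducible.

## Unmixing and cone recovery

S₁′ = S₁ − S₀ − w·S₀(k−p) − w̄·S₀(k+p), restricted to Ψ (outside the
support the subtraction leaves only mirror residue of the shifted copies;
no data live there). For the recovery, branch A(k) = S₁′(k+p)/w is valid
where its source bin lies in Ψ *and* the conjugate sideband at that source
bin was itself subtracted exactly, i.e. Ψ(k+2p); branch B symmetrically
with Ψ(k−p) and Ψ(k−2p). Without the ±2p guard, conjugate-sideband content
that entered the support from beyond the cutoff leaks into the recovered
cone as a ghost displaced by 2p. Where both branches are valid (the
overlap region Ω of the shifted supports) they are averaged; where exactly
one is valid it is taken alone; and the result is restricted to bins
outside Ψ before recombination, so the supports of the two terms of S_OS
are disjoint by construction (an overlap is a programming error and raises).

On the noise-free chirp phantom the recombined spectrum matches the ground
truth to well under 2% relative error over Ψ ∪ recovered cone, judged on
bins whose information passed through OTF values above 10× the support
threshold; below that the Wiener inverse is regularization-dominated and
no estimator could do better.

## Deconvolution

Wiener: S = I·conj(H)/(|H|² + w̃), then zeroed outside Ψ (support threshold
eps = 1e−3 of max|H|, configurable). The regularizer w̃ is a pure
bias-variance dial on the scale of |H|² with H(0) = 1: 1e−3 (the
`ReconOptions` default) suits shot-noise-limited single reconstructions;
1e−6 is appropriate for noise-free validation; the noise-performance
experiment uses 3e−6 — small enough that the in-band response is >97% at
|H| ≥ 0.01 (the experiment asks which frequencies are recoverable, so
response bias would corrupt the answer), large enough to bound the gain at
support-edge bins. Richardson–Lucy is provided as the Poisson-matched
alternative: a multiplicative update with circular FFT convolutions
(matching the package's forward model; the iterate stays non-negative and
conserves flux to numerical precision), default 20 iterations.

## Chirp phantom and profile readout

The phantom is s = ½(1 + cos φ) with stripes perpendicular to an axis
tilted 15° from z in the x–z plane; the instantaneous frequency rises
linearly from 0 at the top plane to f_max at the bottom, and on the central
sampling line of each plane it equals the linear law exactly. f_max is the
full confocal axial cutoff for the resolution experiment and 50% of it for
the noise experiment. The ½(1 + cos) profile is a modelling choice; only
"sinusoidal stripes with a linear frequency chirp" is prescribed by the
design.

`modulation_profile` samples the (y-averaged — phantom and illumination are
y-invariant) volume along the tilted axis through each depth-row centre.
Two readings:

* **minmax** (default): (max − min)/(max + min) in a window of one local
  period (≥ 8 samples) — the visual line-profile reading, used for
  noise-free comparisons.
* **demod**: least-squares fit of a + b·cos(φ_gt) + c·sin(φ_gt) against
  the phantom's known stripe phase over four local periods (clipped to the
  volume interior near edges); modulation = b/a. Zero-mean shot noise
  averages out of the fit instead of inflating a min/max spread, which
  would otherwise score a noise-dominated reconstruction as fully
  modulated. Used by the noise sweep.

The recovered axial cutoff is the local frequency of the shallowest depth
where the modulation drops below 25% and stays below for ≥ 3 consecutive
observable rows (rows whose window fits the volume); a profile below
threshold from the first observable row scores zero, and one that never
drops scores the deepest observable frequency. `recovered_fraction`
normalizes by the confocal cutoff 1/Δz.

## Noise experiment

For each photon level the noise-free raw pair is scaled jointly (shared
peak) and corrupted with independently seeded Poisson draws per repeat;
each repeat is reconstructed blind (pattern re-estimated from the noisy
data) and profiled with the demod reading; the recovered cutoff is
expressed as a fraction of the phantom's maximum frequency and averaged
over repeats. A repeat whose pattern cannot be detected counts as zero
recovery — at starved budgets detection failure *is* the failure mode.
Seeding uses a spawned `SeedSequence` tree, so a master seed reproduces the
sweep bit-for-bit. Default: levels {1e2, 1e3, 1e4, 1e5}, 50 repeats
(configurable; the statistics at 50 are already stable to ~±0.03 in the
mean fraction).

Under these conditions the mean recovered fraction is ≈0.26–0.31 at 1e2
photons, ≈0.5 at 1e3, ≥0.98 at 1e4 and 1.0 at 1e5: full-range recovery
requires on the order of 10⁴ photons in the brightest pixel, 10³ recovers
about half the range, 10² fails.

## Emulation from three-phase SIM data

A ssOS pair can be emulated from conventional 2π/3-stepped SIM frames: the
phase-0 frame is i′ and the average of the other two is i″, since
cos(θ+2π/3) + cos(θ+4π/3) = −cos θ — same wave-vector, π phase shift, half
the modulation. The widefield average of such a pair retains a residual
n/4 modulation (the two frames' contrasts differ), which biases the
*contrast* estimate upward; frequency and phase estimation are unaffected,
and the modulation ratio 0.5 is returned as a diagnostic.

## What the simulations do and do not show

The generator emulates pattern projection, anisotropy mixing at a single
global ratio t, diffraction blur and shot noise. It does not model camera
read noise or fixed-pattern noise, rotational diffusion of fluorophores
(anisotropy is taken as static), refractive-index mismatch, sample
scattering, or pattern imperfections beyond a global contrast m. Passing
tests therefore demonstrate the correctness and noise behaviour of the
*reconstruction*, not the performance of a physical instrument. The y
extent of the default grid (8 voxels) is deliberately thin — the phantom
is y-invariant — so lateral-y resolution statements are outside scope.

## Known limitations

* Pattern frequency is estimated at integer-bin precision; off-lattice
  experimental patterns will show stripe artifacts (expected and
  reproducible, see above).
* The recovery assumes equal modulation in both raw frames; emulated pairs
  violate this mildly (handled as described).
* With n below `n_min` = 0.01 the unmixing division is numerically
  meaningless and the pipeline raises rather than silently degrading to
  widefield deconvolution.
* The homodyne three-phase baseline is provided for comparison only; it is
  non-linear and has no PSF, so no spectral claims are made about it.
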