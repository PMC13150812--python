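# Methods

This note records the models implemented in `swim2d`, their assumptions,
the parameters that matter, and the numerical and design choices made
where the design was genuinely open.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Encoding model

An ion of mass-to-charge m/z in an ideal linear quadrupole driven at
`f_trap` with zero-to-peak rod amplitude `V_trap` has Mathieu parameter

    q = e V_trap / (π² (m/z) u r0² f_trap²)

(dimensionless; the charge count cancels) and secular frequency
`f_s = β f_trap / 2`.  Three β(q) treatments are provided:

- **dehmelt** — `β = q/√2`, the adiabatic approximation, reliable below
  q ≈ 0.4.  It underlies the closed reciprocal first-pass mass axis
  `m/z = k1/(f_e + k0)`.
- **koizumi** — the three-term harmonic-balance truncation of the Mathieu
  continued fraction, `q² = β²(4−β²)²/(8+2β²)`.  It is exact as q → 0,
  within 0.3% of the exact exponent at q = 0.5 and ~3% at the q = 0.908
  stability boundary, and — crucially for decoding — closed-form in the
  β → q direction, i.e. from measured frequency to mass.  Its use for
  mass conversion is capped at `f_s/f_trap = arccos(−11/14)/(2π) ≈ 0.394`
  (β ≈ 0.788); beyond that cutoff `mz_from_encoding` switches to numeric
  inversion of the exact exponent (or raises, in strict mode).
- **exact** — the continued-fraction characteristic exponent, truncated
  when terms fall below 1e-12; the oracle for both approximations.

The SWIM magnitude law `M(f, n) = ½(1 + sin(nπx − π/2))`,
`x = (f−f_min)/(f_max−f_min)`, makes the per-frequency amplitude a sampled
sinusoid in the index n, so each species is tagged with
`f_e = (f_s − f_min)/(2(f_max − f_min))` cycles per index — the [0, 0.5]
Nyquist interval when one summed spectrum is saved per index.

**Field radius.**  Absolute frequency predictions require `r0`, which is
instrument-specific.  The shipped default (2.895435 mm) was back-solved
once from the predicted substance P [M+3H]³⁺ encoding frequency
(0.102 Hz at m/z 449.92) under the default band and RF settings, and is a
fixture convention, not a measured value.  With it, the Dehmelt map spans
m/z ≈ 99–4947 across the band, while the q < 0.908 stability requirement
cuts the low-mass end at m/z ≈ 154; the nominal m/z 90–4500 precursor
range used for axis sentinels is therefore nominal only.

## Pulse synthesis

Pulses are synthesized on the DFT grid of the pulse window (default 20 ms
at 25 Msamples/s): magnitudes `M(f, n)` inside [f_min, f_max], exactly
zero outside, a quadratic spreading phase, inverse real FFT.  The phase
convention is chosen so the group delay rises linearly from 0 at `f_min`
to `T` at `f_max` (energy localized in a window of width ≈ T; default
T = 10 ms); the literal quadratic form `T(f−f_min)²/(f_max−f_min)`, which
is dimensionally a pure number rather than radians, remains available as
`convention="literal"` for cross-checks.  No apodization is applied before
the inverse transform.  The overall voltage scale is free: by default the
sequence is normalized so the n = 2 pulse peaks at the configured
amplitude (1 V zero-to-peak), matching the regime of long, low-amplitude
excitation.  The polarity-inverted twin required for dipolar drive is
`SwimPulse.inverted()`; no DAC hardware is driven.

## Signal-level forward model

The ion cloud's radial excursion is represented by the scalar excitation
amplitude `a(n) = A_exc · M(f_s, n)` — a resonant-response proxy that
keeps the simulator analytic and fast; the trajectory simulator provides
the dynamical cross-check.  Per index, the bookkeeping is:

1. **In-trap fragmentation.**  UVPD: fragmentation probability
   `p = p_max exp(−a²/2σ²)` with σ = `laser_sigma_frac · A_exc` — maximal
   at zero radius (beam centre), so fragment traces are 180° out of phase
   with the precursor.  In-trap CID: `p` is a linear ramp from
   `cid_threshold` up to the full excitation scale, clipped at 1 —
   threshold behaviour that yields periodic but asymmetric waveforms and
   hence harmonics.  Per channel, the fragment fraction is
   `p · max_yield`; survival is one minus their sum, so flux-constant
   totals are conserved identically for any yield sum ≤ 1.
2. **Exit-aperture transmission.**  Unity up to `v_crit`, then a smooth
   tanh-shaped loss of depth `loss_depth` (default 0.8) and width
   `loss_width` (default 0.125 V) — a smooth stand-in for the hard
   aperture cut, applied to the whole cloud (precursor and in-trap
   fragments alike).  `v_crit = ∞` is the flux-constant mode;
   `A_exc = 2 v_crit` with UVPD on reproduces the mixed-mode double dip
   and its 2 f_e harmonic.
3. **Beam CID.**  Downstream of the trap, a fixed fraction
   `beam_cid_frac · max_yield` of transmitted precursors converts, so
   those fragment traces are in phase with the precursor.

Isotopologues are treated as independent sub-species with their own
secular frequencies; fragments inherit the isotopologue index at the
product-charge spacing (1.003355/z).  Species fs values default to the
Dehmelt map, consistent with the first-pass axis; `fs_method="koizumi"`
generates deliberately miscalibrated cubes for recalibration tests.
Upstream photofragmentation (ions fragmented before SWIM applies) is
emulated as a constant, unmodulated fragment baseline
(`upstream_frac`, default 2% of channel capacity), which mean
subtraction confines to row 0.

Peaks are rendered as bin-integrated Gaussians (difference of error
functions over bin edges, ±8σ support) of ppm-constant FWHM (default
20 ppm), so integrated intensity is conserved exactly regardless of the
bin-to-width ratio.  Noise is `noise_prop · signal · N(0,1) + floor ·
N(0,1)` per bin per index, clipped at zero, with the floor expressed
relative to the cube maximum (defaults 0.05 and 0.001) — the
signal-proportional structure seen in modulated ion signals.  The 50
trap-and-release fills summed per index are represented implicitly by
this noise scale rather than by simulating sub-fills.

What the generator does *not* emulate: space charge and trap-capacity
saturation, ion–ion reactions, secular-frequency line width (amplitude
dither, collision broadening), detector saturation, and chemical
background.  Passing tests therefore demonstrate the correctness of the
encoding/decoding chain under the stated noise model, not robustness to
every artifact of real spectra.

## Trajectory-level model

Dynamics are integrated in the radial plane only (axial motion decouples
in an ideal trap; the laser propagates axially so exposure depends only
on radial position).  The force is the ideal quadrupole RF field plus a
uniform dipolar field `V_exc(t)/r0` along x; the integrator is velocity
Verlet at `dt ≤ 1/(50 f_trap)` with numba-compiled kernels.  Convergence
is second order; the secular-frequency error against the exact exponent
is < 0.5% across q ≤ 0.4 at the default step.

Collisions follow a hard-sphere model: per step, a 2D Maxwell–Boltzmann
gas partner is sampled and a collision accepted with probability
`n_gas σ v_rel dt`, followed by an elastic, isotropic-angle update in the
centre-of-mass frame.  Because the model is two-dimensional, ensembles
relax to mean kinetic energy kT (two degrees of freedom), not (3/2)kT.
Default gas parameters (N₂ at 10⁻³ Pa, 300 K, σ = 2 nm²) are plausible
trap-chamber values, not measurements, and pulse-sequence runs default to
collisionless for speed.

UVPD: the path-averaged fluence over one secular orbit through a Gaussian
beam (0.6 mm fwhm, 25 µJ, 213 nm defaults) drives a Monte Carlo fate
`P(fragment) = 1 − exp(−k · exposure)`; the default rate constant is
calibrated so an on-axis ion fragments with probability ½ per evaluation.
Fragments receive an isotropic centre-of-mass kick carrying a
configurable fraction (default 10%) of one photon's energy.  Ions whose
radial amplitude over the final orbit exceeds `loss_radius_frac · r0`
(default 0.8) at release are tallied as lost — the exit-aperture
criterion that produces flux-periodic behaviour at high drive amplitude.
The initial ensemble is a thermal 2D Gaussian cloud (σ = 0.2 mm default)
rather than an injection-optics simulation.

Desk-scale runs use shortened pulses (1–2 ms) and hundreds of ions; the
encoding physics is unchanged because it depends only on the trap
parameters and the magnitude law, not the pulse length.

## Decoding

Per product-m/z column: subtract the column mean (suppressing the f_e = 0
ridge so unmodulated baselines stay in row 0), optionally apodize
(rectangular default, Hann available — the resolving-power figure assumes
rectangular), zero-fill once (N → 2N), FFT, keep the N non-negative
frequency magnitudes.  The first-pass precursor axis is the reciprocal
Dehmelt map ("eq5") or the high-q closed form ("eq6"); on the eq6 axis
the beyond-cutoff rows use the exact-exponent inversion scaled to join
the closed form continuously at the domain edge, keeping the axis
strictly monotone (those rows lie at m/z ≲ 163, at the trap-stability
edge).  Rows mapping outside the nominal m/z 90–4500 band carry NaN
sentinels and are never dropped.

Recalibration fits a polynomial (order 1–3) in the *first-pass mass* to
(f_e, product m/z) pairs harvested from the autocorrelation line, with
harmonic peaks flagged and excluded first.  Peak picking finds 2D local
maxima above a per-column SNR threshold (noise = 1.4826 × median absolute
deviation per column, threshold default 5 — which also suppresses
vertical streaking, since a streaked column's own floor raises its
threshold), merges candidates split across adjacent product bins, and
suppresses weaker same/adjacent-column maxima lying within the
rectangular-window sidelobe envelope (≈ 2/(πd) at row offset d ≤ 40,
margin 2 — zero-fill-once pins sidelobes at fixed row offsets, so the
rule is independent of the index count).  Precursor coordinates are
refined with a 7-point intensity-weighted centroid (apex row ± 3) in
precursor-m/z coordinates.  Harmonic flagging labels a peak whose
frequency is an integer multiple (folded at the Nyquist edge if above
0.5) of a stronger peak's frequency in the same product column, within
1.5 frequency bins.

Resolving power is measured as apex m/z over the FWHM obtained by linear
interpolation of the half-maximum crossings in row space, mapped through
the precursor axis.  With 1024 indices, rectangular window and zero-fill
once, the window-limited width is ≈ 1.21/1024 cycles/index, which the
reciprocal axis converts to M/ΔM = (f_e + k0)/Δf_e ≈ 100 for a mid-band
species — the figure `scripts/acceptance.py` recomputes by simulation.

## Degenerate inputs and numerical conventions

Out-of-band or Mathieu-unstable species are rejected with specific
exceptions rather than aliased or clipped.  The n = 0 pulse is exactly
zero.  Empty peak lists and all-zero cubes are valid; columns of zeros
get a floored noise estimate so SNR stays finite.  All stochastic
components (cube noise, collision draws, Monte Carlo fates, thermal
clouds) descend from explicit seeds; identical configurations reproduce
outputs bit for bit, and every CLI output embeds a manifest (configs,
hashes, seed, version) sufficient to regenerate it.

## Known limitations

- The high-q ("koizumi") closed form is an approximation; its ~2–3% error
  near the stability boundary is visible as the seam handled above, and
  recalibration absorbs the remainder only within the calibrant span.
- The forward model's scalar-radius proxy has no amplitude-dependent
  frequency shifts, so encoding frequencies are exact by construction;
  real traps show small shifts that would appear as calibration error.
- The trajectory model is 2D and ideal-field; higher-order field
  components, axial gating dynamics and injection optics are out of scope.
- mzML export writes centroid-free profile arrays with minimal metadata —
  enough for interoperability, not a full instrument-metadata record.
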