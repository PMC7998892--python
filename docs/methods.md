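# Methods

This note records the model, the numerical choices, and the reasoning
behind the places where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Forward optical model

**Structure.** A NAA-GIF is modelled as a strictly 1-D layered medium:
an optional continuous cargo film on top, a top rugate stack (period
Λ_top), a bottom rugate stack (Λ_bottom), and a compact pure-oxide
barrier layer, free-standing in the release medium (no substrate — the
aluminium is removed for flow-cell work, and including it would only add
a broadband background). The host volume fraction within each stack is
f_host(z) = f̄ + Δf·sin(2πz/Λ) with z = 0 at the top of that stack: the
phase restarts at 0 at the stack junction because the physical phase
relationship between the two growth stages is not known; a fixed
convention makes results reproducible. Each period is discretized into
`layers_per_period` uniform sub-layers whose composition is sampled at
the sub-layer midpoint (second-order accurate). The modulation is applied
to the volume fraction directly, not to a pore radius followed by an r²
mapping, since the fraction modulation is itself the stated first-order
description. The cargo fraction is constant with depth (a conformal layer
on the pore walls); the medium fraction closes each layer to 1.

Discretization adequacy: staircasing a sinusoid into m layers scales its
fundamental Fourier component by sinc(π/m), i.e. the 8-layer default
carries a ~2% deficit in coupling strength. The test suite checks
Richardson-style that refinement contracts (order ≥ 1) and that 16 layers
are converged to < 1% in band height. Eight layers per period is the
package default because band *positions* and all qualitative observables
are insensitive to it, and it keeps a 1600-layer structure cheap.

**Materials.** The alumina host uses a two-term Cauchy law
n(λ) = A + B/λ² with A = 1.59, B = 1.4·10⁴ nm² (≈1.67 at 400 nm → ≈1.61
at 900 nm, around the handbook value ~1.66 mid-visible), with a
constant-index override; a Cauchy fit is used instead of shipping a
tabulation, and the spectral window (300–1000 nm) is narrow enough that
two terms suffice. The cargo molecule is a single Lorentz oscillator,
ε(ω) = ε_∞ + S·ω₀²/(ω₀² − ω² − iγω), parameterized by a resonance
wavelength (default 530 nm, inside the signal band, matching the visible
absorption of rhodamine 6G), ε_∞ = 1.96 (background index 1.4, typical
organic film), strength S = 0.05 and a damping given as a
wavelength-equivalent linewidth (default 90 nm, an 80–100 nm-wide
absorption band). These are configuration, not constants: the exact
oscillator parameters of the reference experiments are not available.
All materials obey the passive convention Im(ε) ≥ 0, Im(n) ≥ 0 under
exp(−iωt).

**Mixing.** The Bruggeman equation Σ fᵢ(εᵢ − ε_eff)/(εᵢ + 2ε_eff) = 0 is
recast as a degree-n polynomial and solved by batched companion-matrix
eigenvalues (vectorized over the wavelength grid), followed by Newton
polishing to a residual ≤ 1e−10. Root selection: discard roots on the
non-positive real axis or with negative imaginary part — for passive
components the spurious roots cluster near −εⱼ/2 and always have
Im ≤ 0 — and among admissible roots take the largest real part
(deterministic tie-break). Layers sharing a composition are mixed once; a
rugate stack has only `layers_per_period` distinct compositions.

**Reflectance.** Standard 2×2 characteristic matrices with tilted
admittances (η = n·cosθ for s, n/cosθ for p), complex Snell's law with
the branch Im(n·cosθ) ≥ 0 (decaying evanescent waves), unpolarized light
as the mean of s and p. With the n + ik convention the off-diagonal
matrix elements carry −i (the +i form belongs to n − ik; the two give
identical R for lossless stacks, which makes the sign error invisible to
lossless-only validation — the suite therefore includes an absorbing-film
Airy check). Validation: bare-interface Fresnel and single-film Airy
closed forms to 1e−10, R + T = 1 to 1e−9 for lossless stacks at 0°, 8°
and 30°, reciprocity, and s ≡ p at normal incidence. Default incidence
0° (configurable; the experimental 8° changes the spectrum negligibly),
default grid 400–900 nm at 1 nm.

A Bragg-condition oracle (λ = 2·n̄·Λ with n̄ the Bruggeman index of the
period-average composition, solved self-consistently in λ) predicts the
stopband positions independently of the transfer-matrix path and anchors
the band-position tests. For the published simulation geometry
(Λ = 164/284 nm, f_host 0.9) the two bands land near 528 and 897 nm, so
simulation-level checks use a 400–1000 nm grid; the default *analysis*
windows (430–560 and 600–800 nm) instead bracket the measured band
positions of the fabricated filters, which do not scale with the stated
simulation periods.

## Observables

Band maxima are raw maxima within a window (no baseline subtraction or
lineshape fit), ties broken toward shorter wavelengths; the
signal/reference ratio is therefore invariant under any positive
rescaling of the spectrum and applies to raw flow-cell intensity as well
as calibrated reflectance. An optional centred moving average (odd width)
can be applied before peak-picking for noisy data; the default is none.
The wetting redshift is the difference of peak wavelengths after minus
before.

## Release kinetics

Phases: wetting (t < 0, dry lead-in), stabilization (first scheduled pH,
7.4), release (any later, more acidic pH). The fit uses release-phase
points only.

The anchored exponential R(t) = R_max + A·(1 − exp(−(t − t_max)/t_release))
fixes (t_max, R_max) at the measured maximum of the analyzed trace and
fits (A, t_release) by trust-region least squares with the analytic
Jacobian, initialized at A₀ = R_max − R(first release point),
τ₀ = span/3, with exponents clipped at ±100 so probing a tiny τ cannot
overflow. The model family C − B·e^(−t/τ) is closed under re-anchoring,
so anchoring costs no generality; the fitted curve passes exactly through
the anchor. Note the anchored geometry: A is the *remaining* rise beyond
the anchor, so for a trace anchored at its end A is small even when the
observed rise is large, and admissible A is bounded by
R_max/(e^(span/τ) − 1) if the backward extrapolation is to stay positive.
Both signs of A are permitted; a flat trace sets a `degenerate` flag
(t_release is then unidentifiable).

**Anchor estimation.** On noisy traces the raw sample maximum is an
extreme-value statistic sitting several noise standard deviations above
the underlying curve, and the anchored fit amplifies anchor error into
t_release with a gain of ~3. The anchor is therefore read from a
Savitzky–Golay (local quadratic) smooth of the release-phase trace —
unbiased for smooth trends, identical to the raw maximum in the
noise-free limit — and when the smoothed maximum lies in the final
window (the monotone saturating case) the anchor time is pinned to the
last point, so the anchor value estimate has *symmetric* noise and the
median recovered t_release over noise realizations is unbiased. The
window is `anchor_smooth` (odd; "auto" = ~5% of the points). For
12-hour flow-cell traces a wider window (1201 samples ≈ 3.3 h, used by
the acceptance study) further suppresses anchor noise; for short traces
the default keeps the noise-free round trip exact to < 0.1%.

`percent_change` reports 100·(t_b − t_a)/t_a rounded to the nearest
integer percent (half away from zero), the precision at which such
comparisons are quoted.

## Synthetic data generator

The generator drives the full forward optical model, so synthetic
observables inherit the physics rather than being drawn from the model
being fitted (the direct Eq.-2 sampler `generate_ratio_trace` exists
separately, precisely for round-trip tests).

**Drop/dry series**: one simulated spectrum per loading level
(nondecreasing f_drug), optional seeded Gaussian noise; with zero noise
the spectra are bit-identical to `simulate_gif_spectrum`.

**Flow-cell series**: dry spectra (medium index 1.0) during the lead-in;
wet spectra (1.33) from t = 0 — the index step produces the wetting
redshift and intensity drop; constant loading during stabilization; from
the pH switch the in-pore cargo fraction decays as
f(t) = f₀·exp(−(t − t_switch)/t_release). The exponential *microscopic*
law is a modelling choice that keeps the truth parameter directly
comparable to the fitted t_release. Spectra at intermediate loadings are
linearly interpolated in f between 25 exactly-simulated knot spectra
(the spectrum is smooth in f; the knot error is far below the noise).
Noise is additive Gaussian, σ expressed relative to the maximum intensity
of the clean series — the simplest defensible model of a fiber
spectrometer — and `add_noise` re-noises a clean series so Monte-Carlo
replicates share one forward simulation.

Default flow-cell conditions (chosen once, with reasons):

- protocol: 10 s sampling, 0.5 h dry lead-in, 2 h at pH 7.4, 10 h at
  pH 5.0 (the experimental schedule);
- `f_host_avg = 0.75`: the released samples are pore-widened; ~25%
  porosity is what yields the observed ~20–25 nm wetting redshift (at
  10% porosity the air→water shift is only ~10 nm);
- Λ = 165/225 nm: puts the wet stopbands at the measured band positions
  (~516 and ~698 nm), inside the default analysis windows;
- `f_ampl = 0.06`: broad (~10 nm), strong but unsaturated stopbands. A
  much smaller amplitude gives a few-nm band whose sampled peak height
  is numerically jumpy; a much larger one drives the band into the
  saturated (tanh²) regime where it stops responding to absorption in
  the pores;
- output grid 420–820 nm at 0.25 nm with a 2 nm FWHM Gaussian
  instrument convolution: a fiber spectrometer has sub-nm pixels but
  ~2 nm optical resolution, and the ~45 µm coherent membrane's ~2 nm
  Fabry–Pérot fringes — real in the ideal calculation, invisible to the
  instrument — would otherwise alias into the band maxima;
- initial loading `f₀ = 0.004` (dilute): the band ratio responds to the
  cargo fraction approximately as exp(−c·f) (a Beer–Lambert-type law),
  so an exponentially decaying f(t) maps to a single-exponential ratio
  trace only when c·f₀ ≪ 1. A dilute residual loading — what remains
  after coating and washing — operates in this linear regime, which is
  also the regime in which fitting a single exponential to the trace is
  self-consistent. At heavy loading (f₀ ≈ 0.05) the trace is
  Gompertz-shaped and a single-exponential fit misestimates the time
  constant severely; this is a property of the method, not of the
  implementation.

**What the generator does not emulate:** polyelectrolyte swelling
chemistry and pK_a-dependent gating (these enter only through the
effective kinetic parameters), burst release, baseline drift of the lamp,
wavelength-correlated noise, sample roughness/scattering, and any
pore-blocking inhomogeneity. Passing tests therefore show that the
analysis recovers the truth of *this* physical forward model under
*these* noise conditions — not that every real flow-cell trace is a clean
single exponential.

**Analysis protocol for flow-cell traces** (used by the acceptance
study): spectral smoothing width 9 samples (2.25 nm, matched to the
instrument resolution — wider smoothing measurably distorts the trace
because the evolving band shape interacts with the smoothing kernel) and
`anchor_smooth = 1201`. With the published release times as ground truth,
the t_release = 47,038 s case is intrinsically the hardest: the 10 h
release window covers only 0.77 of one time constant, so the curvature
that identifies τ is weak and the per-replicate scatter is large; the
median over replicates is the meaningful summary.

## Numerical conventions

Lengths nm, times s, angles degrees; seeds explicit everywhere, default
0. Spectrum CSVs carry 6 significant digits. Reflectance is clipped to
[0, 1] only within 1e−9 round-off; larger violations raise. Config files
reject unknown keys. The composition closure is enforced to 1e−12.

## Known limitations

- Strictly 1-D coherent optics: no roughness, scattering, lateral
  inhomogeneity, or partial coherence.
- The Bragg oracle uses the period-average index and first-order
  diffraction only; it locates bands to within a bandwidth, not exactly.
- The release fit is a two-parameter single-exponential: it cannot
  represent burst release, bi-exponential kinetics, or baseline drift,
  and with data covering ≲1 time constant the estimate of t_release is
  noise-sensitive (reported per fit via `residual_sum` and the
  `degenerate` flag, not hidden).
- The alumina Cauchy fit and Lorentz defaults are stand-ins calibrated to
  handbook-scale values, not to a specific measured film.
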