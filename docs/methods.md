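# Methods

## Two-state lineshape model

A nascent chain in slow exchange between unfolded (U) and folded (F) states
gives two resolved resonances whose integrals are proportional to the state
populations. The spectral model is

    m(ν) = Σ_k a_k e^{iφ_k} / (π w_k/2 + i π (ν − ν_k))  +  Σ_j c_j x^j

with ν in Hz, positions ν_k (stored in ppm, converted through the
transmitter frequency), full widths at half maximum w_k in Hz, complex
amplitudes split into area a_k ≥ 0 and phase φ_k ∈ (−π, π], an optional
very broad Lorentzian (FWHM ≥ 500 Hz) representing exchange-broadened
background signal, and a complex polynomial baseline (degree ≤ 3) on the
axis rescaled to [−1, 1]. Each Lorentzian is normalized so the integral of
its absorptive part equals a_k; the broad component and baseline never
enter population sums.

### Discrete fit kernel

A sampled, truncated Lorentzian FID does not transform to the exact
continuous Lorentzian; the discrepancy is below the noise at SNR ≈ 20 but
resolvable in high-SNR or noiseless data, where it biases fitted positions
by ~10⁻³ ppm. The fit therefore evaluates each component as the same
discrete operation the data underwent: synthesize the decay on the time
grid implied by the frequency axis, halve the first point, FFT, scale by
2·dwell. Fitting the spectrum this way is exactly likelihood-equivalent to
fitting the FID itself (the transform is unitary up to a constant), which
is why the frequency domain — where the baseline is interpretable — can be
used without loss. The continuous closed form remains available
(`model_spectrum`) for display and analytic work. Fits assume the spectrum
was not zero filled (`zero_fill_factor=1`); zero filling correlates
adjacent noise points and mildly shrinks the apparent noise floor, which
the i.i.d. Gaussian likelihood would misread.

### Estimation

Real and imaginary parts are fitted jointly by trust-region nonlinear least
squares with an analytic Jacobian; starting values come from smoothed
magnitude-spectrum peak picking, with the initial phase read from the
complex value at each picked maximum and up to three jittered restarts.
The noise s.d. is estimated once from the signal-free baseline as
1.4826 × MAD of the real part and held fixed thereafter. Model choice
(number of peaks, baseline degree, broad component) minimizes
BIC = k ln n − 2 ln L̂ with n = 2 × the number of spectral points; ties
break toward fewer parameters, independent of candidate order.

### Hamiltonian Monte Carlo

Uncertainties come from HMC over all model parameters, using analytic
gradients of the log posterior:

* transforms: positions, log-FWHM and phases map to unconstrained space
  through scaled logistic functions; areas through log.
* priors: positions uniform over the spectral window; FWHM log-uniform on
  [1, 2000] Hz ([500, 20000] Hz for the broad component); areas half-normal
  scaled to the total spectral integral; phases uniform; baseline
  coefficients normal(0, 10 × noise s.d.).
* integrator: leapfrog with ~20 steps (uniformly jittered ±50 %), step size
  adapted by Nesterov dual averaging to a 0.8 acceptance target.
* metric: diagonal inverse mass initialized from the finite-difference
  curvature of −log posterior at the MAP — the parameter scales span many
  orders of magnitude and a unit metric freezes the chains — then refreshed
  once mid-warmup from the chain variance.
* diagnostics: split-R̂ per parameter (flagged above 1.01); an error is
  raised if more than 5 % of post-warmup trajectories diverge.

Populations are computed per posterior draw, p_F = a_F/(a_F + a_U), so the
reported s.d. carries all parameter correlations. U/F labels follow
proximity to configured reference shifts; without references the downfield
peak is folded (matching the synthetic generator's convention of placing F
0.8 ppm downfield of U). Calibration is checked by a coverage test: ≥ 80 %
of central 95 % intervals for p_F must cover the generating truth over 50
replicates (observed ≈ 86–92 %).

## Thermodynamics

ΔG_F-U = −RT ln(P_F/P_U) with R = 1.9872 × 10⁻³ kcal/(mol·K) and T =
298.15 K by default (¹⁹F spectra recorded at 25 °C; ¹⁵N-derived quantities
can override to 283.15 K). Error propagation is first-order
(sd = RT·sd_P/(p(1−p))) or Monte Carlo over truncated-normal population
draws. The first-order form is accurate to ~10 % only while the
quadratic term |1−2p|·sd/(p(1−p)) stays small — at p = 0.2, sd = 0.1 the
Monte-Carlo spread is ~23 % larger, so the Monte-Carlo mode is preferred
for skewed populations.

When no folded signal is visible, the largest population that could hide in
the noise is computed from a hypothetical peak of height 3 × noise s.d.
with the U-state linewidth (Lorentzian area = height·π·FWHM/2), capped at
1 %, and all downstream energies are flagged as bounds; bounds never enter
means or regressions silently.

Length attenuation is, per variant, 100 × (|ΔΔG_L31| − |ΔΔG_L34|)/|ΔΔG_L31|,
summarized as mean ± sample s.d. across the six uL23/uL24 variants
quantified at both lengths (bound-derived values included by default, since
the 1 % cap is how those variants were quantified). The WT reference
population at the longer length is 59 % by default with a documented 58 %
alternative, both having been reported.

Binding: p_b = (δ_obs − δ_ub)/(δ_b − δ_ub) under fast exchange, shifts
slightly outside the reference interval clamped with a warning;
ΔG_bind = −RT ln(p_b/p_ub) so that weaker binding on a variant gives
positive ΔΔG_binding. The fully-bound reference shift must be supplied — no
default is invented.

## Profiles

Relative intensities divide each marker's volume by scans × concentration,
average across markers (defaults: V682/A683/A694 for the ¹⁵N unfolded
channel, I674/I695/I738/I743 for the ¹³C folded channel), and normalize to
the reference length (shortest linker = fully unfolded; longest = fully
folded). Volume and concentration relative errors combine in quadrature.
The folding onset is the first 0.5 crossing by linear interpolation between
measured lengths, returning explicit "< L_min"/"> L_max" bounds when the
grid does not bracket the crossing — this makes qualitative onset
statements machine-checkable. The four-point moving average is a display
aid and never feeds the onset estimator.

## Ensemble metrics

Tunnel volume is a grid count: inclusion spheres (20 Å) seeded at
nascent-chain Cα positions, cubic grid (2.0 Å pitch) anchored at integer
multiples of the pitch so identical specifications share identical grids,
grid points deleted within vdW radius (Bondi set, 1.7 Å fallback) + 1.09 Å
of any heavy atom. The cutoff semantics (vdW + cutoff vs plain center
distance) are switchable because grid-volume tools differ on this point;
differences between variants are computed on the shared grid. The
single-sphere volume converges to the analytic 4/3 π r³ within 3 % at 2 Å
pitch and changes < 1 % on halving the pitch.

Contact frequencies count frames with any heavy-atom pair within 4.5 Å
between a nascent-chain residue and a ribosomal component, as % of frames;
the KD-tree implementation is verified exactly against an all-pairs scan.
The 4.5 Å default is the common heavy-atom contact convention; it is
configurable because reported contact maps rarely state one.

S² uses the second-rank orientational tensor of unit C→O bond vectors
averaged over all frames (no windowing): S² = (3(⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² +
2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²) − 1)/2, giving exactly 1 for a rigid vector,
0.25 for two orthogonal orientations, → 0 isotropically. The ribosome
frame is fixed, so no alignment is applied.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure of each observable —
two-resonance slow-exchange spectra (0.8 ppm separation, 60–150 Hz
linewidths, optional ≥ 500 Hz background, circular complex Gaussian noise
at SNR ≈ 20 on the dominant peak), fast-exchange shift series, logistic
intensity-vs-length profiles with shared multiplicative concentration
noise, and a self-avoiding jointed chain in a frozen cylindrical
pseudo-atom wall with per-residue mobility in [0, 1] interpolating rigid →
isotropic. SNR ≈ 20 is a stability choice, not a measured value. The toy
wall is a cylinder — no attempt to mimic rRNA geometry — so passing tests
demonstrate correct estimators and calibrated uncertainties on data of the
right form, not agreement with any real structure; real spectra also carry
phase/baseline artifacts and field inhomogeneity the generator omits, which
is precisely what the baseline polynomial and free phases are there to
absorb.

## Problem sizes and determinism

Default analyses use 2048–4096 complex points per spectrum, HMC with 2–4
chains × (300–1000 warmup + draws), 50-replicate calibration runs at 1024
points, and 20–400-frame ensembles; these sizes put every recovery
statistic well inside its tolerance while keeping a full run to minutes on
one CPU. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical outputs,
and the pipeline driver stamps every output with the seed and a
configuration hash.

## Known limitations

* Lorentzian-only lineshapes: no Voigt/Gaussian components, no chemical
  exchange lineshape modelling (slow exchange is assumed), no
  intermediate-state quantification beyond the broad background component.
* The noise s.d. is fixed during sampling rather than marginalized; at the
  baseline sizes used its estimation error (< few %) is negligible against
  the reported population s.d.
* Half-axis peak integration is not a substitute for fitting: with 60–150
  Hz Lorentzians 0.8 ppm apart, tail overlap across the midpoint moves the
  naive integral ratio by ~3 percentage points (w/(2πΔ) per peak).
* The onset estimator's threshold (0.5) and linear interpolation are a
  construction; reported onsets are grid-resolution-limited and the
  estimator returns bounds rather than extrapolating.
* Mobility in the toy ensemble couples position and orientation through a
  single per-residue parameter; it controls the S² endpoints exactly but
  intermediate values are not calibrated to any physical diffusion model.
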