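# tunnelfold

Quantitative analysis of co-translational protein folding on engineered
ribosomes.

Ribosomal exit-tunnel loops (uL22, uL23, uL24) can be truncated or extended
to reshape the tunnel and shift the folding equilibrium of a nascent chain
(NC) such as the immunoglobulin-like FLN5 domain. The readouts are
spectroscopic and structural: 1D ¹⁹F NMR spectra resolve the folded (F) and
unfolded (U) nascent-chain states in slow exchange, ¹H–¹⁵N/¹³C cross-peak
intensities track the unfolded and folded populations along elongation, and
coordinate ensembles report the tunnel's geometry and the chain's mobility.
`tunnelfold` implements the full quantitative chain from these raw
observables to thermodynamic and structural conclusions, with a synthetic
data generator so every stage is testable by parameter recovery — no
downloads required.

## What it computes

**Lineshape deconvolution.** A 1D complex spectrum is modelled as Lorentzian
peaks (U and F), an optional very broad background component, and a complex
polynomial baseline; real and imaginary parts are fitted jointly. The number
of components is chosen by the Bayesian information criterion,
BIC = k ln n − 2 ln L̂, and uncertainties come from a Hamiltonian Monte Carlo
sampler over all parameters. State populations follow from the peak areas,
P_F = A_F / (A_F + A_U), evaluated per posterior draw.

**Two-state thermodynamics.** ΔG_F-U = −RT ln(P_F/P_U) at 298.15 K,
ΔΔG = ΔG(variant) − ΔG(WT), first-order and Monte-Carlo error propagation, a
signal-to-noise detection cap (default 1 %) for spectra with no folded
signal, the length attenuation of |ΔΔG| between elongation snapshots, and
ordinary least squares for folding–binding correlations.

**Binding from chemical shifts.** In fast exchange the observed shift is the
population-weighted average of bound and unbound references,
p_b = (δ_obs − δ_ub)/(δ_b − δ_ub), converted to ΔG_binding by the same
two-state expression; weaker binding gives positive ΔΔG_binding.

**Intensity profiles.** Peak volumes normalized by scan count and NC
concentration, averaged over marker residues, referenced to fully unfolded
(short linker) or fully folded (long linker) states; folding onset by
threshold crossing with linear interpolation; arrest-peptide force-assay
fraction f_FL = FL/(FL + A).

**Ensemble metrics.** POVME-style tunnel volume (20 Å inclusion spheres at
nascent-chain Cα positions, 2.0 Å grid, exclusion within vdW radius +
1.09 Å), same-grid volume differencing between variants, NC–ribosome contact
frequencies (% of frames, heavy atoms within 4.5 Å), and S² order parameters
of backbone carbonyl C→O vectors (1 = rigid, 0 = isotropic).

## Worked example

```python
from tunnelfold.nmr_core import AcquisitionParams, estimate_noise, fourier_transform
from tunnelfold.synthetic_data import GroundTruthSpectrum, simulate_fid
from tunnelfold.lineshape_fit import select_model, sample_posterior, populations_from_fit
from tunnelfold.energetics import ThermoConfig, delta_g_folding

truth = GroundTruthSpectrum.two_state(0.59, snr=20, seed=3)      # 59 % folded
acq = AcquisitionParams(n_points=4096, dwell=0.350 / 4096)        # 350 ms acquisition
spec = fourier_transform(simulate_fid(truth, acq), zero_fill_factor=1)
spec.noise_sd = estimate_noise(spec, exclusion_windows=[(-61.5, -58.5)])

fit = select_model(spec, [(1, 1, False), (2, 1, False)])          # BIC: 1 vs 2 peaks
fit = sample_posterior(spec, fit, n_chains=2, n_warmup=300, n_draws=300, seed=7)
pops = populations_from_fit(fit)
print(f"P_F = {pops.p_f:.3f} +/- {pops.sd_pf:.3f}")
fe = delta_g_folding(pops, ThermoConfig())
print(f"dG_F-U = {fe.dg:+.3f} +/- {fe.sd:.3f} kcal/mol")
```

prints

```
P_F = 0.592 +/- 0.003
dG_F-U = -0.221 +/- 0.008 kcal/mol
```

i.e. the BIC-selected two-peak fit recovers the generating 59 % folded
population within one posterior standard deviation, and the folding free
energy is mildly negative, as expected when the folded state dominates.

The `analysis/` directory holds numbered drivers that run the full study
sequence (simulate spectra → fit → folding energetics → binding →
intensity profiles → ensemble metrics), printing what each step found and
writing tables under `results/`. A `tunnelfold` command-line interface
exposes the same stages (`tunnelfold simulate fid ...`, `tunnelfold fitspec
...`, `tunnelfold run --config ...`).

## Layout

```
src/tunnelfold/        library: synthetic_data, nmr_core, lineshape_fit,
                       energetics, profiles, ensemble_analysis, cli
analysis/              numbered study drivers (01..06)
tests/                 pytest suite incl. end-to-end acceptance checks
scripts/acceptance.py  headline-number reproduction
docs/methods.md        models, assumptions, numerical choices
```
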