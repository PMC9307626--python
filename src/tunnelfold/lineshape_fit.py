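"""Deconvolution of 1D complex spectra into state populations.

A two-state nascent chain in slow exchange gives two resolved Lorentzian
resonances (unfolded U and folded F) whose integrals are proportional to the
state populations.  The model fitted here is a sum of complex Lorentzians,
an optional very broad Lorentzian (intermediate/background signal, excluded
from population sums), and a complex polynomial baseline:

    m(nu) = sum_k  a_k e^{i phi_k} / (pi w_k / 2 + i pi (nu - nu_k))
            + sum_j c_j T_j(x)

with ``nu`` in Hz, ``w_k`` the full width at half maximum in Hz, and the
polynomial evaluated on the axis rescaled to [-1, 1].  Each Lorentzian is
normalized so the integral of its absorptive (real, phi=0) part equals the
area ``a_k``.

Real and imaginary spectral components are fitted jointly under an i.i.d.
Gaussian noise model; the number of peaks and the baseline degree are chosen
by the Bayesian information criterion BIC = k ln(n) - 2 ln L with
n = 2 x (number of spectral points).  Parameter uncertainties come from a
Hamiltonian Monte Carlo sampler (leapfrog integrator, dual-averaging step
size adaptation, diagonal mass matrix adapted during warmup) run over all
model parameters, and state populations are evaluated per posterior draw so
their reported s.d. includes all parameter correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .nmr_core import Spectrum1D, estimate_noise

__all__ = [
    "LorentzianPeak",
    "LineshapeModel",
    "FitResult",
    "StatePopulations",
    "FitFailureError",
    "SamplingQualityError",
    "PopulationUndefinedError",
    "model_spectrum",
    "fit_map",
    "select_model",
    "sample_posterior",
    "populations_from_fit",
]

# FWHM bounds in Hz for regular and broad components (log-uniform priors)
FWHM_BOUNDS = (1.0, 2000.0)
BROAD_FWHM_BOUNDS = (500.0, 20000.0)


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best residual norm."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class SamplingQualityError(RuntimeError):
    """Too many divergent HMC trajectories for the posterior to be trusted."""


class PopulationUndefinedError(ValueError):
    """Fewer than two non-broad peaks: populations are not defined.

    Callers should route such spectra to the detection-bound workflow
    (energetics.detection_bound)."""


@dataclass
class LorentzianPeak:
    position: float  # ppm
    fwhm: float  # Hz
    area: float  # a.u. (integral of the absorptive part)
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")


@dataclass
class LineshapeModel:
    peaks: list[LorentzianPeak] = field(default_factory=list)
    broad: LorentzianPeak | None = None
    baseline_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))

    def __post_init__(self) -> None:
        self.baseline_coeffs = np.asarray(self.baseline_coeffs, dtype=complex)
        if self.baseline_coeffs.size > 4:
            raise ValueError("baseline degree capped at 3")

    @property
    def degree(self) -> int:
        return self.baseline_coeffs.size - 1


@dataclass
class StatePopulations:
    p_f: float
    p_u: float
    sd_pf: float
    source: str = ""
    bounded: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_f <= 1 and 0 <= self.p_u <= 1):
            raise ValueError("populations must lie in [0, 1]")
        if abs(self.p_f + self.p_u - 1.0) > 1e-9:
            raise ValueError("p_f + p_u must equal 1")


@dataclass
class FitResult:
    map_model: LineshapeModel
    log_likelihood_max: float
    bic: float
    noise_sd: float
    n_points: int
    param_names: list[str]
    map_params: np.ndarray
    posterior: np.ndarray | None = None  # (chains, draws, k), natural units
    rhat: dict[str, float] | None = None
    n_divergent: int = 0
    warnings: list[str] = field(default_factory=list)
    # fitting context needed to resume sampling
    _spec: Spectrum1D | None = None

    @property
    def converged(self) -> bool:
        return np.all(np.isfinite(self.map_params))

    def posterior_mean_model(self) -> LineshapeModel:
        if self.posterior is None:
            return self.map_model
        flat = self.posterior.reshape(-1, self.posterior.shape[-1])
        return _unpack_model(flat.mean(axis=0), _layout_of(self.map_model))


# ---------------------------------------------------------------------------
# forward model


def _complex_lorentzian(nu_hz, position_hz, fwhm, area, phase):
    """Unit-area-normalized complex Lorentzian (absorptive integral = area)."""
    denom = np.pi * fwhm / 2.0 + 1j * np.pi * (nu_hz - position_hz)
    return area * np.exp(1j * phase) / denom


def model_spectrum(model: LineshapeModel, axis: np.ndarray, sfo: float) -> np.ndarray:
    """Evaluate a lineshape model on a ppm axis (returns complex values)."""
    axis = np.asarray(axis, dtype=float)
    nu = axis * sfo
    out = np.zeros(axis.size, dtype=complex)
    for pk in model.peaks:
        out += _complex_lorentzian(nu, pk.position * sfo, pk.fwhm, pk.area, pk.phase)
    if model.broad is not None:
        b = model.broad
        out += _complex_lorentzian(nu, b.position * sfo, b.fwhm, b.area, b.phase)
    if model.baseline_coeffs.size:
        x = _rescale_axis(axis)
        out += np.polynomial.polynomial.polyval(x, model.baseline_coeffs)
    return out


def _rescale_axis(axis: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(axis)), float(np.max(axis))
    return 2.0 * (axis - lo) / (hi - lo) - 1.0


# ---------------------------------------------------------------------------
# parameter packing

@dataclass(frozen=True)
class _Layout:
    n_peaks: int
    broad: bool
    degree: int  # -1 = no baseline

    @property
    def n_lorentzians(self) -> int:
        return self.n_peaks + (1 if self.broad else 0)

    @property
    def n_baseline(self) -> int:
        return 2 * (self.degree + 1) if self.degree >= 0 else 0

    @property
    def size(self) -> int:
        return 4 * self.n_lorentzians + self.n_baseline

    def names(self) -> list[str]:
        out = []
        for i in range(self.n_peaks):
            out += [f"peak{i}_position", f"peak{i}_fwhm", f"peak{i}_area", f"peak{i}_phase"]
        if self.broad:
            out += ["broad_position", "broad_fwhm", "broad_area", "broad_phase"]
        for j in range(self.degree + 1):
            out += [f"baseline{j}_re", f"baseline{j}_im"]
        return out


def _layout_of(model: LineshapeModel) -> _Layout:
    return _Layout(len(model.peaks), model.broad is not None, model.degree)


def _pack_model(model: LineshapeModel) -> np.ndarray:
    theta = []
    for pk in model.peaks:
        theta += [pk.position, pk.fwhm, pk.area, pk.phase]
    if model.broad is not None:
        b = model.broad
        theta += [b.position, b.fwhm, b.area, b.phase]
    for c in model.baseline_coeffs:
        theta += [c.real, c.imag]
    return np.array(theta)


def _unpack_model(theta: np.ndarray, layout: _Layout) -> LineshapeModel:
    peaks = []
    for i in range(layout.n_peaks):
        p, w, a, ph = theta[4 * i: 4 * i + 4]
        peaks.append(LorentzianPeak(p, max(w, 1e-12), max(a, 0.0), ph))
    broad = None
    off = 4 * layout.n_peaks
    if layout.broad:
        p, w, a, ph = theta[off: off + 4]
        broad = LorentzianPeak(p, max(w, 1e-12), max(a, 0.0), ph)
        off += 4
    coeffs = theta[off:].reshape(-1, 2)
    return LineshapeModel(peaks, broad, coeffs[:, 0] + 1j * coeffs[:, 1])


class _SpectralKernel:
    """Discrete Lorentzian kernel consistent with the data's transform.

    A sampled, truncated Lorentzian FID does not transform to the exact
    continuous Lorentzian; at high signal-to-noise the difference is
    resolvable.  The fit therefore evaluates each component as the same
    discrete operation the data underwent: synthesize the time-domain decay
    on the grid implied by the frequency axis, halve the first point, FFT,
    and scale by 2*dwell.  This makes fitting the spectrum exactly
    likelihood-equivalent to fitting the FID itself.
    """

    def __init__(self, axis: np.ndarray, sfo: float):
        self.axis = axis
        self.sfo = sfo
        n = axis.size
        dnu = abs(float(axis[1] - axis[0])) * sfo
        self.dwell = 1.0 / (n * dnu)
        # frequency-zero position of the fftshift layout on the reversed axis
        self.carrier_ppm = float(axis[::-1][n // 2])
        self.t = np.arange(n) * self.dwell

    def peak(self, pos_ppm, fwhm, area, phase):
        """Returns (S, S_t): the component spectrum and the transform of
        t * s(t) (shared by the position and width derivatives)."""
        nu = (pos_ppm - self.carrier_ppm) * self.sfo
        s = area * np.exp(1j * phase) * np.exp((2j * np.pi * nu - np.pi * fwhm) * self.t)
        st = self.t * s
        s = s.copy()
        s[0] *= 0.5  # st[0] is already 0
        scale = 2.0 * self.dwell
        S = (np.fft.fftshift(np.fft.fft(s)) * scale)[::-1]
        St = (np.fft.fftshift(np.fft.fft(st)) * scale)[::-1]
        return S, St


def _eval_theta(theta: np.ndarray, layout: _Layout, kernel: _SpectralKernel, xresc):
    """Forward model straight from the packed parameter vector."""
    out = np.zeros(kernel.axis.size, dtype=complex)
    for i in range(layout.n_lorentzians):
        p, w, a, ph = theta[4 * i: 4 * i + 4]
        out += kernel.peak(p, w, a, ph)[0]
    if layout.n_baseline:
        c = theta[4 * layout.n_lorentzians:].reshape(-1, 2)
        out += np.polynomial.polynomial.polyval(xresc, c[:, 0] + 1j * c[:, 1])
    return out


# ---------------------------------------------------------------------------
# MAP fitting


def _init_guess(spec: Spectrum1D, layout: _Layout, rng: np.random.Generator | None = None):
    """Heuristic starting point: pick the n strongest well-separated maxima
    of the magnitude spectrum."""
    mag = np.abs(spec.values)
    # light smoothing against noise spikes
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(mag, kernel, mode="same")
    order = np.argsort(smooth)[::-1]
    min_sep = max(3, spec.axis.size // 200)
    picked: list[int] = []
    for idx in order:
        if all(abs(idx - j) >= min_sep for j in picked):
            picked.append(int(idx))
        if len(picked) == layout.n_peaks:
            break
    picked.sort()
    dppm = abs(spec.dppm)
    total_area = float(np.trapezoid(np.abs(spec.values.real), dx=dppm * spec.sfo))
    theta = []
    phases = []
    for idx in picked:
        pos = float(spec.axis[idx])
        phase0 = float(np.angle(spec.values[idx]))  # absorptive peak phase
        theta += [pos, 60.0, total_area / max(layout.n_peaks, 1), phase0]
        phases.append(phase0)
    if layout.broad:
        center = float(np.mean(spec.axis[picked])) if picked else float(np.mean(spec.axis))
        theta += [center, 1500.0, 0.1 * total_area, 0.0]
        phases.append(0.0)
    theta += [0.0] * layout.n_baseline
    theta = np.array(theta)
    if rng is not None:
        jitter = rng.normal(scale=0.05, size=theta.size)
        theta = theta * (1 + jitter)
        theta[3::4][: layout.n_lorentzians] = phases  # keep estimated phases
    return theta


def _bounds(spec: Spectrum1D, layout: _Layout):
    lo_ppm, hi_ppm = float(np.min(spec.axis)), float(np.max(spec.axis))
    dppm = abs(spec.dppm)
    big = float(np.trapezoid(np.abs(spec.values), dx=dppm * spec.sfo)) * 10 + 1e-30
    lo, hi = [], []
    for i in range(layout.n_lorentzians):
        is_broad = layout.broad and i == layout.n_lorentzians - 1
        wb = BROAD_FWHM_BOUNDS if is_broad else FWHM_BOUNDS
        lo += [lo_ppm, wb[0], 0.0, -np.pi]
        hi += [hi_ppm, wb[1], big, np.pi]
    amax = float(np.max(np.abs(spec.values))) * 10 + 1e-30
    lo += [-amax] * layout.n_baseline
    hi += [amax] * layout.n_baseline
    return np.array(lo), np.array(hi)


def _loglike(chi_sq: float, n_resid: int, sigma: float) -> float:
    """Gaussian log likelihood from the noise-scaled residual sum of squares."""
    return -0.5 * chi_sq - n_resid * np.log(sigma * np.sqrt(2 * np.pi))


def fit_map(
    spec: Spectrum1D,
    n_peaks: int,
    degree: int = 0,
    broad: bool = False,
    init: LineshapeModel | np.ndarray | None = None,
    max_restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Maximum-a-posteriori lineshape fit by nonlinear least squares.

    Real and imaginary spectral components are fitted jointly.  The noise
    s.d. is taken from ``spec.noise_sd`` or estimated from the baseline.
    ``degree`` is the baseline polynomial degree (-1 for none, capped at 3).
    """
    if n_peaks not in (0, 1, 2, 3):
        raise ValueError("n_peaks must be in {0, 1, 2, 3}")
    if degree > 3:
        raise ValueError("baseline degree capped at 3")
    layout = _Layout(n_peaks, broad, degree)
    sigma = spec.noise_sd if spec.noise_sd is not None else estimate_noise(spec)
    sigma = max(sigma, 1e-30)
    xresc = _rescale_axis(spec.axis)
    kernel = _SpectralKernel(spec.axis, spec.sfo)
    data = np.concatenate([spec.values.real, spec.values.imag])

    def resid(theta):
        m = _eval_theta(theta, layout, kernel, xresc)
        return (np.concatenate([m.real, m.imag]) - data) / sigma

    def jac(theta):
        cols = []
        for i in range(layout.n_lorentzians):
            p, w, a, ph = theta[4 * i: 4 * i + 4]
            u_s, u_st = kernel.peak(p, w, 1.0, ph)
            cols.append(a * 2j * np.pi * kernel.sfo * u_st)  # d/d position(ppm)
            cols.append(-np.pi * a * u_st)  # d/d fwhm
            cols.append(u_s)  # d/d area
            cols.append(1j * a * u_s)  # d/d phase
        for j in range((layout.degree + 1) if layout.degree >= 0 else 0):
            cols.append(xresc**j + 0j)
            cols.append(1j * xresc**j)
        J = np.empty((data.size, layout.size))
        for k, c in enumerate(cols):
            J[: data.size // 2, k] = c.real / sigma
            J[data.size // 2:, k] = c.imag / sigma
        return J

    lo, hi = _bounds(spec, layout)
    rng = np.random.default_rng(seed)
    if init is not None:
        theta0s = [_pack_model(init) if isinstance(init, LineshapeModel) else np.asarray(init, float)]
    else:
        theta0s = [_init_guess(spec, layout)]
        theta0s += [_init_guess(spec, layout, rng) for _ in range(max_restarts)]

    best = None
    for theta0 in theta0s:
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(resid, theta0, jac=jac, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        # residuals at the noise floor: no need for more restarts
        if best.cost <= 0.65 * data.size:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError(
            "lineshape fit failed to converge",
            best_residual=None if best is None else float(np.sqrt(2 * best.cost)),
        )

    n_resid = data.size  # 2 x number of spectral points
    ll = _loglike(2.0 * best.cost, n_resid, sigma)
    k = layout.size
    bic = k * np.log(n_resid) - 2.0 * ll
    model = _unpack_model(best.x, layout)
    warns: list[str] = []
    positions = sorted(pk.position for pk in model.peaks)
    for a, b in zip(positions, positions[1:]):
        if abs(b - a) < 1e-3:
            warns.append(f"degenerate peak collision: positions {a:.5f} and {b:.5f} ppm")
    return FitResult(
        map_model=model,
        log_likelihood_max=float(ll),
        bic=float(bic),
        noise_sd=float(sigma),
        n_points=spec.axis.size,
        param_names=layout.names(),
        map_params=best.x.copy(),
        warnings=warns,
        _spec=spec,
    )


def select_model(
    spec: Spectrum1D,
    candidates: list[tuple[int, int, bool]],
    seed: int = 0,
) -> FitResult:
    """Fit every (n_peaks, degree, broad) candidate; return the minimal BIC.

    Ties (within 1e-9) break toward the model with fewer free parameters,
    independent of candidate order.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    fits: list[tuple[float, int, FitResult]] = []
    errors = []
    for n_peaks, degree, broad in candidates:
        try:
            fr = fit_map(spec, n_peaks, degree, broad, seed=seed)
        except (FitFailureError, ValueError) as exc:
            errors.append(f"({n_peaks},{degree},{broad}): {exc}")
            continue
        fits.append((fr.bic, len(fr.map_params), fr))
    if not fits:
        raise FitFailureError("all candidate fits failed: " + "; ".join(errors))
    fits.sort(key=lambda t: (round(t[0] / 1e-9) * 1e-9, t[1]))
    return fits[0][2]


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
#
# Parameters are mapped to an unconstrained space: bounded parameters
# (position, log-FWHM, phase) through a scaled logistic, areas through log.
# Priors: position uniform over the spectral window, FWHM log-uniform within
# its bounds, area half-normal scaled to the total spectral integral, phase
# uniform, baseline coefficients normal(0, 10 x noise sd).


def _sigmoid(z):
    from scipy.special import expit

    return expit(z)


class _Posterior:
    def __init__(self, spec: Spectrum1D, layout: _Layout, sigma: float):
        self.layout = layout
        self.axis = spec.axis
        self.sfo = spec.sfo
        self.sigma = sigma
        self.x = _rescale_axis(spec.axis)
        self.data = spec.values
        self.kernel = _SpectralKernel(spec.axis, spec.sfo)
        dppm = abs(float(spec.axis[1] - spec.axis[0]))
        self.area_scale = max(
            float(np.trapezoid(np.abs(spec.values.real), dx=dppm * spec.sfo)), 1e-30
        )
        self.base_sd = 10.0 * sigma
        self.pos_lo = float(np.min(spec.axis))
        self.pos_hi = float(np.max(spec.axis))
        # powers of the rescaled axis for the baseline
        self.xp = np.vstack([self.x**j for j in range(max(layout.degree + 1, 0))]) \
            if layout.degree >= 0 else np.zeros((0, self.x.size))

    # -- transforms ---------------------------------------------------------
    def theta_to_z(self, theta: np.ndarray) -> np.ndarray:
        z = np.empty_like(theta)
        L = self.layout
        eps = 1e-9

        def logit(u):
            u = np.clip(u, eps, 1 - eps)
            return np.log(u / (1 - u))

        for i in range(L.n_lorentzians):
            p, w, a, ph = theta[4 * i: 4 * i + 4]
            wb = BROAD_FWHM_BOUNDS if (L.broad and i == L.n_lorentzians - 1) else FWHM_BOUNDS
            z[4 * i] = logit((p - self.pos_lo) / (self.pos_hi - self.pos_lo))
            z[4 * i + 1] = logit((np.log(w) - np.log(wb[0])) / (np.log(wb[1]) - np.log(wb[0])))
            z[4 * i + 2] = np.log(max(a, 1e-12 * self.area_scale))
            z[4 * i + 3] = logit((ph + np.pi) / (2 * np.pi))
        z[4 * L.n_lorentzians:] = theta[4 * L.n_lorentzians:]
        return z

    def z_to_theta(self, z: np.ndarray) -> np.ndarray:
        theta = np.empty_like(z)
        L = self.layout
        for i in range(L.n_lorentzians):
            wb = BROAD_FWHM_BOUNDS if (L.broad and i == L.n_lorentzians - 1) else FWHM_BOUNDS
            s = _sigmoid(z[4 * i: 4 * i + 4])
            theta[4 * i] = self.pos_lo + (self.pos_hi - self.pos_lo) * s[0]
            theta[4 * i + 1] = np.exp(np.log(wb[0]) + (np.log(wb[1]) - np.log(wb[0])) * s[1])
            theta[4 * i + 2] = np.exp(np.clip(z[4 * i + 2], -700.0, 700.0))
            theta[4 * i + 3] = -np.pi + 2 * np.pi * s[3]
        theta[4 * L.n_lorentzians:] = z[4 * L.n_lorentzians:]
        return theta

    # -- log posterior and gradient in z ------------------------------------
    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        # exploratory warmup steps can overflow; non-finite logp is treated
        # as a rejected/divergent trajectory by the sampler
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(z)

    def _logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        L = self.layout
        theta = self.z_to_theta(z)
        nL = L.n_lorentzians
        # forward model and per-Lorentzian caches (discrete kernel)
        m = np.zeros(self.axis.size, dtype=complex)
        units = []
        for i in range(nL):
            p, w, a, ph = theta[4 * i: 4 * i + 4]
            u_s, u_st = self.kernel.peak(p, w, 1.0, ph)
            units.append((u_s, u_st))
            m += a * u_s
        if L.n_baseline:
            c = theta[4 * nL:].reshape(-1, 2)
            m += (c[:, 0] + 1j * c[:, 1]) @ self.xp
        e = self.data - m
        s2 = self.sigma**2
        loglike = -0.5 * float(np.sum(e.real**2 + e.imag**2)) / s2

        # d loglike / d theta = sum Re(conj(e) dm/dtheta) / sigma^2
        g_theta = np.empty_like(theta)
        ec = np.conj(e)
        for i in range(nL):
            p, w, a, ph = theta[4 * i: 4 * i + 4]
            u_s, u_st = units[i]
            dpos = a * 2j * np.pi * self.sfo * u_st  # per ppm
            dw = -np.pi * a * u_st
            da = u_s
            dph = 1j * a * u_s
            g_theta[4 * i] = np.sum((ec * dpos).real) / s2
            g_theta[4 * i + 1] = np.sum((ec * dw).real) / s2
            g_theta[4 * i + 2] = np.sum((ec * da).real) / s2
            g_theta[4 * i + 3] = np.sum((ec * dph).real) / s2
        if L.n_baseline:
            # d/dRe(c_j) = sum x^j Re(e) / s2;  d/dIm(c_j) = sum x^j Im(e) / s2
            g_theta[4 * nL::2] = (self.xp @ e.real) / s2
            g_theta[4 * nL + 1::2] = (self.xp @ e.imag) / s2

        # priors and change of variables
        logprior = 0.0
        g_z = np.empty_like(z)
        for i in range(nL):
            wb = BROAD_FWHM_BOUNDS if (L.broad and i == L.n_lorentzians - 1) else FWHM_BOUNDS
            for j, (span, flat) in enumerate(
                [
                    (self.pos_hi - self.pos_lo, True),  # position, uniform
                    (np.log(wb[1]) - np.log(wb[0]), True),  # log-fwhm, log-uniform
                    (None, False),  # area, half-normal via log transform
                    (2 * np.pi, True),  # phase, uniform
                ]
            ):
                idx = 4 * i + j
                if j == 2:
                    a = theta[idx]
                    # half-normal prior on a, Jacobian a from the log transform
                    logprior += -0.5 * (a / self.area_scale) ** 2 + np.log(a)
                    # d/dz of (loglike(theta(z)) + logprior): dtheta/dz = a
                    g_z[idx] = (g_theta[idx] - a / self.area_scale**2) * a + 1.0
                elif j == 1:
                    # theta = exp(loglo + span*sigmoid(z)); dtheta/dz = theta*span*s(1-s)
                    s = _sigmoid(z[idx])
                    dtheta_dz = theta[idx] * span * s * (1 - s)
                    logprior += np.log(max(s * (1 - s), 1e-300))  # log-uniform x Jacobian
                    g_z[idx] = g_theta[idx] * dtheta_dz + (1 - 2 * s)
                else:
                    s = _sigmoid(z[idx])
                    dtheta_dz = span * s * (1 - s)
                    logprior += np.log(max(dtheta_dz, 1e-300))
                    g_z[idx] = g_theta[idx] * dtheta_dz + (1 - 2 * s)
        for idx in range(4 * nL, theta.size):
            c = theta[idx]
            logprior += -0.5 * (c / self.base_sd) ** 2
            g_z[idx] = g_theta[idx] - c / self.base_sd**2
        return loglike + logprior, g_z


def _map_inverse_mass(post: _Posterior, z_map: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Diagonal inverse mass from the curvature of -log posterior at the MAP.

    Whitens the wildly different parameter scales so a single step size
    works for every coordinate."""
    dim = z_map.size
    inv_mass = np.ones(dim)
    _, g0 = post.logp_grad(z_map)
    for i in range(dim):
        zp = z_map.copy()
        zp[i] += h
        _, gp = post.logp_grad(zp)
        hess_ii = -(gp[i] - g0[i]) / h
        if np.isfinite(hess_ii) and hess_ii > 1e-12:
            inv_mass[i] = 1.0 / hess_ii
    return inv_mass


def _hmc_chain(post: _Posterior, z0, n_warmup, n_draws, rng, inv_mass=None,
               target_accept=0.8, n_leapfrog=20):
    dim = z0.size
    z = z0.copy()
    logp, grad = post.logp_grad(z)

    # dual averaging (step size), diagonal mass refreshed midway through warmup
    eps = 0.5
    mu = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    inv_mass = np.ones(dim) if inv_mass is None else inv_mass.copy()
    warm_hist = []
    draws = np.empty((n_draws, dim))
    n_div = 0
    mass_update_at = n_warmup // 2

    total = n_warmup + n_draws
    for it in range(total):
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * float(np.sum(inv_mass * r**2))
        zn, rn, gn, lpn = z.copy(), r.copy(), grad.copy(), logp
        steps = max(1, int(rng.integers(n_leapfrog // 2, n_leapfrog + n_leapfrog // 2 + 1)))
        diverged = False
        for _ in range(steps):
            rn = rn + 0.5 * eps * gn
            zn = zn + eps * inv_mass * rn
            lpn, gn = post.logp_grad(zn)
            rn = rn + 0.5 * eps * gn
            if not np.isfinite(lpn):
                diverged = True
                break
        if diverged:
            accept_prob = 0.0
        else:
            with np.errstate(over="ignore"):
                h1 = lpn - 0.5 * float(np.sum(inv_mass * rn**2))
            dh = h1 - h0
            if not np.isfinite(dh):
                dh = -np.inf
            if dh < -1000:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = min(1.0, float(np.exp(min(dh, 0.0))))
        if not diverged and rng.uniform() < accept_prob:
            z, logp, grad = zn, lpn, gn

        if it < n_warmup:
            # Nesterov dual averaging on log step size
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            warm_hist.append(z.copy())
            if it == mass_update_at and len(warm_hist) > 20:
                hist = np.array(warm_hist[len(warm_hist) // 2:])
                var = hist.var(axis=0)
                # refresh only if the chain actually moved in every direction
                if np.all(var > 0):
                    inv_mass = var
                    mu = np.log(10 * eps)
                    h_bar, log_eps_bar = 0.0, 0.0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = z
            if diverged:
                n_div += 1
    return draws, n_div


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for draws (chains, n)."""
    n_chains, n = x.shape
    half = n // 2
    if half < 2:
        return np.nan
    halves = np.vstack([x[:, :half], x[:, half: 2 * half]])
    m, nn = halves.shape
    means = halves.mean(axis=1)
    b = nn * means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))


def sample_posterior(
    spec: Spectrum1D | None,
    model_init: FitResult,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    max_divergence_frac: float = 0.05,
) -> FitResult:
    """HMC posterior sampling around a converged MAP fit.

    Returns a new FitResult carrying draws (chains x draws x params, natural
    units), split-Rhat per parameter, and a warning flag if any Rhat > 1.01.
    Raises SamplingQualityError when more than ``max_divergence_frac`` of the
    post-warmup trajectories diverge.
    """
    spec = spec if spec is not None else model_init._spec
    if spec is None:
        raise ValueError("spectrum required for sampling")
    if not model_init.converged:
        raise FitFailureError("initial MAP fit did not converge")
    layout = _layout_of(model_init.map_model)
    post = _Posterior(spec, layout, model_init.noise_sd)
    z_map = post.theta_to_z(model_init.map_params)
    rng = np.random.default_rng(seed)
    inv_mass = _map_inverse_mass(post, z_map)
    chains = np.empty((n_chains, n_draws, layout.size))
    n_div = 0
    for c in range(n_chains):
        z0 = z_map + 0.01 * np.sqrt(inv_mass) * rng.standard_normal(layout.size)
        draws_z, div = _hmc_chain(post, z0, n_warmup, n_draws, rng, inv_mass=inv_mass)
        n_div += div
        for d in range(n_draws):
            chains[c, d] = post.z_to_theta(draws_z[d])
    if n_div > max_divergence_frac * n_chains * n_draws:
        raise SamplingQualityError(
            f"{n_div}/{n_chains * n_draws} divergent trajectories"
        )
    names = layout.names()
    rhat = {nm: _split_rhat(chains[:, :, i]) for i, nm in enumerate(names)}
    warns = list(model_init.warnings)
    bad = [nm for nm, r in rhat.items() if np.isfinite(r) and r > 1.01]
    if bad:
        warns.append("rhat > 1.01 for: " + ", ".join(bad))
    return FitResult(
        map_model=model_init.map_model,
        log_likelihood_max=model_init.log_likelihood_max,
        bic=model_init.bic,
        noise_sd=model_init.noise_sd,
        n_points=model_init.n_points,
        param_names=names,
        map_params=model_init.map_params,
        posterior=chains,
        rhat=rhat,
        n_divergent=n_div,
        warnings=warns,
        _spec=spec,
    )


# ---------------------------------------------------------------------------
# populations


def populations_from_fit(
    fit: FitResult,
    ref_shifts: tuple[float, float] | None = None,
) -> StatePopulations:
    """Folded/unfolded populations from peak areas.

    ``ref_shifts`` is (delta_U, delta_F) in ppm; peaks are labeled by
    proximity to these references.  Without references the downfield
    (higher-ppm) peak is taken as F.  The broad component and the baseline
    never enter the population sums.  Posterior draws, when present, yield
    the point estimate (posterior mean of p_f) and its s.d.
    """
    model = fit.map_model
    if len(model.peaks) < 2:
        raise PopulationUndefinedError(
            f"{len(model.peaks)} non-broad peak(s); populations undefined — "
            "use the detection-bound workflow"
        )
    positions = np.array([pk.position for pk in model.peaks])
    if ref_shifts is not None:
        d_u, d_f = ref_shifts
        i_f = int(np.argmin(np.abs(positions - d_f)))
        i_u = int(np.argmin(np.abs(positions - d_u)))
        if i_f == i_u:  # tie: downfield = F
            i_f = int(np.argmax(positions))
            i_u = int(np.argmin(positions))
    else:
        i_f = int(np.argmax(positions))
        i_u = int(np.argmin(positions))

    if fit.posterior is not None:
        names = fit.param_names
        a_f = fit.posterior[:, :, names.index(f"peak{i_f}_area")].ravel()
        a_u = fit.posterior[:, :, names.index(f"peak{i_u}_area")].ravel()
        pf_draws = a_f / (a_f + a_u)
        pf = float(pf_draws.mean())
        sd = float(pf_draws.std(ddof=1))
    else:
        a_f, a_u = model.peaks[i_f].area, model.peaks[i_u].area
        pf = a_f / (a_f + a_u)
        sd = 0.0
    return StatePopulations(p_f=pf, p_u=1.0 - pf, sd_pf=sd, source="lineshape_fit")
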