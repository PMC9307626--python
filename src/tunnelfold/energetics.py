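"""Folding and binding free energies from state populations.

Two-state thermodynamics: for folded/unfolded populations P_F, P_U = 1-P_F
in equilibrium, the folding free energy is

    dG_F-U = -R T ln(P_F / P_U)

and differences between ribosome variants are dd G = dG(variant) - dG(WT).
When no folded signal is detected, a spectral signal-to-noise argument caps
the undetected folded population (default 1 %) and dG becomes a bound.

Binding of the unfolded nascent chain to the ribosome surface is in fast
exchange, so an observed chemical shift is the population-weighted average
of bound and unbound reference shifts; populations convert to dG_binding by
the same two-state expression.  All energies carry their temperature so
quantities from different conditions cannot be silently mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lineshape_fit import LorentzianPeak, StatePopulations

__all__ = [
    "ThermoConfig",
    "FoldingEnergetics",
    "BindingObservation",
    "BindingEnergetics",
    "InfiniteEnergyError",
    "TemperatureMismatchError",
    "delta_g_folding",
    "ddg",
    "detection_bound",
    "propagate_error",
    "length_attenuation",
    "csp_population",
    "ddg_binding",
    "energy_correlation",
    "frequency_separation",
]

#: gyromagnetic ratio relative to 1H
GYROMAGNETIC_RATIOS = {"1H": 1.0, "19F": 0.9407, "13C": 0.2515, "15N": 0.1013}


class InfiniteEnergyError(ValueError):
    """Population at 0 or 1: the free energy diverges.

    Route such cases through detection_bound instead."""


class TemperatureMismatchError(ValueError):
    """Energies at different temperatures cannot be combined."""


@dataclass(frozen=True)
class ThermoConfig:
    """Gas constant in kcal/(mol K) and temperature in K (19F data: 25 C)."""

    gas_constant: float = 1.9872e-3
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class FoldingEnergetics:
    dg: float  # kcal/mol
    sd: float  # kcal/mol
    variant: str = ""
    linker_l: int | None = None
    temperature: float = 298.15
    bounded: bool = False  # True: dg is a ">=" bound from a detection limit

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class BindingObservation:
    delta_obs: float  # ppm
    delta_unbound: float  # ppm, isolated-protein reference
    delta_bound: float  # ppm, fully-bound reference
    sd_obs: float = 0.0
    variant: str = ""

    def __post_init__(self) -> None:
        if self.delta_bound == self.delta_unbound:
            raise ValueError("bound and unbound reference shifts must differ")


@dataclass
class BindingEnergetics:
    p_b: float
    p_ub: float
    dg_bind: float  # kcal/mol
    sd: float
    variant: str = ""
    temperature: float = 298.15
    sd_pb: float = 0.0


def delta_g_folding(
    pop: StatePopulations,
    cfg: ThermoConfig = ThermoConfig(),
    variant: str = "",
    linker_l: int | None = None,
    mode: str = "delta",
    n_mc: int = 10000,
    seed: int = 0,
) -> FoldingEnergetics:
    """dG_F-U = -RT ln(P_F/P_U) with propagated uncertainty."""
    if not 0.0 < pop.p_f < 1.0:
        raise InfiniteEnergyError(
            f"p_f = {pop.p_f}: free energy diverges; use detection_bound"
        )
    dg = -cfg.rt * np.log(pop.p_f / pop.p_u)
    sd = propagate_error(pop, cfg, mode=mode, n_mc=n_mc, seed=seed)
    return FoldingEnergetics(
        dg=float(dg), sd=float(sd), variant=variant, linker_l=linker_l,
        temperature=cfg.temperature, bounded=pop.bounded,
    )


def ddg(variant: FoldingEnergetics, wt: FoldingEnergetics) -> FoldingEnergetics:
    """ddG_F-U = dG(variant) - dG(WT) at matched linker length and T."""
    if variant.linker_l != wt.linker_l:
        raise ValueError(
            f"linker lengths differ ({variant.linker_l} vs {wt.linker_l})"
        )
    if abs(variant.temperature - wt.temperature) > 1e-9:
        raise TemperatureMismatchError(
            f"temperatures differ ({variant.temperature} vs {wt.temperature} K)"
        )
    return FoldingEnergetics(
        dg=variant.dg - wt.dg,
        sd=float(np.hypot(variant.sd, wt.sd)),
        variant=f"{variant.variant}-{wt.variant}",
        linker_l=variant.linker_l,
        temperature=variant.temperature,
        bounded=variant.bounded or wt.bounded,
    )


def detection_bound(
    spec_noise: float,
    u_peak: LorentzianPeak,
    k_sigma: float = 3.0,
    cap: float = 0.01,
) -> StatePopulations:
    """Maximum undetected folded population from the spectral noise floor.

    The largest F peak that could hide in the noise has height
    ``k_sigma x noise`` and the U-state linewidth; a Lorentzian of height h
    and FWHM w has area h*pi*w/2.  The bound is min(cap, that area over the
    total), flagged so downstream energies are reported as inequalities.
    """
    if u_peak.area <= 0:
        raise ValueError("U peak area must be positive")
    if spec_noise <= 0:
        warnings.warn("zero spectral noise: detection bound falls back to cap")
        pf_max = cap
    else:
        hidden_area = k_sigma * spec_noise * np.pi * u_peak.fwhm / 2.0
        pf_max = min(cap, hidden_area / (hidden_area + u_peak.area))
    return StatePopulations(
        p_f=float(pf_max), p_u=float(1 - pf_max), sd_pf=0.0,
        source="detection_bound", bounded=True,
    )


def propagate_error(
    pop: StatePopulations,
    cfg: ThermoConfig = ThermoConfig(),
    mode: str = "delta",
    n_mc: int = 10000,
    seed: int = 0,
) -> float:
    """Uncertainty of dG from the uncertainty of P_F.

    ``delta``: first-order propagation, sd = RT * sd_pf / (p_f (1 - p_f)).
    ``monte_carlo``: sd of dG over draws p ~ Normal(p_f, sd_pf) truncated
    to (0, 1).  The two agree to ~10 % for sd_pf <= 0.1 and moderate p_f.
    """
    if pop.sd_pf == 0:
        return 0.0
    if mode == "delta":
        return float(cfg.rt * pop.sd_pf / (pop.p_f * (1.0 - pop.p_f)))
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        draws = np.empty(0)
        while draws.size < n_mc:
            x = rng.normal(pop.p_f, pop.sd_pf, size=2 * n_mc)
            draws = np.concatenate([draws, x[(x > 0) & (x < 1)]])
        draws = draws[:n_mc]
        dg = -cfg.rt * np.log(draws / (1 - draws))
        return float(dg.std(ddof=1))
    raise ValueError(f"unknown propagation mode {mode!r}")


def length_attenuation(
    energies_l31: list[FoldingEnergetics],
    energies_l34: list[FoldingEnergetics],
    include_bounded: bool = True,
) -> tuple[float, float | None, np.ndarray]:
    """Mean percentage decrease of |ddG| from the shorter to the longer linker.

    Inputs are ddG values (one per variant, paired by order) at the two
    linker lengths.  Per variant the decrease is
    100 x (|ddG_L31| - |ddG_L34|) / |ddG_L31|; returns (mean, sample sd,
    per-variant values).  The sd is None for a single variant.  Bound-derived
    entries participate by default (flag to exclude).
    """
    if len(energies_l31) != len(energies_l34) or not energies_l31:
        raise ValueError("need one ddG per variant at both lengths")
    vals = []
    for e31, e34 in zip(energies_l31, energies_l34):
        if not include_bounded and (e31.bounded or e34.bounded):
            continue
        vals.append(100.0 * (abs(e31.dg) - abs(e34.dg)) / abs(e31.dg))
    if not vals:
        raise ValueError("no variant pairs left after filtering")
    arr = np.array(vals)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return float(arr.mean()), sd, arr


def csp_population(obs: BindingObservation, clamp_tol: float = 0.05) -> BindingEnergetics:
    """Bound/unbound populations from a fast-exchange chemical shift.

    p_b = (delta_obs - delta_ub) / (delta_b - delta_ub); shifts slightly
    outside the reference interval (within ``clamp_tol`` of it, as a
    fraction of the interval) are clamped with a warning.  The s.d. of p_b
    follows from sd_obs by the delta method (the mapping is linear).
    """
    span = obs.delta_bound - obs.delta_unbound
    p_b = (obs.delta_obs - obs.delta_unbound) / span
    if not 0.0 <= p_b <= 1.0:
        if -clamp_tol <= p_b <= 1.0 + clamp_tol:
            warnings.warn(
                f"observed shift outside references (p_b={p_b:.3f}); clamped"
            )
            p_b = min(max(p_b, 0.0), 1.0)
        else:
            raise ValueError(
                f"observed shift far outside the reference interval (p_b={p_b:.3f})"
            )
    sd_pb = abs(obs.sd_obs / span)
    return BindingEnergetics(
        p_b=float(p_b), p_ub=float(1 - p_b), dg_bind=np.nan, sd=np.nan,
        variant=obs.variant, sd_pb=float(sd_pb),
    )


def _dg_binding(be: BindingEnergetics, cfg: ThermoConfig) -> tuple[float, float]:
    if not 0.0 < be.p_b < 1.0:
        raise InfiniteEnergyError(f"p_b = {be.p_b}: binding free energy diverges")
    dg = -cfg.rt * np.log(be.p_b / be.p_ub)
    sd = cfg.rt * be.sd_pb / (be.p_b * be.p_ub)
    return float(dg), float(sd)


def ddg_binding(
    variant: BindingEnergetics,
    wt: BindingEnergetics,
    cfg: ThermoConfig = ThermoConfig(),
) -> BindingEnergetics:
    """ddG_binding = dG_bind(variant) - dG_bind(WT).

    dG_bind = -RT ln(p_b / p_ub), so weaker binding (smaller p_b than WT)
    gives a positive ddG_binding; errors propagate in quadrature from the
    population s.d. of each term.
    """
    dg_v, sd_v = _dg_binding(variant, cfg)
    dg_w, sd_w = _dg_binding(wt, cfg)
    return BindingEnergetics(
        p_b=variant.p_b, p_ub=variant.p_ub,
        dg_bind=dg_v - dg_w, sd=float(np.hypot(sd_v, sd_w)),
        variant=f"{variant.variant}-{wt.variant}", temperature=cfg.temperature,
        sd_pb=variant.sd_pb,
    )


def energy_correlation(
    ddg_fold: list[float] | np.ndarray,
    ddg_bind: list[float] | np.ndarray,
) -> tuple[float, float]:
    """Ordinary least squares of ddG_fold on ddG_bind: returns (R^2, slope).

    Detection-limit bounds must be excluded by the caller (they are censored
    values, not measurements)."""
    x = np.asarray(ddg_bind, dtype=float)
    y = np.asarray(ddg_fold, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(r2), float(slope)


def frequency_separation(
    delta_ppm: float,
    sfo_1h: float,
    nucleus: str = "19F",
) -> float:
    """A chemical-shift difference as a frequency separation in s^-1.

    ``sfo_1h`` is the spectrometer 1H frequency in MHz; the nucleus'
    gyromagnetic ratio relative to 1H rescales it.  0.8 ppm of 19F on a
    500.13 MHz instrument is ~376 s^-1, the scale against which exchange
    rates are judged slow.
    """
    try:
        ratio = GYROMAGNETIC_RATIOS[nucleus]
    except KeyError:
        raise KeyError(
            f"no gyromagnetic ratio configured for nucleus {nucleus!r}"
        ) from None
    return float(delta_ppm * sfo_1h * ratio)
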