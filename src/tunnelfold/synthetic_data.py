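"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of experimental observable so that the
downstream estimators can be validated by parameter recovery:

* two-resonance 19F FIDs in slow exchange (0.8 ppm separation, 60-150 Hz
  linewidths, optional very broad background component, circular complex
  Gaussian noise),
* fast-exchange chemical-shift-perturbation series,
* sigmoidal folded/unfolded intensity-vs-linker-length peak-volume tables
  with shared multiplicative concentration noise,
* toy nascent-chain + tunnel-wall coordinate ensembles with per-residue
  controllable mobility (the wall is a frozen cylinder of pseudo-atoms; only
  the statistics operators are under test, not ribosome geometry).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import BindingObservation
from .nmr_core import AcquisitionParams, Fid
from .profiles import F_MARKERS, U_MARKERS, PeakVolumeTable
from .ensemble_analysis import StructureEnsemble

__all__ = [
    "GroundTruthSpectrum",
    "EnsembleSpec",
    "GenerationFailureError",
    "simulate_fid",
    "simulate_csp_series",
    "simulate_intensity_profile",
    "simulate_ensemble",
    "DELTA_U_PPM",
    "DELTA_F_PPM",
]

#: default 19F reference shifts: folded peak 0.8 ppm downfield of unfolded
DELTA_U_PPM = -60.4
DELTA_F_PPM = -59.6


class GenerationFailureError(RuntimeError):
    """Chain placement failed after bounded retries."""


@dataclass
class GroundTruthSpectrum:
    """Ground truth for a 1D 19F spectrum.

    ``peaks`` are (position ppm, FWHM Hz, area a.u., phase rad); the
    downfield-most peak is the folded state.  ``broad`` is an optional
    (position ppm, FWHM Hz >= 500, area) background component, excluded
    from the folded fraction.  ``noise_sd`` is per complex time point.
    """

    peaks: list[tuple[float, float, float, float]]
    broad: tuple[float, float, float] | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pos, fwhm, area, _ in self.peaks:
            if fwhm <= 0:
                raise ValueError("linewidths must be positive")
            if area < 0:
                raise ValueError("areas must be >= 0")
        if self.broad is not None and self.broad[1] < 500:
            raise ValueError("broad component FWHM must be >= 500 Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def folded_fraction(self) -> float | None:
        """area(F)/(area(F)+area(U)) with F the downfield peak; None unless
        the spectrum has exactly two (non-broad) peaks."""
        if len(self.peaks) != 2:
            return None
        by_pos = sorted(self.peaks, key=lambda p: p[0])
        a_u, a_f = by_pos[0][2], by_pos[1][2]
        if a_u + a_f == 0:
            return None
        return a_f / (a_f + a_u)

    @classmethod
    def two_state(
        cls,
        folded_fraction: float,
        total_area: float = 1.0,
        delta_u: float = DELTA_U_PPM,
        delta_f: float = DELTA_F_PPM,
        fwhm_u: float = 80.0,
        fwhm_f: float = 110.0,
        phase: float = 0.0,
        broad: tuple[float, float, float] | None = None,
        snr: float | None = 20.0,
        noise_sd: float | None = None,
        seed: int = 0,
    ) -> "GroundTruthSpectrum":
        """Two-state truth at a given folded fraction.

        Defaults mirror the experimental regime: 0.8 ppm U/F separation,
        linewidths within 60-150 Hz, and noise set for SNR ~ 20 on the
        dominant peak unless ``noise_sd`` is given explicitly.
        """
        if not 0.0 <= folded_fraction <= 1.0:
            raise ValueError("folded_fraction must lie in [0, 1]")
        a_f = folded_fraction * total_area
        a_u = total_area - a_f
        peaks = [(delta_u, fwhm_u, a_u, phase), (delta_f, fwhm_f, a_f, phase)]
        if noise_sd is None:
            if snr is None:
                noise_sd = 0.0
            else:
                # absorptive peak height of a Lorentzian of area a: 2a/(pi w)
                heights = [2 * a / (np.pi * w) for _, w, a, _ in peaks if a > 0]
                # time-domain noise maps to the frequency domain through the
                # transform scaling 2*dwell*sqrt(n_fft); use defaults
                acq = AcquisitionParams()
                freq_noise = max(heights) / snr
                noise_sd = freq_noise / (2 * acq.dwell * np.sqrt(2 * acq.n_points))
        return cls(peaks=peaks, broad=broad, noise_sd=noise_sd, seed=seed)


def simulate_fid(truth: GroundTruthSpectrum, acq: AcquisitionParams | None = None) -> Fid:
    """Sum of exponentially decaying complex sinusoids plus circular noise.

    s(t) = sum_k a_k exp(i (2 pi nu_k t + phi_k)) exp(-pi FWHM_k t) + noise,
    with nu_k the Hz offset of the peak from the carrier.  The t=0 value of
    each noiseless component equals its area.
    """
    acq = acq or AcquisitionParams()
    t = np.arange(acq.n_points) * acq.dwell
    s = np.zeros(acq.n_points, dtype=complex)
    components = list(truth.peaks)
    if truth.broad is not None:
        pos, fwhm, area = truth.broad
        components.append((pos, fwhm, area, 0.0))
    for pos, fwhm, area, phase in components:
        nu = (pos - acq.carrier) * acq.sfo
        s += area * np.exp(1j * (2 * np.pi * nu * t + phase)) * np.exp(-np.pi * fwhm * t)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        s += truth.noise_sd * (
            rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
        )
    return Fid(points=s, dwell=acq.dwell, sfo=acq.sfo, carrier=acq.carrier, nucleus="19F")


def simulate_csp_series(
    p_bound_list: list[float],
    delta_bound: float,
    delta_unbound: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BindingObservation]:
    """Fast-exchange observed shifts: delta_obs = p*delta_b + (1-p)*delta_ub."""
    if delta_bound == delta_unbound:
        raise ValueError("bound and unbound shifts must differ")
    for p in p_bound_list:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"bound population {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for p in p_bound_list:
        obs = p * delta_bound + (1 - p) * delta_unbound
        if noise_sd > 0:
            obs += rng.normal(scale=noise_sd)
        out.append(
            BindingObservation(
                delta_obs=float(obs),
                delta_unbound=delta_unbound,
                delta_bound=delta_bound,
                sd_obs=noise_sd,
            )
        )
    return out


def _logistic(length: np.ndarray, onset: float, steepness: float) -> np.ndarray:
    if np.isinf(steepness):
        return np.where(length > onset, 1.0, np.where(length < onset, 0.0, 0.5))
    z = np.clip(steepness * (length - onset), -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_intensity_profile(
    onset_l: float,
    steepness: float,
    lengths: list[int],
    conc_noise_frac: float = 0.0,
    n_scans: int = 128,
    volume_noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[PeakVolumeTable, PeakVolumeTable]:
    """Complementary U/F peak-volume tables following a logistic in L.

    The folded channel's underlying relative intensity is
    1/(1+exp(-steepness (L - onset))) and the unfolded channel its
    complement.  Multiplicative concentration noise (fraction
    ``conc_noise_frac``) is drawn once per length and applied identically
    to both channels, as a shared sample property would be.
    """
    if not lengths:
        raise ValueError("lengths must be non-empty")
    lengths_arr = np.asarray(lengths, dtype=float)
    if not np.all(np.diff(lengths_arr) > 0):
        raise ValueError("lengths must be strictly increasing")
    rng = np.random.default_rng(seed)
    f_true = _logistic(lengths_arr, onset_l, steepness)
    conc = np.ones(lengths_arr.size)
    if conc_noise_frac > 0:
        conc *= 1.0 + conc_noise_frac * rng.standard_normal(lengths_arr.size)
        conc = np.clip(conc, 0.05, None)

    def build(markers: tuple[str, ...], channel_vals: np.ndarray, channel: str) -> PeakVolumeTable:
        rows = []
        base = {m: 100.0 * (1 + 0.2 * i) for i, m in enumerate(markers)}
        for j, l_val in enumerate(lengths_arr):
            for m in markers:
                vol = base[m] * channel_vals[j] * n_scans * conc[j]
                if volume_noise_frac > 0:
                    vol *= 1.0 + volume_noise_frac * rng.standard_normal()
                    vol = max(vol, 0.0)
                rows.append(
                    {
                        "residue": m,
                        "linker_l": int(l_val),
                        "volume": vol,
                        "volume_sd": volume_noise_frac * max(vol, 1e-12),
                        "n_scans": n_scans,
                        "concentration": conc[j],
                        "concentration_sd": conc_noise_frac * conc[j],
                    }
                )
        return PeakVolumeTable(pd.DataFrame(rows), channel=channel)

    return build(U_MARKERS, 1.0 - f_true, "U"), build(F_MARKERS, f_true, "F")


# ---------------------------------------------------------------------------
# toy coordinate ensembles


@dataclass
class EnsembleSpec:
    """Toy nascent chain threaded through a frozen cylindrical tunnel wall.

    ``mobility_profile`` gives one value in [0, 1] per residue: 0 pins the
    residue (identical across frames), 1 makes its carbonyl orientation
    isotropic and its position maximally dispersed.
    """

    n_frames: int = 100
    nc_length: int = 20
    mobility_profile: np.ndarray | float = 0.3
    tunnel_radius: float = 12.0
    residue_spacing: float = 3.0
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.nc_length < 2:
            raise ValueError("nc_length must be >= 2")
        prof = np.broadcast_to(
            np.asarray(self.mobility_profile, dtype=float), (self.nc_length,)
        ).copy()
        if np.any(prof < 0) or np.any(prof > 1):
            raise ValueError("mobility values must lie in [0, 1]")
        self.mobility_profile = prof


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _wall_atoms(spec: EnsembleSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Cylinder of pseudo-atoms; rings assigned alternately to two wall
    components so contact statistics have multiple partners to resolve."""
    length = spec.nc_length * spec.residue_spacing + 10.0
    ring_z = np.arange(0.0, length, 3.0)
    n_per_ring = 16
    angles = np.linspace(0, 2 * np.pi, n_per_ring, endpoint=False)
    rows, xyz = [], []
    comp_names = ["ribosome-protein:uL23", "ribosome-protein:uL24"]
    for i, z in enumerate(ring_z):
        comp = comp_names[i % 2]
        for j, a in enumerate(angles):
            rows.append(
                {
                    "name": "W",
                    "element": "C",
                    "residue_id": 1000 + i * n_per_ring + j,
                    "residue_name": "WAL",
                    "role": comp,
                }
            )
            xyz.append(
                [spec.tunnel_radius * np.cos(a), spec.tunnel_radius * np.sin(a), z]
            )
    return pd.DataFrame(rows), np.array(xyz)


def simulate_ensemble(spec: EnsembleSpec) -> StructureEnsemble:
    """Self-avoiding jointed chain inside a frozen cylindrical wall.

    Each residue carries a backbone carbonyl carbon C and oxygen O; the unit
    C->O vector of residue i is drawn around a fixed mean direction with
    dispersion set by ``mobility_profile[i]`` (0 rigid, 1 isotropic), and
    the backbone position is jittered with the same amplitude.  Raises
    GenerationFailureError if a clash-free chain cannot be placed within
    ``max_retries`` attempts for some frame.
    """
    rng = np.random.default_rng(spec.seed)
    wall_atoms, wall_xyz = _wall_atoms(spec)
    n = spec.nc_length
    prof = spec.mobility_profile
    # base conformation: straight along the cylinder axis
    base_c = np.column_stack(
        [np.zeros(n), np.zeros(n), 2.0 + spec.residue_spacing * np.arange(n)]
    )
    base_u = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))  # mean C->O direction

    nc_rows = []
    for i in range(n):
        for name, element in (("C", "C"), ("O", "O")):
            nc_rows.append(
                {
                    "name": name,
                    "element": element,
                    "residue_id": i + 1,
                    "residue_name": "GLY",
                    "role": "NC",
                }
            )
    atoms = pd.concat([pd.DataFrame(nc_rows), wall_atoms], ignore_index=True)

    min_self = 2.0  # A, non-adjacent C-C self-avoidance
    min_wall = 2.5  # A, clearance from wall pseudo-atoms
    frames = np.empty((spec.n_frames, len(atoms), 3))
    bond = 1.23  # carbonyl C=O bond length
    for f in range(spec.n_frames):
        for attempt in range(spec.max_retries + 1):
            disp = (prof[:, None] * 1.5) * rng.standard_normal((n, 3))
            c_pos = base_c + disp
            # radial clamp keeps the chain inside the wall
            r = np.linalg.norm(c_pos[:, :2], axis=1)
            over = r > (spec.tunnel_radius - min_wall)
            if over.any():
                scale = (spec.tunnel_radius - min_wall) / r[over]
                c_pos[over, :2] *= scale[:, None]
            d_wall = np.min(
                np.linalg.norm(c_pos[:, None, :] - wall_xyz[None, :, :], axis=-1), axis=1
            )
            if np.any(d_wall < min_wall - 1e-9):
                continue
            diffs = np.linalg.norm(c_pos[:, None, :] - c_pos[None, :, :], axis=-1)
            iu = np.triu_indices(n, k=2)
            if np.any(diffs[iu] < min_self):
                continue
            break
        else:
            raise GenerationFailureError(
                f"could not place a clash-free chain for frame {f} "
                f"after {spec.max_retries} retries"
            )
        rand_u = _random_unit(rng, n)
        mix = (1.0 - prof[:, None]) * base_u + prof[:, None] * rand_u
        u = mix / np.linalg.norm(mix, axis=1, keepdims=True)
        o_pos = c_pos + bond * u
        nc_xyz = np.empty((2 * n, 3))
        nc_xyz[0::2] = c_pos
        nc_xyz[1::2] = o_pos
        frames[f] = np.vstack([nc_xyz, wall_xyz])
    return StructureEnsemble(atoms=atoms, coords=frames)
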