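"""Relative intensity profiles along the elongation coordinate.

Cross-peak volumes of unfolded-state (1H-15N) and folded-state (1H-13C
methyl) marker residues, recorded on nascent chains of increasing linker
length L, are normalized by scan count and relative nascent-chain
concentration, averaged over the markers, and expressed relative to a fully
unfolded (short-L) or fully folded (long-L) reference.  The rising folded
profile crossing 0.5 defines the folding onset; arrest-peptide force assays
provide an orthogonal readout via the fraction of full-length product
f_FL = FL / (FL + A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakVolumeTable",
    "IntensityProfile",
    "GelDensitometry",
    "OnsetResult",
    "U_MARKERS",
    "F_MARKERS",
    "relative_profile",
    "moving_average",
    "folding_onset",
    "f_fl",
]

#: default marker residues: unfolded-state amides and folded-state Ile methyls
U_MARKERS = ("V682", "A683", "A694")
F_MARKERS = ("I674", "I695", "I738", "I743")

_TABLE_COLUMNS = [
    "residue", "linker_l", "volume", "volume_sd",
    "n_scans", "concentration", "concentration_sd",
]


@dataclass
class PeakVolumeTable:
    """Per-residue, per-length peak volumes for one spectral channel."""

    data: pd.DataFrame
    channel: str  # "U" (15N) or "F" (13C)

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak volume table missing columns: {missing}")
        if (self.data["volume"] < 0).any():
            raise ValueError("volumes must be >= 0")
        if self.data.duplicated(["residue", "linker_l"]).any():
            raise ValueError("duplicate (residue, linker_l) rows")
        if self.channel not in ("U", "F"):
            raise ValueError("channel must be 'U' or 'F'")

    @property
    def lengths(self) -> np.ndarray:
        return np.sort(self.data["linker_l"].unique())


@dataclass
class IntensityProfile:
    lengths: np.ndarray
    intensity: np.ndarray  # I / I0
    sd: np.ndarray
    channel: str
    reference_l: int
    flags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)


@dataclass
class GelDensitometry:
    fl: float  # full-length band, a.u.
    arrested: float  # arrested band, a.u.
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.fl < 0 or self.arrested < 0:
            raise ValueError("band densities must be >= 0")
        if self.fl + self.arrested == 0:
            raise ValueError("FL + A must be positive")


@dataclass
class OnsetResult:
    """Onset linker length; ``kind`` is 'crossing', '<' (upper bound when the
    profile starts above threshold) or '>' (lower bound when it never
    crosses)."""

    value: float
    kind: str = "crossing"

    def __str__(self) -> str:
        return f"{self.value:g}" if self.kind == "crossing" else f"{self.kind} {self.value:g}"


def relative_profile(
    table: PeakVolumeTable,
    marker_residues: tuple[str, ...] | None = None,
    reference_l: int | None = None,
) -> IntensityProfile:
    """Scan- and concentration-normalized relative intensity I/I0 per length.

    Per L, volumes are divided by (n_scans x concentration), averaged over
    the marker residues, and divided by the same quantity at ``reference_l``
    (the fully unfolded or fully folded reference state).  The s.d. combines
    the spectral-noise s.d. and the concentration s.d. in quadrature; if a
    marker is missing at some L the value is computed from the reduced
    marker set and flagged.
    """
    if marker_residues is None:
        marker_residues = U_MARKERS if table.channel == "U" else F_MARKERS
    df = table.data[table.data["residue"].isin(marker_residues)].copy()
    if reference_l is None:
        reference_l = int(df["linker_l"].min() if table.channel == "U" else df["linker_l"].max())
    ref = df[df["linker_l"] == reference_l]
    if ref.empty or not set(marker_residues) <= set(ref["residue"]):
        raise ValueError(
            f"reference L={reference_l} missing marker residues"
        )

    def normalized(sub: pd.DataFrame) -> tuple[float, float]:
        scaled = sub["volume"] / (sub["n_scans"] * sub["concentration"])
        # relative error per marker: spectral noise and concentration, quadrature
        rel_var = np.zeros(len(sub))
        nonzero = sub["volume"].to_numpy() > 0
        rel_var[nonzero] = (
            (sub["volume_sd"].to_numpy()[nonzero] / sub["volume"].to_numpy()[nonzero]) ** 2
            + (sub["concentration_sd"].to_numpy()[nonzero] / sub["concentration"].to_numpy()[nonzero]) ** 2
        )
        mean = float(scaled.mean())
        sd = float(np.sqrt(np.sum(rel_var * scaled.to_numpy() ** 2)) / len(sub))
        return mean, sd

    i0, i0_sd = normalized(ref)
    if i0 == 0:
        raise ValueError(f"reference intensity at L={reference_l} is zero")

    lengths, vals, sds, flags = [], [], [], {}
    for l_val, sub in df.groupby("linker_l"):
        present = set(sub["residue"])
        if not set(marker_residues) <= present:
            flags[int(l_val)] = (
                "markers missing: " + ",".join(sorted(set(marker_residues) - present))
            )
        mean, sd = normalized(sub)
        lengths.append(int(l_val))
        vals.append(mean / i0)
        # relative errors of the ratio in quadrature
        rel = np.sqrt((sd / mean) ** 2 + (i0_sd / i0) ** 2) if mean != 0 else 0.0
        sds.append(abs(mean / i0) * rel)
    order = np.argsort(lengths)
    return IntensityProfile(
        lengths=np.array(lengths)[order],
        intensity=np.array(vals)[order],
        sd=np.array(sds)[order],
        channel=table.channel,
        reference_l=int(reference_l),
        flags=flags,
    )


def moving_average(series: np.ndarray, window: int = 4) -> np.ndarray:
    """Unweighted moving average, output length n - window + 1, no padding.

    A display aid only; never feeds the onset estimator."""
    series = np.asarray(series, dtype=float)
    if not 1 <= window <= series.size:
        raise ValueError(f"window must be in [1, {series.size}], got {window}")
    kernel = np.ones(window) / window
    return np.convolve(series, kernel, mode="valid")


def folding_onset(profile: IntensityProfile, threshold: float = 0.5) -> OnsetResult:
    """Smallest L where the rising profile crosses the threshold.

    Linear interpolation between adjacent measured points; returns an upper
    bound ('< L_min') when the first point already exceeds the threshold and
    a lower bound ('> L_max') when the profile never reaches it.
    """
    l_vals = np.asarray(profile.lengths, dtype=float)
    y = profile.intensity
    if y[0] >= threshold:
        return OnsetResult(value=float(l_vals[0]), kind="<")
    for i in range(1, y.size):
        if y[i] >= threshold:
            y0, y1 = y[i - 1], y[i]
            frac = (threshold - y0) / (y1 - y0)
            return OnsetResult(value=float(l_vals[i - 1] + frac * (l_vals[i] - l_vals[i - 1])))
    return OnsetResult(value=float(l_vals[-1]), kind=">")


def f_fl(gels: GelDensitometry | list[GelDensitometry]) -> tuple[float, float | None]:
    """Fraction of full-length product f_FL = FL / (FL + A).

    A list of replicates yields (mean, sample sd); a single measurement
    yields (value, None)."""
    if isinstance(gels, GelDensitometry):
        return gels.fl / (gels.fl + gels.arrested), None
    if not gels:
        raise ValueError("no densitometry records")
    vals = np.array([g.fl / (g.fl + g.arrested) for g in gels])
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return float(vals.mean()), sd
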