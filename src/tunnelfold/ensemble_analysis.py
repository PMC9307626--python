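"""Structural statistics over coordinate ensembles.

Three post-hoc observables computed from multi-frame structures of a
nascent chain (NC) in the ribosomal exit tunnel:

* **Tunnel volume** — a POVME-style grid count: inclusion spheres (20 A
  radius by default) seeded at NC C-alpha positions define the region of
  interest; grid points within a van der Waals radius + cutoff (1.09 A) of
  any wall atom are deleted; the volume is the retained point count times
  the grid-cell volume (2.0 A pitch by default).  Differencing two
  structures on the identical grid isolates the effect of a loop
  modification.
* **Contact frequencies** — per NC residue and ribosomal component, the
  percentage of frames with any heavy-atom pair within a cutoff (4.5 A).
* **S2 order parameters** — rotational mobility of backbone C->O bond
  vectors from the second-rank orientational tensor, 1 = rigid,
  0 = isotropic.  The ribosome frame is fixed, so no alignment is applied.

Ensembles interchange as multi-model PDB (MODEL/ENDMDL); a chain-role map
assigns PDB chain ids to "NC", "ribosome-protein:<name>" or "rRNA:<helix>".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "StructureEnsemble",
    "VolumeGridSpec",
    "ContactMap",
    "OrderParameters",
    "tunnel_volume",
    "volume_difference",
    "contact_frequencies",
    "order_parameters",
    "read_ensemble",
    "write_ensemble",
]

#: Bondi van der Waals radii (A); unknown elements fall back to 1.7 A
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "MG": 1.73, "ZN": 1.39,
}
_FALLBACK_RADIUS = 1.7

_ATOM_COLUMNS = ["name", "element", "residue_id", "residue_name", "role"]


@dataclass
class StructureEnsemble:
    """Multi-frame coordinate set with a fixed atom roster.

    ``atoms`` has one row per atom (name, element, residue_id, residue_name,
    role); ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom.  Roles
    are free-form labels; "NC" marks the nascent chain.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        missing = [c for c in _ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, mask: np.ndarray) -> "StructureEnsemble":
        return StructureEnsemble(
            self.atoms[mask].reset_index(drop=True), self.coords[:, mask, :]
        )

    def heavy_mask(self) -> np.ndarray:
        return (self.atoms["element"].str.upper() != "H").to_numpy()


@dataclass(frozen=True)
class VolumeGridSpec:
    """POVME-style grid: 20 A inclusion spheres, 2.0 A pitch, 1.09 A cutoff."""

    seed_points: np.ndarray
    sphere_radius: float = 20.0
    grid_spacing: float = 2.0
    distance_cutoff: float = 1.09
    use_vdw: bool = True  # False: plain center-distance exclusion

    def __post_init__(self) -> None:
        object.__setattr__(self, "seed_points", np.atleast_2d(np.asarray(self.seed_points, float)))
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.sphere_radius <= self.grid_spacing:
            raise ValueError("sphere radius must exceed the grid spacing")
        if self.seed_points.shape[0] < 1 or self.seed_points.shape[1] != 3:
            raise ValueError("need at least one (x, y, z) seed point")


@dataclass
class ContactMap:
    """NC residue x ribosomal component -> % of frames with a contact."""

    frequencies: pd.DataFrame  # columns: nc_residue, component, frequency
    cutoff: float
    n_frames: int


@dataclass
class OrderParameters:
    residues: np.ndarray
    s2: np.ndarray
    skipped: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tunnel volume


def _vdw_radius(element: str) -> float:
    r = BONDI_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"no vdW radius for element {element!r}; using {_FALLBACK_RADIUS} A")
        return _FALLBACK_RADIUS
    return r


def _grid_points(spec: VolumeGridSpec) -> np.ndarray:
    """Cubic grid over the bounding box of the seed spheres, kept if within
    the sphere radius of any seed point.  The grid is anchored at integer
    multiples of the spacing so that identical specs share identical grids."""
    h = spec.grid_spacing
    lo = np.floor((spec.seed_points.min(axis=0) - spec.sphere_radius) / h) * h
    hi = np.ceil((spec.seed_points.max(axis=0) + spec.sphere_radius) / h) * h
    axes = [np.arange(lo[d], hi[d] + 0.5 * h, h) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(spec.seed_points)
    dist, _ = tree.query(pts, k=1)
    return pts[dist <= spec.sphere_radius]


def tunnel_volume(
    atoms: pd.DataFrame | None,
    coords: np.ndarray | None,
    spec: VolumeGridSpec,
) -> float:
    """Grid-counted void volume (A^3) inside the seeded inclusion spheres.

    Grid points within (vdW radius + distance_cutoff) of any atom center
    are deleted (with ``use_vdw=False``, within distance_cutoff alone).
    Hydrogens are ignored.  An empty atom set returns the unoccluded union
    volume with a warning.
    """
    pts = _grid_points(spec)
    if atoms is None or coords is None or len(atoms) == 0:
        warnings.warn("no atoms supplied: returning unoccluded sphere-union volume")
        return pts.shape[0] * spec.grid_spacing**3
    coords = np.atleast_2d(np.asarray(coords, float))
    elements = atoms["element"].to_numpy()
    heavy = np.char.upper(elements.astype(str)) != "H"
    coords, elements = coords[heavy], elements[heavy]
    if coords.size == 0:
        return pts.shape[0] * spec.grid_spacing**3
    if spec.use_vdw:
        radii = np.array([_vdw_radius(e) for e in elements]) + spec.distance_cutoff
    else:
        radii = np.full(len(elements), spec.distance_cutoff)
    tree = cKDTree(pts)
    kill = np.zeros(pts.shape[0], dtype=bool)
    for r in np.unique(radii):
        sub = coords[radii == r]
        for hits in tree.query_ball_point(sub, r):
            kill[hits] = True
    return float(np.count_nonzero(~kill)) * spec.grid_spacing**3


def volume_difference(
    mutant: tuple[pd.DataFrame, np.ndarray],
    wildtype: tuple[pd.DataFrame, np.ndarray],
    spec: VolumeGridSpec,
) -> float:
    """Volume(mutant) - volume(wild type) on the identical grid (A^3).

    Both structures must be evaluated with the same spec (seeds, radius,
    spacing); the shared grid makes the difference meaningful.
    """
    return tunnel_volume(*mutant, spec) - tunnel_volume(*wildtype, spec)


# ---------------------------------------------------------------------------
# contacts


def contact_frequencies(
    ens: StructureEnsemble,
    cutoff: float = 4.5,
    partners: list[str] | None = None,
    method: str = "tree",
) -> ContactMap:
    """Per-residue NC contact frequencies as % of frames.

    For each NC residue and each non-NC component role, a frame counts as a
    contact when any heavy-atom pair lies strictly within ``cutoff`` A.
    ``partners`` restricts the component roles considered.  ``method`` is
    "tree" (KD-tree accelerated) or "brute" (all-pairs reference; identical
    result, used as the cross-check oracle in tests).
    """
    if ens.n_frames < 1:
        raise ValueError("ensemble has no frames")
    heavy = ens.select(ens.heavy_mask())
    roles = heavy.atoms["role"].to_numpy()
    nc_mask = roles == "NC"
    if not nc_mask.any():
        raise ValueError("no NC chain present in the ensemble")
    comp_roles = sorted({r for r in roles if r != "NC"})
    if partners is not None:
        comp_roles = [r for r in comp_roles if r in partners]
    nc_res = heavy.atoms["residue_id"].to_numpy()[nc_mask]
    residues = np.unique(nc_res)
    counts = {(int(res), comp): 0 for res in residues for comp in comp_roles}

    for f in range(heavy.n_frames):
        xyz = heavy.coords[f]
        nc_xyz = xyz[nc_mask]
        for comp in comp_roles:
            cmask = roles == comp
            cxyz = xyz[cmask]
            if method == "tree":
                tree = cKDTree(cxyz)
                d, _ = tree.query(nc_xyz, k=1)
                close = d < cutoff
            elif method == "brute":
                diff = nc_xyz[:, None, :] - cxyz[None, :, :]
                dmat = np.sqrt(np.sum(diff**2, axis=-1))
                close = (dmat < cutoff).any(axis=1)
            else:
                raise ValueError(f"unknown method {method!r}")
            for res in np.unique(nc_res[close]):
                counts[(int(res), comp)] += 1

    rows = [
        {"nc_residue": res, "component": comp, "frequency": 100.0 * n / heavy.n_frames}
        for (res, comp), n in sorted(counts.items())
    ]
    return ContactMap(pd.DataFrame(rows, columns=["nc_residue", "component", "frequency"]),
                      cutoff=cutoff, n_frames=heavy.n_frames)


# ---------------------------------------------------------------------------
# order parameters


def order_parameters(
    ens: StructureEnsemble,
    atom_from: str = "C",
    atom_to: str = "O",
    roles: tuple[str, ...] = ("NC",),
) -> OrderParameters:
    """S2 of backbone carbonyl C->O unit vectors, per residue.

    With u the unit bond vector and <.> the ensemble average over frames,

        S2 = (3 (<x^2>^2 + <y^2>^2 + <z^2>^2
                 + 2<xy>^2 + 2<xz>^2 + 2<yz>^2) - 1) / 2

    i.e. the second-rank orientational order parameter; 1 for a rigid
    vector, 0 in the isotropic limit.  Residues missing either atom in any
    frame are skipped and listed.
    """
    df = ens.atoms
    sel = df["role"].isin(roles)
    residues = np.unique(df.loc[sel, "residue_id"])
    out_res, out_s2, skipped = [], [], []
    for res in residues:
        i_c = df.index[sel & (df["residue_id"] == res) & (df["name"] == atom_from)]
        i_o = df.index[sel & (df["residue_id"] == res) & (df["name"] == atom_to)]
        if len(i_c) != 1 or len(i_o) != 1:
            skipped.append(int(res))
            continue
        v = ens.coords[:, i_o[0], :] - ens.coords[:, i_c[0], :]
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        u = v / norm
        x, y, z = u[:, 0], u[:, 1], u[:, 2]
        s2 = 0.5 * (
            3.0
            * (
                np.mean(x * x) ** 2 + np.mean(y * y) ** 2 + np.mean(z * z) ** 2
                + 2 * np.mean(x * y) ** 2 + 2 * np.mean(x * z) ** 2 + 2 * np.mean(y * z) ** 2
            )
            - 1.0
        )
        out_res.append(int(res))
        out_s2.append(float(s2))
    if skipped:
        warnings.warn(f"residues skipped (missing {atom_from}/{atom_to}): {skipped}")
    return OrderParameters(np.array(out_res), np.array(out_s2), skipped)


# ---------------------------------------------------------------------------
# multi-model PDB interchange (model numbers define frame order)


def write_ensemble(ens: StructureEnsemble, path: str | Path,
                   role_chains: dict[str, str] | None = None) -> None:
    """Write a multi-model PDB.  ``role_chains`` maps role -> chain id;
    unmapped roles are assigned single-letter ids in sorted role order."""
    roles = sorted(ens.atoms["role"].unique())
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    mapping = dict(role_chains or {})
    taken = set(mapping.values())
    free = iter(c for c in alphabet if c not in taken)
    for r in roles:
        if r not in mapping:
            mapping[r] = next(free)

    st = gemmi.Structure()
    st.name = "tunnelfold-ensemble"
    for f in range(ens.n_frames):
        model = gemmi.Model(f + 1)
        for role in roles:
            chain = gemmi.Chain(mapping[role])
            sub = ens.atoms[ens.atoms["role"] == role]
            for res_id, res_rows in sub.groupby("residue_id", sort=True):
                res = gemmi.Residue()
                res.name = str(res_rows["residue_name"].iloc[0])
                res.seqid = gemmi.SeqId(int(res_id), " ")
                for idx in res_rows.index:
                    at = gemmi.Atom()
                    at.name = str(ens.atoms.at[idx, "name"])
                    at.element = gemmi.Element(str(ens.atoms.at[idx, "element"]))
                    x, y, z = ens.coords[f, ens.atoms.index.get_loc(idx)]
                    at.pos = gemmi.Position(x, y, z)
                    res.add_atom(at)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
    # sidecar mapping so readers can restore roles
    Path(str(path) + ".roles").write_text(
        "\n".join(f"{cid}\t{role}" for role, cid in sorted(mapping.items(), key=lambda kv: kv[1]))
        + "\n"
    )


def read_ensemble(path: str | Path, chain_roles: dict[str, str] | None = None) -> StructureEnsemble:
    """Read a multi-model PDB.  ``chain_roles`` maps chain id -> role; when
    omitted, the sidecar ``<path>.roles`` file is used if present, else the
    chain id itself becomes the role."""
    path = Path(path)
    if chain_roles is None:
        side = Path(str(path) + ".roles")
        chain_roles = {}
        if side.exists():
            for line in side.read_text().splitlines():
                cid, _, role = line.partition("\t")
                if role:
                    chain_roles[cid] = role
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    rows, frames = [], []
    for i_model, model in enumerate(st):
        xyz = []
        for chain in model:
            role = chain_roles.get(chain.name, chain.name)
            for res in chain:
                for at in res:
                    if i_model == 0:
                        rows.append(
                            {
                                "name": at.name,
                                "element": at.element.name,
                                "residue_id": res.seqid.num,
                                "residue_name": res.name,
                                "role": role,
                            }
                        )
                    xyz.append([at.pos.x, at.pos.y, at.pos.z])
        frames.append(xyz)
    coords = np.array(frames)
    atoms = pd.DataFrame(rows)
    return StructureEnsemble(atoms=atoms, coords=coords)
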