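"""Tunnel volumes, contact frequencies and order parameters."""

import numpy as np
import pandas as pd
import pytest

from tunnelfold.ensemble_analysis import (
    StructureEnsemble,
    VolumeGridSpec,
    contact_frequencies,
    order_parameters,
    tunnel_volume,
    volume_difference,
)
from tunnelfold.synthetic_data import EnsembleSpec, simulate_ensemble


def atoms_df(rows):
    return pd.DataFrame(rows, columns=["name", "element", "residue_id", "residue_name", "role"])


def carbon(residue_id, role="wall"):
    return {"name": "C", "element": "C", "residue_id": residue_id,
            "residue_name": "X", "role": role}


class TestTunnelVolume:
    def test_unoccluded_single_sphere(self):
        """Grid count of one 20 A inclusion sphere at 2 A pitch approximates
        4/3 pi r^3 = 33510 A^3 within 3 %."""
        spec = VolumeGridSpec(seed_points=np.zeros((1, 3)))
        with pytest.warns(UserWarning):
            vol = tunnel_volume(None, None, spec)
        assert vol == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.03)

    def test_grid_refinement_converges(self):
        """Halving the pitch changes the single-sphere volume by < 1 %."""
        v2 = tunnel_volume(atoms_df([]), np.zeros((0, 3)),
                           VolumeGridSpec(seed_points=np.zeros((1, 3)), grid_spacing=2.0))
        v1 = tunnel_volume(atoms_df([]), np.zeros((0, 3)),
                           VolumeGridSpec(seed_points=np.zeros((1, 3)), grid_spacing=1.0))
        assert abs(v1 - v2) / v1 < 0.01

    def test_densely_filled_region_zero(self):
        spec = VolumeGridSpec(seed_points=np.zeros((1, 3)), sphere_radius=6.0,
                              grid_spacing=2.0)
        g = np.arange(-8, 8.5, 2.0)
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        dense = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        atoms = atoms_df([carbon(i) for i in range(len(dense))])
        assert tunnel_volume(atoms, dense, spec) == 0.0

    def test_removing_atoms_never_decreases_volume(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-15, 15, size=(40, 3))
        atoms = atoms_df([carbon(i) for i in range(40)])
        spec = VolumeGridSpec(seed_points=np.zeros((1, 3)))
        full = tunnel_volume(atoms, coords, spec)
        for k in (30, 20, 5):
            sub = tunnel_volume(atoms.iloc[:k], coords[:k], spec)
            assert sub >= full
            full_prev, full = full, sub  # noqa: F841 (monotone chain)

    def test_hydrogens_ignored(self):
        h_atoms = atoms_df([{**carbon(0), "element": "H", "name": "H"}])
        spec = VolumeGridSpec(seed_points=np.zeros((1, 3)), sphere_radius=5.0, grid_spacing=1.0)
        empty = tunnel_volume(atoms_df([]), np.zeros((0, 3)), spec)
        assert tunnel_volume(h_atoms, np.zeros((1, 3)), spec) == empty

    def test_brute_force_grid_oracle(self):
        """The KD-tree-pruned count must equal direct enumeration over the
        anchored grid (independent oracle)."""
        rng = np.random.default_rng(7)
        coords = rng.uniform(-10, 10, size=(15, 3))
        atoms = atoms_df([carbon(i) for i in range(15)])
        spec = VolumeGridSpec(seed_points=np.array([[0.0, 0.0, 0.0]]),
                              sphere_radius=12.0, grid_spacing=2.0)
        got = tunnel_volume(atoms, coords, spec)
        # oracle: same anchored grid, O(n_grid x n_atoms) loops
        h = spec.grid_spacing
        lo = np.floor((spec.seed_points.min(0) - spec.sphere_radius) / h) * h
        hi = np.ceil((spec.seed_points.max(0) + spec.sphere_radius) / h) * h
        count = 0
        r_excl = 1.70 + spec.distance_cutoff  # all atoms are carbon
        for x in np.arange(lo[0], hi[0] + h / 2, h):
            for y in np.arange(lo[1], hi[1] + h / 2, h):
                for z in np.arange(lo[2], hi[2] + h / 2, h):
                    p = np.array([x, y, z])
                    if np.linalg.norm(p) > spec.sphere_radius:
                        continue
                    if np.min(np.linalg.norm(coords - p, axis=1)) <= r_excl:
                        continue
                    count += 1
        assert got == pytest.approx(count * h**3, abs=1e-9)

    def test_volume_difference_identical_zero(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-10, 10, size=(20, 3))
        atoms = atoms_df([carbon(i) for i in range(20)])
        spec = VolumeGridSpec(seed_points=np.zeros((1, 3)))
        assert volume_difference((atoms, coords), (atoms, coords), spec) == 0.0

    def test_loop_deletion_increases_volume(self):
        """Deleting an occluding 'loop' of atoms opens up volume, and the
        difference equals an independent recount."""
        rng = np.random.default_rng(9)
        wt_coords = rng.uniform(-12, 12, size=(30, 3))
        wt_atoms = atoms_df([carbon(i) for i in range(30)])
        mut_atoms, mut_coords = wt_atoms.iloc[:22], wt_coords[:22]
        spec = VolumeGridSpec(seed_points=np.zeros((1, 3)), sphere_radius=15.0)
        dv = volume_difference((mut_atoms, mut_coords), (wt_atoms, wt_coords), spec)
        assert dv > 0
        recount = tunnel_volume(mut_atoms, mut_coords, spec) - tunnel_volume(wt_atoms, wt_coords, spec)
        assert dv == pytest.approx(recount, abs=1e-9)

    def test_rigid_motion_invariance(self):
        """Moving seeds and atoms together leaves the volume unchanged (to
        grid-anchoring tolerance: translation by grid multiples is exact)."""
        rng = np.random.default_rng(13)
        coords = rng.uniform(-10, 10, size=(25, 3))
        atoms = atoms_df([carbon(i) for i in range(25)])
        shift = np.array([4.0, -6.0, 8.0])  # multiple of the 2 A pitch
        v0 = tunnel_volume(atoms, coords, VolumeGridSpec(seed_points=np.zeros((1, 3))))
        v1 = tunnel_volume(atoms, coords + shift,
                           VolumeGridSpec(seed_points=shift[None, :]))
        assert v0 == pytest.approx(v1, abs=1e-9)


def two_chain_ensemble(nc_frames, partner_xyz, partner_role="ribosome-protein:uL23"):
    """NC with one atom per residue plus one partner atom, coordinates given
    per frame."""
    n_res = nc_frames.shape[1]
    rows = [carbon(i + 1, role="NC") for i in range(n_res)]
    rows.append(carbon(999, role=partner_role))
    coords = np.concatenate(
        [nc_frames, np.tile(partner_xyz, (nc_frames.shape[0], 1, 1))], axis=1
    )
    return StructureEnsemble(atoms_df(rows), coords)


class TestContactFrequencies:
    def test_fraction_of_frames(self):
        """A residue within cutoff in 3 of 10 frames scores 30 %."""
        nc = np.tile(np.array([[[0.0, 0.0, 10.0]]]), (10, 1, 1))
        nc[:3, 0, 2] = 2.0  # close in first three frames
        ens = two_chain_ensemble(nc, np.array([[0.0, 0.0, 0.0]]))
        cmap = contact_frequencies(ens, cutoff=4.5)
        assert cmap.frequencies["frequency"].iloc[0] == pytest.approx(30.0)

    def test_zero_cutoff_all_zero(self):
        nc = np.zeros((5, 3, 3))
        ens = two_chain_ensemble(nc, np.array([[0.0, 0.0, 0.1]]))
        cmap = contact_frequencies(ens, cutoff=0.0)
        assert (cmap.frequencies["frequency"] == 0).all()

    def test_single_frame_frequencies_binary(self):
        ens = simulate_ensemble(EnsembleSpec(n_frames=1, nc_length=8, mobility_profile=0.3, seed=3))
        cmap = contact_frequencies(ens)
        assert set(np.unique(cmap.frequencies["frequency"])) <= {0.0, 100.0}

    def test_tree_equals_brute_force(self):
        """KD-tree-accelerated frequencies must equal the all-pairs oracle
        exactly on a random 20-frame fixture."""
        ens = simulate_ensemble(EnsembleSpec(n_frames=20, nc_length=10, mobility_profile=0.6, seed=5))
        fast = contact_frequencies(ens, method="tree").frequencies
        slow = contact_frequencies(ens, method="brute").frequencies
        pd.testing.assert_frame_equal(fast, slow)

    def test_no_nc_chain_rejected(self):
        rows = [carbon(1, role="rRNA:H24")]
        ens = StructureEnsemble(atoms_df(rows), np.zeros((1, 1, 3)))
        with pytest.raises(ValueError, match="NC"):
            contact_frequencies(ens)

    def test_rigid_motion_invariance(self):
        ens = simulate_ensemble(EnsembleSpec(n_frames=5, nc_length=8, mobility_profile=0.5, seed=8))
        base = contact_frequencies(ens).frequencies
        # rotate all frames identically
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        moved = StructureEnsemble(ens.atoms, ens.coords @ rot.T + np.array([5.0, -3.0, 2.0]))
        pd.testing.assert_frame_equal(contact_frequencies(moved).frequencies, base)


class TestOrderParameters:
    def co_ensemble(self, unit_vectors):
        """One residue; C at origin, O displaced along the given unit vector
        per frame."""
        n = unit_vectors.shape[0]
        rows = [
            {"name": "C", "element": "C", "residue_id": 1, "residue_name": "GLY", "role": "NC"},
            {"name": "O", "element": "O", "residue_id": 1, "residue_name": "GLY", "role": "NC"},
        ]
        coords = np.zeros((n, 2, 3))
        coords[:, 1, :] = 1.23 * unit_vectors
        return StructureEnsemble(atoms_df(rows), coords)

    def test_rigid_limit(self):
        u = np.tile(np.array([[0.0, 0.0, 1.0]]), (10, 1))
        op = order_parameters(self.co_ensemble(u))
        assert op.s2[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_orthogonal_orientations(self):
        """Equal weight on two orthogonal directions gives S2 = 0.25."""
        u = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        op = order_parameters(self.co_ensemble(u))
        assert op.s2[0] == pytest.approx(0.25, abs=1e-12)

    def test_isotropic_limit(self):
        rng = np.random.default_rng(17)
        v = rng.standard_normal((10_000, 3))
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        op = order_parameters(self.co_ensemble(u))
        assert op.s2[0] < 0.05

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(23)
        v = rng.standard_normal((50, 3))
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        base = order_parameters(self.co_ensemble(u)).s2[0]
        ang = 1.1
        rot = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]])
        rotated = order_parameters(self.co_ensemble(u @ rot.T)).s2[0]
        assert rotated == pytest.approx(base, abs=1e-12)

    def test_s2_bounded_in_unit_interval(self):
        ens = simulate_ensemble(EnsembleSpec(n_frames=50, nc_length=12,
                                             mobility_profile=0.7, seed=31))
        op = order_parameters(ens)
        assert np.all(op.s2 >= -1e-9)
        assert np.all(op.s2 <= 1 + 1e-9)

    def test_missing_atoms_skipped_with_warning(self):
        rows = [
            {"name": "C", "element": "C", "residue_id": 1, "residue_name": "GLY", "role": "NC"},
        ]
        ens = StructureEnsemble(atoms_df(rows), np.zeros((2, 1, 3)))
        with pytest.warns(UserWarning, match="skipped"):
            op = order_parameters(ens)
        assert op.skipped == [1]
        assert op.s2.size == 0

    def test_mobility_profile_orders_s2(self):
        """Residues generated with higher mobility end up with lower S2."""
        profile = np.linspace(0.0, 1.0, 10)
        ens = simulate_ensemble(EnsembleSpec(n_frames=400, nc_length=10,
                                             mobility_profile=profile, seed=41))
        op = order_parameters(ens)
        assert op.s2[0] == pytest.approx(1.0, abs=1e-9)
        assert op.s2[-1] < 0.2
        # broadly decreasing along the profile
        assert np.corrcoef(profile, op.s2)[0, 1] < -0.9
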