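"""Local frames, masked environment extraction and voxelization."""

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import stabscan as ss
from stabscan.structure import AtomRecord, Residue, ResidueSite, Structure
from stabscan.voxel import GridSpec, VoxelGrid


def brute_force_grid(env, spec):
    """Independent oracle: loop over atoms x all voxel centers."""
    s = spec.side_voxels
    centers = (np.arange(s) + 0.5) * spec.voxel_edge - spec.radius
    grid = np.zeros(spec.shape, dtype=np.float32)
    for ch, xyz in env:
        best, best_d = None, np.inf
        for i in range(s):
            for j in range(s):
                for k in range(s):
                    d = ((xyz[0] - centers[i]) ** 2 + (xyz[1] - centers[j]) ** 2
                         + (xyz[2] - centers[k]) ** 2)
                    if d < best_d:
                        best, best_d = (i, j, k), d
        grid[(ch,) + best] += 1
    return grid


def random_environment(rng, n_atoms, spec):
    out = []
    for _ in range(n_atoms):
        while True:
            p = rng.uniform(-spec.radius, spec.radius, 3)
            if np.linalg.norm(p) <= spec.radius:
                break
        out.append((int(rng.integers(0, 6)), p))
    return out


def single_residue_structure(extra_atoms=()):
    """One alanine at the origin, plus optional loose carbon atoms given as
    coordinates relative to its CA."""
    res = Residue(chain_id="A", residue_index=1, res_name="ALA")
    ca = np.array([1.458, 0.0, 0.0])
    for name, el, coords in [("N", "N", np.zeros(3)), ("CA", "C", ca),
                             ("C", "C", ca + np.array([-0.55, 1.42, 0.0]))]:
        res.atoms.append(AtomRecord(name, el, coords, 1, "A"))
    st = Structure(source_id="single", chain_id="A", residues=[res])
    for i, rel in enumerate(extra_atoms):
        other = Residue(chain_id="A", residue_index=50 + i, res_name="GLY")
        other.atoms.append(AtomRecord("C1", "C", ca + np.asarray(rel),
                                      50 + i, "A"))
        st.residues.append(other)
    return st


class TestLocalFrame:
    def test_orthonormal_right_handed(self, helix30):
        for site in ss.residue_sites(helix30):
            f = ss.local_frame(site)
            assert np.allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-8)
            assert np.linalg.det(f.axes) == pytest.approx(1.0, abs=1e-8)
            assert np.allclose(f.origin, site.ca)

    def test_translation_moves_origin_only(self, helix30):
        site = ss.residue_sites(helix30)[5]
        shifted = ResidueSite(site.chain_id, site.residue_index, site.wt_aa,
                              site.n + [10, 0, 0], site.ca + [10, 0, 0],
                              site.c + [10, 0, 0])
        f0, f1 = ss.local_frame(site), ss.local_frame(shifted)
        assert np.allclose(f0.axes, f1.axes, atol=1e-12)
        assert np.allclose(f1.origin - f0.origin, [10, 0, 0])

    def test_rotation_rotates_axes(self, helix30):
        site = ss.residue_sites(helix30)[5]
        R = Rotation.random(random_state=11).as_matrix()
        rot = ResidueSite(site.chain_id, site.residue_index, site.wt_aa,
                          R @ site.n, R @ site.ca, R @ site.c)
        f0, f1 = ss.local_frame(site), ss.local_frame(rot)
        assert np.allclose(f1.axes, f0.axes @ R.T, atol=1e-8)

    def test_collinear_backbone_is_an_error(self):
        site = ResidueSite("A", 7, "A", np.array([0.0, 0, 0]),
                           np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))
        with pytest.raises(ValueError, match="collinear.*7"):
            ss.local_frame(site)


class TestExtractEnvironment:
    def test_single_residue_environment_is_empty(self):
        st = single_residue_structure()
        site = ss.residue_sites(st)[0]
        assert ss.extract_environment(st, site) == []

    def test_radius_cut_excludes_beyond_9(self):
        st = single_residue_structure(extra_atoms=[(9.5, 0, 0), (3.0, 0, 0)])
        site = ss.residue_sites(st)[0]
        env = ss.extract_environment(st, site)
        assert len(env) == 1
        ch, xyz = env[0]
        assert ch == 0 and np.linalg.norm(xyz) == pytest.approx(3.0, abs=1e-9)

    def test_masking_excludes_every_target_atom(self, helix30):
        for site in ss.residue_sites(helix30)[:5]:
            target = next(r for r in helix30.residues
                          if r.residue_index == site.residue_index)
            n_near_own = sum(
                1 for a in target.atoms
                if a.channel is not None
                and np.linalg.norm(a.coords - site.ca) <= 9.0)
            env = ss.extract_environment(helix30, site)
            all_atoms_near = sum(
                1 for a in helix30.atoms if a.channel is not None
                and np.linalg.norm(a.coords - site.ca) <= 9.0)
            assert len(env) == all_atoms_near - n_near_own


class TestVoxelize:
    def test_empty_environment_gives_zero_grid(self):
        g = ss.voxelize([])
        assert g.values.shape == (6, 18, 18, 18)
        assert g.values.sum() == 0

    def test_atom_near_origin_lands_in_center_voxel(self):
        g = ss.voxelize([(0, np.array([0.2, 0.2, 0.2]))])
        assert g.values[0, 9, 9, 9] == 1.0
        assert g.values.sum() == 1.0

    def test_counts_match_environment_size(self, helix30):
        site = ss.residue_sites(helix30)[10]
        env = ss.extract_environment(helix30, site)
        g = ss.voxelize(env)
        for ch in range(6):
            assert g.values[ch].sum() == sum(1 for c, _ in env if c == ch)

    def test_matches_brute_force_oracle(self):
        spec = GridSpec()
        rng = np.random.default_rng(42)
        for _ in range(20):
            env = random_environment(rng, int(rng.integers(1, 40)), spec)
            got = ss.voxelize(env, spec).values
            want = brute_force_grid(env, spec)
            assert np.array_equal(got, want)


class TestGaussianBlur:
    def test_zero_grid_stays_zero(self):
        g = ss.gaussian_blur(VoxelGrid(np.zeros((6, 18, 18, 18), np.float32)))
        assert g.values.sum() == 0

    def test_center_unit_mass_is_conserved(self):
        v = np.zeros((6, 18, 18, 18), np.float32)
        v[2, 9, 9, 9] = 1.0
        out = ss.gaussian_blur(VoxelGrid(v), sigma=1.0)
        assert out.values[2].sum() == pytest.approx(1.0, abs=1e-6)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_tiny_sigma_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.random((6, 18, 18, 18)).astype(np.float32)
        out = ss.gaussian_blur(VoxelGrid(v), sigma=1e-3)
        assert np.abs(out.values - v).max() < 1e-6

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ss.gaussian_blur(VoxelGrid(np.zeros((6, 18, 18, 18))), sigma=0.0)


def test_rigid_motion_leaves_grids_unchanged(helix30):
    R = Rotation.random(random_state=3).as_matrix()
    t = np.array([5.0, -7.0, 11.0])
    moved = copy.deepcopy(helix30)
    for res in moved.residues:
        for a in res.atoms:
            a.coords = R @ a.coords + t
    for s1, s2 in zip(ss.residue_sites(helix30)[:8], ss.residue_sites(moved)[:8]):
        g1 = ss.gaussian_blur(ss.featurize_site(helix30, s1))
        g2 = ss.gaussian_blur(ss.featurize_site(moved, s2))
        assert np.abs(g1.values - g2.values).max() <= 1e-6


def test_environment_dataset_round_trip(tmp_path, helix30):
    grids, labels, pids, ridx = ss.build_environment_dataset([helix30])
    path = tmp_path / "env.h5"
    ss.save_environment_dataset(path, grids, labels, pids, ridx, GridSpec())
    g2, l2, p2, r2, spec = ss.load_environment_dataset(path)
    assert np.array_equal(grids, g2) and np.array_equal(labels, l2)
    assert p2 == pids and np.array_equal(ridx, r2) and spec == GridSpec()


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        GridSpec(radius=-1.0)
    with pytest.raises(ValueError):
        GridSpec(radius=9.0, voxel_edge=0.7)
    assert GridSpec().side_voxels == 18
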