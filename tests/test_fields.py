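import numpy as np
import pytest

from abvisc.constants import COULOMB_KT_ANG
from abvisc.errors import ConfigError
from abvisc.fields import (
    build_combined_input,
    build_esp_input,
    eisenberg_density,
    build_eisenberg_input,
    random_rotation_matrices,
    random_rotations,
    solve_esp_debye,
    solve_esp_fd_pb,
    ScalarField,
)
from abvisc.surface import GridSpec, ShellMask, compute_ses, compute_shell

from conftest import make_atoms


def point_charge(q, pos=(0.0, 0.0, 0.0)):
    return make_atoms([("C", "C", 1, pos, q, 1.9)])


def charges(entries):
    return make_atoms(
        [("C", "C", i + 1, p, q, 1.9) for i, (p, q) in enumerate(entries)]
    )


@pytest.fixture
def field_grid():
    return GridSpec(extent=9.0, spacing=0.75, padded_dim=25)


class TestDebye:
    def test_single_charge_exact_coulomb(self, field_grid):
        s = point_charge(1.0)
        phi = solve_esp_debye(s, field_grid, eps_out=80.0)
        pts = field_grid.voxel_centers()
        r = np.linalg.norm(pts, axis=-1)
        sel = r > 1.0
        expected = COULOMB_KT_ANG / (80.0 * r[sel])
        np.testing.assert_allclose(phi.values[sel], expected, rtol=1e-12)

    def test_strong_screening_kills_far_field(self, field_grid):
        s = point_charge(1.0)
        phi = solve_esp_debye(s, field_grid, eps_out=80.0, ionic_strength=5.0)
        pts = field_grid.voxel_centers()
        r = np.linalg.norm(pts, axis=-1)
        far = phi.values[r > 6.0]
        near = phi.values[tuple(np.array([12, 12, 12]) + np.array([2, 0, 0]))]
        assert np.abs(far).max() < 1e-2 * abs(near)

    def test_superposition(self, field_grid):
        a = charges([((-2.0, 0, 0), 1.0)])
        b = charges([((2.0, 0, 0), -0.5)])
        both = charges([((-2.0, 0, 0), 1.0), ((2.0, 0, 0), -0.5)])
        pa = solve_esp_debye(a, field_grid).values
        pb = solve_esp_debye(b, field_grid).values
        pab = solve_esp_debye(both, field_grid).values
        np.testing.assert_allclose(pab, pa + pb, rtol=1e-12, atol=1e-12)


class TestFdPb:
    def test_uniform_dielectric_matches_coulomb(self):
        # 33-point grid; analytic Coulomb within 5% in the 3..8 A range
        spec = GridSpec(extent=12.0, spacing=0.75, padded_dim=33)
        s = point_charge(1.0)
        phi = solve_esp_fd_pb(s, spec, eps_in=80.0, eps_out=80.0)
        pts = spec.voxel_centers()
        r = np.linalg.norm(pts, axis=-1)
        sel = (r >= 3.0) & (r <= 8.0)
        expected = COULOMB_KT_ANG / (80.0 * r[sel])
        rel = np.abs(phi.values[sel] - expected) / expected
        assert rel.max() < 0.05

    def test_zero_charges_zero_potential(self, field_grid):
        s = point_charge(0.0)
        phi = solve_esp_fd_pb(s, field_grid)
        np.testing.assert_allclose(phi.values, 0.0, atol=1e-12)

    def test_mirror_antisymmetry(self, field_grid):
        s = charges([((-2.25, 0, 0), 1.0), ((2.25, 0, 0), -1.0)])
        phi = solve_esp_fd_pb(s, field_grid, eps_in=80.0, eps_out=80.0).values
        mirrored = phi[::-1, :, :]
        np.testing.assert_allclose(phi, -mirrored, atol=1e-4 * np.abs(phi).max())

    def test_agrees_with_debye_in_uniform_medium(self, field_grid):
        s = charges([((-1.5, 0.75, 0), 1.0), ((1.5, -0.75, 0.75), -1.0)])
        pb = solve_esp_fd_pb(s, field_grid, eps_in=80.0, eps_out=80.0).values
        db = solve_esp_debye(s, field_grid).values
        pts = field_grid.voxel_centers()
        d = np.minimum(
            np.linalg.norm(pts - np.array([-1.5, 0.75, 0]), axis=-1),
            np.linalg.norm(pts - np.array([1.5, -0.75, 0.75]), axis=-1),
        )
        sel = d > 3.0
        denom = np.abs(db[sel]).max()
        assert np.abs(pb[sel] - db[sel]).max() / denom < 0.05

    def test_invalid_dielectric_raises(self, field_grid):
        with pytest.raises(ConfigError):
            solve_esp_fd_pb(point_charge(1.0), field_grid, eps_in=-1.0)


class TestInputAssembly:
    def test_all_inactive_shell_zero_grid(self, field_grid):
        phi = solve_esp_debye(point_charge(1.0), field_grid)
        shell = ShellMask(
            spec=field_grid,
            active=np.zeros((field_grid.n_points,) * 3, dtype=bool),
        )
        g = build_esp_input(phi, shell, field_grid)
        assert not np.any(g.channels)

    def test_single_active_voxel(self, field_grid):
        n = field_grid.n_points
        values = np.zeros((n, n, n))
        values[3, 4, 5] = 2.5
        phi = ScalarField(spec=field_grid, values=values, kind="esp")
        active = np.zeros((n, n, n), dtype=bool)
        active[3, 4, 5] = True
        g = build_esp_input(phi, ShellMask(field_grid, active), field_grid)
        o = field_grid.pad_offset
        assert g.channels[0, o + 3, o + 4, o + 5] == 2.5
        assert np.count_nonzero(g.channels) == 1

    def test_nonzero_set_equals_shell(self, toy_structure, desk_grid):
        occ = compute_ses(toy_structure, desk_grid)
        shell = compute_shell(occ, 2.0)
        phi = solve_esp_debye(toy_structure, desk_grid)
        g = build_esp_input(phi, shell, desk_grid)
        o = desk_grid.pad_offset
        n = desk_grid.n_points
        block = g.channels[0, o : o + n, o : o + n, o : o + n]
        # phi is nonzero on every shell voxel of this charged structure
        np.testing.assert_array_equal(block != 0.0, shell.active)

    def test_spec_mismatch_raises(self, field_grid, desk_grid):
        phi = solve_esp_debye(point_charge(1.0), field_grid)
        shell = ShellMask(
            spec=desk_grid, active=np.zeros((desk_grid.n_points,) * 3, bool)
        )
        with pytest.raises(ConfigError):
            build_esp_input(phi, shell, field_grid)


class TestEisenberg:
    def test_hydrophilic_only_structure_empty_phobic_channel(
        self, desk_grid
    ):
        from abvisc.structure_io import assign_parameters, canonicalize
        from abvisc.synthetic import PatchSpec, ToySpec, make_toy_structure

        s = make_toy_structure(
            ToySpec(n_residues=12, filler=("SER",), patches=(), seed=2)
        )
        s = canonicalize(assign_parameters(s))
        occ = compute_ses(s, desk_grid)
        shell = compute_shell(occ, 2.0)
        g = build_eisenberg_input(s, shell, desk_grid)
        assert not np.any(g.channels[0])  # hydrophobic channel
        assert np.any(g.channels[1])

    def test_single_atom_monotone_decay(self, field_grid):
        s = make_atoms([("CB", "C", 1, (0.0, 0.0, 0.0), 0.0, 1.9)], resname="LEU")
        dens = eisenberg_density(s, field_grid, hydrophobic=True).values
        c = field_grid.n_points // 2
        ray = dens[c, c, c:]
        assert np.all(np.diff(ray) < 0)

    def test_two_atom_linearity(self, field_grid):
        a = make_atoms([("CB", "C", 1, (-2.0, 0, 0), 0.0, 1.9)], resname="LEU")
        b = make_atoms([("CB", "C", 1, (2.0, 0, 0), 0.0, 1.9)], resname="LEU")
        ab = make_atoms(
            [
                ("CB", "C", 1, (-2.0, 0, 0), 0.0, 1.9),
                ("CB", "C", 2, (2.0, 0, 0), 0.0, 1.9),
            ],
            resname="LEU",
        )
        da = eisenberg_density(a, field_grid, True).values
        db = eisenberg_density(b, field_grid, True).values
        dab = eisenberg_density(ab, field_grid, True).values
        np.testing.assert_allclose(dab, da + db, rtol=1e-12, atol=1e-12)

    def test_combined_is_concatenation(self, toy_structure, desk_grid):
        occ = compute_ses(toy_structure, desk_grid)
        shell = compute_shell(occ, 2.0)
        phi = solve_esp_debye(toy_structure, desk_grid)
        combined = build_combined_input(phi, toy_structure, shell, desk_grid)
        esp = build_esp_input(phi, shell, desk_grid)
        eis = build_eisenberg_input(toy_structure, shell, desk_grid)
        assert combined.channels.shape[0] == 3
        np.testing.assert_array_equal(combined.channels[0], esp.channels[0])
        np.testing.assert_array_equal(combined.channels[1:], eis.channels)


class TestRotations:
    def test_count_and_rigidity(self, toy_structure):
        rots = random_rotations(toy_structure, 10, seed=4)
        assert len(rots) == 10
        x0 = toy_structure.coords()
        d0 = np.linalg.norm(x0[:20, None] - x0[None, :20], axis=-1)
        for r in rots[:3]:
            x = r.coords()
            d = np.linalg.norm(x[:20, None] - x[None, :20], axis=-1)
            np.testing.assert_allclose(d, d0, atol=1e-9)

    def test_seed_determinism(self):
        m1 = random_rotation_matrices(5, seed=9)
        m2 = random_rotation_matrices(5, seed=9)
        np.testing.assert_array_equal(m1, m2)
        m3 = random_rotation_matrices(5, seed=10)
        assert not np.allclose(m1, m3)

    def test_invalid_count_raises(self, toy_structure):
        with pytest.raises(ConfigError):
            random_rotations(toy_structure, 0, seed=1)
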