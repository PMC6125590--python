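"""Grid construction, dielectric maps, LPBE solver properties, qE forces."""

import numpy as np
import pytest
from scipy import constants as const

import tailbind.electrostatics as es
from tailbind.errors import (IncompleteStructureError, InvalidSelectionError,
                             InvalidSpecError)
from tailbind.structure import Atom, Structure


def point_charges(entries):
    """entries: (position, charge, radius) triples."""
    atoms = [Atom(i + 1, "ION", "C", "ION", i + 1, "I", p, charge=q, radius=r)
             for i, (p, q, r) in enumerate(entries)]
    return Structure.from_atoms(atoms)


@pytest.fixture(scope="module")
def unit_charge_structure():
    return point_charges([([0.0, 0.0, 0.0], 1.0, 0.1)])


class TestGrid:
    def test_perfil_arithmetic(self):
        # extent 70 Å, perfil 70 -> edge >= 100 Å; scale 2 -> spacing 0.5 Å
        s = point_charges([([0, 0, 0], 0.0, 0.0), ([70, 0, 0], 0.0, 0.0)])
        g = es.build_grid(s, scale=2.0, perfil=70.0)
        assert g.spacing == pytest.approx(0.5)
        assert g.edge_lengths.min() >= 100.0
        assert all(n % 2 == 1 for n in g.shape)

    @pytest.mark.parametrize("scale,expected_h", [(2.0, 0.5), (1.0, 1.0),
                                                  (4.0, 0.25)])
    def test_spacing_is_inverse_scale(self, scale, expected_h,
                                      unit_charge_structure):
        g = es.build_grid(unit_charge_structure, scale=scale)
        assert g.spacing == pytest.approx(expected_h)

    def test_zero_extent_uses_minimum_edge(self, unit_charge_structure):
        g = es.build_grid(unit_charge_structure, min_edge=24.0)
        assert g.edge_lengths.min() >= 24.0

    def test_odd_node_counts_enforced(self):
        with pytest.raises(InvalidSpecError):
            es.GridSpec(origin=[0, 0, 0], spacing=0.5, shape=(10, 11, 11))


class TestDielectric:
    def test_node_inside_atom_gets_eps_in_kappa_zero(self):
        s = point_charges([([0.0, 0.0, 0.0], 1.0, 2.0)])
        g = es.build_grid(s, scale=2.0, min_edge=20)
        d = es.assign_dielectric_and_kappa(g, s)
        c = tuple(n // 2 for n in g.shape)
        assert d.node_eps[c] == pytest.approx(2.0)
        assert not d.ion_accessible[c]

    def test_far_node_gets_bulk_solvent(self):
        s = point_charges([([0.0, 0.0, 0.0], 1.0, 2.0)])
        g = es.build_grid(s, scale=1.0, min_edge=40)
        d = es.assign_dielectric_and_kappa(g, s)
        assert d.node_eps[0, 0, 0] == pytest.approx(80.0)
        assert d.ion_accessible[0, 0, 0]
        assert d.kappa > 0

    def test_debye_length_closed_form(self):
        # independent arrangement of the Debye-Hückel expression
        for I in (0.05, 0.15, 0.5):
            lam = np.sqrt(const.epsilon_0 * 80 * const.k * 298.15
                          / (2 * const.Avogadro * const.e ** 2 * I * 1000)) \
                * 1e10
            assert 1.0 / es.debye_kappa(I, 80, 298.15) == pytest.approx(
                lam, rel=1e-3)

    def test_missing_radii_rejected(self, unit_charge_structure):
        s = unit_charge_structure.copy()
        s.radius[:] = np.nan
        g = es.GridSpec(origin=[-10, -10, -10], spacing=1.0, shape=(21,) * 3)
        with pytest.raises(IncompleteStructureError):
            es.assign_dielectric_and_kappa(g, s)


class TestSolver:
    def test_zero_charges_zero_potential(self, unit_charge_structure):
        g = es.build_grid(unit_charge_structure, scale=1.0, min_edge=20)
        d = es.assign_dielectric_and_kappa(g, unit_charge_structure,
                                           eps_in=80, eps_out=80)
        pot = es.solve_lpbe(g, d, [[0.0, 0.0, 0.0]], [0.0])
        assert not pot.phi.any()

    def test_linearity_in_source_charge(self, unit_charge_structure):
        g = es.build_grid(unit_charge_structure, scale=1.0, min_edge=24)
        d = es.assign_dielectric_and_kappa(g, unit_charge_structure,
                                           eps_in=80, eps_out=80,
                                           ionic_strength=0.15)
        p1 = es.solve_lpbe(g, d, [[0.0, 0.0, 0.0]], [1.0])
        p2 = es.solve_lpbe(g, d, [[0.0, 0.0, 0.0]], [2.0])
        np.testing.assert_allclose(p2.phi, 2 * p1.phi, rtol=1e-4,
                                   atol=1e-6 * np.abs(p1.phi).max())

    def test_charge_outside_interior_rejected(self, unit_charge_structure):
        g = es.build_grid(unit_charge_structure, scale=1.0, min_edge=20)
        d = es.assign_dielectric_and_kappa(g, unit_charge_structure,
                                           eps_in=80, eps_out=80)
        with pytest.raises(InvalidSpecError):
            es.solve_lpbe(g, d, [[1e4, 0.0, 0.0]], [1.0])

    def test_refinement_improves_coulomb_shell(self, unit_charge_structure):
        """Halving h shrinks the far-shell error (monotone convergence)."""
        errors = []
        for scale in (1.0, 2.0):
            g = es.build_grid(unit_charge_structure, scale=scale, min_edge=24)
            d = es.assign_dielectric_and_kappa(g, unit_charge_structure,
                                               eps_in=80, eps_out=80,
                                               ionic_strength=0.0)
            pot = es.solve_lpbe(g, d, [[0.0, 0.0, 0.0]], [1.0])
            ax = g.axes()
            x, y, z = np.meshgrid(*ax, indexing="ij")
            r = np.sqrt(x * x + y * y + z * z)
            mask = (r >= 3.0) & (r <= 7.5)  # fixed physical shell, Å
            ana = es.coulomb_potential(1.0, r[mask], 80)
            errors.append(np.max(np.abs(pot.phi[mask] - ana) / np.abs(ana)))
        assert errors[1] < errors[0]
        assert errors[1] < 0.05


class TestField:
    def make_linear_potential(self, slope):
        g = es.GridSpec(origin=[-5, -5, -5], spacing=1.0, shape=(11, 11, 11))
        y = g.axes()[1]
        phi = np.broadcast_to(slope * y[None, :, None], g.shape).copy()
        return es.PotentialGrid(grid=g, phi=phi, iterations=0, residual=0.0)

    def test_uniform_potential_zero_field(self):
        pot = self.make_linear_potential(0.0)
        e = es.field_at([[0.3, 0.2, -0.7]], pot)
        np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_linear_potential_constant_field(self):
        pot = self.make_linear_potential(2.5)
        e = es.field_at([[0.0, 0.0, 0.0], [1.2, -2.3, 0.4]], pot)
        np.testing.assert_allclose(e, [[0.0, -2.5, 0.0]] * 2, atol=1e-10)

    def test_out_of_grid_query_rejected(self):
        pot = self.make_linear_potential(1.0)
        with pytest.raises(InvalidSelectionError):
            es.field_at([[0.0, 4.9, 0.0]], pot)


class TestForces:
    def test_newtons_third_law_in_homogeneous_solvent(self):
        s = point_charges([([0.0, 0.0, 0.0], 1.0, 0.1),
                           ([0.0, 12.0, 0.0], -1.0, 0.1)])
        s.groups = {"a": np.array([0]), "b": np.array([1])}
        kw = dict(scale=1.0, eps_in=80, eps_out=80, ionic_strength=0.15,
                  min_edge=30)
        f_ab = es.electrostatic_force(s, "a", "b", **kw).force
        f_ba = es.electrostatic_force(s, "b", "a", **kw).force
        assert np.linalg.norm(f_ab + f_ba) <= 1e-3 * np.linalg.norm(f_ab)

    def test_overlapping_groups_rejected(self):
        s = point_charges([([0.0, 0.0, 0.0], 1.0, 0.1),
                           ([0.0, 12.0, 0.0], -1.0, 0.1)])
        s.groups = {"a": np.array([0, 1]), "b": np.array([1])}
        with pytest.raises(InvalidSelectionError):
            es.electrostatic_force(s, "a", "b")

    def test_force_profile_single_snapshot_and_sign(self):
        # a force along -axis must be reported with negative F_perp
        s = point_charges([([0.0, 0.0, 0.0], -1.0, 0.1),
                           ([0.0, 15.0, 0.0], 1.0, 0.1)])
        s.groups = {"src": np.array([0]), "tgt": np.array([1])}
        prof = es.force_distance_profile(
            {15.0: [s]}, "src", "tgt", axis=(0, 1, 0),
            scale=1.0, eps_in=80, eps_out=80, ionic_strength=0.0,
            min_edge=40)
        assert prof.n_snapshots.tolist() == [1]
        assert prof.perpendicular[0] < 0  # attraction pulls toward source
        single = es.electrostatic_force(
            s, "src", "tgt", scale=1.0, eps_in=80, eps_out=80,
            ionic_strength=0.0, min_edge=40).force
        np.testing.assert_allclose(prof.mean_forces[0], single, atol=1e-12)

    def test_zero_distance_excluded_by_default(self):
        s = point_charges([([0.0, 0.0, 0.0], -1.0, 0.1),
                           ([0.0, 10.0, 0.0], 1.0, 0.1)])
        s.groups = {"src": np.array([0]), "tgt": np.array([1])}
        with pytest.raises(InvalidSpecError):
            es.force_distance_profile({0.0: [s]}, "src", "tgt")


def test_opendx_writer_round_trips_values(tmp_path):
    g = es.GridSpec(origin=[-2, -2, -2], spacing=1.0, shape=(5, 5, 5))
    phi = np.arange(125, dtype=float).reshape(5, 5, 5)
    pot = es.PotentialGrid(grid=g, phi=phi, iterations=1, residual=0.0)
    path = tmp_path / "pot.dx"
    es.write_opendx(pot, path)
    lines = path.read_text().splitlines()
    assert "object 1 class gridpositions counts 5 5 5" in lines[1]
    data = []
    for ln in lines:
        parts = ln.split()
        if parts and all(p.replace("e", "").replace("-", "").replace("+", "")
                         .replace(".", "").isdigit() for p in parts):
            data.extend(float(p) for p in parts)
    np.testing.assert_allclose(np.array(data).reshape(5, 5, 5), phi)
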