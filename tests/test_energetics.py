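"""MM/GBSA machinery: pairwise terms, Born radii, GB, SASA, composition
and per-residue decomposition, against closed forms and quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from bindscape import (
    AtomRecord,
    Selection,
    Topology,
    Trajectory,
    aggregate_components,
    coulomb_inter,
    gb_energy,
    hct_radii,
    lj_inter,
    mmgbsa,
    per_residue_decomposition,
    sasa,
    select,
)
from bindscape.constants import GB_KCAL, GB_OFFSET
from bindscape.energetics import GBSAParams, _hct_integral
from bindscape.errors import ClashError, ParameterError, ValidationError
from bindscape.synthetic import ToySpec, build_toy_complex, simulate_two_basin


def _atom(i, rid=None, **kw):
    defaults = dict(name=f"A{i}", residue_id=rid if rid is not None else i + 1,
                    residue_name="R", segment="protein", mass=12.0)
    defaults.update(kw)
    return AtomRecord(index=i, **defaults)


def _sel(*idx):
    return Selection(indices=tuple(idx))


class TestCoulomb:
    def test_zero_charges_zero_energy(self):
        top = Topology(atoms=[_atom(0, charge=0.0), _atom(1, charge=1.0)])
        c = np.array([[0.0, 0, 0], [3, 0, 0]])
        assert coulomb_inter(c, top, _sel(0), _sel(1)) == 0.0

    def test_unit_charges_at_scaled_distance(self):
        # 332.0716 / 3.320716 = 100 kcal/mol exactly
        top = Topology(atoms=[_atom(0, charge=1.0), _atom(1, charge=1.0)])
        c = np.array([[0.0, 0, 0], [3.320716, 0, 0]])
        assert coulomb_inter(c, top, _sel(0), _sel(1)) == pytest.approx(100.0)

    def test_sign_flips_with_charge(self):
        top_pp = Topology(atoms=[_atom(0, charge=0.7), _atom(1, charge=0.4)])
        top_pm = Topology(atoms=[_atom(0, charge=0.7), _atom(1, charge=-0.4)])
        c = np.array([[0.0, 0, 0], [2.5, 1, 0]])
        assert coulomb_inter(c, top_pp, _sel(0), _sel(1)) == pytest.approx(
            -coulomb_inter(c, top_pm, _sel(0), _sel(1)))

    def test_clash_names_pair(self):
        top = Topology(atoms=[_atom(0, charge=1.0), _atom(1, charge=1.0)])
        c = np.array([[0.0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(ClashError, match="0.*1"):
            coulomb_inter(c, top, _sel(0), _sel(1))


class TestLennardJones:
    def test_minimum_depth_at_rmin(self):
        top = Topology(atoms=[
            _atom(0, lj_rmin_half=1.9, lj_epsilon=0.12),
            _atom(1, lj_rmin_half=1.7, lj_epsilon=0.08),
        ])
        rmin = 1.9 + 1.7
        eps = np.sqrt(0.12 * 0.08)
        c = np.array([[0.0, 0, 0], [rmin, 0, 0]])
        assert lj_inter(c, top, _sel(0), _sel(1)) == pytest.approx(-eps)

    def test_double_rmin_direct_recomputation(self):
        top = Topology(atoms=[
            _atom(0, lj_rmin_half=1.9, lj_epsilon=0.12),
            _atom(1, lj_rmin_half=1.7, lj_epsilon=0.08),
        ])
        rmin = 3.6
        eps = np.sqrt(0.12 * 0.08)
        c = np.array([[0.0, 0, 0], [2 * rmin, 0, 0]])
        expected = eps * ((rmin / (2 * rmin)) ** 12 - 2 * (rmin / (2 * rmin)) ** 6)
        assert lj_inter(c, top, _sel(0), _sel(1)) == pytest.approx(expected)
        assert expected == pytest.approx(eps * (1 / 4096 - 2 / 64))

    def test_zero_epsilon_gives_zero(self):
        top = Topology(atoms=[
            _atom(0, lj_rmin_half=1.9, lj_epsilon=0.0),
            _atom(1, lj_rmin_half=1.7, lj_epsilon=0.08),
        ])
        c = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert lj_inter(c, top, _sel(0), _sel(1)) == 0.0


def hct_quadrature(r, rho, s):
    """Numerical descreening integral: (1/4pi) ∫ u^-4 over the scaled
    neighbor sphere minus the self sphere."""
    def shell_fraction(u):
        if u < s - r:
            return 1.0
        if abs(r - s) <= u <= r + s:
            return (s**2 - (r - u) ** 2) / (4 * r * u)
        return 0.0

    val, _ = integrate.quad(lambda u: shell_fraction(u) / u**2, rho, r + s,
                            limit=400)
    return val


class TestHctRadii:
    def _top2(self, rho1=1.5, rho2=1.6, s2=0.8):
        return Topology(atoms=[
            _atom(0, gb_radius=rho1, gb_screen=0.7),
            _atom(1, gb_radius=rho2, gb_screen=s2),
        ])

    def test_single_atom_reduced_radius(self):
        top = Topology(atoms=[_atom(0, gb_radius=1.7, gb_screen=0.8)])
        radii = hct_radii(np.zeros((1, 3)), top, _sel(0))
        assert radii[0] == pytest.approx(1.7 - GB_OFFSET)

    def test_distant_neighbor_limit(self):
        top = self._top2()
        c = np.array([[0.0, 0, 0], [4000.0, 0, 0]])
        radii = hct_radii(c, top, _sel(0, 1))
        assert radii[0] == pytest.approx(1.5 - GB_OFFSET, abs=1e-9)
        assert radii[1] == pytest.approx(1.6 - GB_OFFSET, abs=1e-9)

    @pytest.mark.parametrize("r", [4.0, 2.5, 1.2])
    def test_pair_integral_matches_quadrature(self, r):
        top = self._top2()
        c = np.array([[0.0, 0, 0], [r, 0, 0]])
        radii = hct_radii(c, top, _sel(0, 1))
        rho1 = 1.5 - GB_OFFSET
        s_j = (1.6 - GB_OFFSET) * 0.8
        expected_inv = 1.0 / rho1 - hct_quadrature(r, rho1, s_j)
        assert 1.0 / radii[0] == pytest.approx(expected_inv, abs=1e-4)

    def test_analytic_integral_matches_quadrature_engulfed(self):
        # self sphere entirely inside the scaled neighbor sphere
        h = _hct_integral(np.array([0.4]), 0.9, 2.0)[0]
        assert h == pytest.approx(hct_quadrature(0.4, 0.9, 2.0), abs=1e-8)

    def test_nonpositive_radius_rejected(self):
        top = Topology(atoms=[_atom(0, gb_radius=0.0, gb_screen=0.8)])
        with pytest.raises(ParameterError):
            hct_radii(np.zeros((1, 3)), top, _sel(0))


class TestGbEnergy:
    @pytest.mark.parametrize("q,R", [(1.0, 4.0), (-1.0, 2.0), (0.5, 1.5),
                                     (2.0, 3.3)])
    def test_born_ion_closed_form(self, q, R):
        top = Topology(atoms=[_atom(0, charge=q, gb_radius=R, gb_screen=0.8)])
        e = gb_energy(np.zeros((1, 3)), top, _sel(0), eps_in=1.0,
                      eps_out=78.5, radii=np.array([R]))
        expected = -GB_KCAL * (1 - 1 / 78.5) * q * q / R
        assert e == pytest.approx(expected, abs=1e-10)

    def test_all_zero_charges(self):
        top = Topology(atoms=[_atom(0, charge=0.0, gb_radius=1.5,
                                    gb_screen=0.8),
                              _atom(1, charge=0.0, gb_radius=1.5,
                                    gb_screen=0.8)])
        c = np.array([[0.0, 0, 0], [3, 0, 0]])
        assert gb_energy(c, top, _sel(0, 1), radii=np.array([1.5, 1.5])) == 0.0

    def test_two_charge_direct_formula(self):
        q1, q2, R1, R2, r = 0.6, -0.8, 1.4, 1.9, 3.2
        top = Topology(atoms=[
            _atom(0, charge=q1, gb_radius=R1, gb_screen=0.8),
            _atom(1, charge=q2, gb_radius=R2, gb_screen=0.8),
        ])
        c = np.array([[0.0, 0, 0], [r, 0, 0]])
        e = gb_energy(c, top, _sel(0, 1), eps_in=1.0, eps_out=78.5,
                      radii=np.array([R1, R2]))
        pref = -GB_KCAL * (1 - 1 / 78.5)
        fgb = np.sqrt(r**2 + R1 * R2 * np.exp(-(r**2) / (4 * R1 * R2)))
        direct = pref * (q1**2 / R1 + q2**2 / R2 + 2 * q1 * q2 / fgb)
        assert e == pytest.approx(direct, abs=1e-10)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        top = Topology(atoms=[_atom(0, lj_rmin_half=1.5)])
        areas = sasa(np.zeros((1, 3)), top, _sel(0), probe_radius=1.4,
                     n_sphere_points=960)
        expected = 4 * np.pi * (1.5 + 1.4) ** 2
        assert expected == pytest.approx(105.68, abs=0.01)
        assert areas[0] == pytest.approx(expected, rel=0.01)

    def test_coincident_atoms_equal_one_sphere(self):
        top = Topology(atoms=[_atom(0, lj_rmin_half=1.5),
                              _atom(1, lj_rmin_half=1.5)])
        c = np.zeros((2, 3))
        total = sasa(c, top, _sel(0, 1), 1.4, 960).sum()
        assert total == pytest.approx(4 * np.pi * 2.9**2, rel=0.01)

    def test_buried_atom_is_zero(self):
        # central atom caged by six tight neighbors
        atoms = [_atom(0, lj_rmin_half=1.5)]
        coords = [[0.0, 0, 0]]
        for k, v in enumerate([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)]):
            atoms.append(_atom(k + 1, lj_rmin_half=2.5))
            coords.append([2.0 * x for x in v])
        top = Topology(atoms=atoms)
        areas = sasa(np.array(coords), top,
                     Selection(indices=tuple(range(7))), 1.4, 500)
        assert areas[0] == 0.0

    def test_too_few_points_rejected(self):
        top = Topology(atoms=[_atom(0, lj_rmin_half=1.5)])
        with pytest.raises(ParameterError):
            sasa(np.zeros((1, 3)), top, _sel(0), 1.4, 12)


@pytest.fixture()
def toy_system():
    spec = ToySpec(seed=5, n_frames=30)
    trajectory, _, _ = simulate_two_basin(spec)
    topology, _, _ = build_toy_complex(spec)
    receptor = select(topology, "segment:protein")
    ligand = select(topology, "segment:ligand")
    return trajectory, topology, receptor, ligand


class TestMmgbsa:
    def test_component_identities_hold_per_frame(self, toy_system):
        trajectory, topology, receptor, ligand = toy_system
        comps = mmgbsa(trajectory, topology, receptor, ligand)
        np.testing.assert_allclose(comps.gas, comps.vdw + comps.eel, atol=1e-10)
        np.testing.assert_allclose(comps.solv, comps.gb + comps.surf, atol=1e-10)
        np.testing.assert_allclose(comps.total, comps.gas + comps.solv, atol=1e-10)

    def test_separated_complex_all_components_vanish(self, toy_system):
        trajectory, topology, receptor, ligand = toy_system
        coords = trajectory.coordinates[:1].copy()
        coords[0, ligand.as_array()] += np.array([500.0, 0, 0])
        far = Trajectory(coords, 1.0)
        comps = mmgbsa(far, topology, receptor, ligand)
        for name in ("vdw", "eel", "gb", "surf", "gas", "solv", "total"):
            assert abs(comps.mean()[name]) <= 1e-3

    def test_single_frame_sd_zero(self, toy_system):
        trajectory, topology, receptor, ligand = toy_system
        comps = mmgbsa(trajectory, topology, receptor, ligand,
                       frame_window=(0, 1))
        assert all(v == 0.0 for v in comps.sd().values())

    def test_composition_matches_manual_stage_outputs(self, toy_system):
        from bindscape.energetics import _union_selection

        trajectory, topology, receptor, ligand = toy_system
        params = GBSAParams()
        comps = mmgbsa(trajectory, topology, receptor, ligand,
                       frame_window=(3, 4), params=params)
        coords = trajectory.coordinates[3]
        cx = _union_selection(receptor, ligand)
        vdw = lj_inter(coords, topology, receptor, ligand)
        eel = coulomb_inter(coords, topology, receptor, ligand, params.eps_in)
        gb_parts, sa_parts = {}, {}
        for name, grp in (("c", cx), ("r", receptor), ("l", ligand)):
            radii = hct_radii(coords, topology, grp)
            gb_parts[name] = gb_energy(coords, topology, grp, params.eps_in,
                                       params.eps_out, radii)
            sa_parts[name] = sasa(coords, topology, grp, params.probe_radius,
                                  params.n_sphere_points).sum()
        gb = gb_parts["c"] - gb_parts["r"] - gb_parts["l"]
        surf = params.surf_gamma * (sa_parts["c"] - sa_parts["r"] - sa_parts["l"])
        assert comps.vdw[0] == pytest.approx(vdw, abs=1e-8)
        assert comps.eel[0] == pytest.approx(eel, abs=1e-8)
        assert comps.gb[0] == pytest.approx(gb, abs=1e-8)
        assert comps.surf[0] == pytest.approx(surf, abs=1e-8)
        assert comps.total[0] == pytest.approx(vdw + eel + gb + surf, abs=1e-8)


class TestDecomposition:
    def test_sums_to_total_binding_energy(self, toy_system):
        trajectory, topology, receptor, ligand = toy_system
        window = (0, 10)
        comps = mmgbsa(trajectory, topology, receptor, ligand, window)
        decomp = per_residue_decomposition(trajectory, topology, receptor,
                                           ligand, window)
        np.testing.assert_allclose(decomp.totals_per_frame(), comps.total,
                                   atol=1e-6)

    def test_uncharged_residue_has_zero_mm_parts(self):
        atoms = [
            _atom(0, rid=1, charge=0.5, lj_rmin_half=1.8, lj_epsilon=0.1,
                  gb_radius=1.6, gb_screen=0.8),
            _atom(1, rid=2, charge=0.0, lj_rmin_half=0.0, lj_epsilon=0.0,
                  gb_radius=1.6, gb_screen=0.8),
            _atom(2, rid=3, charge=-0.5, lj_rmin_half=1.7, lj_epsilon=0.1,
                  gb_radius=1.5, gb_screen=0.8, segment="ligand",
                  residue_name="LIG"),
        ]
        top = Topology(atoms=atoms)
        coords = np.array([[[0.0, 0, 0], [4, 0, 0], [0, 4, 0]]])
        traj = Trajectory(coords, 1.0)
        decomp = per_residue_decomposition(traj, top, _sel(0, 1), _sel(2))
        parts = decomp.residues[("protein", 2, "R")]
        assert parts["eel"][0] == 0.0
        assert parts["vdw"][0] == 0.0

    def test_doubling_residue_charges_doubles_its_eel_share(self, toy_system):
        import dataclasses

        trajectory, topology, receptor, ligand = toy_system
        window = (0, 2)
        d1 = per_residue_decomposition(trajectory, topology, receptor,
                                       ligand, window)
        key = ("protein", 3, "ALA")
        res = next(r for r in topology.residues if r[0] == "protein" and r[1] == 3)
        atoms = list(topology.atoms)
        for i in range(res[3], res[4]):
            atoms[i] = dataclasses.replace(atoms[i], charge=2 * atoms[i].charge)
        top2 = Topology(atoms=atoms)
        d2 = per_residue_decomposition(trajectory, top2, receptor, ligand,
                                       window)
        np.testing.assert_allclose(d2.residues[key]["eel"],
                                   2 * d1.residues[key]["eel"], atol=1e-10)
        other = ("protein", 7, "ALA")
        np.testing.assert_allclose(d2.residues[other]["eel"],
                                   d1.residues[other]["eel"], atol=1e-10)


class TestAggregateComponents:
    # printed per-component values and their printed sums for several
    # systems of the study this package's workflow reproduces
    @pytest.mark.parametrize("vdw,eel,gb,surf,gas,solv,total", [
        (-47.91, -36.47, 50.08, -4.22, -84.38, 45.86, -38.52),
        (-54.29, -38.30, 49.66, -4.33, -92.59, 45.33, -47.26),
        (-44.42, -40.14, 52.63, -3.59, -84.56, 49.04, -35.52),
        (-35.05, -21.31, 29.45, -2.87, -56.36, 26.58, -29.78),
        (-35.17, -24.76, 30.68, -3.12, -59.93, 27.56, -32.37),
        # for this system the printed total (-38.36) reflects rounding of
        # the unrounded components; the re-added printed values give
        # -38.35, so only the gas/solv sums are checked
        (-44.87, -28.63, 38.87, -3.72, -73.50, 35.15, None),
    ])
    def test_reproduces_printed_sums(self, vdw, eel, gb, surf, gas, solv, total):
        comps = aggregate_components(vdw, eel, gb, surf)
        assert comps.gas[0] == pytest.approx(gas, abs=5e-3)
        assert comps.solv[0] == pytest.approx(solv, abs=5e-3)
        if total is not None:
            assert comps.total[0] == pytest.approx(total, abs=5e-3)

    def test_zeros(self):
        comps = aggregate_components(0.0, 0.0, 0.0, 0.0)
        assert comps.total[0] == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=8),
           st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100))
    def test_identities_for_arbitrary_inputs(self, vdw, eel, gb, surf):
        n = len(vdw)
        comps = aggregate_components(np.array(vdw), np.full(n, eel),
                                     np.full(n, gb), np.full(n, surf))
        np.testing.assert_allclose(comps.gas, comps.vdw + comps.eel, atol=0)
        np.testing.assert_allclose(comps.total, comps.gas + comps.solv, atol=0)
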