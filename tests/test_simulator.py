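"""Energies, forces, integrator and statistical-mechanics checks."""

import math

import numpy as np
import pytest
from scipy import stats

from gosbm.simulator import (
    SimParams,
    SimulationError,
    compute_energy,
    compute_forces,
    contact_potential,
    dihedral_potential,
    reduced_to_mdp_temperature,
    run_langevin,
)
from gosbm.structure_io import make_fixture
from gosbm.topology_builder import ContactForm, assemble_topology


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------


class TestDihedralPotential:
    def test_anchor_values(self):
        assert dihedral_potential(0.0) == 0.0
        assert dihedral_potential(math.pi) == pytest.approx(3.0, abs=1e-12)

    def test_global_minimum_on_fine_grid(self):
        grid = np.arange(-math.pi, math.pi, 1e-4)
        v = dihedral_potential(grid)
        k = int(np.argmin(v))
        assert abs(grid[k]) < 1e-4
        assert v[k] == pytest.approx(0.0, abs=1e-7)
        assert np.all(v >= -1e-12)


class TestContactPotential:
    def test_minimum_at_native_distance(self):
        assert contact_potential(0.5, 0.5, 1.0) == pytest.approx(-1.0, abs=1e-14)
        grid = np.linspace(0.3, 1.5, 2_000_001)
        v = contact_potential(grid, 0.5, 1.0)
        k = int(np.argmin(v))
        assert grid[k] == pytest.approx(0.5, abs=1e-6)
        assert v[k] == pytest.approx(-1.0, abs=1e-10)

    def test_monotone_decay_beyond_minimum(self):
        r = np.linspace(0.5, 50.0, 1000)
        v = contact_potential(r, 0.5, 1.0)
        assert np.all(np.diff(v) > 0)
        assert v[-1] == pytest.approx(0.0, abs=1e-10)

    def test_derivative_vanishes_at_minimum(self):
        h = 1e-7
        d = (contact_potential(0.5 + h, 0.5) - contact_potential(0.5 - h, 0.5)) / (2 * h)
        assert abs(d) < 1e-6

    def test_gaussian_and_harmonic_forms(self):
        assert contact_potential(0.5, 0.5, 2.0, ContactForm.GAUSSIAN) == pytest.approx(-2.0)
        assert contact_potential(0.6, 0.5, 100.0, ContactForm.HARMONIC) == pytest.approx(0.5)

    def test_zero_distance_guarded(self):
        with pytest.raises(SimulationError):
            contact_potential(0.0, 0.5)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


def _naive_energy(top, xyz):
    """Slow term-by-term reference implementation (plain loops)."""
    from gosbm.topology_builder import measure_angle, measure_dihedral

    e_b = sum(
        0.5 * b.eps * (np.linalg.norm(xyz[b.j] - xyz[b.i]) - b.r0) ** 2
        for b in top.bonds
    )
    e_a = sum(
        0.5 * a.eps * (measure_angle(xyz, a.i, a.j, a.k) - a.theta0) ** 2
        for a in top.angles
    )
    e_d = 0.0
    for d in top.dihedrals:
        dphi = measure_dihedral(xyz, d.i, d.j, d.k, d.l) - d.phi0
        e_d += d.eps * ((1 - math.cos(dphi)) + 0.5 * (1 - math.cos(3 * dphi)))
    e_c = sum(
        contact_potential(np.linalg.norm(xyz[c.j] - xyz[c.i]), c.r0, c.eps,
                          c.form, c.width)
        for c in top.contacts
    )
    c12 = top.atom_c12()
    e_x = 0.0
    for i in range(top.n_atoms):
        for j in range(i + 1, top.n_atoms):
            if (i, j) in top.exclusions:
                continue
            r = np.linalg.norm(xyz[j] - xyz[i])
            e_x += math.sqrt(c12[i] * c12[j]) / r**12
    return e_b, e_a, e_d, e_c, e_x


def test_energy_matches_naive_loop_oracle(ci2_cg, rng):
    top = ci2_cg["topology"]
    native = ci2_cg["structure"].coords()
    for _ in range(3):
        xyz = native + 0.03 * rng.standard_normal(native.shape)
        e = compute_energy(top, xyz)
        ref = _naive_energy(top, xyz)
        for got, want in zip(e.as_tuple()[:5], ref):
            assert got == pytest.approx(want, abs=1e-10, rel=1e-10)
        assert e.total == pytest.approx(sum(ref), rel=1e-12)


def test_native_coordinates_minimize_structure_derived_terms(ci2_cg, helix_topology, helix10):
    """The '?' parameterization pins every term's minimum at the native
    geometry: zero bonded energies, contact energy exactly -sum(eps_C)."""
    for top, xyz in (
        (ci2_cg["topology"], ci2_cg["structure"].coords()),
        (helix_topology, helix10.coords()),
    ):
        e = compute_energy(top, xyz)
        assert e.bonds == pytest.approx(0.0, abs=1e-20)
        assert e.angles == pytest.approx(0.0, abs=1e-20)
        assert e.dihedrals == pytest.approx(0.0, abs=1e-20)
        assert e.contacts == pytest.approx(-sum(c.eps for c in top.contacts),
                                           abs=1e-9)


def test_two_isolated_atoms_at_sigma(ca_templates):
    from gosbm.structure_io import Atom, Structure

    atoms = [
        Atom(1, "CA", "GLY", 1, "A", np.zeros(3)),
        Atom(2, "CA", "GLY", 30, "B", np.array([0.0, 0.0, 0.4])),
    ]
    st = Structure(atoms=atoms, chain_breaks=[1])
    top = assemble_topology(st, ca_templates)
    assert len(top.bonds) == 0
    e = compute_energy(top, st.coords())
    assert e.excluded == pytest.approx(top.settings.epsilon_nc)  # (sigma/r)^12 = 1


def test_shape_mismatch_rejected(helix_topology):
    with pytest.raises(SimulationError, match="shape"):
        compute_energy(helix_topology, np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def test_forces_match_central_differences(ci2_cg, rng):
    top = ci2_cg["topology"]
    xyz = ci2_cg["structure"].coords() + 0.03 * rng.standard_normal((64, 3))
    f = compute_forces(top, xyz)
    h = 1e-6
    fd = np.zeros_like(f)
    for a in range(top.n_atoms):
        for d in range(3):
            xp = xyz.copy(); xp[a, d] += h
            xm = xyz.copy(); xm[a, d] -= h
            fd[a, d] = -(compute_energy(top, xp).total
                         - compute_energy(top, xm).total) / (2 * h)
    assert np.abs(f - fd).max() / np.abs(fd).max() < 1e-6


def test_net_force_and_torque_vanish(ci2_cg, rng):
    top = ci2_cg["topology"]
    for _ in range(3):
        xyz = ci2_cg["structure"].coords() + 0.05 * rng.standard_normal((64, 3))
        f = compute_forces(top, xyz)
        assert np.abs(f.sum(axis=0)).max() < 1e-9
        torque = np.cross(xyz, f).sum(axis=0)
        assert np.abs(torque).max() < 1e-9


def test_stretched_bond_force_is_analytic(ca_templates):
    st = make_fixture("dimer")
    top = assemble_topology(st, ca_templates)
    delta = 0.01
    xyz = st.coords().copy()
    xyz[1, 2] += delta
    f = compute_forces(top, xyz)
    assert np.linalg.norm(f[0]) == pytest.approx(20000.0 * delta, rel=1e-12)
    assert np.linalg.norm(f[1]) == pytest.approx(20000.0 * delta, rel=1e-12)


def test_jit_kernel_agrees_with_reference_forces(ci2_cg, rng):
    from gosbm.simulator import _forces_kernel, _neighbor_pairs, _pack

    top = ci2_cg["topology"]
    p = _pack(top)
    xyz = ci2_cg["structure"].coords() + 0.05 * rng.standard_normal((64, 3))
    nb_i, nb_j, nb_c12 = _neighbor_pairs(p, xyz, 1e3, 0.0)
    f = np.zeros_like(xyz)
    _forces_kernel(
        xyz, f,
        p.bond_i, p.bond_j, p.bond_r0, p.bond_k,
        p.ang_i, p.ang_j, p.ang_k, p.ang_t0, p.ang_eps,
        p.dih_i, p.dih_j, p.dih_k, p.dih_l, p.dih_phi0, p.dih_eps,
        p.con_i, p.con_j, p.con_r0, p.con_eps, p.con_form, p.con_width,
        nb_i, nb_j, nb_c12, 1e6,
    )
    ref = compute_forces(top, xyz)
    assert np.abs(f - ref).max() < 1e-9


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def test_nve_energy_drift_on_dimer(ca_templates):
    """gamma = 0, T = 0 reduces BAOAB to velocity Verlet: total energy of a
    slightly stretched dimer is conserved to < 1e-6 eps over 1e5 steps."""
    st = make_fixture("dimer")
    top = assemble_topology(st, ca_templates)
    xyz = st.coords().copy()
    xyz[1, 2] += 0.001  # small stretch: E = eps_b/2 * delta^2 = 0.01 eps
    params = SimParams(n_steps=100_000, dt=1e-4, temperature=0.0, friction=0.0,
                       save_every=1000, seed=0)
    traj = run_langevin(top, xyz, params)
    total = np.array([e.total for e in traj.energies]) + traj.kinetic
    assert np.abs(total - total[0]).max() < 1e-6


def test_equipartition_of_a_single_bond(ca_templates):
    """<(r - r0)^2> at T = 1 equals k_B T / eps_b = 1/20000 within 5%."""
    st = make_fixture("dimer")
    top = assemble_topology(st, ca_templates)
    params = SimParams(n_steps=4_000_000, dt=2e-4, temperature=1.0,
                       friction=10.0, save_every=200, seed=42,
                       compute_energies=False)
    traj = run_langevin(top, st.coords(), params)
    burn = traj.n_frames // 10
    r = np.linalg.norm(traj.frames[burn:, 1] - traj.frames[burn:, 0], axis=1)
    msd = float(np.mean((r - 0.38) ** 2))
    assert msd == pytest.approx(1.0 / 20000.0, rel=0.05)


def test_same_seed_is_bit_identical(ci2_cg):
    top = ci2_cg["topology"]
    x0 = ci2_cg["structure"].coords()
    params = SimParams(n_steps=20_000, save_every=2000, temperature=1.1, seed=9,
                       compute_energies=False)
    a = run_langevin(top, x0, params)
    b = run_langevin(top, x0, params)
    assert np.array_equal(a.frames, b.frames)


def test_neighbor_list_misses_no_pairs(ci2_cg):
    """Stochastic audit: an oversized skin makes the pair list effectively
    exhaustive; with the cutoff applied inside the kernel, a correct
    displacement trigger must give bit-identical trajectories."""
    top = ci2_cg["topology"]
    x0 = ci2_cg["structure"].coords()
    common = dict(n_steps=50_000, save_every=5000, temperature=1.3, seed=17,
                  compute_energies=False)
    tight = run_langevin(top, x0, SimParams(nb_skin=0.3, **common))
    loose = run_langevin(top, x0, SimParams(nb_skin=2.0, **common))
    assert np.array_equal(tight.frames, loose.frames)


def test_blowup_aborts_with_diagnostics(ca_templates):
    st = make_fixture("dimer")
    top = assemble_topology(st, ca_templates)
    params = SimParams(n_steps=10_000, dt=0.5, temperature=1.0, seed=0,
                       compute_energies=False)
    with pytest.raises(SimulationError, match="blow-up"):
        run_langevin(top, st.coords(), params)


def test_boltzmann_bond_length_distribution(ca_templates):
    """Detailed-balance smoke test: dimer bond lengths follow
    p(r) ~ r^2 exp(-V(r)/kT) (KS test at alpha = 0.01)."""
    st = make_fixture("dimer")
    top = assemble_topology(st, ca_templates)
    params = SimParams(n_steps=2_000_000, dt=2e-4, temperature=1.0,
                       friction=10.0, save_every=2000, seed=7,
                       compute_energies=False)
    traj = run_langevin(top, st.coords(), params)
    burn = traj.n_frames // 10
    r = np.linalg.norm(traj.frames[burn:, 1] - traj.frames[burn:, 0], axis=1)

    grid = np.linspace(0.38 - 0.05, 0.38 + 0.05, 4001)
    pdf = grid**2 * np.exp(-0.5 * 20000.0 * (grid - 0.38) ** 2)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    result = stats.kstest(r, lambda x: np.interp(x, grid, cdf))
    assert result.pvalue > 0.01


# ---------------------------------------------------------------------------
# unit mapping
# ---------------------------------------------------------------------------


class TestMdpTemperature:
    def test_printed_figure_values(self):
        assert reduced_to_mdp_temperature(1.17) == pytest.approx(140.7, abs=0.05)
        assert reduced_to_mdp_temperature(0.97) == pytest.approx(116.7, abs=0.05)

    def test_zero_and_negative(self):
        assert reduced_to_mdp_temperature(0.0) == 0.0
        with pytest.raises(SimulationError):
            reduced_to_mdp_temperature(-0.1)
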