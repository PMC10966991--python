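"""Potential-energy terms: analytic limits, finite differences, invariances."""

import numpy as np
import pytest

from diffmd import autodiff as ad
from diffmd import energetics as en
from diffmd import forcefield as ff
from diffmd import topology as topo


@pytest.fixture(scope="module")
def two_atoms(registry):
    vec, reg = registry

    def make(types, sep, charges=(0.0, 0.0)):
        s = topo.system_from_bond_graph(
            list(types), [], np.array([[0.0, 0, 0], [sep, 0, 0]]), reg,
            charges=np.array(charges))
        return ff.apply_parameter_vector(vec, s)

    return make


def test_lj_zero_at_sigma_and_minimum(two_atoms, registry):
    vec, _ = registry
    sig = vec.values[vec.index("lj_sigma:CT")]
    eps = vec.values[vec.index("lj_epsilon:CT")]
    s = two_atoms(("CT", "CT"), sig)
    assert float(ad.val(en.lennard_jones_energy(s))) == pytest.approx(0.0,
                                                                      abs=1e-9)
    s = two_atoms(("CT", "CT"), sig * 2 ** (1 / 6))
    assert float(ad.val(en.lennard_jones_energy(s))) == pytest.approx(-eps,
                                                                      rel=1e-9)


def test_lj_combining_rule(two_atoms, registry):
    vec, _ = registry
    s1 = vec.values[vec.index("lj_sigma:CT")]
    s2 = vec.values[vec.index("lj_sigma:N")]
    e1 = vec.values[vec.index("lj_epsilon:CT")]
    e2 = vec.values[vec.index("lj_epsilon:N")]
    sig_mix = 0.5 * (s1 + s2)
    s = two_atoms(("CT", "N"), sig_mix * 2 ** (1 / 6))
    assert float(ad.val(en.lennard_jones_energy(s))) == pytest.approx(
        -np.sqrt(e1 * e2), rel=1e-6)


def test_coulomb_unit_charges_at_1nm(two_atoms):
    s = two_atoms(("N3", "O2"), 1.0, charges=(1.0, -1.0))
    e = en.coulomb_energy(s, charges=np.array([1.0, -1.0]))
    assert float(ad.val(e)) == pytest.approx(-138.935458, rel=1e-9)
    # neutral pair contributes nothing
    s0 = two_atoms(("CT", "CT"), 0.5)
    assert float(ad.val(en.coulomb_energy(s0))) == pytest.approx(0.0,
                                                                 abs=1e-12)


def test_single_ion_born_limit(registry):
    """Polar energy of an isolated ion reduces to the Born formula at
    kappa = 0 (acceptance: exact analytic limit)."""
    vec, reg = registry
    s = topo.system_from_bond_graph(["N3"], [], np.zeros((1, 3)), reg,
                                    charges=np.array([1.0]))
    s = ff.apply_parameter_vector(vec, s)
    r_born = 0.15
    e = en.gb_energy(s, np.array([r_born]), charges=np.array([1.0]),
                     kappa=0.0)
    expected = -138.935458 * (1 - 1 / 78.5) / (2 * r_born)
    assert float(ad.val(e)) == pytest.approx(expected, rel=1e-6)


def test_born_radii_isolated_and_monotonic(two_atoms, registry):
    vec, _ = registry
    rho = vec.values[vec.index("gb_radius:C")]
    offset = vec.values[vec.index("gb_global:offset")]
    s = two_atoms(("CT", "CT"), 50.0)
    radii, rho_red, _ = en.born_radii(s, np.array([[0.0, 0, 0], [50.0, 0, 0]]))
    assert ad.val(radii)[0] == pytest.approx(rho - offset, rel=1e-6)
    # monotone burial is a property of the bare descreening integral; the
    # neck correction is a peaked function of separation by construction
    v = ff.build_default_registry()[0].values.copy()
    v[np.argmax([n == "gb_global:neck_scale"
                 for n in ff.build_default_registry()[0].names])] = 0.0
    tb = en.pair_tables(s, ff.unpack(v), np.float64)
    prev = None
    for sep in (3.0, 1.5, 0.8, 0.5, 0.35, 0.3):
        radii, _, _ = en.born_radii(s, np.array([[0.0, 0, 0], [sep, 0, 0]]),
                                    tables=tb)
        r0 = float(ad.val(radii)[0])
        if prev is not None:
            assert r0 >= prev - 1e-12  # burial only increases the radius
        prev = r0
    assert prev > rho - offset


def test_born_radii_vs_quadrature_oracle(registry):
    """Effective radii agree with direct numerical quadrature of the
    descreening integral (Coulomb-field approximation) within 15%."""
    vec, reg = registry
    rng = np.random.default_rng(4)
    coords = rng.normal(scale=0.12, size=(5, 3))
    coords -= coords.mean(axis=0)
    s = topo.system_from_bond_graph(["CT", "CT", "N", "O", "CT"], [],
                                    coords, reg, charges=np.zeros(5))
    s = ff.apply_parameter_vector(vec, s)
    # suppress the neck surrogate: the oracle integrates the bare CFA kernel
    v = vec.values.copy()
    v[vec.index("gb_global:neck_scale")] = 0.0
    up = ff.unpack(v)
    tb = en.pair_tables(s, up, np.float64)
    radii = ad.val(en.born_radii(s, coords, tables=tb)[0])
    rho = ad.val(tb.rho)
    rho_red = ad.val(tb.rho_red)
    screen = up.gb_screen
    obc = up.gb_obc
    rng2 = np.random.default_rng(0)
    for i in range(5):
        # Monte-Carlo volume quadrature of sum_j (1/4pi) int_sphere_j r^-4 dV
        integral = 0.0
        for j in range(5):
            if j == i:
                continue
            sj = screen[s.elem_idx[j]] * rho_red[j]
            n_mc = 200000
            pts = rng2.normal(size=(n_mc, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            pts *= sj * rng2.random(n_mc)[:, None] ** (1 / 3)
            pts += coords[j]
            r4 = np.sum((pts - coords[i]) ** 2, axis=1) ** 2
            inside_core = r4 < rho_red[i] ** 4
            vol = 4 / 3 * np.pi * sj ** 3
            integral += vol * np.mean(
                np.where(inside_core, 0.0, 1.0 / r4)) / (4 * np.pi)
        psi = integral * rho_red[i]
        a_, b_, g_ = obc[s.elem_idx[i]]
        inner = a_ * psi - b_ * psi ** 2 + g_ * psi ** 3
        b_oracle = 1.0 / (1.0 / rho_red[i] - np.tanh(inner) / rho[i])
        assert radii[i] == pytest.approx(b_oracle, rel=0.15)


def test_surface_area_term(registry):
    vec, reg = registry
    s = topo.system_from_bond_graph(["CT"], [], np.zeros((1, 3)), reg)
    s = ff.apply_parameter_vector(vec, s)
    rho = vec.values[vec.index("gb_radius:C")]
    probe = vec.values[vec.index("gb_global:probe_radius")]
    offset = vec.values[vec.index("gb_global:offset")]
    factor = vec.values[vec.index("gb_global:surface_area_factor")]
    radii = np.array([rho - offset])  # fully exposed
    e = en.surface_area_energy(s, radii)
    assert float(ad.val(e)) == pytest.approx(
        factor * 4 * np.pi * (rho + probe) ** 2, rel=1e-9)
    # deeply buried atom contributes ~nothing
    e2 = en.surface_area_energy(s, np.array([10.0 * (rho - offset)]))
    assert float(ad.val(e2)) < 1e-5 * float(ad.val(e))
    # zero factor kills the term
    v = vec.values.copy()
    v[vec.index("gb_global:surface_area_factor")] = 0.0
    e3 = en.surface_area_energy(s, radii,
                                tables=en.pair_tables(s, ff.unpack(v)))
    assert float(ad.val(e3)) == 0.0


def test_torsion_cosine_extrema(registry):
    vec, reg = registry
    # 4-atom chain with a single torsion; check E(phi) at the extrema of
    # the k(1+cos(n phi - delta)) form via direct geometry
    coords = np.array([[0.0, 0.1, 0], [0, 0, 0], [0.15, 0, 0],
                       [0.15, 0.1, 0]])  # cis, phi = 0
    s = topo.system_from_bond_graph(["HC", "C8", "C9", "HC"],
                                    [(0, 1), (1, 2), (2, 3)], coords, reg)
    s = ff.apply_parameter_vector(vec, s)
    s.bond_k = s.bond_k * 0
    s.angle_k = s.angle_k * 0
    e_cis = float(ad.val(en.bonded_energy(s)[2]))
    coords_trans = coords.copy()
    coords_trans[3] = [0.15, -0.1, 0]  # phi = pi
    e_trans = float(ad.val(en.bonded_energy(s, coords_trans)[2]))
    # terms for this key: n=1 k=0.25 delta=0; n=3 k=0.65 delta=0
    assert e_cis == pytest.approx(2 * (0.25 + 0.65), rel=1e-6)
    assert e_trans == pytest.approx(0.0, abs=1e-9)


def test_forces_match_finite_differences(pentapeptide):
    rng = np.random.default_rng(1)
    x = pentapeptide.coordinates + rng.normal(scale=0.004,
                                              size=pentapeptide.coordinates.shape)
    force, e0 = en.forces(pentapeptide, x)
    h = 1e-6
    for _ in range(12):
        i = rng.integers(pentapeptide.n_atoms)
        d = rng.integers(3)
        step = np.zeros_like(x)
        step[i, d] = h
        ep = float(ad.val(en.total_potential(pentapeptide, x + step).total))
        em = float(ad.val(en.total_potential(pentapeptide, x - step).total))
        fd = -(ep - em) / (2 * h)
        assert force[i, d] == pytest.approx(fd, rel=1e-5, abs=1e-4)


def test_analytic_force_equals_ad_force(pentapeptide):
    """The hand-assembled force matches the energy-gradient force exactly."""
    rng = np.random.default_rng(5)
    up = pentapeptide.params
    tb = en.pair_tables(pentapeptide, up, np.float64)
    for _ in range(3):
        x = pentapeptide.coordinates + rng.normal(
            scale=0.01, size=pentapeptide.coordinates.shape)
        f_ad, _ = en.forces(pentapeptide, x, up, tables=tb)
        f_an = ad.val(en.force_analytic(pentapeptide, x, tb))
        assert np.allclose(f_an, f_ad, rtol=1e-12, atol=1e-9)


def test_rigid_motion_invariance(pentapeptide):
    rng = np.random.default_rng(2)
    x = pentapeptide.coordinates
    e0 = float(ad.val(en.total_potential(pentapeptide, x).total))
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    e1 = float(ad.val(en.total_potential(
        pentapeptide, x @ q.T + np.array([1.0, -2.0, 0.5])).total))
    assert e1 == pytest.approx(e0, rel=1e-8)
    f, _ = en.forces(pentapeptide, x)
    assert np.linalg.norm(f.sum(axis=0)) < 1e-6 * np.abs(f).max()


def test_parameter_gradients_match_fd(ethane):
    vec, _ = ff.build_default_registry()
    x = ethane.coordinates
    vv = ad.Var(vec.values.copy())
    e = en.total_potential(ethane, x, ff.unpack(vv)).total
    (g,) = ad.grad(e, [vv])
    for i in range(108):
        scale = max(abs(vec.values[i]), 1e-3)
        h = 1e-4 * scale
        vp = vec.values.copy(); vp[i] += h
        vm = vec.values.copy(); vm[i] -= h
        ep = float(ad.val(en.total_potential(ethane, x, ff.unpack(vp)).total))
        em = float(ad.val(en.total_potential(ethane, x, ff.unpack(vm)).total))
        fd = (ep - em) / (2 * h)
        if abs(fd) < 1e-9 and abs(g[i]) < 1e-9:
            continue
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-8), vec.names[i]


def test_screening_monotonicity(registry):
    """A solvent-exposed charge is better solvated than the same charge with
    an artificially enlarged Born radius."""
    vec, reg = registry
    s = topo.system_from_bond_graph(["O2"], [], np.zeros((1, 3)), reg,
                                    charges=np.array([-1.0]))
    s = ff.apply_parameter_vector(vec, s)
    e_small = float(ad.val(en.gb_energy(s, np.array([0.15]),
                                        charges=np.array([-1.0]))))
    e_large = float(ad.val(en.gb_energy(s, np.array([0.60]),
                                        charges=np.array([-1.0]))))
    assert e_small < e_large < 0


def test_singular_geometry_error(two_atoms):
    s = two_atoms(("CT", "CT"), 0.4)
    bad = np.zeros((2, 3))
    with pytest.raises(en.SingularGeometryError):
        en.lennard_jones_energy(s, bad)


def test_energy_breakdown_totals(pentapeptide):
    bd = en.total_potential(pentapeptide)
    d = bd.as_floats()
    assert d["total"] == pytest.approx(
        sum(d[k] for k in d if k != "total"), rel=1e-12)
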