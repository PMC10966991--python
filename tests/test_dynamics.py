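"""Integrator, checkpointing and gradient propagation."""

import numpy as np
import pytest

from diffmd import autodiff as ad
from diffmd import dynamics as dyn
from diffmd import energetics as en
from diffmd import forcefield as ff
from diffmd import loss as ls
from diffmd import synthetic as syn
from diffmd import topology as topo
from diffmd.energetics import KB


def test_minimize_descends_and_converges(registry):
    vec, reg = registry
    # stretched harmonic bond converges to its rest length
    s = topo.system_from_bond_graph(["CT", "CT"], [(0, 1)],
                                    np.array([[0.0, 0, 0], [0.30, 0, 0]]),
                                    reg)
    s = ff.apply_parameter_vector(vec, s)
    x = dyn.minimize(s, vec, max_iter=500, tolerance=1.0)
    r = np.linalg.norm(x[1] - x[0])
    # LJ+GB shift the optimum only marginally from the bond rest length
    assert r == pytest.approx(s.bond_r0[0], abs=2e-3)
    # clashed pair: energy strictly decreases
    s2 = topo.system_from_bond_graph(["CT", "CT"], [],
                                     np.array([[0.0, 0, 0], [0.25, 0, 0]]),
                                     reg)
    s2 = ff.apply_parameter_vector(vec, s2)
    e0 = float(ad.val(en.total_potential(s2).total))
    x2 = dyn.minimize(s2, vec, max_iter=100)
    e1 = float(ad.val(en.total_potential(s2, x2).total))
    assert e1 < e0


def test_verlet_limit_conserves_energy():
    """gamma = 0 and zero noise reduce BAOAB to velocity Verlet."""
    k, m = 1000.0, 12.0
    masses = np.array([m])
    x = np.array([[0.05, 0.0, 0.0]])
    v = np.zeros((1, 3))
    dt = 0.001

    def force(xx):
        return -k * xx

    def energy(xx, vv):
        return 0.5 * k * np.sum(ad.val(xx) ** 2) + 0.5 * m * np.sum(vv ** 2)

    e0 = energy(x, v)
    zero_noise = np.zeros((1, 3))
    f = None
    for _ in range(10000):
        x, v, f = dyn.langevin_step(x, v, force, masses, dt, 0.0, 300.0,
                                    zero_noise, f0=f)
    drift = abs(energy(x, v) - e0) / e0
    assert drift < 1e-3  # O(dt^2) energy error, no secular drift


def test_langevin_samples_gibbs_variance():
    """Tethered particle: Var(x) -> kT/k per axis (pooled over axes).

    gamma = 10/ps keeps the position autocorrelation time near 200 steps,
    so the pooled Monte-Carlo error at 2e5 steps is about 3.5%; the 10%
    band is roughly 3 sigma.
    """
    k, m, temp = 1000.0, 12.011, 300.0
    masses = np.array([m])
    gamma, dt = 10.0, 0.001
    x = np.zeros((1, 3))
    v = dyn._noise(3, -1, (1, 3), np.float64) * np.sqrt(KB * temp / m)

    def force(xx):
        return -k * xx

    n_steps, burn = 200000, 10000
    acc = []
    f = None
    for step in range(n_steps):
        noise = dyn._noise(3, step, (1, 3), np.float64)
        x, v, f = dyn.langevin_step(x, v, force, masses, dt, gamma, temp,
                                    noise, f0=f)
        if step >= burn:
            acc.append(x[0])
    var = np.var(np.array(acc), axis=0).mean()
    assert var == pytest.approx(KB * temp / k, rel=0.10)


def test_equipartition_velocity_variance():
    m, temp = 12.011, 300.0
    masses = np.array([m])
    x = np.zeros((1, 3))
    v = np.zeros((1, 3))

    def force(xx):
        return 0.0 * ad.val(xx)

    samples = []
    f = None
    for step in range(150000):
        noise = dyn._noise(11, step, (1, 3), np.float64)
        x, v, f = dyn.langevin_step(x, v, force, masses, 0.001, 20.0, temp,
                                    noise, f0=f)
        if step > 5000:
            samples.append(v[0])
    var = np.var(np.array(samples), axis=0).mean()
    # ~2% Monte-Carlo error at this length; 5% is ~2.5 sigma
    assert var == pytest.approx(KB * temp / m, rel=0.05)


def test_clip_adjoints():
    a = np.full((4, 3), 0.1)  # norm > 0.1
    b = np.full((4, 3), 0.001)
    ca, cb = dyn.clip_adjoints(a, b, 0.1)
    assert np.linalg.norm(ca) == pytest.approx(0.1)
    assert np.allclose(ca / np.linalg.norm(ca), a / np.linalg.norm(a))
    assert np.array_equal(cb, b)  # below threshold: untouched
    za, zb = dyn.clip_adjoints(np.zeros((2, 3)), np.zeros((2, 3)), 0.1)
    assert np.all(za == 0) and np.all(zb == 0)
    # a norm-0.2 adjoint is exactly halved
    a2 = np.zeros((2, 3)); a2[0, 0] = 0.2
    ca2, _ = dyn.clip_adjoints(a2, zb, 0.1)
    assert ca2[0, 0] == pytest.approx(0.1)


def test_simulation_determinism_and_frame_count(tripeptide, registry):
    vec, _ = registry
    cfg = topo.SimulationConfig(n_steps=300, record_interval=30,
                                checkpoint_interval=100, seed=7)
    r1, s1 = dyn.simulate_with_checkpoints(tripeptide, vec, cfg)
    r2, s2 = dyn.simulate_with_checkpoints(tripeptide, vec, cfg)
    assert np.array_equal(r1.final_state[0], r2.final_state[0])
    assert np.array_equal(r1.final_state[1], r2.final_state[1])
    assert s1.frame_count == 10 == len(r1.snapshots)
    assert len(s1.states) == 3
    # different seed, different trajectory
    cfg2 = topo.SimulationConfig(n_steps=300, record_interval=30,
                                 checkpoint_interval=100, seed=8)
    r3, _ = dyn.simulate_with_checkpoints(tripeptide, vec, cfg2)
    assert not np.allclose(r3.final_state[0], r1.final_state[0])


def test_checkpoint_replay_is_bit_exact(tripeptide, registry):
    """Re-running one block from its stored state and noise key reproduces
    the next checkpoint state bit for bit."""
    vec, _ = registry
    cfg = topo.SimulationConfig(n_steps=200, record_interval=100,
                                checkpoint_interval=100, seed=3)
    record, store = dyn.simulate_with_checkpoints(tripeptide, vec, cfg)
    x, v = (a.copy() for a in store.states[1])
    up = ff.unpack(vec.values.astype(cfg.dtype))
    tables = en.pair_tables(tripeptide, up, cfg.dtype)
    masses = tripeptide.masses.astype(cfg.dtype)
    seed, step0 = store.seeds[1]
    f = None
    for local in range(100):
        noise = dyn._noise(seed, step0 + local, x.shape, cfg.dtype)
        x, v, f = dyn.langevin_step(
            x, v, lambda xx: en.force_analytic(tripeptide, xx, tables),
            masses, cfg.dt, cfg.friction, cfg.temperature, noise, f0=f)
    assert np.array_equal(x, record.final_state[0])
    assert np.array_equal(v, record.final_state[1])


def test_rigid_two_residue_statistics(registry):
    """A rigid pair of residues records mu = the fixed distance, sigma at
    the floor."""
    vec, reg = registry
    _, system = syn.make_toy_chain(syn.ToySpec(2, "extended"), reg)
    system = ff.apply_parameter_vector(vec, system)
    x0 = dyn.minimize(system, vec, max_iter=300, tolerance=5.0)
    d0 = np.linalg.norm(np.diff(x0[system.ca_indices], axis=0))
    cfg = topo.SimulationConfig(n_steps=100, record_interval=10,
                                checkpoint_interval=100, seed=1,
                                temperature=1e-6)  # effectively frozen
    _, store = dyn.simulate_with_checkpoints(system, vec, cfg, coords=x0)
    stats = ls.finalize_statistics(store.sum_x, store.sum_x2,
                                   store.frame_count, 2)
    assert stats.mu[0] == pytest.approx(d0, rel=1e-3)
    assert stats.sigma[0] <= 2e-3


def _tiny_training_problem(registry, n_res=3, seed=11):
    vec, reg = registry
    _, system = syn.make_toy_chain(syn.ToySpec(n_res, "extended"), reg)
    system = ff.apply_parameter_vector(vec, system)
    x0 = dyn.minimize(system, vec, max_iter=80)
    ref_cfg = topo.SimulationConfig(n_steps=400, record_interval=40,
                                    checkpoint_interval=100, seed=seed)
    pert = vec.values.copy()
    pert[vec.index("torsion_k:psi:n2")] *= 1.2
    ref = syn.make_reference_stats(system, pert, ref_cfg, coords=x0)
    return system, x0, ref


def test_checkpointed_gradient_equals_whole_graph(registry):
    """Gradient checkpointing is exact: the segmented reverse pass agrees
    with differentiating the whole unrolled trajectory."""
    vec, _ = registry
    system, x0, ref = _tiny_training_problem(registry)
    cfg = topo.SimulationConfig(n_steps=500, record_interval=50,
                                checkpoint_interval=100, seed=5)
    l1, g1, _ = dyn.loss_and_gradient(system, vec, cfg, ref, coords=x0,
                                      clip=False)
    l2, g2 = dyn.simulate_and_loss_direct(system, vec, cfg, ref, coords=x0)
    assert l1 == pytest.approx(l2, rel=1e-12)
    nz = np.abs(g2) > 1e-14
    assert np.max(np.abs(g1[nz] - g2[nz]) / np.abs(g2[nz])) < 1e-10


def test_clipping_with_huge_threshold_is_identity(registry):
    vec, _ = registry
    system, x0, ref = _tiny_training_problem(registry)
    cfg = topo.SimulationConfig(n_steps=200, record_interval=50,
                                checkpoint_interval=100, seed=5,
                                clip_threshold=1e9)
    _, g_clip, _ = dyn.loss_and_gradient(system, vec, cfg, ref, coords=x0,
                                         clip=True)
    _, g_off, _ = dyn.loss_and_gradient(system, vec, cfg, ref, coords=x0,
                                        clip=False)
    assert np.array_equal(g_clip, g_off)


def test_unstable_simulation_reports_step(registry):
    vec, reg = registry
    s = topo.system_from_bond_graph(
        ["CT", "CT"], [(0, 1)], np.array([[0.0, 0, 0], [1e-4, 0, 0]]), reg)
    s = ff.apply_parameter_vector(vec, s)
    cfg = topo.SimulationConfig(n_steps=100, record_interval=100,
                                checkpoint_interval=100, seed=0, dt=0.05)
    with pytest.raises(dyn.SimulationUnstableError):
        dyn.simulate_with_checkpoints(s, vec, cfg)
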