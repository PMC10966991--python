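"""Langevin dynamics with reverse-mode gradients through the integrator.

The integrator is the BAOAB splitting of Langevin dynamics: half kick (B),
half drift (A), full Ornstein-Uhlenbeck exchange with the heat bath (O),
half drift (A), half kick (B). With friction 0 and the noise disabled it
reduces exactly to velocity Verlet.

Gradients of a trajectory-derived loss with respect to the force-field
parameters are obtained by reverse-mode differentiation through the steps.
Memory is bounded by gradient checkpointing: the state is saved every
``checkpoint_interval`` steps during the forward run, and the reverse pass
re-simulates one block at a time (noise is counter-based on (seed, step) so
replay is bit-exact). At each block boundary the adjoints of coordinates and
velocities are rescaled to ``clip_threshold`` if either norm exceeds it,
which prevents gradient explosion through chaotic dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import energetics as en
from . import forcefield as ff
from .energetics import KB


class SimulationUnstableError(RuntimeError):
    def __init__(self, step):
        super().__init__(f"non-finite coordinates at step {step}")
        self.step = step


@dataclass
class TrajectoryRecord:
    times: list
    snapshots: list
    rng_seeds: list
    final_state: tuple


@dataclass
class CheckpointStore:
    states: list          # (coords, velocities) at the start of each block
    seeds: list           # per-block noise keys (seed, first_step)
    config: object
    sum_x: np.ndarray = None
    sum_x2: np.ndarray = None
    frame_count: int = 0
    #: optional fine-grained state cache at sub-chunk boundaries (a few MB);
    #: lets the reverse pass skip the tape-free block replay
    sub_states: dict = None


def _noise(seed, step, shape, dtype):
    """Counter-based Gaussian noise: reproducible per (seed, step)."""
    bg = np.random.Philox(key=(np.uint64(seed) << np.uint64(20)) + np.uint64(step + 1))
    z = np.random.Generator(bg).standard_normal(shape)
    return z.astype(dtype, copy=False)


def initial_velocities(system, temperature, seed, dtype=np.float64):
    """Maxwell-Boltzmann draw at the target temperature."""
    z = _noise(seed, -1, (system.n_atoms, 3), np.float64)
    v = z * np.sqrt(KB * temperature / system.masses)[:, None]
    return v.astype(dtype, copy=False)


def langevin_step(x, v, force_fn, masses, dt, friction, temperature, noise,
                  f0=None):
    """One BAOAB step. ``noise`` is the pre-drawn standard normal array.

    ``force_fn(x)`` returns the force at x; inputs may be Vars for
    differentiable stepping. ``f0`` is the force at the incoming x (carried
    between steps; recomputed when absent). Returns (x', v', force_at_x').
    """
    dt_t = masses.dtype.type  # keep integrator constants in the state dtype
    inv_m = (1.0 / masses)[:, None]
    c1 = dt_t(np.exp(-friction * dt))
    c2 = (np.sqrt(KB * temperature * (1.0 - float(c1) * float(c1))) /
          np.sqrt(masses)).astype(masses.dtype)[:, None]
    half_dt = dt_t(0.5 * dt)
    f = f0 if f0 is not None else force_fn(x)
    v = v + half_dt * f * inv_m
    x = x + half_dt * v
    v = c1 * v + c2 * noise
    x = x + half_dt * v
    f = force_fn(x)
    v = v + half_dt * f * inv_m
    return x, v, f


def clip_adjoints(adj_coords, adj_vels, threshold):
    """Rescale either adjoint block to ``threshold`` if its norm exceeds it."""
    out = []
    for a in (adj_coords, adj_vels):
        nrm = float(np.linalg.norm(a))
        if nrm > threshold:
            a = a * (threshold / nrm)
        out.append(a)
    return out[0], out[1]


def minimize(system, vector=None, max_iter=500, tolerance=10.0, coords=None,
             params=None):
    """Steepest-descent energy minimisation with backtracking line search.

    Stops when the largest force component falls below ``tolerance``
    (kJ/mol/nm) or after ``max_iter`` accepted steps. The energy never
    increases across accepted steps.
    """
    up = params
    if up is None:
        up = ff.unpack(vector.values if isinstance(vector, ff.ParameterVector)
                       else vector) if vector is not None else system.params
    x = np.array(coords if coords is not None else system.coordinates,
                 dtype=float)
    tables = en.pair_tables(system, up, np.float64)
    f, e = en.forces(system, x, up, tables=tables)
    if not np.isfinite(e):
        raise ValueError("non-finite starting energy")
    step = 1e-5
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tolerance:
            break
        direction = f / max(np.linalg.norm(f), 1e-12)
        while step > 1e-12:
            xn = x + step * direction
            fn, en_ = en.forces(system, xn, up, tables=tables)
            if np.isfinite(en_) and en_ <= e:
                x, f, e = xn, fn, en_
                step *= 1.6
                break
            step *= 0.5
        else:
            break
        step = min(step, 0.01)
    return x


def _ca_distances(coords, ca_idx):
    """Condensed upper-triangle Calpha distance vector (Var-aware)."""
    ca = ad.getitem(coords, ca_idx)
    ii, jj = np.triu_indices(len(ca_idx), 1)
    d = ad.getitem(ca, ii) - ad.getitem(ca, jj)
    return ad.sqrt(ad.asum(d * d, axis=1))


def simulate_with_checkpoints(system, vector, config, coords=None,
                              store_snapshots=True):
    """Forward Langevin run with checkpointing and distance accumulation.

    Returns ``(TrajectoryRecord, CheckpointStore)``; the store carries the
    accumulated sum(X) and sum(X^2) per Calpha pair. Deterministic for a
    given seed and precision.
    """
    dtype = config.dtype
    values = vector.values if isinstance(vector, ff.ParameterVector) else np.asarray(vector)
    up = ff.unpack(values.astype(dtype))
    x = np.array(coords if coords is not None else system.coordinates,
                 dtype=dtype)
    v = initial_velocities(system, config.temperature, config.seed, dtype)
    masses = system.masses.astype(dtype)
    tables = en.pair_tables(system, up, dtype)

    def force_fn(xx):
        return en.force_analytic(system, xx, tables, kappa=config.kappa)

    n_ca = len(system.ca_indices)
    n_pairs = n_ca * (n_ca - 1) // 2
    sum_x = np.zeros(n_pairs)
    sum_x2 = np.zeros(n_pairs)
    frames = 0
    snapshots, times, seeds, states = [], [], [], []
    sub = min(SUBCHUNK_STEPS, config.checkpoint_interval)
    sub_states = {}
    fcur = None
    for step in range(config.n_steps):
        if step % config.checkpoint_interval == 0:
            states.append((x.copy(), v.copy()))
            seeds.append((config.seed, step))
        if step % sub == 0:
            sub_states[step] = (x.copy(), v.copy())
        noise = _noise(config.seed, step, x.shape, dtype)
        x, v, fcur = langevin_step(x, v, force_fn, masses, config.dt,
                                   config.friction, config.temperature, noise,
                                   f0=fcur)
        if not np.all(np.isfinite(x)):
            raise SimulationUnstableError(step)
        if (step + 1) % config.record_interval == 0:
            if n_pairs:
                d = ad.val(_ca_distances(x, system.ca_indices)).astype(float)
                sum_x += d
                sum_x2 += d * d
            frames += 1
            times.append((step + 1) * config.dt)
            if store_snapshots:
                snapshots.append(np.array(x, dtype=float))
    record = TrajectoryRecord(times=times, snapshots=snapshots,
                              rng_seeds=list(seeds),
                              final_state=(x.copy(), v.copy()))
    store = CheckpointStore(states=states, seeds=seeds, config=config,
                            sum_x=sum_x, sum_x2=sum_x2, frame_count=frames,
                            sub_states=sub_states)
    return record, store


#: steps per taped sub-chunk inside one checkpoint block; bounds graph memory
#: without changing the mathematics (clipping stays at block boundaries)
SUBCHUNK_STEPS = 10


def backprop_gradients(system, vector, store, d_sum_x, d_sum_x2,
                       clip=True):
    """Parameter gradient via checkpointed reverse-mode differentiation.

    ``d_sum_x``/``d_sum_x2`` are the adjoints of the accumulated distance
    sums (i.e. dLoss/dsum(X), dLoss/dsum(X^2)); the reverse pass re-runs each
    block from its saved state and noise key, seeds the recorded frames with
    these adjoints, and propagates coordinate/velocity adjoints backwards
    with norm clipping at block boundaries. Memory is bounded by one
    sub-chunk of a block regardless of trajectory length: each block is
    first re-run cheaply without the tape to recover sub-chunk starting
    states, then differentiated one sub-chunk at a time.
    """
    config = store.config
    dtype = config.dtype
    values = vector.values if isinstance(vector, ff.ParameterVector) else np.asarray(vector)
    vvar = ad.Var(values.astype(dtype))
    up = ff.unpack(vvar)
    masses = system.masses.astype(dtype)
    tables = en.pair_tables(system, up, dtype)
    tables_plain = en.pair_tables(
        system, ff.unpack(values.astype(dtype)), dtype)
    d_sum_x = np.asarray(d_sum_x, dtype=dtype)
    d_sum_x2 = np.asarray(d_sum_x2, dtype=dtype)

    def force_taped(xx):
        return en.force_analytic(system, xx, tables, kappa=config.kappa)

    def force_plain(xx):
        return en.force_analytic(system, xx, tables_plain, kappa=config.kappa)

    n_blocks = len(store.states)
    bs = config.checkpoint_interval
    sub = min(SUBCHUNK_STEPS, bs)
    ax = np.zeros_like(store.states[0][0])
    av = np.zeros_like(ax)
    g_theta = np.zeros(108, dtype=np.float64)
    for b in range(n_blocks - 1, -1, -1):
        x0, v0 = store.states[b]
        seed, step0 = store.seeds[b]
        cache = store.sub_states or {}
        if all(step0 + c * sub in cache for c in range(-(-bs // sub))):
            sub_states = [cache[step0 + c * sub]
                          for c in range(-(-bs // sub))]
        else:
            # tape-free replay of the block recovers sub-chunk start states
            sub_states = []
            x, v, fcur = x0.copy(), v0.copy(), None
            for local in range(bs):
                if local % sub == 0:
                    sub_states.append((x.copy(), v.copy()))
                noise = _noise(seed, step0 + local, x0.shape, dtype)
                x, v, fcur = langevin_step(x, v, force_plain, masses,
                                           config.dt, config.friction,
                                           config.temperature, noise, f0=fcur)
        # differentiate sub-chunks in reverse; no clipping inside the block
        for c in range(len(sub_states) - 1, -1, -1):
            xs, vs = sub_states[c]
            xv = ad.Var(xs)
            vv = ad.Var(vs)
            x, v = xv, vv
            contrib = None
            fcur = None
            for local in range(c * sub, min((c + 1) * sub, bs)):
                step = step0 + local
                noise = _noise(seed, step, x0.shape, dtype)
                x, v, fcur = langevin_step(x, v, force_taped, masses,
                                           config.dt, config.friction,
                                           config.temperature, noise, f0=fcur)
                if (step + 1) % config.record_interval == 0 and len(d_sum_x):
                    d = _ca_distances(x, system.ca_indices)
                    piece = ad.asum(d * d_sum_x) + ad.asum(d * d * d_sum_x2)
                    contrib = piece if contrib is None else contrib + piece
            total = ad.asum(x * ax) + ad.asum(v * av)
            if contrib is not None:
                total = total + contrib
            gx, gv, gt = ad.grad(total, [xv, vv, vvar], taped=False)
            ax, av = gx, gv
            g_theta += gt.astype(np.float64)
        if clip:
            ax, av = clip_adjoints(ax, av, config.clip_threshold)
    return g_theta


def loss_and_gradient(system, vector, config, ref_stats, coords=None,
                      include_zero_weight=True, clip=True):
    """Run one training simulation and return (loss, dloss/dparams, stats).

    The forward pass accumulates distance sums; the loss (two-way Gaussian
    KL, see :mod:`diffmd.loss`) is evaluated from the sums, its adjoints with
    respect to the sums are computed, and the checkpointed reverse pass
    propagates them to the 108 parameters.
    """
    from . import loss as ls
    record, store = simulate_with_checkpoints(system, vector, config,
                                              coords=coords,
                                              store_snapshots=False)
    sx = ad.Var(store.sum_x.copy())
    sx2 = ad.Var(store.sum_x2.copy())
    stats = ls.finalize_statistics(sx, sx2, store.frame_count,
                                   len(system.ca_indices))
    lval = ls.aggregate_loss(stats, ref_stats,
                             include_zero_weight=include_zero_weight)
    gsx, gsx2 = ad.grad(lval, [sx, sx2], taped=False)
    grad = backprop_gradients(system, vector, store, gsx, gsx2, clip=clip)
    stats_val = ls.DistanceStatistics(stats.n_residues, ad.val(stats.mu),
                                      ad.val(stats.sigma), stats.frame_count)
    return float(ad.val(lval)), grad, stats_val


def simulate_and_loss_direct(system, vector, config, ref_stats, coords=None,
                             include_zero_weight=True):
    """Whole-graph differentiable run (no checkpointing); for short runs.

    Builds the full computation graph over all steps and differentiates the
    aggregate loss directly. Memory grows linearly with n_steps; used to
    validate the checkpointed path and for finite-difference oracles.
    """
    from . import loss as ls
    dtype = config.dtype
    values = vector.values if isinstance(vector, ff.ParameterVector) else np.asarray(vector)
    vvar = ad.Var(values.astype(dtype))
    up = ff.unpack(vvar)
    masses = system.masses.astype(dtype)
    tables = en.pair_tables(system, up, dtype)
    x = np.array(coords if coords is not None else system.coordinates, dtype=dtype)
    v = initial_velocities(system, config.temperature, config.seed, dtype)
    x, v = ad.Var(x), ad.Var(v)

    def force_fn(xx):
        return en.force_analytic(system, xx, tables, kappa=config.kappa)

    sum_x, sum_x2 = None, None
    frames = 0
    fcur = None
    for step in range(config.n_steps):
        noise = _noise(config.seed, step, ad.val(x).shape, dtype)
        x, v, fcur = langevin_step(x, v, force_fn, masses, config.dt,
                                   config.friction, config.temperature, noise,
                                   f0=fcur)
        if (step + 1) % config.record_interval == 0:
            d = _ca_distances(x, system.ca_indices)
            sum_x = d if sum_x is None else sum_x + d
            sum_x2 = d * d if sum_x2 is None else sum_x2 + d * d
            frames += 1
    stats = ls.finalize_statistics(sum_x, sum_x2, frames,
                                   len(system.ca_indices))
    lval = ls.aggregate_loss(stats, ref_stats,
                             include_zero_weight=include_zero_weight)
    (g,) = ad.grad(lval, [vvar], taped=False)
    return float(ad.val(lval)), g.astype(np.float64)
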