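"""The force-field training loop.

Each epoch simulates every training protein with the current parameters
(disordered proteins twice with different seeds), computes the
distance-distribution loss against its reference statistics and the gradient
of that loss with respect to the 108 trainable parameters, and then updates
the parameters by gradient descent with three stabilising transforms:

1. per-protein gradients are divided by the median of their absolute values
   so every protein contributes comparably;
2. entries for LJ sigma and for hydrogen atom types are damped by a factor
   of 0.02 (their raw gradients are large and destabilising);
3. the parameter change is capped at 0.5% of the epoch-start value per
   protein and 3% combined per epoch.

Training is run several times from different seeds and the run with the
lowest final training loss is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import dynamics as dyn
from . import forcefield as ff


@dataclass
class GradientBundle:
    protein_id: str
    repeat_id: int
    gradient: np.ndarray
    loss: float
    seed: int

    def __post_init__(self):
        self.gradient = np.asarray(self.gradient, dtype=float)
        if self.gradient.shape != (108,):
            raise ValueError("gradient must have length 108")
        if not np.all(np.isfinite(self.gradient)):
            raise ValueError("non-finite gradient entries")


@dataclass
class TrainingConfig:
    learning_rate: float = 4e-4
    per_protein_cap: float = 0.005
    per_epoch_cap: float = 0.03
    class_weight: float = 0.02
    n_epochs: int = 5
    idp_repeats: int = 2
    #: absolute fallback cap for a (hypothetical) zero-valued parameter
    zero_value_cap: float = 0.005

    def __post_init__(self):
        if not (0 < self.per_protein_cap < 1 and 0 < self.per_epoch_cap < 1):
            raise ValueError("caps must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingProtein:
    """One entry of the training set."""

    protein_id: str
    system: object
    ref_stats: object
    sim_config: object
    is_idp: bool = False
    start_coords: np.ndarray = None


@dataclass
class EpochReport:
    epoch: int
    losses: dict
    grad_norms: dict
    params_before: np.ndarray
    params_after: np.ndarray

    @property
    def mean_loss(self):
        return float(np.mean(list(self.losses.values())))


@dataclass
class RunReport:
    run_id: int
    epochs: list = field(default_factory=list)
    final_params: np.ndarray = None

    @property
    def final_mean_loss(self):
        return self.epochs[-1].mean_loss


def combine_repeat_gradients(bundles):
    """Elementwise mean over the repeats of one protein."""
    if not bundles:
        raise ValueError("no gradient bundles")
    pid = bundles[0].protein_id
    if any(b.protein_id != pid for b in bundles):
        raise ValueError("bundles mix different proteins")
    return np.mean([b.gradient for b in bundles], axis=0)


def median_normalize(gradient):
    """Divide by the median absolute entry (over all 108 entries)."""
    gradient = np.asarray(gradient, dtype=float)
    med = np.median(np.abs(gradient))
    if med == 0.0:
        warnings.warn("all-zero median gradient; skipping normalisation")
        return gradient.copy()
    return gradient / med


def apply_class_weights(gradient, labels, hydrogen_flags, weight=0.02):
    """Damp LJ sigma entries and entries of hydrogen atom types."""
    out = np.asarray(gradient, dtype=float).copy()
    mask = np.asarray([lab == "lj_sigma" for lab in labels]) | \
        np.asarray(hydrogen_flags, dtype=bool)
    out[mask] *= weight
    return out


def cap_and_update(params, per_protein_gradients, config):
    """Capped gradient-descent update.

    ``per_protein_gradients`` maps protein id -> processed (normalised,
    class-weighted) gradient. Each protein's proposed change -lr*g is clamped
    to +-per_protein_cap of the epoch-start parameter magnitude; the summed
    change is clamped again to +-per_epoch_cap.
    """
    base = np.abs(params.values)
    cap_base = np.where(base > 0, base, config.zero_value_cap)
    total = np.zeros(108)
    for g in per_protein_gradients.values():
        change = -config.learning_rate * np.asarray(g)
        lim = config.per_protein_cap * cap_base
        total += np.clip(change, -lim, lim)
    lim = config.per_epoch_cap * cap_base
    total = np.clip(total, -lim, lim)
    new = params.copy()
    new.values = params.values + total
    return new


def evaluate_protein(protein, params, config, seed):
    """One training simulation for one protein: minimise then simulate."""
    system = ff.apply_parameter_vector(params, protein.system)
    coords = protein.start_coords
    if coords is None:
        coords = dyn.minimize(system, params, max_iter=200)
    sim_cfg = replace(protein.sim_config, seed=seed)
    loss, grad, stats = dyn.loss_and_gradient(system, params, sim_cfg,
                                              protein.ref_stats,
                                              coords=coords)
    return GradientBundle(protein.protein_id, seed, grad, loss, seed)


def run_epoch(proteins, params, config, seeds):
    """Simulate every protein, combine gradients, update the parameters.

    ``seeds`` is the per-epoch base seed; repeat r of protein p runs with
    seed ``seeds + 1000 * index(p) + r`` so repeats and proteins decorrelate.
    """
    losses, grad_norms, processed = {}, {}, {}
    for ip, prot in enumerate(proteins):
        n_rep = config.idp_repeats if prot.is_idp else 1
        bundles = [evaluate_protein(prot, params, config,
                                    seeds + 1000 * ip + r)
                   for r in range(n_rep)]
        g = combine_repeat_gradients(bundles)
        g = median_normalize(g)
        g = apply_class_weights(g, params.labels, params.hydrogen_flag,
                                config.class_weight)
        processed[prot.protein_id] = g
        losses[prot.protein_id] = float(np.mean([b.loss for b in bundles]))
        grad_norms[prot.protein_id] = float(np.linalg.norm(g))
    new_params = cap_and_update(params, processed, config)
    report = EpochReport(epoch=-1, losses=losses, grad_norms=grad_norms,
                         params_before=params.values.copy(),
                         params_after=new_params.values.copy())
    return new_params, report


def train(proteins, params, config, run_id=0, base_seed=0):
    """Full training run of ``config.n_epochs`` epochs."""
    report = RunReport(run_id=run_id)
    current = params.copy()
    for epoch in range(config.n_epochs):
        current, ep = run_epoch(proteins, current, config,
                                seeds=base_seed + 100000 * epoch)
        ep.epoch = epoch
        report.epochs.append(ep)
    report.final_params = current.values.copy()
    return current, report


def select_best_run(run_reports):
    """The run with the lowest mean training loss at the final epoch.

    Ties break to the lowest run index.
    """
    if not run_reports:
        raise ValueError("no completed runs")
    best = min(run_reports, key=lambda r: (r.final_mean_loss, r.run_id))
    return best


def paired_gradient_experiment(seed, n_residues=15, n_steps=20000,
                               record_interval=50, perturbation=0.03):
    """Two independent stochastic gradient evaluations of the training loss.

    Builds a synthetic helical peptide, generates reference statistics from
    the default parameter vector perturbed by multiplicative Gaussian noise
    of relative scale ``perturbation``, runs two full loss-plus-gradient
    evaluations with different seeds (single precision, training protocol),
    and returns ``(g1, g2, losses)``. Used to quantify how reproducible the
    stochastic gradients are across repeated runs.
    """
    from . import synthetic as syn
    from . import topology as topo

    seed = int(seed) % (2 ** 31)
    vec, reg = ff.build_default_registry()
    _, system = syn.make_toy_chain(syn.ToySpec(n_residues, "helical"), reg)
    system = ff.apply_parameter_vector(vec, system)
    x0 = dyn.minimize(system, vec, max_iter=300)

    def config(s):
        return topo.SimulationConfig(
            n_steps=n_steps, record_interval=record_interval,
            checkpoint_interval=100, clip_threshold=0.1, seed=s,
            precision="single", dt=0.001, temperature=300.0, friction=0.1,
            kappa=0.7)

    rng = np.random.default_rng(seed)
    perturbed = vec.values * (1.0 + perturbation * rng.standard_normal(108))
    ref = syn.make_reference_stats(system, perturbed, config(seed),
                                   coords=x0)
    grads, losses = [], []
    for k in (1, 2):
        run_seed = (seed * 7919 + k) % (2 ** 31)
        loss, grad, _ = dyn.loss_and_gradient(system, vec, config(run_seed),
                                              ref, coords=x0)
        grads.append(grad)
        losses.append(loss)
    return grads[0], grads[1], losses


def gradient_sign_agreement(g1, g2, negligible=1e-3):
    """Fraction of paired gradients sharing a sign, and the entries used.

    Entries count as non-negligible when both gradients are nonzero and the
    larger magnitude exceeds ``negligible`` times the largest entry.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    nonzero = (g1 != 0.0) & (g2 != 0.0)
    mag = np.maximum(np.abs(g1), np.abs(g2))
    considered = nonzero & (mag > negligible * mag.max())
    frac = float(np.mean(np.sign(g1[considered]) == np.sign(g2[considered])))
    return frac, considered
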