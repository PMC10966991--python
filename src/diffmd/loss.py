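"""Distance-distribution statistics and the two-way Gaussian-KL training loss.

During a training simulation the Calpha residue-residue distances X and X^2
are accumulated at a fixed recording interval. At the end of the run each
pair's distance distribution is summarised by its mean mu and standard
deviation sigma, modelled as a 1-D Gaussian. Simulated and reference
distributions are compared by the closed-form Gaussian KL divergence in both
directions; per-pair losses are compressed as ln(D + 1), down-weighted for
sequence-near pairs (weight 0 at separation 0, rising linearly to 1 at
separation >= 10), and averaged over all unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import asum, log, maximum, sqrt

#: floor on per-pair standard deviations (nm); prevents division by zero for
#: rigid pairs and round-off-negative variances
SIGMA_MIN = 1e-3

TSV_VERSION = "diffmd-stats-1"


@dataclass
class DistanceStatistics:
    """Per-pair mean/std of Calpha distances over recorded frames.

    ``mu`` and ``sigma`` are condensed upper-triangle vectors over unordered
    residue pairs (i < j), ordered as numpy's ``triu_indices``.
    """

    n_residues: int
    mu: object      # (P,) array or Var
    sigma: object
    frame_count: int

    @property
    def pair_indices(self):
        return np.triu_indices(self.n_residues, 1)


#: reference statistics share the container; the name documents intent
ReferenceStatistics = DistanceStatistics


def finalize_statistics(sum_x, sum_x2, frame_count, n_residues,
                        sigma_min=SIGMA_MIN):
    """Moments from accumulated sums: mu = E[X], sigma = sqrt(E[X^2]-E[X]^2).

    The variance is clamped at zero before the square root and sigma floored
    at ``sigma_min`` so rigid pairs stay finite.
    """
    if frame_count < 2:
        raise ValueError("need at least 2 recorded frames for statistics")
    mu = sum_x / float(frame_count)
    var = maximum(sum_x2 / float(frame_count) - mu * mu, 0.0)
    sigma = maximum(sqrt(var + sigma_min * sigma_min * 1e-6), sigma_min)
    return DistanceStatistics(n_residues, mu, sigma, frame_count)


def gaussian_kl(mu_s, sigma_s, mu_r, sigma_r):
    """Closed-form KL(P||Q) between 1-D Gaussians P=(mu_s, sigma_s), Q=(mu_r, sigma_r)."""
    if np.any(ad.val(sigma_s) <= 0) or np.any(ad.val(sigma_r) <= 0):
        raise ValueError("standard deviations must be positive")
    d = mu_s - mu_r
    return (log(sigma_r / sigma_s) +
            (sigma_s * sigma_s + d * d) / (2.0 * sigma_r * sigma_r) - 0.5)


def pair_loss(d_pq, d_qp):
    """Log-compressed symmetric combination ln(D_PQ + 1) + ln(D_QP + 1)."""
    return log(d_pq + 1.0) + log(d_qp + 1.0)


def separation_weight(i, j):
    """0 at |i-j| = 0, 1 at |i-j| >= 10, linear in between."""
    return np.minimum(np.abs(np.asarray(i) - np.asarray(j)), 10) / 10.0


def aggregate_loss(sim, ref, include_zero_weight=True):
    """Mean over unordered residue pairs of the weighted two-way KL loss.

    ``include_zero_weight`` keeps zero-weight (sequence-adjacent) pairs in
    the denominator; set False to average over positive-weight pairs only.
    Differentiable through the simulated statistics.
    """
    if sim.n_residues != ref.n_residues:
        raise ValueError("simulated and reference statistics differ in size")
    ii, jj = np.triu_indices(sim.n_residues, 1)
    w = separation_weight(ii, jj)
    d_pq = gaussian_kl(sim.mu, sim.sigma, ref.mu, ref.sigma)
    d_qp = gaussian_kl(ref.mu, ref.sigma, sim.mu, sim.sigma)
    l_ij = pair_loss(d_pq, d_qp)
    total = asum(w * l_ij)
    denom = len(w) if include_zero_weight else int(np.sum(w > 0))
    if denom == 0:
        raise ValueError("no residue pairs to average over")
    return total / float(denom)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def write_statistics_tsv(path, stats):
    ii, jj = stats.pair_indices
    df = pd.DataFrame({"i": ii, "j": jj,
                       "mu_nm": ad.val(stats.mu),
                       "sigma_nm": ad.val(stats.sigma)})
    with open(path, "w") as f:
        f.write(f"# {TSV_VERSION} n_residues={stats.n_residues} "
                f"frames={stats.frame_count}\n")
        df.to_csv(f, sep="\t", index=False)


def read_statistics_tsv(path):
    with open(path) as f:
        header = f.readline()
        if TSV_VERSION not in header:
            raise ValueError(f"unrecognised statistics file header: {header!r}")
        fields = dict(tok.split("=") for tok in header.split() if "=" in tok)
        df = pd.read_csv(f, sep="\t")
    n = int(fields["n_residues"])
    ii, jj = np.triu_indices(n, 1)
    if not (np.array_equal(df["i"].values, ii) and
            np.array_equal(df["j"].values, jj)):
        raise ValueError("statistics file pair ordering mismatch")
    return DistanceStatistics(n, df["mu_nm"].values.astype(float),
                              df["sigma_nm"].values.astype(float),
                              int(fields["frames"]))
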