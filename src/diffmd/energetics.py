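"""Differentiable potential energy for the implicit-solvent force field.

Terms
-----
* Harmonic bonds ``k (r - r0)^2`` and angles ``k (theta - theta0)^2``,
  periodic proper torsions ``k (1 + cos(n phi - delta))``.
* Lennard-Jones with Lorentz-Berthelot combining and a trainable 1-4 scale;
  vacuum Coulomb with a trainable 1-4 scale; no distance cutoff.
* Generalized-Born polar solvation in the GB-Neck2/OBC family: pairwise HCT
  descreening integrals with per-element screening factors and a smooth
  analytic neck correction, tanh-rescaled effective Born radii, and the
  Still-style pair function f_ij = sqrt(r^2 + Ri Rj exp(-r^2 / 4 Ri Rj))
  with Debye-Hueckel salt screening exp(-kappa f).
* An ACE-style nonpolar surface-area term
  ``factor * sum_i 4 pi (rho_i + probe)^2 (rho~_i / R_i)^6``.

All pairwise work runs on condensed upper-triangle vectors (one entry per
unordered atom pair) with constant sparse incidence matrices supplying the
coordinate differences, which keeps both the forward evaluation and the
reverse-mode graph compact. Parameter-only pair tables (combined LJ
coefficients, charge products, descreening radii, 1-4 weights) are built
once per evaluation context by :func:`pair_tables` and reused across
integration steps.

All functions accept coordinates and parameters as plain arrays or as
autodiff Vars; outputs are differentiable with respect to any Var inputs.
Solute and solvent dielectrics are fixed at 1.0 and 78.5.

The neck correction of the reference GB model is defined by per-radius-pair
tables; here it is an analytic surrogate with the same role and trainable
handles: a rational bump of Mongan form centred where the solvent probe just
bridges the two spheres (r ~ rho_i + rho_j + probe), multiplied by the
trainable neck scale and smoothly windowed at the trainable neck cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import (absolute, arccos, arctan2, asum, cos, exp, getitem,
                       log, maximum, minimum, power, reshape, scatter_add,
                       spmatmul, sqrt, stack_last, tanh, where)

KE = 138.935458           # Coulomb constant, kJ mol^-1 nm e^-2
KB = 0.00831446261815324  # Boltzmann constant, kJ mol^-1 K^-1
EPS_SOLUTE = 1.0
EPS_SOLVENT = 78.5
_NECK_WIDTH = 0.1         # nm, width of the surrogate neck bump
_NECK_WINDOW = 0.01       # nm, smoothness of the neck cutoff window


class SingularGeometryError(ValueError):
    pass


@dataclass
class EnergyBreakdown:
    bond: object
    angle: object
    torsion: object
    lj: object
    coulomb: object
    gb_polar: object
    gb_surface: object

    @property
    def total(self):
        return (self.bond + self.angle + self.torsion + self.lj +
                self.coulomb + self.gb_polar + self.gb_surface)

    def as_floats(self):
        d = {k: float(ad.val(getattr(self, k)))
             for k in ("bond", "angle", "torsion", "lj", "coulomb",
                       "gb_polar", "gb_surface")}
        d["total"] = float(ad.val(self.total))
        return d


def _params(system, params):
    up = params if params is not None else system.params
    if up is None:
        raise ValueError("system has no applied parameters; call "
                         "forcefield.apply_parameter_vector first")
    return up


def _incidence(pairs_a, pairs_b, n, dtype):
    """Sparse (P, n) difference operator: (S @ x)[p] = x[a_p] - x[b_p]."""
    p = len(pairs_a)
    rows = np.repeat(np.arange(p), 2)
    cols = np.empty(2 * p, dtype=int)
    cols[0::2] = pairs_a
    cols[1::2] = pairs_b
    data = np.empty(2 * p, dtype=dtype)
    data[0::2] = 1.0
    data[1::2] = -1.0
    return sp.csr_matrix((data, (rows, cols)), shape=(p, n))


def _structure_cache(system, dtype):
    """Constant index/mask/incidence structures, cached per dtype."""
    key = ("struct", np.dtype(dtype).name)
    if key in system._nb_masks:
        return system._nb_masks[key]
    n = system.n_atoms
    ii, jj = np.triu_indices(n, 1)
    pairkey = ii * n + jj
    excl = np.zeros(len(ii), dtype=bool)
    if system.exclusions:
        ek = np.array([min(a, b) * n + max(a, b) for a, b in system.exclusions])
        excl = np.isin(pairkey, ek)
    is14 = np.zeros(len(ii), dtype=bool)
    if system.pairs_14:
        fk = np.array([min(a, b) * n + max(a, b) for a, b in system.pairs_14])
        is14 = np.isin(pairkey, fk)
    p = len(ii)
    c = {
        "ii": ii, "jj": jj,
        "tile": np.concatenate([np.arange(p), np.arange(p)]),
        "atom_cat": np.concatenate([ii, jj]),
        "incl": (~excl & ~is14).astype(dtype),
        "is14": is14,
        "S": _incidence(ii, jj, n, dtype),
        "ST": _incidence(ii, jj, n, dtype).T.tocsr(),
    }
    if len(system.bonds):
        c["SB"] = _incidence(system.bonds[:, 0], system.bonds[:, 1], n, dtype)
        c["SBT"] = c["SB"].T.tocsr()
    if len(system.angles):
        c["SU"] = _incidence(system.angles[:, 0], system.angles[:, 1], n, dtype)
        c["SUT"] = c["SU"].T.tocsr()
        c["SV"] = _incidence(system.angles[:, 2], system.angles[:, 1], n, dtype)
        c["SVT"] = c["SV"].T.tocsr()
    if len(system.torsion_atoms):
        t = system.torsion_atoms
        for nm, (a, b) in (("S1", (1, 0)), ("S2", (2, 1)), ("S3", (3, 2))):
            c[nm] = _incidence(t[:, a], t[:, b], n, dtype)
            c[nm + "T"] = c[nm].T.tocsr()
    system._nb_masks[key] = c
    return c


class PairTables:
    """Parameter-dependent condensed pair tables (possibly Var-valued).

    Build once per evaluation context (e.g. per checkpoint block) and reuse
    across steps; everything here depends on the parameters but not on the
    coordinates.
    """

    __slots__ = ("struct", "dtype", "charges", "sig2", "eps4", "w_lj",
                 "keqq_c", "keqq_all", "qdiag", "rho", "rho_red",
                 "rho_red_cat", "s_cat", "d0", "alpha", "beta", "gamma",
                 "area0", "neck_cutoff", "neck_scale", "surface_factor",
                 "up", "n")

    def __init__(self, system, up, dtype=np.float64, charges=None):
        from . import forcefield as ff
        st = _structure_cache(system, dtype)
        self.struct = st
        self.dtype = np.dtype(dtype)
        self.up = up
        self.n = system.n_atoms
        ii, jj = st["ii"], st["jj"]
        if charges is None:
            charges = ff.compute_system_charges(system, up.charge_scale)
        self.charges = charges
        q = charges
        si = getitem(up.sigma, system.type_idx)
        ei = getitem(up.epsilon, system.type_idx)
        sig = (getitem(si, ii) + getitem(si, jj)) * 0.5
        self.sig2 = sig * sig
        self.eps4 = 4.0 * sqrt(getitem(ei, ii) * getitem(ei, jj) + 1e-30)
        self.w_lj = where(st["is14"], up.lj_14, st["incl"])
        qq = getitem(q, ii) * getitem(q, jj)
        self.keqq_c = KE * qq * where(st["is14"], up.coulomb_14, st["incl"])
        self.keqq_all = KE * qq
        self.qdiag = q * q
        rho = getitem(up.gb_radii, system.gb_class_idx)
        if np.any(ad.val(rho) <= 0.0):
            raise ValueError("non-positive intrinsic GB radius")
        self.rho = rho
        rho_red = rho - up.offset
        if np.any(ad.val(rho_red) <= 0.0):
            raise ValueError("non-positive reduced intrinsic GB radius")
        self.rho_red = rho_red
        screen = getitem(up.gb_screen, system.elem_idx)
        s = screen * rho_red
        # both descreening directions stacked into one (2P,) computation:
        # entry p descreens atom ii[p] by sphere jj[p]; entry P+p the reverse
        self.rho_red_cat = ad.concat([getitem(rho_red, ii),
                                      getitem(rho_red, jj)])
        self.s_cat = ad.concat([getitem(s, jj), getitem(s, ii)])
        self.d0 = getitem(rho, ii) + getitem(rho, jj) + up.probe_radius
        self.alpha = getitem(up.gb_obc[:, 0], system.elem_idx)
        self.beta = getitem(up.gb_obc[:, 1], system.elem_idx)
        self.gamma = getitem(up.gb_obc[:, 2], system.elem_idx)
        self.area0 = 4.0 * np.pi * power(rho + up.probe_radius, 2)
        self.neck_cutoff = up.neck_cutoff
        self.neck_scale = up.neck_scale
        self.surface_factor = up.surface_area_factor
        # keep the working dtype uniform so mixed-precision upcasts cannot
        # silently promote the whole graph
        t = self.dtype.type
        for slot in ("charges", "sig2", "eps4", "w_lj", "keqq_c", "keqq_all",
                     "qdiag", "rho", "rho_red", "rho_red_cat", "s_cat",
                     "d0", "alpha", "beta", "gamma", "area0"):
            v = getattr(self, slot)
            if not ad.is_var(v) and np.asarray(v).dtype != self.dtype:
                setattr(self, slot, np.asarray(v, dtype=self.dtype))
        for slot in ("neck_cutoff", "neck_scale", "surface_factor"):
            v = getattr(self, slot)
            if not ad.is_var(v):
                setattr(self, slot, t(v))


def pair_tables(system, up=None, dtype=np.float64, charges=None):
    return PairTables(system, _params(system, up), dtype, charges=charges)


def _pair_r(system, coords, tables):
    st = tables.struct
    d = spmatmul(st["S"], coords, st["ST"])
    r2 = asum(d * d, axis=1)
    r = sqrt(r2)
    return r2, r, 1.0 / r


def _check_singular(tables, r2):
    rv = ad.val(r2)
    if np.any((rv <= 0.0) & (ad.val(tables.w_lj) != 0.0)):
        raise SingularGeometryError("coincident atoms in an interacting pair")


def _cross(u, v):
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    vx, vy, vz = v[..., 0], v[..., 1], v[..., 2]
    return stack_last([uy * vz - uz * vy, uz * vx - ux * vz, ux * vy - uy * vx])


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bonded_energy(system, coords=None, params=None, tables=None):
    """Bond + angle + torsion energies (each returned separately)."""
    up = _params(system, params)
    x = coords if coords is not None else system.coordinates
    dtype = ad.val(x).dtype
    st = (tables.struct if tables is not None
          else _structure_cache(system, dtype))
    zero = np.asarray(0.0, dtype=dtype)

    if len(system.bonds):
        d = spmatmul(st["SB"], x, st["SBT"])
        r = sqrt(asum(d * d, axis=1))
        e_bond = asum(system.bond_k.astype(dtype) *
                      power(r - system.bond_r0.astype(dtype), 2))
    else:
        e_bond = zero

    if len(system.angles):
        u = spmatmul(st["SU"], x, st["SUT"])
        v = spmatmul(st["SV"], x, st["SVT"])
        cosang = asum(u * v, axis=1) / sqrt(asum(u * u, axis=1) *
                                            asum(v * v, axis=1))
        cosang = minimum(maximum(cosang, -1.0 + 1e-9), 1.0 - 1e-9)
        theta = arccos(cosang)
        e_angle = asum(system.angle_k.astype(dtype) *
                       power(theta - system.angle_theta0.astype(dtype), 2))
    else:
        e_angle = zero

    if len(system.torsion_atoms):
        b1 = spmatmul(st["S1"], x, st["S1T"])
        b2 = spmatmul(st["S2"], x, st["S2T"])
        b3 = spmatmul(st["S3"], x, st["S3T"])
        n1 = _cross(b1, b2)
        n2 = _cross(b2, b3)
        m1 = _cross(n1, b2 / reshape(sqrt(asum(b2 * b2, axis=1)), (-1, 1)))
        cosphi = asum(n1 * n2, axis=1)
        sinphi = asum(m1 * n2, axis=1)
        phi = arctan2(sinphi, cosphi)
        trainable = system.torsion_kidx >= 0
        amp = where(trainable,
                    getitem(up.torsion_k, np.maximum(system.torsion_kidx, 0)),
                    system.torsion_kfixed.astype(dtype))
        e_tors = asum(amp * (1.0 + cos(system.torsion_n.astype(dtype) * phi -
                                       system.torsion_phase.astype(dtype))))
    else:
        e_tors = zero
    if system.tether_k:
        c = system.tether_center if system.tether_center is not None else 0.0
        dx = x - np.asarray(c, dtype=dtype)
        e_bond = e_bond + 0.5 * system.tether_k * asum(dx * dx)
    return e_bond, e_angle, e_tors


# ---------------------------------------------------------------------------
# non-bonded terms (condensed pair vectors)
# ---------------------------------------------------------------------------

def lennard_jones_energy(system, coords=None, params=None, tables=None,
                         r2=None):
    """LJ over non-excluded pairs; 1-4 pairs scaled by the trainable weight."""
    x = coords if coords is not None else system.coordinates
    if tables is None:
        tables = pair_tables(system, _params(system, params),
                             ad.val(x).dtype)
    if r2 is None:
        r2, _, _ = _pair_r(system, x, tables)
    _check_singular(tables, r2)
    sr2 = tables.sig2 / r2
    sr6 = sr2 * sr2 * sr2
    return asum(tables.w_lj * tables.eps4 * (sr6 * sr6 - sr6))


def coulomb_energy(system, coords=None, params=None, tables=None,
                   inv_r=None, charges=None):
    """Vacuum Coulomb over non-excluded pairs with trainable 1-4 scaling.

    Salt screening is deliberately absent here; it lives in the GB term.
    """
    x = coords if coords is not None else system.coordinates
    if tables is None:
        tables = pair_tables(system, _params(system, params),
                             ad.val(x).dtype, charges=charges)
    if inv_r is None:
        r2, _, inv_r = _pair_r(system, x, tables)
        _check_singular(tables, r2)
    return asum(tables.keqq_c * inv_r)


def _hct_direction(r, inv_r, rho_i, s_j):
    """HCT descreening of atom i by sphere (s_j) at distance r; all (P,)."""
    u = r + s_j
    l = maximum(absolute(r - s_j), rho_i)
    inv_l = 1.0 / l
    inv_u = 1.0 / u
    integral = 0.5 * (inv_l - inv_u +
                      0.25 * (r - s_j * s_j * inv_r) *
                      (inv_u * inv_u - inv_l * inv_l) +
                      0.5 * log(l * inv_u) * inv_r)
    engulf = ad.val(rho_i) < ad.val(s_j) - ad.val(r)
    if engulf.any():
        integral = integral + where(engulf, 1.0 / rho_i - inv_l, 0.0)
    active = ad.val(rho_i) < ad.val(u)
    return where(active, integral, 0.0)


def born_radii(system, coords=None, params=None, tables=None, rr=None):
    """Effective Born radii via HCT descreening + neck + OBC tanh rescaling.

    Returns (radii, rho_reduced, rho_intrinsic); radii are bounded below by
    the reduced intrinsic radius by construction of the tanh form.
    """
    x = coords if coords is not None else system.coordinates
    if tables is None:
        tables = pair_tables(system, _params(system, params),
                             ad.val(x).dtype)
    if rr is None:
        r2, r, inv_r = _pair_r(system, x, tables)
    else:
        r2, r, inv_r = rr
    st = tables.struct
    n = tables.n
    r_cat = getitem(r, st["tile"])
    inv_r_cat = getitem(inv_r, st["tile"])
    integral = _hct_direction(r_cat, inv_r_cat, tables.rho_red_cat,
                              tables.s_cat)
    # analytic surrogate neck, windowed at the trainable cutoff (symmetric)
    delta = (r - tables.d0) / _NECK_WIDTH
    d2 = delta * delta
    bump = 0.3 / (1.0 + d2 + 0.3 * d2 * d2 * d2)
    window = 0.5 * (1.0 + tanh((tables.neck_cutoff - r) / (2.0 * _NECK_WINDOW)))
    neck = tables.neck_scale * bump * window
    integral = integral + getitem(neck, st["tile"])
    i_sum = scatter_add(integral, st["atom_cat"], (n,))
    psi = i_sum * tables.rho_red
    inner = psi * (tables.alpha - psi * (tables.beta - psi * tables.gamma))
    radii = 1.0 / (1.0 / tables.rho_red - tanh(inner) / tables.rho)
    return radii, tables.rho_red, tables.rho


def gb_energy(system, radii, coords=None, params=None, kappa=0.7,
              tables=None, r2=None, charges=None):
    """GB polar solvation with Debye-Hueckel screening.

    E = -1/2 ke sum_ij (1/eps_p - exp(-kappa f)/eps_w) qi qj / f_ij over the
    full pair matrix including the i = j Born self terms (f_ii = R_i).
    """
    x = coords if coords is not None else system.coordinates
    if tables is None:
        tables = pair_tables(system, _params(system, params),
                             ad.val(x).dtype, charges=charges)
    if np.any(ad.val(radii) <= 0.0):
        raise ValueError("non-positive Born radius")
    if r2 is None:
        r2, _, _ = _pair_r(system, x, tables)
    st = tables.struct
    bi = getitem(radii, st["ii"])
    bj = getitem(radii, st["jj"])
    bb = bi * bj
    f = sqrt(r2 + bb * exp(-r2 / (4.0 * bb)))
    inv_f = 1.0 / f
    tau = 1.0 / EPS_SOLUTE - exp(-kappa * f) / EPS_SOLVENT
    e_off = asum(tables.keqq_all * tau * inv_f)
    tau_d = 1.0 / EPS_SOLUTE - exp(-kappa * radii) / EPS_SOLVENT
    e_diag = 0.5 * KE * asum(tables.qdiag * tau_d / radii)
    return -(e_off + e_diag)


def surface_area_energy(system, radii, params=None, tables=None):
    """ACE-style nonpolar term: factor * 4 pi (rho + probe)^2 (rho~/R)^6."""
    if tables is None:
        tables = pair_tables(system, _params(system, params),
                             ad.val(radii).dtype)
    ratio = tables.rho_red / radii
    r2_ = ratio * ratio
    r6 = r2_ * r2_ * r2_
    return tables.surface_factor * asum(tables.area0 * r6)


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

def total_potential(system, coords=None, params=None, kappa=0.7,
                    charges=None, tables=None):
    """Full energy breakdown; differentiable w.r.t. coords and parameters."""
    x = coords if coords is not None else system.coordinates
    if tables is None:
        up = _params(system, params)
        tables = pair_tables(system, up, ad.val(x).dtype, charges=charges)
    else:
        up = tables.up
    e_bond, e_angle, e_tors = bonded_energy(system, x, up, tables=tables)
    rr = _pair_r(system, x, tables)
    r2 = rr[0]
    e_lj = lennard_jones_energy(system, x, tables=tables, r2=r2)
    e_coul = coulomb_energy(system, x, tables=tables, inv_r=rr[2])
    radii, _, _ = born_radii(system, x, tables=tables, rr=rr)
    e_gb = gb_energy(system, radii, x, kappa=kappa, tables=tables, r2=r2)
    e_sa = surface_area_energy(system, radii, tables=tables)
    return EnergyBreakdown(e_bond, e_angle, e_tors, e_lj, e_coul, e_gb, e_sa)


def forces(system, coords, params=None, kappa=0.7, charges=None,
           tables=None):
    """-dE/dx as a plain array (coords may be array or Var)."""
    xv = ad.Var(np.asarray(ad.val(coords)))
    e = total_potential(system, xv, params, kappa=kappa, charges=charges,
                        tables=tables).total
    (g,) = ad.grad(e, [xv], taped=False)
    return -g, float(ad.val(e))


# ---------------------------------------------------------------------------
# analytic forces
# ---------------------------------------------------------------------------

def force_analytic(system, coords, tables, kappa=0.7):
    """-dE/dx assembled from hand-derived per-term gradients.

    Mathematically identical to differentiating :func:`total_potential`
    (asserted against it in the test suite) but with a much smaller
    expression graph, which matters when the force itself is differentiated
    through thousands of integrator steps. Built entirely from autodiff
    primitives, so it remains differentiable with respect to coordinates and
    any Var-valued pair tables.
    """
    x = coords
    st = tables.struct
    n = tables.n
    dtype = np.asarray(ad.val(x)).dtype

    d = spmatmul(st["S"], x, st["ST"])
    r2 = asum(d * d, axis=1)
    r = sqrt(r2)
    inv_r = 1.0 / r
    inv_r2 = inv_r * inv_r

    # LJ + Coulomb: dE/dr2
    sr2 = tables.sig2 / r2
    sr6 = sr2 * sr2 * sr2
    c_r2 = (tables.w_lj * tables.eps4 * (3.0 * sr6 - 6.0 * sr6 * sr6) * (1.0 / r2)
            - 0.5 * tables.keqq_c * inv_r * inv_r2)

    # Born radii (primal, as in born_radii) ------------------------------
    r_cat = getitem(r, st["tile"])
    inv_r_cat = getitem(inv_r, st["tile"])
    rho_i = tables.rho_red_cat
    s_j = tables.s_cat
    u = r_cat + s_j
    l_abs = absolute(r_cat - s_j)
    mask_rho = ad.val(rho_i) >= ad.val(l_abs)          # L clamped at rho~
    l = where(mask_rho, rho_i, l_abs)
    inv_l = 1.0 / l
    inv_u = 1.0 / u
    s2 = s_j * s_j
    hterm = 0.5 * (inv_l - inv_u +
                   0.25 * (r_cat - s2 * inv_r_cat) *
                   (inv_u * inv_u - inv_l * inv_l) +
                   0.5 * log(l * inv_u) * inv_r_cat)
    engulf = ad.val(rho_i) < ad.val(s_j) - ad.val(r_cat)
    any_engulf = engulf.any()
    if any_engulf:
        hterm = hterm + where(engulf, 1.0 / rho_i - inv_l, 0.0)
    active = ad.val(rho_i) < ad.val(u)
    hterm = where(active, hterm, 0.0)
    # neck (on condensed pairs)
    delta = (r - tables.d0) / _NECK_WIDTH
    d2_ = delta * delta
    d4 = d2_ * d2_
    denom = 1.0 + d2_ + 0.3 * d2_ * d4
    bump = 0.3 / denom
    z = (tables.neck_cutoff - r) / (2.0 * _NECK_WINDOW)
    tz = tanh(z)
    window = 0.5 * (1.0 + tz)
    neck = tables.neck_scale * bump * window
    integral = hterm + getitem(neck, st["tile"])
    i_sum = scatter_add(integral, st["atom_cat"], (n,))
    psi = i_sum * tables.rho_red
    inner = psi * (tables.alpha - psi * (tables.beta - psi * tables.gamma))
    tin = tanh(inner)
    b_radii = 1.0 / (1.0 / tables.rho_red - tin / tables.rho)

    # GB pair term: dE/dr2 at fixed B, and dE/dB accumulation ------------
    bi = getitem(b_radii, st["ii"])
    bj = getitem(b_radii, st["jj"])
    bb = bi * bj
    uexp = exp(-r2 / (4.0 * bb))
    f2 = r2 + bb * uexp
    f = sqrt(f2)
    inv_f = 1.0 / f
    ekf = exp(-kappa * f)
    tau = 1.0 / EPS_SOLUTE - ekf / EPS_SOLVENT
    # dE/df per pair (off-diagonal counts once in condensed form, but the
    # double sum counts it twice; keqq_all already folds ke)
    g_f = -tables.keqq_all * ((kappa / EPS_SOLVENT) * ekf * inv_f -
                              tau * inv_f * inv_f)
    g_f2 = 0.5 * g_f * inv_f                       # dE/d(f^2)
    c_r2 = c_r2 + g_f2 * (1.0 - 0.25 * uexp)
    # dE/dB via pair function
    dbb = g_f2 * uexp * (1.0 + r2 / (4.0 * bb))
    g_b = (scatter_add(dbb * bj, st["ii"], (n,)) +
           scatter_add(dbb * bi, st["jj"], (n,)))
    # diagonal Born self-energy: E = -0.5 ke q^2 tau(B)/B
    ekb = exp(-kappa * b_radii)
    tau_d = 1.0 / EPS_SOLUTE - ekb / EPS_SOLVENT
    inv_b = 1.0 / b_radii
    g_b = g_b - 0.5 * KE * tables.qdiag * ((kappa / EPS_SOLVENT) * ekb * inv_b -
                                           tau_d * inv_b * inv_b)
    # surface area: E = saf * area0 * (rho~/B)^6
    ratio = tables.rho_red * inv_b
    ratio2 = ratio * ratio
    g_b = g_b - 6.0 * tables.surface_factor * tables.area0 * \
        ratio2 * ratio2 * ratio2 * inv_b

    # chain to r through the Born radii ----------------------------------
    sech2 = 1.0 - tin * tin
    inner_p = tables.alpha - psi * (2.0 * tables.beta - psi * (3.0 * tables.gamma))
    g_psi = g_b * b_radii * b_radii * sech2 * inner_p / tables.rho
    g_i = g_psi * tables.rho_red
    g_i_cat = getitem(g_i, st["atom_cat"])
    # dH/dr (structural form; L' = 0 on the clamped branch, sign(r-s) else)
    lp = np.where(mask_rho, 0.0,
                  np.sign(ad.val(r_cat) - ad.val(s_j))).astype(dtype)
    inv_l2 = inv_l * inv_l
    inv_u2 = inv_u * inv_u
    dh = 0.5 * (-lp * inv_l2 + inv_u2 +
                0.25 * (1.0 + s2 * inv_r_cat * inv_r_cat) * (inv_u2 - inv_l2) +
                0.5 * (r_cat - s2 * inv_r_cat) *
                (lp * inv_l2 * inv_l - inv_u2 * inv_u) +
                0.5 * ((lp * inv_l - inv_u) * inv_r_cat -
                       log(l * inv_u) * inv_r_cat * inv_r_cat))
    if any_engulf:
        dh = dh + where(engulf, -inv_l2, 0.0)
    dh = where(active, dh, 0.0)
    # dneck/dr (condensed)
    dbump = -0.3 * (2.0 * delta + 1.8 * delta * d4) / (denom * denom * _NECK_WIDTH)
    dwindow = -(1.0 - tz * tz) / (4.0 * _NECK_WINDOW)
    dneck = tables.neck_scale * (dbump * window + bump * dwindow)
    prod = g_i_cat * dh
    p = len(st["ii"])
    c_r_born = (asum(reshape(prod, (2, p)), axis=0) +
                asum(reshape(g_i_cat, (2, p)), axis=0) * dneck)
    c_r2 = c_r2 + 0.5 * c_r_born * inv_r

    force = -2.0 * spmatmul(st["ST"], reshape(c_r2, (-1, 1)) * d, st["S"])

    # bonds ---------------------------------------------------------------
    if len(system.bonds):
        db = spmatmul(st["SB"], x, st["SBT"])
        rb = sqrt(asum(db * db, axis=1))
        coef = 2.0 * system.bond_k.astype(dtype) * \
            (rb - system.bond_r0.astype(dtype)) / rb
        force = force - spmatmul(st["SBT"], reshape(coef, (-1, 1)) * db,
                                 st["SB"])
    if system.tether_k:
        c = system.tether_center if system.tether_center is not None else 0.0
        force = force - system.tether_k * (x - np.asarray(c, dtype=dtype))

    # angles --------------------------------------------------------------
    if len(system.angles):
        uu = spmatmul(st["SU"], x, st["SUT"])
        vv = spmatmul(st["SV"], x, st["SVT"])
        nu2 = asum(uu * uu, axis=1)
        nv2 = asum(vv * vv, axis=1)
        inv_nunv = 1.0 / sqrt(nu2 * nv2)
        cosang = asum(uu * vv, axis=1) * inv_nunv
        cosang = minimum(maximum(cosang, -1.0 + 1e-9), 1.0 - 1e-9)
        theta = arccos(cosang)
        dedth = 2.0 * system.angle_k.astype(dtype) * \
            (theta - system.angle_theta0.astype(dtype))
        gcos = -dedth / sqrt(1.0 - cosang * cosang)
        du = reshape(gcos * inv_nunv, (-1, 1)) * vv - \
            reshape(gcos * cosang / nu2, (-1, 1)) * uu
        dv = reshape(gcos * inv_nunv, (-1, 1)) * uu - \
            reshape(gcos * cosang / nv2, (-1, 1)) * vv
        force = force - spmatmul(st["SUT"], du, st["SU"]) - \
            spmatmul(st["SVT"], dv, st["SV"])

    # torsions ------------------------------------------------------------
    if len(system.torsion_atoms):
        b1 = spmatmul(st["S1"], x, st["S1T"])
        b2 = spmatmul(st["S2"], x, st["S2T"])
        b3 = spmatmul(st["S3"], x, st["S3T"])
        n1 = _cross(b1, b2)
        n2 = _cross(b2, b3)
        nb2 = sqrt(asum(b2 * b2, axis=1))
        m1 = _cross(n1, b2 / reshape(nb2, (-1, 1)))
        cphi = asum(n1 * n2, axis=1)
        sphi = asum(m1 * n2, axis=1)
        phi = arctan2(sphi, cphi)
        trainable = system.torsion_kidx >= 0
        amp = where(trainable,
                    getitem(tables.up.torsion_k,
                            np.maximum(system.torsion_kidx, 0)),
                    system.torsion_kfixed.astype(dtype))
        nper = system.torsion_n.astype(dtype)
        dedphi = -amp * nper * ad.sin(nper * phi -
                                      system.torsion_phase.astype(dtype))
        n1sq = asum(n1 * n1, axis=1)
        n2sq = asum(n2 * n2, axis=1)
        dphi_db1 = reshape(-nb2 / n1sq, (-1, 1)) * n1
        dphi_db3 = reshape(-nb2 / n2sq, (-1, 1)) * n2
        b1b2 = asum(b1 * b2, axis=1)
        b3b2 = asum(b2 * b3, axis=1)
        dphi_db2 = reshape(b1b2 / (nb2 * nb2), (-1, 1)) * \
            (reshape(nb2 / n1sq, (-1, 1)) * n1) + \
            reshape(b3b2 / (nb2 * nb2), (-1, 1)) * \
            (reshape(nb2 / n2sq, (-1, 1)) * n2)
        gd = reshape(dedphi, (-1, 1))
        force = force - spmatmul(st["S1T"], gd * dphi_db1, st["S1"]) - \
            spmatmul(st["S2T"], gd * dphi_db2, st["S2"]) - \
            spmatmul(st["S3T"], gd * dphi_db3, st["S3"])

    return force
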