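"""Deterministic toy-system generation for closed-loop testing.

Every stage of the training pipeline can be exercised without external
downloads: idealised polyalanine/glycine chains built from internal
coordinates, a single tethered particle with an analytic Gibbs distribution,
self-generated reference distance statistics (the engine run with a stated
parameter vector stands in for explicit-solvent reference trajectories,
preserving the structure of the training problem - matching another
Hamiltonian's distance distributions - at desk scale), and rigid multi-copy
fixtures for contact/oligomer analysis.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np

from . import dynamics as dyn
from . import forcefield as ff
from . import loss as ls
from . import topology as topo

# idealised backbone geometry (nm / degrees)
_B = {"N-CA": 0.1449, "CA-C": 0.1522, "C-N": 0.1335, "C-O": 0.1229,
      "N-H": 0.101, "C-H": 0.109, "CA-CB": 0.1526, "CB-OG": 0.141,
      "O-H": 0.096}
_A = {"N-CA-C": 110.1, "CA-C-N": 116.6, "C-N-CA": 121.9, "CA-C-O": 120.4,
      "C-N-H": 119.0, "tet": 109.47}

GEOMETRIES = {"extended": (-180.0, 180.0), "helical": (-57.0, -47.0)}


@dataclass
class ToySpec:
    n_residues: int
    geometry: str = "extended"   # extended | helical | custom
    seed: int = 0
    noise_amplitude: float = 0.0  # nm
    sequence: str = None          # e.g. "AGA"; default polyalanine
    phi_psi: tuple = None         # for geometry == "custom"

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors and internal coordinates."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= max(np.linalg.norm(n), 1e-12)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _tetra_pair(center, n1, n2):
    """The two remaining tetrahedral directions at ``center``."""
    b1 = (n1 - center) / np.linalg.norm(n1 - center)
    b2 = (n2 - center) / np.linalg.norm(n2 - center)
    u = b1 + b2
    u /= np.linalg.norm(u)
    w = np.cross(b1, b2)
    w /= np.linalg.norm(w)
    return -0.5774 * u + 0.8165 * w, -0.5774 * u - 0.8165 * w


def _build_backbone(n_res, phi, psi):
    """N/CA/C/O positions with ideal bonds/angles and given (phi, psi)."""
    N = [np.zeros(3)]
    CA = [np.array([_B["N-CA"], 0.0, 0.0])]
    ang = math.radians(_A["N-CA-C"])
    C = [CA[0] + _B["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(_nerf(N[-1], CA[-1], C[-1], _B["C-N"], _A["CA-C-N"], psi))
        CA.append(_nerf(CA[-1], C[-1], N[-1], _B["N-CA"], _A["C-N-CA"], 180.0))
        C.append(_nerf(C[-1], N[-1], CA[-1], _B["CA-C"], _A["N-CA-C"], phi))
    O = []
    for i in range(n_res):
        ref = N[i + 1] if i + 1 < n_res else None
        tor = psi + 180.0
        O.append(_nerf(N[i], CA[i], C[i], _B["C-O"], _A["CA-C-O"], tor))
    return N, CA, C, O


def make_toy_chain(spec, registry=None):
    """Idealised Ala/Gly chain: returns (pdb_text, MolecularSystem).

    The first and last residues take the charged-terminus templates. With
    ``noise_amplitude > 0`` deterministic Gaussian noise (per ``seed``) is
    added to every coordinate.
    """
    if registry is None:
        _, registry = ff.build_default_registry()
    seq = spec.sequence or "A" * spec.n_residues
    if len(seq) != spec.n_residues:
        raise ValueError("sequence length mismatch")
    resnames = [{"A": "ALA", "G": "GLY"}[c] for c in seq]
    if spec.geometry == "custom":
        phi, psi = spec.phi_psi
    else:
        phi, psi = GEOMETRIES[spec.geometry]
    n_res = spec.n_residues
    N, CA, C, O = _build_backbone(n_res, phi, psi)

    names, coords, res_of = [], [], []

    def put(i, name, pos):
        names.append(name)
        coords.append(pos)
        res_of.append(i)

    for i in range(n_res):
        first, last = i == 0, i == n_res - 1
        put(i, "N", N[i])
        put(i, "CA", CA[i])
        put(i, "C", C[i])
        put(i, "O", O[i])
        if last:
            put(i, "OXT", _nerf(N[i], CA[i], C[i], _B["C-O"], _A["CA-C-O"],
                                psi))
        # amide / ammonium hydrogens
        if first:
            for k, tor in enumerate((60.0, 180.0, 300.0)):
                put(i, f"H{k+1}", _nerf(C[i], CA[i], N[i], _B["N-H"],
                                        _A["tet"], tor))
        else:
            put(i, "H", _nerf(C[i - 1], CA[i], N[i], _B["N-H"],
                              _A["C-N-H"], 180.0))
        if resnames[i] == "ALA":
            d_cb, d_ha = _tetra_pair(CA[i], N[i], C[i])
            cb = CA[i] + _B["CA-CB"] * d_cb
            put(i, "CB", cb)
            put(i, "HA", CA[i] + _B["C-H"] * d_ha)
            for k, tor in enumerate((60.0, 180.0, 300.0)):
                put(i, f"HB{k+1}", _nerf(N[i], CA[i], cb, _B["C-H"],
                                         _A["tet"], tor))
        else:  # GLY
            d1, d2 = _tetra_pair(CA[i], N[i], C[i])
            put(i, "HA2", CA[i] + _B["C-H"] * d1)
            put(i, "HA3", CA[i] + _B["C-H"] * d2)
    coords = np.array(coords)
    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(scale=spec.noise_amplitude,
                                     size=coords.shape)
    atoms = {"atom_names": names, "residue_of_atom": np.array(res_of),
             "residue_names": resnames, "coordinates": coords}
    system = topo.build_system(atoms, registry)
    buf = io.StringIO()
    topo.write_pdb(buf, system)
    return buf.getvalue(), system


def make_harmonic_system(k=1000.0, mass=12.011, temperature=300.0,
                         registry=None):
    """Single particle in an isotropic well E = k/2 |x|^2 (Gibbs Var = kT/k)."""
    if k <= 0 or mass <= 0:
        raise ValueError("k and mass must be positive")
    if registry is None:
        _, registry = ff.build_default_registry()
    s = topo.system_from_bond_graph(["C9"], [], np.zeros((1, 3)), registry,
                                    charges=np.zeros(1), masses=[mass])
    s.tether_k = k
    s.tether_center = np.zeros(3)
    return s


def make_reference_stats(system, vector, config, coords=None):
    """Reference distance statistics from a plain (non-differentiable) run."""
    _, store = dyn.simulate_with_checkpoints(
        system, vector, config, coords=coords, store_snapshots=False)
    return ls.finalize_statistics(store.sum_x, store.sum_x2,
                                  store.frame_count, len(system.ca_indices))


def make_dimer_fixture(separation, n_peptides, box=None, gaps=None,
                       registry=None):
    """Rigid peptide copies along x at controlled surface separations.

    ``gaps`` (length n_peptides - 1) overrides the uniform ``separation``
    between consecutive copies' nearest atoms. Returns (coords, groups,
    template system).
    """
    if separation <= 0:
        raise ValueError("peptides would overlap at the requested separation")
    if registry is None:
        _, registry = ff.build_default_registry()
    _, base = make_toy_chain(ToySpec(n_residues=2, geometry="extended"),
                             registry)
    xyz = base.coordinates - base.coordinates.mean(axis=0)
    extent = xyz[:, 0].max() - xyz[:, 0].min()
    gaps = list(gaps) if gaps is not None else [separation] * (n_peptides - 1)
    if len(gaps) != n_peptides - 1:
        raise ValueError("need one gap per consecutive pair")
    if any(g <= 0 for g in gaps):
        raise ValueError("peptides would overlap at the requested separation")
    coords, groups = [], []
    xpos = 0.0
    for p in range(n_peptides):
        shifted = xyz + np.array([xpos, 0.0, 0.0])
        groups.append(np.arange(len(xyz)) + p * len(xyz))
        coords.append(shifted)
        if p < n_peptides - 1:
            xpos += extent + gaps[p]
    return np.concatenate(coords), groups, base
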