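"""Build a MolecularSystem from a PDB file and the force-field registry.

Atoms are matched to residue templates; bonded terms (bonds, angles, proper
torsions) are enumerated from the residue bond graph plus the backbone
C(i)-N(i+1) peptide bonds. Exclusions are atom pairs within two bonds, 1-4
pairs are those at exactly three bonds. Indexing is 0-based throughout; PDB
serial numbers are ignored.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from . import autodiff as ad
from . import forcefield as ff

AMINO_ACIDS = {"ALA", "GLY", "SER"}
CAPS = {"ACE", "NME"}

_H_BOND_LENGTH = {"N": 0.101, "N3": 0.101, "CT": 0.109, "C8": 0.109,
                  "C9": 0.109, "OH": 0.096, "CA": 0.108}


class TopologyError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Integrator, thermostat, screening and recording settings for one run."""

    dt: float = 0.001            # ps
    temperature: float = 300.0   # K
    friction: float = 0.1        # 1/ps
    kappa: float = 0.7           # 1/nm (Debye-Hueckel)
    n_steps: int = 5000
    record_interval: int = 5000
    checkpoint_interval: int = 100
    clip_threshold: float = 0.1
    seed: int = 0
    precision: str = "double"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.clip_threshold <= 0:
            raise ValueError("clip_threshold must be positive")
        for name in ("record_interval", "checkpoint_interval"):
            iv = getattr(self, name)
            if self.n_steps % iv != 0:
                raise ValueError(f"{name}={iv} must divide n_steps={self.n_steps}")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")

    @property
    def dtype(self):
        return np.float32 if self.precision == "single" else np.float64


@dataclass
class MolecularSystem:
    """Atoms, typed bonded/non-bonded terms and pair tables for one molecule."""

    atom_names: list
    atom_types: list
    type_idx: np.ndarray
    residue_index: np.ndarray
    residue_names: list            # per residue
    template_names: list           # per residue (terminal variants resolved)
    masses: np.ndarray
    base_charges: np.ndarray
    res_formal: np.ndarray
    coordinates: np.ndarray        # (N, 3) nm
    bonds: np.ndarray              # (B, 2) int
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray             # (A, 3) int
    angle_k: np.ndarray
    angle_theta0: np.ndarray
    torsion_atoms: np.ndarray      # (M, 4) int, one row per periodic term
    torsion_n: np.ndarray
    torsion_phase: np.ndarray
    torsion_kidx: np.ndarray       # index into the 33 trainable amplitudes, -1 fixed
    torsion_kfixed: np.ndarray
    exclusions: set                # frozenset pairs within 2 bonds
    pairs_14: set
    ca_indices: np.ndarray
    gb_class_idx: np.ndarray       # index into forcefield.GB_CLASSES
    elem_idx: np.ndarray           # index into forcefield.ELEMENTS
    registry_version: str = ""
    charges: Optional[np.ndarray] = None   # final rescaled charges
    params: object = None                  # UnpackedParameters after apply
    tether_k: float = 0.0
    tether_center: Optional[np.ndarray] = None
    _nb_masks: dict = field(default_factory=dict, repr=False)

    @property
    def n_atoms(self):
        return len(self.atom_names)

    def with_parameters(self, up):
        import copy as _copy
        new = _copy.copy(self)
        new.params = up
        new.charges = ad.val(ff.compute_system_charges(self, up.charge_scale))
        new._nb_masks = dict(self._nb_masks)
        return new

    def nb_masks(self):
        """(include, is14) boolean (N, N) upper-triangle masks, cached."""
        if "include" not in self._nb_masks:
            n = self.n_atoms
            triu = np.triu(np.ones((n, n), dtype=bool), 1)
            excl = np.zeros((n, n), dtype=bool)
            for (i, j) in self.exclusions:
                excl[i, j] = excl[j, i] = True
            is14 = np.zeros((n, n), dtype=bool)
            for (i, j) in self.pairs_14:
                is14[i, j] = is14[j, i] = True
            self._nb_masks["include"] = triu & ~excl
            self._nb_masks["is14"] = triu & is14
        return self._nb_masks["include"], self._nb_masks["is14"]


def bond_graph_distances(n_atoms, bonds, max_dist=3):
    """Pairs at bonded distance 1..max_dist via BFS from each atom.

    Returns a dict mapping distance -> set of frozen (i, j) pairs with i < j.
    """
    adj = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    out = {d: set() for d in range(1, max_dist + 1)}
    for start in range(n_atoms):
        dist = {start: 0}
        q = deque([start])
        while q:
            u = q.popleft()
            if dist[u] >= max_dist:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for v, d in dist.items():
            if 0 < d and start < v:
                out[d].add((start, v))
    return out


def load_pdb(path_or_file):
    """Read atom records from a PDB file.

    Coordinates are converted from Angstrom to nm; residue indices are made
    contiguous from 0. Unknown residue names (e.g. HETATM ligands without a
    template) raise a :class:`TopologyError` naming the residue.
    """
    if hasattr(path_or_file, "read"):
        f = pdb.PDBFile.read(path_or_file)
    else:
        f = pdb.PDBFile.read(str(path_or_file))
    arr = f.get_structure(model=1)
    names = list(arr.atom_name)
    resnames = []
    residue_of_atom = []
    last = None
    for rid, rname, ch in zip(arr.res_id, arr.res_name, arr.chain_id):
        key = (ch, int(rid), rname)
        if key != last:
            resnames.append(str(rname))
            last = key
        residue_of_atom.append(len(resnames) - 1)
    for rn in resnames:
        if rn not in AMINO_ACIDS and rn not in CAPS:
            raise TopologyError(f"no residue template for '{rn}'")
    coords = np.asarray(arr.coord, dtype=float) * 0.1
    return {"atom_names": names, "residue_of_atom": np.array(residue_of_atom),
            "residue_names": resnames, "coordinates": coords}


def _resolve_template_name(resnames, i, registry):
    """Pick the template: terminal variants for uncapped chain ends."""
    name = resnames[i]
    if name in CAPS:
        return name
    first = i == 0 or resnames[i - 1] == "NME"  # new chain start
    capped_front = i > 0 and resnames[i - 1] in (AMINO_ACIDS | {"ACE"})
    last = i == len(resnames) - 1 or resnames[i + 1] == "ACE"
    capped_back = i < len(resnames) - 1 and resnames[i + 1] in (AMINO_ACIDS | {"NME"})
    if first and not capped_front:
        cand = "N" + name
        if cand not in registry.residues:
            raise TopologyError(f"no N-terminal template for '{name}'")
        return cand
    if last and not capped_back:
        cand = "C" + name
        if cand not in registry.residues:
            raise TopologyError(f"no C-terminal template for '{name}'")
        return cand
    return name


def _place_missing_hydrogens(tpl, present, coords_by_name, rng):
    """Idealised placement of template hydrogens absent from the input."""
    heavy_of = {}
    for a, b in tpl.bonds:
        for h, x in ((a, b), (b, a)):
            if tpl.atom_types[tpl.atom_names.index(h)].startswith("H"):
                heavy_of[h] = x
    for name in tpl.atom_names:
        if name in present:
            continue
        ty = tpl.atom_types[tpl.atom_names.index(name)]
        if not ty.startswith("H"):
            raise TopologyError(f"missing heavy atom {name} in residue "
                                f"{tpl.residue_name}")
        heavy = heavy_of[name]
        if heavy not in coords_by_name:
            raise TopologyError(f"cannot place {name}: {heavy} missing")
        hpos = coords_by_name[heavy]
        nbrs = [coords_by_name[a if b == heavy else b]
                for a, b in tpl.bonds
                if heavy in (a, b) and (a if b == heavy else b) in coords_by_name
                and (a if b == heavy else b) != heavy]
        blen = _H_BOND_LENGTH.get(tpl.atom_types[tpl.atom_names.index(heavy)], 0.105)
        if nbrs:
            d = -np.sum([(p - hpos) / np.linalg.norm(p - hpos) for p in nbrs], axis=0)
            if np.linalg.norm(d) < 1e-6:
                d = rng.normal(size=3)
        else:
            d = rng.normal(size=3)
        d = d / np.linalg.norm(d)
        # nudge so several hydrogens on one centre do not coincide
        d = d + 0.25 * rng.normal(size=3)
        d = d / np.linalg.norm(d)
        coords_by_name[name] = hpos + blen * d



def _enumerate_bonded(types, bonds_arr, registry):
    """Bond/angle/torsion parameter arrays from a bond list."""
    n = len(types)
    adj = [[] for _ in range(n)]
    for i, j in bonds_arr:
        adj[i].append(j)
        adj[j].append(i)
    bk, br0 = [], []
    for i, j in bonds_arr:
        k, r0 = registry.bond_param(types[i], types[j])
        bk.append(k)
        br0.append(r0)
    angles, ak, ath = [], [], []
    for j in range(n):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                angles.append((i, j, k))
                kk, th = registry.angle_param(types[i], types[j], types[k])
                ak.append(kk)
                ath.append(th)
    tor_atoms, tor_n, tor_phase, tor_kidx, tor_kfix = [], [], [], [], []
    key_term_offset = np.cumsum([0] + [len(k["terms"])
                                       for k in registry.torsion_keys])
    seen = set()
    for j, k in bonds_arr:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l in (j, i):
                    continue
                quad = (i, j, k, l) if (i, j, k, l) <= (l, k, j, i) else (l, k, j, i)
                if quad in seen:
                    continue
                seen.add(quad)
                ki = registry.match_torsion(types[quad[0]], types[quad[1]],
                                            types[quad[2]], types[quad[3]])
                if ki >= 0:
                    for m, (per, amp, phase) in enumerate(
                            registry.torsion_keys[ki]["terms"]):
                        tor_atoms.append(quad)
                        tor_n.append(per)
                        tor_phase.append(phase)
                        tor_kidx.append(key_term_offset[ki] + m)
                        tor_kfix.append(amp)
    return dict(
        adj=adj,
        bond_k=np.array(bk), bond_r0=np.array(br0),
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        angle_k=np.array(ak), angle_theta0=np.array(ath),
        torsion_atoms=np.array(tor_atoms, dtype=int).reshape(-1, 4),
        torsion_n=np.array(tor_n, dtype=float),
        torsion_phase=np.array(tor_phase, dtype=float),
        torsion_kidx=np.array(tor_kidx, dtype=int),
        torsion_kfixed=np.array(tor_kfix, dtype=float),
    )

def build_system(atoms, registry, tether_k=0.0, tether_center=None):
    """Instantiate a :class:`MolecularSystem` from loaded atom records.

    ``atoms`` is the dict returned by :func:`load_pdb`. Missing hydrogens are
    added at idealised positions; missing heavy atoms are an error.
    """
    resnames = atoms["residue_names"]
    nres = len(resnames)
    rng = np.random.default_rng(0)

    tpl_names = [_resolve_template_name(resnames, i, registry) for i in range(nres)]
    names, types, res_of, base_q, coords = [], [], [], [], []
    res_formal = []
    bonds = []
    offset = 0
    prev_c = None
    for i, tname in enumerate(tpl_names):
        tpl = registry.residues[tname]
        in_res = atoms["residue_of_atom"] == i
        have = {n: atoms["coordinates"][j]
                for j, n in enumerate(atoms["atom_names"]) if in_res[j]}
        extra = set(have) - set(tpl.atom_names)
        if extra:
            raise TopologyError(f"unknown atoms {sorted(extra)} in residue {tname}")
        _place_missing_hydrogens(tpl, set(have), have, rng)
        for n, ty, q in zip(tpl.atom_names, tpl.atom_types, tpl.base_charges):
            names.append(n)
            types.append(ty)
            res_of.append(i)
            base_q.append(q)
            coords.append(have[n])
        for a, b in tpl.bonds:
            bonds.append((offset + tpl.atom_names.index(a),
                          offset + tpl.atom_names.index(b)))
        # peptide bond to previous residue
        link_n = "N" if tname != "NME" else "N"
        if prev_c is not None and tname not in ("ACE",):
            if link_n in tpl.atom_names:
                bonds.append((prev_c, offset + tpl.atom_names.index(link_n)))
        prev_c = offset + tpl.atom_names.index("C") if "C" in tpl.atom_names else None
        res_formal.append(tpl.formal_charge)
        offset += len(tpl.atom_names)

    n = len(names)
    type_idx = np.array([ff.ATOM_TYPES.index(t) for t in types])
    masses = np.array([registry.masses[t] for t in types])
    coords = np.array(coords, dtype=float)
    bonds_arr = np.array(sorted({(min(b), max(b)) for b in bonds}), dtype=int)

    dists = bond_graph_distances(n, bonds_arr, max_dist=3)
    exclusions = dists[1] | dists[2]
    pairs_14 = dists[3] - exclusions
    bonded = _enumerate_bonded(types, bonds_arr, registry)
    adj = bonded.pop("adj")

    ca = []
    for i in range(nres):
        if resnames[i] in AMINO_ACIDS:
            idx = [a for a in range(n) if res_of[a] == i and names[a] == "CA"]
            ca.append(idx[0])
    gb_cls = []
    for a in range(n):
        bonded_types = [types[b] for b in adj[a]]
        gb_cls.append(ff.GB_CLASSES.index(ff.gb_class_of(types[a], bonded_types)))
    elem_idx = np.array([ff.ELEMENTS.index(registry.elements[t]) for t in types])

    return MolecularSystem(
        atom_names=names, atom_types=types, type_idx=type_idx,
        residue_index=np.array(res_of), residue_names=list(resnames),
        template_names=tpl_names, masses=masses,
        base_charges=np.array(base_q), res_formal=np.array(res_formal, dtype=float),
        coordinates=coords,
        bonds=bonds_arr,
        exclusions=exclusions, pairs_14=pairs_14,
        ca_indices=np.array(ca, dtype=int),
        gb_class_idx=np.array(gb_cls), elem_idx=elem_idx,
        registry_version=registry.version,
        tether_k=tether_k,
        tether_center=tether_center,
        **bonded,
    )


def system_from_pdb(path, registry, **kw):
    return build_system(load_pdb(path), registry, **kw)


def system_from_bond_graph(types, bonds, coordinates, registry, charges=None,
                           masses=None):
    """Minimal system from an explicit bond graph (toy molecules, tests)."""
    n = len(types)
    bonds_arr = np.array(sorted({(min(b), max(b)) for b in bonds}),
                         dtype=int).reshape(-1, 2)
    dists = bond_graph_distances(n, bonds_arr, max_dist=3)
    bonded = _enumerate_bonded(types, bonds_arr, registry)
    adj = bonded.pop("adj")
    if charges is None:
        charges = np.zeros(n)
    if masses is None:
        masses = np.array([registry.masses[t] for t in types])
    gb_cls = [ff.GB_CLASSES.index(ff.gb_class_of(types[a],
                                                 [types[b] for b in adj[a]]))
              for a in range(n)]
    return MolecularSystem(
        atom_names=[f"X{i}" for i in range(n)], atom_types=list(types),
        type_idx=np.array([ff.ATOM_TYPES.index(t) for t in types]),
        residue_index=np.zeros(n, dtype=int), residue_names=["UNK"],
        template_names=["UNK"], masses=np.asarray(masses, dtype=float),
        base_charges=np.asarray(charges, dtype=float),
        res_formal=np.array([np.sum(charges)], dtype=float),
        coordinates=np.asarray(coordinates, dtype=float),
        bonds=bonds_arr,
        exclusions=dists[1] | dists[2], pairs_14=dists[3] - (dists[1] | dists[2]),
        ca_indices=np.array([], dtype=int),
        gb_class_idx=np.array(gb_cls),
        elem_idx=np.array([ff.ELEMENTS.index(t[0]) for t in types]),
        registry_version=registry.version,
        **bonded,
    )


def write_pdb(path, system, coordinates=None, models=None):
    """Write a PDB snapshot (or multi-model trajectory) for a system."""
    coords_list = models if models is not None else [
        coordinates if coordinates is not None else system.coordinates]
    arrs = []
    for c in coords_list:
        arr = struc.AtomArray(system.n_atoms)
        arr.coord = np.asarray(c) * 10.0
        arr.atom_name = np.array(system.atom_names)
        arr.res_name = np.array([system.residue_names[r]
                                 for r in system.residue_index])
        arr.res_id = np.array(system.residue_index) + 1
        arr.chain_id = np.array(["A"] * system.n_atoms)
        arr.element = np.array([t[0] for t in system.atom_types])
        arrs.append(arr)
    stack = struc.stack(arrs) if len(arrs) > 1 else arrs[0]
    f = pdb.PDBFile()
    f.set_structure(stack)
    if hasattr(path, "write"):
        f.write(path)
    else:
        f.write(str(path))
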