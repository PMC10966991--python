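"""Trajectory analysis operators: compactness, stability, contacts, clusters.

These mirror the observables used to validate implicit-solvent force fields
on disordered and aggregating systems: the radius of gyration, the windowed
RMSD to a reference structure, per-residue ligand contact fractions with a
6 Angstrom minimum-distance rule, and oligomer sizes from single-linkage
clustering of peptides with a 4 Angstrom atom-contact criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation


@dataclass
class Trajectory:
    """In-memory trajectory: frames (list of (N, 3) nm arrays) + metadata."""

    frames: list
    atom_names: list = None
    masses: np.ndarray = None
    box: float = None            # cubic box edge (nm) or None
    frame_interval: float = None  # ps

    def __post_init__(self):
        n = {np.asarray(f).shape for f in self.frames}
        if len(n) > 1:
            raise ValueError("frames differ in atom count")

    @classmethod
    def from_record(cls, record, system):
        return cls(frames=record.snapshots, atom_names=system.atom_names,
                   masses=system.masses,
                   frame_interval=(record.times[1] - record.times[0]
                                   if len(record.times) > 1 else None))


def _min_image(diff, box):
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return diff


def radius_of_gyration(frame, masses):
    """Mass-weighted RMS distance from the centre of mass (nm)."""
    frame = np.asarray(frame, dtype=float)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    com = (masses[:, None] * frame).sum(axis=0) / total
    d2 = ((frame - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * d2).sum() / total))


def rg_series(trajectory):
    return np.array([radius_of_gyration(f, trajectory.masses)
                     for f in trajectory.frames])


def _fit_rmsd(mobile, reference):
    """Best-fit (Kabsch) RMSD after removing translation and rotation."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref, mob)
    return float(np.sqrt(((rot.apply(mob) - ref) ** 2).sum(axis=1).mean()))


def windowed_rmsd(trajectory, reference, selection=None, window=10):
    """Per-frame best-fit RMSD, smoothed over +-``window`` frames.

    ``selection`` is an index array (e.g. the Calpha atoms); the window mean
    truncates at the trajectory edges.
    """
    if len(trajectory.frames) < 1:
        raise ValueError("empty trajectory")
    reference = np.asarray(reference, dtype=float)
    raw = []
    for f in trajectory.frames:
        f = np.asarray(f, dtype=float)
        if selection is not None:
            f = f[selection]
        raw.append(_fit_rmsd(f, reference))
    raw = np.array(raw)
    out = np.empty_like(raw)
    n = len(raw)
    for t in range(n):
        lo, hi = max(0, t - window), min(n, t + window + 1)
        out[t] = raw[lo:hi].mean()
    return out


def ligand_contact_fraction(trajectory, ligand_indices, residue_heavy_sets,
                            cutoff=0.6):
    """Fraction of frames in which each residue contacts the ligand.

    A contact is a minimum distance below ``cutoff`` (strict) between any
    ligand atom and any atom of the residue's side-chain heavy-atom set
    (Calpha for glycine). Minimum-image distances are used when the
    trajectory has a box.
    """
    ligand_indices = np.asarray(ligand_indices, dtype=int)
    if len(ligand_indices) == 0:
        raise ValueError("empty ligand atom set")
    counts = np.zeros(len(residue_heavy_sets))
    for frame in trajectory.frames:
        frame = np.asarray(frame, dtype=float)
        lig = frame[ligand_indices]
        for ri, rset in enumerate(residue_heavy_sets):
            res = frame[np.asarray(rset, dtype=int)]
            if trajectory.box is not None:
                diff = lig[:, None, :] - res[None, :, :]
                diff = _min_image(diff, trajectory.box)
                dmin = np.sqrt((diff ** 2).sum(axis=2)).min()
            else:
                dmin = cdist(lig, res).min()
            if dmin < cutoff:
                counts[ri] += 1
    return counts / len(trajectory.frames)


def oligomer_sizes(frame, groups, cutoff=0.4, box=None):
    """Connected-component cluster sizes of contacting peptides.

    Peptides (atom-index groups) are nodes; an edge joins two peptides when
    any inter-peptide atom pair is closer than ``cutoff`` (nm). Returns the
    component sizes sorted descending (so ``[0]`` is the largest oligomer).
    """
    if not groups:
        raise ValueError("no peptide groups")
    flat = np.concatenate([np.asarray(g) for g in groups])
    if len(np.unique(flat)) != len(flat):
        raise ValueError("peptide groups overlap")
    frame = np.asarray(frame, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(range(len(groups)))
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            pa = frame[np.asarray(groups[a], dtype=int)]
            pb = frame[np.asarray(groups[b], dtype=int)]
            if box is not None:
                diff = pa[:, None, :] - pb[None, :, :]
                diff = _min_image(diff, box)
                dmin = np.sqrt((diff ** 2).sum(axis=2)).min()
            else:
                dmin = cdist(pa, pb).min()
            if dmin < cutoff:
                g.add_edge(a, b)
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return sizes


def oligomer_size_series(trajectory, groups, cutoff=0.4, window=10):
    """Largest-cluster size per frame, window-smoothed as in the validation
    plots (mean over +-``window`` frames, truncated at the edges)."""
    largest = np.array([oligomer_sizes(f, groups, cutoff, trajectory.box)[0]
                        for f in trajectory.frames], dtype=float)
    out = np.empty_like(largest)
    n = len(largest)
    for t in range(n):
        lo, hi = max(0, t - window), min(n, t + window + 1)
        out[t] = largest[lo:hi].mean()
    return out
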