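"""Trainable force-field parameter registry.

The trainable surface is 108 scalars spanning an Amber-style protein force
field combined with a Generalized-Born (GB-Neck2 family) implicit solvent:

* per-atom-type partial-charge scaling, LJ sigma and LJ epsilon for 16 common
  atom types (46 non-zero entries — the hydroxyl hydrogen HO has sigma and
  epsilon fixed at zero and non-trainable),
* the amplitudes of 13 common proper torsions (33 entries; phases frozen),
* the Coulomb and LJ 1-4 scalings (2),
* GB per-class intrinsic radii (6), OBC alpha/beta/gamma rescaling
  coefficients for 4 element classes (12), descreening screening factors (4),
* and 5 GB globals: neck cutoff, neck scale, radius offset, probe radius and
  surface-area factor.

Partial charges are never trained directly. Each atom type carries a scaling
factor applied to the template charges, and the residue sum is restored by
subtracting the excess in proportion to each scaled charge's absolute value,
so every residue keeps its formal charge exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources
import xml.etree.ElementTree as ET

import numpy as np

from . import autodiff as ad

ATOM_TYPES = ["CA", "CT", "C", "C8", "C9", "N", "N3", "O", "O2", "OH",
              "H", "H1", "HA", "HC", "HO", "HP"]
GB_CLASSES = ["H", "HN", "C", "N", "O", "OC"]
ELEMENTS = ["H", "C", "N", "O"]
#: per-atom-type entries excluded from the trainable LJ block
LJ_EXCLUDED = ["HO"]

CATEGORY_COUNTS = {"charge_scale": 16, "lj_sigma": 15, "lj_epsilon": 15,
                   "torsion_k": 33, "scale_14": 2, "gb_radius": 6,
                   "gb_obc": 12, "gb_screen": 4, "gb_global": 5}


class ConfigurationError(ValueError):
    pass


class DegenerateResidueError(ValueError):
    pass


@dataclass
class ResidueTemplate:
    residue_name: str
    atom_names: list
    atom_types: list
    base_charges: np.ndarray
    formal_charge: int
    bonds: list  # pairs of atom names

    def __post_init__(self):
        if abs(float(np.sum(self.base_charges)) - self.formal_charge) > 1e-6:
            raise ConfigurationError(
                f"template {self.residue_name}: charges sum to "
                f"{np.sum(self.base_charges)}, formal charge {self.formal_charge}")


@dataclass
class ForceFieldRegistry:
    """Embedded defaults plus the non-trainable bonded tables (read-only)."""

    version: str
    lj_sigma: dict
    lj_epsilon: dict
    masses: dict
    elements: dict
    scale_14: dict
    torsion_keys: list          # dicts: name, types (4, "X" wildcard), terms [(n,k,phase)]
    gb_radii: dict              # per GB class, nm
    gb_obc: dict                # per element: (alpha, beta, gamma)
    gb_screening: dict          # per element
    gb_globals: dict
    bond_params: dict           # frozenset-of-types-like tuple key -> (k, r0)
    angle_defaults: dict        # centre type -> (k, theta0)
    angle_overrides: dict       # (t1, t2, t3) -> (k, theta0)
    residues: dict = field(default_factory=dict)  # name -> ResidueTemplate

    def bond_param(self, t1, t2):
        for key in ((t1, t2), (t2, t1)):
            if key in self.bond_params:
                return self.bond_params[key]
        raise ConfigurationError(f"no bond parameters for type pair {t1}-{t2}")

    def angle_param(self, t1, t2, t3):
        for key in ((t1, t2, t3), (t3, t2, t1)):
            if key in self.angle_overrides:
                return self.angle_overrides[key]
        if t2 in self.angle_defaults:
            return self.angle_defaults[t2]
        raise ConfigurationError(f"no angle parameters for centre type {t2}")

    def match_torsion(self, t1, t2, t3, t4):
        """Index of the trainable torsion key matching a type quadruple, or -1.

        Exact quadruples take precedence over wildcard (middle-bond) keys;
        both orientations are tried.
        """
        quads = [(t1, t2, t3, t4), (t4, t3, t2, t1)]
        for i, key in enumerate(self.torsion_keys):
            if tuple(key["types"]) in quads:
                return i
        for i, key in enumerate(self.torsion_keys):
            a, b, c, d = key["types"]
            if a == "X" and d == "X" and ((b, c) == (t2, t3) or (b, c) == (t3, t2)):
                return i
        return -1


def gb_class_of(atom_type, bonded_types=()):
    """GB radius class for an atom: H / H-on-N / C / N / O / carbonyl-O."""
    el = atom_type[0]
    if el == "H":
        return "HN" if any(t.startswith("N") for t in bonded_types) else "H"
    if el == "O":
        return "OC" if atom_type in ("O", "O2") else "O"
    return el


@dataclass
class ParameterVector:
    """The ordered 108 trainable scalars with per-entry metadata."""

    values: np.ndarray
    labels: list
    names: list
    hydrogen_flag: np.ndarray

    def __len__(self):
        return len(self.values)

    def copy(self):
        return ParameterVector(self.values.copy(), list(self.labels),
                               list(self.names), self.hydrogen_flag.copy())

    def index(self, name):
        return self.names.index(name)


def _load_defaults():
    with resources.files("diffmd.data").joinpath("forcefield_defaults.json").open() as f:
        return json.load(f)


def load_registry():
    d = _load_defaults()
    at = d["atom_types"]
    for t in ATOM_TYPES:
        if t not in at:
            raise ConfigurationError(f"missing template entry for atom type {t}")
    residues = {}
    for name, r in d["residues"].items():
        residues[name] = ResidueTemplate(
            residue_name=name,
            atom_names=[a[0] for a in r["atoms"]],
            atom_types=[a[1] for a in r["atoms"]],
            base_charges=np.array([a[2] for a in r["atoms"]], dtype=float),
            formal_charge=r["formal_charge"],
            bonds=[tuple(b) for b in r["bonds"]],
        )
    return ForceFieldRegistry(
        version=d["version"],
        lj_sigma={t: at[t]["sigma"] for t in ATOM_TYPES},
        lj_epsilon={t: at[t]["epsilon"] for t in ATOM_TYPES},
        masses={t: at[t]["mass"] for t in ATOM_TYPES},
        elements={t: at[t]["element"] for t in ATOM_TYPES},
        scale_14=dict(d["scale_14"]),
        torsion_keys=copy.deepcopy(d["torsion_keys"]),
        gb_radii=dict(d["gb"]["radii"]),
        gb_obc={e: tuple(v) for e, v in d["gb"]["obc"].items()},
        gb_screening=dict(d["gb"]["screening"]),
        gb_globals=dict(d["gb"]["globals"]),
        bond_params={(b[0], b[1]): (b[2], b[3]) for b in d["bond_params"]},
        angle_defaults={k: tuple(v) for k, v in d["angle_defaults"].items()},
        angle_overrides={(a[0], a[1], a[2]): (a[3], a[4]) for a in d["angle_overrides"]},
        residues=residues,
    )


def _vector_layout(reg):
    """Ordered (label, name, default) triples defining the 108-vector."""
    rows = []
    for t in ATOM_TYPES:
        rows.append(("charge_scale", f"charge_scale:{t}", 1.0))
    for t in ATOM_TYPES:
        if t not in LJ_EXCLUDED:
            rows.append(("lj_sigma", f"lj_sigma:{t}", reg.lj_sigma[t]))
    for t in ATOM_TYPES:
        if t not in LJ_EXCLUDED:
            rows.append(("lj_epsilon", f"lj_epsilon:{t}", reg.lj_epsilon[t]))
    for key in reg.torsion_keys:
        for m, (n, k, phase) in enumerate(key["terms"]):
            rows.append(("torsion_k", f"torsion_k:{key['name']}:n{n}", k))
    rows.append(("scale_14", "scale_14:coulomb", reg.scale_14["coulomb"]))
    rows.append(("scale_14", "scale_14:lj", reg.scale_14["lj"]))
    for c in GB_CLASSES:
        rows.append(("gb_radius", f"gb_radius:{c}", reg.gb_radii[c]))
    for e in ELEMENTS:
        for j, greek in enumerate(("alpha", "beta", "gamma")):
            rows.append(("gb_obc", f"gb_obc:{e}:{greek}", reg.gb_obc[e][j]))
    for e in ELEMENTS:
        rows.append(("gb_screen", f"gb_screen:{e}", reg.gb_screening[e]))
    for gname in ("neck_cutoff", "neck_scale", "offset", "probe_radius",
                  "surface_area_factor"):
        rows.append(("gb_global", f"gb_global:{gname}", reg.gb_globals[gname]))
    return rows


def build_default_registry():
    """Load embedded defaults: (108-entry ParameterVector, full registry)."""
    reg = load_registry()
    rows = _vector_layout(reg)
    labels = [r[0] for r in rows]
    names = [r[1] for r in rows]
    values = np.array([r[2] for r in rows], dtype=float)
    hflag = np.array([(":" in n and n.split(":")[1].startswith("H") and
                       n.split(":")[0] in ("charge_scale", "lj_sigma", "lj_epsilon"))
                      for n in names])
    vec = ParameterVector(values, labels, names, hflag)
    assert len(vec) == 108, f"registry defines {len(vec)} trainable scalars"
    return vec, reg


# ---------------------------------------------------------------------------
# parameter unpacking (Var-aware)
# ---------------------------------------------------------------------------

class UnpackedParameters:
    """Structured view of a (possibly Var) 108-vector.

    Fields are numpy arrays or Var slices aligned with the registry orders:
    ``charge_scale`` (16,), ``sigma``/``epsilon`` (16, HO entry zero),
    ``torsion_k`` (33,), ``coulomb_14``/``lj_14`` scalars, ``gb_radii`` (6,),
    ``gb_obc`` (4, 3), ``gb_screen`` (4,), and the 5 named GB globals.
    """

    __slots__ = ("charge_scale", "sigma", "epsilon", "torsion_k",
                 "coulomb_14", "lj_14", "gb_radii", "gb_obc", "gb_screen",
                 "neck_cutoff", "neck_scale", "offset", "probe_radius",
                 "surface_area_factor")

    def __init__(self, values):
        n_lj = 16 - len(LJ_EXCLUDED)
        included = np.array([i for i, t in enumerate(ATOM_TYPES)
                             if t not in LJ_EXCLUDED])
        o = 0
        self.charge_scale = values[0:16]; o = 16
        self.sigma = ad.scatter_add(values[o:o + n_lj], included, (16,)); o += n_lj
        self.epsilon = ad.scatter_add(values[o:o + n_lj], included, (16,)); o += n_lj
        self.torsion_k = values[o:o + 33]; o += 33
        self.coulomb_14 = values[o]; self.lj_14 = values[o + 1]; o += 2
        self.gb_radii = values[o:o + 6]; o += 6
        self.gb_obc = ad.reshape(values[o:o + 12], (4, 3)); o += 12
        self.gb_screen = values[o:o + 4]; o += 4
        (self.neck_cutoff, self.neck_scale, self.offset, self.probe_radius,
         self.surface_area_factor) = (values[o], values[o + 1], values[o + 2],
                                      values[o + 3], values[o + 4])


def unpack(vector_values):
    """Structured view of 108 values; accepts an ndarray or a Var."""
    if not ad.is_var(vector_values):
        vector_values = np.asarray(vector_values)
        if vector_values.dtype.kind != "f":
            vector_values = vector_values.astype(float)
        if vector_values.shape != (108,):
            raise ConfigurationError("parameter vector must have length 108")
        vector_values = ad.Var(vector_values)
        up = UnpackedParameters(vector_values)
        for name in UnpackedParameters.__slots__:
            setattr(up, name, ad.val(getattr(up, name)))
        return up
    if ad.val(vector_values).shape != (108,):
        raise ConfigurationError("parameter vector must have length 108")
    return UnpackedParameters(vector_values)


# ---------------------------------------------------------------------------
# charge scaling
# ---------------------------------------------------------------------------

def rescale_residue_charges(template, charge_scales):
    """Scaled-and-recentred charges for one residue.

    q' = s_t(i) * q_i, then the excess Delta = sum(q') - formal_charge is
    removed in proportion to |q'| so the residue sum is restored exactly.
    ``charge_scales`` maps atom type -> multiplier (dict) or is the (16,)
    array/Var aligned with ``ATOM_TYPES``.
    """
    if isinstance(charge_scales, dict):
        scales = np.array([charge_scales.get(t, 1.0) for t in ATOM_TYPES])
    else:
        scales = charge_scales
    tidx = np.array([ATOM_TYPES.index(t) for t in template.atom_types])
    q = template.base_charges * ad.getitem(scales, tidx)
    absq = ad.absolute(q)
    denom = ad.asum(absq)
    if float(ad.val(denom)) == 0.0:
        if abs(template.formal_charge) > 0:
            raise DegenerateResidueError(
                f"residue {template.residue_name}: all scaled charges zero "
                "but formal charge is nonzero")
        return q
    delta = ad.asum(q) - template.formal_charge
    return q - delta * absq / denom


def compute_system_charges(system, charge_scale16):
    """Vectorised charge rescaling across all residues of a system.

    Differentiable with respect to ``charge_scale16`` when it is a Var.
    """
    dt = np.asarray(ad.val(charge_scale16)).dtype
    q = system.base_charges.astype(dt) * ad.getitem(charge_scale16,
                                                    system.type_idx)
    absq = ad.absolute(q)
    nres = len(system.res_formal)
    ridx = system.residue_index
    qsum = ad.scatter_add(q, ridx, (nres,))
    asum = ad.scatter_add(absq, ridx, (nres,))
    delta = qsum - system.res_formal.astype(dt)
    zero = ad.val(asum) == 0.0
    if np.any(zero & (np.abs(ad.val(delta)) > 1e-12)):
        raise DegenerateResidueError(
            "a residue has all scaled charges zero but a nonzero formal charge")
    denom = ad.where(zero, 1.0, asum)
    frac = absq / ad.getitem(denom, ridx)
    return q - ad.getitem(delta, ridx) * frac


def apply_parameter_vector(vector, system):
    """New MolecularSystem with per-atom/per-term parameters from ``vector``.

    With a plain ParameterVector the returned system holds numeric arrays;
    energetics can also consume Var-valued unpacked parameters directly via
    :func:`unpack` for differentiable evaluation.
    """
    if isinstance(vector, ParameterVector):
        values = vector.values
        if len(values) != 108:
            raise ConfigurationError("parameter vector must have length 108")
    else:
        values = vector
    up = unpack(values)
    new = system.with_parameters(up)
    return new


# ---------------------------------------------------------------------------
# XML export / import
# ---------------------------------------------------------------------------

def export_forcefield_xml(vector, registry, path):
    """Write a self-contained force-field XML file.

    Sections: AtomTypes, Residues (with final rescaled charges), bonded
    tables, NonbondedForce (with 1-4 scales) and a GB parameter block. The
    harmonic convention in the file is the common MD-file ``0.5 k x^2``; the
    in-memory convention ``k x^2`` is converted on write and read.
    """
    up = unpack(vector.values if isinstance(vector, ParameterVector) else vector)
    root = ET.Element("ForceField", version=registry.version)
    at = ET.SubElement(root, "AtomTypes")
    for i, t in enumerate(ATOM_TYPES):
        ET.SubElement(at, "Type", name=t, element=registry.elements[t],
                      mass=repr(registry.masses[t]),
                      chargeScale=repr(float(up.charge_scale[i])))
    res = ET.SubElement(root, "Residues")
    for name, tpl in sorted(registry.residues.items()):
        q = rescale_residue_charges(tpl, up.charge_scale)
        r = ET.SubElement(res, "Residue", name=name,
                          formalCharge=str(tpl.formal_charge))
        for an, ty, bq, fq in zip(tpl.atom_names, tpl.atom_types,
                                  tpl.base_charges, q):
            ET.SubElement(r, "Atom", name=an, type=ty, baseCharge=repr(float(bq)),
                          charge=repr(float(fq)))
        for b in tpl.bonds:
            ET.SubElement(r, "Bond", atomName1=b[0], atomName2=b[1])
    hb = ET.SubElement(root, "HarmonicBondForce")
    for (t1, t2), (k, r0) in sorted(registry.bond_params.items()):
        ET.SubElement(hb, "Bond", type1=t1, type2=t2, length=repr(r0),
                      k=repr(2.0 * k))
    ha = ET.SubElement(root, "HarmonicAngleForce")
    for t, (k, th) in sorted(registry.angle_defaults.items()):
        ET.SubElement(ha, "AngleDefault", centre=t, angle=repr(th), k=repr(2.0 * k))
    for (t1, t2, t3), (k, th) in sorted(registry.angle_overrides.items()):
        ET.SubElement(ha, "Angle", type1=t1, type2=t2, type3=t3,
                      angle=repr(th), k=repr(2.0 * k))
    pt = ET.SubElement(root, "PeriodicTorsionForce")
    m = 0
    for key in registry.torsion_keys:
        el = ET.SubElement(pt, "Proper", name=key["name"],
                           **{f"type{i+1}": t for i, t in enumerate(key["types"])})
        for (n, _k, phase) in key["terms"]:
            ET.SubElement(el, "Term", periodicity=str(n),
                          k=repr(float(up.torsion_k[m])), phase=repr(phase))
            m += 1
    nb = ET.SubElement(root, "NonbondedForce",
                       coulomb14scale=repr(float(up.coulomb_14)),
                       lj14scale=repr(float(up.lj_14)))
    for i, t in enumerate(ATOM_TYPES):
        ET.SubElement(nb, "Atom", type=t, sigma=repr(float(up.sigma[i])),
                      epsilon=repr(float(up.epsilon[i])))
    gb = ET.SubElement(root, "GeneralizedBornForce")
    for i, c in enumerate(GB_CLASSES):
        ET.SubElement(gb, "Radius", cls=c, radius=repr(float(up.gb_radii[i])))
    for i, e in enumerate(ELEMENTS):
        ET.SubElement(gb, "OBC", element=e, alpha=repr(float(up.gb_obc[i, 0])),
                      beta=repr(float(up.gb_obc[i, 1])),
                      gamma=repr(float(up.gb_obc[i, 2])))
        ET.SubElement(gb, "Screening", element=e, value=repr(float(up.gb_screen[i])))
    ET.SubElement(gb, "Globals", neckCutoff=repr(float(up.neck_cutoff)),
                  neckScale=repr(float(up.neck_scale)), offset=repr(float(up.offset)),
                  probeRadius=repr(float(up.probe_radius)),
                  surfaceAreaFactor=repr(float(up.surface_area_factor)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def import_forcefield_xml(path):
    """Read a file written by :func:`export_forcefield_xml`.

    Returns ``(ParameterVector, ForceFieldRegistry)`` equivalent to the
    exported state (round-trip identity).
    """
    root = ET.parse(path).getroot()
    masses, elements, cscale = {}, {}, {}
    for el in root.find("AtomTypes"):
        masses[el.get("name")] = float(el.get("mass"))
        elements[el.get("name")] = el.get("element")
        cscale[el.get("name")] = float(el.get("chargeScale"))
    residues = {}
    for r in root.find("Residues"):
        residues[r.get("name")] = ResidueTemplate(
            residue_name=r.get("name"),
            atom_names=[a.get("name") for a in r.findall("Atom")],
            atom_types=[a.get("type") for a in r.findall("Atom")],
            base_charges=np.array([float(a.get("baseCharge"))
                                   for a in r.findall("Atom")]),
            formal_charge=int(r.get("formalCharge")),
            bonds=[(b.get("atomName1"), b.get("atomName2"))
                   for b in r.findall("Bond")],
        )
    bond_params = {(b.get("type1"), b.get("type2")):
                   (0.5 * float(b.get("k")), float(b.get("length")))
                   for b in root.find("HarmonicBondForce")}
    angle_defaults, angle_overrides = {}, {}
    for el in root.find("HarmonicAngleForce"):
        if el.tag == "AngleDefault":
            angle_defaults[el.get("centre")] = (0.5 * float(el.get("k")),
                                                float(el.get("angle")))
        else:
            angle_overrides[(el.get("type1"), el.get("type2"), el.get("type3"))] = \
                (0.5 * float(el.get("k")), float(el.get("angle")))
    torsion_keys = []
    for p in root.find("PeriodicTorsionForce"):
        torsion_keys.append({
            "name": p.get("name"),
            "types": [p.get(f"type{i+1}") for i in range(4)],
            "terms": [[int(t.get("periodicity")), float(t.get("k")),
                       float(t.get("phase"))] for t in p.findall("Term")],
        })
    nb = root.find("NonbondedForce")
    sigma = {a.get("type"): float(a.get("sigma")) for a in nb}
    epsilon = {a.get("type"): float(a.get("epsilon")) for a in nb}
    gb = root.find("GeneralizedBornForce")
    radii = {el.get("cls"): float(el.get("radius")) for el in gb.findall("Radius")}
    obc = {el.get("element"): (float(el.get("alpha")), float(el.get("beta")),
                               float(el.get("gamma"))) for el in gb.findall("OBC")}
    screening = {el.get("element"): float(el.get("value"))
                 for el in gb.findall("Screening")}
    g = gb.find("Globals")
    gglob = {"neck_cutoff": float(g.get("neckCutoff")),
             "neck_scale": float(g.get("neckScale")),
             "offset": float(g.get("offset")),
             "probe_radius": float(g.get("probeRadius")),
             "surface_area_factor": float(g.get("surfaceAreaFactor"))}
    reg = ForceFieldRegistry(
        version=root.get("version"), lj_sigma=sigma, lj_epsilon=epsilon,
        masses=masses, elements=elements,
        scale_14={"coulomb": float(nb.get("coulomb14scale")),
                  "lj": float(nb.get("lj14scale"))},
        torsion_keys=torsion_keys, gb_radii=radii, gb_obc=obc,
        gb_screening=screening, gb_globals=gglob, bond_params=bond_params,
        angle_defaults=angle_defaults, angle_overrides=angle_overrides,
        residues=residues)
    rows = _vector_layout(reg)
    labels = [r[0] for r in rows]
    names = [r[1] for r in rows]
    values = np.array([r[2] for r in rows], dtype=float)
    for i, t in enumerate([t for t in ATOM_TYPES]):
        values[i] = cscale[t]
    hflag = np.array([(n.split(":")[1].startswith("H") and
                       n.split(":")[0] in ("charge_scale", "lj_sigma", "lj_epsilon"))
                      for n in names])
    return ParameterVector(values, labels, names, hflag), reg
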