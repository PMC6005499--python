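"""Seeded generators for every input class the pipeline consumes.

Each generator returns its artificial data together with a
:class:`GroundTruth` record that fully determines the expected output of
the downstream stage at zero noise:

* :func:`gen_toy_complex` — a minimal receptor built from amino-acid
  fragments placed around a small multifunctional ligand so that each
  requested interaction satisfies the geometric perception rules exactly.
* :func:`gen_hit_library` — multi-conformer molecules whose pharmacophoric
  features sit at a hypothesis's centers (hits), lack two of them
  (non-hits), or additionally reproduce an anti-target hypothesis in a
  second conformer (dual binders).  Molecules are chemically valid graphs
  (amine/ether/alkyl/phenyl fragments on a spacer chain); their conformer
  coordinates are synthetic poses, not energy-minimised geometries.
* :func:`gen_decoy_pool` — constitutional-isomer-style rewirings of the
  actives: same heavy-atom composition, randomised connectivity, so
  physicochemical windows are met while path fingerprints diverge.
* :func:`gen_two_state_trajectory` — Gaussian jitter around two reference
  conformations separated by a controlled superposition RMSD.

All generators are deterministic given (parameters, seed).
"""
from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from . import chem as chemmod
from .chem import Molecule, ProteinComplex, ReceptorAtoms, compute_properties
from .cluster import Trajectory
from .features import Hypothesis, PharmacophoreFeature
from .superpose import kabsch
from .validation import DecoyTolerances, _fingerprint

log = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """What the stage under test must recover."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_interactions: List[str] = field(default_factory=list)
    feature_types: List[str] = field(default_factory=list)
    cluster_labels: Optional[np.ndarray] = None
    labels: Dict[str, str] = field(default_factory=dict)   # molecule id -> role


# ==========================================================================
# Toy receptor-ligand complexes
# ==========================================================================

_LIGAND_SMILES = "CCOc1ccc(cc1)C(=O)NC"   # ether-O / aromatic ring / amide

_PLANT_KINDS = ("hbond_ligand_acceptor", "hbond_ligand_donor",
                "hydrophobic", "pi_stack")


@functools.lru_cache(maxsize=1)
def _ligand_template() -> Chem.Mol:
    m = Chem.MolFromSmiles(_LIGAND_SMILES)
    m = Chem.AddHs(m)
    params = AllChem.ETKDGv3()
    params.randomSeed = 1234
    AllChem.EmbedMolecule(m, params)
    return m


def _ligand_anchor_sites(m: Chem.Mol, coords: np.ndarray) -> dict:
    """Positions of the ligand groups each interaction kind is planted on."""
    carbonyl_o = m.GetSubstructMatches(Chem.MolFromSmarts("[CX3]=[OX1]"))[0][1]
    amide_n = m.GetSubstructMatches(Chem.MolFromSmarts("[NX3][CX3]=[OX1]"))[0][0]
    n_h = [nb.GetIdx() for nb in m.GetAtomWithIdx(amide_n).GetNeighbors()
           if nb.GetSymbol() == "H"][0]
    hyd_group = chemmod.hydrophobic_groups(m)[0]
    ring = chemmod.aromatic_rings(m)[0]
    ring_coords = coords[ring]
    return {
        "hbond_ligand_acceptor": {"pos": coords[carbonyl_o], "atom": carbonyl_o},
        "hbond_ligand_donor": {"pos": coords[amide_n], "h": coords[n_h],
                               "atom": amide_n},
        "hydrophobic": {"pos": coords[hyd_group].mean(axis=0)},
        "pi_stack": {"pos": ring_coords.mean(axis=0),
                     "normal": chemmod.ring_normal(ring_coords)},
    }


def _frag_donor(base: np.ndarray, u: np.ndarray, dist: float, resid: int):
    """Backbone-amide donor fragment: N(+H) pointing at the acceptor."""
    n = base + dist * u
    h = n - 1.0 * u                       # H on the N->acceptor line
    perp = _any_perpendicular(u)
    ca = n + 1.47 * (0.6 * u + 0.8 * perp)
    return [("N", "N", n), ("H", "H", h), ("CA", "C", ca)], "GLY", resid


def _frag_acceptor(base_h: np.ndarray, base_n: np.ndarray, dist: float, resid: int):
    """Backbone-carbonyl acceptor fragment placed along the ligand N-H bond."""
    u = base_h - base_n
    u = u / np.linalg.norm(u)
    o = base_n + dist * u
    perp = _any_perpendicular(u)
    c = o + 1.23 * (0.5 * u + 0.87 * perp)
    ca = c + 1.52 * perp
    return [("O", "O", o), ("C", "C", c), ("CA", "C", ca)], "GLY", resid


def _frag_hydrophobic(base: np.ndarray, u: np.ndarray, dist: float, resid: int):
    cg = base + dist * u
    p1 = _any_perpendicular(u)
    p2 = np.cross(u, p1)
    cd1 = cg + 1.53 * p1
    cd2 = cg + 1.53 * p2
    cb = cg + 1.53 * u
    return [("CG", "C", cg), ("CD1", "C", cd1), ("CD2", "C", cd2),
            ("CB", "C", cb)], "LEU", resid


def _frag_ring(base: np.ndarray, normal: np.ndarray, dist: float, resid: int):
    """Phenyl fragment stacked face-to-face over the ligand ring."""
    center = base + dist * normal
    p1 = _any_perpendicular(normal)
    p2 = np.cross(normal, p1)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for k, name in enumerate(names):
        ang = np.pi / 3 * k
        pos = center + 1.39 * (np.cos(ang) * p1 + np.sin(ang) * p2)
        atoms.append((name, "C", pos))
    return atoms, "PHE", resid


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


def gen_toy_complex(planted: Sequence[str], seed: int = 0,
                    noise: float = 0.0) -> Tuple[ProteinComplex, GroundTruth]:
    """Build a minimal complex with exactly the planted interactions.

    ``planted`` lists interaction kinds (each at most once):
    ``hbond_ligand_acceptor`` (receptor N-H to the ligand carbonyl O),
    ``hbond_ligand_donor`` (receptor C=O along the ligand amide N-H),
    ``hydrophobic`` (apolar side-chain cluster at the ethyl group), and
    ``pi_stack`` (phenyl parallel to the ligand ring).  ``noise`` displaces
    every receptor atom in a random direction by a bounded amount drawn
    uniformly from [0, noise] Å.
    """
    bad = [k for k in planted if k not in _PLANT_KINDS]
    if bad:
        raise ValueError(f"cannot plant interaction kinds {bad}; "
                         f"choose from {_PLANT_KINDS}")
    if len(set(planted)) != len(planted):
        raise ValueError("each interaction kind can be planted at most once")
    rng = np.random.default_rng(seed)
    lig = Chem.Mol(_ligand_template())
    coords = np.array(lig.GetConformer().GetPositions(), dtype=float)
    centroid = coords.mean(axis=0)
    sites = _ligand_anchor_sites(lig, coords)

    atoms: List[Tuple[str, str, np.ndarray]] = []
    resnames: List[str] = []
    resids: List[int] = []
    for i, kind in enumerate(planted):
        resid = 10 * (i + 1)
        site = sites[kind]
        if kind == "hbond_ligand_acceptor":
            u = site["pos"] - centroid
            u /= np.linalg.norm(u)
            dist = rng.uniform(2.8, 3.1)
            frag, rn, ri = _frag_donor(site["pos"], u, dist, resid)
        elif kind == "hbond_ligand_donor":
            dist = rng.uniform(2.8, 3.1)
            frag, rn, ri = _frag_acceptor(site["h"], site["pos"], dist, resid)
        elif kind == "hydrophobic":
            u = site["pos"] - centroid
            u /= np.linalg.norm(u)
            frag, rn, ri = _frag_hydrophobic(site["pos"], u, rng.uniform(3.6, 4.0),
                                             resid)
        else:  # pi_stack
            normal = site["normal"]
            if np.dot(normal, site["pos"] - centroid) < 0:
                normal = -normal
            frag, rn, ri = _frag_ring(site["pos"], normal, rng.uniform(3.6, 3.9),
                                      resid)
        for name, elem, pos in frag:
            p = np.asarray(pos, dtype=float)
            if noise > 0:
                d = rng.normal(size=3)
                p = p + rng.uniform(0.0, noise) * d / np.linalg.norm(d)
            atoms.append((name, elem, p))
            resnames.append(rn)
            resids.append(resid)

    if atoms:
        rec_coords = np.array([a[2] for a in atoms])
        lig_heavy = coords[[a.GetIdx() for a in lig.GetAtoms()
                            if a.GetSymbol() != "H"]]
        dmin = np.linalg.norm(rec_coords[:, None, :] - lig_heavy[None, :, :],
                              axis=2).min()
        if dmin < 1.0:
            raise ValueError(f"unrealizable plant: receptor/ligand clash at {dmin:.2f} Å")
    else:
        rec_coords = np.zeros((0, 3))

    receptor = ReceptorAtoms(
        serials=np.arange(1, len(atoms) + 1),
        names=np.array([a[0] for a in atoms], dtype=object) if atoms else np.empty(0, dtype=object),
        resnames=np.array(resnames, dtype=object) if atoms else np.empty(0, dtype=object),
        resids=np.array(resids, dtype=int),
        chains=np.array(["A"] * len(atoms), dtype=object) if atoms else np.empty(0, dtype=object),
        elements=np.array([a[1] for a in atoms], dtype=object) if atoms else np.empty(0, dtype=object),
        coords=rec_coords.reshape(-1, 3),
    )
    cpx = ProteinComplex(receptor=receptor,
                         ligand=Molecule(id="LIG", rdmol=lig, source="synthetic"),
                         source=f"gen_toy_complex(seed={seed})")
    kind_to_type = {"hbond_ligand_acceptor": "HBA", "hbond_ligand_donor": "HBD",
                    "hydrophobic": "HYD", "pi_stack": "ARO"}
    gt = GroundTruth(seed=seed,
                     params={"noise": noise},
                     planted_interactions=list(planted),
                     feature_types=sorted(kind_to_type[k] for k in planted))
    return cpx, gt


def complex_to_pdb(cpx: ProteinComplex) -> str:
    """Serialise a complex to PDB text (receptor ATOM, ligand HETATM+CONECT)."""
    lines = []
    rec = cpx.receptor
    serial = 0
    for i in range(len(rec)):
        serial += 1
        x, y, z = rec.coords[i]
        lines.append(
            f"ATOM  {serial:5d} {str(rec.names[i]):<4.4s} {str(rec.resnames[i]):>3.3s} "
            f"{str(rec.chains[i]):1.1s}{int(rec.resids[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{str(rec.elements[i]):>2.2s}\n")
    lig = cpx.ligand.rdmol
    lcoords = cpx.ligand.conformer_coords(0)
    offset = serial
    counts: Dict[str, int] = {}
    for a in lig.GetAtoms():
        serial += 1
        sym = a.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        name = f"{sym}{counts[sym]}"
        x, y, z = lcoords[a.GetIdx()]
        lines.append(
            f"HETATM{serial:5d} {name:<4.4s} LIG L 900    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {sym:>2.2s}\n")
    for b in lig.GetBonds():
        i = b.GetBeginAtomIdx() + offset + 1
        j = b.GetEndAtomIdx() + offset + 1
        lines.append(f"CONECT{i:5d}{j:5d}\n")
    lines.append("END\n")
    return "".join(lines)


# ==========================================================================
# Hit libraries
# ==========================================================================

_POLAR = ("HBD", "HBA")


def _order_units(types: List[Tuple[str, Optional[np.ndarray]]]):
    """Interleave polar and apolar units so no two apolar units are chain
    neighbours (keeps spacer carbons out of hydrophobic groups)."""
    polar = [t for t in types if t[0] in _POLAR]
    apolar = [t for t in types if t[0] not in _POLAR]
    out = []
    while polar or apolar:
        if apolar and (not out or out[-1][0] in _POLAR) :
            out.append(apolar.pop(0))
        elif polar:
            out.append(polar.pop(0))
        else:
            out.append(apolar.pop(0))
    return out


def _park_positions(n: int, origin=35.0, spacing=4.0) -> List[np.ndarray]:
    return [np.array([origin + spacing * k, 0.0, 0.0]) for k in range(n)]


class _Scaffold:
    """A feature-bearing molecule whose conformers are assembled pose by
    pose: each unit (feature fragment) can be placed at a target point or
    parked far away and collinear (where it cannot complete any mapping)."""

    def __init__(self, unit_types: List[str], mol_id: str, rng, n_pad: int = 0):
        # fixed unit order (interleaved) and graph; remember atom spans
        ordered = _order_units([(t, None) for t in unit_types])
        self.unit_types = [t for t, _ in ordered]
        self.mol_id = mol_id
        self.rng = rng
        rw = Chem.RWMol()
        self.unit_atoms: List[List[int]] = []
        self.spacer_atoms: List[int] = []
        attach_prev = None
        prev_polar = True
        for utype in self.unit_types:
            if utype in ("HBD", "HBA"):
                idx = rw.AddAtom(Chem.Atom("N" if utype == "HBD" else "O"))
                span = [idx]
                first = last = idx
                polar = True
            elif utype == "HYD":
                i1 = rw.AddAtom(Chem.Atom("C"))
                i2 = rw.AddAtom(Chem.Atom("C"))
                rw.AddBond(i1, i2, Chem.BondType.SINGLE)
                span = [i1, i2]
                first = last = i1
                polar = False
            else:  # ARO
                ring = [rw.AddAtom(Chem.Atom("C")) for _ in range(6)]
                for r in ring:
                    rw.GetAtomWithIdx(r).SetIsAromatic(True)
                for k in range(6):
                    rw.AddBond(ring[k], ring[(k + 1) % 6], Chem.BondType.AROMATIC)
                span = ring
                first = last = ring[0]
                polar = False
            if attach_prev is not None:
                spacer_elem = "C" if (polar or prev_polar) else "O"
                s = rw.AddAtom(Chem.Atom(spacer_elem))
                rw.AddBond(attach_prev, s, Chem.BondType.SINGLE)
                rw.AddBond(s, first, Chem.BondType.SINGLE)
                self.spacer_atoms.append(s)
            self.unit_atoms.append(span)
            attach_prev = last
            prev_polar = polar
        # optional alkyl pad varying the composition across library members;
        # hung off a spacer (spacers always touch a polar anchor, so the pad
        # never merges with a planted hydrophobic group)
        self.pad_atoms: List[int] = []
        if n_pad > 0:
            if self.spacer_atoms:
                anchor = self.spacer_atoms[0]
            else:
                anchor = self.unit_atoms[0][-1]
            prev = anchor
            for _ in range(n_pad):
                c = rw.AddAtom(Chem.Atom("C"))
                rw.AddBond(prev, c, Chem.BondType.SINGLE)
                self.pad_atoms.append(c)
                prev = c
        self.mol = rw.GetMol()
        Chem.SanitizeMol(self.mol)
        # per-unit local geometry direction (fixed per scaffold)
        self.local_dirs = []
        for utype in self.unit_types:
            v = self.rng.normal(size=3)
            self.local_dirs.append(v / np.linalg.norm(v))

    def _unit_coords(self, unit_idx: int, center: np.ndarray) -> List[np.ndarray]:
        utype = self.unit_types[unit_idx]
        v = self.local_dirs[unit_idx]
        if utype in ("HBD", "HBA"):
            return [np.array(center, dtype=float)]
        if utype == "HYD":
            return [center - 0.765 * v, center + 0.765 * v]
        p1 = _any_perpendicular(v)
        p2 = np.cross(v, p1)
        return [center + 1.39 * (np.cos(np.pi / 3 * k) * p1
                                 + np.sin(np.pi / 3 * k) * p2)
                for k in range(6)]

    def add_pose(self, placements: Dict[int, np.ndarray]) -> None:
        """Add a conformer: units in ``placements`` (unit index -> feature
        center) are placed exactly; the rest are parked collinearly far away."""
        n_atoms = self.mol.GetNumAtoms()
        pos = np.zeros((n_atoms, 3))
        parked = [u for u in range(len(self.unit_types)) if u not in placements]
        park = _park_positions(len(parked))
        for u, center in placements.items():
            for idx, p in zip(self.unit_atoms[u], self._unit_coords(u, center)):
                pos[idx] = p
        for u, center in zip(parked, park):
            for idx, p in zip(self.unit_atoms[u], self._unit_coords(u, center)):
                pos[idx] = p
        # spacers midway between the units they join
        for s, (ua, ub) in zip(self.spacer_atoms,
                               itertools.pairwise(range(len(self.unit_types)))):
            pa = pos[self.unit_atoms[ua][-1]]
            pb = pos[self.unit_atoms[ub][0]]
            pos[s] = 0.5 * (pa + pb)
        # pad tail parked on its own distant line
        for k, idx in enumerate(self.pad_atoms):
            pos[idx] = np.array([35.0 + 1.6 * k, 12.0, 0.0])
        conf = Chem.Conformer(n_atoms)
        for i in range(n_atoms):
            conf.SetAtomPosition(i, [float(x) for x in pos[i]])
        self.mol.AddConformer(conf, assignId=True)

    def molecule(self) -> Molecule:
        return Molecule(id=self.mol_id, rdmol=self.mol, source="synthetic")


def _assign_units(unit_types: List[str], feats: List[PharmacophoreFeature],
                  rng, noise_sd: float) -> Dict[int, np.ndarray]:
    """Greedy type-respecting assignment of hypothesis features to units."""
    placements: Dict[int, np.ndarray] = {}
    free = list(range(len(unit_types)))
    for f in feats:
        u = next(u for u in free if unit_types[u] == f.type)
        free.remove(u)
        center = np.array(f.center, dtype=float)
        if noise_sd > 0:
            center = center + rng.normal(0.0, noise_sd, 3)
        placements[u] = center
    return placements


def gen_hit_library(h: Hypothesis, n_hits: int = 5, n_nonhits: int = 20,
                    n_dual: int = 0, anti_h: Optional[Hypothesis] = None,
                    noise_sd: float = 0.0, seed: int = 0,
                    pad_range: Tuple[int, int] = (2, 8)
                    ) -> Tuple[List[Molecule], GroundTruth]:
    """A screening library with planted hits, non-hits, and dual binders.

    Hits carry one conformer whose features sit at the hypothesis centers
    (plus Gaussian noise of ``noise_sd`` Å); non-hits are built without two
    of the hypothesis features; the first ``n_dual`` hits get a second
    conformer reproducing ``anti_h``.  ``pad_range`` draws a per-molecule
    alkyl pad length so library members span a range of compositions (as a
    real library would) without touching the planted features.  Guarantees
    assume hypothesis centers are pairwise separated by more than twice the
    feature radius.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_dual > 0 and anti_h is None:
        raise ValueError("n_dual > 0 requires an anti-target hypothesis")
    if n_dual > n_hits:
        raise ValueError("n_dual cannot exceed n_hits")
    rng = np.random.default_rng(seed)
    target_types = [f.type for f in h.features]
    anti_types = [f.type for f in anti_h.features] if anti_h else []
    # units: target features, plus extras for anti types not already covered
    extra: List[str] = []
    avail = list(target_types)
    for t in anti_types:
        if t in avail:
            avail.remove(t)
        else:
            extra.append(t)

    lib: List[Molecule] = []
    labels: Dict[str, str] = {}
    for k in range(n_hits):
        dual = k < n_dual
        mol_id = f"hit{k + 1}" if not dual else f"dual{k + 1}"
        unit_types = list(target_types) + (list(extra) if dual else [])
        sc = _Scaffold(unit_types, mol_id, rng,
                       n_pad=int(rng.integers(pad_range[0], pad_range[1] + 1)))
        sc.add_pose(_assign_units(sc.unit_types, h.features, rng, noise_sd))
        if dual:
            sc.add_pose(_assign_units(sc.unit_types, anti_h.features, rng,
                                      noise_sd))
        lib.append(sc.molecule())
        labels[mol_id] = "dual" if dual else "hit"
    drop = min(2, max(0, len(h.features) - 1))
    kept_feats = h.features[drop:]
    for k in range(n_nonhits):
        mol_id = f"nonhit{k + 1}"
        sc = _Scaffold([f.type for f in kept_feats], mol_id, rng,
                       n_pad=int(rng.integers(pad_range[0], pad_range[1] + 1)))
        sc.add_pose(_assign_units(sc.unit_types, kept_feats, rng, noise_sd))
        lib.append(sc.molecule())
        labels[mol_id] = "nonhit"
    order = rng.permutation(len(lib))
    lib = [lib[i] for i in order]
    gt = GroundTruth(seed=seed,
                     params={"noise_sd": noise_sd, "n_hits": n_hits,
                             "n_nonhits": n_nonhits, "n_dual": n_dual},
                     labels=labels)
    return lib, gt


# ==========================================================================
# Decoy pools
# ==========================================================================

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1}


def _rewire_profile(mol: Molecule) -> dict:
    """Composition profile preserved by candidate rewiring: chain-carbon
    count, aromatic ring count, and the degree of every acyclic N/O."""
    m = mol.rdmol
    ring_atoms = {i for ring in chemmod.aromatic_rings(m) for i in ring}
    tokens = []
    n_c = 0
    for a in m.GetAtoms():
        if a.GetIdx() in ring_atoms or a.GetSymbol() == "H":
            continue
        if a.GetSymbol() == "C":
            n_c += 1
        elif a.GetSymbol() in ("N", "O"):
            tokens.append((a.GetSymbol(), min(a.GetDegree(), 2)))
    return {"n_chain_c": n_c, "n_rings": len(chemmod.aromatic_rings(m)),
            "tokens": tokens}


def _candidate_like(profile: dict, rng) -> Optional[Molecule]:
    """Random constitutional analogue of the profile: a linearly-biased
    carbon tree with benzene rings attached, heteroatoms spliced into C-C
    edges (degree 2) or hung terminally (degree 1).  Preserves formula and
    donor/acceptor environments while scrambling connectivity."""
    n_c = profile["n_chain_c"]
    if n_c < 2:
        return None
    rw = Chem.RWMol()
    chain = [rw.AddAtom(Chem.Atom("C"))]
    for _ in range(n_c - 1):
        if rng.random() < 0.65:
            parent = chain[-1]
        else:
            parent = int(rng.choice(chain))
        if rw.GetAtomWithIdx(parent).GetDegree() >= 4:
            parent = chain[-1]
        idx = rw.AddAtom(Chem.Atom("C"))
        rw.AddBond(parent, idx, Chem.BondType.SINGLE)
        chain.append(idx)
    for _ in range(profile["n_rings"]):
        ring = [rw.AddAtom(Chem.Atom("C")) for _ in range(6)]
        for r in ring:
            rw.GetAtomWithIdx(r).SetIsAromatic(True)
        for k in range(6):
            rw.AddBond(ring[k], ring[(k + 1) % 6], Chem.BondType.AROMATIC)
        host = int(rng.choice(chain))
        if rw.GetAtomWithIdx(host).GetDegree() >= 4:
            return None
        rw.AddBond(host, ring[0], Chem.BondType.SINGLE)
    for elem, deg in profile["tokens"]:
        if deg >= 2:
            # splice into a random C-C single bond
            edges = [b for b in rw.GetBonds()
                     if not b.GetIsAromatic()
                     and b.GetBeginAtom().GetSymbol() == "C"
                     and b.GetEndAtom().GetSymbol() == "C"]
            if not edges:
                return None
            b = edges[int(rng.integers(len(edges)))]
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            rw.RemoveBond(i, j)
            x = rw.AddAtom(Chem.Atom(elem))
            rw.AddBond(i, x, Chem.BondType.SINGLE)
            rw.AddBond(x, j, Chem.BondType.SINGLE)
        else:
            hosts = [a.GetIdx() for a in rw.GetAtoms()
                     if a.GetSymbol() == "C" and not a.GetIsAromatic()
                     and a.GetDegree() < 4
                     and all(nb.GetSymbol() == "C" for nb in a.GetNeighbors())]
            if not hosts:
                return None
            x = rw.AddAtom(Chem.Atom(elem))
            rw.AddBond(int(rng.choice(hosts)), x, Chem.BondType.SINGLE)
    m = rw.GetMol()
    try:
        Chem.SanitizeMol(m)
    except Exception:
        return None
    return Molecule(id="", rdmol=m, source="synthetic")


def gen_decoy_pool(actives: Sequence[Molecule],
                   tol: DecoyTolerances = DecoyTolerances(),
                   n_eligible_per_active: int = 60,
                   n_distractors: int = 20, seed: int = 0,
                   max_trials_per_active: int = 4000
                   ) -> Tuple[List[Molecule], GroundTruth]:
    """A decoy source pool with guaranteed eligible matches per active.

    Eligible candidates are random connectivity rewirings of the anchor
    active's heavy-atom composition that fall inside the property windows
    and below the fingerprint-similarity cap against *every* active;
    distractors are long alkanes violating the MW window.
    """
    rng = np.random.default_rng(seed)
    pool: List[Molecule] = []
    seen_smiles: set = set()
    active_props = [compute_properties(a) for a in actives]
    active_fps = [_fingerprint(a) for a in actives]
    eligible_of: Dict[str, List[str]] = {}
    for a, aprop in zip(actives, active_props):
        profile = _rewire_profile(a)
        found = []
        trials = 0
        while len(found) < n_eligible_per_active and trials < max_trials_per_active:
            trials += 1
            cand = _candidate_like(profile, rng)
            if cand is None:
                continue
            smi = cand.canonical_smiles()
            if smi in seen_smiles:
                continue
            p = compute_properties(cand)
            if not tol.property_match(p, aprop):
                continue
            fp = _fingerprint(cand)
            if any(DataStructs.TanimotoSimilarity(fp, afp) >= tol.tanimoto_max
                   for afp in active_fps):
                continue
            seen_smiles.add(smi)
            cand.id = f"decoy{len(pool) + 1}"
            pool.append(cand)
            found.append(cand.id)
        if len(found) < n_eligible_per_active:
            log.warning("pool for active %s: only %d/%d eligible after %d trials",
                        a.id, len(found), n_eligible_per_active, trials)
        eligible_of[a.id] = found
    for k in range(n_distractors):
        n_c = 26 + int(rng.integers(0, 10))
        m = Chem.MolFromSmiles("C" * n_c)
        pool.append(Molecule(id=f"distractor{k + 1}", rdmol=m, source="synthetic"))
    gt = GroundTruth(seed=seed,
                     params={"n_eligible_per_active": n_eligible_per_active,
                             "n_distractors": n_distractors},
                     labels={mid: "eligible" for ids in eligible_of.values()
                             for mid in ids})
    gt.params["eligible_of"] = eligible_of
    return pool, gt


# ==========================================================================
# Two-state trajectories
# ==========================================================================

def gen_two_state_trajectory(n_frames: int = 60, state_fraction: float = 0.5,
                             inter_state_rmsd: float = 3.0,
                             jitter_sd: float = 0.1, n_atoms: int = 20,
                             seed: int = 0) -> Tuple[Trajectory, GroundTruth]:
    """Frames jittered around two reference conformations separated by a
    controlled minimum (post-superposition) RMSD."""
    if inter_state_rmsd <= 4 * jitter_sd:
        raise ValueError("states not separable: need inter_state_rmsd > 4*jitter_sd")
    rng = np.random.default_rng(seed)
    ref_a = rng.normal(0.0, 4.0, size=(n_atoms, 3))
    disp = rng.normal(0.0, 1.0, size=(n_atoms, 3))
    ref_b = ref_a + disp
    for _ in range(8):  # rescale to the requested superposition RMSD
        _, _, cur = kabsch(ref_b, ref_a)
        if abs(cur - inter_state_rmsd) < 1e-9 or cur == 0:
            break
        disp *= inter_state_rmsd / cur
        ref_b = ref_a + disp
    n_a = int(round(n_frames * state_fraction))
    labels = np.array([0] * n_a + [1] * (n_frames - n_a))
    rng.shuffle(labels)
    frames = np.empty((n_frames, n_atoms, 3))
    for i, lab in enumerate(labels):
        ref = ref_a if lab == 0 else ref_b
        frames[i] = ref + rng.normal(0.0, jitter_sd, size=(n_atoms, 3))
    traj = Trajectory(
        coords=frames,
        names=np.array(["CA"] * n_atoms, dtype=object),
        resids=np.arange(1, n_atoms + 1),
        resnames=np.array(["GLY"] * n_atoms, dtype=object),
        elements=np.array(["C"] * n_atoms, dtype=object),
    )
    gt = GroundTruth(seed=seed,
                     params={"n_frames": n_frames, "state_fraction": state_fraction,
                             "inter_state_rmsd": inter_state_rmsd,
                             "jitter_sd": jitter_sd},
                     cluster_labels=labels)
    return traj, gt
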