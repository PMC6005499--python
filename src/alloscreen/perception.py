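"""Receptor-based pharmacophore perception.

Detects explicit receptor-ligand interactions in a complex by geometric
rules (H-bonds, hydrophobic contacts, aromatic stacking) and converts them
into a receptor-based pharmacophore hypothesis: features sit on the ligand
side of each interaction and point toward the interacting receptor group,
so a molecule matching the hypothesis can reproduce the interaction
pattern.

All thresholds live in :class:`GeometricRules`; the defaults are
conventional crystallographic values, since commercial perception tools do
not publish theirs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import chem
from .chem import ProteinComplex
from .features import DEFAULT_RADIUS, DEFAULT_WEIGHT, Hypothesis, PharmacophoreFeature

log = logging.getLogger(__name__)

INTERACTION_KINDS = ("hbond_ligand_donor", "hbond_ligand_acceptor",
                     "hydrophobic", "aromatic_ring", "pi_stack")


@dataclass
class GeometricRules:
    """Distance/angle thresholds for interaction perception (Å, degrees)."""

    hbond_dist_min: float = 2.5      # donor heavy atom to acceptor
    hbond_dist_max: float = 3.8
    hbond_angle_min: float = 130.0   # angle at the donor hydrogen
    hydrophobic_dist: float = 5.0    # group centroid to receptor carbon
    hydrophobic_min_contacts: int = 3
    pistack_face_dist: float = 4.5   # ring centroid separation, parallel
    pistack_face_angle: float = 30.0
    pistack_edge_dist: float = 5.5   # ring centroid separation, T-shaped
    pistack_edge_angle: Tuple[float, float] = (60.0, 120.0)


@dataclass
class FeatureConfig:
    radius: float = DEFAULT_RADIUS
    weight: float = DEFAULT_WEIGHT


@dataclass
class Interaction:
    kind: str
    ligand_atoms: List[int]
    receptor_residue: str            # "RESNAME RESID"
    distance: float                  # Å
    angle: Optional[float] = None    # degrees

    def __post_init__(self):
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("interaction distance must be > 0")
        if self.angle is not None and not 0 <= self.angle <= 180:
            raise ValueError("angle must lie in [0, 180]")


# --------------------------------------------------------------------------
# Receptor atom typing (residue-template based)
# --------------------------------------------------------------------------

_SIDECHAIN_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["ND2"], "GLN": ["NE2"], "TRP": ["NE1"], "HIS": ["ND1", "NE2"],
    "LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"],
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"],
}
_AROMATIC_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"]],
}
_AROMATIC_ATOMS = {rn: {a for ring in rings for a in ring}
                   for rn, rings in _AROMATIC_RINGS.items()}
_BACKBONE = {"N", "CA", "C", "O", "H", "HN", "HA", "OXT"}


def _receptor_residues(rec):
    order: List[Tuple[str, int]] = []
    seen = set()
    for rn, ri, ch in zip(rec.resnames, rec.resids, rec.chains):
        key = (str(rn), int(ri), str(ch))
        if key not in seen:
            seen.add(key)
            order.append(key)
    return order


def _res_mask(rec, key):
    rn, ri, ch = key
    return (rec.resnames == rn) & (rec.resids == ri) & (rec.chains == ch)


def _atom_pos(rec, mask, name):
    sel = mask & (rec.names == name)
    if not sel.any():
        return None
    return rec.coords[sel][0]


def _receptor_donors(rec):
    """(position, hydrogens, residue tag) for receptor H-bond donors."""
    out = []
    for key in _receptor_residues(rec):
        rn, ri, ch = key
        mask = _res_mask(rec, key)
        names = list(_SIDECHAIN_DONORS.get(rn, []))
        if rn != "PRO":
            names.append("N")   # backbone amide
        for dn in names:
            pos = _atom_pos(rec, mask, dn)
            if pos is None:
                continue
            hs = [rec.coords[i] for i in np.where(mask)[0]
                  if rec.elements[i] == "H"
                  and np.linalg.norm(rec.coords[i] - pos) < 1.25]
            out.append((pos, hs, f"{rn} {ri}"))
    return out


def _receptor_acceptors(rec):
    out = []
    for key in _receptor_residues(rec):
        rn, ri, ch = key
        mask = _res_mask(rec, key)
        for an in list(_SIDECHAIN_ACCEPTORS.get(rn, [])) + ["O"]:
            pos = _atom_pos(rec, mask, an)
            if pos is not None:
                out.append((pos, f"{rn} {ri}"))
    return out


def _receptor_hydrophobic_atoms(rec):
    """Side-chain carbons outside aromatic rings."""
    out = []
    for i in range(len(rec)):
        name = str(rec.names[i])
        rn = str(rec.resnames[i])
        if rec.elements[i] != "C" or name in _BACKBONE:
            continue
        if name in _AROMATIC_ATOMS.get(rn, ()):
            continue
        out.append((rec.coords[i], f"{rn} {int(rec.resids[i])}"))
    return out


def _receptor_rings(rec):
    out = []
    for key in _receptor_residues(rec):
        rn, ri, ch = key
        mask = _res_mask(rec, key)
        for ring in _AROMATIC_RINGS.get(rn, []):
            pos = [_atom_pos(rec, mask, a) for a in ring]
            if any(p is None for p in pos):
                continue
            coords = np.array(pos)
            out.append((coords.mean(axis=0), chem.ring_normal(coords), f"{rn} {ri}"))
    return out


# --------------------------------------------------------------------------
# Ligand side helpers
# --------------------------------------------------------------------------

def _ligand_h_positions(m, coords, heavy_idx):
    a = m.GetAtomWithIdx(heavy_idx)
    return [coords[nb.GetIdx()] for nb in a.GetNeighbors() if nb.GetSymbol() == "H"]


def _angle_deg(a, vertex, b) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_interactions(c: ProteinComplex,
                        rules: GeometricRules = GeometricRules()) -> List[Interaction]:
    """Find all receptor-ligand interactions satisfying the geometric rules.

    H-bonds require the donor-heavy-atom-to-acceptor distance inside the
    window and, where the donor hydrogen position is known, an angle at the
    hydrogen of at least ``hbond_angle_min`` (donors without resolvable
    hydrogens pass on distance alone).  Hydrophobic contacts require at
    least ``hydrophobic_min_contacts`` receptor apolar carbons within range
    of a ligand hydrophobic-group centroid.  Ring pairs give ``pi_stack``
    (parallel, face-to-face) or ``aromatic_ring`` (tilted, edge-to-face).
    """
    lig = c.ligand.rdmol
    if lig.GetNumHeavyAtoms() < 1:
        raise ValueError("ligand must have at least one heavy atom")
    has_h = any(a.GetSymbol() == "H" for a in lig.GetAtoms()) or any(
        a.GetNumImplicitHs() > 0 for a in lig.GetAtoms())
    if not has_h and not c.ligand_bond_orders_perceived:
        raise ValueError(
            "ligand has no hydrogens and no valence model; add hydrogens before perception")
    coords = c.ligand.conformer_coords(0)
    rec = c.receptor
    out: List[Interaction] = []

    rec_acc = _receptor_acceptors(rec)
    rec_don = _receptor_donors(rec)

    # ligand donor -> receptor acceptor
    for d in chem.donor_atoms(lig):
        dpos = coords[d]
        hpos = _ligand_h_positions(lig, coords, d)
        for apos, tag in rec_acc:
            dist = float(np.linalg.norm(dpos - apos))
            if not rules.hbond_dist_min <= dist <= rules.hbond_dist_max:
                continue
            angle = None
            if hpos:
                angle = max(_angle_deg(dpos, h, apos) for h in hpos)
                if angle < rules.hbond_angle_min:
                    continue
            out.append(Interaction("hbond_ligand_donor", [d], tag, dist, angle))

    # ligand acceptor <- receptor donor
    for a in chem.acceptor_atoms(lig):
        apos = coords[a]
        for dpos, hs, tag in rec_don:
            dist = float(np.linalg.norm(apos - dpos))
            if not rules.hbond_dist_min <= dist <= rules.hbond_dist_max:
                continue
            angle = None
            if hs:
                angle = max(_angle_deg(dpos, h, apos) for h in hs)
                if angle < rules.hbond_angle_min:
                    continue
            out.append(Interaction("hbond_ligand_acceptor", [a], tag, dist, angle))

    # hydrophobic contacts
    rec_hyd = _receptor_hydrophobic_atoms(rec)
    for group in chem.hydrophobic_groups(lig):
        centroid = coords[group].mean(axis=0)
        near = [(np.linalg.norm(centroid - p), tag) for p, tag in rec_hyd
                if np.linalg.norm(centroid - p) <= rules.hydrophobic_dist]
        if len(near) >= rules.hydrophobic_min_contacts:
            near.sort(key=lambda x: x[0])
            out.append(Interaction("hydrophobic", list(group), near[0][1],
                                   float(near[0][0])))

    # aromatic stacking
    rec_rings = _receptor_rings(rec)
    for ring in chem.aromatic_rings(lig):
        rcoords = coords[ring]
        centroid = rcoords.mean(axis=0)
        normal = chem.ring_normal(rcoords)
        for rcent, rnorm, tag in rec_rings:
            dist = float(np.linalg.norm(centroid - rcent))
            cosang = abs(float(np.dot(normal, rnorm)))
            plane_angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if dist <= rules.pistack_face_dist and plane_angle <= rules.pistack_face_angle:
                out.append(Interaction("pi_stack", list(ring), tag, dist, plane_angle))
            elif (dist <= rules.pistack_edge_dist
                  and rules.pistack_edge_angle[0] <= plane_angle <= rules.pistack_edge_angle[1]):
                out.append(Interaction("aromatic_ring", list(ring), tag, dist, plane_angle))
    return out


# --------------------------------------------------------------------------
# Interactions -> hypothesis
# --------------------------------------------------------------------------

def interactions_to_hypothesis(ints: List[Interaction], c: ProteinComplex,
                               cfg: FeatureConfig = FeatureConfig(),
                               name: str = "hypothesis",
                               frame_of_reference: str = "unknown",
                               model_id: Optional[str] = None) -> Hypothesis:
    """Turn detected interactions into ligand-side pharmacophore features.

    HBD/HBA sit on the ligand donor/acceptor atom pointing toward the
    receptor partner; HYD sits at the hydrophobic-group centroid; ARO at
    the ring centroid with the ring normal as direction.
    """
    if not ints:
        raise ValueError("cannot build a hypothesis from an empty interaction list")
    coords = c.ligand.conformer_coords(0)
    rec = c.receptor
    feats = []
    for it in ints:
        prov = {"receptor_residue": it.receptor_residue, "kind": it.kind}
        if model_id is not None:
            prov["model_id"] = model_id
        if it.kind in ("hbond_ligand_donor", "hbond_ligand_acceptor"):
            center = coords[it.ligand_atoms[0]]
            partner = _nearest_receptor_heteroatom(rec, it.receptor_residue, center)
            direction = None
            if partner is not None and np.linalg.norm(partner - center) > 1e-9:
                direction = partner - center
            ftype = "HBD" if it.kind == "hbond_ligand_donor" else "HBA"
            feats.append(PharmacophoreFeature(ftype, center, cfg.radius,
                                              direction, cfg.weight, prov))
        elif it.kind == "hydrophobic":
            center = coords[it.ligand_atoms].mean(axis=0)
            feats.append(PharmacophoreFeature("HYD", center, cfg.radius,
                                              None, cfg.weight, prov))
        else:  # aromatic_ring / pi_stack -> ARO
            rcoords = coords[it.ligand_atoms]
            feats.append(PharmacophoreFeature("ARO", rcoords.mean(axis=0), cfg.radius,
                                              chem.ring_normal(rcoords), cfg.weight, prov))
    return Hypothesis(feats, name=name, frame_of_reference=frame_of_reference)


def _nearest_receptor_heteroatom(rec, residue_tag: str, point: np.ndarray):
    rn, ri = residue_tag.split()
    mask = (rec.resnames == rn) & (rec.resids == int(ri))
    het = mask & np.isin(rec.elements, ("N", "O", "S"))
    if not het.any():
        het = mask
    if not het.any():
        return None
    pts = rec.coords[het]
    return pts[int(np.argmin(np.linalg.norm(pts - point, axis=1)))]


def perceive(c: ProteinComplex, rules: GeometricRules = GeometricRules(),
             cfg: FeatureConfig = FeatureConfig(), **kw) -> Hypothesis:
    """Convenience: detect interactions and build the hypothesis in one call."""
    return interactions_to_hypothesis(detect_interactions(c, rules), c, cfg, **kw)
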