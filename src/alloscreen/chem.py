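"""Molecular data model, file I/O, and physicochemical properties.

Molecules are thin wrappers around RDKit ``Mol`` objects carrying zero or
more 3D conformers.  Property computation follows Lipinski-compatible
typing: HBD counts N-H/O-H hydrogens, HBA counts N/O acceptors (amide
nitrogens and aromatic N-H excluded), ALOGP is the Crippen
atom-contribution estimate, PSA is the topological polar surface area,
rotatable bonds exclude amide C-N, and AROM counts aromatic rings in the
smallest ring set.

Also hosts the pharmacophoric atom-typing shared by perception and
screening: donor heavy atoms, acceptor atoms, hydrophobic groups, and
aromatic rings.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")

HALOGENS = {"F", "Cl", "Br", "I"}


class LibraryParseError(ValueError):
    pass


class PDBParseError(ValueError):
    pass


class LigandNotFoundError(ValueError):
    pass


# --------------------------------------------------------------------------
# Core containers
# --------------------------------------------------------------------------

@dataclass
class PropertyVector:
    """Physicochemical profile used by Lipinski, QED, and decoy matching."""

    mw: float       # Da
    alogp: float    # unitless, Crippen atom-contribution logP
    hbd: int        # N-H / O-H hydrogen count
    hba: int        # N/O acceptors, amide N and aromatic N-H excluded
    psa: float      # Å², topological polar surface area
    rotb: int       # rotatable bonds, amide C-N excluded
    arom: int       # aromatic rings in the smallest ring set

    def as_dict(self) -> dict:
        return {
            "MW": self.mw, "ALOGP": self.alogp, "HBD": self.hbd,
            "HBA": self.hba, "PSA": self.psa, "ROTB": self.rotb,
            "AROM": self.arom,
        }


@dataclass
class Molecule:
    """A chemical graph with optional 3D conformers."""

    id: str
    rdmol: Chem.Mol
    source: str = ""

    @property
    def n_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def n_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    @property
    def is_2d_only(self) -> bool:
        return self.n_conformers == 0

    def conformer_coords(self, i: int = 0) -> np.ndarray:
        if self.n_conformers == 0:
            raise ValueError(f"molecule {self.id!r} has no conformers")
        return np.array(self.rdmol.GetConformer(i).GetPositions(), dtype=float)

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: Optional[str] = None) -> "Molecule":
        m = Chem.MolFromSmiles(smiles)
        if m is None:
            raise LibraryParseError(f"unparseable SMILES: {smiles!r}")
        return cls(id=mol_id or smiles, rdmol=m, source="smiles")

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.rdmol))


@dataclass
class ReceptorAtoms:
    """Receptor half of a complex as flat arrays (PDB field granularity)."""

    serials: np.ndarray    # int
    names: np.ndarray      # str, PDB atom names
    resnames: np.ndarray   # str
    resids: np.ndarray     # int, 1-based as in the PDB records
    chains: np.ndarray     # str
    elements: np.ndarray   # str
    coords: np.ndarray     # (n, 3) Å

    def __len__(self):
        return len(self.serials)


@dataclass
class ProteinComplex:
    receptor: ReceptorAtoms
    ligand: Molecule
    model_index: int = 0
    source: str = ""
    ligand_bond_orders_perceived: bool = True

    def __post_init__(self):
        if not np.isfinite(self.receptor.coords).all():
            raise ValueError("receptor coordinates must be finite")

    def ligand_coords(self) -> np.ndarray:
        return self.ligand.conformer_coords(0)


# --------------------------------------------------------------------------
# Library I/O
# --------------------------------------------------------------------------

def _merge_key(m: Chem.Mol, mol_id: str) -> Tuple[str, str]:
    return mol_id, Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(m)))


def read_library(path) -> List[Molecule]:
    """Read an SDF or SMILES library.

    SDF records sharing an id and identical connectivity are merged into one
    multi-conformer :class:`Molecule`; unparseable records are skipped with a
    logged warning.  SMILES files yield 2D-only molecules (zero conformers).
    """
    path = str(path)
    if path.endswith((".smi", ".smiles", ".txt")):
        return _read_smiles(path)
    return _read_sdf(path)


def _read_smiles(path: str) -> List[Molecule]:
    mols: List[Molecule] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            m = Chem.MolFromSmiles(parts[0])
            if m is None:
                n_bad += 1
                log.warning("skipping unparseable SMILES at %s:%d", path, lineno)
                continue
            mol_id = parts[1] if len(parts) > 1 else f"mol{len(mols) + 1}"
            mols.append(Molecule(id=mol_id, rdmol=m, source=f"{path}:{lineno}"))
    if n_bad:
        log.warning("%d unparseable records skipped in %s", n_bad, path)
    return mols


def _read_sdf(path: str) -> List[Molecule]:
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
    mols: List[Molecule] = []
    index: dict = {}
    n_bad = 0
    for i, m in enumerate(supplier):
        if m is None:
            n_bad += 1
            log.warning("skipping unparseable SDF record %d in %s", i, path)
            continue
        mol_id = m.GetProp("_Name").strip() if m.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"record{i}"
        key = _merge_key(m, mol_id)
        if key in index:
            base = mols[index[key]].rdmol
            if m.GetNumConformers():
                conf = m.GetConformer()
                base.AddConformer(Chem.Conformer(conf), assignId=True)
        else:
            index[key] = len(mols)
            mols.append(Molecule(id=mol_id, rdmol=Chem.Mol(m), source=f"{path}#{i}"))
    if n_bad:
        log.warning("%d unparseable records skipped in %s", n_bad, path)
    return mols


def write_library(mols: Sequence[Molecule], path) -> None:
    """Write molecules to SDF (one record per conformer) or SMILES."""
    path = str(path)
    if path.endswith((".smi", ".smiles")):
        with open(path, "w") as fh:
            for mol in mols:
                fh.write(f"{mol.canonical_smiles()} {mol.id}\n")
        return
    writer = Chem.SDWriter(path)
    try:
        for mol in mols:
            m = Chem.Mol(mol.rdmol)
            m.SetProp("_Name", mol.id)
            if m.GetNumConformers() == 0:
                writer.write(m)
            else:
                for conf in m.GetConformers():
                    writer.write(m, confId=conf.GetId())
    finally:
        writer.close()


# --------------------------------------------------------------------------
# PDB complexes
# --------------------------------------------------------------------------

_PDB_ATOM_RECORDS = ("ATOM  ", "HETATM")


def _parse_pdb_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = "".join(c for c in name if c.isalpha())[:1]
        return serial, name, resname, chain, resid, (x, y, z), element.capitalize()
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}") from exc


def _ligand_mol_from_block(block: str, mol_id: str):
    m = Chem.MolFromPDBBlock(block, removeHs=False, sanitize=False, proximityBonding=True)
    if m is None or m.GetNumAtoms() == 0:
        raise PDBParseError(f"could not build ligand molecule for {mol_id!r}")
    perceived = True
    try:
        from rdkit.Chem import rdDetermineBonds
        rdDetermineBonds.DetermineBondOrders(m, charge=0)
        Chem.SanitizeMol(m)
    except Exception:
        perceived = False
        try:
            Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                             | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
                             | Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
        except Exception:
            pass
    return m, perceived


def read_structure(path, ligand_selector: str) -> List[ProteinComplex]:
    """Read a (multi-model) PDB file into one complex per MODEL record.

    ``ligand_selector`` is the residue name of the ligand; every other
    ATOM/HETATM record (waters excluded) is assigned to the receptor.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.readlines()

    models: List[List[Tuple]] = []
    current: List[Tuple] = []
    conect_lines: List[str] = []
    saw_model = False
    for lineno, line in enumerate(lines, 1):
        rec = line[:6]
        if rec == "MODEL ":
            saw_model = True
            if current:
                models.append(current)
                current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        elif rec in _PDB_ATOM_RECORDS:
            current.append(_parse_pdb_atom_line(line, lineno) + (line,))
        elif rec == "CONECT":
            conect_lines.append(line)
    if current or not models:
        models.append(current)
    if saw_model:
        models = [m for m in models if m]

    complexes = []
    for mi, atoms in enumerate(models):
        lig = [a for a in atoms if a[2] == ligand_selector]
        rec_atoms = [a for a in atoms if a[2] not in (ligand_selector, "HOH", "WAT")]
        if not lig:
            raise LigandNotFoundError(
                f"ligand not found: no residue named {ligand_selector!r} in {path} (model {mi})")
        lig_serials = {a[0] for a in lig}
        block_lines = [a[7] for a in lig]
        block_lines += [l for l in conect_lines
                        if any(int(tok) in lig_serials for tok in l[6:].split() if tok.strip())]
        ligmol, perceived = _ligand_mol_from_block("".join(block_lines) + "END\n",
                                                   ligand_selector)
        receptor = ReceptorAtoms(
            serials=np.array([a[0] for a in rec_atoms], dtype=int),
            names=np.array([a[1] for a in rec_atoms]),
            resnames=np.array([a[2] for a in rec_atoms]),
            resids=np.array([a[4] for a in rec_atoms], dtype=int),
            chains=np.array([a[3] for a in rec_atoms]),
            elements=np.array([a[6] for a in rec_atoms]),
            coords=np.array([a[5] for a in rec_atoms], dtype=float).reshape(-1, 3),
        )
        complexes.append(ProteinComplex(
            receptor=receptor,
            ligand=Molecule(id=ligand_selector, rdmol=ligmol, source=path),
            model_index=mi,
            source=path,
            ligand_bond_orders_perceived=perceived,
        ))
    return complexes


# --------------------------------------------------------------------------
# Properties
# --------------------------------------------------------------------------

def largest_fragment(m: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(m, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return m
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def compute_properties(mol: Molecule, use_largest_fragment: bool = True) -> PropertyVector:
    """Compute the seven-property physicochemical profile of a molecule.

    Salts (disconnected fragments) are reduced to the largest fragment with
    a warning unless ``use_largest_fragment`` is off; properties depend only
    on the chemical graph, never on conformers.
    """
    m = Chem.Mol(mol.rdmol)
    if use_largest_fragment and len(Chem.GetMolFrags(m)) > 1:
        log.warning("molecule %s has disconnected fragments; using largest", mol.id)
        m = largest_fragment(m)
    # implicit-hydrogen graph: explicit Hs would distort the degree-based
    # rotatable-bond definition; all descriptors count implicit Hs correctly
    m = Chem.RemoveHs(m)
    return PropertyVector(
        mw=float(Descriptors.MolWt(m)),
        alogp=float(Crippen.MolLogP(m)),
        # Lipinski-style donor count: one per N-H / O-H hydrogen
        hbd=int(Lipinski.NHOHCount(m)),
        # acceptor rule shared with pharmacophore typing (amide N and
        # aromatic N-H excluded)
        hba=len(acceptor_atoms(m)),
        psa=float(rdMolDescriptors.CalcTPSA(m)),
        rotb=int(rdMolDescriptors.CalcNumRotatableBonds(m)),
        arom=int(rdMolDescriptors.CalcNumAromaticRings(m)),
    )


# --------------------------------------------------------------------------
# Pharmacophoric atom typing (shared by perception and screening)
# --------------------------------------------------------------------------

def donor_atoms(m: Chem.Mol) -> List[int]:
    """Indices of N/O heavy atoms bearing at least one hydrogen."""
    out = []
    for a in m.GetAtoms():
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs(includeNeighbors=True) > 0:
            out.append(a.GetIdx())
    return out


def _is_amide_n(a: Chem.Atom) -> bool:
    if a.GetSymbol() != "N":
        return False
    for nb in a.GetNeighbors():
        if nb.GetSymbol() == "C":
            for b in nb.GetBonds():
                other = b.GetOtherAtom(nb)
                if (other.GetSymbol() == "O"
                        and b.GetBondType() == Chem.BondType.DOUBLE):
                    return True
    return False


def acceptor_atoms(m: Chem.Mol) -> List[int]:
    """N/O acceptors: amide N and aromatic N-H are excluded."""
    out = []
    for a in m.GetAtoms():
        sym = a.GetSymbol()
        if sym not in ("N", "O"):
            continue
        if sym == "N":
            if _is_amide_n(a):
                continue
            if a.GetIsAromatic() and a.GetTotalNumHs(includeNeighbors=True) > 0:
                continue
        out.append(a.GetIdx())
    return out


def hydrophobic_groups(m: Chem.Mol) -> List[List[int]]:
    """Maximal connected sets of non-aromatic carbons (plus halogens) with no
    attached heteroatom.

    Aromatic-ring atoms are handled by the aromatic feature type and are
    excluded here; a lone halogen on an aromatic ring therefore forms its
    own single-atom group.
    """
    eligible = set()
    for a in m.GetAtoms():
        sym = a.GetSymbol()
        if sym == "C" and not a.GetIsAromatic():
            if all(nb.GetSymbol() == "C" or nb.GetSymbol() == "H" or nb.GetSymbol() in HALOGENS
                   for nb in a.GetNeighbors()):
                eligible.add(a.GetIdx())
        elif sym in HALOGENS:
            eligible.add(a.GetIdx())
    groups: List[List[int]] = []
    seen: set = set()
    for idx in sorted(eligible):
        if idx in seen:
            continue
        stack, comp = [idx], []
        seen.add(idx)
        while stack:
            i = stack.pop()
            comp.append(i)
            for nb in m.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in eligible and j not in seen:
                    seen.add(j)
                    stack.append(j)
        groups.append(sorted(comp))
    return groups


def aromatic_rings(m: Chem.Mol) -> List[List[int]]:
    """Atom-index tuples of aromatic rings in the smallest ring set."""
    ri = m.GetRingInfo()
    out = []
    for ring in ri.AtomRings():
        if all(m.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            out.append(list(ring))
    return out


def ring_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best plane through ring atom coordinates."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[2]
    return n / np.linalg.norm(n)


def embed_conformers(mol: Molecule, n_conformers: int = 1, seed: int = 7) -> Molecule:
    """Optional helper: generate conformers with RDKit's ETKDG embedder.

    Conformer ensembles are normally inputs; this wrapper exists so that
    2D-only libraries (e.g. SMILES decoys) can be taken through the
    geometric screen.
    """
    m = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    AllChem.EmbedMultipleConfs(m, numConfs=n_conformers, params=params)
    return Molecule(id=mol.id, rdmol=m, source=mol.source)
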