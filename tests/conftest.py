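import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from alloscreen.chem import Molecule
from alloscreen.features import Hypothesis, PharmacophoreFeature


@pytest.fixture
def target_hypothesis():
    """Five well-separated features (2 HBD, 2 HBA, 1 HYD), unit weights."""
    centers = [(0.0, 0.0, 0.0), (6.0, 0.0, 0.0), (0.0, 6.0, 0.0),
               (6.0, 6.0, 0.0), (3.0, 3.0, 4.5)]
    types = ["HBD", "HBD", "HBA", "HBA", "HYD"]
    feats = [PharmacophoreFeature(t, c) for t, c in zip(types, centers)]
    return Hypothesis(feats, name="target", frame_of_reference="synthetic")


@pytest.fixture
def anti_hypothesis():
    """Four-feature anti-target (types a subset of the target's)."""
    centers = [(0.0, 0.0, 0.0), (5.0, 0.0, 0.0), (0.0, 5.0, 0.0),
               (5.0, 5.0, 3.0)]
    types = ["HBA", "HBA", "HBD", "HYD"]
    feats = [PharmacophoreFeature(t, c) for t, c in zip(types, centers)]
    return Hypothesis(feats, name="anti", frame_of_reference="synthetic")


def embedded(smiles: str, mol_id: str = "mol", seed: int = 3) -> Molecule:
    """Small helper: molecule with one ETKDG conformer."""
    m = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(m, params)
    return Molecule(id=mol_id, rdmol=m)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
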