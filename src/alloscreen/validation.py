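"""Hypothesis validation: decoy sets, test-set classification, statistics.

A pharmacophore hypothesis is stress-tested in two ways:

* **Test-set classification** — known actives/less-actives are fitted and
  called active when FitValue ≥ θ *and* the full feature count is matched.
  A reference 19-molecule PTP1B allosteric-inhibitor test set with reported
  FitValues ships with the package (:func:`load_reference_testset`).
* **Decoy screening** — presumed-inactive molecules physicochemically
  matched to the actives (MW, rotatable bonds, HBD, HBA, logP windows) but
  topologically dissimilar (fingerprint Tanimoto cap) are pooled with the
  actives; retrieval is summarised by the confusion table and by the
  enrichment factor E = (TP·D)/(Ht·A) and the Güner–Henry score
  GH = [TP(3A+Ht)/(4·Ht·A)]·[1−(Ht−TP)/(D−A)], which is 1 for perfect
  retrieval and 0 when nothing relevant is retrieved.
"""
from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs

from .chem import Molecule, PropertyVector, compute_properties

log = logging.getLogger(__name__)

#: FitValue threshold and full-match count used for the reference test set
DEFAULT_FIT_THRESHOLD = 2.94
DEFAULT_FULL_MATCH = 5


class DecoyShortfallError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Confusion table and statistics
# --------------------------------------------------------------------------

@dataclass
class ConfusionTable:
    """Retrieval counts: D molecules, A actives, Ht retrieved, TP actives
    retrieved."""

    D: int
    A: int
    Ht: int
    TP: int

    def __post_init__(self):
        if not (0 <= self.TP <= min(self.A, self.Ht) and self.Ht <= self.D
                and self.A <= self.D):
            raise ValueError(f"inconsistent confusion counts: {self}")
        if self.D - self.A - (self.Ht - self.TP) < 0:
            raise ValueError(
                f"inconsistent confusion counts (TN < 0): {self}")

    @property
    def FP(self) -> int:
        return self.Ht - self.TP

    @property
    def FN(self) -> int:
        return self.A - self.TP

    @property
    def TN(self) -> int:
        return self.D - self.A - self.FP

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.D

    @property
    def precision(self) -> float:
        return self.TP / self.Ht if self.Ht else 0.0

    @property
    def sensitivity(self) -> float:
        return self.TP / self.A if self.A else 0.0

    @property
    def specificity(self) -> float:
        return self.TN / (self.D - self.A) if self.D > self.A else 0.0

    def summary(self) -> Dict[str, float]:
        return {
            "D": self.D, "A": self.A, "Ht": self.Ht, "TP": self.TP,
            "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "E": enrichment(self) if self.Ht and self.A else float("nan"),
            "GH": gh_score(self) if self.Ht and self.A and self.D > self.A
            else float("nan"),
        }


def confusion(labels_true: Dict[str, str], labels_pred: Dict[str, str]) -> ConfusionTable:
    """Build the confusion table from per-id true/predicted labels
    ('active' vs anything else)."""
    if set(labels_true) != set(labels_pred):
        raise ValueError("true and predicted label id sets differ")
    D = len(labels_true)
    A = sum(1 for v in labels_true.values() if v == "active")
    Ht = sum(1 for v in labels_pred.values() if v == "active")
    TP = sum(1 for k in labels_true
             if labels_true[k] == "active" and labels_pred[k] == "active")
    return ConfusionTable(D=D, A=A, Ht=Ht, TP=TP)


def enrichment(t: ConfusionTable) -> float:
    """Enrichment factor E = (TP × D) / (Ht × A)."""
    if t.Ht == 0 or t.A == 0:
        raise ValueError("enrichment undefined for Ht = 0 or A = 0")
    return (t.TP * t.D) / (t.Ht * t.A)


def gh_score(t: ConfusionTable) -> float:
    """Güner–Henry goodness-of-hit:
    GH = [TP(3A + Ht) / (4·Ht·A)] × [1 − (Ht − TP)/(D − A)]."""
    if t.Ht == 0 or t.A == 0:
        raise ValueError("GH undefined for Ht = 0 or A = 0")
    if t.D == t.A:
        raise ValueError("GH undefined for D = A")
    yield_term = t.TP * (3 * t.A + t.Ht) / (4 * t.Ht * t.A)
    penalty = 1.0 - (t.Ht - t.TP) / (t.D - t.A)
    return yield_term * penalty


# --------------------------------------------------------------------------
# Test-set classification
# --------------------------------------------------------------------------

def classify_test_set(fits: Iterable[Tuple[str, float, int]],
                      threshold: float = DEFAULT_FIT_THRESHOLD,
                      full_match: int = DEFAULT_FULL_MATCH) -> Dict[str, str]:
    """Predicted label per id: 'active' iff FitValue ≥ threshold (inclusive)
    and at least ``full_match`` features matched, else 'not_active'."""
    out = {}
    for mol_id, fit_value, n_matched in fits:
        ok = fit_value >= threshold and n_matched >= full_match
        out[str(mol_id)] = "active" if ok else "not_active"
    return out


def load_reference_testset() -> pd.DataFrame:
    """The 19-molecule PTP1B allosteric test set with reported FitValues,
    matched feature counts and activity classes."""
    ref = importlib.resources.files("alloscreen") / "data" / "ptp1b_testset.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def testset_tallies(df: Optional[pd.DataFrame] = None,
                    threshold: float = DEFAULT_FIT_THRESHOLD,
                    full_match: int = DEFAULT_FULL_MATCH) -> Dict[str, int]:
    """Per-class correct-prediction tallies on a test-set table.

    A molecule of class 'active' is correct when predicted active; one of
    class 'less_active' or 'inactive' is correct when predicted not active.
    """
    if df is None:
        df = load_reference_testset()
    pred = classify_test_set(
        zip(df["compound"].astype(str), df["fit_value"], df["n_matched"]),
        threshold, full_match)
    tallies = {"active_total": 0, "active_correct": 0,
               "less_active_total": 0, "less_active_correct": 0,
               "inactive_total": 0, "inactive_correct": 0}
    for _, row in df.iterrows():
        cls = row["activity_class"]
        p = pred[str(row["compound"])]
        tallies[f"{cls}_total"] += 1
        correct = (p == "active") if cls == "active" else (p == "not_active")
        if correct:
            tallies[f"{cls}_correct"] += 1
    return tallies


# --------------------------------------------------------------------------
# Decoy generation
# --------------------------------------------------------------------------

@dataclass
class DecoyTolerances:
    """Physicochemical windows for decoy-active matching plus the topological
    dissimilarity cap."""

    d_mw: float = 25.0       # Da
    d_rotb: int = 1
    d_hbd: int = 1
    d_hba: int = 1
    d_alogp: float = 1.0
    tanimoto_max: float = 0.75   # path-based fingerprint similarity cap

    def __post_init__(self):
        if min(self.d_mw, self.d_rotb, self.d_hbd, self.d_hba, self.d_alogp) < 0:
            raise ValueError("tolerances must be >= 0")
        if not 0 < self.tanimoto_max <= 1:
            raise ValueError("tanimoto_max must be in (0, 1]")

    def property_match(self, a: PropertyVector, b: PropertyVector) -> bool:
        return (abs(a.mw - b.mw) <= self.d_mw
                and abs(a.rotb - b.rotb) <= self.d_rotb
                and abs(a.hbd - b.hbd) <= self.d_hbd
                and abs(a.hba - b.hba) <= self.d_hba
                and abs(a.alogp - b.alogp) <= self.d_alogp)


def _fingerprint(mol: Molecule):
    # hashed path-based bit vector; parameters recorded in reports
    return Chem.RDKFingerprint(Chem.RemoveHs(mol.rdmol), maxPath=5, fpSize=1024)

FINGERPRINT_PARAMS = {"kind": "rdkit_path", "maxPath": 5, "fpSize": 1024}


def generate_decoys(actives: Sequence[Molecule], pool: Sequence[Molecule],
                    tol: DecoyTolerances = DecoyTolerances(),
                    n_per_active: int = 36, seed: int = 0) -> List[Molecule]:
    """Sample ``n_per_active`` decoys per active from the pool.

    A pool molecule is eligible for an active when its property vector lies
    within the tolerance windows of that active's and its fingerprint
    Tanimoto to *every* active is below the cap.  Sampling is uniform and
    seeded; a decoy is never reused across actives.
    """
    if n_per_active < 1:
        raise ValueError("n_per_active must be >= 1")
    pool_ids = {m.id for m in pool}
    if any(a.id in pool_ids for a in actives):
        raise ValueError("pool must be disjoint from actives")
    rng = np.random.default_rng(seed)
    active_props = [compute_properties(a) for a in actives]
    active_fps = [_fingerprint(a) for a in actives]
    pool_props = [compute_properties(m) for m in pool]
    pool_fps = [_fingerprint(m) for m in pool]
    dissimilar = [
        all(DataStructs.TanimotoSimilarity(fp, afp) < tol.tanimoto_max
            for afp in active_fps)
        for fp in pool_fps
    ]
    taken: set = set()
    decoys: List[Molecule] = []
    for a, aprop in zip(actives, active_props):
        eligible = [i for i, (p, ok) in enumerate(zip(pool_props, dissimilar))
                    if ok and i not in taken and tol.property_match(p, aprop)]
        if len(eligible) < n_per_active:
            raise DecoyShortfallError(
                f"active {a.id!r}: only {len(eligible)} eligible pool molecules "
                f"for {n_per_active} requested decoys")
        chosen = rng.choice(len(eligible), size=n_per_active, replace=False)
        for ci in sorted(chosen):
            idx = eligible[ci]
            taken.add(idx)
            decoys.append(pool[idx])
    return decoys
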