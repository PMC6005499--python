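"""Pharmacophore fitting and the sequential selectivity funnel.

Fitting maps hypothesis features onto ligand features of the same type
(injectively), superposes the mapped ligand feature centers onto the
hypothesis centers by least squares, and scores

    FitValue = Σ_mapped  w_f · max(0, 1 − (d_f / r_f)²)

where d_f is the post-superposition center distance and r_f the feature's
tolerance radius.  A mapping is only valid when every mapped feature ends
up inside its tolerance sphere, so the FitValue of a molecule is bounded
by the sum of mapped feature weights (the feature count under unit
weights).

The funnel chains the filters of a selectivity-aware virtual screen:
rule-of-five, target-pharmacophore screen, anti-target (selectivity)
removal, and QED drug-likeness, with named pass-through hooks for
externally computed stages such as toxicity filters or docking.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import Molecule, PropertyVector, compute_properties
from .druglikeness import QEDParams, lipinski_pass, qed
from .features import Hypothesis, PharmacophoreFeature
from .superpose import kabsch

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Ligand-side features
# --------------------------------------------------------------------------

def ligand_features(mol: Molecule, conformer: int = 0) -> List[PharmacophoreFeature]:
    """Pharmacophoric features of one conformer, typed like perception:
    HBD at donor heavy atoms, HBA at acceptor atoms, HYD at
    hydrophobic-group centroids, ARO at aromatic-ring centroids."""
    if mol.is_2d_only:
        raise ValueError(
            f"molecule {mol.id!r} has no 3D conformers; supply conformer input")
    m = mol.rdmol
    coords = mol.conformer_coords(conformer)
    feats: List[PharmacophoreFeature] = []
    for i in chem.donor_atoms(m):
        feats.append(PharmacophoreFeature("HBD", coords[i]))
    for i in chem.acceptor_atoms(m):
        feats.append(PharmacophoreFeature("HBA", coords[i]))
    for g in chem.hydrophobic_groups(m):
        feats.append(PharmacophoreFeature("HYD", coords[g].mean(axis=0)))
    for ring in chem.aromatic_rings(m):
        rc = coords[ring]
        feats.append(PharmacophoreFeature("ARO", rc.mean(axis=0),
                                          direction=chem.ring_normal(rc)))
    return feats


# --------------------------------------------------------------------------
# Fit result
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    molecule_id: str
    conformer: int
    mapping: List[Tuple[int, int]]     # (hypothesis feature idx, ligand feature idx)
    rotation: np.ndarray               # applied to the conformer
    translation: np.ndarray
    fit_value: float
    n_matched: int

    def __post_init__(self):
        lig = [j for _, j in self.mapping]
        if len(set(lig)) != len(lig):
            raise ValueError("mapping must be injective")
        if self.n_matched != len(self.mapping):
            raise ValueError("n_matched must equal |mapping|")


def _score_mapping(hyp_feats, lig_feats, pairs):
    """Superpose mapped ligand features onto the hypothesis; None if any
    mapped feature falls outside its tolerance sphere."""
    P = np.array([lig_feats[j].center for _, j in pairs])
    Q = np.array([hyp_feats[i].center for i, _ in pairs])
    R, t, _ = kabsch(P, Q)
    moved = P @ R.T + t
    fit = 0.0
    for (i, _), pos in zip(pairs, moved):
        f = hyp_feats[i]
        d = float(np.linalg.norm(pos - f.center))
        if d > f.radius:
            return None
        fit += f.weight * max(0.0, 1.0 - (d / f.radius) ** 2)
    return fit, R, t


def map_and_fit(lig_feats: Sequence[PharmacophoreFeature], h: Hypothesis,
                min_features: int = 4, molecule_id: str = "",
                conformer: int = 0, prune: bool = True) -> Optional[FitResult]:
    """Best mapping of hypothesis features onto ligand features.

    Enumerates injective type-compatible correspondences of at least
    ``min_features`` features (backtracking, pruned by pairwise distance
    compatibility |d_hyp − d_lig| ≤ r_i + r_j), scores each accepted
    superposition, and returns the mapping maximising
    (fit_value, n_matched); ties keep the first mapping in enumeration
    order.  ``prune=False`` disables the distance pruning (used for
    oracle cross-checks).
    """
    if min_features < 3:
        raise ValueError("min_features must be >= 3 (superposition needs 3 points)")
    H = len(h.features)
    L = len(lig_feats)
    if H < min_features:
        return None
    cand = [[j for j in range(L) if lig_feats[j].type == h.features[i].type]
            for i in range(H)]
    hyp_d = np.linalg.norm(h.centers()[:, None, :] - h.centers()[None, :, :], axis=2)
    lig_centers = np.array([f.center for f in lig_feats]).reshape(-1, 3)
    lig_d = np.linalg.norm(lig_centers[:, None, :] - lig_centers[None, :, :], axis=2)

    best: Optional[Tuple[float, int, List[Tuple[int, int]], np.ndarray, np.ndarray]] = None
    assigned: List[Tuple[int, int]] = []
    used = [False] * L

    def compatible(i, j):
        for (i2, j2) in assigned:
            tol = h.features[i].radius + h.features[i2].radius
            if abs(hyp_d[i, i2] - lig_d[j, j2]) > tol:
                return False
        return True

    def recurse(i):
        nonlocal best
        if len(assigned) + (H - i) < min_features:
            return
        if i == H:
            if len(assigned) < min_features:
                return
            scored = _score_mapping(h.features, lig_feats, assigned)
            if scored is None:
                return
            fit, R, t = scored
            if best is None or (fit, len(assigned)) > (best[0], best[1]):
                best = (fit, len(assigned), list(assigned), R, t)
            return
        for j in cand[i]:
            if used[j]:
                continue
            if prune and not compatible(i, j):
                continue
            used[j] = True
            assigned.append((i, j))
            recurse(i + 1)
            assigned.pop()
            used[j] = False
        recurse(i + 1)  # skip hypothesis feature i

    recurse(0)
    if best is None:
        return None
    fit, n, pairs, R, t = best
    return FitResult(molecule_id=molecule_id, conformer=conformer,
                     mapping=pairs, rotation=R, translation=t,
                     fit_value=fit, n_matched=n)


def best_fit(mol: Molecule, h: Hypothesis, min_features: int = 4) -> Optional[FitResult]:
    """Best fit over all conformers of a molecule (ties keep the lowest
    conformer index)."""
    if mol.n_conformers == 0:
        raise ValueError(f"molecule {mol.id!r} has no conformers")
    best: Optional[FitResult] = None
    for ci in range(mol.n_conformers):
        feats = ligand_features(mol, ci)
        res = map_and_fit(feats, h, min_features, molecule_id=mol.id, conformer=ci)
        if res is None:
            continue
        if best is None or (res.fit_value, res.n_matched) > (best.fit_value, best.n_matched):
            best = res
    return best


# --------------------------------------------------------------------------
# Library screening
# --------------------------------------------------------------------------

@dataclass
class ScreenReport:
    rows: pd.DataFrame          # id, fit_value, n_matched, hit (library order)
    threshold: float
    min_features: int
    hypothesis: str
    anti_threshold: Optional[float] = None
    anti_hypothesis: Optional[str] = None

    @property
    def hits(self) -> List[str]:
        return self.rows.loc[self.rows["hit"], "id"].tolist()

    @property
    def n_hits(self) -> int:
        return int(self.rows["hit"].sum())


def screen_library(lib: Sequence[Molecule], h: Hypothesis, threshold: float,
                   min_features: int = 4) -> ScreenReport:
    """Screen a library; a molecule is a hit iff its best FitValue is at or
    above the threshold (inclusive).  Per-molecule failures are logged and
    recorded as misses, never abort the run."""
    if len(lib) == 0:
        raise ValueError("library must be non-empty")
    records = []
    for mol in lib:
        fit_value, n_matched = np.nan, 0
        try:
            res = best_fit(mol, h, min_features)
            if res is not None:
                fit_value, n_matched = res.fit_value, res.n_matched
        except Exception as exc:  # noqa: BLE001 - per-molecule resilience
            log.warning("screening failed for %s: %s", mol.id, exc)
        records.append({"id": mol.id, "fit_value": fit_value,
                        "n_matched": n_matched,
                        "hit": bool(fit_value >= threshold)
                        if np.isfinite(fit_value) else False})
    return ScreenReport(rows=pd.DataFrame(records), threshold=threshold,
                        min_features=min_features, hypothesis=h.name)


def selectivity_screen(lib: Sequence[Molecule], target_h: Hypothesis,
                       threshold_target: float, anti_h: Hypothesis,
                       threshold_anti: float,
                       min_features: int = 4) -> ScreenReport:
    """Target screen minus molecules that also fit the anti-target at or
    above its threshold; the report carries both FitValues per molecule."""
    target = screen_library(lib, target_h, threshold_target, min_features)
    anti = screen_library(lib, anti_h, threshold_anti, min_features)
    rows = target.rows.rename(columns={"fit_value": "fit_value_target",
                                       "n_matched": "n_matched_target",
                                       "hit": "hit_target"})
    rows["fit_value_anti"] = anti.rows["fit_value"].values
    rows["hit_anti"] = anti.rows["hit"].values
    rows["hit"] = rows["hit_target"] & ~rows["hit_anti"]
    return ScreenReport(rows=rows, threshold=threshold_target,
                        min_features=min_features, hypothesis=target_h.name,
                        anti_threshold=threshold_anti, anti_hypothesis=anti_h.name)


# --------------------------------------------------------------------------
# Funnel
# --------------------------------------------------------------------------

@dataclass
class FunnelConfig:
    fit_threshold_target: float = 2.94
    fit_threshold_anti: float = 3.66
    min_features: int = 4
    qed_threshold: float = 0.50      # strict: QED must exceed this
    qed_kind: str = "weighted"
    lipinski: bool = True

    def __post_init__(self):
        if min(self.fit_threshold_target, self.fit_threshold_anti,
               self.qed_threshold) < 0:
            raise ValueError("thresholds must be >= 0")


#: a hook maps {molecule id} -> keep? It stands in for externally computed
#: funnel stages (toxicity filters, docking) and is never computed here.
FunnelHook = Callable[[str], bool]


@dataclass
class FunnelReport:
    stages: List[Tuple[str, List[str]]]     # (stage name, surviving ids)
    table: pd.DataFrame                     # per-molecule detail

    @property
    def counts(self) -> Dict[str, int]:
        return {name: len(ids) for name, ids in self.stages}

    def survivors(self) -> List[str]:
        return self.stages[-1][1]

    def to_dict(self) -> dict:
        return {"stages": [{"name": n, "count": len(ids)} for n, ids in self.stages],
                "survivors": self.survivors()}


def run_funnel(lib: Sequence[Molecule], cfg: FunnelConfig, target_h: Hypothesis,
               anti_h: Optional[Hypothesis] = None,
               qed_params: Optional[QEDParams] = None,
               hooks: Optional[Dict[str, FunnelHook]] = None) -> FunnelReport:
    """Sequential screen: Lipinski → toxicity hook → target pharmacophore →
    anti-target removal → QED → docking hook.

    Hooks (``toxicity``, ``docking``) are pass-through stages fed by
    external per-molecule tables; absent hooks keep everything.
    """
    hooks = hooks or {}
    qed_params = qed_params or QEDParams.default()
    ids = [m.id for m in lib]
    by_id = {m.id: m for m in lib}
    stages: List[Tuple[str, List[str]]] = [("input", list(ids))]
    detail: Dict[str, dict] = {i: {"id": i, "stage_dropped": ""} for i in ids}

    props: Dict[str, PropertyVector] = {}
    for m in lib:
        try:
            props[m.id] = compute_properties(m)
        except Exception as exc:  # noqa: BLE001
            log.warning("property computation failed for %s: %s", m.id, exc)

    def apply(name, keep_fn):
        prev = stages[-1][1]
        kept = []
        for i in prev:
            if keep_fn(i):
                kept.append(i)
            else:
                detail[i]["stage_dropped"] = name
        stages.append((name, kept))

    if cfg.lipinski:
        apply("lipinski", lambda i: i in props and lipinski_pass(props[i]))
    if "toxicity" in hooks:
        apply("toxicity", hooks["toxicity"])

    surviving = [by_id[i] for i in stages[-1][1]]
    if surviving:
        tgt = screen_library(surviving, target_h, cfg.fit_threshold_target,
                             cfg.min_features)
        tgt_fit = dict(zip(tgt.rows["id"], tgt.rows["fit_value"]))
        tgt_hit = dict(zip(tgt.rows["id"], tgt.rows["hit"]))
    else:
        tgt_fit, tgt_hit = {}, {}
    for i in ids:
        detail[i]["fit_value_target"] = tgt_fit.get(i, np.nan)
    apply("target_pharmacophore", lambda i: bool(tgt_hit.get(i, False)))

    if anti_h is not None:
        surviving = [by_id[i] for i in stages[-1][1]]
        if surviving:
            anti = screen_library(surviving, anti_h, cfg.fit_threshold_anti,
                                  cfg.min_features)
            anti_fit = dict(zip(anti.rows["id"], anti.rows["fit_value"]))
            anti_hit = dict(zip(anti.rows["id"], anti.rows["hit"]))
        else:
            anti_fit, anti_hit = {}, {}
        for i in ids:
            detail[i]["fit_value_anti"] = anti_fit.get(i, np.nan)
        apply("anti_target_removed", lambda i: not anti_hit.get(i, False))

    qed_vals = {}
    for i in stages[-1][1]:
        if i in props:
            qed_vals[i] = qed(props[i], qed_params)[cfg.qed_kind]
    for i in ids:
        detail[i]["qed"] = qed_vals.get(i, np.nan)
    apply("qed", lambda i: qed_vals.get(i, 0.0) > cfg.qed_threshold)

    if "docking" in hooks:
        apply("docking", hooks["docking"])

    table = pd.DataFrame([detail[i] for i in ids])
    return FunnelReport(stages=stages, table=table)
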