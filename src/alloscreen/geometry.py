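"""Named inter-atomic distance criteria over conformational ensembles.

Receptor states such as the open/closed WPD-loop conformations of protein
tyrosine phosphatases can be told apart by a handful of inter-residue
distances.  Each criterion names two atom selections (residue number +
atom name sets); its per-frame value is the distance between the selection
centroids, its trajectory value the arithmetic mean over frames, and the
state call compares that mean against open/closed reference values with
tolerances.  A majority vote over criteria yields the overall call.

The shipped PTP1B criteria (``data/ptp1b_criteria.yaml``) are editable
placeholders built from WPD-loop/catalytic-site Cα distances — the
framework is fixed, the constants are configuration.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cluster import Trajectory


@dataclass
class GeometryCriterion:
    name: str
    selection_a: List[Tuple[int, str]]   # (resid, atom name)
    selection_b: List[Tuple[int, str]]
    open_ref: float      # Å
    closed_ref: float    # Å
    tolerance: float     # Å

    def __post_init__(self):
        if not self.selection_a or not self.selection_b:
            raise ValueError(f"criterion {self.name!r}: selections must be non-empty")
        if set(self.selection_a) & set(self.selection_b):
            raise ValueError(f"criterion {self.name!r}: selections must be disjoint")
        if self.tolerance <= 0:
            raise ValueError(f"criterion {self.name!r}: tolerance must be > 0")


def _resolve(traj: Trajectory, selection: Sequence[Tuple[int, str]],
             crit: str, which: str) -> np.ndarray:
    idx = []
    for resid, name in selection:
        hits = np.where((traj.resids == resid) & (traj.names == name))[0]
        if len(hits) == 0:
            raise ValueError(
                f"criterion {crit!r}: selection {which} atom "
                f"({resid}, {name!r}) not found in trajectory")
        idx.extend(hits.tolist())
    return np.array(idx, dtype=int)


def evaluate_criteria(traj: Trajectory,
                      crits: Sequence[GeometryCriterion]) -> pd.DataFrame:
    """Per-frame centroid distances for every criterion.

    Returns a frame-indexed DataFrame with one column per criterion; the
    column mean is the trajectory average used for state classification.
    """
    data = {}
    for c in crits:
        ia = _resolve(traj, c.selection_a, c.name, "A")
        ib = _resolve(traj, c.selection_b, c.name, "B")
        ca = traj.coords[:, ia, :].mean(axis=1)
        cb = traj.coords[:, ib, :].mean(axis=1)
        data[c.name] = np.linalg.norm(ca - cb, axis=1)
    return pd.DataFrame(data)


def classify_state(averages: Dict[str, float],
                   crits: Sequence[GeometryCriterion]) -> Dict[str, str]:
    """Per-criterion open/closed/indeterminate call plus the majority call.

    A criterion calls 'open' when its average lies within tolerance of the
    open reference and outside the closed one (symmetrically for 'closed');
    anything else, including ties in the vote, is 'indeterminate'.
    """
    calls = {}
    for c in crits:
        avg = averages[c.name]
        near_open = abs(avg - c.open_ref) <= c.tolerance
        near_closed = abs(avg - c.closed_ref) <= c.tolerance
        if near_open and not near_closed:
            calls[c.name] = "open"
        elif near_closed and not near_open:
            calls[c.name] = "closed"
        else:
            calls[c.name] = "indeterminate"
    n_open = sum(1 for v in calls.values() if v == "open")
    n_closed = sum(1 for v in calls.values() if v == "closed")
    if n_open > n_closed:
        calls["majority"] = "open"
    elif n_closed > n_open:
        calls["majority"] = "closed"
    else:
        calls["majority"] = "indeterminate"
    return calls


def load_criteria(path=None) -> List[GeometryCriterion]:
    """Load criteria from YAML; defaults to the shipped PTP1B placeholders."""
    if path is None:
        ref = importlib.resources.files("alloscreen") / "data" / "ptp1b_criteria.yaml"
        with importlib.resources.as_file(ref) as p:
            doc = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    out = []
    for c in doc["criteria"]:
        out.append(GeometryCriterion(
            name=c["name"],
            selection_a=[(int(r), str(n)) for r, n in c["selection_a"]],
            selection_b=[(int(r), str(n)) for r, n in c["selection_b"]],
            open_ref=float(c["open_ref"]),
            closed_ref=float(c["closed_ref"]),
            tolerance=float(c["tolerance"]),
        ))
    return out
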