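"""Least-squares rigid-body superposition (Kabsch) of point sets."""
from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation


def kabsch(P: np.ndarray, Q: np.ndarray,
           weights: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray, float]:
    """Rigid motion (R, t) minimising ||R P + t - Q|| in the least-squares
    sense, plus the resulting RMSD.

    Proper rotations only (no reflection).  P and Q are (n, 3) with n >= 1;
    for n < 3 or degenerate (collinear) sets the optimum is not unique and
    an arbitrary minimiser is returned.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError("point sets must have identical shapes")
    if weights is None:
        weights = np.ones(len(P))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    with warnings.catch_warnings():
        # planar/collinear point sets are legitimate; any minimiser will do
        warnings.filterwarnings("ignore", message="Optimal rotation is not",
                                category=UserWarning)
        rot, _ = Rotation.align_vectors(Q - qc, P - pc, weights=w)
    R = rot.as_matrix()
    t = qc - R @ pc
    d = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((w * (d ** 2).sum(axis=1)).sum()))
    return R, t, rmsd


def rmsd(P: np.ndarray, Q: np.ndarray, superpose: bool = True) -> float:
    """RMSD between two conformations, optionally after optimal superposition."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if superpose:
        return kabsch(P, Q)[2]
    return float(np.sqrt(((P - Q) ** 2).sum(axis=1).mean()))
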