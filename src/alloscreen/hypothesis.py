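"""Merging per-snapshot hypotheses into a common dynamic pharmacophore.

Each MD-representative complex yields its own hypothesis; features of the
same type that recur across snapshots (within ``merge_radius`` of each
other, single-linkage) are collapsed to one consensus feature at their
centroid.  A feature group survives if it is supported by at least
``min_support`` source hypotheses, or if it carries an essential tag
(curated interactions that must be kept regardless of support).

All inputs must already be expressed in one receptor frame of reference —
merging does not superpose.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .features import (DEFAULT_RADIUS, DEFAULT_WEIGHT, FEATURE_TYPES, Hypothesis,
                       PharmacophoreFeature, load_hypothesis, save_hypothesis,
                       hypothesis_from_dict, HypothesisSchemaError)

__all__ = [
    "MergeConfig", "merge_hypotheses", "save_hypothesis", "load_hypothesis",
    "hypothesis_from_dict", "HypothesisSchemaError",
]


@dataclass
class MergeConfig:
    merge_radius: float = 1.5        # Å; same-type features closer than this merge
    min_support: int = 1             # source hypotheses a merged feature needs
    essential_override: List[str] = field(default_factory=list)
    default_radius: float = DEFAULT_RADIUS

    def __post_init__(self):
        if self.merge_radius <= 0:
            raise ValueError("merge_radius must be > 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


def _is_essential(feat: PharmacophoreFeature, cfg: MergeConfig) -> bool:
    if feat.provenance.get("essential"):
        return True
    tags = {str(v) for v in feat.provenance.values()}
    return any(t in tags for t in cfg.essential_override)


def merge_hypotheses(hyps: Sequence[Hypothesis], cfg: MergeConfig = MergeConfig(),
                     name: str = "merged") -> Hypothesis:
    """Merge aligned per-snapshot hypotheses into one common hypothesis."""
    if not hyps:
        raise ValueError("need at least one hypothesis to merge")
    frames = {h.frame_of_reference for h in hyps}
    if len(frames) > 1:
        raise ValueError(f"mixed frames of reference: {sorted(frames)}")

    merged: List[PharmacophoreFeature] = []
    for ftype in FEATURE_TYPES:
        feats = [(hi, f) for hi, h in enumerate(hyps) for f in h.features
                 if f.type == ftype]
        if not feats:
            continue
        centers = np.array([f.center for _, f in feats])
        if len(feats) == 1:
            groups = [[0]]
        else:
            Z = linkage(pdist(centers), method="single")
            labels = fcluster(Z, t=cfg.merge_radius, criterion="distance")
            groups = [np.where(labels == l)[0].tolist()
                      for l in sorted(set(labels))]
        for g in groups:
            sources = {feats[i][0] for i in g}
            members = [feats[i][1] for i in g]
            essential = any(_is_essential(f, cfg) for f in members)
            if len(sources) < cfg.min_support and not essential:
                continue
            center = centers[g].mean(axis=0)
            dirs = [f.direction for f in members if f.direction is not None]
            direction = None
            if dirs:
                d = np.mean(dirs, axis=0)
                if np.linalg.norm(d) > 1e-9:
                    direction = d
            merged.append(PharmacophoreFeature(
                type=ftype,
                center=center,
                radius=cfg.default_radius,
                direction=direction,
                weight=float(np.mean([f.weight for f in members])),
                provenance={
                    "support": len(sources),
                    "essential": essential,
                    "contributors": [f.provenance for f in members],
                },
            ))
    if not merged:
        raise ValueError("no feature group met the support requirement")
    return Hypothesis(merged, name=name,
                      frame_of_reference=hyps[0].frame_of_reference)
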