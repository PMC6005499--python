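"""Pharmacophore feature and hypothesis containers.

A pharmacophore feature is a typed, positioned tolerance sphere, optionally
carrying a direction (H-bond features point from the ligand atom toward the
interacting receptor atom; aromatic features carry the ring normal).  A
hypothesis is a named set of features sharing one receptor frame of
reference.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Recognised feature types: H-bond donor, H-bond acceptor, hydrophobe,
#: aromatic ring.
FEATURE_TYPES = ("HBD", "HBA", "HYD", "ARO")

SCHEMA_VERSION = 1

DEFAULT_RADIUS = 1.5  # Å tolerance sphere
DEFAULT_WEIGHT = 1.0


class HypothesisSchemaError(ValueError):
    """Raised when a hypothesis JSON document violates the schema."""


@dataclass
class PharmacophoreFeature:
    type: str
    center: np.ndarray  # (3,) Å
    radius: float = DEFAULT_RADIUS
    direction: Optional[np.ndarray] = None  # unit vector
    weight: float = DEFAULT_WEIGHT
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("feature radius must be > 0")
        if self.weight <= 0:
            raise ValueError("feature weight must be > 0")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float).reshape(3)
            n = np.linalg.norm(d)
            if n < 1e-12:
                raise ValueError("feature direction must be non-zero")
            self.direction = d / n

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PharmacophoreFeature":
        """Return a copy moved by the rigid motion x -> R x + t."""
        d = None if self.direction is None else R @ self.direction
        return replace(self, center=R @ self.center + t, direction=d)

    def to_dict(self) -> dict:
        out = {
            "type": self.type,
            "center": [float(x) for x in self.center],
            "radius": float(self.radius),
            "weight": float(self.weight),
            "provenance": dict(self.provenance),
        }
        if self.direction is not None:
            out["direction"] = [float(x) for x in self.direction]
        return out


@dataclass
class Hypothesis:
    features: list
    name: str = "hypothesis"
    frame_of_reference: str = "unknown"

    def __post_init__(self):
        if len(self.features) == 0:
            raise ValueError("a hypothesis needs at least one feature")

    def __len__(self):
        return len(self.features)

    @property
    def total_weight(self) -> float:
        return float(sum(f.weight for f in self.features))

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])

    def type_multiset(self) -> dict:
        out: dict = {}
        for f in self.features:
            out[f.type] = out.get(f.type, 0) + 1
        return out

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Hypothesis":
        return Hypothesis(
            [f.transformed(R, t) for f in self.features],
            name=self.name,
            frame_of_reference=self.frame_of_reference,
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "frame_of_reference": self.frame_of_reference,
            "features": [f.to_dict() for f in self.features],
        }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise HypothesisSchemaError(f"missing required field {key!r} in {where}")
    return d[key]


def hypothesis_from_dict(doc: dict) -> Hypothesis:
    """Build a Hypothesis from a JSON document, applying schema defaults.

    Required per feature: ``type``, ``center``, ``radius``.  Optional with
    defaults: ``weight`` (1.0), ``direction`` (absent), ``provenance`` ({}).
    """
    if not isinstance(doc, dict):
        raise HypothesisSchemaError("hypothesis document must be a JSON object")
    feats_raw = _require(doc, "features", "hypothesis")
    if not isinstance(feats_raw, Sequence) or len(feats_raw) == 0:
        raise HypothesisSchemaError("field 'features' must be a non-empty list")
    feats = []
    for i, f in enumerate(feats_raw):
        where = f"features[{i}]"
        ftype = _require(f, "type", where)
        center = _require(f, "center", where)
        radius = _require(f, "radius", where)
        try:
            feats.append(
                PharmacophoreFeature(
                    type=ftype,
                    center=center,
                    radius=float(radius),
                    direction=f.get("direction"),
                    weight=float(f.get("weight", DEFAULT_WEIGHT)),
                    provenance=dict(f.get("provenance", {})),
                )
            )
        except (TypeError, ValueError) as exc:
            raise HypothesisSchemaError(f"invalid {where}: {exc}") from exc
    return Hypothesis(
        feats,
        name=str(doc.get("name", "hypothesis")),
        frame_of_reference=str(doc.get("frame_of_reference", "unknown")),
    )


def save_hypothesis(h: Hypothesis, path) -> None:
    with open(path, "w") as fh:
        json.dump(h.to_dict(), fh, indent=2)


def load_hypothesis(path) -> Hypothesis:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise HypothesisSchemaError(f"not valid JSON: {exc}") from exc
    return hypothesis_from_dict(doc)
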