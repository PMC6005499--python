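"""Drug-likeness filters: Lipinski's rule of five and QED.

QED (quantitative estimate of drug-likeness) is the geometric mean of
per-property desirability functions d_i:

    QED   = exp( (1/n) Σ ln d_i )
    QEDw  = exp( Σ w_i ln d_i / Σ w_i )

over seven properties (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM).  The
desirability functions are asymmetric double sigmoids; their fitted
parameters and the consensus weights are taken from RDKit's QED module,
which ships the original publication's parameter table.  The structural
alerts term of the original eight-property formulation is out of scope
here, so both means run over the seven physicochemical properties.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from rdkit.Chem import QED as _rdQED

from .chem import PropertyVector

#: property order used throughout
QED_PROPERTIES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM")

_EPS = 1e-6  # floor keeping ln d_i finite


def lipinski_pass(p: PropertyVector) -> bool:
    """Strict rule of five: MW<=500, ALOGP<=5, HBD<=5, HBA<=10 (all four)."""
    return (p.mw <= 500.0 and p.alogp <= 5.0 and p.hbd <= 5 and p.hba <= 10)


@dataclass
class QEDParams:
    """Desirability parameter tuples and weights for the seven properties."""

    ads_params: Dict[str, tuple]
    weights: Dict[str, float]

    def __post_init__(self):
        missing = [k for k in QED_PROPERTIES if k not in self.ads_params]
        if missing:
            raise ValueError(f"missing desirability parameters for {missing}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        if sum(self.weights.get(k, 0.0) for k in QED_PROPERTIES) <= 0:
            raise ValueError("weights must not all be zero")

    @classmethod
    def default(cls) -> "QEDParams":
        ads = {k: _rdQED.adsParameters[k] for k in QED_PROPERTIES}
        wmean = _rdQED.WEIGHT_MEAN._asdict()
        return cls(ads_params=ads,
                   weights={k: float(wmean[k]) for k in QED_PROPERTIES})

    @classmethod
    def unit_weights(cls) -> "QEDParams":
        p = cls.default()
        p.weights = {k: 1.0 for k in QED_PROPERTIES}
        return p

    def desirabilities(self, p: PropertyVector) -> Dict[str, float]:
        values = p.as_dict()
        return {k: max(float(_rdQED.ads(values[k], self.ads_params[k])), _EPS)
                for k in QED_PROPERTIES}


def qed(p: PropertyVector, params: QEDParams | None = None) -> Dict[str, float]:
    """Unweighted and weighted QED of a property vector, both in (0, 1]."""
    params = params or QEDParams.default()
    d = params.desirabilities(p)
    logs = np.array([np.log(d[k]) for k in QED_PROPERTIES])
    w = np.array([params.weights[k] for k in QED_PROPERTIES])
    return {
        "unweighted": float(np.exp(logs.mean())),
        "weighted": float(np.exp((w * logs).sum() / w.sum())),
    }
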