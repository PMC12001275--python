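"""Typical values, IIV structure and the map from (TV, eta) to individual parameters.

An individual PK parameter is

    theta_k,i = TV_k * exp(eta_k,i)   if k is in the IIV set K
    theta_k,i = TV_k                  otherwise,

which keeps every parameter strictly positive for any finite random effect
(log-normal IIV).  A subset L of the typical values is learned during
training; the complement stays fixed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from mmpk.odes import Theta5FU, ThetaSunitinib

#: 5FU typical values: clearance initialized from a published one-compartment
#: model; the volume of distribution is structurally non-identifiable from
#: steady-state samples and stays fixed at 46.1 L.
FU5_DEFAULTS = {"CL": 223.0, "V": 46.1}

#: Sunitinib typical values.  KA (0.13 1/h) and central volume (1820 L) follow
#: the published parent/metabolite model this structure derives from; the
#: remaining entries are implementer-chosen, physiologically plausible
#: defaults (QH = 80 L/h is standard hepatic blood flow) and are meant to be
#: overridden from config when better estimates exist.
SUNITINIB_DEFAULTS = {
    "KA": 0.13, "FM": 0.21, "CLS": 35.0, "QS": 7.0, "CLM": 17.0,
    "QM": 2.5, "QH": 80.0, "V2S": 1820.0, "V3S": 588.0, "V2M": 730.0,
    "V3M": 1230.0,
}

_THETA_FIELD = {
    "CL": "cl", "V": "v", "KA": "ka", "FM": "fm", "CLS": "cls", "QS": "qs",
    "CLM": "clm", "QM": "qm", "QH": "qh", "V2S": "v2s", "V3S": "v3s",
    "V2M": "v2m", "V3M": "v3m",
}


@dataclass
class RandomEffects:
    """Per-patient random effects eta_k, defined only for k in the IIV set."""
    eta: dict

    def __post_init__(self):
        for k, v in self.eta.items():
            if not math.isfinite(v):
                raise ValueError(f"eta[{k}] must be finite")


@dataclass
class PopulationParameterSet:
    drug_type: str
    tv: dict                      # name -> typical value, all > 0
    iiv: frozenset                # K: parameters carrying IIV
    learned: frozenset            # L: typical values learned during training
    prior_scale: float = 1.0      # lambda: SD of the N(0, lambda^2) prior on eta
    error_b: float = 0.2          # proportional residual-error coefficient

    def __post_init__(self):
        self.iiv = frozenset(self.iiv)
        self.learned = frozenset(self.learned)
        names = set(self.tv)
        if not self.iiv <= names:
            raise ValueError("IIV set must be a subset of the parameter names")
        if not self.learned <= names:
            raise ValueError("learned set must be a subset of the parameter names")
        for k, v in self.tv.items():
            if v <= 0:
                raise ValueError(f"TV[{k}] must be > 0")
        if self.prior_scale <= 0 or self.error_b <= 0:
            raise ValueError("prior_scale and error_b must be > 0")

    # -- serialization ------------------------------------------------------
    def to_dict(self):
        return {
            "drug_type": self.drug_type,
            "tv": dict(self.tv),
            "iiv": sorted(self.iiv),
            "learned": sorted(self.learned),
            "prior_scale": self.prior_scale,
            "error_b": self.error_b,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["drug_type"], dict(d["tv"]), frozenset(d["iiv"]),
                   frozenset(d["learned"]), d["prior_scale"], d["error_b"])

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def individual_params(pop, eta):
    """Eq.-style individual parameters: TV_k * exp(eta_k) inside K, TV_k outside."""
    if isinstance(eta, RandomEffects):
        eta = eta.eta
    extra = set(eta) - set(pop.iiv)
    if extra:
        raise ValueError(f"eta keys outside the IIV set: {sorted(extra)}")
    missing = set(pop.iiv) - set(eta)
    if missing:
        raise ValueError(f"eta must cover the IIV set; missing {sorted(missing)}")
    out = {}
    for k, tv in pop.tv.items():
        out[k] = tv * math.exp(eta[k]) if k in pop.iiv else tv
    return out


def theta_from_params(drug_type, params):
    """Build a structural-model parameter object from a named dict."""
    kw = {_THETA_FIELD[k]: v for k, v in params.items()}
    if drug_type == "fu5":
        return Theta5FU(**kw)
    if drug_type == "sunitinib":
        return ThetaSunitinib(**kw)
    raise ValueError(f"unknown drug_type {drug_type!r}")


def default_popset(drug_type):
    """Default population parameter set per drug.

    5FU: J = {CL, V}, IIV on CL only, V fixed (non-identifiable at steady
    state).  Sunitinib: IIV on {CLS, V2S, FM, V2M}; FM, V3S and QH typical
    values fixed, the rest learned.
    """
    if drug_type == "fu5":
        return PopulationParameterSet(
            "fu5", dict(FU5_DEFAULTS), frozenset({"CL"}), frozenset({"CL"}))
    if drug_type == "sunitinib":
        tv = dict(SUNITINIB_DEFAULTS)
        fixed = {"FM", "V3S", "QH"}
        return PopulationParameterSet(
            "sunitinib", tv, frozenset({"CLS", "V2S", "FM", "V2M"}),
            frozenset(set(tv) - fixed))
    raise ValueError(f"unknown drug_type {drug_type!r}")
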