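"""Published clinical risk calculators for pulmonary-nodule malignancy.

Two logistic-regression calculators estimate the clinical malignancy
probability p(y1|x1) from demographics and CT covariates, with no local
training:

* **mayo** (Swensen 1997): age, smoking history, prior extrathoracic cancer,
  nodule diameter, spiculation, upper-lobe location.
* **brock** (McWilliams 2013, full model with spiculation): age (centered at
  62), female sex, family history, emphysema, a -0.5 power transform of the
  nodule size in cm, nodule count (centered at 4), upper lobe, spiculation,
  and nodule-type indicators (part-solid, non-solid).

Coefficients are data, not code: src/fcfmtex/data/risk_coefficients.json,
with source citations. Missing covariates raise, naming the field — these
calculators are only valid on complete records, so no silent imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import expit

from .io import ClinicalRecord


@dataclass(frozen=True)
class RiskModelSpec:
    name: str
    source: str
    intercept: float
    terms: tuple  # of dicts {field, coef, transform}


def _load_specs() -> dict[str, RiskModelSpec]:
    with resources.files("fcfmtex.data").joinpath("risk_coefficients.json").open() as fh:
        raw = json.load(fh)
    specs = {}
    for name, d in raw.items():
        specs[name] = RiskModelSpec(
            name=name,
            source=d["source"],
            intercept=float(d["intercept"]),
            terms=tuple(d["terms"]),
        )
    return specs


_SPECS = _load_specs()


def get_spec(name: str) -> RiskModelSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise ValueError(f"unknown risk model {name!r}; available: {sorted(_SPECS)}")


def _transform(value, spec: dict) -> float:
    kind = spec["type"]
    if kind == "identity":
        return float(value)
    if kind == "center":
        return float(value) - spec["value"]
    if kind == "inverse_sqrt_cm_centered":
        # Brock size term: (diameter_cm)^-0.5, centered at its 4 mm reference
        return (float(value) / 10.0) ** -0.5 - spec["value"]
    if kind == "equals":
        return 1.0 if value == spec["value"] else 0.0
    raise ValueError(f"unknown transform {kind!r}")


def linear_predictor(record: ClinicalRecord, spec: RiskModelSpec) -> float:
    z = spec.intercept
    for term in spec.terms:
        field = term["field"]
        value = getattr(record, field, None)
        if value is None:
            raise ValueError(f"risk model {spec.name!r} requires field {field!r}")
        z += term["coef"] * _transform(value, term["transform"])
    return z


def risk_probability(record: ClinicalRecord, spec: RiskModelSpec | str) -> float:
    """Malignancy probability of one patient under one calculator (in (0, 1))."""
    if isinstance(spec, str):
        spec = get_spec(spec)
    return float(expit(linear_predictor(record, spec)))


def cohort_risk_probabilities(records: list[ClinicalRecord], name: str) -> np.ndarray:
    spec = get_spec(name)
    return np.array([risk_probability(r, spec) for r in records])
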