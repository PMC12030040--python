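"""System (subject-level) physiology and virtual-subject generation.

The reference subject is a 70-kg healthy adult with standard hepatic blood
flow, GFR, liver weight and MPPGL, packaged as a versioned data file.
Populations are sampled with log-normal between-subject variability on the
clearance-side multipliers and on Vss; enzyme phenotypes (e.g. a UGT1A1
poor-metabolizer population) are expressed as multiplicative activity
fractions.
"""
from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class PhysiologySystem(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    body_weight: float = Field(gt=0, description="kg")
    hepatic_blood_flow: float = Field(gt=0, description="L/h")
    gfr: float = Field(gt=0, description="L/h")
    liver_weight: float = Field(gt=0, description="g")
    mppgl: float = Field(gt=0, description="mg microsomal protein / g liver")
    hematocrit: float = Field(default=0.45, gt=0, lt=1)
    plasma_volume_fraction: float = Field(default=0.0436, gt=0, description="L/kg")
    enzyme_activity: dict[str, float] = Field(default_factory=dict)
    transporter_activity: dict[str, float] = Field(default_factory=dict)
    vss_multiplier: float = Field(default=1.0, gt=0)
    sex: str = "F"
    age: float = Field(default=35.0, gt=0)
    subject_id: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhysiologySystem":
        for m in (*self.enzyme_activity.values(), *self.transporter_activity.values()):
            if m < 0:
                raise ValueError("activity multipliers must be >= 0")
        return self

    def enzyme_multiplier(self, enzyme: str) -> float:
        return self.enzyme_activity.get(enzyme, 1.0)

    def transporter_multiplier(self, transporter: str) -> float:
        return self.transporter_activity.get(transporter, 1.0)


class Demographics(BaseModel):
    n_subjects: int = Field(gt=0)
    age_range: tuple[float, float] = (20.0, 50.0)
    proportion_female: float = Field(default=0.5, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "Demographics":
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        return self


class PhenotypeSpec(BaseModel):
    enzyme: str
    activity_fraction: float = Field(ge=0, le=1)
    population_label: str = ""


def _load_reference() -> dict:
    text = resources.files("pbpkddi.data").joinpath("reference_physiology.yaml").read_text()
    return yaml.safe_load(text)


def reference_subject() -> PhysiologySystem:
    """Deterministic healthy-volunteer default subject (packaged constants)."""
    ref = _load_reference()
    ref.pop("version", None)
    return PhysiologySystem.model_validate(ref)


# parameters that sample_population knows how to perturb
_SCALAR_PARAMS = ("body_weight", "gfr", "hepatic_blood_flow")
_MULTIPLIER_PARAMS = ("enzyme_activity", "transporter_activity", "vss")

DEFAULT_VARIABILITY = {"enzyme_activity": 30.0, "transporter_activity": 30.0, "vss": 30.0}


def _lognormal(rng: np.random.Generator, cv_pct: float, size=None):
    """Log-normal multiplier(s) with geometric median 1 and the given CV%."""
    if cv_pct == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + (cv_pct / 100.0) ** 2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def sample_population(
    demographics: Demographics,
    variability: Optional[dict[str, float]] = None,
    reference: Optional[PhysiologySystem] = None,
) -> list[PhysiologySystem]:
    """Sample ``n_subjects`` virtual subjects around the reference physiology.

    ``variability`` maps parameter names to CV% (log-normal, geometric
    median at the reference value).  Recognised keys: ``enzyme_activity``
    and ``transporter_activity`` (independent multiplier per pathway per
    subject), ``vss``, ``body_weight``, ``gfr``, ``hepatic_blood_flow``.
    Zero CV reproduces the reference exactly; the same seed reproduces the
    same population bit-for-bit.
    """
    if variability is None:
        variability = dict(DEFAULT_VARIABILITY)
    unknown = set(variability) - set(_SCALAR_PARAMS) - set(_MULTIPLIER_PARAMS)
    if unknown:
        raise KeyError(f"unknown variability parameters: {sorted(unknown)}")
    if any(cv < 0 for cv in variability.values()):
        raise ValueError("CVs must be >= 0")
    ref = reference if reference is not None else reference_subject()
    rng = np.random.default_rng(demographics.seed)
    subjects = []
    for i in range(demographics.n_subjects):
        fields = ref.model_dump()
        fields["subject_id"] = i
        fields["sex"] = "F" if rng.random() < demographics.proportion_female else "M"
        fields["age"] = rng.uniform(*demographics.age_range)
        for p in _SCALAR_PARAMS:
            if p in variability:
                fields[p] = ref.model_dump()[p] * _lognormal(rng, variability[p])
        if "vss" in variability:
            fields["vss_multiplier"] = ref.vss_multiplier * _lognormal(rng, variability["vss"])
        for p, attr in (("enzyme_activity", "enzyme_activity"),
                        ("transporter_activity", "transporter_activity")):
            if p in variability:
                base = getattr(ref, attr)
                fields[attr] = {
                    k: v * _lognormal(rng, variability[p]) for k, v in base.items()
                }
        subjects.append(PhysiologySystem.model_validate(fields))
    return subjects


def apply_phenotype(
    population: list[PhysiologySystem], spec: PhenotypeSpec
) -> list[PhysiologySystem]:
    """Scale one enzyme's activity multiplier in every subject.

    Multiplicative and composable: applying 0.5 twice equals 0.25 once.
    Raises ``KeyError`` if the enzyme is absent from a subject's map.
    """
    out = []
    for subj in population:
        if spec.enzyme not in subj.enzyme_activity:
            raise KeyError(f"enzyme {spec.enzyme!r} not in subject activity map")
        new = subj.model_copy(deep=True)
        new.enzyme_activity[spec.enzyme] *= spec.activity_fraction
        out.append(new)
    return out
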