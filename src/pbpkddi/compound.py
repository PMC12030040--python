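"""Drug-specific parameter sets ("compound files").

A :class:`CompoundModel` carries everything the simulation engine needs to
know about one drug: physicochemistry, absorption, distribution, elimination
and interaction (inhibition/induction) parameters.  Files are structured
YAML with a ``schema_version`` field; all quantities are normalised to the
internal convention (concentrations µM, volumes L, time h, clearances L/h)
at the I/O boundary.
"""
from __future__ import annotations

import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1

CompoundType = Literal["monoprotic-acid", "monoprotic-base", "neutral", "ampholyte"]


class AbsorptionParams(BaseModel):
    """Oral absorption: dissolution-limited (two-state gut) or first-order.

    In dissolution-limited mode the solid dose dissolves along a Weibull
    curve (``weibull_scale_h``, ``weibull_shape``) or a tabulated
    ``dissolution_curve`` of (time h, cumulative fraction dissolved);
    dissolved drug is absorbed first-order with rate ``ka`` (1/h).  If
    ``ka`` is omitted it is derived from apparent permeability as
    ``ka = ka_per_papp × Papp`` — a documented one-point high-permeability
    calibration.
    """

    model_config = ConfigDict(validate_assignment=True)

    model: Literal["dissolution-limited", "first-order"] = "dissolution-limited"
    weibull_scale_h: Optional[float] = Field(default=None, gt=0)
    weibull_shape: Optional[float] = Field(default=None, gt=0)
    dissolution_curve: Optional[list[tuple[float, float]]] = None
    ka: Optional[float] = Field(default=None, gt=0, description="1/h")
    ka_per_papp: float = Field(default=0.1, gt=0, description="1/h per 1e-6 cm/s")
    fa: float = Field(default=1.0, gt=0, le=1)
    fg: float = Field(default=1.0, gt=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "AbsorptionParams":
        if self.model == "first-order" and self.ka is None:
            raise ValueError("first-order absorption requires ka")
        if self.dissolution_curve is not None:
            times = [t for t, _ in self.dissolution_curve]
            fracs = [f for _, f in self.dissolution_curve]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError("dissolution times must be strictly increasing")
            if any(f2 < f1 for f1, f2 in zip(fracs, fracs[1:])):
                raise ValueError("dissolution fractions must be non-decreasing")
            if any(not 0 <= f <= 1 for f in fracs):
                raise ValueError("dissolution fractions must lie in [0, 1]")
        return self


class DistributionParams(BaseModel):
    """Minimal-PBPK distribution: Vss plus a single adjusting compartment.

    ``vss_mode='predicted'`` triggers the mechanistic tissue-composition
    prediction (scaled by ``kp_scalar``); ``'user'`` takes ``vss_user``
    (L/kg) verbatim.  The peripheral (SAC) compartment exchanges with the
    systemic one at first-order rates kin/kout.
    """

    model_config = ConfigDict(validate_assignment=True)

    vss_mode: Literal["predicted", "user"] = "predicted"
    vss_user: Optional[float] = Field(default=None, gt=0, description="L/kg")
    kp_scalar: float = Field(default=1.0, gt=0)
    sac_kin: float = Field(default=0.0, ge=0, description="1/h")
    sac_kout: float = Field(default=1.0, gt=0, description="1/h")

    @model_validator(mode="after")
    def _check(self) -> "DistributionParams":
        if self.vss_mode == "user" and self.vss_user is None:
            raise ValueError("vss_mode='user' requires vss_user")
        return self


class EnzymeClint(BaseModel):
    """One enzyme's in vitro intrinsic clearance (µL/min/mg protein)."""

    model_config = ConfigDict(validate_assignment=True)

    clint: float = Field(ge=0, description="µL/min/mg microsomal protein")
    fu_mic: float = Field(default=1.0, gt=0, le=1)
    isef: float = Field(default=1.0, gt=0)


class RenalParams(BaseModel):
    """Renal clearance, either direct (L/h, plasma) or decomposed from fe.

    In ``fe_decomposed`` mode the total renal plasma clearance is recovered
    from the fraction excreted unchanged (fe, relative to total plasma
    clearance) and split into glomerular filtration (fu,p × GFR) plus active
    tubular secretion distributed across transporters by
    ``transporter_secretion_fractions``; ``freab`` scales the net by
    (1 − freab).
    """

    model_config = ConfigDict(validate_assignment=True)

    mode: Literal["direct_clr", "fe_decomposed"] = "direct_clr"
    clr_direct: float = Field(default=0.0, ge=0, description="L/h plasma")
    fe_total: float = Field(default=0.0, ge=0, le=1)
    transporter_secretion_fractions: dict[str, float] = Field(default_factory=dict)
    freab: float = Field(default=0.0, ge=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "RenalParams":
        total = sum(self.transporter_secretion_fractions.values())
        if any(f < 0 for f in self.transporter_secretion_fractions.values()):
            raise ValueError("secretion fractions must be non-negative")
        if total > 1 + 1e-9:
            raise ValueError(f"secretion fractions sum to {total} > 1")
        return self


class InductionTerm(BaseModel):
    ind_max: float = Field(ge=0, description="max fold-increase minus 1")
    ind_c50: float = Field(gt=0, description="µM unbound")


class EliminationParams(BaseModel):
    enzyme_clints: dict[str, EnzymeClint] = Field(default_factory=dict)
    renal: RenalParams = Field(default_factory=RenalParams)


class InteractionParams(BaseModel):
    """Perpetrator parameters: competitive Ki (µM, unbound) per target and
    steady-state induction terms per enzyme."""

    inhibition: dict[str, float] = Field(default_factory=dict)
    induction: dict[str, InductionTerm] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "InteractionParams":
        if any(k <= 0 for k in self.inhibition.values()):
            raise ValueError("Ki values must be positive")
        return self

    def is_empty(self) -> bool:
        return not self.inhibition and not self.induction


class CompoundModel(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    name: str
    molecular_weight: float = Field(gt=0, description="g/mol")
    logp: float
    compound_type: CompoundType = "neutral"
    pka1: Optional[float] = None
    blood_plasma_ratio: float = Field(default=1.0, gt=0)
    fu_plasma: float = Field(gt=0, le=1)
    papp: float = Field(default=0.0, ge=0, description="1e-6 cm/s")
    absorption: AbsorptionParams = Field(default_factory=AbsorptionParams)
    distribution: DistributionParams = Field(default_factory=DistributionParams)
    elimination: EliminationParams = Field(default_factory=EliminationParams)
    interaction: InteractionParams = Field(default_factory=InteractionParams)

    @model_validator(mode="after")
    def _check(self) -> "CompoundModel":
        if self.compound_type in ("monoprotic-acid", "monoprotic-base") and self.pka1 is None:
            raise ValueError(f"compound_type={self.compound_type} requires pka1")
        return self

    @property
    def fu_blood(self) -> float:
        """Unbound fraction in blood: fu,p / (B/P)."""
        return self.fu_plasma / self.blood_plasma_ratio

    def absorption_rate_constant(self) -> float:
        """ka in 1/h, explicit or derived from Papp."""
        if self.absorption.ka is not None:
            return self.absorption.ka
        if self.papp <= 0:
            raise ValueError(f"{self.name}: no ka and no Papp to derive it from")
        return self.absorption.ka_per_papp * self.papp


def _clean(obj):
    """Drop empty/None entries recursively so files stay minimal and diffable."""
    if isinstance(obj, dict):
        out = {}
        for k, v in obj.items():
            v = _clean(v)
            if v is None or v == {} or v == []:
                continue
            out[k] = v
        return out
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_compound(model: CompoundModel, path) -> str:
    """Serialise a compound model to structured YAML text.

    Field order follows the model declaration, so files diff cleanly; an
    empty interaction block is omitted.
    """
    doc = {"schema_version": SCHEMA_VERSION}
    dump = model.model_dump(mode="json")
    if model.interaction.is_empty():
        dump.pop("interaction", None)
    doc.update(_clean(dump))
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)


def load_compound(path) -> CompoundModel:
    """Load and validate a compound file (YAML, ``schema_version`` 1)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: not a mapping")
    version = doc.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {version!r}")
    return CompoundModel.model_validate(doc)


def convert_concentration(mass_conc: float, molecular_weight: float) -> float:
    """µg/mL → µM.

    >>> round(convert_concentration(8.0, 405.4), 2)
    19.73
    """
    if mass_conc <= 0 or molecular_weight <= 0:
        raise ValueError("inputs must be positive")
    return mass_conc / molecular_weight * 1000.0


def um_to_ug_ml(conc_um: float, molecular_weight: float) -> float:
    """µM → µg/mL (inverse of :func:`convert_concentration`)."""
    if conc_um <= 0 or molecular_weight <= 0:
        raise ValueError("inputs must be positive")
    return conc_um * molecular_weight / 1000.0
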