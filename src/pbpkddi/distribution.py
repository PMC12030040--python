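"""Mechanistic steady-state volume of distribution and SAC partitioning.

Tissue:plasma partition coefficients (Kp) are predicted by tissue-composition
equations of the Rodgers–Rowland type: Henderson–Hasselbalch ionisation at
plasma and intracellular pH, neutral-lipid/phospholipid partitioning from
logP, and albumin-type protein binding inferred from fu,p.  Vss is the
plasma volume plus the Kp-weighted tissue volumes; a global Kp scalar
(applied to the tissue terms only) allows a middle-out fit to observed
distribution.  The minimal-PBPK peripheral compartment (SAC) takes the share
v_sac/v_systemic = kin/kout of Vss.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml
from pydantic import BaseModel, Field

from .compound import CompoundModel


class TissueEntry(BaseModel):
    f_ew: float = Field(ge=0, le=1)   # extracellular water
    f_iw: float = Field(ge=0, le=1)   # intracellular water
    f_nl: float = Field(ge=0, le=1)   # neutral lipid
    f_np: float = Field(ge=0, le=1)   # neutral phospholipid
    ra: float = Field(ge=0)           # tissue:plasma albumin ratio
    v: float = Field(gt=0)            # tissue volume, L/kg body weight


class TissueCompositionTable(BaseModel):
    version: int = 1
    ph_plasma: float = 7.4
    ph_intracellular: float = 7.0
    plasma_f_nl: float = 0.0023
    plasma_f_np: float = 0.0013
    albumin_accessibility: float = Field(default=1.0, gt=0)
    tissues: dict[str, TissueEntry]


def load_tissue_table() -> TissueCompositionTable:
    """Packaged, versioned tissue-composition constants."""
    text = resources.files("pbpkddi.data").joinpath("tissue_composition.yaml").read_text()
    return TissueCompositionTable.model_validate(yaml.safe_load(text))


@dataclass(frozen=True)
class DistributionResult:
    kp: dict[str, float]       # per tissue, scaled
    vss: float                 # L/kg
    v_systemic: float          # L/kg
    v_sac: float               # L/kg
    plasma_volume: float       # L/kg


def _ionisation(compound_type: str, pka: float | None, ph: float) -> float:
    """1 + ionised:neutral ratio at the given pH (Henderson–Hasselbalch)."""
    if compound_type == "neutral" or pka is None:
        return 1.0
    if compound_type == "monoprotic-acid":
        return 1.0 + 10.0 ** (ph - pka)
    if compound_type == "monoprotic-base":
        return 1.0 + 10.0 ** (pka - ph)
    raise NotImplementedError(f"compound_type {compound_type!r} not supported")


def predict_vss(
    compound: CompoundModel,
    tissues: TissueCompositionTable | None = None,
    kp_scalar: float | None = None,
    plasma_volume_fraction: float = 0.0436,
) -> DistributionResult:
    """Predict Vss (L/kg) from tissue composition for a monoprotic acid,
    neutral, or weak monoprotic base.

    Strong bases (pKa ≥ 7, acidic-phospholipid association mechanism) are
    not implemented.  The Kp scalar multiplies tissue terms only; the plasma
    volume term is fixed.  Drug in blood cells is neglected when the
    blood:plasma ratio is below 1 − hematocrit (plasma-restricted drug).
    """
    if compound.compound_type == "ampholyte":
        raise NotImplementedError("ampholyte Kp prediction not supported")
    if compound.compound_type == "monoprotic-base" and (compound.pka1 or 0) >= 7.0:
        raise NotImplementedError(
            "strong monoprotic bases need the acidic-phospholipid method"
        )
    table = tissues if tissues is not None else load_tissue_table()
    scalar = kp_scalar if kp_scalar is not None else compound.distribution.kp_scalar

    p = 10.0 ** compound.logp
    p_vow = 10.0 ** (1.115 * compound.logp - 1.35)  # vegetable oil:water, adipose
    x_p = _ionisation(compound.compound_type, compound.pka1, table.ph_plasma)
    x_iw = _ionisation(compound.compound_type, compound.pka1, table.ph_intracellular)
    plasma_lipid = (p * table.plasma_f_nl + (0.3 * p + 0.7) * table.plasma_f_np) / x_p
    # albumin (acids/neutrals) or lipoprotein (weak bases) association
    ka_pr = max(1.0 / compound.fu_plasma - 1.0 - plasma_lipid, 0.0)

    kp = {}
    vss = plasma_volume_fraction
    for name, t in table.tissues.items():
        p_use = p_vow if name == "adipose" else p
        kpu = (
            t.f_ew
            + (x_iw / x_p) * t.f_iw
            + (p_use * t.f_nl + (0.3 * p_use + 0.7) * t.f_np) / x_p
            + ka_pr * table.albumin_accessibility * t.ra
        )
        kp[name] = kpu * compound.fu_plasma * scalar
        vss += kp[name] * t.v

    v_sys, v_sac = partition_sac(
        vss, compound.distribution.sac_kin, compound.distribution.sac_kout
    )
    return DistributionResult(
        kp=kp, vss=vss, v_systemic=v_sys, v_sac=v_sac,
        plasma_volume=plasma_volume_fraction,
    )


def partition_sac(vss: float, kin: float, kout: float) -> tuple[float, float]:
    """Split Vss between the systemic and SAC compartments.

    At distributional steady state the amount ratio SAC:systemic is
    kin/kout, so v_systemic = Vss/(1 + kin/kout); kin = 0 collapses the SAC.
    """
    if vss <= 0 or kout <= 0 or kin < 0:
        raise ValueError("vss and kout must be positive, kin >= 0")
    v_sys = vss / (1.0 + kin / kout)
    return v_sys, vss - v_sys


def systemic_volume_l(compound: CompoundModel, system) -> float:
    """Systemic compartment volume (L) for one subject.

    Uses the mechanistic prediction or the user Vss, scaled by the
    subject's Vss variability multiplier and body weight.
    """
    dist = compound.distribution
    if dist.vss_mode == "user":
        vss = dist.vss_user
    else:
        vss = predict_vss(
            compound, plasma_volume_fraction=system.plasma_volume_fraction
        ).vss
    vss = vss * system.vss_multiplier
    v_sys, _ = partition_sac(vss, dist.sac_kin, dist.sac_kout)
    return v_sys * system.body_weight
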