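"""IVIVE clearance scaling, well-stirred liver model and pathway fractions.

In vitro intrinsic clearances (µL/min/mg microsomal protein) are scaled to
whole-liver unbound intrinsic clearance with MPPGL, liver weight and an
inter-system extrapolation factor (ISEF), converted to hepatic blood
clearance by the well-stirred model, and combined with the renal
decomposition (filtration + transporter-mediated secretion) into a total
plasma clearance with per-pathway fractions fm / fe.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .compound import CompoundModel
from .physiology import PhysiologySystem

UL_MIN_TO_L_H = 60e-6  # µL/min → L/h


def scale_hepatic_clint(
    compound: CompoundModel, system: PhysiologySystem
) -> dict[str, float]:
    """Per-enzyme whole-liver unbound intrinsic clearance, L/h.

    CLint,u = (CLint / fu,mic) × ISEF × enzyme activity × MPPGL × liver weight.
    """
    out = {}
    for enzyme, ec in compound.elimination.enzyme_clints.items():
        activity = system.enzyme_multiplier(enzyme)
        out[enzyme] = (
            ec.clint / ec.fu_mic * ec.isef * activity
            * system.mppgl * system.liver_weight * UL_MIN_TO_L_H
        )
    return out


@dataclass(frozen=True)
class WellStirredResult:
    cl_blood: float  # L/h
    eh: float        # hepatic extraction ratio
    fh: float        # fraction escaping hepatic first pass


def well_stirred_hepatic_cl(qh: float, fu_blood: float, clint_u: float) -> WellStirredResult:
    """Well-stirred liver model: CLh = Qh·fu,b·CLint,u / (Qh + fu,b·CLint,u).

    Output is blood clearance, bounded above by hepatic blood flow.
    """
    if qh <= 0 or fu_blood <= 0 or clint_u < 0:
        raise ValueError("qh and fu_blood must be positive, clint_u >= 0")
    x = fu_blood * clint_u
    cl_blood = qh * x / (qh + x)
    eh = cl_blood / qh
    return WellStirredResult(cl_blood=cl_blood, eh=eh, fh=1.0 - eh)


@dataclass(frozen=True)
class RenalClearance:
    """Renal plasma clearance decomposition (all L/h)."""

    cl_total: float
    filtration: float
    secretion: dict[str, float] = field(default_factory=dict)  # per transporter
    freab: float = 0.0

    def with_secretion_factors(self, factors: dict[str, float]) -> "RenalClearance":
        """Recompute total CLr with per-transporter multipliers (inhibition)."""
        sec = {t: cl * factors.get(t, 1.0) for t, cl in self.secretion.items()}
        total = (self.filtration + sum(sec.values())) * (1.0 - self.freab)
        return RenalClearance(total, self.filtration, sec, self.freab)


def assemble_renal_cl(
    compound: CompoundModel,
    system: PhysiologySystem,
    hepatic_cl_plasma: float | None = None,
) -> RenalClearance:
    """Renal plasma clearance, direct or decomposed from fe.

    ``fe_decomposed`` recovers total CLr from the fraction excreted unchanged
    (fe against total plasma clearance): CLr = fe/(1−fe)·CLh,p, then splits
    off filtration (fu,p·GFR, scaled by 1−freab) and distributes the
    secretory remainder across transporters, scaled by their activity
    multipliers.
    """
    renal = compound.elimination.renal
    if renal.mode == "direct_clr":
        return RenalClearance(cl_total=renal.clr_direct, filtration=renal.clr_direct)
    if hepatic_cl_plasma is None:
        raise ValueError("fe_decomposed mode needs the hepatic plasma clearance")
    fe = renal.fe_total
    if fe >= 1:
        raise ValueError("fe_total must be < 1 in fe_decomposed mode")
    cl_total = hepatic_cl_plasma * fe / (1.0 - fe)
    filtration = compound.fu_plasma * system.gfr
    gross = cl_total / (1.0 - renal.freab)
    secretion_total = gross - filtration
    fracs = renal.transporter_secretion_fractions
    if fracs and secretion_total <= 0:
        raise ValueError(
            f"{compound.name}: secretion fractions given but derived secretory "
            f"clearance is {secretion_total:.3g} L/h (fe too small vs filtration)"
        )
    secretion_total = max(secretion_total, 0.0)
    secretion = {
        t: secretion_total * f * system.transporter_multiplier(t)
        for t, f in fracs.items()
    }
    unassigned = secretion_total * (1.0 - sum(fracs.values()))
    if unassigned > 1e-12:
        secretion["renal_unassigned"] = secretion.get("renal_unassigned", 0.0) + unassigned
    cl_total = (filtration + sum(secretion.values())) * (1.0 - renal.freab)
    return RenalClearance(cl_total, filtration, secretion, renal.freab)


@dataclass(frozen=True)
class ClearanceModel:
    """Assembled clearance for one compound on one subject."""

    clint_u: dict[str, float]            # per enzyme, L/h unbound
    hepatic_cl_blood: float              # L/h
    hepatic_cl_plasma: float             # L/h
    hepatic_extraction: float
    fh_firstpass: float
    renal: RenalClearance
    enzyme_cl_plasma: dict[str, float]   # per-enzyme plasma CL share, L/h

    @property
    def total_cl_plasma(self) -> float:
        return self.hepatic_cl_plasma + self.renal.cl_total

    @property
    def fm(self) -> dict[str, float]:
        total = self.total_cl_plasma
        return {e: cl / total for e, cl in self.enzyme_cl_plasma.items()}

    @property
    def fe(self) -> float:
        return self.renal.cl_total / self.total_cl_plasma


def build_clearance_model(
    compound: CompoundModel, system: PhysiologySystem
) -> ClearanceModel:
    """Scale, combine and decompose all clearance pathways for one subject."""
    clint_u = scale_hepatic_clint(compound, system)
    clint_total = sum(clint_u.values())
    if clint_total > 0:
        ws = well_stirred_hepatic_cl(system.hepatic_blood_flow, compound.fu_blood, clint_total)
        cl_blood, eh, fh = ws.cl_blood, ws.eh, ws.fh
    else:
        cl_blood, eh, fh = 0.0, 0.0, 1.0
    cl_plasma = cl_blood * compound.blood_plasma_ratio
    renal = assemble_renal_cl(compound, system, hepatic_cl_plasma=cl_plasma)
    enzyme_cl = {
        e: cl_plasma * (ci / clint_total) if clint_total > 0 else 0.0
        for e, ci in clint_u.items()
    }
    return ClearanceModel(
        clint_u=clint_u,
        hepatic_cl_blood=cl_blood,
        hepatic_cl_plasma=cl_plasma,
        hepatic_extraction=eh,
        fh_firstpass=fh,
        renal=renal,
        enzyme_cl_plasma=enzyme_cl,
    )


def compute_pathway_fractions(clearance: ClearanceModel) -> dict[str, float]:
    """Share of total plasma clearance per pathway; sums to 1.

    Hepatic enzymes appear under their ids, renal excretion under "renal".
    """
    total = clearance.total_cl_plasma
    if total <= 0:
        raise ValueError("total clearance must be positive")
    fractions = {e: cl / total for e, cl in clearance.enzyme_cl_plasma.items()}
    fractions["renal"] = clearance.renal.cl_total / total
    return fractions
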