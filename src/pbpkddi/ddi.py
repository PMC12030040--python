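"""Dynamic and mechanistic-static drug–drug interactions.

A perpetrator's unbound exposure scales the victim's pathway clearances:
hepatic enzymes are driven by the unbound hepatic-inlet concentration
(systemic plus absorption-rate term), renal basolateral transporters by the
unbound systemic plasma concentration.  Competitive inhibition contributes
1/(1 + I/Ki) per pathway; induction contributes a steady-state multiplier
1 + Indmax·I/(IndC50 + I).  The mechanistic static counterpart is
AUCR = 1/Σ f_p·δ_p over pathway fractions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clearance import build_clearance_model
from .compound import CompoundModel
from .engine import (ConcentrationTimeProfile, DosingRegimen, Modifiers,
                     compute_pk_metrics, simulate)
from .physiology import PhysiologySystem


def competitive_inhibition_factor(i_unbound: float, ki: float) -> float:
    """Multiplier on intrinsic clearance: 1/(1 + I_u/Ki)."""
    if ki <= 0:
        raise ValueError("ki must be positive")
    if np.any(np.asarray(i_unbound) < 0):
        raise ValueError("inhibitor concentration must be >= 0")
    return 1.0 / (1.0 + i_unbound / ki)


def induction_factor(i_unbound: float, ind_max: float, ind_c50: float) -> float:
    """Steady-state induction multiplier: 1 + Indmax·I/(IndC50 + I) ≥ 1."""
    if ind_max < 0 or ind_c50 <= 0:
        raise ValueError("ind_max must be >= 0 and ind_c50 > 0")
    return 1.0 + ind_max * i_unbound / (ind_c50 + i_unbound)


def static_auc_ratio(
    pathway_fractions: dict[str, float],
    pathway_multipliers: dict[str, float],
) -> float:
    """Mechanistic static AUC ratio: 1 / Σ f_p·δ_p.

    ``pathway_multipliers`` gives each pathway's net clearance multiplier
    (inhibition × induction); unaffected pathways default to 1.
    """
    total = sum(pathway_fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"pathway fractions sum to {total}, expected 1")
    denom = sum(f * pathway_multipliers.get(p, 1.0)
                for p, f in pathway_fractions.items())
    return 1.0 / denom


def margin_report(baseline_exposure: float, ddi_exposure: float,
                  reference_cap: float) -> float:
    """Fold-distance of the post-DDI exposure to a reference exposure cap.

    Returns cap/ddi_exposure; 1.0 means the DDI consumes the whole margin.
    """
    if min(baseline_exposure, ddi_exposure, reference_cap) <= 0:
        raise ValueError("exposures and cap must be positive")
    return reference_cap / ddi_exposure


@dataclass(frozen=True)
class DDIRatios:
    """With/without-perpetrator ratios for one subject (paired design)."""

    auc_ratio: float
    cmax_ratio: float
    c24_ratio: float
    cl_ratio: float
    half_life_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {"auc_ratio": self.auc_ratio, "cmax_ratio": self.cmax_ratio,
                "c24_ratio": self.c24_ratio, "cl_ratio": self.cl_ratio,
                "half_life_ratio": self.half_life_ratio}


def victim_targets(victim: CompoundModel, system: PhysiologySystem) -> dict[str, str]:
    """Map of the victim's attackable pathways: id → 'enzyme' or 'transporter'."""
    targets = {e: "enzyme" for e in victim.elimination.enzyme_clints}
    renal = victim.elimination.renal
    if renal.mode == "fe_decomposed":
        for tr in renal.transporter_secretion_fractions:
            targets[tr] = "transporter"
    return targets


def build_victim_modifiers(
    victim: CompoundModel,
    perpetrator: CompoundModel,
    system: PhysiologySystem,
    perp_profile: ConcentrationTimeProfile,
) -> Modifiers:
    """Time-varying pathway multipliers on the victim from a simulated
    perpetrator profile.

    Induction is applied as a constant steady-state multiplier driven by the
    average unbound systemic concentration over the perpetrator's last
    dosing interval.
    """
    targets = victim_targets(victim, system)
    interaction = perpetrator.interaction
    shared = (set(interaction.inhibition) | set(interaction.induction)) & set(targets)
    if not shared:
        warnings.warn(
            f"{perpetrator.name} has no targets among {victim.name}'s pathways; "
            "all ratios will be 1.0", stacklevel=2,
        )
        return {}

    t = perp_profile.time
    i_sys = perp_profile.unbound_systemic_um()
    i_inlet = perp_profile.unbound_inlet_um()
    last = perp_profile.regimen.last_dose_time
    tau_mask = (t >= last) & (t <= last + perp_profile.regimen.interval)
    i_avg = float(np.trapezoid(i_sys[tau_mask], t[tau_mask])
                  / (t[tau_mask][-1] - t[tau_mask][0])) if tau_mask.sum() > 1 else float(i_sys[-1])

    modifiers: Modifiers = {}
    for target in sorted(shared):
        kind = targets[target]
        ki = interaction.inhibition.get(target)
        ind = interaction.induction.get(target)
        ind_mult = induction_factor(i_avg, ind.ind_max, ind.ind_c50) if ind else 1.0
        driver = i_inlet if kind == "enzyme" else i_sys

        def modifier(time, _ki=ki, _ind=ind_mult, _t=t, _i=driver) -> float:
            i_u = float(np.interp(time, _t, _i))
            inh = competitive_inhibition_factor(i_u, _ki) if _ki else 1.0
            return inh * _ind

        modifiers[target] = modifier
    return modifiers


def simulate_subject_pair(
    victim: CompoundModel,
    perpetrator: CompoundModel,
    system: PhysiologySystem,
    victim_regimen: DosingRegimen,
    perp_regimen: DosingRegimen,
    t_end: Optional[float] = None,
    grid_dt: float = 0.1,
    washout: float = 240.0,
) -> tuple[ConcentrationTimeProfile, ConcentrationTimeProfile, DDIRatios]:
    """Victim with and without perpetrator on one subject (paired arms).

    The perpetrator is simulated first; its unbound exposure drives the
    victim's pathway modifiers (one-way coupling).  Both victim arms share
    the subject, the regimen and the time grid.
    """
    if t_end is None:
        t_end = victim_regimen.last_dose_time + washout
    perp_profile = simulate(perpetrator, system, perp_regimen,
                            t_end=t_end, grid_dt=grid_dt)
    modifiers = build_victim_modifiers(victim, perpetrator, system, perp_profile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # modifier warning already raised above
        base = simulate(victim, system, victim_regimen, t_end=t_end, grid_dt=grid_dt)
        ddi = simulate(victim, system, victim_regimen, modifiers=modifiers,
                       t_end=t_end, grid_dt=grid_dt)
    m0 = compute_pk_metrics(base)
    m1 = compute_pk_metrics(ddi)
    ratios = DDIRatios(
        auc_ratio=m1.auc_0_inf / m0.auc_0_inf,
        cmax_ratio=m1.cmax / m0.cmax,
        c24_ratio=m1.c24 / m0.c24 if m0.c24 > 0 else float("nan"),
        cl_ratio=m1.cl_over_f / m0.cl_over_f,
        half_life_ratio=m1.t_half / m0.t_half,
    )
    return base, ddi, ratios


def static_ratio_for_pair(
    victim: CompoundModel,
    perpetrator: CompoundModel,
    system: PhysiologySystem,
    i_unbound_um: float,
    i_inlet_um: Optional[float] = None,
) -> float:
    """Mechanistic static AUCR at fixed perpetrator unbound exposure.

    ``i_unbound_um`` drives renal transporters; ``i_inlet_um`` (defaulting
    to the systemic value) drives hepatic enzymes.
    """
    if i_inlet_um is None:
        i_inlet_um = i_unbound_um
    cl = build_clearance_model(victim, system)
    fractions = {e: f for e, f in cl.fm.items()}
    renal_total = cl.renal.cl_total
    multipliers: dict[str, float] = {}
    interaction = perpetrator.interaction
    for e in fractions:
        delta = 1.0
        if e in interaction.inhibition:
            delta *= competitive_inhibition_factor(i_inlet_um, interaction.inhibition[e])
        if e in interaction.induction:
            ind = interaction.induction[e]
            delta *= induction_factor(i_unbound_um, ind.ind_max, ind.ind_c50)
        multipliers[e] = delta
    # split renal into filtration + per-transporter secretion sub-pathways
    if renal_total > 0:
        scale = cl.fe / renal_total * (1.0 - cl.renal.freab)
        fractions["renal_filtration"] = cl.renal.filtration * scale
        for tr, sec in cl.renal.secretion.items():
            key = f"renal_{tr}"
            fractions[key] = sec * scale
            if tr in interaction.inhibition:
                multipliers[key] = competitive_inhibition_factor(
                    i_unbound_um, interaction.inhibition[tr])
    total = sum(fractions.values())
    fractions = {k: v / total for k, v in fractions.items()}  # absorb rounding
    return static_auc_ratio(fractions, multipliers)


def simulate_ddi(victim: CompoundModel, perpetrator: CompoundModel, design):
    """Population DDI trial per a :class:`~pbpkddi.trials.TrialDesign`.

    Thin delegate to :func:`pbpkddi.trials.run_trial_set`.
    """
    from .trials import run_trial_set

    return run_trial_set(design, victim, perpetrator)
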