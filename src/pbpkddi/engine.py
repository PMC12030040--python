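"""Minimal-PBPK simulation engine.

Compartments: gut solid → gut dissolved (Weibull or tabulated dissolution)
→ portal absorption (first-order ka) → hepatic first pass (well-stirred Fh)
→ systemic ↔ single adjusting compartment (kin/kout), with elimination from
the systemic compartment via hepatic enzymatic clearance and renal
clearance.  All amounts are tracked in mg, concentrations output in µg/mL
and µM; cumulative elimination is booked per pathway so mass balance holds
to solver tolerance at every output point.

Time-varying pathway modifiers (from the DDI engine) scale per-pathway
intrinsic (enzymes) or secretory (renal transporters) clearance as functions
of time; the well-stirred model and first-pass extraction are re-evaluated
inside the ODE right-hand side, so inhibition changes Fh as well as CLh.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .clearance import scale_hepatic_clint, assemble_renal_cl, well_stirred_hepatic_cl
from .compound import CompoundModel
from .distribution import systemic_volume_l
from .physiology import PhysiologySystem

Modifiers = dict[str, Callable[[float], float]]


class DosingRegimen(BaseModel):
    route: str = "oral"
    dose: float = Field(gt=0, description="mg")
    interval: float = Field(default=24.0, description="h")
    n_doses: int = Field(default=1, gt=0)
    start_time: float = Field(default=0.0, ge=0, description="h")

    @model_validator(mode="after")
    def _check(self) -> "DosingRegimen":
        if self.route != "oral":
            raise ValueError("only oral dosing is supported")
        if self.n_doses > 1 and self.interval <= 0:
            raise ValueError("interval must be > 0 for multiple doses")
        return self

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_time + self.interval * np.arange(self.n_doses)

    @property
    def last_dose_time(self) -> float:
        return float(self.dose_times[-1])


@dataclass
class ConcentrationTimeProfile:
    """Simulation output for one compound on one subject."""

    time: np.ndarray                    # h, strictly increasing
    conc: np.ndarray                    # plasma, µg/mL
    amounts: dict[str, np.ndarray]      # mg per compartment
    eliminated: dict[str, np.ndarray]   # cumulative mg per pathway
    administered: np.ndarray            # cumulative dose given, mg
    absorption_flux: np.ndarray         # fa·fg·ka·A_dissolved, mg/h
    compound: CompoundModel
    system: PhysiologySystem
    regimen: DosingRegimen
    v_systemic_l: float
    extras: dict = field(default_factory=dict)

    @property
    def conc_um(self) -> np.ndarray:
        return self.conc / self.compound.molecular_weight * 1000.0

    def mass_balance_error(self) -> float:
        """Max relative |administered − (remaining + eliminated)|."""
        total = sum(self.amounts.values()) + sum(self.eliminated.values())
        scale = max(self.administered.max(), 1e-12)
        return float(np.max(np.abs(total - self.administered)) / scale)

    def conc_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.conc)

    def unbound_systemic_um(self) -> np.ndarray:
        """Unbound plasma concentration, µM (drives renal transporter DDIs)."""
        return self.conc_um * self.compound.fu_plasma

    def unbound_inlet_um(self) -> np.ndarray:
        """Unbound hepatic-inlet concentration, µM (drives enzyme DDIs).

        Systemic unbound plus the absorption-rate term fu,b·(flux/Qh).
        """
        inlet_mg_l = (
            self.conc * self.compound.fu_plasma
            + self.compound.fu_blood * self.absorption_flux / self.system.hepatic_blood_flow
        )
        return inlet_mg_l / self.compound.molecular_weight * 1000.0

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"time_h": self.time, "conc_ug_ml": self.conc,
                           "conc_um": self.conc_um})
        for k, v in self.amounts.items():
            df[f"amount_{k}_mg"] = v
        for k, v in self.eliminated.items():
            df[f"eliminated_{k}_mg"] = v
        return df


def _dissolution_hazard(compound: CompoundModel) -> Callable[[float], float]:
    """First-order dissolution hazard as a function of time since last dose."""
    absorption = compound.absorption
    if absorption.dissolution_curve is not None:
        pts = np.asarray(absorption.dissolution_curve, dtype=float)
        t_tab, f_tab = pts[:, 0], pts[:, 1]
        if t_tab[0] > 0:
            t_tab = np.insert(t_tab, 0, 0.0)
            f_tab = np.insert(f_tab, 0, 0.0)
        interp = PchipInterpolator(t_tab, np.clip(f_tab, 0.0, 1.0))
        deriv = interp.derivative()
        t_max = t_tab[-1]

        def hazard(dt: float) -> float:
            if dt >= t_max:
                return 50.0  # beyond the measured curve: dissolve promptly
            f = float(interp(dt))
            return max(float(deriv(dt)), 0.0) / max(1.0 - f, 0.02)

        return hazard
    scale = absorption.weibull_scale_h
    shape = absorption.weibull_shape if absorption.weibull_shape is not None else 1.0
    if scale is None:
        raise ValueError(f"{compound.name}: dissolution-limited absorption "
                         "needs a Weibull scale or a tabulated curve")
    if shape == 1.0:
        k = 1.0 / scale
        return lambda dt: k
    return lambda dt: (shape / scale) * (max(dt, 1e-9) / scale) ** (shape - 1.0)


def simulate(
    compound: CompoundModel,
    system: PhysiologySystem,
    regimen: DosingRegimen,
    modifiers: Optional[Modifiers] = None,
    t_end: Optional[float] = None,
    grid_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationTimeProfile:
    """Integrate the minimal-PBPK system for an oral dosing regimen.

    ``modifiers`` maps pathway ids (hepatic enzyme or renal transporter) to
    functions of absolute time returning a multiplier on that pathway's
    intrinsic/secretory clearance.  Doses are injected by integration
    restarts at dose times (no impulse smoothing).
    """
    modifiers = modifiers or {}
    clint_base = scale_hepatic_clint(compound, system)
    enzymes = list(clint_base.keys())
    renal_base = assemble_renal_cl(
        compound, system,
        hepatic_cl_plasma=_nominal_hepatic_cl_plasma(compound, system, clint_base),
    )
    transporters = list(renal_base.secretion.keys())
    unknown = set(modifiers) - set(enzymes) - set(transporters)
    if unknown:
        raise KeyError(f"modifiers target unknown pathways: {sorted(unknown)}")

    v_sys = systemic_volume_l(compound, system)
    kin = compound.distribution.sac_kin
    kout = compound.distribution.sac_kout
    fa, fg = compound.absorption.fa, compound.absorption.fg
    ka = compound.absorption_rate_constant()
    fu_b = compound.fu_blood
    bp = compound.blood_plasma_ratio
    qh = system.hepatic_blood_flow
    first_order = compound.absorption.model == "first-order"
    hazard = None if first_order else _dissolution_hazard(compound)

    pathways = enzymes + ["renal"]
    n_path = len(pathways)
    # state: [solid, dissolved, systemic, sac, gut_loss, elim_0..elim_{n-1}]
    n_state = 5 + n_path

    def rhs(t: float, y: np.ndarray, dose_time: float) -> np.ndarray:
        solid, dissolved, a_sys, a_sac = y[0], y[1], y[2], y[3]
        dy = np.zeros(n_state)
        clints = [clint_base[e] * (modifiers[e](t) if e in modifiers else 1.0)
                  for e in enzymes]
        clint_tot = sum(clints)
        if clint_tot > 0:
            x = fu_b * clint_tot
            eh = x / (qh + x)
            clh_p = qh * eh * bp
        else:
            eh, clh_p = 0.0, 0.0
        fh = 1.0 - eh
        if transporters:
            factors = {tr: (modifiers[tr](t) if tr in modifiers else 1.0)
                       for tr in transporters}
            clr = renal_base.with_secretion_factors(factors).cl_total
        else:
            clr = renal_base.cl_total
        cp = a_sys / v_sys
        diss_rate = 0.0 if first_order else hazard(t - dose_time) * solid
        flux = ka * dissolved          # leaves the gut lumen
        absorbed = flux * fa * fg      # reaches the portal inlet
        dy[0] = -diss_rate
        dy[1] = diss_rate - flux
        dy[2] = absorbed * fh - (clh_p + clr) * cp - kin * a_sys + kout * a_sac
        dy[3] = kin * a_sys - kout * a_sac
        dy[4] = flux * (1.0 - fa * fg)  # unabsorbed + gut loss
        for i, e in enumerate(enzymes):
            share = clints[i] / clint_tot if clint_tot > 0 else 0.0
            dy[5 + i] = absorbed * (1.0 - fh) * share + clh_p * cp * share
        dy[5 + len(enzymes)] = clr * cp
        return dy

    dose_times = regimen.dose_times
    if t_end is None:
        t_end = regimen.last_dose_time + (240.0 if regimen.n_doses == 1
                                          else regimen.interval)
    if t_end <= regimen.last_dose_time:
        raise ValueError("t_end must exceed the last dose time")

    boundaries = np.concatenate([dose_times[dose_times < t_end], [t_end]])
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    admin: list[np.ndarray] = []
    y = np.zeros(n_state)
    given = 0.0
    if boundaries[0] > 0:
        seg = np.arange(0.0, boundaries[0], grid_dt)
        times.append(seg)
        states.append(np.zeros((n_state, len(seg))))
        admin.append(np.zeros(len(seg)))
    for i, t_start in enumerate(boundaries[:-1]):
        t_stop = boundaries[i + 1]
        y = y.copy()
        y[1 if first_order else 0] += regimen.dose
        given += regimen.dose
        t_eval = np.arange(t_start, t_stop, grid_dt)
        if t_eval[-1] < t_stop - 1e-9:
            t_eval = np.append(t_eval, t_stop)
        sol = solve_ivp(
            rhs, (t_start, t_stop), y, t_eval=t_eval, args=(t_start,),
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{t_start}, {t_stop}]: {sol.message}"
            )
        times.append(sol.t)
        states.append(sol.y)
        admin.append(np.full(len(sol.t), given))
        y = sol.y[:, -1]

    t = np.concatenate(times)
    ystack = np.concatenate(states, axis=1)
    administered = np.concatenate(admin)
    # drop duplicated boundary points
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    t, ystack, administered = t[keep], ystack[:, keep], administered[keep]

    if ystack[:4].min() < -1e-6 * regimen.dose:
        raise RuntimeError(
            f"negative compartment amount ({ystack[:4].min():.3g} mg): "
            "solver tolerance too loose for this problem"
        )

    amounts = {"gut_solid": ystack[0], "gut_dissolved": ystack[1],
               "systemic": ystack[2], "sac": ystack[3]}
    eliminated = {"gut_loss": ystack[4]}
    for i, p in enumerate(pathways):
        eliminated[p] = ystack[5 + i]
    return ConcentrationTimeProfile(
        time=t,
        conc=ystack[2] / v_sys,
        amounts=amounts,
        eliminated=eliminated,
        administered=administered,
        absorption_flux=ka * ystack[1] * fa * fg,
        compound=compound,
        system=system,
        regimen=regimen,
        v_systemic_l=v_sys,
    )


def _nominal_hepatic_cl_plasma(compound, system, clint_base) -> float:
    total = sum(clint_base.values())
    if total <= 0:
        return 0.0
    ws = well_stirred_hepatic_cl(system.hepatic_blood_flow, compound.fu_blood, total)
    return ws.cl_blood * compound.blood_plasma_ratio


@dataclass(frozen=True)
class PKMetrics:
    auc_0_last: float       # µg·h/mL
    auc_0_inf: float        # µg·h/mL
    auc_tau: float          # µg·h/mL over the last dosing interval
    cmax: float             # µg/mL
    tmax: float             # h
    t_half: float           # h
    lambda_z: float         # 1/h
    cl_over_f: float        # L/h (dose / AUC0-inf)
    c24: float              # µg/mL, 24 h after the last dose
    ctrough: float          # µg/mL at end of last interval
    well_characterized: bool  # profile spans >= 5 terminal half-lives


def estimate_lambda_z(
    time: np.ndarray, conc: np.ndarray,
    terminal_fraction: float = 0.25, min_points: int = 4,
) -> float:
    """Terminal slope by log-linear regression over the trailing window."""
    t_cut = time[-1] - terminal_fraction * (time[-1] - time[0])
    mask = (time >= t_cut) & (conc > 0)
    if mask.sum() < min_points:
        raise ValueError("not enough positive terminal points for lambda_z")
    slope = np.polyfit(time[mask], np.log(conc[mask]), 1)[0]
    if slope >= 0:
        raise ValueError("terminal phase is not declining; cannot estimate lambda_z")
    return -float(slope)


def compute_pk_metrics(
    profile: ConcentrationTimeProfile,
    dose: Optional[float] = None,
    terminal_fraction: float = 0.25,
) -> PKMetrics:
    """Non-compartmental metrics: trapezoidal AUC with Clast/λz
    extrapolation, λz from log-linear terminal regression, CL/F = dose/AUC∞.
    """
    t, c = profile.time, profile.conc
    regimen = profile.regimen
    dose = dose if dose is not None else regimen.dose
    imax = int(np.argmax(c))
    lam = estimate_lambda_z(t, c, terminal_fraction)
    auc_last = float(np.trapezoid(c, t))
    auc_inf = auc_last + float(c[-1]) / lam
    last = regimen.last_dose_time
    tau_mask = (t >= last) & (t <= last + regimen.interval)
    auc_tau = float(np.trapezoid(c[tau_mask], t[tau_mask])) if tau_mask.sum() > 1 else auc_last
    span_halves = (t[-1] - t[imax]) * lam / np.log(2)
    return PKMetrics(
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        auc_tau=auc_tau,
        cmax=float(c[imax]),
        tmax=float(t[imax]),
        t_half=float(np.log(2) / lam),
        lambda_z=lam,
        cl_over_f=dose / auc_inf,
        c24=float(np.interp(last + 24.0, t, c)),
        ctrough=float(np.interp(last + regimen.interval, t, c)),
        well_characterized=bool(span_halves >= 5.0),
    )


@dataclass(frozen=True)
class SteadyStateInfo:
    attained: bool
    day_attained: Optional[float]     # h/24 of the first interval at SS
    accumulation_index: float         # AUC_tau(last) / AUC_tau(first)
    interval_aucs: np.ndarray


def simulate_to_steady_state(
    compound: CompoundModel,
    system: PhysiologySystem,
    regimen: DosingRegimen,
    rel_tol: float = 0.01,
    **sim_kwargs,
) -> tuple[ConcentrationTimeProfile, SteadyStateInfo]:
    """Run a multiple-dose regimen and locate steady-state attainment.

    Steady state is declared at the first interval whose AUCτ differs from
    the previous one by less than ``rel_tol`` (default 1%); a regimen that
    never settles returns ``attained=False``.
    """
    if regimen.n_doses < 2:
        raise ValueError("steady-state analysis needs a multiple-dose regimen")
    profile = simulate(compound, system, regimen, **sim_kwargs)
    t, c = profile.time, profile.conc
    aucs = []
    for t0 in regimen.dose_times:
        mask = (t >= t0) & (t <= t0 + regimen.interval)
        aucs.append(float(np.trapezoid(c[mask], t[mask])))
    aucs = np.asarray(aucs)
    attained, day = False, None
    for i in range(1, len(aucs)):
        if abs(aucs[i] - aucs[i - 1]) / max(aucs[i - 1], 1e-12) < rel_tol:
            attained = True
            day = float(regimen.dose_times[i] / 24.0) + 1.0
            break
    info = SteadyStateInfo(
        attained=attained,
        day_attained=day,
        accumulation_index=float(aucs[-1] / aucs[0]),
        interval_aucs=aucs,
    )
    return profile, info
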