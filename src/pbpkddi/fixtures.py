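"""Synthetic compound fixtures and noisy "observed" PK datasets.

Real perpetrator/victim compound files (probenecid, methotrexate,
atazanavir, mefenamic acid, rifampin, ...) belong to proprietary platforms
or unpublished literature syntheses, so this module constructs role-named
stand-ins instead: victims with a stated renal-secretion fraction carried by
OAT1/OAT3, UGT inhibitors/inducers with stated Ki or induction parameters,
and null compounds.  A fixture's headline pathway fractions are hit exactly
on the reference subject by inverting the IVIVE/well-stirred equations, so
`compute_pathway_fractions` recovers the spec values to numerical precision.

Noisy observed datasets are simulated profiles sampled at a clinical-style
schedule with multiplicative log-normal error — synthetic stand-ins for
clinical verification data.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import least_squares

from .clearance import UL_MIN_TO_L_H
from .compound import (AbsorptionParams, CompoundModel, DistributionParams,
                       EliminationParams, EnzymeClint, InductionTerm,
                       InteractionParams, RenalParams, load_compound)
from .engine import DosingRegimen, simulate
from .physiology import PhysiologySystem, reference_subject

Role = Literal["oat1_victim", "oat3_victim", "dual_oat_victim",
               "ugt_inhibitor", "ugt_inducer", "null_compound"]


def cabotegravir() -> CompoundModel:
    """The packaged cabotegravir compound file (printed parameter set plus
    the documented package calibrations)."""
    with resources.as_file(
        resources.files("pbpkddi.data").joinpath("cabotegravir.yaml")
    ) as path:
        return load_compound(path)


class FixtureSpec(BaseModel):
    """Recipe for a synthetic compound fixture.

    Victim roles: ``fe`` is the fraction of total clearance excreted
    unchanged renally and ``secretion_split`` distributes the active
    secretory clearance across transporters.  Perpetrator roles carry a Ki
    map (µM unbound) or induction parameters.  ``cl_total`` (L/h), ``fu``
    and ``vss`` set the PK shape on the reference subject.
    """

    role: Role
    name: str = ""
    fe: float = Field(default=0.8, ge=0, lt=1)
    secretion_split: dict[str, float] = Field(default_factory=dict)
    fm_map: dict[str, float] = Field(default_factory=dict)   # hepatic shares
    ki_map: dict[str, float] = Field(default_factory=dict)
    induction_map: dict[str, tuple[float, float]] = Field(default_factory=dict)
    cl_total: float = Field(default=6.0, gt=0)
    fu: float = Field(default=0.1, gt=0, le=1)
    vss: float = Field(default=0.25, gt=0, description="L/kg")
    ka: float = Field(default=1.5, gt=0)
    molecular_weight: float = Field(default=350.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        if sum(self.secretion_split.values()) > 1 + 1e-9:
            raise ValueError("secretion_split fractions sum to > 1")
        if self.role == "oat1_victim" and self.secretion_split and \
                "OAT1" not in self.secretion_split:
            raise ValueError("oat1_victim must route secretion via OAT1")
        if self.role == "oat3_victim" and self.secretion_split and \
                "OAT3" not in self.secretion_split:
            raise ValueError("oat3_victim must route secretion via OAT3")
        if self.role in ("ugt_inhibitor",) and not self.ki_map:
            raise ValueError("ugt_inhibitor needs a ki_map")
        if self.role == "ugt_inducer" and not self.induction_map:
            raise ValueError("ugt_inducer needs an induction_map")
        return self

    def default_split(self) -> dict[str, float]:
        if self.secretion_split:
            return dict(self.secretion_split)
        return {"oat1_victim": {"OAT1": 1.0},
                "oat3_victim": {"OAT3": 1.0},
                "dual_oat_victim": {"OAT1": 0.5, "OAT3": 0.5}}.get(self.role, {})


def _invert_well_stirred(cl_plasma: float, fu_blood: float, bp: float,
                         system: PhysiologySystem) -> float:
    """Unbound hepatic CLint (L/h) that yields the given plasma clearance."""
    qh = system.hepatic_blood_flow
    cl_blood = cl_plasma / bp
    if cl_blood >= qh:
        raise ValueError(f"requested hepatic clearance {cl_plasma} L/h exceeds "
                         "the flow limit")
    return cl_blood * qh / (qh - cl_blood) / fu_blood


def make_fixture(spec: FixtureSpec,
                 system: Optional[PhysiologySystem] = None) -> CompoundModel:
    """Build a compound fixture whose pathway fractions match the spec
    exactly on the reference subject (deterministic for a given spec)."""
    system = system if system is not None else reference_subject()
    name = spec.name or spec.role
    bp = 1.0
    fu_blood = spec.fu / bp
    is_victim = spec.role in ("oat1_victim", "oat3_victim", "dual_oat_victim",
                              "null_compound")
    fe = spec.fe if is_victim and spec.role != "null_compound" else 0.0

    cl_hepatic = (1.0 - fe) * spec.cl_total
    enzyme_clints: dict[str, EnzymeClint] = {}
    if cl_hepatic > 0:
        clint_total_u = _invert_well_stirred(cl_hepatic, fu_blood, bp, system)
        fm_map = spec.fm_map or {"hepatic_unassigned": 1.0}
        scale = system.mppgl * system.liver_weight * UL_MIN_TO_L_H
        for enzyme, share in fm_map.items():
            activity = system.enzyme_multiplier(enzyme)
            enzyme_clints[enzyme] = EnzymeClint(
                clint=clint_total_u * share / scale / activity, fu_mic=1.0, isef=1.0)

    if fe > 0:
        clr = fe * spec.cl_total
        filtration = spec.fu * system.gfr
        split = spec.default_split()
        if split and clr <= filtration:
            raise ValueError(
                f"{name}: fe {fe} gives CLr {clr:.3g} L/h below the filtration "
                f"clearance {filtration:.3g} L/h; no room for active secretion")
        renal = RenalParams(mode="fe_decomposed", fe_total=fe,
                            transporter_secretion_fractions=split)
    else:
        renal = RenalParams(mode="direct_clr", clr_direct=0.0)

    interaction = InteractionParams(
        inhibition=dict(spec.ki_map),
        induction={e: InductionTerm(ind_max=mx, ind_c50=c50)
                   for e, (mx, c50) in spec.induction_map.items()},
    )
    return CompoundModel(
        name=name,
        molecular_weight=spec.molecular_weight,
        logp=1.0,
        compound_type="neutral",
        blood_plasma_ratio=bp,
        fu_plasma=spec.fu,
        absorption=AbsorptionParams(model="first-order", ka=spec.ka),
        distribution=DistributionParams(vss_mode="user", vss_user=spec.vss,
                                        sac_kin=0.02, sac_kout=0.1),
        elimination=EliminationParams(enzyme_clints=enzyme_clints, renal=renal),
        interaction=interaction,
    )


DEFAULT_SCHEDULE = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0,
                    36.0, 48.0, 72.0, 96.0, 120.0, 168.0)


@dataclass
class ObservedDataset:
    """Synthetic "observed" concentrations: simulated truth sampled at a
    clinical-style schedule with multiplicative log-normal noise."""

    frame: pd.DataFrame          # subject, time_h, conc_ug_ml
    regimen: DosingRegimen
    noise_cv: float
    seed: int

    def times(self) -> np.ndarray:
        return np.unique(self.frame["time_h"].to_numpy())

    def mean_profile(self) -> pd.DataFrame:
        logs = self.frame.assign(logc=np.log(self.frame["conc_ug_ml"]))
        g = logs.groupby("time_h")["logc"].mean()
        return pd.DataFrame({"time_h": g.index.to_numpy(),
                             "conc_ug_ml": np.exp(g.to_numpy())})


def make_observed_dataset(
    compound: CompoundModel,
    regimen: DosingRegimen,
    noise_cv: float = 20.0,
    n_subjects: int = 12,
    seed: int = 0,
    system: Optional[PhysiologySystem] = None,
    schedule=None,
) -> ObservedDataset:
    """Simulate the true profile and emit noisy sampled observations.

    Times are offsets from the last dose; noise is log-normal with the given
    CV%, independent per subject and time point.  ``noise_cv=0`` returns the
    simulated truth exactly at the sampled times.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    system = system if system is not None else reference_subject()
    last = regimen.last_dose_time
    sched = np.asarray(schedule if schedule is not None else DEFAULT_SCHEDULE,
                       dtype=float)
    profile = simulate(compound, system, regimen,
                       t_end=last + float(sched[-1]) + 1.0)
    truth = profile.conc_at(last + sched)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + (noise_cv / 100.0) ** 2))
    rows = []
    for subj in range(n_subjects):
        noise = rng.lognormal(0.0, sigma, size=len(sched)) if sigma > 0 else 1.0
        conc = truth * noise
        for t, c in zip(sched, conc):
            rows.append({"subject": subj, "time_h": last + t, "conc_ug_ml": c})
    return ObservedDataset(pd.DataFrame(rows), regimen, noise_cv, seed)


def fit_distribution_rates(
    dataset: ObservedDataset,
    compound: CompoundModel,
    system: Optional[PhysiologySystem] = None,
    x0: tuple[float, float, float] = (0.05, 0.05, 1.0),
) -> dict[str, float]:
    """Recover SAC kin/kout and ka from a PK dataset by least squares.

    Fits log-concentrations of the dataset's geometric-mean profile;
    on noiseless synthetic data the generating values are recovered to
    within numerical tolerance.
    """
    system = system if system is not None else reference_subject()
    mean = dataset.mean_profile()
    t_obs = mean["time_h"].to_numpy()
    log_obs = np.log(mean["conc_ug_ml"].to_numpy())

    def residuals(log_params):
        kin, kout, ka = np.exp(log_params)
        trial = compound.model_copy(deep=True)
        trial.distribution.sac_kin = float(kin)
        trial.distribution.sac_kout = float(kout)
        trial.absorption.ka = float(ka)
        prof = simulate(trial, system, dataset.regimen,
                        t_end=float(t_obs[-1]) + 1.0, grid_dt=0.25,
                        rtol=1e-10, atol=1e-12)
        pred = prof.conc_at(t_obs)
        return np.log(np.maximum(pred, 1e-12)) - log_obs

    # diff_step well above the solver's noise floor keeps the numeric
    # jacobian informative
    fit = least_squares(residuals, np.log(x0), diff_step=1e-4,
                        xtol=1e-12, ftol=1e-12)
    kin, kout, ka = np.exp(fit.x)
    return {"sac_kin": float(kin), "sac_kout": float(kout), "ka": float(ka),
            "cost": float(fit.cost)}
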