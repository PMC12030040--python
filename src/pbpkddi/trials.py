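"""Virtual population DDI trials and ratio summaries.

Trials follow the paired-arm convention: each subject is simulated with and
without the perpetrator (identical physiology and seeds), so the ratio is a
within-subject quantity.  Ratios are summarised as geometric means with
empirical 5th–95th percentiles (subject level) and a log-scale t-based 90%
confidence interval of the trial means.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .compound import CompoundModel
from .ddi import simulate_subject_pair
from .engine import DosingRegimen, compute_pk_metrics, simulate
from .physiology import (Demographics, PhenotypeSpec, PhysiologySystem,
                         apply_phenotype, sample_population)

RATIO_METRICS = ("auc_ratio", "cmax_ratio", "c24_ratio", "cl_ratio",
                 "half_life_ratio")


class TrialDesign(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    n_trials: int = Field(default=10, gt=0)
    n_subjects_per_trial: int = Field(default=10, gt=0)
    demographics: Demographics = Field(
        default_factory=lambda: Demographics(n_subjects=10))
    victim_regimen: DosingRegimen
    perpetrator_regimen: Optional[DosingRegimen] = None
    stagger: float = Field(default=0.0, ge=0, description="h after perpetrator dose")
    phenotype: Optional[PhenotypeSpec] = None
    variability: Optional[dict[str, float]] = None
    seed: int = 0
    grid_dt: float = Field(default=0.25, gt=0)
    washout: float = Field(default=240.0, gt=0)


@dataclass(frozen=True)
class RatioSummary:
    geometric_mean: float
    p05: float
    p95: float
    ci90_lo: float
    ci90_hi: float
    n: int

    def as_tuple(self):
        return (self.geometric_mean, self.p05, self.p95)


def summarize_ratios(
    ratios: np.ndarray,
    quantiles: tuple[float, float] = (0.05, 0.95),
    confidence: float = 0.90,
) -> RatioSummary:
    """Log-scale geometric mean, empirical quantiles and t-based CI,
    reported on the ratio scale."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("all ratios must be positive")
    logs = np.log(ratios)
    gm = float(np.exp(logs.mean()))
    lo, hi = np.exp(np.quantile(logs, quantiles))
    n = len(ratios)
    if n > 1 and logs.std(ddof=1) > 0:
        half = stats.t.ppf(0.5 + confidence / 2, n - 1) * logs.std(ddof=1) / np.sqrt(n)
    else:
        half = 0.0
    return RatioSummary(gm, float(lo), float(hi),
                        float(np.exp(logs.mean() - half)),
                        float(np.exp(logs.mean() + half)), n)


@dataclass
class TrialResult:
    per_subject: pd.DataFrame               # trial, subject, metric columns
    trial_geomeans: pd.DataFrame            # per-trial geometric means
    pooled: dict[str, RatioSummary] = field(default_factory=dict)

    def trial_means(self, metric: str = "auc_ratio") -> np.ndarray:
        return self.trial_geomeans[metric].to_numpy()


def _summaries(per_subject: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    trial_rows = []
    for trial, grp in per_subject.groupby("trial"):
        row = {"trial": trial}
        for m in RATIO_METRICS:
            row[m] = float(np.exp(np.log(grp[m]).mean()))
        trial_rows.append(row)
    trial_geomeans = pd.DataFrame(trial_rows)
    pooled = {m: summarize_ratios(per_subject[m].to_numpy()) for m in RATIO_METRICS}
    return trial_geomeans, pooled


def _trial_seeds(master_seed: int, n_trials: int) -> list[int]:
    """Deterministic per-trial seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_trials)]


def run_trial_set(
    design: TrialDesign,
    victim: CompoundModel,
    perpetrator: CompoundModel,
) -> TrialResult:
    """Simulate each trial's population twice (with/without perpetrator,
    paired subjects) and aggregate trial-level and pooled ratio statistics."""
    if design.perpetrator_regimen is None:
        raise ValueError("run_trial_set needs a perpetrator regimen")
    victim_regimen = design.victim_regimen.model_copy(
        update={"start_time": design.victim_regimen.start_time + design.stagger})
    rows = []
    for trial, seed in enumerate(_trial_seeds(design.seed, design.n_trials)):
        demo = design.demographics.model_copy(
            update={"n_subjects": design.n_subjects_per_trial, "seed": seed})
        population = sample_population(demo, design.variability)
        if design.phenotype is not None:
            population = apply_phenotype(population, design.phenotype)
        for subject in population:
            _, _, ratios = simulate_subject_pair(
                victim, perpetrator, subject, victim_regimen,
                design.perpetrator_regimen, grid_dt=design.grid_dt,
                washout=design.washout)
            rows.append({"trial": trial, "subject": subject.subject_id,
                         **ratios.as_dict()})
    per_subject = pd.DataFrame(rows)
    trial_geomeans, pooled = _summaries(per_subject)
    return TrialResult(per_subject, trial_geomeans, pooled)


def pm_vs_nm_study(
    compound: CompoundModel,
    design: TrialDesign,
    phenotype: PhenotypeSpec,
) -> TrialResult:
    """Paired phenotype study: the same virtual subjects simulated with
    normal and phenotype-reduced enzyme activity; ratios are
    phenotype/normal per subject."""
    rows = []
    for trial, seed in enumerate(_trial_seeds(design.seed, design.n_trials)):
        demo = design.demographics.model_copy(
            update={"n_subjects": design.n_subjects_per_trial, "seed": seed})
        normal = sample_population(demo, design.variability)
        modified = apply_phenotype(normal, phenotype)
        for subj_n, subj_m in zip(normal, modified):
            prof_n = simulate(compound, subj_n, design.victim_regimen,
                              grid_dt=design.grid_dt)
            prof_m = simulate(compound, subj_m, design.victim_regimen,
                              grid_dt=design.grid_dt)
            m_n = compute_pk_metrics(prof_n)
            m_m = compute_pk_metrics(prof_m)
            rows.append({
                "trial": trial, "subject": subj_n.subject_id,
                "auc_ratio": m_m.auc_0_inf / m_n.auc_0_inf,
                "cmax_ratio": m_m.cmax / m_n.cmax,
                "c24_ratio": m_m.c24 / m_n.c24,
                "cl_ratio": m_m.cl_over_f / m_n.cl_over_f,
                "half_life_ratio": m_m.t_half / m_n.t_half,
            })
    per_subject = pd.DataFrame(rows)
    trial_geomeans, pooled = _summaries(per_subject)
    return TrialResult(per_subject, trial_geomeans, pooled)
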