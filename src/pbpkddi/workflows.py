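"""End-to-end analysis workflows.

Three orchestrations mirror how a DDI risk assessment is actually run:

* model verification — simulate a dosing regimen, compute NCA metrics for
  prediction and for an observed dataset on the same sampling schedule, and
  screen each metric against the 80–125% bioequivalence window;
* perpetrator matrix — one population DDI trial per victim compound against
  a common perpetrator and design, assembled into a summary table with
  per-victim failure isolation;
* victim analysis — the perpetrator's effect on the victim in normal and
  enzyme-poor-metabolizer populations, plus the composite PM × inhibition
  exposure change versus the normal-metabolizer baseline.

All workflows are pure functions of (inputs, master seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compound import CompoundModel
from .engine import DosingRegimen, simulate
from .fixtures import ObservedDataset
from .physiology import PhenotypeSpec, PhysiologySystem, reference_subject
from .stats import VerificationReport, bioequivalence_check
from .trials import RATIO_METRICS, TrialDesign, TrialResult, pm_vs_nm_study, run_trial_set


def _sparse_nca(times: np.ndarray, conc: np.ndarray, dose: float) -> dict[str, float]:
    """NCA on a sparse sampling schedule (identical routine for observed and
    predicted, so a noiseless closed loop is exact)."""
    order = np.argsort(times)
    t, c = np.asarray(times)[order], np.asarray(conc)[order]
    auc = float(np.trapezoid(c, t))
    tail = slice(-4, None)
    slope = np.polyfit(t[tail], np.log(np.maximum(c[tail], 1e-12)), 1)[0]
    out = {"auc_last": auc, "cmax": float(c.max())}
    if slope < 0:
        lam = -slope
        auc_inf = auc + float(c[-1]) / lam
        out["t_half"] = float(np.log(2) / lam)
        out["auc_inf"] = auc_inf
        out["cl_over_f"] = dose / auc_inf
    return out


@dataclass
class VerificationResult:
    report: VerificationReport
    predicted: dict[str, float]
    observed: dict[str, float]

    def to_text(self) -> str:
        lines = ["model verification (predicted vs observed)"]
        for k in sorted(self.observed):
            if k in self.predicted:
                lines.append(f"  {k:<10} predicted {self.predicted[k]:<10.4g} "
                             f"observed {self.observed[k]:<10.4g}")
        lines.append(self.report.to_text())
        return "\n".join(lines) + "\n"


def run_verification(
    compound: CompoundModel,
    observed: ObservedDataset,
    system: Optional[PhysiologySystem] = None,
    metrics: Sequence[str] = ("auc_last", "cmax", "cl_over_f"),
) -> VerificationResult:
    """Simulate the observed dataset's regimen and screen predicted vs
    observed NCA metrics against bioequivalence bounds."""
    system = system if system is not None else reference_subject()
    mean = observed.mean_profile()
    t_obs = mean["time_h"].to_numpy()
    profile = simulate(compound, system, observed.regimen,
                       t_end=float(t_obs[-1]) + 1.0)
    dose = observed.regimen.dose
    pred = _sparse_nca(t_obs, profile.conc_at(t_obs), dose)
    obs = _sparse_nca(t_obs, mean["conc_ug_ml"].to_numpy(), dose)
    report = VerificationReport()
    for m in metrics:
        if m in pred and m in obs:
            report.verdicts[m] = bioequivalence_check(pred[m], obs[m])
    return VerificationResult(report, pred, obs)


@dataclass
class MatrixResult:
    table: pd.DataFrame
    results: dict[str, TrialResult] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def run_perpetrator_matrix(
    victims: Sequence[CompoundModel],
    perpetrator: CompoundModel,
    design: TrialDesign,
) -> MatrixResult:
    """One population DDI trial per victim; failures are isolated per cell
    and reported, the rest of the matrix still runs."""
    rows, results, errors = [], {}, {}
    for victim in victims:
        try:
            res = run_trial_set(design, victim, perpetrator)
        except Exception as exc:  # noqa: BLE001 — cell isolation is the point
            errors[victim.name] = f"{type(exc).__name__}: {exc}"
            continue
        results[victim.name] = res
        row = {"victim": victim.name}
        for m in ("auc_ratio", "cmax_ratio"):
            s = res.pooled[m]
            row[f"{m}_gm"] = s.geometric_mean
            row[f"{m}_p05"] = s.p05
            row[f"{m}_p95"] = s.p95
        rows.append(row)
    return MatrixResult(pd.DataFrame(rows), results, errors)


@dataclass
class VictimAnalysisResult:
    normal: TrialResult                  # perpetrator effect, normal population
    poor_metabolizer: TrialResult        # perpetrator effect, PM population
    pm_baseline: TrialResult             # PM vs normal, no perpetrator
    composite_auc_ratio: float           # PM+perpetrator vs normal baseline

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for label, res in (("normal + perpetrator", self.normal),
                           ("PM + perpetrator", self.poor_metabolizer),
                           ("PM baseline vs normal", self.pm_baseline)):
            s = res.pooled["auc_ratio"]
            rows.append({"scenario": label, "auc_ratio_gm": s.geometric_mean,
                         "p05": s.p05, "p95": s.p95})
        rows.append({"scenario": "composite PM×inhibition vs normal",
                     "auc_ratio_gm": self.composite_auc_ratio,
                     "p05": float("nan"), "p95": float("nan")})
        return pd.DataFrame(rows)


def run_victim_analysis(
    victim: CompoundModel,
    inhibitor: CompoundModel,
    design: TrialDesign,
    phenotype: PhenotypeSpec,
) -> VictimAnalysisResult:
    """Victim DDI in normal and poor-metabolizer populations.

    The composite ratio multiplies the PM-baseline exposure shift by the
    inhibition effect measured within the PM population — the worst-case
    combined scenario versus untreated normal metabolizers.
    """
    normal = run_trial_set(design, victim, inhibitor)
    pm_design = design.model_copy(update={"phenotype": phenotype})
    pm = run_trial_set(pm_design, victim, inhibitor)
    baseline_design = design.model_copy(update={"phenotype": None})
    pm_baseline = pm_vs_nm_study(victim, baseline_design, phenotype)
    composite = (pm_baseline.pooled["auc_ratio"].geometric_mean
                 * pm.pooled["auc_ratio"].geometric_mean)
    return VictimAnalysisResult(normal, pm, pm_baseline, composite)


def trial_report_text(result: TrialResult, title: str) -> str:
    """Deterministic text report of a trial set (stable formatting)."""
    lines = [title]
    for m in RATIO_METRICS:
        s = result.pooled[m]
        lines.append(f"  {m:<16} GM {s.geometric_mean:.4f} "
                     f"(5th-95th {s.p05:.4f}-{s.p95:.4f}; "
                     f"90% CI {s.ci90_lo:.4f}-{s.ci90_hi:.4f}; n={s.n})")
    return "\n".join(lines) + "\n"
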