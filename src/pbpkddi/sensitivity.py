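"""Sensitivity sweeps: DDI magnitude vs Ki potency, dose, and fu,p.

Each grid point re-runs the dynamic DDI on the deterministic reference
subject with only the swept parameter changed: ``ki_fold`` divides the
perpetrator's Ki values (larger fold = more potent), ``dose_fold``
multiplies the perpetrator dose, and ``fu_fold`` multiplies the
perpetrator's fu,p (capped at 1, with a recorded warning) — fu propagates
into both clearance and the predicted Vss, since both depend on it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .compound import CompoundModel
from .ddi import simulate_subject_pair
from .engine import DosingRegimen
from .physiology import PhysiologySystem, reference_subject


@dataclass
class SweepSpec:
    parameter: Literal["ki_fold", "dose_fold", "fu_fold"]
    folds: list[float]
    victim: CompoundModel
    perpetrator: CompoundModel
    victim_regimen: DosingRegimen
    perpetrator_regimen: DosingRegimen
    targets: Optional[list[str]] = None   # restrict ki_fold to these targets
    system: Optional[PhysiologySystem] = None
    grid_dt: float = 0.25

    def __post_init__(self):
        if any(f <= 0 for f in self.folds):
            raise ValueError("folds must be positive")
        if list(self.folds) != sorted(self.folds):
            raise ValueError("fold grid must be sorted ascending")


@dataclass
class SweepResult:
    curve: pd.DataFrame                 # fold, auc_ratio, cmax_ratio
    warnings: list[str] = field(default_factory=list)


def _apply_fold(spec: SweepSpec, fold: float):
    perp = spec.perpetrator.model_copy(deep=True)
    perp_regimen = spec.perpetrator_regimen
    notes = []
    if spec.parameter == "ki_fold":
        targets = spec.targets or list(perp.interaction.inhibition)
        perp.interaction.inhibition = {
            t: (ki / fold if t in targets else ki)
            for t, ki in perp.interaction.inhibition.items()
        }
    elif spec.parameter == "dose_fold":
        perp_regimen = perp_regimen.model_copy(
            update={"dose": perp_regimen.dose * fold})
    else:  # fu_fold
        fu = spec.perpetrator.fu_plasma * fold
        if fu > 1.0:
            notes.append(f"fu_fold {fold}: fu,p clamped from {fu:.3g} to 1.0")
            fu = 1.0
        perp.fu_plasma = fu
    return perp, perp_regimen, notes


def run_sweep(spec: SweepSpec) -> SweepResult:
    """One dynamic DDI evaluation per grid point (deterministic subject)."""
    system = spec.system if spec.system is not None else reference_subject()
    rows, notes = [], []
    for fold in spec.folds:
        perp, perp_regimen, fold_notes = _apply_fold(spec, fold)
        notes.extend(fold_notes)
        _, _, ratios = simulate_subject_pair(
            spec.victim, perp, system, spec.victim_regimen, perp_regimen,
            grid_dt=spec.grid_dt)
        rows.append({"fold": fold, "auc_ratio": ratios.auc_ratio,
                     "cmax_ratio": ratios.cmax_ratio})
    return SweepResult(curve=pd.DataFrame(rows), warnings=notes)


@dataclass(frozen=True)
class ThresholdReport:
    crossed: bool
    fold_at_threshold: float   # interpolated crossing, or grid max if never crossed
    threshold: float


def threshold_report(curve: pd.DataFrame, auc_threshold: float) -> ThresholdReport:
    """Largest fold keeping AUCR below the threshold (log-linear
    interpolation on a monotone curve)."""
    folds = curve["fold"].to_numpy(dtype=float)
    aucr = curve["auc_ratio"].to_numpy(dtype=float)
    if np.any(np.diff(aucr) < -1e-9):
        raise ValueError("threshold_report needs a monotone non-decreasing curve")
    if auc_threshold <= aucr[0]:
        return ThresholdReport(True, 0.0, auc_threshold)
    if auc_threshold > aucr[-1]:
        return ThresholdReport(False, float(folds[-1]), auc_threshold)
    fold = np.interp(auc_threshold, aucr, folds)
    return ThresholdReport(True, float(fold), auc_threshold)
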