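"""Verification statistics: TOST equivalence, percentile containment and
bioequivalence screening.

The equivalence question is whether the simulated trial-mean ratio
distribution is consistent with a published mean ratio to within a fold
bound (default 1.3): two one-sided 95% confidence limits of the log-scale
mean of trial means must both fall inside [published/1.3, published×1.3].
Percentile containment asks whether the published value lies within the
empirical 5th–95th percentiles of the trial means.  Bioequivalence
screening is the plain 80–125% window on a predicted/observed ratio; both
interval checks use closed bounds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats


class EquivalenceSpec(BaseModel):
    equivalence_fold_bound: float = Field(default=1.3, gt=1)
    tost_confidence: float = Field(default=0.95, gt=0, lt=1)
    containment_quantiles: tuple[float, float] = (0.05, 0.95)
    be_bounds: tuple[float, float] = (0.80, 1.25)

    @model_validator(mode="after")
    def _check(self) -> "EquivalenceSpec":
        lo, hi = self.be_bounds
        if not 0 < lo < 1 < hi:
            raise ValueError("be_bounds must straddle 1")
        return self


@dataclass(frozen=True)
class EquivalenceReport:
    passed: bool
    lower_limit: float          # one-sided lower confidence limit (ratio scale)
    upper_limit: float          # one-sided upper confidence limit
    bound_lo: float             # published/fold
    bound_hi: float             # published×fold
    published: float
    n_trials: int
    note: str = "one-sided limits are log-scale t-based on trial means"


def tost_ratio_equivalence(
    published_mean_ratio: float,
    trial_mean_ratios,
    spec: Optional[EquivalenceSpec] = None,
) -> EquivalenceReport:
    """Two one-sided equivalence test of simulated trial means vs a
    published mean ratio.

    On the log scale, the lower and upper one-sided confidence limits of
    the mean of trial means are m ∓ t_{conf,n−1}·s/√n; equivalence passes
    iff both limits fall within the fold bound around the published value
    (closed interval).
    """
    spec = spec or EquivalenceSpec()
    ratios = np.asarray(trial_mean_ratios, dtype=float)
    if len(ratios) < 3:
        raise ValueError("TOST needs at least 3 trial means")
    if published_mean_ratio <= 0 or np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    logs = np.log(ratios)
    n = len(logs)
    m, s = logs.mean(), logs.std(ddof=1)
    half = stats.t.ppf(spec.tost_confidence, n - 1) * s / np.sqrt(n) if s > 0 else 0.0
    lower, upper = np.exp(m - half), np.exp(m + half)
    fold = spec.equivalence_fold_bound
    bound_lo = published_mean_ratio / fold
    bound_hi = published_mean_ratio * fold
    passed = (lower >= bound_lo) and (upper <= bound_hi)
    return EquivalenceReport(
        passed=bool(passed), lower_limit=float(lower), upper_limit=float(upper),
        bound_lo=float(bound_lo), bound_hi=float(bound_hi),
        published=published_mean_ratio, n_trials=n,
    )


@dataclass(frozen=True)
class ContainmentReport:
    passed: bool
    q_lo: float
    q_hi: float
    published: float


def percentile_containment(
    published_mean_ratio: float,
    trial_mean_ratios,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> ContainmentReport:
    """Pass iff the published value lies within the empirical quantile
    interval of the trial means (linear-interpolation quantiles, closed)."""
    ratios = np.asarray(trial_mean_ratios, dtype=float)
    if published_mean_ratio <= 0 or np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    q_lo, q_hi = np.quantile(ratios, quantiles)
    passed = q_lo <= published_mean_ratio <= q_hi
    return ContainmentReport(bool(passed), float(q_lo), float(q_hi),
                             published_mean_ratio)


@dataclass(frozen=True)
class BioequivalenceVerdict:
    passed: bool
    ratio: float
    bounds: tuple[float, float]


def bioequivalence_check(
    predicted: float, observed: float,
    be_bounds: tuple[float, float] = (0.80, 1.25),
) -> BioequivalenceVerdict:
    """Pass iff predicted/observed ∈ [0.80, 1.25] (closed bounds)."""
    if predicted <= 0 or observed <= 0:
        raise ValueError("metrics must be positive")
    ratio = predicted / observed
    lo, hi = be_bounds
    return BioequivalenceVerdict(bool(lo <= ratio <= hi), float(ratio), be_bounds)


@dataclass
class VerificationReport:
    """Per-metric bioequivalence verdicts for a model-vs-observed comparison."""

    verdicts: dict[str, BioequivalenceVerdict] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(v.passed for v in self.verdicts.values())

    def to_text(self) -> str:
        lines = ["metric            ratio    window         verdict"]
        for name, v in sorted(self.verdicts.items()):
            lines.append(
                f"{name:<16}  {v.ratio:>6.3f}   "
                f"[{v.bounds[0]:.2f}, {v.bounds[1]:.2f}]   "
                f"{'PASS' if v.passed else 'FAIL'}"
            )
        lines.append(f"overall: {'PASS' if self.all_passed else 'FAIL'}")
        return "\n".join(lines)
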