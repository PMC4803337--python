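"""Back-transformed goodness of fit and per-component model selection.

Candidates are compared on the arithmetic (kg) scale after bias-corrected
back-transformation, using

    R^2   = 1 - sum (W_i - What_i)^2 / sum (W_i - Wbar)^2
    MAPE  = (1/n) sum |W_i - What_i| / W_i

MAPE is the primary criterion: unlike R^2 it does not inflate with extra
predictors.  A candidate is eligible only when all of its slope
coefficients are significant (two-sided t-test) at the chosen level; the
intercept does not gate eligibility.  Among eligible candidates the lowest
MAPE wins, ties broken by higher R^2, then fewer coefficients, then lower
model index.  If nothing is eligible the lowest-MAPE candidate is returned
flagged as a fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .candidate_models import ModelSpec, OlsFit, predict_biomass_many
from .tree_data import AgeGroup, Component, TreeRecord, ValidationError

__all__ = [
    "EvalStats",
    "CoefficientTest",
    "FitEvaluation",
    "SelectionResult",
    "r_squared",
    "mape",
    "mape_reduction",
    "coefficient_significance",
    "evaluate_fit",
    "select_model",
]

#: Decimal places used when comparing MAPE/R^2 for ties.
_TIE_DECIMALS = 6


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination on the supplied (arithmetic) scale.

    May be negative when predictions do worse than the observed mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValidationError("need two equal-length series of length >= 2")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        raise ValidationError("observed values are all equal; R^2 undefined")
    rss = float(np.sum((obs - pred) ** 2))
    return 1.0 - rss / tss


def mape(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute prediction error as a fraction of the observed value."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 1:
        raise ValidationError("need two equal-length non-empty series")
    if np.any(obs == 0):
        raise ValidationError("MAPE undefined for zero observed values")
    return float(np.mean(np.abs(obs - pred) / np.abs(obs)))


def mape_reduction(mape_reference: float, mape_alternative: float) -> float:
    """Percent reduction of the alternative's MAPE relative to the reference."""
    if mape_reference <= 0:
        raise ValidationError("reference MAPE must be positive")
    if mape_alternative < 0:
        raise ValidationError("MAPE cannot be negative")
    return 100.0 * (mape_reference - mape_alternative) / mape_reference


@dataclass(frozen=True)
class CoefficientTest:
    name: str
    estimate: float
    se: float
    t: float
    p: float
    significant: bool


def coefficient_significance(
    fit: OlsFit, alpha: float = 0.05
) -> list[CoefficientTest]:
    """Two-sided t-tests for every coefficient, df = n - k.

    An exactly interpolating fit (sigma2 == 0) is handled as the limit:
    every nonzero coefficient is exactly determined (t = inf, p = 0) and a
    zero coefficient is indistinguishable from absent (p = 1).  A zero
    standard error with positive residual variance indicates a degenerate
    design and is rejected.
    """
    df = fit.n - fit.k
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    out = []
    for name, est, se in zip(fit.spec.coefficient_names, fit.params, fit.bse):
        if se <= 0:
            if fit.sigma2 == 0:
                p = 0.0 if est != 0 else 1.0
                t = math.inf if est != 0 else 0.0
                out.append(
                    CoefficientTest(name, float(est), 0.0, t, p, p < alpha)
                )
                continue
            raise ValidationError(f"coefficient {name} has zero standard error")
        t = float(est / se)
        p = float(2.0 * stats.t.sf(abs(t), df))
        out.append(CoefficientTest(name, float(est), float(se), t, p, p < alpha))
    return out


@dataclass(frozen=True)
class EvalStats:
    r2: float
    mape: float
    n: int


@dataclass(frozen=True)
class FitEvaluation:
    """One candidate's fit bundled with its evaluation statistics."""

    fit: OlsFit
    stats: EvalStats
    coefficient_tests: tuple[CoefficientTest, ...]

    @property
    def slopes_significant(self) -> bool:
        return all(t.significant for t in self.coefficient_tests[1:])


def evaluate_fit(
    fit: OlsFit, records: Sequence[TreeRecord], alpha: float = 0.05
) -> FitEvaluation:
    """Evaluate a fitted candidate on bias-corrected back-transformed scale."""
    if fit.group is not None:
        records = [r for r in records if r.group is fit.group]
    obs = np.array([r.biomass(fit.component) for r in records])
    pred = predict_biomass_many(fit, records)
    return FitEvaluation(
        fit=fit,
        stats=EvalStats(
            r2=r_squared(obs, pred), mape=mape(obs, pred), n=len(records)
        ),
        coefficient_tests=tuple(coefficient_significance(fit, alpha)),
    )


@dataclass(frozen=True)
class SelectionResult:
    component: Component
    group: AgeGroup | None
    chosen: ModelSpec
    eligible: tuple[ModelSpec, ...]
    evaluations: tuple[FitEvaluation, ...]
    fallback: bool
    rationale: tuple[str, ...] = field(default_factory=tuple)

    def evaluation_for(self, model_id: str) -> FitEvaluation:
        for ev in self.evaluations:
            if ev.fit.spec.id == model_id:
                return ev
        raise KeyError(model_id)


def _sort_key(ev: FitEvaluation) -> tuple:
    # lowest MAPE, then highest R^2, then fewest coefficients, then model index;
    # MAPE/R^2 rounded so float noise does not manufacture distinctions.
    return (
        round(ev.stats.mape, _TIE_DECIMALS),
        -round(ev.stats.r2, _TIE_DECIMALS),
        ev.fit.k,
        ev.fit.spec.index,
    )


def select_model(
    component: Component,
    group: AgeGroup | None,
    evaluations: Sequence[FitEvaluation],
) -> SelectionResult:
    """Pick the best candidate for one component and age group.

    The choice is deterministic: eligibility requires every slope to be
    significant, the primary criterion is MAPE, and all ties resolve by
    fixed ordering (R^2, parsimony, model index).
    """
    if not evaluations:
        raise ValidationError("no fitted candidates supplied")
    evaluations = tuple(evaluations)
    rationale: list[str] = []
    eligible = [ev for ev in evaluations if ev.slopes_significant]
    for ev in evaluations:
        if not ev.slopes_significant:
            bad = [t.name for t in ev.coefficient_tests[1:] if not t.significant]
            rationale.append(
                f"{ev.fit.spec.id}: ineligible, non-significant slope(s) {bad}"
            )
    fallback = not eligible
    pool = eligible if eligible else list(evaluations)
    if fallback:
        warnings.warn(
            f"no candidate for {component.value}/{group} has all slopes "
            "significant; falling back to lowest MAPE overall",
            stacklevel=2,
        )
        rationale.append("fallback: no eligible candidate, lowest MAPE overall")
    best = min(pool, key=_sort_key)
    rationale.append(
        f"chosen {best.fit.spec.id}: MAPE={best.stats.mape:.6f}, "
        f"R2={best.stats.r2:.6f}, k={best.fit.k}"
    )
    return SelectionResult(
        component=component,
        group=group,
        chosen=best.fit.spec,
        eligible=tuple(ev.fit.spec for ev in eligible),
        evaluations=evaluations,
        fallback=fallback,
        rationale=tuple(rationale),
    )
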