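"""Candidate allometric forms, log-scale OLS fits and bias-corrected prediction.

Six log-linear candidates are considered for every biomass component:

    M1: ln W = a + b ln D
    M2: ln W = a + b ln D + c ln H
    M3: ln W = a + b ln D + c ln CR
    M4: ln W = a + b ln(D^2 H)
    M5: ln W = a + b ln(D^2 H) + c ln CR
    M6: ln W = a + b ln D + c ln H + d ln CR

These are the log forms of power-law allometries W = alpha * D^b * ... with
alpha = exp(a).  Fitting in logs linearises the model and tames the
multiplicative heteroscedasticity typical of biomass data, but the naive
back-transform exp(ln W-hat) systematically underestimates the arithmetic
mean; the Baskerville correction factor CF = exp(sigma^2 / 2) removes that
lognormal retransformation bias, so predictions are exp(ln W-hat) * CF.

Natural logarithms throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .tree_data import AgeGroup, Component, TreeRecord, ValidationError

__all__ = [
    "Term",
    "ModelSpec",
    "MODELS",
    "OlsFit",
    "build_design",
    "design_row",
    "fit_log_ols",
    "correction_factor",
    "predict_log",
    "predict_biomass",
]


class Term(enum.Enum):
    """A log-scale regressor."""

    LN_D = "lnD"
    LN_H = "lnH"
    LN_D2H = "lnD2H"
    LN_CR = "lnCR"

    def evaluate(self, D: float, H: float, CR: float) -> float:
        if self is Term.LN_D:
            return math.log(D)
        if self is Term.LN_H:
            return math.log(H)
        if self is Term.LN_D2H:
            # ln(D^2 H) = 2 ln D + ln H
            return 2.0 * math.log(D) + math.log(H)
        return math.log(CR)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate form: an intercept plus an ordered set of log terms."""

    id: str
    terms: tuple[Term, ...]

    @property
    def k(self) -> int:
        """Number of estimated coefficients (intercept included)."""
        return len(self.terms) + 1

    @property
    def index(self) -> int:
        return int(self.id[1:])

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        return ("intercept", *(t.value for t in self.terms))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        rhs = "a" + "".join(
            f" + {letter}·{t.value}" for letter, t in zip("bcd", self.terms)
        )
        return f"{self.id}: lnW = {rhs}"


#: The six candidate forms, keyed by id.
MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", (Term.LN_D,)),
    "M2": ModelSpec("M2", (Term.LN_D, Term.LN_H)),
    "M3": ModelSpec("M3", (Term.LN_D, Term.LN_CR)),
    "M4": ModelSpec("M4", (Term.LN_D2H,)),
    "M5": ModelSpec("M5", (Term.LN_D2H, Term.LN_CR)),
    "M6": ModelSpec("M6", (Term.LN_D, Term.LN_H, Term.LN_CR)),
}


def design_row(spec: ModelSpec, D: float, H: float, CR: float) -> np.ndarray:
    """Design-matrix row (intercept first) for one tree's predictors."""
    return np.array([1.0] + [t.evaluate(D, H, CR) for t in spec.terms])


def build_design(
    spec: ModelSpec,
    records: Sequence[TreeRecord],
    component: Component,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and log-biomass response for a candidate model.

    Raises if the design is rank deficient, naming the model's terms so the
    collinear columns can be identified.
    """
    X = np.array([design_row(spec, r.D, r.H, r.CR) for r in records])
    y = np.array([math.log(r.biomass(component)) for r in records])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"design for {spec.id} is rank deficient; columns "
            f"{spec.coefficient_names} are collinear on these records"
        )
    return X, y


def correction_factor(sigma2: float) -> float:
    """Baskerville lognormal bias correction factor exp(sigma^2 / 2)."""
    if sigma2 < 0:
        raise ValidationError(f"sigma2 must be non-negative, got {sigma2}")
    return math.exp(sigma2 / 2.0)


@dataclass(frozen=True)
class OlsFit:
    """A fitted log-scale regression for one component and age group."""

    spec: ModelSpec
    component: Component
    group: AgeGroup | None
    params: np.ndarray          # intercept first
    cov_params: np.ndarray      # sigma2 * (X'X)^-1
    sigma2: float               # log-scale mean-square error
    cf: float                   # exp(sigma2 / 2)
    n: int
    k: int
    residuals: np.ndarray       # log-scale

    @property
    def bse(self) -> np.ndarray:
        """Coefficient standard errors."""
        return np.sqrt(np.diag(self.cov_params))


DfConvention = Literal["nk", "paper"]


def _resolve_df(n: int, k: int, cf_df: DfConvention) -> int:
    if cf_df == "paper":
        return n - 2
    if cf_df == "nk":
        return n - k
    raise ValueError(f"cf_df must be 'nk' or 'paper', got {cf_df!r}")


def fit_log_ols(
    spec: ModelSpec,
    records: Sequence[TreeRecord],
    component: Component,
    group: AgeGroup | None = None,
    *,
    cf_df: DfConvention = "nk",
) -> OlsFit:
    """Ordinary least squares on the log scale for one candidate form.

    ``sigma2`` is the residual sum of squares over the residual degrees of
    freedom.  The classical presentation of the correction factor divides by
    n - 2, which is exact only for two-coefficient models; the default here
    generalises to n - k so that three- and four-coefficient candidates are
    not biased, while ``cf_df="paper"`` forces n - 2 for emulation of the
    original convention.  The coefficient covariance is sigma2 * (X'X)^-1
    under the same convention.
    """
    if group is not None:
        records = [r for r in records if r.group is group]
    X, y = build_design(spec, records, component)
    n, k = X.shape
    df = _resolve_df(n, k, cf_df)
    if df <= 0:
        raise ValidationError(
            f"{spec.id} needs more than {n - df} observations, got n={n}"
        )
    res = sm.OLS(y, X).fit()
    resid = np.asarray(res.resid)
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return OlsFit(
        spec=spec,
        component=component,
        group=group,
        params=np.asarray(res.params),
        cov_params=cov,
        sigma2=sigma2,
        cf=correction_factor(sigma2),
        n=n,
        k=k,
        residuals=resid,
    )


def predict_log(
    params: np.ndarray, spec: ModelSpec, record: TreeRecord
) -> float:
    """Fitted value on the log scale."""
    return float(design_row(spec, record.D, record.H, record.CR) @ params)


def predict_biomass(fit: OlsFit, record: TreeRecord) -> float:
    """Bias-corrected back-transformed prediction exp(ln W-hat) * CF, kg."""
    return math.exp(predict_log(fit.params, fit.spec, record)) * fit.cf


def predict_biomass_many(
    fit: OlsFit, records: Iterable[TreeRecord]
) -> np.ndarray:
    """Vectorised :func:`predict_biomass`."""
    return np.array([predict_biomass(fit, r) for r in records])
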