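"""Supporting analyses and report rendering.

Covers the study's side analyses: one-way ANOVA of biomass allocation
fractions across age groups, normality diagnostics (Shapiro-Wilk and Q-Q
pairs) of the total-biomass prediction residuals, and deterministic CSV/JSON
report tables mirroring the per-group candidate-fit and SUR layouts.

Allocation fractions are computed per tree and then averaged within groups
(the mean of simplex points, itself a simplex point), not as the ratio of
group-mean biomasses — the two differ whenever allocation covaries with tree
size.  Residuals tested for normality are observed minus predicted totals on
the arithmetic (kg) scale.  Q-Q pairs use Blom plotting positions
(i - 0.375)/(n + 0.25).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .additive_system import (
    SurFit,
    SystemSpec,
    fit_sur,
    predict_total,
    residual_cross_correlation,
)
from .candidate_models import MODELS, Term, fit_log_ols
from .evaluation_selection import SelectionResult, evaluate_fit, select_model
from .synthetic_data import SyntheticConfig, simulate_dataset
from .tree_data import (
    BIOMASS_COMPONENTS,
    AgeGroup,
    Component,
    TreeRecord,
    ValidationError,
    allocation_proportions,
)

__all__ = [
    "AnovaResult",
    "NormalityResult",
    "anova_oneway",
    "shapiro_wilk",
    "allocation_table",
    "allocation_anova",
    "render_report",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    group_means: tuple[float, ...]


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = (SSB / df_between) / (SSW / df_within) with df_between = g - 1 and
    df_within = N - g; the p-value comes from the F distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least two values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    if ssw == 0:
        raise ValidationError("zero within-group variance in every group")
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=F,
        p=p,
        df_between=df_b,
        df_within=df_w,
        group_means=tuple(float(a.mean()) for a in arrays),
    )


@dataclass(frozen=True)
class NormalityResult:
    W: float
    p: float
    n: int
    qq_pairs: tuple[tuple[float, float], ...]


def shapiro_wilk(sample: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk normality test plus normal Q-Q pairs.

    Uses the standard Royston approximation for the null distribution of W
    (3 <= n <= 5000).  Q-Q pairs put sorted sample values against standard
    normal quantiles at Blom plotting positions.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or not (3 <= x.size <= 5000):
        raise ValidationError("sample size must satisfy 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("sample is constant; normality test undefined")
    W, p = stats.shapiro(x)
    n = x.size
    positions = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(positions)
    qq = tuple(zip(theo.tolist(), np.sort(x).tolist()))
    return NormalityResult(W=float(W), p=float(p), n=n, qq_pairs=qq)


def allocation_table(records: Iterable[TreeRecord]) -> pd.DataFrame:
    """Mean per-tree component fractions by age group (rows sum to 1)."""
    by_group: dict[AgeGroup, list[dict]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(allocation_proportions(r))
    if not by_group:
        raise ValidationError("no records supplied")
    rows = {}
    for g in sorted(by_group):
        fr = by_group[g]
        rows[g.label] = {
            c.value: float(np.mean([f[c] for f in fr])) for c in BIOMASS_COMPONENTS
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def allocation_anova(
    records: Sequence[TreeRecord], component: Component
) -> AnovaResult:
    """ANOVA of one component's per-tree allocation fraction across groups."""
    by_group: dict[AgeGroup, list[float]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(
            allocation_proportions(r)[component]
        )
    return anova_oneway([by_group[g] for g in sorted(by_group)])


# ---------------------------------------------------------------------------
# Full pipeline and report rendering


@dataclass(frozen=True)
class PipelineResult:
    records: list[TreeRecord]
    selections: dict[AgeGroup, dict[Component, SelectionResult]]
    sur_fits: dict[AgeGroup, SurFit]
    normality: dict[AgeGroup, NormalityResult]
    allocation: pd.DataFrame
    allocation_tests: dict[Component, AnovaResult]


def run_pipeline(
    records: Sequence[TreeRecord] | None = None,
    config: SyntheticConfig | None = None,
    *,
    alpha: float = 0.05,
    cf_df: str = "nk",
) -> PipelineResult:
    """Fit, select, jointly re-estimate and diagnose, per age group.

    Either pass measured ``records`` or a synthetic ``config`` to generate
    them.  For every group: all six candidates are fitted for each of the
    four components and evaluated on the back-transformed scale; the best
    eligible candidate per component is selected; the four selections are
    re-estimated jointly by SUR; total-biomass residuals are tested for
    normality; allocation fractions are summarised and tested across groups.
    """
    if records is None:
        if config is None:
            raise ValidationError("supply records or a synthetic config")
        records = simulate_dataset(config)
    records = list(records)
    groups = sorted({r.group for r in records})

    selections: dict[AgeGroup, dict[Component, SelectionResult]] = {}
    sur_fits: dict[AgeGroup, SurFit] = {}
    normality: dict[AgeGroup, NormalityResult] = {}
    for g in groups:
        g_records = [r for r in records if r.group is g]
        selections[g] = {}
        for comp in BIOMASS_COMPONENTS:
            evals = [
                evaluate_fit(
                    fit_log_ols(MODELS[mid], g_records, comp, cf_df=cf_df),
                    g_records,
                    alpha,
                )
                for mid in sorted(MODELS)
            ]
            selections[g][comp] = select_model(comp, g, evals)
        system = SystemSpec(
            group=g,
            specs={c: selections[g][c].chosen for c in BIOMASS_COMPONENTS},
        )
        sur_fits[g] = fit_sur(g_records, system, cf_df=cf_df)
        resid_total = np.array(
            [r.total - predict_total(sur_fits[g], r) for r in g_records]
        )
        normality[g] = shapiro_wilk(resid_total)

    allocation = allocation_table(records)
    allocation_tests = {
        c: allocation_anova(records, c) for c in BIOMASS_COMPONENTS
    }
    return PipelineResult(
        records=records,
        selections=selections,
        sur_fits=sur_fits,
        normality=normality,
        allocation=allocation,
        allocation_tests=allocation_tests,
    )


def _selection_frame(
    selections: Mapping[Component, SelectionResult]
) -> pd.DataFrame:
    """Candidate-fit table: 6 models x 4 components, coefficients a-d with
    significance stars, R^2 and MAPE, plus the selection flag."""
    term_order = (Term.LN_D, Term.LN_H, Term.LN_D2H, Term.LN_CR)
    rows = []
    for mid in sorted(MODELS):
        for comp in BIOMASS_COMPONENTS:
            sel = selections[comp]
            ev = sel.evaluation_for(mid)
            row = {"model": mid, "component": comp.value}
            tests = {t.name: t for t in ev.coefficient_tests}
            icpt = tests["intercept"]
            row["a"] = f"{icpt.estimate:.3f}" + ("*" if icpt.significant else "")
            letters = iter("bcd")
            for term in ev.fit.spec.terms:
                t = tests[term.value]
                row[next(letters)] = (
                    f"{t.estimate:.3f}" + ("*" if t.significant else "")
                )
            for letter in letters:
                row[letter] = "-"
            row.setdefault("b", "-")
            row.setdefault("c", "-")
            row.setdefault("d", "-")
            row["R2"] = round(ev.stats.r2, 3)
            row["MAPE"] = round(ev.stats.mape, 3)
            row["selected"] = mid == sel.chosen.id
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["model", "component", "a", "b", "c", "d", "R2", "MAPE", "selected"]
    )


def _sur_frame(fit: SurFit) -> pd.DataFrame:
    rows = []
    for comp in BIOMASS_COMPONENTS:
        spec = fit.system.specs[comp]
        coefs = fit.params[comp]
        row = {"component": comp.value, "model": spec.id}
        for coef, letter in zip(coefs, "abcd"):
            row[letter] = round(float(coef), 4)
        for letter in "abcd":
            row.setdefault(letter, None)
        row["sigma2"] = round(fit.sigma2[comp], 6)
        row["CF"] = round(fit.cf[comp], 6)
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["component", "model", "a", "b", "c", "d", "sigma2", "CF"]
    )


def render_report(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write the full report bundle to ``out_dir``; returns written paths.

    Per group: a selection table (24 rows: 6 models x 4 components), a SUR
    coefficient table, predicted-vs-observed pairs per component and total,
    and total-residual Q-Q pairs; plus the allocation table, allocation
    ANOVAs and normality summary.  Output ordering is deterministic, so
    reruns from the same inputs are byte-identical.
    """
    missing = [
        attr
        for attr in ("records", "selections", "sur_fits", "normality", "allocation")
        if getattr(result, attr, None) is None or len(getattr(result, attr)) == 0
    ]
    if missing:
        raise ValidationError(f"pipeline result is missing: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for g in sorted(result.selections):
        sel_path = out / f"selection_{g.label}.csv"
        _selection_frame(result.selections[g]).to_csv(sel_path, index=False)
        written[f"selection_{g.label}"] = sel_path

        fit = result.sur_fits[g]
        sur_path = out / f"sur_{g.label}.csv"
        _sur_frame(fit).to_csv(sur_path, index=False)
        written[f"sur_{g.label}"] = sur_path

        meta_path = out / f"sur_{g.label}.json"
        meta = {
            "group": g.label,
            "n": fit.n,
            "iterations": fit.iterations,
            "converged": bool(fit.converged),
            "sigma_hat": fit.sigma_hat.tolist(),
            "cross_correlation": residual_cross_correlation(fit).tolist(),
        }
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
        written[f"sur_meta_{g.label}"] = meta_path

        g_records = [r for r in result.records if r.group is g]
        from .additive_system import predict_components  # local to avoid cycle noise

        pred_rows = []
        for r in g_records:
            comps = predict_components(fit, r)
            row = {"tree_id": r.tree_id, "observed_total": r.total,
                   "predicted_total": sum(comps.values())}
            for c in BIOMASS_COMPONENTS:
                row[f"observed_{c.value}"] = r.biomass(c)
                row[f"predicted_{c.value}"] = comps[c]
            pred_rows.append(row)
        pred_path = out / f"predictions_{g.label}.csv"
        pd.DataFrame(pred_rows).to_csv(pred_path, index=False)
        written[f"predictions_{g.label}"] = pred_path

        qq_path = out / f"qq_total_{g.label}.csv"
        pd.DataFrame(
            result.normality[g].qq_pairs,
            columns=["theoretical_quantile", "sample_quantile"],
        ).to_csv(qq_path, index=False)
        written[f"qq_{g.label}"] = qq_path

    alloc_path = out / "allocation.csv"
    result.allocation.to_csv(alloc_path, index_label="group")
    written["allocation"] = alloc_path

    diag_path = out / "diagnostics.json"
    diag = {
        "allocation_anova": {
            c.value: {
                "F": t.F,
                "p": t.p,
                "df_between": t.df_between,
                "df_within": t.df_within,
                "group_means": list(t.group_means),
            }
            for c, t in result.allocation_tests.items()
        },
        "total_residual_normality": {
            g.label: {"W": r.W, "p": r.p, "n": r.n}
            for g, r in result.normality.items()
        },
    }
    diag_path.write_text(json.dumps(diag, indent=2, sort_keys=True))
    written["diagnostics"] = diag_path
    return written
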