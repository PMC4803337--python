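"""Fit the six candidate allometric forms and pick the best one.

For one component and age group, all six log-linear candidates are fitted,
back-transformed with the Baskerville correction factor, and scored by MAPE
(primary) and R^2 on the kg scale.  A candidate is only eligible if all of
its slope coefficients are significant at the 5% level.
"""

from treeallom import (
    AgeGroup,
    Component,
    MODELS,
    default_config,
    evaluate_fit,
    fit_log_ols,
    select_model,
    simulate_dataset,
)

records = [
    r for r in simulate_dataset(default_config(seed=0))
    if r.group is AgeGroup.YOUNG
]

evaluations = []
for model_id in sorted(MODELS):
    fit = fit_log_ols(MODELS[model_id], records, Component.TRUNK)
    ev = evaluate_fit(fit, records)
    evaluations.append(ev)
    stars = "" if ev.slopes_significant else "  (slope n.s.)"
    print(
        f"{model_id}: MAPE={ev.stats.mape:.3f}  R2={ev.stats.r2:.3f}  "
        f"CF={ev.fit.cf:.4f}{stars}"
    )

selection = select_model(Component.TRUNK, AgeGroup.YOUNG, evaluations)
print(f"\nselected: {selection.chosen}")
print("rationale:", selection.rationale[-1])

# Lower MAPE means smaller average relative prediction error; the correction
# factor CF > 1 is the multiplicative fix for the back-transformation bias of
# a log-scale regression.  The selected form is the one the additive system
# will use for this component.
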