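"""Game features vs MoCA as predictors of below/above-median gait score.

Dichotomizes DGI at its sample median and evaluates two elastic-net
logistic arms with identical cross-validation folds: one on the nine
game variables, one on the single MoCA score.  Prints cross-validated
accuracy with the exact binomial test against a coin flip, AUCs, and
DeLong's one-sided test that the game arm's AUC is larger.
"""

from gglearn import CohortConfig, CVConfig, compare_predictors, fit_cohort, generate_cohort

cohort = generate_cohort(CohortConfig(), seed=7)
features, _ = fit_cohort(cohort.trials)

report = compare_predictors(
    features.drop(columns="patient_id").to_numpy(),
    cohort.clinical["moca_total"].to_numpy(),
    cohort.clinical["dgi_total"].to_numpy(),
    CVConfig(seed=1),
)

print(f"DGI median: {report.median}; class sizes "
      f"{int(report.labels.sum())} above / {int((1 - report.labels).sum())} at-or-below")
for name, ev in (("game features", report.gg), ("MoCA", report.moca)):
    print(f"{name:14s} accuracy {ev.accuracy:.3f} "
          f"(binomial p vs chance {ev.binomial_p:.3f}), AUC {ev.auc:.3f}")
print(f"DeLong one-sided p (game AUC > MoCA AUC): {report.delong.p_value:.3f}")
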