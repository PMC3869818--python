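"""Evaluate a qPCR biomarker: ddCt fold change, covariates, and ROC.

Simulates a case-control cohort (planted dCt shift of -log2(5), i.e. a
true five-fold up-regulation in cases), quantifies expression relative to
healthy controls, tests the group difference on the dCt scale, screens
covariates, and measures diagnostic accuracy.
"""

from netconverge import (covariate_screen, delta_delta_ct, group_difference,
                         make_paperlike_bundle, roc_analysis)

bundle = make_paperlike_bundle(seed=17)
data = bundle.qpcr["discovery"]

ddct = delta_delta_ct(data, calibrator_group="HC")
case = ddct.group_summary.set_index("group").loc["PD"]
print(f"case fold change: mean +/- SEM = {case['mean_fold_change']:.2f} "
      f"+/- {case['sem_fold_change']:.2f}; "
      f"group-level estimate 2^(-mean ddCt) = {case['fold_change_group']:.2f} "
      f"(truth: 5.0)")

t, p = group_difference(data, "PD", "HC")
print(f"pooled t-test on dCt: t = {t:.2f}, p = {p:.2e}")

screen = covariate_screen(-ddct.per_sample["delta_ct"],
                          data[["age", "sex", "bmi", "hoehn_yahr"]])
print("\ncovariate screen (expression vs covariate):")
print(screen.to_string(index=False))

roc = roc_analysis(-ddct.per_sample["delta_ct"], ddct.per_sample["group"],
                   case_label="PD")
print(f"\nROC: AUC = {roc.auc:.2f} "
      f"(95% CI {roc.ci_low:.2f}-{roc.ci_high:.2f}, p = {roc.p_value:.1e})")
print("Covariates were simulated independent of disease, so |R| stays "
      "small; the AUC tracks the analytic value Phi(2.32/sqrt(2)) ~ 0.95.")
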