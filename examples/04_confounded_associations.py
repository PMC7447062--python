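"""Closed-form genetically confounded associations.

With NO causal maternal path, a maternal trait still correlates with a
pregnancy outcome because mother and child share half their alleles and
the child's alleles act directly on the outcome.  The closed form
(h^2/2) * beta_FY / beta_MX predicts that observational slope.
"""

import dataclasses

import numpy as np

from duomr import (
    ModelSpec,
    SimulationConfig,
    confounded_mat_to_outcome,
    confounded_outcome_to_adult,
    contrast,
    fit_haplotype_model,
    score_trait_regression,
    simulate_study,
)

cfg = SimulationConfig(
    n_pregnancies=30_000, n_snps=40, seed=4,
    instrument_r2=0.2, maternal_effect=0.0, maternal_effect_bw=0.0,
    confounding_gest=0.0, fetal_drive_effect=0.0, fetal_effect_per_score=-2.0,
)
study = simulate_study(cfg)
sc, ph = study.scores, study.phenotypes

fit = fit_haplotype_model(sc, ph, ModelSpec(outcome="gestational_days",
                                            covariates=()))
fy = contrast(fit, "fetal")
inst = score_trait_regression(sc, ph, "sbp")
pred = confounded_mat_to_outcome(fy, (inst.beta, inst.se),
                                 study.truth["h2_trait"])
obs = np.polyfit(ph.sbp, ph.gestational_days, 1)[0]
print("maternal trait -> outcome (no causal path planted):")
print(f"  predicted confounded slope {pred.estimate:+.4f} d/mmHg")
print(f"  realized observational slope {obs:+.4f} d/mmHg")

# outcome -> adult offspring trait, after rescaling the fit so one score
# unit predicts one unit of the adult trait
b = study.truth["adult_beta_per_score"]
fit_ad = dataclasses.replace(fit, beta=fit.beta / b, cov=fit.cov / b**2)
for method in (1, 2):
    est = confounded_outcome_to_adult(
        fit_ad, study.truth["h2_adult"], study.truth["var_adult"],
        float(np.var(ph.gestational_days)), method=method,
    )
    extra = ""
    if method == 1:
        extra = (f"  [maternal {est.maternal_component:+.4f}"
                 f" + fetal {est.fetal_component:+.4f}]")
    print(f"method {method}: {est.estimate:+.4f} SD(X')/SD(Y){extra}")
zy = (ph.gestational_days - ph.gestational_days.mean()) / ph.gestational_days.std()
zx = (ph.adult_trait - ph.adult_trait.mean()) / ph.adult_trait.std()
print(f"realized standardized slope {np.polyfit(zy, zx, 1)[0]:+.4f}")
# Both formulas track the realized slope; Method 1 also splits it into
# the maternal and fetal components.
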