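"""Fit the latent-component model and test associations in both directions.

Fits per-CpG cell-type means/variances by maximum marginal likelihood, then
runs (a) the X|Y generalized-least-squares test and (b) the Y|X route:
posterior-mean tensor estimation followed by a logistic score test of the
phenotype on each estimated cell-type component.
"""

import numpy as np

from dmdir import (ScenarioConfig, estimate_tensor, fit_tca, simulate_cohort,
                   tca_test_xgy, tca_test_ygx)

config = ScenarioConfig(direction="ygx", scenario="uni1c", n=500, m=100,
                        m_true=2, k=3, dirichlet_alpha=(4.0, 2.0, 1.0),
                        effect_size=4.0, liability_sd=0.2, seed=3)
cohort = simulate_cohort(config)
ids = dict(cpg_ids=cohort.cpg_ids, celltype_ids=cohort.celltype_ids)

params = fit_tca(cohort.X, cohort.W)
print(f"latent-model fit: {params.n_iter} iterations, "
      f"{params.converged.mean():.0%} CpGs converged")
print(f"mean |mu_hat - mu_true| = "
      f"{np.abs(params.mu - cohort.mu).mean():.4f} (methylation scale)")

xgy = tca_test_xgy(cohort.X, cohort.W, cohort.y, params=params, **ids)
tensor = estimate_tensor(cohort.X, cohort.W, params)
ygx = tca_test_ygx(tensor, cohort.y, **ids)

truth_pairs = {(cohort.cpg_ids[j], cohort.celltype_ids[h])
               for j, h in cohort.truth.pairs()}
print(f"\ntrue entries: {sorted(truth_pairs)}")
for name, table in (("X|Y (GLS on bulk)", xgy),
                    ("Y|X (score test on tensor)", ygx)):
    top = table.nsmallest(3, "p_value")
    print(f"\n{name} — top 3:")
    print(top[["cpg", "cell_type", "statistic", "p_value"]]
          .to_string(index=False))
print("\nthe data were simulated Y|X: methylation drives the phenotype, so "
      "the Y|X test should rank the true entries highest")
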