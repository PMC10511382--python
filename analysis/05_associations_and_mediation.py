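#!/usr/bin/env python
"""Associations of processing speed with arousal indices in the patients.

Reads results/cohort.csv and, within the patient group: the Spearman
correlation matrix with BH-FDR, the two regression models predicting
processing speed C from pupillary unrest and mental fatigue (model 1) plus
covariates (model 2) with bootstrap CIs and their nested-model F-test, and
the mediation of the PUI–K association by C.  Writes
results/associations.json.
"""

import json
from pathlib import Path

from tva_arousal.io import read_cohort, write_json
from tva_arousal.stats_pipeline import (
    CORRELATION_VARIABLES,
    mediate,
    nested_model_f_test,
    ols_regression,
    spearman_matrix,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 5


def main() -> None:
    pat = read_cohort(OUT / "cohort.csv").query("group == 'patient'")
    corr = spearman_matrix(pat, CORRELATION_VARIABLES)
    for pair in [("C", "PUI"), ("C", "fatigue_mental"), ("PUI", "PD"), ("C", "K")]:
        a, b = pair
        print(f"rho({a}, {b}) = {corr.rho.loc[a, b]:6.3f}  "
              f"p_fdr = {corr.p_adjusted.loc[a, b]:.4f}")

    m1 = ols_regression(pat, "C", ["PUI", "fatigue_mental"], n_boot=1000, seed=SEED)
    m2 = ols_regression(
        pat, "C",
        ["PUI", "fatigue_mental", "depression", "sleepiness",
         "days_since_infection", "age"],
        n_boot=1000, seed=SEED,
    )
    F, dfs, p_nested = nested_model_f_test(m1, m2)
    print(f"model 1: R2={m1.R2:.3f} R2_adj={m1.R2_adj:.3f} f2={m1.f2:.2f} "
          f"p={m1.model_p:.2g}; b(PUI)={m1.b['PUI']:.2f} "
          f"b(fatigue)={m1.b['fatigue_mental']:.2f}")
    print(f"model 2: R2_adj={m2.R2_adj:.3f}; covariates add "
          f"F({dfs[0]}, {dfs[1]}) = {F:.2f}, p = {p_nested:.3f}")

    med = mediate(pat, "PUI", "C", "K", n_boot=1000, seed=SEED)
    print(f"mediation PUI -> C -> K: direct {med.direct:.3f} "
          f"CI [{med.direct_ci[0]:.3f}, {med.direct_ci[1]:.3f}]; "
          f"indirect {med.indirect:.3f} "
          f"CI [{med.indirect_ci[0]:.3f}, {med.indirect_ci[1]:.3f}]; "
          f"full mediation: {med.full_mediation}")

    write_json(
        {
            "spearman": {"rho": corr.rho.round(3).to_dict(),
                         "p_fdr": corr.p_adjusted.round(4).to_dict()},
            "model1": {"b": m1.b, "b_ci": m1.b_ci, "beta": m1.beta,
                       "R2": m1.R2, "R2_adj": m1.R2_adj, "f2": m1.f2,
                       "model_p": m1.model_p},
            "model2": {"b": m2.b, "R2_adj": m2.R2_adj, "model_p": m2.model_p},
            "nested_F": {"F": F, "df": dfs, "p": p_nested},
            "mediation": {"direct": med.direct, "direct_ci": med.direct_ci,
                          "indirect": med.indirect, "indirect_ci": med.indirect_ci,
                          "full_mediation": med.full_mediation},
        },
        OUT / "associations.json",
    )
    print(f"wrote {OUT / 'associations.json'}")


if __name__ == "__main__":
    main()
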