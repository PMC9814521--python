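"""Observed vs permuted-label AUC distributions (the chance-level control).

Reruns the whole discovery workflow with randomly shuffled case/control
labels; the pooled external AUCs estimate what the pipeline would report on
pure noise.  A rank-sum test then asks whether the observed distribution is
genuinely better than chance.
"""

import numpy as np

from cmpanel import (
    SimulationConfig, WorkflowConfig, generate_cohort,
    run_workflow_on_cohort, run_permuted, compare_distributions,
)

sim = SimulationConfig(n_cases=35, n_proteins=500, n_planted=5,
                       effect_size=1.0, seed=7)
matrices, cohort, _ = generate_cohort(sim)
status = cohort.drop_duplicates("sample_id").set_index("sample_id")["status"]
y = (status.loc[matrices["T2"].sample_ids] == "case").astype(int).to_numpy()

wf = WorkflowConfig(n_iterations=30, seed=1)
observed = run_workflow_on_cohort(matrices["T2"], cohort, wf)

# 5 permuted runs x 10 iterations each, a fresh label shuffle per run
perm_cfg = WorkflowConfig(n_iterations=10, seed=2)
permuted = run_permuted(matrices["T2"].values, y, perm_cfg, n_runs=5,
                        feature_names=matrices["T2"].protein_ids, seed=3)

comp = compare_distributions(observed.external_aucs, permuted)
print(f"observed mean AUC: {comp.observed_mean:.3f} "
      f"({len(comp.observed_aucs)} iterations)")
print(f"permuted mean AUC: {comp.permuted_mean:.3f} "
      f"({len(comp.permuted_aucs)} pooled iterations)")
print(f"{comp.test}: p = {comp.p_value:.3g}")
comp.density.to_csv("observed_vs_permuted_density.csv", index=False)
print("density curves written to observed_vs_permuted_density.csv "
      "(grid, observed_density, permuted_density) for plotting")
# A permuted mean near 0.5 with the observed mean well above it is the
# signature of real signal rather than pipeline overfitting.
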