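"""End-to-end: find the TFs that rewire between two phenotypes.

Simulates two-group expression data in which one TF pair swaps its target
sets between the control and case states, runs the full pipeline
(network per group -> transition matrix -> dTFI -> permutation null) and
prints the ranked dTFI table alongside the ground truth.
"""

import monster as ms

expr, prior, truth = ms.generate(p=200, m=10, targets_per_gene=2,
                                 n_per_group=(30, 30), effect_size=1.0,
                                 noise_sd=0.5, n_drivers=1,
                                 rewire_mode="swap", seed=3)
expr, prior = ms.harmonize(expr, prior)

observed = ms.observed_dtfi(expr, prior)          # alpha=0.5, OLS transition
null = ms.permutation_null(expr, prior, n_perm=100, seed=4)
table = ms.significance(observed, null, tf_ids=prior.tf_ids)

print(f"true rewired drivers: {sorted(truth.driver_tfs)}\n")
frame = table.to_frame().sort_values("dtfi", ascending=False)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

report = ms.score_recovery(table, truth)
print(f"\ndriver ranks in descending dTFI: {report.driver_ranks} "
      f"(recovered in top {report.top_k}: {report.success})")
print("-> the two swapped TFs carry the largest off-diagonal transition "
      "mass; their dTFI stands far above the permutation null, so they are "
      "flagged as candidate drivers of the state change.")
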