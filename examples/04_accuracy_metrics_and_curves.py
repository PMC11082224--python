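"""Estimate ratio-form accuracy metrics and weighted AUC/AUPRC from a run.

After a short active-testing run, the labeled subset is reweighted by the
kernel-estimated cumulative inclusion probabilities to estimate TPR, PPV
and the F1-type component ratio at a risk cutoff, plus AUC and AUPRC
integrated across all cutoffs — all from ~300 labels.
"""

from activetest import (
    ExperimentConfig,
    MetricSpec,
    SamplingPlan,
    SyntheticSpec,
    conventional_f1,
    full_data_benchmark,
    generate_pool,
    run_active_testing,
    weighted_curve_metrics,
)

pool = generate_pool(SyntheticSpec(n_records=2000, miscalibration=(0.0, 0.6), seed=7))
metrics = (MetricSpec("TPR", 0.5), MetricSpec("PPV", 0.5), MetricSpec("F1", 0.5))

config = ExperimentConfig(
    plan=SamplingPlan(total_steps=3, expected_subsample_size=100),
    estimators=("AIIPW",), prob_update="Ori", metrics=metrics,
    repetitions=1, seed=21)
frame, info = run_active_testing(pool, config)

final = frame[frame.step == 3].set_index("metric")["value"]
for spec in metrics:
    bench = full_data_benchmark(pool, spec)
    print(f"{spec.identifier}: estimate {final[spec.identifier]:.3f} "
          f"(full-data {bench:.3f})")
print(f"conventional F1 from the component ratio: "
      f"{conventional_f1(final['F1@0.5']):.3f}")

ledger = info["ledger"]
labels = pool.revealed_labels(ledger)
auc, auprc = weighted_curve_metrics(ledger, pool.scores, labels, info["inclusion"])
print(f"weighted AUC {auc:.3f}, weighted AUPRC {auprc:.3f} "
      f"from {ledger.n_labeled} labels")
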