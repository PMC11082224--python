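"""Generate a synthetic evaluation pool and compute full-data benchmarks.

The pool mimics the evaluation setting: a pre-trained binary classifier
whose training data is inaccessible, evaluated on N records where only
its scores are visible.  The evaluated model here is under-confident
(logit slope 0.6).  In simulation mode the hidden labels allow full-data
benchmark metrics, the ground truth that active testing tries to reach
with far fewer labels.
"""

from activetest import (
    LossSpec,
    MetricSpec,
    SyntheticSpec,
    full_data_benchmark,
    generate_pool,
)

pool = generate_pool(SyntheticSpec(n_records=2000, miscalibration=(0.0, 0.6), seed=7))
print(f"pool: N={pool.n_records}, binary scores in "
      f"[{pool.scores.min():.3f}, {pool.scores.max():.3f}]")

ce = full_data_benchmark(pool, LossSpec("cross_entropy"))
tpr = full_data_benchmark(pool, MetricSpec("TPR", cutoff=0.5))
ppv = full_data_benchmark(pool, MetricSpec("PPV", cutoff=0.5))
print(f"full-data cross-entropy benchmark: {ce:.4f}")
print(f"full-data TPR at cutoff 0.5:       {tpr:.4f}")
print(f"full-data PPV at cutoff 0.5:       {ppv:.4f}")
print("these are the targets the sequential estimators should recover "
      "from ~300 labels instead of 2000")
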