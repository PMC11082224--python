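"""Point estimators of model-performance metrics under active testing.

Three estimators of a mean loss M = E[L{g(X), Y}] from sequentially
labeled data:

* LUR — the levelled unbiased risk estimator, a step-weighted
  Horvitz-Thompson average over sampling rounds using the *true* per-round
  selection probabilities, with round weights
  w_j = N(N-s) / {(N-j)(N-j+1)} removing finite-pool bias;
* AILUR — the same form with the true per-round probabilities replaced by
  kernel-smoothed estimates computed on the previously-unlabeled support;
* AIIPW — a single inverse-probability-weighted average with weights given
  by a kernel-smoothed estimate of the cumulative inclusion expectation
  E{delta^s | g(X)}, so it needs no per-round probability history.

Ratio-form predictive-accuracy metrics D = E[d1] / E[d2] are estimated by
inverse-weighting both component sums; weighted AUC and AUPRC integrate
the resulting TPR/FPR/PPV across all cutoffs.
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    ContractError,
    LabelLedger,
    MetricSpec,
    UndefinedMetricError,
)

__all__ = [
    "lur_weight",
    "lur_estimate",
    "aiipw_estimate",
    "ipw_oracle_estimate",
    "aiipw_ratio_metric",
    "lur_ratio_metric",
    "weighted_curve_metrics",
]


def lur_weight(N: int, s: int, j: int) -> float:
    """Round weight w_j = N(N-s) / {(N-j)(N-j+1)} of the LUR estimator."""
    if not (1 <= j <= s):
        raise ContractError(f"need 1 <= j <= s, got j={j}, s={s}")
    if s >= N:
        raise ContractError(f"need s < N, got s={s}, N={N}")
    return N * (N - s) / ((N - j) * (N - j + 1))


def _selection_probs(ledger: LabelLedger, weight_source: str) -> np.ndarray:
    if weight_source == "true":
        probs = ledger.true_selection_prob
    elif weight_source == "estimated":
        probs = ledger.estimated_selection_prob
    else:
        raise ContractError(f"weight_source must be 'true' or 'estimated', got {weight_source!r}")
    labeled = ledger.labeled_mask
    if np.any(~np.isfinite(probs[labeled])):
        raise ContractError(f"missing {weight_source} selection probability for a labeled record")
    return probs


def _lur_weighted_sum(ledger: LabelLedger, values: np.ndarray, probs: np.ndarray) -> float:
    """sum_j w_j [ sum_{selected at j} v_i / pi_i + sum_{selected before j} v_i ].

    Exploits pi = 1 for previously labeled records, so only each record's
    own selection-step probability is needed.
    """
    N, s = ledger.n_records, ledger.step
    total = 0.0
    cum_prev = 0.0  # running sum of v over records selected before step j
    for j in range(1, s + 1):
        new_j = ledger.new_at_step(j)
        inner = float((values[new_j] / probs[new_j]).sum()) + cum_prev
        total += lur_weight(N, s, j) * inner
        cum_prev += float(values[new_j].sum())
    return total


def lur_estimate(ledger: LabelLedger, losses: np.ndarray, weight_source: str = "true") -> float:
    """LUR (weight_source='true') or AILUR (weight_source='estimated') loss estimate.

    ``losses`` is a full-length array; only labeled entries are read.
    """
    if ledger.step < 1:
        raise ContractError("no completed sampling step")
    losses = np.asarray(losses, dtype=float)
    probs = _selection_probs(ledger, weight_source)
    s, N = ledger.step, ledger.n_records
    return _lur_weighted_sum(ledger, losses, probs) / (s * N)


def aiipw_estimate(ledger: LabelLedger, losses: np.ndarray, inclusion_weights: np.ndarray) -> float:
    """AIIPW loss estimate (1/N) sum_i delta^s_i L_i / E_hat{delta^s_i | g(X_i)}.

    Consumes only the current cumulative indicator and weights — no
    per-round probability history.
    """
    losses = np.asarray(losses, dtype=float)
    w = np.asarray(inclusion_weights, dtype=float)
    labeled = ledger.labeled_mask
    if np.any(w[labeled] <= 0) or np.any(~np.isfinite(w[labeled])):
        raise ContractError("inclusion weights must be positive for labeled records")
    return float((losses[labeled] / w[labeled]).sum() / ledger.n_records)


def ipw_oracle_estimate(ledger: LabelLedger, losses: np.ndarray, true_inclusion: np.ndarray) -> float:
    """IPW estimate using the exact recursion weights E{delta^s | g(X)}.

    Simulation/testing oracle for the AIIPW estimator.
    """
    return aiipw_estimate(ledger, losses, true_inclusion)


def aiipw_ratio_metric(
    ledger: LabelLedger,
    spec: MetricSpec,
    scores: np.ndarray,
    labels: np.ndarray,
    inclusion_weights: np.ndarray,
) -> float:
    """AIIPW estimate of a ratio metric: weighted d1 sum over weighted d2 sum.

    ``scores`` and ``inclusion_weights`` are full-length; ``labels`` holds
    the labeled records' outcomes aligned to ``ledger.labeled_indices``.
    """
    labeled = ledger.labeled_mask
    w = np.asarray(inclusion_weights, dtype=float)[labeled]
    if np.any(w <= 0):
        raise ContractError("inclusion weights must be positive for labeled records")
    d1, d2 = spec.components(np.asarray(scores, dtype=float)[labeled], labels)
    den = float((d2 / w).sum())
    if den <= 0.0:
        raise UndefinedMetricError(
            f"metric {spec.identifier} undefined at step {ledger.step}: zero weighted d2 sum")
    return float((d1 / w).sum() / den)


def lur_ratio_metric(
    ledger: LabelLedger,
    spec: MetricSpec,
    scores: np.ndarray,
    labels: np.ndarray,
    weight_source: str = "true",
) -> float:
    """Ratio metric with LUR-form weighting of both component sums.

    Applies the step-weighted Horvitz-Thompson sum of the loss estimator to
    d1 and d2 separately and takes the ratio (the common 1/(sN) factors
    cancel).  This extends the loss-metric estimators to accuracy metrics
    in the natural way for the LUR/AILUR family.
    """
    if ledger.step < 1:
        raise ContractError("no completed sampling step")
    probs = _selection_probs(ledger, weight_source)
    scores = np.asarray(scores, dtype=float)
    d1_full = np.zeros(ledger.n_records)
    d2_full = np.zeros(ledger.n_records)
    labeled = ledger.labeled_mask
    d1, d2 = spec.components(scores[labeled], labels)
    d1_full[labeled], d2_full[labeled] = d1, d2
    num = _lur_weighted_sum(ledger, d1_full, probs)
    den = _lur_weighted_sum(ledger, d2_full, probs)
    if den <= 0.0:
        raise UndefinedMetricError(
            f"metric {spec.identifier} undefined at step {ledger.step}: zero weighted d2 sum")
    return num / den


def weighted_curve_metrics(
    ledger: LabelLedger,
    scores: np.ndarray,
    labels: np.ndarray,
    inclusion_weights: np.ndarray,
) -> tuple[float, float]:
    """Weighted AUC and AUPRC over the labeled records.

    Sweeps risk cutoffs at the distinct labeled score values plus the {0, 1}
    endpoints, computes inverse-probability-weighted TPR/FPR/PPV at each
    cutoff (strict '>' indicator), and integrates by the trapezoidal rule:
    AUC as TPR against FPR, AUPRC as PPV against TPR with the curve
    extended to TPR=0 at the PPV of the highest-score cutoff.
    """
    labeled = ledger.labeled_mask
    s = np.asarray(scores, dtype=float)[labeled]
    y = np.asarray(labels, dtype=float)
    w = 1.0 / np.asarray(inclusion_weights, dtype=float)[labeled]
    if y.shape != s.shape:
        raise ContractError("labels must align with the labeled records")
    if not ((y == 1).any() and (y == 0).any()):
        raise UndefinedMetricError("AUC/AUPRC need both classes among labeled records")
    pos_w = float((w * y).sum())
    neg_w = float((w * (1 - y)).sum())
    cutoffs = np.concatenate(([0.0], np.unique(s), [1.0]))
    tpr, fpr, ppv, ppw = [], [], [], []
    for c in cutoffs:
        above = s > c
        tp = float((w * above * y).sum())
        fp = float((w * above * (1 - y)).sum())
        pp = tp + fp
        tpr.append(tp / pos_w)
        fpr.append(fp / neg_w)
        ppv.append(tp / pp if pp > 0 else np.nan)
        ppw.append(pp)
    tpr, fpr, ppv = np.array(tpr), np.array(fpr), np.array(ppv)
    # ROC: ascending (FPR, TPR); equal-FPR ties order by TPR so horizontal
    # segments leave from the attained (maximal) TPR
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    # PR: keep cutoffs with positive predicted-positive mass, sort by TPR,
    # extend to TPR=0 at the PPV of the highest-score point
    keep = np.array(ppw) > 0
    t, p = tpr[keep], ppv[keep]
    # ascending TPR; descending PPV within a TPR tie, so each horizontal
    # segment enters a recall level at its attained (maximal) precision
    order = np.lexsort((-p, t))
    t, p = t[order], p[order]
    t = np.concatenate(([0.0], t))
    p = np.concatenate(([p[0]], p))
    auprc = float(np.trapezoid(p, t))
    return auc, auprc
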