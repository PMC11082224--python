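"""Synthetic evaluation pools with known ground truth.

The generator emulates the situation active testing is built for: a
pre-trained classifier whose training data is inaccessible, evaluated on a
pool where only covariates and the model's scores are visible.  Covariates
are spherical Gaussian; the true conditional outcome probabilities follow
a logistic (or softmax) model in the covariates; labels are drawn from
those probabilities and hidden behind the label oracle.  The evaluated
model's score is a controllably miscalibrated version of the truth:
score = sigmoid(a + b * logit(true prob)), so (a, b) = (0, 1) is a
perfectly calibrated model and b < 1 an under-confident one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax

from .datamodel import ConfigurationError, TestPool

#: default true-model coefficients (binary); linear predictor sd ~ 1.5
DEFAULT_COEF = (1.0, -0.8, 0.6, -0.4)


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of one synthetic evaluation pool.

    ``miscalibration = (a, b)`` distorts the evaluated model on the logit
    scale.  For multiclass pools the same distortion applies to the true
    class logits before the softmax (a shared temperature-style change).
    """

    n_records: int = 2000
    n_features: int = 4
    outcome: str = "binary"  # {"binary", "multiclass"}
    n_classes: int = 3
    coef: tuple = DEFAULT_COEF
    miscalibration: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigurationError("n_records must be positive")
        if self.outcome not in {"binary", "multiclass"}:
            raise ConfigurationError(f"unknown outcome kind {self.outcome!r}")
        if self.outcome == "multiclass" and self.n_classes < 2:
            raise ConfigurationError("multiclass pools need n_classes >= 2")
        coef = np.asarray(self.coef, dtype=float)
        if tuple(self.coef) == DEFAULT_COEF and self.n_features != len(DEFAULT_COEF):
            # adapt the default template to the requested dimension
            tiled = np.resize(np.asarray(DEFAULT_COEF), self.n_features)
            object.__setattr__(self, "coef", tuple(tiled))
            coef = tiled
        if self.outcome == "binary":
            if coef.shape != (self.n_features,):
                raise ConfigurationError("binary coef must have one entry per feature")
        else:
            if coef.ndim == 1:
                return  # per-feature template expanded per class at generation
            if coef.shape != (self.n_features, self.n_classes):
                raise ConfigurationError("multiclass coef must be (p, C)")


def _class_coef(spec: SyntheticSpec) -> np.ndarray:
    coef = np.asarray(spec.coef, dtype=float)
    if coef.ndim == 2:
        return coef
    # deterministic (p, C) expansion of the per-feature template: rotate the
    # template across classes so classes are separable but overlapping
    cols = [np.roll(coef, c) for c in range(spec.n_classes)]
    return np.column_stack(cols)


def generate_pool(spec: SyntheticSpec) -> TestPool:
    """Draw a pool with hidden labels and retained true probabilities."""
    rng = np.random.default_rng(spec.seed)
    a, b = spec.miscalibration
    x = rng.standard_normal((spec.n_records, spec.n_features))
    if spec.outcome == "binary":
        eta = x @ np.asarray(spec.coef, dtype=float)
        p_true = expit(eta)
        labels = (rng.random(spec.n_records) < p_true).astype(int)
        scores = expit(a + b * eta)  # eta is logit(p_true)
        true_probs = p_true
    else:
        logits = x @ _class_coef(spec)
        p_true = softmax(logits, axis=1)
        cum = np.cumsum(p_true, axis=1)
        u = rng.random(spec.n_records)[:, None]
        labels = 1 + (u > cum).sum(axis=1)
        scores = softmax(a + b * logits, axis=1)
        true_probs = p_true
    return TestPool.from_arrays(scores, labels=labels, covariates=x, true_probs=true_probs)


# ---------------------------------------------------------------------------
# Deterministic 8-record fixture with hand-computed reference values
# ---------------------------------------------------------------------------

FIXTURE_SCORES = (0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9)
FIXTURE_LABELS = (0, 0, 1, 0, 1, 0, 1, 1)

#: hand-computed reference values for the fixture (risk cutoff 0.5):
#:   cross_entropy = mean of -[y ln g + (1-y) ln(1-g)]
#:                 = (2 ln(10/9) + 2 ln(5/4) + 2 ln(10/3) + 2 ln(5/3)) / 8
#:   TPR: positives at scores {0.3, 0.6, 0.8, 0.9}, 3 of 4 above 0.5
#:   PPV: predicted positives {0.6, 0.7, 0.8, 0.9}, 3 true
#:   F1 component ratio TP / (PP + P) = 3 / (4 + 4)
FIXTURE_BENCHMARKS = {
    "cross_entropy": 0.5108256237659907,
    "squared_error": 0.175,
    "TPR@0.5": 0.75,
    "PPV@0.5": 0.75,
    "F1@0.5": 0.375,
}


def make_fixture() -> tuple[TestPool, dict[str, float]]:
    """The 8-record deterministic pool used across the unit tests."""
    pool = TestPool.from_arrays(np.array(FIXTURE_SCORES), labels=np.array(FIXTURE_LABELS))
    return pool, dict(FIXTURE_BENCHMARKS)
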