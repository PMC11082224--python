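"""Core data types for active testing of pre-trained classifiers.

The central objects are a :class:`TestPool` — the unlabeled evaluation set
carrying the evaluated model's prediction scores and a label oracle that
reveals an outcome only once the record has been selected for labeling —
and a :class:`LabelLedger` recording, step by step, which records were
labeled and with what selection probability.

Targets of estimation are either a mean loss E[L{g(X), Y}] (cross-entropy
or squared error; :class:`LossSpec`) or a ratio-form predictive-accuracy
metric E[d1{g(X),Y}] / E[d2{g(X),Y}] at a risk cutoff c (:class:`MetricSpec`)
— TPR, FPR, PPV, NPV and the F1-type ratio are expressed through their
component functions (d1, d2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: scores are clipped into [SCORE_CLIP, 1 - SCORE_CLIP] at ingestion so that
#: cross-entropy is always finite.
SCORE_CLIP = 1e-12

SIMPLEX_TOL = 1e-9


class ContractError(ValueError):
    """A documented precondition of an operation was violated."""


class ConfigurationError(ValueError):
    """An experiment or metric configuration is inconsistent."""


class UndefinedMetricError(ValueError):
    """A ratio metric's denominator is zero (metric undefined)."""


class UnlabeledAccessError(LookupError):
    """A label was requested for a record that has not been selected."""


# ---------------------------------------------------------------------------
# TestPool
# ---------------------------------------------------------------------------


@dataclass
class TestPool:
    """An evaluation pool of N records with scores and access-controlled labels.

    ``scores`` is ``(N,)`` for a binary model (P(Y=1|X) in (0,1)) or
    ``(N, C)`` for a C-class model (rows on the probability simplex).
    Binary labels are {0, 1}; multiclass labels are 1-based class indices
    mapped to score columns in input-column order.

    Labels are hidden behind the oracle methods: :meth:`label_of` and
    :meth:`revealed_labels` release a label only for records flagged as
    labeled in the accompanying :class:`LabelLedger`.  :meth:`full_labels`
    is the simulation-mode escape hatch used to compute benchmarks.
    """

    scores: np.ndarray
    _labels: np.ndarray | None = None
    covariates: np.ndarray | None = None
    true_probs: np.ndarray | None = None  # oracle tests only (simulation)
    n_clipped: int = 0

    @classmethod
    def from_arrays(
        cls,
        scores: np.ndarray,
        labels: np.ndarray | None = None,
        covariates: np.ndarray | None = None,
        true_probs: np.ndarray | None = None,
    ) -> "TestPool":
        scores = np.asarray(scores, dtype=float)
        if scores.ndim not in (1, 2):
            raise ContractError("scores must be a vector (binary) or matrix (multiclass)")
        n = scores.shape[0]
        if n < 1:
            raise ContractError("pool must contain at least one record")
        n_clipped = 0
        if scores.ndim == 1:
            if np.any(scores <= 0.0) or np.any(scores >= 1.0):
                bad = (scores <= 0.0) | (scores >= 1.0)
                n_clipped = int(bad.sum())
                logger.warning("clipped %d binary scores into (0, 1)", n_clipped)
                scores = np.clip(scores, SCORE_CLIP, 1.0 - SCORE_CLIP)
        else:
            if scores.shape[1] < 2:
                raise ContractError("multiclass scores need at least 2 classes")
            if np.any(scores < 0):
                raise ContractError("multiclass score components must be nonnegative")
            sums = scores.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > SIMPLEX_TOL):
                raise ContractError("multiclass score rows must sum to 1 within 1e-9")
            bad = (scores < SCORE_CLIP).any(axis=1)
            if bad.any():
                n_clipped = int(bad.sum())
                logger.warning("clipped %d multiclass score rows away from 0", n_clipped)
                scores = np.clip(scores, SCORE_CLIP, None)
                scores = scores / scores.sum(axis=1, keepdims=True)
        if labels is not None:
            labels = np.asarray(labels)
            if labels.shape[0] != n:
                raise ContractError("labels and scores must have equal length")
            if scores.ndim == 1:
                if not np.isin(labels, [0, 1]).all():
                    raise ContractError("binary labels must be in {0, 1}")
            else:
                c = scores.shape[1]
                if labels.min() < 1 or labels.max() > c:
                    raise ContractError(f"multiclass labels must be 1..{c}")
            labels = labels.astype(int)
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != n:
                raise ContractError("covariates and scores must have equal length")
        return cls(scores=scores, _labels=labels, covariates=covariates,
                   true_probs=true_probs, n_clipped=n_clipped)

    # -- basic shape queries ------------------------------------------------

    @property
    def n_records(self) -> int:
        return int(self.scores.shape[0])

    @property
    def is_multiclass(self) -> bool:
        return self.scores.ndim == 2

    @property
    def n_classes(self) -> int:
        return int(self.scores.shape[1]) if self.is_multiclass else 2

    # -- label oracle -------------------------------------------------------

    def label_of(self, index: int, ledger: "LabelLedger") -> int:
        """Reveal one record's label; raises unless the record is labeled."""
        if self._labels is None:
            raise ContractError("pool carries no labels (not in simulation mode)")
        if not ledger.cumulative_indicator[index]:
            raise UnlabeledAccessError(f"record {index} has not been selected for labeling")
        return int(self._labels[index])

    def revealed_labels(self, ledger: "LabelLedger") -> np.ndarray:
        """Labels of currently labeled records, aligned to ``ledger.labeled_indices``."""
        if self._labels is None:
            raise ContractError("pool carries no labels (not in simulation mode)")
        return self._labels[ledger.labeled_mask]

    def full_labels(self) -> np.ndarray:
        """All labels — simulation-mode only, for full-data benchmarks."""
        if self._labels is None:
            raise ContractError("full labels unavailable: pool not in simulation mode")
        return self._labels


# ---------------------------------------------------------------------------
# LabelLedger
# ---------------------------------------------------------------------------


@dataclass
class LabelLedger:
    """Per-step bookkeeping of the sequential labeling process.

    For each record i the ledger stores the cumulative inclusion indicator
    delta_i (monotone across steps: once labeled, always labeled), the step
    at which it was first selected, and the selection probability that
    applied at that step — the true Poisson probability and, once computed,
    its kernel-smoothed estimate.  Records selected at earlier steps carry
    probability one at later steps, so a single scalar per record suffices.
    """

    n_records: int
    step: int = 0
    cumulative_indicator: np.ndarray = field(default=None)  # type: ignore[assignment]
    selection_step: np.ndarray = field(default=None)  # type: ignore[assignment]
    true_selection_prob: np.ndarray = field(default=None)  # type: ignore[assignment]
    estimated_selection_prob: np.ndarray = field(default=None)  # type: ignore[assignment]
    per_step_new_count: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_records
        if n < 1:
            raise ContractError("ledger needs at least one record")
        if self.cumulative_indicator is None:
            self.cumulative_indicator = np.zeros(n, dtype=bool)
        if self.selection_step is None:
            self.selection_step = np.full(n, -1, dtype=int)
        if self.true_selection_prob is None:
            self.true_selection_prob = np.full(n, np.nan)
        if self.estimated_selection_prob is None:
            self.estimated_selection_prob = np.full(n, np.nan)

    # -- views --------------------------------------------------------------

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.cumulative_indicator

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.cumulative_indicator)

    @property
    def n_labeled(self) -> int:
        return int(self.cumulative_indicator.sum())

    def new_at_step(self, j: int) -> np.ndarray:
        """Boolean mask of records first selected at step j (1-based)."""
        return self.selection_step == j

    def unlabeled_before_current_step(self) -> np.ndarray:
        """Support mask for the step-selection kernel estimate: records that
        were unlabeled when the current step's draw was made."""
        if self.step == 0:
            return np.ones(self.n_records, dtype=bool)
        return (~self.cumulative_indicator) | (self.selection_step == self.step)

    # -- mutation -----------------------------------------------------------

    def record_step(self, new_mask: np.ndarray, true_probs: np.ndarray) -> None:
        """Record one completed sampling step.

        ``new_mask`` flags newly selected records (must be disjoint from the
        already-labeled set); ``true_probs`` gives, per newly selected
        record (in index order), the selection probability P{delta^s=1 |
        g^s(X)} that generated the draw.
        """
        new_mask = np.asarray(new_mask, dtype=bool)
        if new_mask.shape != (self.n_records,):
            raise ContractError("new_mask must be a full-length boolean mask")
        if np.any(new_mask & self.cumulative_indicator):
            raise ContractError("a record already labeled cannot be selected again")
        true_probs = np.asarray(true_probs, dtype=float)
        n_new = int(new_mask.sum())
        if true_probs.shape != (n_new,):
            raise ContractError("one selection probability per newly selected record")
        if n_new and (np.any(true_probs <= 0.0) or np.any(true_probs > 1.0)):
            raise ContractError("selection probabilities must lie in (0, 1]")
        self.step += 1
        self.cumulative_indicator = self.cumulative_indicator | new_mask
        self.selection_step[new_mask] = self.step
        self.true_selection_prob[new_mask] = true_probs
        self.per_step_new_count.append(n_new)

    def set_estimated_probs(self, mask: np.ndarray, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0.0) or np.any(values > 1.0):
            raise ContractError("estimated selection probabilities must lie in (0, 1]")
        self.estimated_selection_prob[mask] = values


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------


def cross_entropy_loss(score: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Pointwise cross-entropy of prediction(s) against observed label(s).

    Binary: -[y log g + (1-y) log(1-g)].  Multiclass: -log g_y where y is
    the (1-based) observed class.  Scores exactly at 0 or 1 are a domain
    error naming the offending record.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    scalar_out = label.ndim == 0
    if score.ndim == 1 and label.ndim == 0:
        if score.size > 1:  # single multiclass record given as a vector
            score = score[None, :]
        label = np.atleast_1d(label)
    elif score.ndim == 0:
        score, label = np.atleast_1d(score), np.atleast_1d(label)
    bad = (score <= 0.0) | (score >= 1.0)
    if bad.any():
        rec = int(np.flatnonzero(bad.reshape(score.shape[0], -1).any(axis=1))[0])
        raise ContractError(f"score exactly 0 or 1 at record index {rec}")
    if score.ndim == 1:
        y = label.astype(float)
        out = -(y * np.log(score) + (1.0 - y) * np.log1p(-score))
    else:
        idx = np.asarray(label, dtype=int) - 1
        if idx.min() < 0 or idx.max() >= score.shape[1]:
            raise ContractError("multiclass label outside 1..C")
        out = -np.log(score[np.arange(score.shape[0]), idx])
    return float(out[0]) if scalar_out else out


def squared_error_loss(score: np.ndarray, label: np.ndarray) -> np.ndarray:
    """(g - y)^2 for binary; squared distance to the one-hot label otherwise."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    if score.ndim == 1 or score.ndim == 0:
        return (score - label.astype(float)) ** 2
    onehot = np.zeros_like(score)
    onehot[np.arange(score.shape[0]), np.asarray(label, dtype=int) - 1] = 1.0
    return ((score - onehot) ** 2).sum(axis=1)


@dataclass(frozen=True)
class LossSpec:
    """A pointwise loss defining the target M = E[L{g(X), Y}]."""

    name: str = "cross_entropy"

    _FUNCS = {"cross_entropy": cross_entropy_loss, "squared_error": squared_error_loss}

    def __post_init__(self) -> None:
        if self.name not in self._FUNCS:
            raise ConfigurationError(f"unknown loss {self.name!r}")

    def pointwise(self, scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
        return np.atleast_1d(self._FUNCS[self.name](scores, labels))

    @property
    def identifier(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# Ratio metrics (d1, d2) at a risk cutoff
# ---------------------------------------------------------------------------

# component tables: each entry maps (z1=score, z2=label, c=cutoff) -> value.
_METRIC_TABLE: dict[str, tuple[Callable, Callable]] = {
    # strict inequality z1 > c throughout (z1 < c for NPV), boundary counts
    # as "not above".
    "TPR": (lambda z1, z2, c: (z1 > c) * z2, lambda z1, z2, c: z2),
    "FPR": (lambda z1, z2, c: (z1 > c) * (1 - z2), lambda z1, z2, c: (1 - z2)),
    "PPV": (lambda z1, z2, c: (z1 > c) * z2, lambda z1, z2, c: (z1 > c) * 1.0),
    "NPV": (lambda z1, z2, c: (z1 < c) * (1 - z2), lambda z1, z2, c: (z1 < c) * 1.0),
    "F1": (lambda z1, z2, c: (z1 > c) * z2, lambda z1, z2, c: (z1 > c) + z2),
}


@dataclass(frozen=True)
class MetricSpec:
    """A ratio metric D = E[d1{g(X),Y}] / E[d2{g(X),Y}] at risk cutoff c.

    Built-in names cover TPR, FPR, PPV, NPV and the F1-type ratio whose
    components are d1 = I(z1>c) z2 and d2 = I(z1>c) + z2; the conventional
    F1 = 2 TP / (predicted-positive + positive) equals twice that ratio
    (see :func:`conventional_f1`).  Custom component functions may be
    supplied instead of a name.
    """

    name: str = "TPR"
    cutoff: float = 0.5
    d1: Callable | None = None
    d2: Callable | None = None

    def __post_init__(self) -> None:
        if (self.d1 is None) != (self.d2 is None):
            raise ConfigurationError("custom metrics must supply both d1 and d2")
        if self.d1 is None and self.name not in _METRIC_TABLE:
            raise ConfigurationError(f"unknown metric {self.name!r}")
        if not 0.0 < self.cutoff < 1.0:
            raise ConfigurationError("cutoff must lie strictly inside (0, 1)")

    def components(self, scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=float)
        if scores.ndim != 1:
            raise ContractError("ratio metrics are defined for binary scores")
        if self.d1 is not None:
            d1 = np.asarray(self.d1(scores, labels, self.cutoff), dtype=float)
            d2 = np.asarray(self.d2(scores, labels, self.cutoff), dtype=float)
        else:
            f1, f2 = _METRIC_TABLE[self.name]
            d1 = np.asarray(f1(scores, labels, self.cutoff), dtype=float)
            d2 = np.asarray(f2(scores, labels, self.cutoff), dtype=float)
        if np.any(d1 < 0) or np.any(d2 < 0) or not (np.isfinite(d1).all() and np.isfinite(d2).all()):
            raise ContractError("metric components must be nonnegative and finite")
        return d1, d2

    @property
    def identifier(self) -> str:
        return f"{self.name}@{self.cutoff:g}"


def metric_components(spec: MetricSpec, score, label) -> tuple[float, float]:
    """Evaluate one record's (d1, d2) components under ``spec``."""
    d1, d2 = spec.components(np.atleast_1d(score), np.atleast_1d(label))
    return float(d1[0]), float(d2[0])


def conventional_f1(table_ratio: float) -> float:
    """Conventional F1 from the component-table ratio TP/(PP + P): exactly 2x."""
    return 2.0 * table_ratio


# ---------------------------------------------------------------------------
# Full-data benchmark (simulation ground truth)
# ---------------------------------------------------------------------------


def full_data_benchmark(pool: TestPool, target: LossSpec | MetricSpec) -> float:
    """Target value computed from all N labels (simulation mode only)."""
    labels = pool.full_labels()
    if isinstance(target, LossSpec):
        return float(np.mean(target.pointwise(pool.scores, labels)))
    d1, d2 = target.components(pool.scores, labels)
    den = d2.sum()
    if den <= 0:
        raise UndefinedMetricError(f"metric {target.identifier} undefined: zero d2 sum")
    return float(d1.sum() / den)


# ---------------------------------------------------------------------------
# Score-table CSV contract
# ---------------------------------------------------------------------------


def read_score_table(path) -> TestPool:
    """Read a score-table CSV: columns ``id``, ``score`` (binary) or
    ``score_1..score_C`` (multiclass), optional ``label``, optional
    covariates ``x_*``."""
    df = pd.read_csv(path)
    score_cols = sorted([c for c in df.columns if c.startswith("score_")],
                        key=lambda c: int(c.split("_")[1]))
    if "score" in df.columns:
        scores = df["score"].to_numpy(float)
    elif score_cols:
        scores = df[score_cols].to_numpy(float)
    else:
        raise ConfigurationError("score table needs a 'score' or 'score_1..C' columns")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    x_cols = [c for c in df.columns if c.startswith("x_")]
    covariates = df[x_cols].to_numpy(float) if x_cols else None
    return TestPool.from_arrays(scores, labels=labels, covariates=covariates)


def write_score_table(pool: TestPool, path, include_labels: bool = True) -> None:
    """Write a pool under the score-table CSV contract."""
    data: dict[str, Sequence] = {"id": np.arange(pool.n_records)}
    if pool.is_multiclass:
        for c in range(pool.n_classes):
            data[f"score_{c + 1}"] = pool.scores[:, c]
    else:
        data["score"] = pool.scores
    if include_labels and pool._labels is not None:
        data["label"] = pool._labels
    if pool.covariates is not None:
        for j in range(pool.covariates.shape[1]):
            data[f"x_{j + 1}"] = pool.covariates[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
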