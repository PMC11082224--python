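"""Sampling probabilities and selection schemes for active testing.

Each sampling step turns per-record expected-loss scores into selection
probabilities for the currently-unlabeled records (entropy sampling:
probability proportional to the expected cross-entropy of the evaluated
model under plug-in outcome probabilities), then draws a new labeled batch
under a Poisson scheme (independent Bernoulli selections with expected
batch size n_s), an optional without-replacement scheme, or uniformly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ConfigurationError, ContractError

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1e-3


@dataclass(frozen=True)
class SamplingPlan:
    """The per-step sampling design: scheme, expected batch size n_s per
    step, probability floor, total number of steps S and base seed."""

    scheme: str = "poisson"  # {"poisson", "swr", "uniform"}
    expected_subsample_size: int = 100
    probability_floor: float = DEFAULT_FLOOR
    total_steps: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in {"poisson", "swr", "uniform"}:
            raise ConfigurationError(f"unknown sampling scheme {self.scheme!r}")
        if self.expected_subsample_size < 1:
            raise ConfigurationError("expected subsample size must be positive")
        if not 0.0 < self.probability_floor < 1.0:
            raise ConfigurationError("probability floor must lie in (0, 1)")
        if self.total_steps < 1:
            raise ConfigurationError("total_steps must be >= 1")


@dataclass
class SamplingProbabilities:
    """Selection probabilities for the currently-unlabeled records at one step.

    ``alpha`` is the final proportional scale: the emitted probability of a
    record with raw score t is clip(alpha * t, floor, 1), which makes each
    step's realized probability a closed-form function of the raw score
    (used by the exact inclusion recursion).
    """

    values: np.ndarray
    step: int = 0
    alpha: float | None = None
    floor: float = DEFAULT_FLOOR
    uniform_value: float | None = None

    def prob_of_raw_score(self, raw: np.ndarray) -> np.ndarray:
        """Probability this step would have assigned to a raw score value."""
        if self.uniform_value is not None:
            return np.full(np.shape(raw), self.uniform_value)
        if self.alpha is None:
            raise ContractError("no scale recorded for this probability set")
        return np.clip(self.alpha * np.asarray(raw, dtype=float), self.floor, 1.0)


def expected_loss_score(scores: np.ndarray, reference_probs: np.ndarray) -> np.ndarray:
    """Expected cross-entropy of the evaluated model under plug-in outcome
    probabilities — the (nonnegative) entropy-sampling score.

    Binary: -[p log g + (1-p) log(1-g)]; multiclass: -sum_c p_c log g_c.
    Larger expected loss means a record is more informative to label.
    """
    g = np.asarray(scores, dtype=float)
    p = np.asarray(reference_probs, dtype=float)
    if g.shape != p.shape:
        raise ContractError(f"scores {g.shape} and reference probs {p.shape} differ in shape")
    if np.any(g <= 0) or np.any(g >= 1):
        raise ContractError("scores must lie strictly inside (0, 1)")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ContractError("reference probabilities must lie strictly inside (0, 1)")
    if g.ndim == 2:
        return -(p * np.log(g)).sum(axis=1)
    return -(p * np.log(g) + (1.0 - p) * np.log1p(-g))


def normalize_to_probabilities(
    raw_scores: np.ndarray,
    n_s: int,
    floor: float = DEFAULT_FLOOR,
    step: int = 0,
) -> SamplingProbabilities:
    """Scale nonnegative raw scores to selection probabilities summing to n_s.

    Proportional scaling with iterative capping: probabilities exceeding 1
    are fixed at 1 and the residual expected count is redistributed over the
    uncapped records until no cap binds; the composition of the passes is a
    single final scale alpha, so p_i = min(1, alpha * score_i).  Values
    below the floor are then raised to the floor (excess expected count is
    logged, not rebalanced).
    """
    raw = np.asarray(raw_scores, dtype=float)
    m = raw.size
    if n_s > m:
        raise ContractError(f"n_s={n_s} exceeds the {m} unlabeled records")
    if np.any(raw < 0) or not np.isfinite(raw).all():
        raise ContractError("raw scores must be finite and nonnegative")
    total = raw.sum()
    if total <= 0.0:
        warnings.warn("all raw sampling scores are zero; falling back to uniform")
        return uniform_probabilities(m, n_s, step=step)
    capped = np.zeros(m, dtype=bool)
    alpha = float(n_s) / total
    while True:
        residual = float(n_s) - float(capped.sum())
        denom = raw[~capped].sum()
        if residual <= 0.0 or denom <= 0.0:
            break
        alpha = residual / denom
        newly = ~capped & (alpha * raw > 1.0)
        if not newly.any():
            break
        capped |= newly
    probs = np.minimum(1.0, alpha * raw)
    below = probs < floor
    if below.any():
        excess = float((floor - probs[below]).sum())
        logger.info("floor raised %d probabilities (excess expected count %.4g)",
                    int(below.sum()), excess)
        probs = np.maximum(probs, floor)
    return SamplingProbabilities(values=probs, step=step, alpha=alpha, floor=floor)


def uniform_probabilities(m: int, n_s: int, step: int = 0) -> SamplingProbabilities:
    """Constant probability n_s / m for each of the m unlabeled records."""
    if n_s > m:
        raise ContractError(f"n_s={n_s} exceeds the {m} unlabeled records")
    value = n_s / m
    return SamplingProbabilities(values=np.full(m, value), step=step,
                                 alpha=None, floor=min(value, DEFAULT_FLOOR),
                                 uniform_value=value)


def poisson_draw(probs: SamplingProbabilities, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draws; realized count is random with mean sum(p)."""
    p = probs.values
    if np.any(p <= 0) or np.any(p > 1):
        raise ContractError("probabilities must lie in (0, 1]")
    return rng.random(p.size) < p


def swr_draw(
    raw_scores: np.ndarray, n_s: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential sampling without replacement, proportional to raw scores.

    Returns (selection mask, per-selected approximate first-order inclusion
    probability n_s * score / sum(score), capped into (0, 1]).  The
    approximation is documented: exact joint inclusion probabilities under
    sequential proportional draws are not computed.
    """
    raw = np.asarray(raw_scores, dtype=float)
    m = raw.size
    if n_s > m:
        raise ContractError(f"n_s={n_s} exceeds the {m} available records")
    if np.any(raw < 0):
        raise ContractError("raw scores must be nonnegative")
    total = raw.sum()
    if total <= 0:
        p = np.full(m, 1.0 / m)
    else:
        p = raw / total
    positive = int((p > 0).sum())
    if positive < n_s:
        # not enough positive-score records: pad with uniform mass
        p = (p + 1e-12) / (p + 1e-12).sum()
    chosen = rng.choice(m, size=n_s, replace=False, p=p)
    mask = np.zeros(m, dtype=bool)
    mask[chosen] = True
    if total <= 0:
        incl = np.full(n_s, min(1.0, n_s / m))
    else:
        incl = np.clip(n_s * raw[mask] / total, 1e-12, 1.0)
    return mask, incl
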