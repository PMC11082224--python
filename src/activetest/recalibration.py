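"""One-parameter model recalibration driving the "Rec" sampling scheme.

The recalibration parameter theta solves the weighted estimating equation

    sum_i delta^s_i g(X_i) [Y_i - h{theta g(X_i)}] / E_hat{delta^s_i|g(X_i)} = 0

with h the logistic link (or identity for a linear model).  The
recalibrated probabilities h(theta_hat g) replace the raw scores as the
plug-in outcome probabilities when updating the sampling probabilities.
Note the link is applied to theta times the *probability-scale* score; a
logit-scale variant is exposed as a non-default option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .datamodel import ContractError

logger = logging.getLogger(__name__)

THETA_MAX = 20.0
RESIDUAL_TOL = 1e-8
PROB_CLIP = 1e-3


@dataclass(frozen=True)
class RecalibrationFit:
    """Solution of the recalibration estimating equation at one step."""

    theta: float
    link: str = "logistic"
    step: int = 0
    converged: bool = True
    fallback_used: bool = False
    residual: float = 0.0
    input_scale: str = "probability"


def _link(link: str):
    if link == "logistic":
        return expit
    if link == "linear":
        return lambda u: u
    raise ContractError(f"unknown link {link!r}")


def solve_recalibration(
    labeled_labels: np.ndarray,
    labeled_scores: np.ndarray,
    inclusion_weights: np.ndarray,
    link: str = "logistic",
    theta_max: float = THETA_MAX,
    step: int = 0,
    input_scale: str = "probability",
) -> RecalibrationFit:
    """Solve the weighted estimating equation for theta by scalar root finding.

    For the logistic link the residual theta -> sum w g (y - h(theta g)) is
    continuous and strictly decreasing (h increasing, g > 0), so a sign
    change on [-theta_max, theta_max] brackets the unique root.  One-class
    labeled sets have no finite root: theta is capped at +/- theta_max with
    ``fallback_used`` set, as is a residual that cannot be bracketed.
    """
    y = np.asarray(labeled_labels, dtype=float)
    g = np.asarray(labeled_scores, dtype=float)
    w = 1.0 / np.asarray(inclusion_weights, dtype=float)
    if not (y.shape == g.shape == w.shape):
        raise ContractError("labels, scores and weights must align")
    if np.any(np.asarray(inclusion_weights) <= 0):
        raise ContractError("inclusion weights must be positive")
    if input_scale == "logit":
        u = np.log(g) - np.log1p(-g)
    elif input_scale == "probability":
        u = g
    else:
        raise ContractError(f"unknown input_scale {input_scale!r}")
    h = _link(link)

    def residual(theta: float) -> float:
        return float((w * u * (y - h(theta * u))).sum())

    if link == "linear":
        denom = float((w * u * u).sum())
        if denom <= 0:
            raise ContractError("degenerate scores: zero weighted sum of squares")
        theta = float((w * u * y).sum()) / denom
        return RecalibrationFit(theta=theta, link=link, step=step,
                                converged=True, residual=residual(theta),
                                input_scale=input_scale)
    lo, hi = residual(-theta_max), residual(theta_max)
    if lo * hi > 0:
        # no sign change on the cap interval (e.g., one-class labeled set)
        theta = theta_max if hi > 0 else -theta_max
        logger.warning("recalibration root not bracketable; capping theta at %+g", theta)
        return RecalibrationFit(theta=theta, link=link, step=step, converged=False,
                                fallback_used=True, residual=residual(theta),
                                input_scale=input_scale)
    theta = float(brentq(residual, -theta_max, theta_max, xtol=1e-12, rtol=8.9e-16))
    res = residual(theta)
    return RecalibrationFit(theta=theta, link=link, step=step,
                            converged=abs(res) <= RESIDUAL_TOL, residual=res,
                            input_scale=input_scale)


def recalibrated_probs(fit: RecalibrationFit, scores: np.ndarray,
                       clip: float = PROB_CLIP) -> np.ndarray:
    """Recalibrated outcome probabilities h(theta_hat g), clipped to (clip, 1-clip).

    These feed the entropy-sampling score as the plug-in P(Y=1|X) under the
    "Rec" scheme.
    """
    g = np.asarray(scores, dtype=float)
    if fit.input_scale == "logit":
        g = np.log(g) - np.log1p(-g)
    h = _link(fit.link)
    return np.clip(h(fit.theta * g), clip, 1.0 - clip)


def multiclass_recalibrated_probs(
    labeled_labels: np.ndarray,
    labeled_scores: np.ndarray,
    inclusion_weights: np.ndarray,
    pool_scores: np.ndarray,
    theta_max: float = THETA_MAX,
    step: int = 0,
) -> np.ndarray:
    """One-vs-rest recalibration of multiclass score vectors (stand-in).

    Applies the scalar estimating equation to each class's score against
    the one-vs-rest outcome indicator and renormalizes the recalibrated
    class probabilities to the simplex.  The per-class link acts on the
    logit of the class score, so already-calibrated scores are (near) a
    fixed point (theta = 1 reproduces them), which the probability-scale
    link cannot do.  A class absent from the labeled data keeps its raw
    scores (identity recalibration), logged.
    """
    y = np.asarray(labeled_labels, dtype=int)
    s = np.asarray(labeled_scores, dtype=float)
    if s.ndim != 2:
        raise ContractError("multiclass recalibration needs score matrices")
    n_classes = s.shape[1]
    if np.unique(y).size < 2:
        raise ContractError("need at least two classes among labeled records")
    pool = np.asarray(pool_scores, dtype=float)
    out = np.empty_like(pool)
    for c in range(n_classes):
        y_c = (y == c + 1).astype(float)
        if y_c.sum() == 0:
            # no information for this class: pass its scores through unchanged
            logger.warning("class %d absent from labeled data; identity recalibration", c + 1)
            out[:, c] = np.clip(pool[:, c], PROB_CLIP, 1.0 - PROB_CLIP)
            continue
        fit = solve_recalibration(y_c, s[:, c], inclusion_weights,
                                  link="logistic", theta_max=theta_max, step=step,
                                  input_scale="logit")
        out[:, c] = recalibrated_probs(fit, pool[:, c])
    return out / out.sum(axis=1, keepdims=True)
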