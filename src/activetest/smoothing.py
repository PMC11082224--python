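"""Nadaraya-Watson kernel regression of selection indicators on model scores.

Two smoothed quantities drive the actively-improved estimators: the
per-step selection probability P{delta^s = 1 | g^s(X)} estimated on the
records that were still unlabeled before the step (AILUR weights), and the
cumulative inclusion expectation E{delta^s | g(X)} estimated over the whole
pool (AIIPW weights).  The exact product-form recursion for the cumulative
inclusion probability is implemented alongside as a testing oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .datamodel import ContractError, LabelLedger
from .sampling import DEFAULT_FLOOR

logger = logging.getLogger(__name__)

#: bandwidth returned when the support has zero spread
DEGENERATE_BANDWIDTH = 1e-2


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) m^(-1/5).

    Uses the sample standard deviation (ddof=1).  If one spread measure is
    zero the other is used; if both are zero the documented fallback
    constant is returned with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ContractError("bandwidth needs at least two values")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    tiny = 1e-9 * max(1.0, float(np.abs(x).max()))
    candidates = [c for c in (sd, iqr / 1.34) if c > tiny]
    if not candidates:
        warnings.warn("zero spread in bandwidth support; using fallback constant")
        return DEGENERATE_BANDWIDTH
    return 0.9 * min(candidates) * x.size ** (-0.2)


def _gaussian(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


_KERNELS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "gaussian": _gaussian,
    "epanechnikov": _epanechnikov,
}

#: variance-matched self-inclusion weight: integral of K^2 over K(0).  When a
#: 0/1 response is smoothed and the fit is then inverted as a weight at the
#: response's own support point, full self-inclusion (weight 1) correlates the
#: estimate with the record's own indicator (downward-biasing the inverse
#: weight) while leaving it out entirely exposes the Jensen convexity of
#: x -> 1/x (upward bias).  The two leading-order terms cancel when the self
#: term enters with weight int K^2 / K(0): 1/sqrt(2) for the Gaussian kernel,
#: 0.8 for Epanechnikov.
_SELF_WEIGHT = {"gaussian": 1.0 / np.sqrt(2.0), "epanechnikov": 0.8}


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and bandwidth rule for the weight smoother.

    ``bandwidth`` fixes b directly; otherwise ``rule='silverman'`` resolves
    it from the support each time.  ``grid``, when set, evaluates the
    regression on that many equispaced points spanning the support and
    linearly interpolates — an O(support x grid) approximation used by the
    experiment harness on large pools.
    """

    kernel: str = "gaussian"
    bandwidth: float | None = None
    rule: str = "silverman"
    grid: int | None = None
    self_weight: float | str = 1.0
    bandwidth_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ContractError(f"unknown kernel {self.kernel!r}")
        if isinstance(self.self_weight, str) and self.self_weight != "matched":
            raise ContractError("self_weight must be a number or 'matched'")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ContractError("bandwidth must be positive")
        if self.bandwidth is None and self.rule not in {"silverman", "fixed"}:
            raise ContractError(f"unknown bandwidth rule {self.rule!r}")
        if self.bandwidth is None and self.rule == "fixed":
            raise ContractError("rule 'fixed' requires an explicit bandwidth")

    def resolve_bandwidth(self, support: np.ndarray) -> float:
        if self.bandwidth is not None:
            return float(self.bandwidth) * self.bandwidth_scale
        return silverman_bandwidth(support) * self.bandwidth_scale


def nw_regress(
    responses: np.ndarray,
    covariate: np.ndarray,
    queries: np.ndarray,
    spec: KernelSpec = KernelSpec(),
) -> np.ndarray:
    """Nadaraya-Watson estimate sum_i r_i K_b(x_i - z) / sum_i K_b(x_i - z).

    For 0/1 responses the output lies in [0, 1].  Zero denominators
    (possible for compact kernels) fall back to the global response mean
    with a logged warning.
    """
    r = np.asarray(responses, dtype=float)
    x = np.asarray(covariate, dtype=float)
    z = np.atleast_1d(np.asarray(queries, dtype=float))
    if r.size == 0 or x.size == 0:
        raise ContractError("kernel regression needs a nonempty support")
    if r.shape != x.shape:
        raise ContractError("responses and covariate must align")
    if x.size == 1:
        return np.full(z.shape, float(r[0]))
    b = spec.resolve_bandwidth(x)
    kern = _KERNELS[spec.kernel]
    if spec.grid is not None and z.size > spec.grid:
        lo, hi = float(x.min()), float(x.max())
        lo, hi = min(lo, z.min()), max(hi, z.max())
        pts = np.linspace(lo, hi, spec.grid)
        vals = _nw_exact(r, x, pts, b, kern)
        return np.interp(z, pts, vals)
    return _nw_exact(r, x, z, b, kern)


def _nw_sums(r, x, z, b, kern) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-weighted numerator and denominator sums at each query point,
    chunked to bound the (queries x support) kernel matrix."""
    num = np.empty(z.size)
    den = np.empty(z.size)
    chunk = max(1, int(8_000_000 // max(1, x.size)))
    for start in range(0, z.size, chunk):
        w = kern((x[None, :] - z[start:start + chunk, None]) / b)
        den[start:start + chunk] = w.sum(axis=1)
        num[start:start + chunk] = w @ r
    return num, den


def _nw_exact(r, x, z, b, kern) -> np.ndarray:
    num, den = _nw_sums(r, x, z, b, kern)
    bad = den <= 0.0
    if bad.any():
        logger.warning("zero kernel denominator at %d queries; using support mean",
                       int(bad.sum()))
        den[bad] = 1.0
        num[bad] = float(r.mean())
    return num / den


def nw_self_regress(
    responses: np.ndarray,
    covariate: np.ndarray,
    spec: KernelSpec = KernelSpec(),
) -> np.ndarray:
    """NW regression evaluated at each support point's own covariate value.

    The self term enters with weight ``spec.self_weight``: 1 (default) is
    the plain estimator whose sums run over all support records;
    ``"matched"`` applies the variance-matched factor used where the
    fitted value is inverted into a sampling weight at the record's own
    position (see ``_SELF_WEIGHT`` for the rationale).
    """
    r = np.asarray(responses, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if r.size == 0:
        raise ContractError("kernel regression needs a nonempty support")
    if r.shape != x.shape:
        raise ContractError("responses and covariate must align")
    if x.size == 1:
        return np.array([float(r[0])])
    b = spec.resolve_bandwidth(x)
    kern = _KERNELS[spec.kernel]
    k0 = float(kern(np.zeros(1))[0])
    gamma = (_SELF_WEIGHT[spec.kernel] if spec.self_weight == "matched"
             else float(spec.self_weight))
    if spec.grid is not None and x.size > spec.grid:
        pts = np.linspace(float(x.min()), float(x.max()), spec.grid)
        num_g, den_g = _nw_sums(r, x, pts, b, kern)
        num = np.interp(x, pts, num_g)
        den = np.interp(x, pts, den_g)
    else:
        num, den = _nw_sums(r, x, x, b, kern)
    num = num + (gamma - 1.0) * k0 * r
    den = den + (gamma - 1.0) * k0
    bad = den <= 0.0
    if bad.any():
        logger.warning("zero kernel denominator at %d queries; using support mean",
                       int(bad.sum()))
        den[bad] = 1.0
        num[bad] = float(r.mean())
    return num / den


def estimate_step_selection_prob(
    ledger: LabelLedger,
    step_scores: np.ndarray,
    spec: KernelSpec = KernelSpec(),
    floor: float = DEFAULT_FLOOR,
    store: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel estimate of the just-completed step's selection probability.

    Regresses the new-selection indicator delta^s (1 - delta^{s-1}) on the
    step's conditioning score over the records that were unlabeled before
    the step, evaluated at each such record's own score.  Estimates are
    clipped to [floor, 1] and, when ``store`` is set, written into the
    ledger for the records selected at this step.

    Returns (support index array, estimates aligned with it).
    """
    if ledger.step < 1:
        raise ContractError("no completed sampling step to estimate")
    support_mask = ledger.unlabeled_before_current_step()
    if not support_mask.any():
        raise ContractError("no previously-unlabeled records at this step")
    step_scores = np.asarray(step_scores, dtype=float)
    x = step_scores[support_mask]
    newly = ledger.new_at_step(ledger.step)[support_mask].astype(float)
    est = np.clip(nw_self_regress(newly, x, spec), floor, 1.0)
    support_idx = np.flatnonzero(support_mask)
    if store:
        new_mask = ledger.new_at_step(ledger.step)
        pos = np.flatnonzero(new_mask[support_mask])
        ledger.set_estimated_probs(support_idx[pos], est[pos])
    return support_idx, est


def estimate_cumulative_inclusion(
    ledger: LabelLedger,
    base_scores: np.ndarray,
    spec: KernelSpec = KernelSpec(),
    floor: float = DEFAULT_FLOOR,
) -> np.ndarray:
    """Kernel estimate of E{delta^s | g(X)} over all N records.

    The conditioning covariate is the *original* model score (valid when
    every step's sampling probability was a function of g).  Output is
    clipped to [floor, 1].
    """
    if ledger.n_labeled == 0:
        raise ContractError("no labeled records: cumulative inclusion undefined")
    x = np.asarray(base_scores, dtype=float)
    if x.shape != (ledger.n_records,):
        raise ContractError("base_scores must be a scalar covariate per record")
    est = nw_self_regress(ledger.cumulative_indicator.astype(float), x, spec)
    return np.clip(est, floor, 1.0)


def true_cumulative_inclusion(
    history: Sequence[Callable[[np.ndarray], np.ndarray]],
    base_scores: np.ndarray,
) -> np.ndarray:
    """Exact recursion for E{delta^s | g(X)} from per-step probability functions.

    ``history`` holds, for steps 1..s, a function mapping the conditioning
    score to that step's selection probability (a precomputed per-record
    probability array is also accepted).  The recursion is
    E{delta^1|g} = q_1(g) and, for s > 1,
    E{delta^s|g} = E{delta^{s-1}|g} + q_s(g) prod_{j<s} (1 - q_j(g)).
    """
    if not len(history):
        raise ContractError("history must contain at least one step function")
    g = np.asarray(base_scores, dtype=float)
    expect = None
    surv = np.ones_like(g, dtype=float)
    for fn in history:
        if fn is None:
            raise ContractError("missing step probability function")
        q = np.asarray(fn(g) if callable(fn) else fn, dtype=float)
        if q.shape != g.shape:
            raise ContractError("step probabilities must align with base scores")
        q = np.clip(q, 0.0, 1.0)
        if expect is None:
            expect = q.copy()
        else:
            expect = expect + q * surv
        surv = surv * (1.0 - q)
    return np.clip(expect, 0.0, 1.0)
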