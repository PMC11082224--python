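"""End-to-end active-testing loop and the repetition experiment harness.

One repetition iterates S sampling steps: build selection probabilities
over the unlabeled records from the current plug-in outcome model, draw a
new labeled batch, refresh the kernel-smoothed weight estimates, compute
every configured estimator on the accumulated labeled data, and (under the
"Rec" scheme) refit the recalibration parameter to sharpen the next step's
probabilities.  The harness repeats this R times against a fixed (or
regenerated) pool and aggregates root-mean-square error curves and
relative-efficiency tables against the full-data benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigurationError,
    ContractError,
    LabelLedger,
    LossSpec,
    MetricSpec,
    TestPool,
    full_data_benchmark,
)
from .estimators import (
    aiipw_estimate,
    aiipw_ratio_metric,
    ipw_oracle_estimate,
    lur_estimate,
    lur_ratio_metric,
)
from .recalibration import (
    multiclass_recalibrated_probs,
    recalibrated_probs,
    solve_recalibration,
)
from .sampling import (
    SamplingPlan,
    expected_loss_score,
    normalize_to_probabilities,
    poisson_draw,
    swr_draw,
    uniform_probabilities,
)
from .smoothing import (
    KernelSpec,
    estimate_cumulative_inclusion,
    estimate_step_selection_prob,
    true_cumulative_inclusion,
)

ESTIMATOR_NAMES = ("LUR", "AILUR", "AIIPW", "IPW_oracle")
#: updaters whose sampling probability is a function of the evaluated model's
#: score, the precondition for the cumulative-inclusion weights
SCORE_FUNCTION_UPDATERS = {"Ori", "Rec", "Uniform"}


class RandomForestUpdater:
    """Pluggable auxiliary probability model (the "RF" slot).

    Fits on the accumulated labeled (covariates, outcomes) and predicts
    outcome probabilities for the whole pool.  The default delegates to a
    random-forest classifier; any object with the same two methods works.
    """

    def __init__(self, **kwargs):
        kwargs.setdefault("n_estimators", 100)
        kwargs.setdefault("random_state", 0)
        self._kwargs = kwargs

    def fit(self, covariates: np.ndarray, labels: np.ndarray) -> None:
        from sklearn.ensemble import RandomForestClassifier

        self._model = RandomForestClassifier(**self._kwargs)
        self._model.fit(covariates, labels)

    def predict_probs(self, covariates: np.ndarray, pool: TestPool) -> np.ndarray:
        proba = self._model.predict_proba(covariates)
        classes = self._model.classes_
        if pool.is_multiclass:
            out = np.full((covariates.shape[0], pool.n_classes), 1e-3)
            for k, c in enumerate(classes):
                out[:, int(c) - 1] = proba[:, k]
            return np.clip(out / out.sum(axis=1, keepdims=True), 1e-3, 1 - 1e-3)
        if proba.shape[1] == 1:  # single class seen so far
            p1 = np.full(covariates.shape[0], float(classes[0]))
        else:
            p1 = proba[:, list(classes).index(1)]
        return np.clip(p1, 1e-3, 1 - 1e-3)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of one active-testing experiment."""

    plan: SamplingPlan = field(default_factory=SamplingPlan)
    estimators: tuple[str, ...] = ("LUR", "AILUR", "AIIPW")
    prob_update: str = "Ori"  # {"Ori", "RF", "Rec", "Uniform"}
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec(
        grid=256, self_weight="matched", bandwidth_scale=3.0))
    metrics: tuple = (LossSpec("cross_entropy"),)
    repetitions: int = 100
    seed: int = 0
    regenerate_pool: bool = False
    prob_model: object | None = None

    def __post_init__(self) -> None:
        for e in self.estimators:
            if e not in ESTIMATOR_NAMES:
                raise ConfigurationError(f"unknown estimator {e!r}")
        if self.prob_update not in {"Ori", "RF", "Rec", "Uniform"}:
            raise ConfigurationError(f"unknown prob_update {self.prob_update!r}")
        needs_score_fn = {"AIIPW", "IPW_oracle"} & set(self.estimators)
        if needs_score_fn and self.prob_update not in SCORE_FUNCTION_UPDATERS:
            raise ConfigurationError(
                "AIIPW/IPW_oracle require a sampling probability that is a "
                "function of the evaluated model's score (Ori, Rec or Uniform)")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")

    @property
    def method_label(self) -> str:
        return self.prob_update


def _conditioning_scores(pool: TestPool) -> np.ndarray:
    """Scalar covariate for the weight smoother: the binary score itself, or
    (multiclass) the expected self-entropy of the score vector — a
    deterministic scalar function of g(X)."""
    if pool.is_multiclass:
        return expected_loss_score(pool.scores, pool.scores)
    return pool.scores


def _plugin_probs(pool: TestPool, prob_update: str) -> np.ndarray | None:
    if prob_update == "Uniform":
        return None
    return pool.scores  # Ori, and the initial step of Rec / RF


def run_active_testing(
    pool: TestPool,
    config: ExperimentConfig,
    repetition: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run one repetition of the sequential evaluation loop.

    Returns the per-step estimate records (tidy frame with columns
    repetition, step, estimator, metric, value) and an ``info`` dict with
    the final ledger, the per-step realized probability arrays (for the
    exact-recursion oracle), the final inclusion-weight estimates and the
    recalibration fits.
    """
    plan = config.plan
    N = pool.n_records
    if plan.total_steps * plan.expected_subsample_size > N:
        raise ConfigurationError("total_steps * n_s exceeds the pool size")
    ledger = LabelLedger(N)
    plugin = _plugin_probs(pool, config.prob_update)
    cond_base = _conditioning_scores(pool)
    scores = pool.scores
    n_s = plan.expected_subsample_size
    floor = plan.probability_floor
    records: list[dict] = []
    step_prob_arrays: list[np.ndarray] = []
    fits = []
    inclusion = None

    for s in range(1, plan.total_steps + 1):
        rng = np.random.default_rng([config.seed, repetition, s])
        unlabeled = ~ledger.labeled_mask
        m = int(unlabeled.sum())
        if m < n_s:
            warnings.warn(f"pool exhausted before step {s}; stopping early")
            break

        # (1) selection probabilities over unlabeled records
        if plugin is None:
            probs = uniform_probabilities(m, n_s, step=s)
            raw_full = None
        else:
            raw_full = expected_loss_score(scores, plugin)
            probs = normalize_to_probabilities(raw_full[unlabeled], n_s, floor, step=s)

        # (2) draw the new batch
        if plan.scheme == "swr":
            raw_unl = (np.ones(m) if raw_full is None else raw_full[unlabeled])
            sel_unl, incl = swr_draw(raw_unl, n_s, rng)
            new_probs = incl
        else:
            sel_unl = poisson_draw(probs, rng)
            new_probs = probs.values[sel_unl]
        new_mask = np.zeros(N, dtype=bool)
        new_mask[np.flatnonzero(unlabeled)[sel_unl]] = True
        ledger.record_step(new_mask, new_probs)

        # realized per-record probability as a function of the score, for
        # the exact inclusion recursion
        if plugin is None:
            step_prob_arrays.append(np.full(N, n_s / m))
        else:
            step_prob_arrays.append(probs.prob_of_raw_score(raw_full))

        # (3) kernel-smoothed weights; the step's conditioning covariate is
        # the current plug-in model's score g^s (scalarized for multiclass)
        if pool.is_multiclass:
            step_cond = cond_base if raw_full is None else raw_full
        else:
            step_cond = cond_base if plugin is None else plugin
        if "AILUR" in config.estimators:
            estimate_step_selection_prob(ledger, step_cond, config.kernel, floor)
        if "AIIPW" in config.estimators or config.prob_update == "Rec":
            inclusion = estimate_cumulative_inclusion(ledger, cond_base, config.kernel, floor)
        true_inclusion = None
        if "IPW_oracle" in config.estimators:
            true_inclusion = np.clip(
                true_cumulative_inclusion(step_prob_arrays, cond_base), floor, 1.0)

        # (4) estimators on the accumulated labeled data
        labeled = ledger.labeled_mask
        labels_lab = pool.revealed_labels(ledger)
        for metric in config.metrics:
            if isinstance(metric, LossSpec):
                losses = np.full(N, np.nan)
                losses[labeled] = metric.pointwise(
                    scores[labeled], np.asarray(labels_lab))
                for est in config.estimators:
                    if est == "LUR":
                        value = lur_estimate(ledger, losses, "true")
                    elif est == "AILUR":
                        value = lur_estimate(ledger, losses, "estimated")
                    elif est == "AIIPW":
                        value = aiipw_estimate(ledger, losses, inclusion)
                    else:
                        value = ipw_oracle_estimate(ledger, losses, true_inclusion)
                    records.append({"repetition": repetition, "step": s,
                                    "estimator": est, "metric": metric.identifier,
                                    "value": value})
            else:
                for est in config.estimators:
                    if est == "LUR":
                        value = lur_ratio_metric(ledger, metric, scores, labels_lab, "true")
                    elif est == "AILUR":
                        value = lur_ratio_metric(ledger, metric, scores, labels_lab, "estimated")
                    elif est == "AIIPW":
                        value = aiipw_ratio_metric(ledger, metric, scores, labels_lab, inclusion)
                    else:
                        value = aiipw_ratio_metric(ledger, metric, scores, labels_lab, true_inclusion)
                    records.append({"repetition": repetition, "step": s,
                                    "estimator": est, "metric": metric.identifier,
                                    "value": value})

        # (5) refresh the plug-in outcome model for the next step
        if config.prob_update == "Rec" and s < plan.total_steps:
            if pool.is_multiclass:
                plugin = multiclass_recalibrated_probs(
                    np.asarray(labels_lab), scores[labeled], inclusion[labeled],
                    scores, step=s)
            else:
                fit = solve_recalibration(np.asarray(labels_lab), scores[labeled],
                                          inclusion[labeled], link="logistic", step=s)
                fits.append(fit)
                plugin = recalibrated_probs(fit, scores)
        elif config.prob_update == "RF" and s < plan.total_steps:
            if pool.covariates is None:
                raise ConfigurationError("RF probability updates need pool covariates")
            model = config.prob_model or RandomForestUpdater()
            model.fit(pool.covariates[labeled], np.asarray(labels_lab))
            plugin = model.predict_probs(pool.covariates, pool)

    frame = pd.DataFrame.from_records(
        records, columns=["repetition", "step", "estimator", "metric", "value"])
    info = {"ledger": ledger, "step_probs": step_prob_arrays,
            "inclusion": inclusion, "fits": fits}
    return frame, info


@dataclass
class ExperimentResult:
    """Aggregated output of a repetition experiment."""

    estimates: pd.DataFrame
    benchmark: dict[str, float]
    rmse: pd.DataFrame
    config: ExperimentConfig | None = None

    def to_csv(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(d / "estimates.csv", index=False)
        self.rmse.to_csv(d / "rmse.csv", index=False)
        pd.DataFrame([{"metric": k, "benchmark": v} for k, v in self.benchmark.items()]
                     ).to_csv(d / "benchmark.csv", index=False)


def run_repetitions(
    pool_source: TestPool | Callable[[int], TestPool],
    config: ExperimentConfig,
) -> ExperimentResult:
    """Run R independent repetitions and aggregate RMSE curves.

    ``pool_source`` is either a fixed pool (sampling randomness only, the
    default reading of the experiment protocol) or, with
    ``config.regenerate_pool``, a callable mapping a derived seed to a
    fresh pool per repetition.
    """
    if config.repetitions < 2:
        raise ConfigurationError("repetition experiments need R >= 2")
    frames = []
    fixed_pool = pool_source if isinstance(pool_source, TestPool) else None
    if fixed_pool is None and not config.regenerate_pool:
        fixed_pool = pool_source(config.seed)
    benchmark: dict[str, float] = {}
    for rep in range(config.repetitions):
        if config.regenerate_pool:
            pool_seed = int(np.random.SeedSequence([config.seed, rep]).generate_state(1)[0]
                            % (2 ** 31))
            pool = pool_source(pool_seed)
        else:
            pool = fixed_pool
        frame, _ = run_active_testing(pool, config, repetition=rep)
        bench = {m.identifier: full_data_benchmark(pool, m) for m in config.metrics}
        frame["benchmark"] = frame["metric"].map(bench)
        frames.append(frame)
        if rep == 0:
            benchmark = bench
    estimates = pd.concat(frames, ignore_index=True)
    estimates["method"] = estimates["estimator"] + "-" + config.method_label
    rmse = rmse_curve(estimates, benchmark)
    return ExperimentResult(estimates=estimates, benchmark=benchmark, rmse=rmse,
                            config=config)


def rmse_curve(estimates: pd.DataFrame, benchmark: dict[str, float] | float | None = None
               ) -> pd.DataFrame:
    """sqrt(mean over repetitions of (estimate - benchmark)^2) per cell.

    Cells are (step, estimator, metric) — and method, when present.  The
    benchmark is read from an embedded ``benchmark`` column if available
    (per-repetition benchmarks for regenerated pools), else from the
    mapping/scalar argument.
    """
    df = estimates.copy()
    if "benchmark" not in df.columns:
        if benchmark is None:
            raise ContractError("no benchmark column and no benchmark argument")
        if isinstance(benchmark, dict):
            df["benchmark"] = df["metric"].map(benchmark)
        else:
            df["benchmark"] = float(benchmark)
    df["sqerr"] = (df["value"] - df["benchmark"]) ** 2
    keys = [k for k in ("step", "estimator", "method", "metric") if k in df.columns]
    counts = df.groupby(keys)["sqerr"].count()
    if (counts < 2).any():
        raise ContractError("every (step, estimator, metric) cell needs >= 2 repetitions")
    out = df.groupby(keys, as_index=False)["sqerr"].mean()
    out["rmse"] = np.sqrt(out.pop("sqerr"))
    return out


def relative_efficiency(
    rmse_table: pd.DataFrame,
    reference: tuple[str, int],
) -> pd.DataFrame:
    """Relative efficiency RE = MSE(reference method at its step) / MSE(cell).

    ``reference`` is a (method, step) pair; the ratio is computed within
    each metric.  RE > 1 at step s means the cell's method needs fewer
    labeling steps than the reference to reach the reference's precision.
    """
    method_col = "method" if "method" in rmse_table.columns else "estimator"
    ref_method, ref_step = reference
    out = rmse_table.copy()
    out["mse"] = out["rmse"] ** 2
    res = []
    for metric, sub in out.groupby("metric"):
        ref_rows = sub[(sub[method_col] == ref_method) & (sub["step"] == ref_step)]
        if ref_rows.empty:
            raise ContractError(f"reference cell {reference} absent for metric {metric}")
        ref_mse = float(ref_rows["mse"].iloc[0])
        if ref_mse <= 0:
            raise ContractError("zero reference MSE: relative efficiency undefined")
        sub = sub.copy()
        sub["re"] = ref_mse / sub["mse"]
        res.append(sub)
    return pd.concat(res, ignore_index=True).drop(columns=["mse"])


def subsample_size_sweep(
    pool_source: TestPool | Callable[[int], TestPool],
    base_config: ExperimentConfig,
    combos: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Final-step RMSE for (total_steps, n_s) combinations at a fixed budget.

    All combinations must spend the same expected total label budget
    S * n_s; unequal budgets are a configuration error.
    """
    budgets = {S * n for S, n in combos}
    if len(budgets) != 1:
        raise ConfigurationError(f"combos spend unequal label budgets: {sorted(budgets)}")
    rows = []
    for S, n in combos:
        cfg = replace(base_config,
                      plan=replace(base_config.plan, total_steps=S,
                                   expected_subsample_size=n))
        result = run_repetitions(pool_source, cfg)
        final = result.rmse[result.rmse["step"] == result.rmse["step"].max()]
        for _, row in final.iterrows():
            rows.append({"total_steps": S, "n_s": n, "estimator": row["estimator"],
                         "method": row.get("method", row["estimator"]),
                         "metric": row["metric"], "rmse": row["rmse"]})
    return pd.DataFrame(rows)
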