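"""Training and evaluation pipeline for HOS-trained MLP classifiers.

The workflow mirrors the standard metaheuristic-trainer protocol: scale the
features to [0, 1], split the data with stratification (two thirds train by
default), encode all MLP weights and biases as one flat vector, minimize the
training-set mean squared error with the hypercube optimization search, and
report test-set accuracy and MSE.  Experiments are repeated over reseeded
runs and summarized as best / worst / mean rows, with a uniform
random-search trainer at matched evaluation budget as the internal baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data import (
    Dataset,
    MinMaxRecord,
    SplitDataset,
    minmax_scale,
    one_hot,
    stratified_split,
)
from .hos import HOSConfig, OptimizationTrace, hos_minimize
from .mlp import MLPArchitecture, hidden_size, mse_fitness, predict

__all__ = [
    "RunSummary",
    "TrainedClassifier",
    "architecture_for",
    "evaluate",
    "prepare",
    "repeated_runs",
    "summary_table",
    "train_hos_mlp",
    "train_random_search",
]

DEFAULT_TRAIN_FRACTION = 0.6666
DEFAULT_WEIGHT_BOUND = 10.0
DEFAULT_N_RUNS = 20


@dataclass
class TrainedClassifier:
    """An MLP with optimizer-chosen parameters plus its training record."""

    architecture: MLPArchitecture
    best_params: np.ndarray
    scaler_record: Optional[MinMaxRecord]
    training_mse: float
    trace: OptimizationTrace
    seed: Optional[int]


@dataclass
class RunSummary:
    """Best/worst/mean test metrics over repeated reseeded runs.

    Accuracies are fractions in [0, 1]; "best" accuracy is the maximum and
    "best" MSE the minimum, matching how trainer comparisons are tabulated.
    """

    per_run_test_accuracy: np.ndarray
    per_run_test_mse: np.ndarray

    def __post_init__(self) -> None:
        self.per_run_test_accuracy = np.asarray(self.per_run_test_accuracy, dtype=float)
        self.per_run_test_mse = np.asarray(self.per_run_test_mse, dtype=float)
        if self.per_run_test_accuracy.shape != self.per_run_test_mse.shape:
            raise ValueError("accuracy and MSE vectors must have equal length")
        if self.per_run_test_accuracy.size < 1:
            raise ValueError("at least one run is required")

    @property
    def accuracy_best(self) -> float:
        return float(self.per_run_test_accuracy.max())

    @property
    def accuracy_worst(self) -> float:
        return float(self.per_run_test_accuracy.min())

    @property
    def accuracy_mean(self) -> float:
        return float(self.per_run_test_accuracy.mean())

    @property
    def mse_best(self) -> float:
        return float(self.per_run_test_mse.min())

    @property
    def mse_worst(self) -> float:
        return float(self.per_run_test_mse.max())

    @property
    def mse_mean(self) -> float:
        return float(self.per_run_test_mse.mean())


def architecture_for(n_features: int, n_classes: int) -> MLPArchitecture:
    """Network shape for a dataset: Kolmogorov hidden width, one output per class."""
    return MLPArchitecture(
        n_input=n_features, n_hidden=hidden_size(n_features), n_output=n_classes
    )


def prepare(
    data: Dataset,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    rng=None,
    fit_on_train_only: bool = False,
) -> tuple[SplitDataset, MinMaxRecord]:
    """Scale features to [0, 1] and split with stratification.

    By default the min-max transform is fitted on the full table before
    splitting; ``fit_on_train_only`` instead fits on the training rows and
    replays the stored transform on the test rows (the leakage-safe variant).
    """
    if fit_on_train_only:
        split = stratified_split(data, train_fraction, rng)
        train_scaled, record = minmax_scale(split.train)
        test_scaled, _ = minmax_scale(split.test, record)
        return (
            SplitDataset(train=train_scaled, test=test_scaled, train_fraction=train_fraction),
            record,
        )
    scaled, record = minmax_scale(data)
    return stratified_split(scaled, train_fraction, rng), record


def _training_objective(split: SplitDataset):
    arch = architecture_for(split.train.n_features, split.train.n_classes)
    X = split.train.features
    T = one_hot(split.train.labels, split.train.n_classes)

    def objective(params: np.ndarray) -> float:
        return mse_fitness(arch, params, X, T)

    return arch, objective


def train_hos_mlp(
    split: SplitDataset,
    hos_config: Optional[HOSConfig] = None,
    weight_bound: float = DEFAULT_WEIGHT_BOUND,
    scaler_record: Optional[MinMaxRecord] = None,
) -> TrainedClassifier:
    """Train the MLP by minimizing training-set MSE with HOS.

    Every weight and bias is searched inside ``[-weight_bound, weight_bound]``.
    """
    if weight_bound <= 0:
        raise ValueError("weight_bound must be positive")
    if hos_config is None:
        hos_config = HOSConfig()
    arch, objective = _training_objective(split)
    p = arch.parameter_count
    lower = np.full(p, -weight_bound)
    upper = np.full(p, weight_bound)
    best, best_f, trace = hos_minimize(objective, lower, upper, hos_config)
    return TrainedClassifier(
        architecture=arch,
        best_params=best,
        scaler_record=scaler_record,
        training_mse=best_f,
        trace=trace,
        seed=hos_config.seed,
    )


def train_random_search(
    split: SplitDataset,
    budget_evaluations: int,
    weight_bound: float = DEFAULT_WEIGHT_BOUND,
    seed: Optional[int] = None,
    batch: int = 70,
    scaler_record: Optional[MinMaxRecord] = None,
) -> TrainedClassifier:
    """Uniform random-search baseline at a fixed evaluation budget.

    Parameter vectors are drawn uniformly from the search box; the best by
    training MSE is kept.  With a common seed the sample stream is nested, so
    enlarging the budget can only improve (never worsen) the result.
    """
    if budget_evaluations < 1:
        raise ValueError("budget_evaluations must be >= 1")
    if weight_bound <= 0:
        raise ValueError("weight_bound must be positive")
    arch, objective = _training_objective(split)
    p = arch.parameter_count
    gen = np.random.default_rng(seed)

    best: Optional[np.ndarray] = None
    best_f = np.inf
    fit_hist: list[float] = []
    remaining = budget_evaluations
    while remaining > 0:
        k = min(batch, remaining)
        cand = gen.uniform(-weight_bound, weight_bound, size=(k, p))
        for row in cand:
            f = objective(row)
            if f < best_f:
                best_f = f
                best = row.copy()
        fit_hist.append(best_f)
        remaining -= k

    n_iters = len(fit_hist)
    half_norm = float(np.linalg.norm(np.full(p, weight_bound)))
    trace = OptimizationTrace(
        best_fitness_per_iteration=np.asarray(fit_hist),
        hypercube_half_size_norm_per_iteration=np.full(n_iters, half_norm),
        dnn_per_iteration=np.ones(n_iters),
        iterations_run=n_iters,
        termination_reason="max_iterations",
        seed=seed,
    )
    assert best is not None
    return TrainedClassifier(
        architecture=arch,
        best_params=best,
        scaler_record=scaler_record,
        training_mse=float(best_f),
        trace=trace,
        seed=seed,
    )


def evaluate(classifier: TrainedClassifier, test: Dataset) -> tuple[float, float]:
    """Test-set accuracy (fraction correct) and MSE against one-hot targets."""
    arch = classifier.architecture
    if test.n_features != arch.n_input:
        raise ValueError(
            f"test set has {test.n_features} features, classifier expects {arch.n_input}"
        )
    labels = predict(arch, classifier.best_params, test.features)
    accuracy = float(np.mean(labels == test.labels))
    T = one_hot(test.labels, arch.n_output)
    mse = mse_fitness(arch, classifier.best_params, test.features, T)
    return accuracy, mse


def repeated_runs(
    split_source: Dataset,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    hos_config: Optional[HOSConfig] = None,
    trainer: str = "hos",
    weight_bound: float = DEFAULT_WEIGHT_BOUND,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    fixed_split: bool = False,
) -> RunSummary:
    """Repeat the full scale/split/train/evaluate protocol over reseeded runs.

    Run ``i`` uses seed ``base_seed + i`` for both the stratified split and
    the trainer (``fixed_split`` keeps one split, reseeding only the
    trainer).  ``trainer`` selects "hos" or the "random" search baseline; the
    baseline's budget equals the HOS population size times its iteration cap.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if trainer not in ("hos", "random"):
        raise ValueError(f"unknown trainer {trainer!r}")
    if hos_config is None:
        hos_config = HOSConfig()
    accs = np.empty(n_runs)
    mses = np.empty(n_runs)
    for i in range(n_runs):
        seed = base_seed + i
        split_seed = base_seed if fixed_split else seed
        split, record = prepare(split_source, train_fraction, split_seed)
        if trainer == "hos":
            clf = train_hos_mlp(
                split, replace(hos_config, seed=seed), weight_bound, record
            )
        else:
            budget = hos_config.population_size * hos_config.max_iterations
            clf = train_random_search(
                split,
                budget,
                weight_bound,
                seed,
                batch=hos_config.population_size,
                scaler_record=record,
            )
        accs[i], mses[i] = evaluate(clf, split.test)
    return RunSummary(per_run_test_accuracy=accs, per_run_test_mse=mses)


def summary_table(summaries: dict[str, RunSummary]) -> pd.DataFrame:
    """Tabulate run summaries: one row per trainer, accuracy in percent.

    Columns follow the usual trainer-comparison layout: MSE best / worst /
    mean then accuracy best / worst / mean, accuracies rounded to 3 decimals.
    """
    rows = []
    for name, s in summaries.items():
        rows.append(
            {
                "trainer": name,
                "mse_best": s.mse_best,
                "mse_worst": s.mse_worst,
                "mse_mean": s.mse_mean,
                "accuracy_best_pct": round(100.0 * s.accuracy_best, 3),
                "accuracy_worst_pct": round(100.0 * s.accuracy_worst, 3),
                "accuracy_mean_pct": round(100.0 * s.accuracy_mean, 3),
            }
        )
    return pd.DataFrame(rows)
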