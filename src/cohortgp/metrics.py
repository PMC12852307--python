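"""Emulator validation: posterior-sampled R², ISE coverage, splits, sweeps.

The protocol used throughout the package: each member's simulations are split
80:20 into train/test; emulators are trained on seeded subsamples of the
training split (5 replicates by default); accuracy is the coefficient of
determination R² = 1 - RSS/TSS averaged over posterior draws (1000 by
default), and calibration is the independent standard error (ISE): the
percentage of test points within two posterior standard deviations of the
predictive mean (ideally ~96% for a Gaussian predictive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .cohort import CohortDataset, SimulationEnsemble
from .errors import ArgumentError, BudgetError, DataError, ShapeError
from .gp import PosteriorPrediction

__all__ = [
    "SplitRecord",
    "OutputScores",
    "ValidationReport",
    "r_squared",
    "posterior_r_squared",
    "independent_standard_error",
    "split_80_20",
    "replicate_evaluation",
    "training_size_sweep",
    "summarize_sweep",
]


class Predictive(Protocol):
    """Anything that predicts a Gaussian posterior at query inputs."""

    def predict(
        self, queries: np.ndarray, *, full_covariance: bool = ..., include_noise: bool = ...
    ) -> PosteriorPrediction: ...


@dataclass
class SplitRecord:
    """A disjoint train/test partition of one member's rows."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


@dataclass
class OutputScores:
    r2_mean: float
    r2_sd: float
    ise_percent: float


@dataclass
class ValidationReport:
    """Per-output accuracy/calibration scores for one training configuration."""

    scores: dict[str, OutputScores]
    n_posterior_samples: int
    n_replicates: int
    training_size: int


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS.

    Negative values mean the prediction is worse than always predicting the
    mean of the observations.
    """
    y = np.asarray(observed, dtype=float).ravel()
    f = np.asarray(predicted, dtype=float).ravel()
    if len(y) != len(f):
        raise ShapeError("observed and predicted lengths differ")
    if len(y) < 2:
        raise ArgumentError("need at least 2 points for R^2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise DataError("observed values are constant; TSS = 0 leaves R^2 undefined")
    return 1.0 - float(np.sum((y - f) ** 2)) / tss


def _sample_from_prediction(
    pred: PosteriorPrediction, n_samples: int, seed: int, joint: bool
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = len(pred.mean)
    Z = rng.standard_normal((n_samples, q))
    if joint and pred.full_covariance is not None:
        C = pred.full_covariance.copy()
        dmax = max(float(np.max(np.diag(C))), 0.0)
        if dmax == 0.0:  # exactly degenerate posterior: a point mass
            return np.tile(pred.mean, (n_samples, 1))
        C[np.diag_indices_from(C)] += 1e-10 * dmax
        L = np.linalg.cholesky(C)
        return pred.mean[None, :] + Z @ L.T
    return pred.mean[None, :] + Z * np.sqrt(np.maximum(pred.variance, 0.0))[None, :]


def posterior_r_squared(
    predictor: Predictive,
    test_inputs: np.ndarray,
    test_outputs: np.ndarray,
    n_samples: int = 1000,
    seed: int = 0,
    *,
    joint: bool = True,
) -> tuple[float, float]:
    """Mean and sd of R² over posterior draws at the test inputs.

    Draws are taken jointly over the test set (full posterior covariance) by
    default; set ``joint=False`` for marginal draws.
    """
    if n_samples < 2:
        raise ArgumentError("n_samples must be >= 2")
    r2s = posterior_r_squared_samples(
        predictor, test_inputs, test_outputs, n_samples, seed, joint=joint
    )
    return float(r2s.mean()), float(r2s.std())


def posterior_r_squared_samples(
    predictor: Predictive,
    test_inputs: np.ndarray,
    test_outputs: np.ndarray,
    n_samples: int = 1000,
    seed: int = 0,
    *,
    joint: bool = True,
) -> np.ndarray:
    """The individual per-draw R² values behind :func:`posterior_r_squared`."""
    y = np.asarray(test_outputs, dtype=float).ravel()
    pred = predictor.predict(test_inputs, full_covariance=joint)
    draws = _sample_from_prediction(pred, n_samples, seed, joint)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise DataError("observed values are constant; TSS = 0 leaves R^2 undefined")
    rss = np.sum((draws - y[None, :]) ** 2, axis=1)
    return 1.0 - rss / tss


def independent_standard_error(
    observed: np.ndarray, post_mean: np.ndarray, post_sd: np.ndarray
) -> float:
    """Percentage of points with |y - mu| <= 2 sigma (boundary inclusive)."""
    y = np.asarray(observed, dtype=float).ravel()
    mu = np.asarray(post_mean, dtype=float).ravel()
    sd = np.asarray(post_sd, dtype=float).ravel()
    if not (len(y) == len(mu) == len(sd)):
        raise ShapeError("observed/post_mean/post_sd lengths differ")
    if np.any(sd < 0):
        raise ArgumentError("posterior sd must be non-negative")
    return 100.0 * float(np.mean(np.abs(y - mu) <= 2.0 * sd))


def split_80_20(ensemble: SimulationEnsemble, seed: int = 0) -> SplitRecord:
    """Uniform random disjoint 80:20 train/test split of one member's rows."""
    n = ensemble.n_sims
    if n < 5:
        raise ArgumentError(f"need at least 5 rows for an 80:20 split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(0.8 * n + 0.5))
    return SplitRecord(
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
        seed=seed,
    )


Trainer = Callable[[SimulationEnsemble, int], dict[str, Predictive]]
"""Training contract: (training ensemble, seed) -> per-output predictives."""


def replicate_evaluation(
    train: SimulationEnsemble,
    test: SimulationEnsemble,
    m: int,
    trainer: Trainer,
    replicates: int = 5,
    seed: int = 0,
    n_posterior_samples: int = 1000,
    *,
    joint: bool = True,
) -> ValidationReport:
    """Train on seeded size-``m`` subsamples, score on the untouched test set.

    The reported sd pools posterior draws across the subsampling replicates, so
    it reflects both posterior and training-subset variability.
    """
    if m > train.n_sims:
        raise BudgetError(f"m={m} exceeds the {train.n_sims} available training rows")
    per_output_r2: dict[str, list[np.ndarray]] = {n: [] for n in train.output_names}
    per_output_ise: dict[str, list[float]] = {n: [] for n in train.output_names}
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        rows = (
            np.arange(train.n_sims)
            if m >= train.n_sims
            else np.sort(rng.choice(train.n_sims, size=m, replace=False))
        )
        models = trainer(train.subset(rows), int(rng.integers(2**31)))
        for name in train.output_names:
            y = test.output(name)
            model = models[name]
            r2s = posterior_r_squared_samples(
                model, test.design, y, n_posterior_samples, seed=[seed, rep, 1], joint=joint
            )
            per_output_r2[name].append(r2s)
            pred = model.predict(test.design, include_noise=True)
            per_output_ise[name].append(
                independent_standard_error(y, pred.mean, np.sqrt(pred.variance))
            )
    scores = {
        name: OutputScores(
            r2_mean=float(np.mean(np.concatenate(per_output_r2[name]))),
            r2_sd=float(np.std(np.concatenate(per_output_r2[name]))),
            ise_percent=float(np.mean(per_output_ise[name])),
        )
        for name in train.output_names
    }
    return ValidationReport(
        scores=scores,
        n_posterior_samples=n_posterior_samples,
        n_replicates=replicates,
        training_size=int(m),
    )


def training_size_sweep(
    cohort: CohortDataset,
    trainer: Trainer,
    m_grid: list[int],
    replicates: int = 5,
    seed: int = 0,
    n_posterior_samples: int = 1000,
    method_name: str = "individual",
) -> pd.DataFrame:
    """Per-member training-size sweep with the standard split/replicate protocol.

    Returns a tidy table (method, member_id, output, m, r2_mean, r2_sd,
    ise_percent); average over members with :func:`summarize_sweep` to obtain
    cohort-level curves.
    """
    max_m = min(
        int(np.floor(0.8 * mem.n_sims + 0.5)) for mem in cohort.members
    )
    for m in m_grid:
        if m > max_m:
            raise BudgetError(f"m={m} exceeds the {max_m} available training rows")
    rows = []
    for member in cohort.members:
        split = split_80_20(member, seed=seed)
        train = member.subset(split.train_indices)
        test = member.subset(split.test_indices)
        for m in m_grid:
            report = replicate_evaluation(
                train,
                test,
                m,
                trainer,
                replicates=replicates,
                seed=seed,
                n_posterior_samples=n_posterior_samples,
            )
            for name, sc in report.scores.items():
                rows.append(
                    {
                        "method": method_name,
                        "member_id": member.member_id,
                        "output": name,
                        "m": m,
                        "r2_mean": sc.r2_mean,
                        "r2_sd": sc.r2_sd,
                        "ise_percent": sc.ise_percent,
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Average member-level scores into cohort-level (method, output, m) rows."""
    return (
        table.groupby(["method", "output", "m"], as_index=False)
        .agg(r2_mean=("r2_mean", "mean"), r2_sd=("r2_sd", "mean"), ise_percent=("ise_percent", "mean"))
        .sort_values(["method", "output", "m"], ignore_index=True)
    )
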