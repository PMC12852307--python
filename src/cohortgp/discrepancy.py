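"""Discrepancy emulation: a new member as a weighted sum of references plus a GP.

A new cohort member's simulator is modelled as

    f_new(theta) = sum_i a_i f_i(theta) + delta(theta),

where the f_i are the existing members (represented by their fitted reference
emulators g_i) and delta is a GP correction fitted to the new member's own
(few) simulations.  Since a weighted sum of GPs plus an independent GP is a
GP, the combined emulator's posterior is Gaussian with

    mean     sum_i a_i mu_i(theta) + mu_delta(theta)
    variance sum_i a_i^2 k_i(theta, theta) + k_delta(theta, theta).

Six weight-learning strategies are provided:

``fixed_one``
    one randomly selected reference, a = 1;
``single_ls``
    one randomly selected reference, a by least squares;
``single_hyper``
    one randomly selected reference, a optimized jointly with the delta GP
    hyperparameters by marginal likelihood;
``cohort_hyper``
    all I weights optimized jointly with the delta GP hyperparameters;
``lasso_fixed``
    weights fixed at the L1-regularized (lasso) least-squares solution, the
    regularization strength chosen by cross-validation;
``lasso_indicator_hyper``
    lasso selects which references get non-zero weight; the surviving weights
    are then optimized jointly with the delta GP hyperparameters.

Training touches only the new member's m simulations and the already-fitted
references; no further simulations of the existing cohort are needed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.optimize import minimize
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .cohort import (
    CohortDataset,
    IndividualCohortEmulators,
    SimulationEnsemble,
    train_individual_cohort,
)
from .errors import (
    ArgumentError,
    BudgetError,
    RankError,
    ShapeError,
    StateError,
)
from .gp import (
    GPEmulator,
    KernelSpec,
    MeanSpec,
    OptimizerConfig,
    PosteriorPrediction,
    _Component,
    _corr_product,
    _mean_basis,
    _safe_cholesky,
    fit_gp,
)
from .metrics import (
    independent_standard_error,
    posterior_r_squared_samples,
    split_80_20,
)

__all__ = [
    "STRATEGIES",
    "WeightVector",
    "DiscrepancyEmulator",
    "reference_means",
    "compute_residuals",
    "learn_weights_lasso",
    "learn_weight_least_squares",
    "train_discrepancy",
    "predict_discrepancy",
    "discrepancy_study",
]

STRATEGIES = (
    "fixed_one",
    "single_ls",
    "single_hyper",
    "cohort_hyper",
    "lasso_fixed",
    "lasso_indicator_hyper",
)
_SINGLE_REF = {"fixed_one", "single_ls", "single_hyper"}
SUPPORT_TOL = 1e-6


@dataclass
class WeightVector:
    """Reference weights {a_i}, their non-zero support, and provenance."""

    values: np.ndarray
    strategy: str
    lam: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.strategy not in STRATEGIES and self.strategy != "fixed":
            raise ArgumentError(f"unknown weight strategy {self.strategy!r}")

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(np.abs(self.values) > SUPPORT_TOL)[0]


@dataclass
class _OutputDiscrepancy:
    references: list[GPEmulator]
    weights: WeightVector
    delta: GPEmulator


@dataclass
class DiscrepancyEmulator:
    """Per-output reference list, weight vector and fitted delta GP."""

    reference_ids: list[str]
    per_output: dict[str, _OutputDiscrepancy]
    training_design: np.ndarray
    training_rows: np.ndarray
    strategy: str

    def weights(self, output: str) -> WeightVector:
        return self.per_output[output].weights

    def predictive(self, output: str) -> "DiscrepancyPredictive":
        return DiscrepancyPredictive(self.per_output[output])

    def predict(
        self, queries: np.ndarray, *, include_noise: bool = False
    ) -> dict[str, PosteriorPrediction]:
        return predict_discrepancy(self, queries, include_noise=include_noise)


@dataclass
class DiscrepancyPredictive:
    """Single-output predictive combining references and delta per additivity."""

    od: _OutputDiscrepancy

    def predict(
        self, queries: np.ndarray, *, full_covariance: bool = False, include_noise: bool = False
    ) -> PosteriorPrediction:
        od = self.od
        dpred = od.delta.predict(
            queries, full_covariance=full_covariance, include_noise=include_noise
        )
        mean = dpred.mean.copy()
        var = dpred.variance.copy()
        cov = None if dpred.full_covariance is None else dpred.full_covariance.copy()
        for a_i, ref in zip(od.weights.values, od.references):
            if a_i == 0.0:
                continue
            rpred = ref.predict(queries, full_covariance=full_covariance)
            mean += a_i * rpred.mean
            var += a_i**2 * rpred.variance
            if cov is not None:
                cov = cov + a_i**2 * rpred.full_covariance
        return PosteriorPrediction(
            query_inputs=dpred.query_inputs, mean=mean, variance=var, full_covariance=cov
        )


# ----------------------------------------------------------------------------
# weight learning


def reference_means(refs: list[GPEmulator], queries: np.ndarray) -> np.ndarray:
    """(q, I) matrix whose column i is reference i's posterior mean."""
    if not refs:
        raise StateError("no reference emulators")
    cols = []
    for ref in refs:
        if not isinstance(ref, GPEmulator):
            raise StateError("references must be fitted GPEmulator objects")
        cols.append(ref.predict(queries).mean)
    return np.column_stack(cols)


def compute_residuals(
    outputs: np.ndarray, ref_means: np.ndarray, weights: WeightVector
) -> np.ndarray:
    """r_j = f_new(theta_j) - sum_i a_i mu_i(theta_j)."""
    y = np.asarray(outputs, dtype=float).ravel()
    M = np.atleast_2d(ref_means)
    if M.shape[0] != len(y):
        raise ShapeError("ref_means rows do not align with outputs")
    if M.shape[1] != len(weights.values):
        raise ShapeError("ref_means columns do not match the weight vector length")
    return y - M @ weights.values


def default_lambda_grid(ref_means: np.ndarray, outputs: np.ndarray, n: int = 20) -> np.ndarray:
    """Log-spaced grid spanning [1e-4, 1e2] x (max |X^T y| / m)."""
    scale = float(np.max(np.abs(ref_means.T @ outputs))) / len(outputs)
    scale = max(scale, 1e-12)
    return np.geomspace(1e-4 * scale, 1e2 * scale, n)


def _lasso_path_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve argmin_a sum_j (y_j - X_j a)^2 + lam * ||a||_1 (no intercept)."""
    m = len(y)
    if lam <= 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    # sklearn's Lasso minimizes (1/2m)||y - Xa||^2 + alpha ||a||_1
    model = Lasso(alpha=lam / (2.0 * m), fit_intercept=False, max_iter=50_000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_.copy()


def learn_weights_lasso(
    outputs: np.ndarray,
    ref_means: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> WeightVector:
    """L1-regularized weights with the penalty chosen by k-fold cross-validation.

    Solves argmin_a sum_j (f_new(theta_j) - sum_i a_i g_i(theta_j))^2
    + lambda ||a||_1 with no intercept; the grid defaults to 20 log-spaced
    values scaled to the data.  Ties in CV error break toward the sparser
    (larger) lambda.
    """
    y = np.asarray(outputs, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(ref_means, dtype=float))
    m = len(y)
    if X.shape[0] != m:
        raise ShapeError("ref_means rows do not align with outputs")
    if cv_folds < 2:
        raise ArgumentError("cv_folds must be >= 2")
    if m < cv_folds:
        raise ArgumentError(f"need at least cv_folds={cv_folds} rows, got {m}")
    if np.allclose(X, 0.0):
        warnings.warn("all reference predictors are zero; returning zero weights")
        return WeightVector(np.zeros(X.shape[1]), "lasso_fixed", lam=None)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ArgumentError("lambda_grid is empty")

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    cv_err = np.zeros(len(lambda_grid))
    for li, lam in enumerate(lambda_grid):
        errs = []
        for tr, te in folds:
            a = _lasso_path_fit(X[tr], y[tr], lam * len(tr) / m)
            errs.append(np.mean((y[te] - X[te] @ a) ** 2))
        cv_err[li] = np.mean(errs)
    # tie-break toward sparser solutions: last index attaining the minimum of
    # an ascending-lambda grid
    order = np.argsort(lambda_grid)
    best = order[np.nonzero(cv_err[order] <= cv_err.min() + 1e-15)[0][-1]]
    lam_hat = float(lambda_grid[best])
    a_hat = _lasso_path_fit(X, y, lam_hat)
    a_hat[np.abs(a_hat) <= SUPPORT_TOL] = 0.0
    return WeightVector(a_hat, "lasso_fixed", lam=lam_hat)


def learn_weight_least_squares(
    outputs: np.ndarray, single_ref_means: np.ndarray
) -> WeightVector:
    """Single-reference least-squares weight a = <g, f> / <g, g>."""
    y = np.asarray(outputs, dtype=float).ravel()
    g = np.asarray(single_ref_means, dtype=float).ravel()
    if len(y) != len(g):
        raise ShapeError("outputs and reference means have different lengths")
    gg = float(g @ g)
    if gg == 0.0:
        raise RankError("reference predictor is identically zero")
    return WeightVector(np.array([float(g @ y) / gg]), "single_ls")


# ----------------------------------------------------------------------------
# joint weight + hyperparameter optimization


def _fit_joint_weights_delta(
    X: np.ndarray,
    y: np.ndarray,
    M: np.ndarray,  # (m, J) reference posterior means on the support
    C_list: list[np.ndarray],  # (m, m) reference posterior covariances
    a0: np.ndarray,
    kernel_spec: KernelSpec,
    mean_form: str,
    opt: OptimizerConfig,
    seed: int,
) -> tuple[np.ndarray, GPEmulator]:
    """Maximize the marginal likelihood of y over (weights, delta GP hypers).

    Model: y ~ N(M a + H beta, sum_j a_j^2 C_j + K_delta + sigma_n^2 I), with
    beta profiled out by GLS.  Returns the weights and a delta GPEmulator
    conditioned on y - M a with the reference covariance as fixed noise.
    """
    n, k = X.shape
    J = M.shape[1]
    # internal scales: inputs to [0,1], outputs by std(y)
    in_shift = X.min(axis=0)
    span = X.max(axis=0) - in_shift
    in_scale = np.where(span > 0, span, 1.0)
    Xs = (X - in_shift) / in_scale
    s = float(y.std()) or 1.0
    ys = y / s
    Ms = M / s
    Cs = [C / s**2 for C in C_list]
    H = _mean_basis(mean_form, Xs)
    jitter = kernel_spec.jitter

    comp = _Component(kernel_spec.family, np.arange(k), np.log(np.full(k, 0.5)))

    def unpack(p):
        a = p[:J]
        comp.log_ls = p[J : J + k].copy()
        sv = float(np.exp(p[J + k]))
        nv = float(np.exp(p[J + k + 1]))
        return a, sv, nv

    def nll_grad(p):
        a, sv, nv = unpack(p)
        from .gp import _component_corr, _component_dcorr_dlogls

        C_corr, parts = _component_corr(comp, Xs, Xs, with_grad_parts=True)
        Sigma = sv * C_corr + nv * np.eye(n)
        for a_j, Cj in zip(a, Cs):
            Sigma = Sigma + a_j**2 * Cj
        try:
            L, _ = _safe_cholesky(Sigma, jitter * sv)
        except Exception:
            return 1e25, np.zeros_like(p)
        Kin = cho_solve((L, True), np.eye(n))
        beta = np.linalg.lstsq(H.T @ Kin @ H, H.T @ Kin @ (ys - Ms @ a), rcond=None)[0]
        e = ys - Ms @ a - H @ beta
        alpha = Kin @ e
        nll = 0.5 * float(e @ alpha) + float(np.log(np.diag(L)).sum())
        A = Kin - np.outer(alpha, alpha)
        g = np.zeros_like(p)
        for j in range(J):
            g[j] = a[j] * float(np.sum(A * Cs[j])) - float(Ms[:, j] @ alpha)
        for d in range(k):
            dC = _component_dcorr_dlogls(comp, parts, d)
            g[J + d] = 0.5 * float(np.sum(A * (sv * dC)))
        g[J + k] = 0.5 * float(np.sum(A * (sv * C_corr)))
        g[J + k + 1] = 0.5 * nv * float(np.trace(A))
        return nll, g

    p0 = np.concatenate([a0, np.log(np.full(k, 0.5)), [0.0], [np.log(1e-2)]])
    bounds = [(-10.0, 10.0)] * J
    bounds += [(np.log(1e-3), np.log(1e3))] * k
    bounds += [(np.log(1e-8), np.log(1e4)), (np.log(1e-9), np.log(1e2))]
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(opt.restarts, 1)):
        start = p0.copy()
        if r > 0:
            start[J:] = start[J:] + rng.normal(0.0, 1.0, size=len(p0) - J)
            start[:J] = start[:J] * rng.uniform(0.5, 1.5, size=J)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            nll_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opt.max_iter, "ftol": opt.tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    a_hat, sv, nv = unpack(best.x)

    # build the conditioned delta GP on the internal scales decided above
    noise_cov_internal = sum(
        (a_j**2) * Cj for a_j, Cj in zip(a_hat, Cs)
    ) if J else np.zeros((n, n))
    Kd = sv * _corr_product([comp], Xs, Xs) + nv * np.eye(n) + noise_cov_internal
    L, jitter_used = _safe_cholesky(Kd, jitter * sv)
    Kin = cho_solve((L, True), np.eye(n))
    resid_s = ys - Ms @ a_hat
    beta = np.linalg.lstsq(H.T @ Kin @ H, H.T @ Kin @ resid_s, rcond=None)[0]

    delta = GPEmulator(
        training_inputs=X,
        training_outputs=resid_s * s,
        components=[comp],
        signal_variance=sv,
        noise_variance=nv,
        jitter=jitter,
        jitter_used=jitter_used,
        mean_form=mean_form,
        mean_coefficients=np.asarray(beta, dtype=float),
        in_shift=in_shift,
        in_scale=in_scale,
        out_shift=0.0,
        out_scale=s,
        noise_diag=noise_cov_internal,
        fit_diagnostics={"log_marginal_likelihood": -float(best.fun), "joint": True},
    )
    return a_hat, delta


# ----------------------------------------------------------------------------
# training and prediction


def train_discrepancy(
    new_sims: SimulationEnsemble,
    refs: IndividualCohortEmulators,
    strategy: str,
    m: int | None = None,
    seed: int = 0,
    *,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    reference_seed: int | None = None,
    reference_noise: str = "propagate",
    kernel_spec: KernelSpec | None = None,
    mean_spec: MeanSpec | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> DiscrepancyEmulator:
    """Train a discrepancy emulator for a new member against fitted references.

    ``m`` subsamples the new member's rows (seeded, uniform without
    replacement); ``reference_noise="propagate"`` adds the weighted reference
    predictive variance as fixed noise when conditioning the delta GP,
    ``"ignore"`` fits delta to plain residuals.
    """
    if strategy not in STRATEGIES:
        raise ArgumentError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if not refs.member_ids:
        raise StateError("reference cohort is empty")
    if reference_noise not in ("propagate", "ignore"):
        raise ArgumentError("reference_noise must be 'propagate' or 'ignore'")
    kernel_spec = kernel_spec or KernelSpec()
    mean_spec_ = mean_spec or MeanSpec()
    opt = optimizer_config or OptimizerConfig()

    if m is not None and m > new_sims.n_sims:
        raise BudgetError(
            f"m={m} exceeds the {new_sims.n_sims} available rows for "
            f"member {new_sims.member_id!r}"
        )
    rng = np.random.default_rng(
        [seed, zlib.crc32(new_sims.member_id.encode()), 7]
    )
    if m is None or m >= new_sims.n_sims:
        rows = np.arange(new_sims.n_sims)
    else:
        rows = np.sort(rng.choice(new_sims.n_sims, size=m, replace=False))
    X = new_sims.design[rows]

    ref_ids = refs.member_ids
    I = len(ref_ids)
    if strategy in _SINGLE_REF:
        ref_rng = np.random.default_rng(seed if reference_seed is None else reference_seed)
        chosen = int(ref_rng.integers(I))

    per_output: dict[str, _OutputDiscrepancy] = {}
    for name in new_sims.output_names:
        ref_gps = [refs.member(mid)[name] for mid in ref_ids]
        y = new_sims.outputs[rows, new_sims.output_names.index(name)]
        M = reference_means(ref_gps, X)

        need_joint = strategy in ("single_hyper", "cohort_hyper", "lasso_indicator_hyper")
        if strategy == "fixed_one":
            a = np.zeros(I)
            a[chosen] = 1.0
            weights = WeightVector(a, strategy)
        elif strategy == "single_ls":
            w1 = learn_weight_least_squares(y, M[:, chosen])
            a = np.zeros(I)
            a[chosen] = w1.values[0]
            weights = WeightVector(a, strategy)
        elif strategy == "lasso_fixed":
            weights = learn_weights_lasso(y, M, lambda_grid, cv_folds, seed)
            weights = WeightVector(weights.values, strategy, lam=weights.lam)
        elif strategy == "single_hyper":
            support = np.array([chosen])
            a0 = np.array([learn_weight_least_squares(y, M[:, chosen]).values[0]])
        elif strategy == "cohort_hyper":
            support = np.arange(I)
            a0 = np.linalg.lstsq(M, y, rcond=None)[0]
        else:  # lasso_indicator_hyper
            lw = learn_weights_lasso(y, M, lambda_grid, cv_folds, seed)
            # indicator selection: drop coefficients that are numerical dust
            # relative to the dominant weight before re-learning on the support
            thr = max(SUPPORT_TOL, 1e-3 * float(np.max(np.abs(lw.values), initial=0.0)))
            support = np.nonzero(np.abs(lw.values) > thr)[0]
            a0 = lw.values[support]
            if support.size == 0:
                weights = WeightVector(np.zeros(I), strategy, lam=lw.lam)
                need_joint = False

        if need_joint:
            C_list = [
                ref_gps[j].predict(X, full_covariance=True).full_covariance
                for j in support
            ]
            a_hat, delta = _fit_joint_weights_delta(
                X,
                y,
                M[:, support],
                C_list,
                np.asarray(a0, dtype=float),
                kernel_spec,
                mean_spec_.form,
                opt,
                seed,
            )
            a = np.zeros(I)
            a[support] = a_hat
            lam = lw.lam if strategy == "lasso_indicator_hyper" else None
            weights = WeightVector(a, strategy, lam=lam)
        else:
            resid = compute_residuals(y, M, weights)
            nd = None
            if reference_noise == "propagate" and weights.support.size:
                nd = np.zeros(len(rows))
                for j in weights.support:
                    nd = nd + weights.values[j] ** 2 * ref_gps[j].predict(X).variance
            delta = fit_gp(
                X,
                resid,
                kernel_spec=kernel_spec,
                mean_spec=mean_spec,
                optimizer_config=opt,
                seed=seed,
                noise_diag=nd,
            )
        per_output[name] = _OutputDiscrepancy(ref_gps, weights, delta)

    return DiscrepancyEmulator(
        reference_ids=list(ref_ids),
        per_output=per_output,
        training_design=X,
        training_rows=rows,
        strategy=strategy,
    )


def predict_discrepancy(
    em: DiscrepancyEmulator, queries: np.ndarray, *, include_noise: bool = False
) -> dict[str, PosteriorPrediction]:
    """Per-output combined posterior: weighted references plus delta."""
    return {
        name: em.predictive(name).predict(queries, include_noise=include_noise)
        for name in em.per_output
    }


# ----------------------------------------------------------------------------
# study runner


def discrepancy_study(
    cohort: CohortDataset,
    m_grid: list[int],
    strategies: tuple[str, ...] = STRATEGIES,
    replicates: int = 5,
    seed: int = 0,
    *,
    new_members: list[str] | None = None,
    reference_m: int | None = None,
    n_posterior_samples: int = 1000,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    optimizer_config: OptimizerConfig | None = None,
    include_individual_baseline: bool = True,
) -> pd.DataFrame:
    """Rotate members as the "new" member; references are the rest.

    For each new member the remaining members' emulators are trained once on
    their full 80% training splits (or ``reference_m`` rows), then each
    strategy is trained on seeded size-``m`` subsamples of the new member's
    training split and scored on its untouched test split.  Single-reference
    strategies re-draw the random reference each replicate.  Returns a tidy
    table (new_member, model, output, m, r2_mean, r2_sd, ise_percent).
    """
    opt = optimizer_config or OptimizerConfig()
    splits = {mem.member_id: split_80_20(mem, seed=seed) for mem in cohort.members}
    targets = new_members if new_members is not None else cohort.member_ids
    rows_out = []
    for new_id in targets:
        rest = cohort.drop(new_id)
        ref_train = CohortDataset(
            [mem.subset(splits[mem.member_id].train_indices) for mem in rest.members]
        )
        refs = train_individual_cohort(
            ref_train, m=reference_m, seed=seed, optimizer_config=opt
        )
        new_member = cohort.member(new_id)
        new_train = new_member.subset(splits[new_id].train_indices)
        new_test = new_member.subset(splits[new_id].test_indices)

        models = list(strategies)
        if include_individual_baseline:
            models.append("individual")
        for model_name in models:
            for m in m_grid:
                if m > new_train.n_sims:
                    raise BudgetError(f"m={m} exceeds {new_train.n_sims} training rows")
                acc_r2 = {o: [] for o in cohort.output_names}
                acc_ise = {o: [] for o in cohort.output_names}
                for rep in range(replicates):
                    rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31))
                    if model_name == "individual":
                        rng = np.random.default_rng([rep_seed, 3])
                        rws = np.sort(rng.choice(new_train.n_sims, size=m, replace=False)) if m < new_train.n_sims else np.arange(new_train.n_sims)
                        sub = new_train.subset(rws)
                        preds = {
                            o: fit_gp(
                                sub.design,
                                sub.output(o),
                                optimizer_config=opt,
                                seed=rep_seed,
                            )
                            for o in cohort.output_names
                        }
                    else:
                        em = train_discrepancy(
                            new_train,
                            refs,
                            model_name,
                            m=m,
                            seed=rep_seed,
                            lambda_grid=lambda_grid,
                            cv_folds=cv_folds,
                            reference_seed=rep_seed,
                            optimizer_config=opt,
                        )
                        preds = {o: em.predictive(o) for o in cohort.output_names}
                    for o in cohort.output_names:
                        r2s = posterior_r_squared_samples(
                            preds[o],
                            new_test.design,
                            new_test.output(o),
                            n_posterior_samples,
                            seed=[rep_seed, 11],
                        )
                        acc_r2[o].append(r2s)
                        p = preds[o].predict(new_test.design, include_noise=True)
                        acc_ise[o].append(
                            independent_standard_error(
                                new_test.output(o), p.mean, np.sqrt(p.variance)
                            )
                        )
                for o in cohort.output_names:
                    pooled = np.concatenate(acc_r2[o])
                    rows_out.append(
                        {
                            "new_member": new_id,
                            "model": model_name,
                            "output": o,
                            "m": m,
                            "r2_mean": float(pooled.mean()),
                            "r2_sd": float(pooled.std()),
                            "ise_percent": float(np.mean(acc_ise[o])),
                        }
                    )
    return pd.DataFrame(rows_out)
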