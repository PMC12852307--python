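"""Exact single-output Gaussian-process regression.

This module is the engine every emulator type in :mod:`cohortgp` builds on.  It
implements Gaussian-process regression with

* stationary ARD kernels (squared-exponential by default, Matérn-5/2 as an
  alternative), optionally structured as a *product* of components acting on
  disjoint input blocks — the construction used by the latent-feature emulator,
  where ``K((theta, l), (theta', l')) = kappa(theta, theta') * kappa_L(l, l')``;
* a parametric mean (constant, or linear-plus-constant) whose coefficients are
  profiled out of the marginal likelihood by generalized least squares, or held
  fixed when supplied;
* type-II maximum-likelihood hyperparameter estimation: L-BFGS-B on the log
  hyperparameters with analytic gradients and seeded restarts;
* posterior prediction (marginal or full covariance) and posterior sampling;
* optional fixed per-point noise (a diagonal added to the likelihood
  covariance), used when a discrepancy GP must absorb the predictive variance
  of reference emulators at its training points.

Inputs are affinely rescaled per dimension to [0, 1] over the training design
and outputs standardized to zero mean / unit variance before fitting; all
predictions are reported back on the original scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize

from .errors import (
    ArgumentError,
    ConditioningError,
    DataError,
    ShapeError,
    StateError,
)

__all__ = [
    "KernelSpec",
    "MeanSpec",
    "OptimizerConfig",
    "PosteriorPrediction",
    "GPEmulator",
    "fit_gp",
    "predict",
    "sample_posterior",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_SQRT5 = float(np.sqrt(5.0))

KERNEL_FAMILIES = ("rbf", "matern52")
MEAN_FORMS = ("constant", "linear")


@dataclass
class KernelSpec:
    """Stationary ARD kernel specification.

    ``lengthscales`` live on the (internally rescaled) input space; ``None``
    means "initialize from a heuristic and learn".  ``noise_variance`` is the
    initial (or fixed) observation-noise variance on the standardized output
    scale.  ``jitter`` is the relative nugget added to the Gram diagonal.
    """

    family: str = "rbf"
    lengthscales: np.ndarray | None = None
    signal_variance: float = 1.0
    noise_variance: float = 1e-2
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ArgumentError(f"unknown kernel family {self.family!r}")
        if self.lengthscales is not None:
            self.lengthscales = np.asarray(self.lengthscales, dtype=float)
            if np.any(self.lengthscales <= 0):
                raise ArgumentError("lengthscales must be positive")
        if self.signal_variance <= 0:
            raise ArgumentError("signal_variance must be positive")
        if self.noise_variance < 0:
            raise ArgumentError("noise_variance must be non-negative")
        if self.jitter <= 0:
            raise ArgumentError("jitter must be positive")


@dataclass
class MeanSpec:
    """Prior mean specification.

    ``form`` is ``"constant"`` (intercept only) or ``"linear"`` (intercept plus
    a linear trend in every input).  When ``coefficients`` is ``None`` the
    coefficients are profiled out by generalized least squares at every
    likelihood evaluation; when given (intercept first) they are held fixed on
    the internal, possibly standardized, scale.
    """

    form: str = "linear"
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.form not in MEAN_FORMS:
            raise ArgumentError(f"unknown mean form {self.form!r}")
        if self.coefficients is not None:
            self.coefficients = np.asarray(self.coefficients, dtype=float)


@dataclass
class OptimizerConfig:
    """Hyperparameter-optimization settings.

    ``restarts`` counts optimizer runs; restart 0 starts from the heuristic (or
    user-supplied) values, later restarts from seeded log-normal perturbations.
    ``optimize=False`` keeps the supplied hyperparameters (coefficients are
    still profiled unless fixed in the :class:`MeanSpec`).
    """

    restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-6
    optimize: bool = True
    optimize_noise: bool = True


@dataclass
class PosteriorPrediction:
    """Posterior mean/variance at a batch of query points (original scale)."""

    query_inputs: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    full_covariance: np.ndarray | None = None


# ----------------------------------------------------------------------------
# kernel components


@dataclass
class _Component:
    family: str
    dims: np.ndarray  # column indices this component acts on
    log_ls: np.ndarray  # one log lengthscale per dim


def _sq_scaled_dists(X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Per-dimension squared scaled distances, shape (n1, n2, d)."""
    diff = (X1[:, None, :] - X2[None, :, :]) / ls
    return diff * diff


def _component_corr(
    comp: _Component, X1: np.ndarray, X2: np.ndarray, *, with_grad_parts: bool = False
):
    ls = np.exp(comp.log_ls)
    S = _sq_scaled_dists(X1[:, comp.dims], X2[:, comp.dims], ls)
    r2 = S.sum(axis=-1)
    if comp.family == "rbf":
        C = np.exp(-0.5 * r2)
        parts = (S,) if with_grad_parts else None
    else:  # matern52
        r = np.sqrt(np.maximum(r2, 0.0))
        e = np.exp(-_SQRT5 * r)
        C = (1.0 + _SQRT5 * r + (5.0 / 3.0) * r2) * e
        parts = (S, r, e) if with_grad_parts else None
    return C, parts


def _component_dcorr_dlogls(comp: _Component, parts, d: int) -> np.ndarray:
    """d corr / d log(lengthscale_d) for one component."""
    if comp.family == "rbf":
        (S,) = parts
        # corr * s_d, with corr = exp(-0.5 sum S)
        return np.exp(-0.5 * S.sum(axis=-1)) * S[..., d]
    S, r, e = parts
    return (5.0 / 3.0) * S[..., d] * e * (1.0 + _SQRT5 * r)


def _corr_product(comps: Sequence[_Component], X1, X2):
    C = np.ones((X1.shape[0], X2.shape[0]))
    for c in comps:
        Cc, _ = _component_corr(c, X1, X2)
        C *= Cc
    return C


# ----------------------------------------------------------------------------
# emulator object


@dataclass
class GPEmulator:
    """A fitted single-output Gaussian-process emulator.

    All stored arrays except ``training_inputs``/``training_outputs`` live on
    the internal scale: inputs mapped to [0, 1] per dimension, outputs
    standardized.  ``predict``/``sample`` invert the transforms.
    """

    training_inputs: np.ndarray
    training_outputs: np.ndarray
    components: list[_Component]
    signal_variance: float
    noise_variance: float
    jitter: float
    jitter_used: float
    mean_form: str
    mean_coefficients: np.ndarray  # on internal scale
    in_shift: np.ndarray
    in_scale: np.ndarray
    out_shift: float
    out_scale: float
    noise_diag: np.ndarray | None = None  # fixed per-point noise, internal scale
    fit_diagnostics: dict = field(default_factory=dict)
    # cached factorization
    _Xs: np.ndarray | None = field(default=None, repr=False)
    _L: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    # -- transforms -------------------------------------------------------
    def _tx(self, X: np.ndarray) -> np.ndarray:
        return (X - self.in_shift) / self.in_scale

    def _basis(self, Xs: np.ndarray) -> np.ndarray:
        return _mean_basis(self.mean_form, Xs)

    @property
    def n_inputs(self) -> int:
        return self.training_inputs.shape[1]

    @property
    def kernel(self) -> KernelSpec:
        """A KernelSpec view of the fitted hyperparameters (internal scale)."""
        ls = np.concatenate([np.exp(c.log_ls) for c in self.components])
        return KernelSpec(
            family=self.components[0].family,
            lengthscales=ls,
            signal_variance=self.signal_variance,
            noise_variance=self.noise_variance,
            jitter=self.jitter,
        )

    @property
    def log_marginal_likelihood(self) -> float:
        return self.fit_diagnostics.get("log_marginal_likelihood", np.nan)

    # -- factorization ----------------------------------------------------
    def _ensure_factorization(self) -> None:
        if self._L is not None:
            return
        Xs = self._tx(self.training_inputs)
        ys = (self.training_outputs - self.out_shift) / self.out_scale
        K = self.signal_variance * _corr_product(self.components, Xs, Xs)
        K[np.diag_indices_from(K)] += self.noise_variance
        if self.noise_diag is not None:
            if self.noise_diag.ndim == 2:
                K = K + self.noise_diag
            else:
                K[np.diag_indices_from(K)] += self.noise_diag
        L, used = _safe_cholesky(K, self.jitter * self.signal_variance)
        H = self._basis(Xs)
        e = ys - H @ self.mean_coefficients
        self._Xs = Xs
        self._L = L
        self._alpha = cho_solve((L, True), e)
        self.jitter_used = used

    # -- public API -------------------------------------------------------
    def predict(
        self,
        queries: np.ndarray,
        *,
        full_covariance: bool = False,
        include_noise: bool = False,
    ) -> PosteriorPrediction:
        return predict(
            self, queries, full_covariance=full_covariance, include_noise=include_noise
        )

    def sample(
        self,
        queries: np.ndarray,
        n_samples: int,
        seed: int,
        *,
        joint: bool = True,
        include_noise: bool = False,
    ) -> np.ndarray:
        return sample_posterior(
            self, queries, n_samples, seed, joint=joint, include_noise=include_noise
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "training_inputs": self.training_inputs.tolist(),
            "training_outputs": self.training_outputs.tolist(),
            "components": [
                {
                    "family": c.family,
                    "dims": c.dims.tolist(),
                    "log_lengthscales": c.log_ls.tolist(),
                }
                for c in self.components
            ],
            "signal_variance": self.signal_variance,
            "noise_variance": self.noise_variance,
            "jitter": self.jitter,
            "mean_form": self.mean_form,
            "mean_coefficients": self.mean_coefficients.tolist(),
            "in_shift": self.in_shift.tolist(),
            "in_scale": self.in_scale.tolist(),
            "out_shift": self.out_shift,
            "out_scale": self.out_scale,
            "noise_diag": None if self.noise_diag is None else self.noise_diag.tolist(),
            "fit_diagnostics": {
                k: (float(v) if np.isscalar(v) else v)
                for k, v in self.fit_diagnostics.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "GPEmulator":
        comps = [
            _Component(
                family=c["family"],
                dims=np.asarray(c["dims"], dtype=int),
                log_ls=np.asarray(c["log_lengthscales"], dtype=float),
            )
            for c in d["components"]
        ]
        return cls(
            training_inputs=np.asarray(d["training_inputs"], dtype=float),
            training_outputs=np.asarray(d["training_outputs"], dtype=float),
            components=comps,
            signal_variance=float(d["signal_variance"]),
            noise_variance=float(d["noise_variance"]),
            jitter=float(d["jitter"]),
            jitter_used=float(d["jitter"]),
            mean_form=d["mean_form"],
            mean_coefficients=np.asarray(d["mean_coefficients"], dtype=float),
            in_shift=np.asarray(d["in_shift"], dtype=float),
            in_scale=np.asarray(d["in_scale"], dtype=float),
            out_shift=float(d["out_shift"]),
            out_scale=float(d["out_scale"]),
            noise_diag=(
                None
                if d.get("noise_diag") is None
                else np.asarray(d["noise_diag"], dtype=float)
            ),
            fit_diagnostics=dict(d.get("fit_diagnostics", {})),
        )

    @classmethod
    def from_json(cls, s: str) -> "GPEmulator":
        return cls.from_dict(json.loads(s))


# ----------------------------------------------------------------------------
# helpers


def _mean_basis(form: str, Xs: np.ndarray) -> np.ndarray:
    if form == "constant":
        return np.ones((Xs.shape[0], 1))
    return np.column_stack([np.ones(Xs.shape[0]), Xs])


def _safe_cholesky(K: np.ndarray, base_jitter: float, max_rel_jitter: float = 1e-2):
    """Cholesky with escalating relative jitter; raises ConditioningError."""
    n = K.shape[0]
    scale = max(float(np.mean(np.diag(K))), 1e-300)
    j = max(base_jitter, 1e-12 * scale)
    while j <= max_rel_jitter * scale:
        try:
            L = np.linalg.cholesky(K + j * np.eye(n))
            return L, j
        except np.linalg.LinAlgError:
            j *= 10.0
    raise ConditioningError(
        "Gram matrix (training covariance) not positive definite after jitter "
        f"escalation up to {max_rel_jitter:g} of its diagonal scale"
    )


def _gls_beta(L: np.ndarray, H: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Generalized-least-squares mean coefficients given chol(K)."""
    Kin_H = cho_solve((L, True), H)
    A = H.T @ Kin_H
    b = Kin_H.T @ y
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


# ----------------------------------------------------------------------------
# fitting


def _nll_and_grad(
    p: np.ndarray,
    Xs: np.ndarray,
    ys: np.ndarray,
    comps: list[_Component],
    mean_form: str,
    fixed_beta: np.ndarray | None,
    noise_diag: np.ndarray | None,
    jitter: float,
    optimize_noise: bool,
    fixed_noise: float,
):
    """Negative log marginal likelihood and gradient wrt log hyperparameters.

    Parameter layout: [log_ls (all components, concatenated), log_sv,
    (log_nv if optimize_noise)].  The mean coefficients are profiled out by
    GLS unless ``fixed_beta`` is given; by the envelope theorem the gradient
    at the profiled optimum needs no extra term.
    """
    n = len(ys)
    idx = 0
    corr_list, parts_list = [], []
    for c in comps:
        d = len(c.dims)
        c.log_ls = p[idx : idx + d].copy()
        idx += d
        C, parts = _component_corr(c, Xs, Xs, with_grad_parts=True)
        corr_list.append(C)
        parts_list.append(parts)
    sv = float(np.exp(p[idx]))
    idx += 1
    nv = float(np.exp(p[idx])) if optimize_noise else fixed_noise

    Cprod = np.ones((n, n))
    for C in corr_list:
        Cprod *= C
    K = sv * Cprod
    K[np.diag_indices_from(K)] += nv
    if noise_diag is not None:
        if noise_diag.ndim == 2:
            K = K + noise_diag
        else:
            K[np.diag_indices_from(K)] += noise_diag

    try:
        L, _ = _safe_cholesky(K, jitter * sv)
    except ConditioningError:
        return 1e25, np.zeros_like(p)

    H = _mean_basis(mean_form, Xs)
    beta = fixed_beta if fixed_beta is not None else _gls_beta(L, H, ys)
    e = ys - H @ beta
    alpha = cho_solve((L, True), e)
    nll = 0.5 * float(e @ alpha) + float(np.log(np.diag(L)).sum()) + 0.5 * n * _LOG2PI

    # grad = 0.5 * sum(A * dK), A = K^-1 - alpha alpha^T
    A = cho_solve((L, True), np.eye(n)) - np.outer(alpha, alpha)

    grad = np.zeros_like(p)
    gidx = 0
    for ci, c in enumerate(comps):
        # product of the other components' correlations
        other = sv * np.ones((n, n))
        for cj, C in enumerate(corr_list):
            if cj != ci:
                other *= C
        for d in range(len(c.dims)):
            dC = _component_dcorr_dlogls(c, parts_list[ci], d)
            grad[gidx] = 0.5 * float(np.sum(A * (other * dC)))
            gidx += 1
    grad[gidx] = 0.5 * float(np.sum(A * (sv * Cprod)))  # d/dlog sv
    gidx += 1
    if optimize_noise:
        grad[gidx] = 0.5 * nv * float(np.trace(A))
    return nll, grad


def fit_gp(
    design: np.ndarray,
    outputs: np.ndarray,
    kernel_spec: KernelSpec | Sequence[tuple[KernelSpec, Sequence[int]]] | None = None,
    mean_spec: MeanSpec | None = None,
    optimizer_config: OptimizerConfig | None = None,
    seed: int = 0,
    *,
    standardize: bool = True,
    noise_diag: np.ndarray | None = None,
) -> GPEmulator:
    """Fit a single-output GP emulator by maximum marginal likelihood.

    Parameters
    ----------
    design, outputs
        Training design (n, k) and responses (n,).
    kernel_spec
        A :class:`KernelSpec` acting on all inputs, or a sequence of
        ``(KernelSpec, dims)`` pairs whose correlations are multiplied
        (product-kernel structure; the first spec's signal/noise/jitter are
        shared).  ``None`` uses the ARD squared-exponential default.
    mean_spec
        Prior-mean form; default linear-plus-constant with profiled
        coefficients.
    optimizer_config
        Restart/tolerance settings; ``optimize=False`` keeps the supplied
        hyperparameters (a "frozen" GP).
    seed
        Seeds the restart perturbations only; the fit is deterministic given
        the seed.
    standardize
        Map inputs to [0, 1] per dimension and outputs to zero-mean/unit
        variance before fitting (recommended; disable for closed-form
        comparisons on the raw scale).
    noise_diag
        Optional fixed noise on the *original* output scale, added to the
        likelihood covariance: a length-n vector of per-point variances, or a
        full (n, n) noise covariance matrix.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outputs, dtype=float).ravel()
    if X.ndim != 2:
        raise ShapeError("design must be a 2-D array")
    if X.shape[0] != len(y):
        raise ShapeError("design and outputs disagree on the number of rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("design/outputs contain non-finite values")
    n, k = X.shape
    if k < 1:
        raise ShapeError("design needs at least one column")

    opt = optimizer_config or OptimizerConfig()
    if n < 2 and opt.optimize:
        raise DataError("at least 2 training rows are required to fit a GP")
    if n < 1:
        raise DataError("empty training set")

    # normalize the kernel argument into components + shared scalars
    if kernel_spec is None:
        kernel_spec = KernelSpec()
    if isinstance(kernel_spec, KernelSpec):
        comp_specs = [(kernel_spec, np.arange(k))]
    else:
        comp_specs = [(ks, np.asarray(dims, dtype=int)) for ks, dims in kernel_spec]
        covered = np.concatenate([d for _, d in comp_specs])
        if sorted(covered.tolist()) != list(range(k)):
            raise ShapeError("kernel components must partition the input dimensions")
    head = comp_specs[0][0]
    mean = mean_spec or MeanSpec()

    # transforms
    if standardize:
        in_shift = X.min(axis=0)
        span = X.max(axis=0) - X.min(axis=0)
        in_scale = np.where(span > 0, span, 1.0)
        out_shift = float(y.mean())
        ystd = float(y.std())
        out_scale = ystd if ystd > 0 else 1.0
    else:
        in_shift = np.zeros(k)
        in_scale = np.ones(k)
        out_shift = 0.0
        out_scale = 1.0
    Xs = (X - in_shift) / in_scale
    ys = (y - out_shift) / out_scale
    nd_internal = (
        None if noise_diag is None else np.asarray(noise_diag, dtype=float) / out_scale**2
    )

    comps = []
    p0 = []
    for ks, dims in comp_specs:
        if ks.lengthscales is not None:
            if len(ks.lengthscales) != len(dims):
                raise ShapeError("lengthscale count must match component dims")
            ls0 = ks.lengthscales
        else:
            ls0 = np.full(len(dims), 0.5)
        comps.append(_Component(ks.family, dims, np.log(ls0)))
        p0.extend(np.log(ls0))
    p0.append(np.log(head.signal_variance))
    fixed_noise = head.noise_variance
    optimize_noise = opt.optimize_noise and opt.optimize
    if optimize_noise:
        p0.append(np.log(max(head.noise_variance, 1e-8)))
    p0 = np.asarray(p0)

    fixed_beta = mean.coefficients
    nll_args = (
        Xs,
        ys,
        comps,
        mean.form,
        fixed_beta,
        nd_internal,
        head.jitter,
        optimize_noise,
        fixed_noise,
    )

    if opt.optimize:
        n_ls = sum(len(c.dims) for c in comps)
        bounds = [(np.log(1e-3), np.log(1e3))] * n_ls
        bounds.append((np.log(1e-8), np.log(1e4)))
        if optimize_noise:
            bounds.append((np.log(1e-9), np.log(1e2)))
        rng = np.random.default_rng(seed)
        best = None
        restarts_used = 0
        for r in range(max(opt.restarts, 1)):
            start = p0 if r == 0 else p0 + rng.normal(0.0, 1.0, size=p0.shape)
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(
                _nll_and_grad,
                start,
                args=nll_args,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": opt.max_iter, "ftol": opt.tol},
            )
            restarts_used += 1
            if best is None or res.fun < best.fun:
                best = res
        p_hat = best.x
        lml = -float(best.fun)
    else:
        p_hat = p0
        restarts_used = 0
        lml = -float(_nll_and_grad(p0, *nll_args)[0])

    # unpack the winner into the components (side effect of _nll_and_grad is
    # not relied upon: set explicitly)
    idx = 0
    for c in comps:
        d = len(c.dims)
        c.log_ls = p_hat[idx : idx + d].copy()
        idx += d
    sv = float(np.exp(p_hat[idx]))
    idx += 1
    nv = float(np.exp(p_hat[idx])) if optimize_noise else fixed_noise

    # final mean coefficients (profiled at the optimum unless fixed)
    K = sv * _corr_product(comps, Xs, Xs)
    K[np.diag_indices_from(K)] += nv
    if nd_internal is not None:
        if nd_internal.ndim == 2:
            K = K + nd_internal
        else:
            K[np.diag_indices_from(K)] += nd_internal
    L, jitter_used = _safe_cholesky(K, head.jitter * sv)
    H = _mean_basis(mean.form, Xs)
    beta = fixed_beta if fixed_beta is not None else _gls_beta(L, H, ys)
    alpha = cho_solve((L, True), ys - H @ beta)

    gp = GPEmulator(
        training_inputs=X,
        training_outputs=y,
        components=comps,
        signal_variance=sv,
        noise_variance=nv,
        jitter=head.jitter,
        jitter_used=jitter_used,
        mean_form=mean.form,
        mean_coefficients=np.asarray(beta, dtype=float),
        in_shift=in_shift,
        in_scale=in_scale,
        out_shift=out_shift,
        out_scale=out_scale,
        noise_diag=nd_internal,
        fit_diagnostics={
            "log_marginal_likelihood": lml,
            "restarts_used": restarts_used,
        },
    )
    gp._Xs = Xs
    gp._L = L
    gp._alpha = alpha
    return gp


def predict(
    gp: GPEmulator,
    queries: np.ndarray,
    *,
    full_covariance: bool = False,
    include_noise: bool = False,
) -> PosteriorPrediction:
    """Posterior mean/variance at ``queries``, on the original output scale.

    ``include_noise`` adds the fitted observation-noise variance to the
    predictive variance (predictive rather than latent-function uncertainty).
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != gp.n_inputs:
        raise ShapeError(
            f"queries have {Q.shape[1]} columns, emulator expects {gp.n_inputs}"
        )
    gp._ensure_factorization()
    Qs = gp._tx(Q)
    Ks = gp.signal_variance * _corr_product(gp.components, Qs, gp._Xs)
    Hq = gp._basis(Qs)
    mean_s = Hq @ gp.mean_coefficients + Ks @ gp._alpha
    V = solve_triangular(gp._L, Ks.T, lower=True)
    var_s = np.maximum(gp.signal_variance - np.einsum("ij,ij->j", V, V), 0.0)
    cov = None
    if full_covariance:
        Kqq = gp.signal_variance * _corr_product(gp.components, Qs, Qs)
        cov_s = Kqq - V.T @ V
        if include_noise:
            cov_s = cov_s + gp.noise_variance * np.eye(len(Qs))
        cov = cov_s * gp.out_scale**2
        var_s = np.maximum(np.diag(cov_s), 0.0)
    elif include_noise:
        var_s = var_s + gp.noise_variance
    return PosteriorPrediction(
        query_inputs=Q,
        mean=mean_s * gp.out_scale + gp.out_shift,
        variance=var_s * gp.out_scale**2,
        full_covariance=cov,
    )


def sample_posterior(
    gp: GPEmulator,
    queries: np.ndarray,
    n_samples: int,
    seed: int,
    *,
    joint: bool = True,
    include_noise: bool = False,
) -> np.ndarray:
    """Draw seeded posterior samples, shape (n_samples, q).

    With ``joint`` the draws use the full posterior covariance over the
    queries; otherwise they are marginal per query point.
    """
    if n_samples < 1:
        raise ArgumentError("n_samples must be >= 1")
    pred = predict(gp, queries, full_covariance=joint, include_noise=include_noise)
    rng = np.random.default_rng(seed)
    q = len(pred.mean)
    Z = rng.standard_normal((n_samples, q))
    if joint:
        C = pred.full_covariance.copy()
        # nugget keeps near-degenerate posteriors factorizable
        C[np.diag_indices_from(C)] += max(1e-12, 1e-10 * max(np.max(np.diag(C)), 0.0))
        Lc = np.linalg.cholesky(C)
        return pred.mean[None, :] + Z @ Lc.T
    return pred.mean[None, :] + Z * np.sqrt(pred.variance)[None, :]
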