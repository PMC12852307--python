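"""Synthetic cohorts of smooth, exactly evaluable multi-output functions.

The generator emulates the statistical structure the cohort methods assume:
every member i computes

    f_i(theta) = sum_b w_b(l_i) phi_b(theta) + gamma * psi_i(theta),

where the phi_b are shared smooth basis functions (seeded mixtures of radial
bumps, so the true functions can be evaluated exactly anywhere), the weights
w_b vary smoothly with the member's latent coordinate l_i (lengthscale
``latent_smoothness``), and psi_i is an independent member-specific smooth
discrepancy scaled by gamma.  Small gamma gives a high-similarity cohort
where transfer should help; large gamma gives members whose outputs vary
wildly and transfer may not.  Designs are Latin hypercubes on [0,1]^k and
optional iid Gaussian observation noise can be added.

Default shapes mirror the whole-heart electrophysiology case study
(I=19 members, k=6 parameters, 9 latent modes, 180 simulations per member,
2 outputs); the simulators being emulated are deterministic, so the default
observation noise is zero.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import qmc

from .cohort import CohortDataset, SimulationEnsemble
from .errors import ArgumentError, ShapeError
from .latent import LatentFeatures

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "latin_hypercube",
    "generate_cohort",
    "make_linear_member",
]


def latin_hypercube(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Space-filling design on [0,1]^k with one point per 1/n bin per margin."""
    if n < 1 or k < 1:
        raise ArgumentError("latin_hypercube needs n >= 1 and k >= 1")
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    return sampler.random(n)


@dataclass
class SyntheticCohortConfig:
    """Generation parameters for a synthetic cohort.

    ``latent_smoothness`` is the lengthscale (in latent units; latents are
    drawn on [-1,1]^d_latent) over which member weights vary — larger means
    more similar members.  ``discrepancy_scale`` (gamma) scales the
    member-specific term; ``noise_sd`` is iid observation noise.
    """

    n_inputs: int = 6
    d_latent: int = 9
    n_members: int = 19
    n_basis: int = 8
    latent_smoothness: float = 1.0
    discrepancy_scale: float = 0.1
    noise_sd: float = 0.0
    n_sims: int = 180
    n_outputs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_inputs", "d_latent", "n_members", "n_basis", "n_sims", "n_outputs"):
            if getattr(self, name) < 1:
                raise ArgumentError(f"{name} must be >= 1")
        if self.latent_smoothness <= 0:
            raise ArgumentError("latent_smoothness must be positive")
        if self.discrepancy_scale < 0 or self.noise_sd < 0:
            raise ArgumentError("scales must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        return cls(**d)


@dataclass
class _Bumps:
    """A smooth function as a finite mixture of Gaussian radial bumps."""

    centers: np.ndarray  # (C, dim)
    widths: np.ndarray  # (C,)
    amps: np.ndarray  # (C,)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        return np.exp(-0.5 * d2 / self.widths**2) @ self.amps


def _random_bumps(rng: np.random.Generator, dim: int, n_centers: int, box: tuple[float, float], width_range: tuple[float, float]) -> _Bumps:
    lo, hi = box
    return _Bumps(
        centers=rng.uniform(lo, hi, size=(n_centers, dim)),
        widths=rng.uniform(*width_range, size=n_centers),
        amps=rng.normal(0.0, 1.0, size=n_centers) / np.sqrt(n_centers),
    )


@dataclass
class SyntheticCohort:
    """A generated cohort with exact true-function handles per member."""

    dataset: CohortDataset
    latents: LatentFeatures
    true_functions: dict[str, Callable[[np.ndarray], np.ndarray]]
    config: SyntheticCohortConfig
    # generator internals kept so linear combinations of members can be built
    _basis: list[list[_Bumps]] = field(default_factory=list, repr=False)
    _latent_weights: list[list[_Bumps]] = field(default_factory=list, repr=False)

    def true_function(self, member_id: str) -> Callable[[np.ndarray], np.ndarray]:
        """Exact noiseless evaluator: theta (q,k) -> outputs (q, N)."""
        return self.true_functions[member_id]


def _member_function(cfg, basis, latent_weights, l, psi_list, gamma):
    """Closure computing all outputs exactly at arbitrary theta."""

    wmat = np.array(
        [
            [latent_weights[o][b](l[None, :])[0] for b in range(cfg.n_basis)]
            for o in range(cfg.n_outputs)
        ]
    )  # (N, B)

    def f(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        cols = []
        for o in range(cfg.n_outputs):
            val = np.zeros(len(theta))
            for b in range(cfg.n_basis):
                val += wmat[o, b] * basis[o][b](theta)
            val += gamma * psi_list[o](theta)
            cols.append(val)
        return np.column_stack(cols)

    return f


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a cohort; regeneration from the same config is bit-identical.

    Designs, true functions and observation noise use separated seeded
    streams, so changing only the noise realization (via ``noise_sd``'s
    stream) never perturbs designs or true functions.
    """
    cfg = config
    struct_rng = np.random.default_rng([cfg.seed, 1])  # basis + weights
    member_rng = np.random.default_rng([cfg.seed, 2])  # latents + discrepancies
    noise_rng = np.random.default_rng([cfg.seed, 3])  # observation noise only

    n_centers = 10
    basis = [
        [_random_bumps(struct_rng, cfg.n_inputs, n_centers, (-0.2, 1.2), (0.25, 0.7)) for _ in range(cfg.n_basis)]
        for _ in range(cfg.n_outputs)
    ]
    latent_weights = [
        [
            _random_bumps(
                struct_rng,
                cfg.d_latent,
                n_centers,
                (-1.2, 1.2),
                (cfg.latent_smoothness, 2.0 * cfg.latent_smoothness),
            )
            for _ in range(cfg.n_basis)
        ]
        for _ in range(cfg.n_outputs)
    ]

    members, latent_table, true_fns = [], {}, {}
    for i in range(cfg.n_members):
        mid = f"member_{i:02d}"
        l = member_rng.uniform(-1.0, 1.0, size=cfg.d_latent)
        psi_list = [
            _random_bumps(member_rng, cfg.n_inputs, n_centers, (-0.2, 1.2), (0.25, 0.7))
            for _ in range(cfg.n_outputs)
        ]
        f = _member_function(cfg, basis, latent_weights, l, psi_list, cfg.discrepancy_scale)
        design = latin_hypercube(cfg.n_sims, cfg.n_inputs, seed=int(member_rng.integers(2**31)))
        clean = f(design)
        noisy = clean + cfg.noise_sd * noise_rng.standard_normal(clean.shape)
        names = [f"y{o}" for o in range(cfg.n_outputs)]
        members.append(SimulationEnsemble(mid, design, noisy, names))
        latent_table[mid] = l
        true_fns[mid] = f

    return SyntheticCohort(
        dataset=CohortDataset(members),
        latents=LatentFeatures(latent_table, provenance="synthetic"),
        true_functions=true_fns,
        config=cfg,
        _basis=basis,
        _latent_weights=latent_weights,
    )


def make_linear_member(
    cohort: SyntheticCohort,
    weights: np.ndarray,
    discrepancy_scale: float = 0.0,
    n_sims: int | None = None,
    seed: int = 0,
    *,
    noise_sd: float | None = None,
    member_id: str = "member_new",
) -> SimulationEnsemble:
    """A new member whose true function is a weighted sum of existing members.

    f_new(theta) = sum_i a_i f_i(theta) + discrepancy_scale * psi_new(theta);
    ground truth for support-recovery and zero-discrepancy experiments.
    """
    cfg = cohort.config
    a = np.asarray(weights, dtype=float).ravel()
    if len(a) != cfg.n_members:
        raise ShapeError(f"weights must have length {cfg.n_members}")
    if n_sims is None:
        n_sims = cfg.n_sims
    if noise_sd is None:
        noise_sd = cfg.noise_sd
    rng = np.random.default_rng([cfg.seed, 4, seed])
    psi_list = [
        _random_bumps(rng, cfg.n_inputs, 10, (-0.2, 1.2), (0.25, 0.7))
        for _ in range(cfg.n_outputs)
    ]
    design = latin_hypercube(n_sims, cfg.n_inputs, seed=int(rng.integers(2**31)))
    fns = [cohort.true_function(mid) for mid in cohort.dataset.member_ids]
    vals = np.zeros((n_sims, cfg.n_outputs))
    for a_i, f in zip(a, fns):
        if a_i != 0.0:
            vals += a_i * f(design)
    for o in range(cfg.n_outputs):
        vals[:, o] += discrepancy_scale * psi_list[o](design)
    vals += noise_sd * rng.standard_normal(vals.shape)
    return SimulationEnsemble(
        member_id, design, vals, [f"y{o}" for o in range(cfg.n_outputs)]
    )
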