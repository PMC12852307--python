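"""Cohort-wide emulation on the product space of parameters and latent features.

Each cohort member i carries a latent coordinate ``l_i`` (for example the
leading modes of a statistical shape model of the anatomy).  Concatenating
every member's simulations with its latent vector gives a hybrid dataset of
rows ``((theta; l_i), f_i(theta))``; a single GP over the joint space with the
product kernel ``K((theta,l),(theta',l')) = kappa(theta,theta') *
kappa_L(l,l')`` then emulates the whole cohort at once, and — in principle —
new members whose latents are known.

The module also provides a generic PCA latent-feature extractor (a stand-in
for anatomy-specific shape models) and the leave-one-member-out study
protocol with matched-budget individual-emulator baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import (
    CohortDataset,
    SimulationEnsemble,
    matched_budget_allocation,
    train_individual_cohort,
)
from .errors import (
    ArgumentError,
    BudgetError,
    CoverageError,
    RankError,
    ShapeError,
)
from .gp import (
    GPEmulator,
    KernelSpec,
    MeanSpec,
    OptimizerConfig,
    PosteriorPrediction,
    fit_gp,
)
from .metrics import (
    independent_standard_error,
    posterior_r_squared_samples,
    split_80_20,
)

__all__ = [
    "LatentFeatures",
    "HybridDataset",
    "LatentEmulator",
    "PcaLatentModel",
    "build_hybrid_dataset",
    "train_latent_emulator",
    "predict_for_member",
    "pca_latent_features",
    "leave_one_member_out",
]


@dataclass
class LatentFeatures:
    """Per-member latent vectors l_i indexing the cohort."""

    vectors: dict[str, np.ndarray]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        self.vectors = {k: np.asarray(v, dtype=float).ravel() for k, v in self.vectors.items()}
        if not self.vectors:
            raise ArgumentError("latent feature table is empty")
        dims = {len(v) for v in self.vectors.values()}
        if len(dims) != 1:
            raise ShapeError("latent vectors must share one dimension")
        for k, v in self.vectors.items():
            if not np.all(np.isfinite(v)):
                raise ShapeError(f"latent vector for {k!r} has non-finite entries")

    @property
    def d_latent(self) -> int:
        return len(next(iter(self.vectors.values())))

    def vector(self, member_id: str) -> np.ndarray:
        if member_id not in self.vectors:
            raise CoverageError(f"no latent vector for member {member_id!r}")
        return self.vectors[member_id]


@dataclass
class HybridDataset:
    """Concatenated (theta; l) inputs and outputs over included members."""

    inputs: np.ndarray  # (sum J_i, k + d_L)
    outputs: np.ndarray  # (sum J_i, N)
    row_member_ids: np.ndarray
    output_names: list[str]
    n_theta: int
    d_latent: int

    @property
    def n_rows(self) -> int:
        return self.inputs.shape[0]


@dataclass
class PcaLatentModel:
    """Truncated principal-component latent extractor."""

    modes: np.ndarray  # (n_modes, p), orthonormal rows
    explained_variance_fractions: np.ndarray
    centering: np.ndarray
    n_modes: int

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(vectors) - self.centering) @ self.modes.T


@dataclass
class LatentEmulator:
    """One product-kernel GP per output over the joint (theta, latent) space."""

    emulators: dict[str, GPEmulator]
    latents: LatentFeatures
    n_theta: int
    d_latent: int
    output_names: list[str]
    training_subset: np.ndarray | None = None

    def for_member(self, output: str, latent: np.ndarray) -> "LatentMemberPredictive":
        return LatentMemberPredictive(self, output, np.asarray(latent, dtype=float))


@dataclass
class LatentMemberPredictive:
    """Predictive view of a latent emulator at one fixed latent vector."""

    emulator: LatentEmulator
    output: str
    latent: np.ndarray

    def predict(
        self, queries: np.ndarray, *, full_covariance: bool = False, include_noise: bool = False
    ) -> PosteriorPrediction:
        Q = np.atleast_2d(np.asarray(queries, dtype=float))
        if len(self.latent) != self.emulator.d_latent:
            raise ShapeError("latent vector dimension mismatch")
        joint = np.column_stack([Q, np.tile(self.latent, (len(Q), 1))])
        return self.emulator.emulators[self.output].predict(
            joint, full_covariance=full_covariance, include_noise=include_noise
        )


def build_hybrid_dataset(
    cohort: CohortDataset,
    latents: LatentFeatures,
    include_members: list[str] | None = None,
) -> HybridDataset:
    """Concatenate members' designs with their latent vectors.

    Row order is deterministic: members in cohort order, then each member's
    simulation rows in stored order.
    """
    ids = include_members if include_members is not None else cohort.member_ids
    blocks_X, blocks_Y, row_ids = [], [], []
    for mid in ids:
        member = cohort.member(mid)
        l = latents.vector(mid)
        blocks_X.append(np.column_stack([member.design, np.tile(l, (member.n_sims, 1))]))
        blocks_Y.append(member.outputs)
        row_ids.extend([mid] * member.n_sims)
    return HybridDataset(
        inputs=np.vstack(blocks_X),
        outputs=np.vstack(blocks_Y),
        row_member_ids=np.asarray(row_ids),
        output_names=list(cohort.output_names),
        n_theta=cohort.n_inputs,
        d_latent=latents.d_latent,
    )


def train_latent_emulator(
    hybrid: HybridDataset,
    theta_kernel: KernelSpec | None = None,
    latent_kernel: KernelSpec | None = None,
    subsample_size: int | None = None,
    seed: int = 0,
    *,
    latents: LatentFeatures | None = None,
    mean_spec: MeanSpec | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> LatentEmulator:
    """Fit one product-kernel GP per output on (a subsample of) the hybrid rows.

    The kernel is structured as the product of a parameter-space component and
    a latent-space component, each with its own ARD lengthscales; by default
    both are squared-exponential.
    """
    if subsample_size is not None and subsample_size > hybrid.n_rows:
        raise BudgetError(
            f"subsample_size={subsample_size} exceeds the {hybrid.n_rows} hybrid rows"
        )
    theta_kernel = theta_kernel or KernelSpec()
    latent_kernel = latent_kernel or KernelSpec(family=theta_kernel.family)
    k, dL = hybrid.n_theta, hybrid.d_latent
    components = [(theta_kernel, list(range(k))), (latent_kernel, list(range(k, k + dL)))]

    rng = np.random.default_rng(seed)
    if subsample_size is None or subsample_size >= hybrid.n_rows:
        rows = np.arange(hybrid.n_rows)
    else:
        rows = np.sort(rng.choice(hybrid.n_rows, size=subsample_size, replace=False))

    emulators = {}
    for j, name in enumerate(hybrid.output_names):
        emulators[name] = fit_gp(
            hybrid.inputs[rows],
            hybrid.outputs[rows, j],
            kernel_spec=components,
            mean_spec=mean_spec,
            optimizer_config=optimizer_config,
            seed=seed,
        )
    if latents is None:
        table = {}
        for mid in np.unique(hybrid.row_member_ids):
            row = np.nonzero(hybrid.row_member_ids == mid)[0][0]
            table[str(mid)] = hybrid.inputs[row, k:]
        latents = LatentFeatures(table, provenance="hybrid-rows")
    return LatentEmulator(
        emulators=emulators,
        latents=latents,
        n_theta=k,
        d_latent=dL,
        output_names=list(hybrid.output_names),
        training_subset=rows,
    )


def predict_for_member(
    em: LatentEmulator,
    queries: np.ndarray,
    latent: np.ndarray,
    *,
    include_noise: bool = False,
) -> dict[str, PosteriorPrediction]:
    """Predict every output at (theta; latent) pairs for one (possibly new) member."""
    latent = np.asarray(latent, dtype=float).ravel()
    if len(latent) != em.d_latent:
        raise ShapeError(
            f"latent vector has dimension {len(latent)}, emulator expects {em.d_latent}"
        )
    return {
        name: em.for_member(name, latent).predict(queries, include_noise=include_noise)
        for name in em.output_names
    }


def pca_latent_features(
    member_vectors: np.ndarray,
    n_modes: int,
    member_ids: list[str] | None = None,
) -> tuple[PcaLatentModel, LatentFeatures]:
    """Truncated-PCA latent coordinates from per-member descriptor vectors.

    A generic stand-in for anatomy-specific statistical shape models: latent
    vectors are the projections of the centered descriptors onto the top
    ``n_modes`` principal directions.  Mode signs are fixed by making each
    mode's largest-magnitude loading positive.
    """
    V = np.atleast_2d(np.asarray(member_vectors, dtype=float))
    I, p = V.shape
    if n_modes > min(I - 1, p):
        raise RankError(
            f"n_modes={n_modes} exceeds the rank bound min(I-1, p) = {min(I - 1, p)}"
        )
    if member_ids is None:
        member_ids = [f"member_{i:02d}" for i in range(I)]
    pca = PCA(n_components=n_modes, svd_solver="full")
    scores = pca.fit_transform(V)
    modes = pca.components_
    # deterministic sign convention
    for j in range(n_modes):
        i_max = np.argmax(np.abs(modes[j]))
        if modes[j, i_max] < 0:
            modes[j] = -modes[j]
            scores[:, j] = -scores[:, j]
    model = PcaLatentModel(
        modes=modes,
        explained_variance_fractions=pca.explained_variance_ratio_,
        centering=pca.mean_,
        n_modes=n_modes,
    )
    feats = LatentFeatures(
        {mid: scores[i] for i, mid in enumerate(member_ids)}, provenance="pca"
    )
    return model, feats


def leave_one_member_out(
    cohort: CohortDataset,
    latents: LatentFeatures,
    total_training_sizes: list[int],
    replicates: int = 5,
    seed: int = 0,
    *,
    n_posterior_samples: int = 1000,
    optimizer_config: OptimizerConfig | None = None,
    holdout_members: list[str] | None = None,
) -> pd.DataFrame:
    """Leave-one-member-out study of the latent emulator vs matched baselines.

    For each held-out member, a latent emulator is trained on subsamples of the
    remaining members' 80% training splits at each total budget, and evaluated
    on (a) the left-in members' test rows (averaging member-level R²) and
    (b) the held-out member's test rows.  A matched-budget ensemble of
    individual emulators (budget split evenly across the left-in members) is
    scored the same way; in the left-out case each left-in individual emulator
    predicts the held-out test rows and the scores are averaged.

    Returns a tidy table with columns (held_out, model, evaluation, output,
    total_m, r2_mean, r2_sd, ise_percent).
    """
    if cohort.size < 2:
        raise ArgumentError("leave-one-member-out needs a cohort of size >= 2")
    opt = optimizer_config or OptimizerConfig()
    rows_out = []
    splits = {m.member_id: split_80_20(m, seed=seed) for m in cohort.members}
    holdouts = holdout_members if holdout_members is not None else cohort.member_ids
    for held_out in holdouts:
        rest = cohort.drop(held_out)
        train_cohort = CohortDataset(
            [m.subset(splits[m.member_id].train_indices) for m in rest.members]
        )
        test_sets = {
            m.member_id: m.subset(splits[m.member_id].test_indices) for m in rest.members
        }
        ho_test = cohort.member(held_out).subset(splits[held_out].test_indices)
        hybrid = build_hybrid_dataset(train_cohort, latents)
        for budget in total_training_sizes:
            if budget > hybrid.n_rows:
                raise BudgetError(f"budget {budget} exceeds {hybrid.n_rows} pooled rows")
            alloc = matched_budget_allocation(budget, train_cohort.member_ids)
            acc = {("latent", ev, o): ([], []) for ev in ("left_in", "left_out") for o in cohort.output_names}
            acc.update({("individual", ev, o): ([], []) for ev in ("left_in", "left_out") for o in cohort.output_names})
            for rep in range(replicates):
                rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31))
                lat_em = train_latent_emulator(
                    hybrid,
                    subsample_size=budget,
                    seed=rep_seed,
                    latents=latents,
                    optimizer_config=opt,
                )
                ind = _train_matched_ensemble(train_cohort, alloc, rep_seed, opt)
                for o in cohort.output_names:
                    # left-in: average member-level scores
                    for model_name, per_member in (
                        ("latent", lambda mid: lat_em.for_member(o, latents.vector(mid))),
                        ("individual", lambda mid: ind.member(mid)[o]),
                    ):
                        r2s_members, ise_members = [], []
                        for mid, ts in test_sets.items():
                            pred_obj = per_member(mid)
                            r2s = posterior_r_squared_samples(
                                pred_obj, ts.design, ts.output(o),
                                n_posterior_samples, seed=[rep_seed, 1],
                            )
                            r2s_members.append(r2s)
                            p = pred_obj.predict(ts.design, include_noise=True)
                            ise_members.append(
                                independent_standard_error(ts.output(o), p.mean, np.sqrt(p.variance))
                            )
                        # member-level means averaged; draws pooled for the sd
                        acc[(model_name, "left_in", o)][0].append(
                            np.mean([r.mean() for r in r2s_members])
                        )
                        acc[(model_name, "left_in", o)][1].append(np.mean(ise_members))
                        # left-out
                        if model_name == "latent":
                            pred_objs = [lat_em.for_member(o, latents.vector(held_out))]
                        else:
                            pred_objs = [ind.member(mid)[o] for mid in train_cohort.member_ids]
                        r2s_ho, ise_ho = [], []
                        for pobj in pred_objs:
                            r2s = posterior_r_squared_samples(
                                pobj, ho_test.design, ho_test.output(o),
                                n_posterior_samples, seed=[rep_seed, 2],
                            )
                            r2s_ho.append(r2s.mean())
                            p = pobj.predict(ho_test.design, include_noise=True)
                            ise_ho.append(
                                independent_standard_error(ho_test.output(o), p.mean, np.sqrt(p.variance))
                            )
                        acc[(model_name, "left_out", o)][0].append(np.mean(r2s_ho))
                        acc[(model_name, "left_out", o)][1].append(np.mean(ise_ho))
            for (model_name, ev, o), (r2_list, ise_list) in acc.items():
                rows_out.append(
                    {
                        "held_out": held_out,
                        "model": model_name,
                        "evaluation": ev,
                        "output": o,
                        "total_m": budget,
                        "r2_mean": float(np.mean(r2_list)),
                        "r2_sd": float(np.std(r2_list)),
                        "ise_percent": float(np.mean(ise_list)),
                    }
                )
    return pd.DataFrame(rows_out)


def _train_matched_ensemble(train_cohort, alloc, seed, opt):
    """Individual emulators with per-member budgets from a matched allocation."""
    from .cohort import IndividualCohortEmulators

    ems, subsets = {}, {}
    for member in train_cohort.members:
        single = CohortDataset([member])
        fitted = train_individual_cohort(
            single, m=alloc[member.member_id], seed=seed, optimizer_config=opt
        )
        ems[member.member_id] = fitted.emulators[member.member_id]
        subsets[member.member_id] = fitted.training_subset_indices[member.member_id]
    return IndividualCohortEmulators(ems, subsets)
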