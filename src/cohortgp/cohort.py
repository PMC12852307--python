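"""Cohort data containers and the individual-emulator baseline.

A cohort is a set of personalized simulators (one per member — e.g. one per
patient heart mesh) that share the same input parameters and output names.
The baseline strategy trains, for every member and every output, an
independent GP emulator on that member's simulations only: no information
flows between members.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, BudgetError, DataError, LookupError_, ShapeError
from .gp import GPEmulator, KernelSpec, MeanSpec, OptimizerConfig, PosteriorPrediction, fit_gp

__all__ = [
    "SimulationEnsemble",
    "CohortDataset",
    "IndividualCohortEmulators",
    "train_individual_cohort",
    "predict_member",
    "matched_budget_allocation",
]


@dataclass
class SimulationEnsemble:
    """One member's simulation ensemble: a design matrix and named outputs."""

    member_id: str
    design: np.ndarray  # (J_i, k)
    outputs: np.ndarray  # (J_i, N)
    output_names: list[str]

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.outputs.ndim == 1:
            self.outputs = self.outputs[:, None]
        if self.design.shape[0] != self.outputs.shape[0]:
            raise ShapeError(
                f"member {self.member_id!r}: design has {self.design.shape[0]} rows "
                f"but outputs have {self.outputs.shape[0]}"
            )
        if self.outputs.shape[1] != len(self.output_names):
            raise ShapeError(
                f"member {self.member_id!r}: {self.outputs.shape[1]} output columns "
                f"vs {len(self.output_names)} names"
            )
        if len(set(self.output_names)) != len(self.output_names):
            raise ArgumentError("output names must be unique")
        if not (np.all(np.isfinite(self.design)) and np.all(np.isfinite(self.outputs))):
            raise DataError(f"member {self.member_id!r}: non-finite values")

    @property
    def n_sims(self) -> int:
        return self.design.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.design.shape[1]

    def output(self, name: str) -> np.ndarray:
        try:
            j = self.output_names.index(name)
        except ValueError:
            raise LookupError_(f"unknown output {name!r}") from None
        return self.outputs[:, j]

    def subset(self, rows: np.ndarray) -> "SimulationEnsemble":
        return SimulationEnsemble(
            self.member_id, self.design[rows], self.outputs[rows], list(self.output_names)
        )


@dataclass
class CohortDataset:
    """An ordered collection of members sharing inputs and output names."""

    members: list[SimulationEnsemble]

    def __post_init__(self) -> None:
        if not self.members:
            raise ArgumentError("cohort must contain at least one member")
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ArgumentError("member ids must be unique")
        k = self.members[0].n_inputs
        names = self.members[0].output_names
        for m in self.members[1:]:
            if m.n_inputs != k:
                raise ShapeError(f"member {m.member_id!r} has input dim {m.n_inputs} != {k}")
            if m.output_names != names:
                raise ShapeError(f"member {m.member_id!r} has different output names")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    @property
    def n_inputs(self) -> int:
        return self.members[0].n_inputs

    @property
    def output_names(self) -> list[str]:
        return self.members[0].output_names

    def member(self, member_id: str) -> SimulationEnsemble:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise LookupError_(f"unknown member {member_id!r}")

    def drop(self, member_id: str) -> "CohortDataset":
        kept = [m for m in self.members if m.member_id != member_id]
        if len(kept) == len(self.members):
            raise LookupError_(f"unknown member {member_id!r}")
        return CohortDataset(kept)


@dataclass
class IndividualCohortEmulators:
    """Per-member, per-output independent emulators (the cohort baseline)."""

    emulators: dict[str, dict[str, GPEmulator]]  # member_id -> output -> GP
    training_subset_indices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def member_ids(self) -> list[str]:
        return list(self.emulators)

    def member(self, member_id: str) -> dict[str, GPEmulator]:
        if member_id not in self.emulators:
            raise LookupError_(f"unknown member {member_id!r}")
        return self.emulators[member_id]


def matched_budget_allocation(total_budget: int, member_ids: list[str]) -> dict[str, int]:
    """Split a total simulation budget evenly over members.

    Each member receives ``total_budget // I`` points; any remainder is given
    one extra point per member in id order.
    """
    I = len(member_ids)
    base, rem = divmod(int(total_budget), I)
    return {mid: base + (1 if i < rem else 0) for i, mid in enumerate(member_ids)}


def _subsample_rows(n: int, m: int | None, rng: np.random.Generator) -> np.ndarray:
    if m is None or m >= n:
        return np.arange(n)
    return np.sort(rng.choice(n, size=m, replace=False))


def train_individual_cohort(
    cohort: CohortDataset,
    m: int | str | None = "all",
    seed: int = 0,
    *,
    kernel_spec: KernelSpec | None = None,
    mean_spec: MeanSpec | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> IndividualCohortEmulators:
    """Train independent per-member, per-output emulators.

    ``m`` is the per-member training size (``"all"``/``None`` uses every row);
    the size-``m`` subset is drawn uniformly without replacement with a
    per-member seeded stream, so results are reproducible and deleting other
    members does not change a member's emulator.
    """
    if m in ("all", None):
        m_int = None
    else:
        m_int = int(m)
        if m_int < 1:
            raise ArgumentError("training size m must be >= 1")
    emulators: dict[str, dict[str, GPEmulator]] = {}
    subsets: dict[str, np.ndarray] = {}
    for member in cohort.members:
        if m_int is not None and m_int > member.n_sims:
            raise BudgetError(
                f"member {member.member_id!r} has {member.n_sims} rows, "
                f"cannot train on m={m_int}"
            )
        # per-member stream: independent of cohort composition; crc32 is a
        # process-stable hash (builtin str hash is salted per interpreter run)
        rng = np.random.default_rng([seed, zlib.crc32(member.member_id.encode())])
        rows = _subsample_rows(member.n_sims, m_int, rng)
        subsets[member.member_id] = rows
        per_output: dict[str, GPEmulator] = {}
        for j, name in enumerate(cohort.output_names):
            per_output[name] = fit_gp(
                member.design[rows],
                member.outputs[rows, j],
                kernel_spec=kernel_spec,
                mean_spec=mean_spec,
                optimizer_config=optimizer_config,
                seed=seed,
            )
        emulators[member.member_id] = per_output
    return IndividualCohortEmulators(emulators, subsets)


def predict_member(
    emulators: IndividualCohortEmulators,
    member_id: str,
    queries: np.ndarray,
    *,
    include_noise: bool = False,
) -> dict[str, PosteriorPrediction]:
    """Per-output posterior predictions from one member's emulators only."""
    member = emulators.member(member_id)
    return {
        name: gp.predict(queries, include_noise=include_noise)
        for name, gp in member.items()
    }
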