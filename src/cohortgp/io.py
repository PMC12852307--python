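"""Cohort/latent CSV schema, deposit loaders, experiment configs and runners.

The generic cohort table is a single CSV with a ``member_id`` column plus the
numeric input and output columns named in a small YAML manifest
(``{"inputs": [...], "outputs": [...]}``).  Latent features live in a second
CSV keyed by ``member_id``.  Numerics are written with 17 significant digits
so round-trips are lossless.

Loaders for the two deposited cardiac case-study ensembles (whole-heart
electrophysiology; atrial mechanics) consume this same schema after a one-off
conversion (see :func:`convert_deposit`), and validate the documented shapes
(19 members x 180 rows, 6 EP parameters + 9 shape modes, outputs A_TAT/V_TAT;
10 members x 200 rows, 9 parameters, 7 outputs) loudly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset, SimulationEnsemble
from .discrepancy import STRATEGIES, discrepancy_study
from .errors import ArgumentError, SchemaError
from .gp import KernelSpec, MeanSpec, OptimizerConfig
from .latent import LatentFeatures, leave_one_member_out
from .metrics import summarize_sweep, training_size_sweep

log = logging.getLogger("cohortgp")

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_latents_csv",
    "read_latents_csv",
    "load_ep_ensemble",
    "load_atrial_ensemble",
    "convert_deposit",
    "ExperimentConfig",
    "run_experiment",
]

_FLOAT_FMT = "%.17g"

EP_INPUTS = ["CV_ventricles", "CV_atria", "k_ventricles", "k_atria", "k_FEC", "k_BB"]
EP_OUTPUTS = ["A_TAT", "V_TAT"]
ATRIAL_INPUTS = [
    "alpha_anterior",
    "alpha_posterior",
    "alpha_septum",
    "alpha_lateral",
    "alpha_roof",
    "EDP",
    "ESV_in",
    "k_peri",
    "PTH",
]
ATRIAL_OUTPUTS = [
    "d_global",
    "d_anterior",
    "d_posterior",
    "d_septum",
    "d_lateral",
    "d_roof",
    "ESV",
]


# ----------------------------------------------------------------------------
# generic schema


def write_cohort_csv(cohort: CohortDataset, csv_path, manifest_path=None) -> None:
    """Write the cohort table plus its column manifest."""
    csv_path = Path(csv_path)
    inputs = [f"x{j}" for j in range(cohort.n_inputs)]
    frames = []
    for member in cohort.members:
        df = pd.DataFrame(member.design, columns=inputs)
        for j, name in enumerate(cohort.output_names):
            df[name] = member.outputs[:, j]
        df.insert(0, "member_id", member.member_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    manifest_path = Path(manifest_path) if manifest_path else csv_path.with_suffix(".manifest.yaml")
    manifest_path.write_text(
        yaml.safe_dump({"inputs": inputs, "outputs": list(cohort.output_names)})
    )


def read_cohort_csv(csv_path, manifest) -> CohortDataset:
    """Read a cohort table; ``manifest`` is a path or a dict with inputs/outputs."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise SchemaError(f"cohort file {csv_path} does not exist")
    if not isinstance(manifest, dict):
        manifest = yaml.safe_load(Path(manifest).read_text())
    try:
        inputs = list(manifest["inputs"])
        outputs = list(manifest["outputs"])
    except (KeyError, TypeError) as exc:
        raise SchemaError("manifest must declare 'inputs' and 'outputs'") from exc
    if set(inputs) & set(outputs):
        raise SchemaError("input and output column sets must be disjoint")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in ["member_id", *inputs, *outputs] if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {csv_path} is missing columns {missing}")
    for col in inputs + outputs:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise SchemaError(
                f"non-numeric cell(s) in column {col!r}, first at row {int(bad[0])}"
            )
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"missing value in column {col!r} at row {row}")
    members = []
    for mid, grp in df.groupby("member_id", sort=False):
        if len(grp) < 2:
            raise SchemaError(f"member {mid!r} has fewer than 2 rows")
        members.append(
            SimulationEnsemble(
                str(mid), grp[inputs].to_numpy(float), grp[outputs].to_numpy(float), outputs
            )
        )
    return CohortDataset(members)


def write_latents_csv(latents: LatentFeatures, path) -> None:
    rows = [
        {"member_id": mid, **{f"l{j}": v for j, v in enumerate(vec)}}
        for mid, vec in latents.vectors.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_latents_csv(path, provenance: str = "user-supplied") -> LatentFeatures:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"latent file {path} does not exist")
    df = pd.read_csv(path, float_precision="round_trip")
    if "member_id" not in df.columns:
        raise SchemaError("latent file must have a member_id column")
    value_cols = [c for c in df.columns if c != "member_id"]
    if not value_cols:
        raise SchemaError("latent file has no latent columns")
    return LatentFeatures(
        {str(r["member_id"]): r[value_cols].to_numpy(float) for _, r in df.iterrows()},
        provenance=provenance,
    )


# ----------------------------------------------------------------------------
# case-study deposits (converted layout)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise SchemaError(msg)


def load_ep_ensemble(deposit_dir) -> tuple[CohortDataset, LatentFeatures]:
    """Load the converted whole-heart electrophysiology ensemble.

    Expects ``cohort.csv`` (member_id, the 6 conduction parameters, A_TAT and
    V_TAT) and ``latents.csv`` (member_id plus 9 shape-mode columns) under
    ``deposit_dir``; validates 19 members x 180 simulations each.
    """
    deposit_dir = Path(deposit_dir)
    cohort = read_cohort_csv(
        deposit_dir / "cohort.csv", {"inputs": EP_INPUTS, "outputs": EP_OUTPUTS}
    )
    latents = read_latents_csv(deposit_dir / "latents.csv", provenance="shape-model")
    _check(cohort.size == 19, f"expected 19 members, found {cohort.size}")
    for member in cohort.members:
        _check(
            member.n_sims == 180,
            f"member {member.member_id!r} has {member.n_sims} rows, expected 180",
        )
    _check(latents.d_latent == 9, f"expected 9 shape modes, found {latents.d_latent}")
    for mid in cohort.member_ids:
        latents.vector(mid)
    return cohort, latents


def load_atrial_ensemble(deposit_dir) -> CohortDataset:
    """Load the converted atrial mechanics ensemble (10 members x 200 rows)."""
    deposit_dir = Path(deposit_dir)
    cohort = read_cohort_csv(
        deposit_dir / "cohort.csv", {"inputs": ATRIAL_INPUTS, "outputs": ATRIAL_OUTPUTS}
    )
    _check(cohort.size == 10, f"expected 10 members, found {cohort.size}")
    for member in cohort.members:
        _check(
            member.n_sims == 200,
            f"member {member.member_id!r} has {member.n_sims} rows, expected 200",
        )
    return cohort


def convert_deposit(raw_dir, out_dir, inputs: list[str], outputs: list[str]) -> None:
    """Convert per-member CSV files into the generic cohort schema.

    ``raw_dir`` holds one ``<member_id>.csv`` per member with the named input
    and output columns, and optionally ``latents.csv``; the converted
    ``cohort.csv`` (+ manifest) and ``latents.csv`` are written to ``out_dir``.
    """
    raw_dir, out_dir = Path(raw_dir), Path(out_dir)
    files = sorted(p for p in raw_dir.glob("*.csv") if p.stem != "latents")
    if not files:
        raise SchemaError(f"no per-member CSV files found in {raw_dir}")
    members = []
    for p in files:
        df = pd.read_csv(p)
        missing = [c for c in inputs + outputs if c not in df.columns]
        if missing:
            raise SchemaError(f"{p.name} is missing columns {missing}")
        members.append(
            SimulationEnsemble(p.stem, df[inputs].to_numpy(float), df[outputs].to_numpy(float), list(outputs))
        )
    cohort = CohortDataset(members)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs_named = pd.concat(
        [
            pd.DataFrame(m.design, columns=inputs).assign(member_id=m.member_id)
            for m in cohort.members
        ],
        ignore_index=True,
    )
    outputs_named = pd.concat(
        [pd.DataFrame(m.outputs, columns=outputs) for m in cohort.members],
        ignore_index=True,
    )
    table = pd.concat([inputs_named[["member_id", *inputs]], outputs_named], axis=1)
    table.to_csv(out_dir / "cohort.csv", index=False, float_format=_FLOAT_FMT)
    (out_dir / "cohort.manifest.yaml").write_text(
        yaml.safe_dump({"inputs": list(inputs), "outputs": list(outputs)})
    )
    if (raw_dir / "latents.csv").exists():
        read_latents_csv(raw_dir / "latents.csv")  # validate
        (out_dir / "latents.csv").write_bytes((raw_dir / "latents.csv").read_bytes())


# ----------------------------------------------------------------------------
# experiment configuration and runner


@dataclass
class ExperimentConfig:
    """A fully serializable description of one study run."""

    method: str  # individual | latent | discrepancy
    m_grid: list[int]
    strategy: str | None = None  # discrepancy only; None means all six
    replicates: int = 5
    seed: int = 0
    kernel_family: str = "rbf"
    mean_form: str = "linear"
    restarts: int = 5
    n_posterior_samples: int = 1000
    lambda_grid: list[float] | None = None
    cv_folds: int = 5
    out_prefix: str = "experiment"

    def __post_init__(self) -> None:
        if self.method not in ("individual", "latent", "discrepancy"):
            raise ArgumentError(f"unknown method {self.method!r}")
        if self.strategy is not None and self.strategy not in STRATEGIES:
            raise ArgumentError(f"unknown strategy {self.strategy!r}")
        if not self.m_grid:
            raise ArgumentError("m_grid must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_experiment(
    config: ExperimentConfig,
    cohort: CohortDataset,
    latents: LatentFeatures | None = None,
    out_dir=".",
) -> pd.DataFrame:
    """Execute the configured protocol and write CSV + JSON with provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opt = OptimizerConfig(restarts=config.restarts)
    kspec = KernelSpec(family=config.kernel_family)
    mspec = MeanSpec(form=config.mean_form)
    log.info("run_experiment method=%s seed=%d", config.method, config.seed)
    if config.method == "individual":
        from .gp import fit_gp

        def trainer(ens, seed):
            return {
                name: fit_gp(
                    ens.design,
                    ens.output(name),
                    kernel_spec=kspec,
                    mean_spec=mspec,
                    optimizer_config=opt,
                    seed=seed,
                )
                for name in ens.output_names
            }

        table = training_size_sweep(
            cohort,
            trainer,
            config.m_grid,
            replicates=config.replicates,
            seed=config.seed,
            n_posterior_samples=config.n_posterior_samples,
        )
        summary = summarize_sweep(table)
    elif config.method == "latent":
        if latents is None:
            raise ArgumentError("the latent method requires latent features")
        table = leave_one_member_out(
            cohort,
            latents,
            config.m_grid,
            replicates=config.replicates,
            seed=config.seed,
            n_posterior_samples=config.n_posterior_samples,
            optimizer_config=opt,
        )
        summary = (
            table.groupby(["model", "evaluation", "output", "total_m"], as_index=False)
            .agg(r2_mean=("r2_mean", "mean"), r2_sd=("r2_sd", "mean"), ise_percent=("ise_percent", "mean"))
        )
    else:
        strategies = (config.strategy,) if config.strategy else STRATEGIES
        table = discrepancy_study(
            cohort,
            config.m_grid,
            strategies=strategies,
            replicates=config.replicates,
            seed=config.seed,
            n_posterior_samples=config.n_posterior_samples,
            lambda_grid=None if config.lambda_grid is None else np.asarray(config.lambda_grid),
            cv_folds=config.cv_folds,
            optimizer_config=opt,
        )
        summary = (
            table.groupby(["model", "output", "m"], as_index=False)
            .agg(r2_mean=("r2_mean", "mean"), r2_sd=("r2_sd", "mean"), ise_percent=("ise_percent", "mean"))
        )
    csv_path = out_dir / f"{config.out_prefix}_table.csv"
    table.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    report = {
        "config": config.to_dict(),
        "summary": summary.to_dict(orient="records"),
    }
    (out_dir / f"{config.out_prefix}_report.json").write_text(json.dumps(report, indent=2))
    log.info("wrote %s", csv_path)
    return table
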