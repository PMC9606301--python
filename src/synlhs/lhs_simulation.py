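"""Continuous-learning simulation of the ML-enabled learning health system.

Each learning cycle adds one fresh patient batch to the accumulated
population, rebuilds the whole data pipeline (standard data -> profiles
-> ML table -> balancing -> conversion -> variable selection) on the
*union* of all data seen so far, retrains every configured algorithm
from scratch, and evaluates on a freshly drawn held-out split.  The
trajectory of per-cycle metrics is the simulation's product: with a
fixed occurrence cutoff, more accumulated patients mean more selected
variables and (tendentially) better recall/AUC.

All randomness is a pure function of (plan, base_seed, cycle index), so
an entire simulation is exactly reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ml_table as mlt
from . import modeling as mdl
from .ml_table import BalanceConfig, ConversionMap, VariableSelection
from .modeling import ModelSpec, SplitSpec
from .profile_builder import ProfileReport, WindowSpec, build_profiles
from .standard_data import to_standard_records
from .synthetic_ehr import (
    DOMAIN_TABLES,
    DiseaseSpec,
    DomainBundle,
    PopulationConfig,
    generate_population,
    read_domain_files,
)


def derive_seed(base_seed: int, *path: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and indices."""
    ss = np.random.SeedSequence([int(base_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


def default_algorithms() -> tuple[ModelSpec, ...]:
    return tuple(ModelSpec(a) for a in mdl.ALGORITHMS)


@dataclass(frozen=True)
class CyclePlan:
    """Configuration of one full simulation.

    ``population`` is the per-batch generator template; its
    ``n_patients`` is the batch size and its disease/risk model define
    the planted structure.  Batch k is generated with a seed derived
    from (base_seed, k), so batches are independent draws.
    """

    population: PopulationConfig
    n_cycles: int = 5
    selection: VariableSelection = VariableSelection()
    balance: BalanceConfig = BalanceConfig()
    window: WindowSpec = WindowSpec()
    conversion: ConversionMap | None = None
    algorithms: tuple[ModelSpec, ...] = field(default_factory=default_algorithms)
    split: SplitSpec = SplitSpec()
    base_seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def batch_size(self) -> int:
        return self.population.n_patients

    @property
    def disease(self) -> DiseaseSpec:
        return self.population.target_disease


@dataclass
class CycleResult:
    """One dataset row of the metric trajectory (counts plus per-algorithm metrics)."""

    cycle_index: int
    dataset: str
    cumulative_patients: int
    n_targets: int
    n_backgrounds: int
    n_variables: int  # variables the models actually used (after any n_top cap)
    n_variables_available: int  # variables passing the fixed occurrence cutoff
    variables: list[str]
    metrics: dict[str, mdl.ModelMetrics]
    profile_report: ProfileReport
    seed: int

    def to_rows(self) -> list[dict]:
        rows = []
        for algo, m in self.metrics.items():
            rows.append(
                {
                    "cycle": self.cycle_index,
                    "dataset": self.dataset,
                    "patients": self.cumulative_patients,
                    "n_targets": self.n_targets,
                    "n_backgrounds": self.n_backgrounds,
                    "variables": self.n_variables,
                    "variables_available": self.n_variables_available,
                    "algorithm": algo,
                    **m.as_dict(),
                    "seed": self.seed,
                }
            )
        return rows


@dataclass
class SimulationResult:
    plan: CyclePlan
    cycles: list[CycleResult]

    @property
    def trajectory(self) -> pd.DataFrame:
        """Wide trajectory frame: one row per (cycle, algorithm)."""
        return pd.DataFrame([r for c in self.cycles for r in c.to_rows()])

    def to_long(self) -> pd.DataFrame:
        """One row per (cycle, algorithm, metric)."""
        traj = self.trajectory
        return traj.melt(
            id_vars=["cycle", "dataset", "patients", "variables", "algorithm"],
            value_vars=["recall", "precision", "auc", "accuracy"],
            var_name="metric",
            value_name="value",
        )

    def write_ledger(self, path: str | Path) -> None:
        """JSON-lines run ledger: per-cycle counts, seeds and metrics."""
        with open(path, "w") as fh:
            for c in self.cycles:
                fh.write(
                    json.dumps(
                        {
                            "cycle": c.cycle_index,
                            "dataset": c.dataset,
                            "cumulative_patients": c.cumulative_patients,
                            "n_targets": c.n_targets,
                            "n_backgrounds": c.n_backgrounds,
                            "n_variables": c.n_variables,
                            "dropped_targets": c.profile_report.n_dropped_targets,
                            "dropped_backgrounds": c.profile_report.n_dropped_backgrounds,
                            "seed": c.seed,
                            "metrics": {a: m.as_dict() for a, m in c.metrics.items()},
                        }
                    )
                    + "\n"
                )


def merge_bundles(bundles: list[DomainBundle]) -> DomainBundle:
    """Concatenate batches table-by-table; patient ids must be disjoint."""
    all_ids = pd.concat([b.patients["id"] for b in bundles], ignore_index=True)
    dup = all_ids[all_ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id across batches, e.g. {dup.iloc[0]!r}")
    tables = {
        name: pd.concat([b.table(name) for b in bundles], ignore_index=True)
        for name in DOMAIN_TABLES
    }
    return DomainBundle(**tables)


def ingest_external_batches(directories: list[str | Path]) -> DomainBundle:
    """Load Synthea-dialect CSV batch directories and merge them."""
    bundles = [read_domain_files(d) for d in directories]
    if not bundles:
        raise ValueError("no batch directories given")
    return merge_bundles(bundles)


def run_cycle(
    records: pd.DataFrame,
    patients: pd.DataFrame,
    plan: CyclePlan,
    cycle_index: int,
) -> CycleResult:
    """Execute one full pipeline pass on the accumulated standard data."""
    try:
        targets_long, backgrounds_long, report = build_profiles(records, patients, plan.disease, plan.window)
    except Exception as exc:
        raise RuntimeError(f"learning cycle {cycle_index} failed: {exc}") from exc
    return _cycle_from_profiles(targets_long, backgrounds_long, report, len(patients), plan, cycle_index)


def _cycle_from_profiles(
    targets_long: pd.DataFrame,
    backgrounds_long: pd.DataFrame,
    report: ProfileReport,
    cumulative: int,
    plan: CyclePlan,
    cycle_index: int,
) -> CycleResult:
    try:
        codes = mlt.shared_codes(targets_long, backgrounds_long)
        table = mlt.build_table(targets_long, backgrounds_long, codes)
        table = mlt.balance(table, plan.balance)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unmapped numeric codes use the documented median-split fallback
            table = mlt.convert_values(table, plan.conversion)
        variables = mlt.select_variables(table, plan.selection)
        # growth under the fixed cutoff alone (no n_top cap) is the
        # emergent property tracked across cycles
        n_available = len(mlt.select_variables(table, replace(plan.selection, n_top=None)))

        split_seed = derive_seed(plan.base_seed, cycle_index, 1)
        split = replace(plan.split, seed=split_seed)
        metrics: dict[str, mdl.ModelMetrics] = {}
        for i, spec in enumerate(plan.algorithms):
            model_seed = derive_seed(plan.base_seed, cycle_index, 2 + i)
            run = mdl.fit_and_evaluate(table, variables, spec, split, model_seed)
            metrics[spec.algorithm] = run.metrics
    except Exception as exc:
        raise RuntimeError(f"learning cycle {cycle_index} failed: {exc}") from exc

    return CycleResult(
        cycle_index=cycle_index,
        dataset=_dataset_name(cumulative),
        cumulative_patients=cumulative,
        n_targets=table.n_targets,
        n_backgrounds=table.n_backgrounds,
        n_variables=len(variables),
        n_variables_available=n_available,
        variables=variables,
        metrics=metrics,
        profile_report=report,
        seed=plan.base_seed,
    )


def _dataset_name(n: int) -> str:
    return f"pt{n // 1000}k" if n >= 1000 and n % 1000 == 0 else f"pt{n}"


def run_simulation(plan: CyclePlan, batches: list[DomainBundle] | None = None) -> SimulationResult:
    """Run all learning cycles, generating (or ingesting) one batch each.

    When ``batches`` is given it must hold ``n_cycles`` pre-built
    bundles (e.g. from :func:`ingest_external_batches`); otherwise each
    batch is generated from the plan's population template with a
    cycle-derived seed.
    """
    if batches is not None and len(batches) != plan.n_cycles:
        raise ValueError("need exactly one batch per cycle")
    seen_ids: set[str] = set()
    t_parts: list[pd.DataFrame] = []
    b_parts: list[pd.DataFrame] = []
    reports: list[ProfileReport] = []
    cumulative = 0
    cycles: list[CycleResult] = []
    for k in range(1, plan.n_cycles + 1):
        if batches is None:
            cfg = replace(plan.population, seed=derive_seed(plan.base_seed, k, 0))
            batch = generate_population(cfg)
        else:
            batch = batches[k - 1]
        ids = set(batch.patients["id"])
        if ids & seen_ids:
            raise ValueError(f"cycle {k}: duplicate patient_id across batches")
        seen_ids |= ids
        cumulative += batch.n_patients
        # profiles are per-patient and batches hold disjoint patients, so
        # building them batch-by-batch equals rebuilding on the full
        # accumulated record stream (re-sorting restores the global order)
        records = to_standard_records(batch)
        t_long, b_long, rep = build_profiles(records, batch.patients, plan.disease, plan.window)
        t_parts.append(t_long)
        b_parts.append(b_long)
        reports.append(rep)
        targets_long = _sorted_concat(t_parts)
        backgrounds_long = _sorted_concat(b_parts)
        report = ProfileReport(
            n_targets=sum(r.n_targets for r in reports),
            n_backgrounds=sum(r.n_backgrounds for r in reports),
            n_dropped_targets=sum(r.n_dropped_targets for r in reports),
            n_dropped_backgrounds=sum(r.n_dropped_backgrounds for r in reports),
        )
        cycles.append(_cycle_from_profiles(targets_long, backgrounds_long, report, cumulative, plan, k))
    return SimulationResult(plan, cycles)


def _sorted_concat(parts: list[pd.DataFrame]) -> pd.DataFrame:
    if len(parts) == 1:
        return parts[0]
    return pd.concat(parts, ignore_index=True).sort_values(["patient_id", "code"], kind="stable", ignore_index=True)


def compare_algorithms(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle ranking of algorithms by recall (ties: algorithm name)."""
    if trajectory["algorithm"].nunique() < 2:
        raise ValueError("need at least two algorithms to rank")
    out = []
    for cycle, grp in trajectory.groupby("cycle"):
        ranked = grp.sort_values(["recall", "algorithm"], ascending=[False, True], kind="stable").copy()
        ranked["rank"] = np.arange(1, len(ranked) + 1)
        out.append(ranked)
    return pd.concat(out, ignore_index=True)[
        ["cycle", "dataset", "algorithm", "rank", "recall", "precision", "auc", "accuracy"]
    ]
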