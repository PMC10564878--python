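"""Experiment grid orchestration: setups x replicate seeds.

One integer replicate seed expands deterministically (splitmix64) into the
three seeds a run consumes — split_seed, init_seed, shuffle_seed — so a
single seed column is enough to reproduce any run.  Grids are resumable:
each completed run leaves a JSON manifest keyed on (setup, seed, config
hash), and re-running a finished grid retrains nothing.  A failing run is
recorded and the grid continues.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import compute_importance
from .cohort_io import Cohort, make_split
from .controls import apply_control
from .graphkit import LayeredDAG
from .sparse_net import NetworkConfig, init_network, train

logger = logging.getLogger("biasaudit")

SETUPS = ("original", "deterministic", "shuffled")

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_seeds(base_seed: int, replicate_seed: int) -> tuple[int, int, int]:
    """(split_seed, init_seed, shuffle_seed) for one replicate.

    A splitmix64 stream seeded on (base_seed, replicate_seed); each output
    is reduced below 2**31.
    """
    state = _splitmix64((base_seed << 20) ^ replicate_seed)
    out = []
    for _ in range(3):
        state = _splitmix64(state)
        out.append(state % (1 << 31))
    return tuple(out)


@dataclass(frozen=True)
class ExperimentPlan:
    """Which setups to run, with which replicate seeds and training config."""

    setups: tuple[str, ...] = SETUPS
    seeds: tuple[int, ...] = tuple(range(50))
    config: NetworkConfig = field(default_factory=NetworkConfig)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    base_seed: int = 0
    importance_mode: str = "mean_abs"
    normalize: str = "degree"
    partition: str = "test"

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("duplicate replicate seeds")
        if not self.setups:
            raise ValueError("at least one setup required")
        unknown = set(self.setups) - set(SETUPS)
        if unknown:
            raise ValueError(f"unknown setups: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = {
            "config": asdict(self.config),
            "fractions": self.fractions,
            "base_seed": self.base_seed,
            "importance_mode": self.importance_mode,
            "normalize": self.normalize,
            "partition": self.partition,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ImportanceMatrix:
    """Hidden-node x replicate importance scores for one setup."""

    scores: pd.DataFrame  # rows: node_id; columns: "<setup>:<seed>"
    setup: str
    aggregation_mode: str
    normalize_mode: str

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("importance scores must be finite and >= 0")


@dataclass
class GridResult:
    importance: dict[str, ImportanceMatrix]
    metrics: pd.DataFrame
    failures: list[dict]

    def column_counts(self) -> dict[str, int]:
        return {s: m.scores.shape[1] for s, m in self.importance.items()}


def _run_one(plan: ExperimentPlan, dag: LayeredDAG, cohort: Cohort,
             setup: str, seed: int):
    split_seed, init_seed, shuffle_seed = derive_seeds(plan.base_seed, seed)
    ctrl = apply_control(cohort, setup, shuffle_seed=shuffle_seed)
    split = make_split(ctrl, fractions=plan.fractions, split_seed=split_seed)
    net = init_network(dag, plan.config.with_seed(init_seed))
    net.setup = setup
    train(net, ctrl, split)
    partition = plan.partition
    imp = compute_importance(
        net, ctrl, split, partition=partition,
        mode=plan.importance_mode, normalize=plan.normalize,
    )
    metrics = {k: v for k, v in net.metrics.items() if k != "roc"}
    metrics.update(setup=setup, seed=seed, split_seed=split_seed, init_seed=init_seed)
    roc = net.metrics["roc"]
    return imp, metrics, roc


def run_plan(
    plan: ExperimentPlan,
    dag: LayeredDAG,
    cohort: Cohort,
    outdir: str | Path | None = None,
    resume: bool = True,
) -> GridResult:
    """Execute the full grid and collect importance matrices and metrics.

    With ``outdir``, every completed run writes a manifest and per-run
    outputs; runs whose manifest matches the plan's config hash are
    skipped on re-execution.  Per-run failures are collected, not raised.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        (outdir / "runs").mkdir(parents=True, exist_ok=True)
    chash = plan.config_hash()
    columns: dict[str, dict[str, pd.Series]] = {s: {} for s in plan.setups}
    metric_rows: list[dict] = []
    failures: list[dict] = []

    for setup in plan.setups:
        for seed in plan.seeds:
            key = f"{setup}:{seed}"
            manifest_path = (outdir / "runs" / f"{setup}_{seed}.json") if outdir else None
            if resume and manifest_path is not None and manifest_path.exists():
                saved = json.loads(manifest_path.read_text())
                if saved.get("config_hash") == chash:
                    logger.info("resume: skipping completed run %s", key)
                    columns[setup][key] = pd.Series(saved["importance"], name=key)
                    metric_rows.append(saved["metrics"])
                    continue
            try:
                imp, metrics, roc = _run_one(plan, dag, cohort, setup, seed)
            except Exception as exc:  # grid continues past failures
                logger.warning("run %s failed: %s", key, exc)
                failures.append({"setup": setup, "seed": seed, "error": str(exc)})
                continue
            columns[setup][key] = imp.rename(key)
            metric_rows.append(metrics)
            if outdir is not None:
                roc.to_csv(outdir / f"roc_{setup}_{seed}.csv", index=False)
                manifest = {
                    "config_hash": chash,
                    "setup": setup,
                    "seed": seed,
                    "metrics": metrics,
                    "importance": imp.to_dict(),
                }
                manifest_path.write_text(json.dumps(manifest, sort_keys=True))

    importance = {}
    for setup in plan.setups:
        if not columns[setup]:
            continue
        df = pd.DataFrame(columns[setup])
        df.index.name = "node_id"
        importance[setup] = ImportanceMatrix(
            scores=df, setup=setup,
            aggregation_mode=plan.importance_mode,
            normalize_mode=plan.normalize,
        )
    metrics = pd.DataFrame(metric_rows)
    if outdir is not None:
        for setup, mat in importance.items():
            mat.scores.to_csv(outdir / f"importance_{setup}.csv")
        metrics.to_csv(outdir / "metrics.csv", index=False)
        if failures:
            (outdir / "failures.json").write_text(json.dumps(failures, indent=2))
    if failures:
        logger.warning("grid finished with %d failed runs", len(failures))
    return GridResult(importance=importance, metrics=metrics, failures=failures)


def summarize_robustness(
    matrix: ImportanceMatrix | pd.DataFrame,
    reference_column: str | None = None,
) -> pd.DataFrame:
    """Per-node five-number summary with 1.5 x IQR whiskers and outliers.

    Boxes are the median and 25/75% quartiles; whiskers extend to the most
    extreme value inside 1.5 x IQR; values beyond are outliers.  If a
    reference column is named (the "original seed" network), its rank
    within each node's replicate distribution is reported (rank 1 =
    largest).
    """
    scores = matrix.scores if isinstance(matrix, ImportanceMatrix) else matrix
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 replicate columns")
    ref = scores[reference_column] if reference_column is not None else None
    rep = scores.drop(columns=[reference_column]) if reference_column else scores

    q1 = rep.quantile(0.25, axis=1)
    med = rep.quantile(0.5, axis=1)
    q3 = rep.quantile(0.75, axis=1)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    rows = []
    for node in rep.index:
        vals = rep.loc[node]
        inside = vals[(vals >= lo_fence[node]) & (vals <= hi_fence[node])]
        outliers = vals[(vals < lo_fence[node]) | (vals > hi_fence[node])]
        row = {
            "node_id": node,
            "median": med[node],
            "q1": q1[node],
            "q3": q3[node],
            "whisker_low": inside.min() if len(inside) else np.nan,
            "whisker_high": inside.max() if len(inside) else np.nan,
            "outliers": ";".join(f"{v:g}" for v in sorted(outliers)),
        }
        if ref is not None:
            row["reference_rank"] = int((rep.loc[node] > ref[node]).sum()) + 1
        rows.append(row)
    return pd.DataFrame(rows).set_index("node_id")
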