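"""The replicate grid: configuration, seeding, execution, aggregation.

A run evaluates every configured dataset under every prior fraction with
``replicates`` independently seeded screening simulations per cell — the
study design is |datasets| x |fractions| x replicates trajectories, each
scored under all configured stop criteria.  Cells are independently
reproducible: the seed of replicate k of fraction j of dataset i is a pure
function of (base_seed, i, j, k), so interrupted runs resume without
recomputing completed cells and identical configs give byte-identical
aggregates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, read_labeled_corpus
from .metrics import stats_frame, trajectory_stats, write_table
from .screener import simulate_screening, write_trajectory
from .stopping import (
    apply_criterion1,
    apply_criterion2,
    apply_criterion3,
    estimate_relevant_total,
)
from .synthetic import SyntheticSpec, generate_corpus

log = logging.getLogger("screenstop")

#: the study's prior-fraction levels: 1%..30% of the corpus
DEFAULT_PRIOR_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class RunConfig:
    """Declarative description of one simulation grid.

    ``datasets`` entries are either ``{"path": ..., "dialect": ...}`` for a
    corpus on disk or ``{"synthetic": {...SyntheticSpec fields...}}``.
    There are no hidden defaults beyond the field defaults here; the config
    is echoed verbatim into the run manifest.
    """

    datasets: list[dict[str, Any]]
    prior_fractions: list[float] = field(
        default_factory=lambda: list(DEFAULT_PRIOR_FRACTIONS)
    )
    replicates: int = 1000
    base_seed: int = 0
    alpha: float = 1.0
    retrain_every: int = 1
    prior_policy: str = "resample"
    criterion2_scope: str = "active-only"
    c2_thresholds: list[int] = field(default_factory=lambda: [50, 100, 200])
    c3_percentages: list[float] = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8, 1.0])
    save_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not 0 < f < 1 for f in self.prior_fractions):
            raise ValueError("prior fractions must be in (0,1)")
        if not self.datasets:
            raise ValueError("no datasets configured")

    @property
    def n_cells(self) -> int:
        return len(self.datasets) * len(self.prior_fractions)

    @property
    def n_trajectories(self) -> int:
        return self.n_cells * self.replicates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")
        return path

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def cell_seed(base_seed: int, i: int, j: int, k: int) -> int:
    """Deterministic, collision-resistant seed for replicate k of cell (i,j)."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(i, j, k))
    return int(ss.generate_state(1)[0] % 2**31)


def load_dataset(entry: dict[str, Any]) -> Corpus:
    if "synthetic" in entry:
        return generate_corpus(SyntheticSpec(**entry["synthetic"]))
    if "path" in entry:
        kw = {k: v for k, v in entry.items() if k not in ("path",)}
        return read_labeled_corpus(entry["path"], **kw)
    raise ValueError(f"dataset entry needs 'path' or 'synthetic': {entry}")


def _evaluate(traj, config: RunConfig) -> list[dict[str, Any]]:
    """Score one trajectory under every configured criterion/threshold."""
    rows = []
    base = {"dataset": traj.dataset, "f": traj.f, "seed": traj.seed}

    def add(criterion, threshold, out):
        rows.append(
            {
                **base,
                "criterion": criterion,
                "threshold": threshold,
                "stop_index": out.stop_index,
                "triggered": out.triggered,
                "recall": out.recall,
                "missed": out.missed,
                "work_saved_pct": out.work_saved_pct,
            }
        )

    if traj.prior is not None:
        R_hat = estimate_relevant_total(traj.prior.n_s, traj.prior.r_s, traj.N)
        add(1, R_hat, apply_criterion1(traj, R_hat))
    for c in config.c2_thresholds:
        add(2, c, apply_criterion2(traj, c, scope=config.criterion2_scope))
    for p in config.c3_percentages:
        add(3, p, apply_criterion3(traj, p))
    return rows


def run_grid(config: RunConfig, out_dir: str | Path, *, resume: bool = True) -> Path:
    """Execute the full grid and write stats, evaluations, tables, manifest.

    Layout of the run directory::

        config.yaml                 echo of the config
        cells/<ds>_f<j>.stats.csv   per-run statistics, one cell per file
        cells/<ds>_f<j>.evals.csv   stop-criterion evaluations
        stats.csv, evaluations.csv  concatenated long-format outputs
        table_t3.txt, table_t4.txt, table_t5.txt
        manifest.json               config hash, seeds policy, completion

    With ``resume=True`` a cell whose stats file already holds the full
    replicate count is skipped; partial cells are recomputed from their
    seeds.
    """
    out = Path(out_dir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    if config.save_trajectories:
        (out / "trajectories").mkdir(exist_ok=True)

    corpora = [load_dataset(entry) for entry in config.datasets]
    names = [c.name for c in corpora]
    if len(set(names)) != len(names):
        raise ValueError(f"dataset names must be unique, got {names}")
    for c in corpora:
        c.validate_for_screening()

    completed: dict[str, int] = {}
    for i, corpus in enumerate(corpora):
        for j, f in enumerate(config.prior_fractions):
            cell = f"{corpus.name}_f{j}"
            stats_path = out / "cells" / f"{cell}.stats.csv"
            evals_path = out / "cells" / f"{cell}.evals.csv"
            if resume and stats_path.exists():
                prev = pd.read_csv(stats_path)
                if len(prev) == config.replicates and evals_path.exists():
                    log.info("cell %s complete, skipping", cell)
                    completed[cell] = len(prev)
                    continue
                log.info("cell %s partial (%d rows), recomputing", cell, len(prev))
            cell_stats, cell_evals = [], []
            for k in range(config.replicates):
                seed = cell_seed(config.base_seed, i, j, k)
                traj = simulate_screening(
                    corpus,
                    f,
                    seed,
                    retrain_every=config.retrain_every,
                    alpha=config.alpha,
                    prior_policy=config.prior_policy,
                )
                cell_stats.append(trajectory_stats(traj))
                cell_evals.extend(_evaluate(traj, config))
                if config.save_trajectories:
                    write_trajectory(traj, out / "trajectories" / f"{cell}_r{k}.csv")
            stats_frame(cell_stats).to_csv(stats_path, index=False)
            pd.DataFrame(cell_evals).to_csv(evals_path, index=False)
            completed[cell] = config.replicates
            log.info("cell %s: %d runs done", cell, config.replicates)

    stats = pd.concat(
        [
            pd.read_csv(out / "cells" / f"{c.name}_f{j}.stats.csv")
            for c in corpora
            for j in range(len(config.prior_fractions))
        ],
        ignore_index=True,
    )
    evals = pd.concat(
        [
            pd.read_csv(out / "cells" / f"{c.name}_f{j}.evals.csv")
            for c in corpora
            for j in range(len(config.prior_fractions))
        ],
        ignore_index=True,
    )
    stats.to_csv(out / "stats.csv", index=False)
    evals.to_csv(out / "evaluations.csv", index=False)
    for t in ("t3", "t4", "t5"):
        write_table(stats, t, out / f"table_{t}.txt")

    n_done = int(sum(completed.values()))
    manifest = {
        "config_hash": config.config_hash(),
        "seed_scheme": "SeedSequence(base_seed, spawn_key=(dataset, fraction, replicate))",
        "base_seed": config.base_seed,
        "datasets": names,
        "prior_fractions": config.prior_fractions,
        "replicates": config.replicates,
        "cells": completed,
        "n_trajectories": n_done,
        "n_expected": config.n_trajectories,
    }
    if n_done != config.n_trajectories:
        raise AssertionError(
            f"grid cardinality mismatch: {n_done} != {config.n_trajectories}"
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return out


def demo_config(base_seed: int = 0, *, replicates: int = 20) -> RunConfig:
    """A small grid that exercises the whole pipeline in minutes.

    Two synthetic corpora spanning the prevalence range seen in real
    screening benchmarks — a very rare class (0.6%, no hard relevants at
    the default hard_fraction) and a common one (6%, three background-like
    relevants) — under three prior fractions, 20 replicates each.
    """
    return RunConfig(
        datasets=[
            {
                "synthetic": {
                    "N": 500,
                    "R": 3,
                    "separability": 0.8,
                    "hard_fraction": 0.1,
                    "seed": 11,
                    "name": "rare",
                }
            },
            {
                "synthetic": {
                    "N": 500,
                    "R": 30,
                    "separability": 0.8,
                    "hard_fraction": 0.1,
                    "seed": 12,
                    "name": "common",
                }
            },
        ],
        prior_fractions=[0.01, 0.05, 0.10],
        replicates=replicates,
        base_seed=base_seed,
        c2_thresholds=[10, 25, 50, 100],
        c3_percentages=[0.2, 0.4, 0.6, 0.8, 1.0],
    )
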