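"""Per-trajectory statistics and replicate-grid aggregates.

The headline per-run statistics are:

* ``pct_to_last_relevant`` — the 1-based position of the final relevant
  record, as a percentage of corpus size.  This is both the theoretical
  upper bound on work that early stopping could save and the per-run
  break-even threshold for criterion 3.
* the minimal safe streak ``g`` (break-even of criterion 2), and
* the criterion-1 estimate, its relative error, and its outcome category.

Aggregation over replicates reports min / max / mean / sample SD (n-1
denominator) per dataset x prior-fraction cell, and the grid reports render
as aligned plain-text tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screener import Trajectory
from .stopping import (
    C1_CATEGORIES,
    classify_c1_outcome,
    estimate_relevant_total,
    minimal_safe_streak,
    relative_estimation_error,
)


@dataclass(frozen=True)
class TrajectoryStats:
    """All per-run statistics of one screening trajectory."""

    dataset: str
    f: float | None
    seed: int | None
    N: int
    R: int
    pct_to_last_relevant: float
    g: int
    g_pct: float
    R_hat: int | None = None
    relative_error_pct: float | None = None
    c1_outcome: str | None = None


def pct_to_last_relevant(traj: Trajectory) -> float:
    """Position of the final relevant record as a % of corpus size.

    1-based over the full trajectory, prior phase included: those records
    were manually reviewed, so they count as screened.
    """
    rel = np.nonzero(traj.labels == 1)[0]
    if rel.size == 0:
        raise ValueError("trajectory has no relevant records")
    return (int(rel[-1]) + 1) / traj.N * 100


def trajectory_stats(traj: Trajectory) -> TrajectoryStats:
    """Compute every per-run statistic; criterion-1 fields need a prior."""
    g, g_pct = minimal_safe_streak(traj)
    R_hat = rel_err = outcome = None
    if traj.prior is not None:
        R_hat = estimate_relevant_total(traj.prior.n_s, traj.prior.r_s, traj.N)
        rel_err = relative_estimation_error(R_hat, traj.R)
        outcome = classify_c1_outcome(R_hat, traj.R)
    return TrajectoryStats(
        dataset=traj.dataset,
        f=traj.f,
        seed=traj.seed,
        N=traj.N,
        R=traj.R,
        pct_to_last_relevant=pct_to_last_relevant(traj),
        g=g,
        g_pct=g_pct,
        R_hat=R_hat,
        relative_error_pct=rel_err,
        c1_outcome=outcome,
    )


def stats_frame(stats: Iterable[TrajectoryStats]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in stats])


def aggregate(
    df: pd.DataFrame,
    value: str,
    by: Sequence[str] = ("dataset", "f"),
) -> pd.DataFrame:
    """min / max / mean / sample SD of one statistic per grid cell.

    Cells need at least two values for the SD to exist; an empty frame is
    an error rather than an empty answer.
    """
    if df.empty:
        raise ValueError("nothing to aggregate")
    by = list(by)
    out = (
        df.groupby(by, dropna=False)[value]
        .agg(n_runs="count", min="min", max="max", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if (out["n_runs"] < 2).any():
        raise ValueError("need >= 2 values per cell for the sample SD")
    return out


def c1_outcome_shares(outcomes: Iterable[str]) -> dict[str, float]:
    """Percentage share of each criterion-1 outcome category."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to tally")
    n = len(outcomes)
    return {cat: outcomes.count(cat) / n * 100 for cat in C1_CATEGORIES}


def _fmt_row(cells: Sequence[str], widths: Sequence[int]) -> str:
    return "  ".join(c.rjust(w) if i else c.ljust(w) for i, (c, w) in enumerate(zip(cells, widths)))


def _render(header: Sequence[str], rows: list[Sequence[str]], title: str) -> str:
    widths = [max(len(h), *(len(r[i]) for r in rows)) for i, h in enumerate(header)]
    lines = [title, _fmt_row(header, widths), _fmt_row(["-" * w for w in widths], widths)]
    lines += [_fmt_row(r, widths) for r in rows]
    return "\n".join(lines) + "\n"


def render_table(
    stats: pd.DataFrame,
    table: str,
    *,
    total_mode: str = "pooled",
) -> str:
    """Render one of the three grid reports as an aligned plain-text table.

    ``t3``: mean/SD of the criterion-1 relative estimation error per
    dataset x prior fraction, with a Total row (``total_mode="pooled"``
    pools all runs; ``"mean-of-means"`` averages the cell means).
    ``t4``: min/max/mean/SD of the % screened to find the last relevant
    record, per dataset (all prior fractions pooled).
    ``t5``: min/max/mean/SD of the minimal safe streak (% of corpus),
    per dataset.

    Rendering is deterministic: identical input gives byte-identical text.
    """
    d1 = lambda x: f"{x:.1f}"
    if table == "t3":
        fracs = sorted(stats["f"].dropna().unique())
        need = {(ds, f) for ds in stats["dataset"].unique() for f in fracs}
        have = set(map(tuple, stats[["dataset", "f"]].drop_duplicates().values))
        holes = sorted(need - have)
        if holes:
            raise ValueError(f"incomplete grid, missing cells: {holes}")
        agg = aggregate(stats, "relative_error_pct", by=["dataset", "f"])
        header = ["Dataset"] + [x for f in fracs for x in (f"{f*100:g}% M", "SD")]
        rows = []
        for ds in sorted(stats["dataset"].unique()):
            sub = agg[agg["dataset"] == ds].set_index("f")
            rows.append([ds] + [d1(sub.loc[f, k]) for f in fracs for k in ("mean", "sd")])
        if total_mode == "pooled":
            tot = aggregate(stats, "relative_error_pct", by=["f"]).set_index("f")
            rows.append(["Total"] + [d1(tot.loc[f, k]) for f in fracs for k in ("mean", "sd")])
        elif total_mode == "mean-of-means":
            cells = []
            for f in fracs:
                sub = agg[agg["f"] == f]
                cells += [d1(sub["mean"].mean()), d1(sub["sd"].mean())]
            rows.append(["Total"] + cells)
        else:
            raise ValueError(f"unknown total_mode {total_mode!r}")
        title = "Relative error of the criterion-1 estimate (%), by prior fraction"
    elif table in ("t4", "t5"):
        value = "pct_to_last_relevant" if table == "t4" else "g_pct"
        agg = aggregate(stats, value, by=["dataset"])
        header = ["Dataset", "n", "Min", "Max", "Mean", "SD"]
        rows = [
            [r.dataset, str(r.n_runs), d1(r.min), d1(r.max), d1(r.mean), d1(r.sd)]
            for r in agg.sort_values("dataset").itertuples(index=False)
        ]
        title = (
            "% of corpus screened to find all relevant records"
            if table == "t4"
            else "Minimal safe criterion-2 streak (% of corpus)"
        )
    else:
        raise ValueError(f"unknown table {table!r}")
    return _render(header, rows, title)


def write_table(stats: pd.DataFrame, table: str, path: str | Path, **kw) -> Path:
    path = Path(path)
    path.write_text(render_table(stats, table, **kw), encoding="utf-8")
    return path
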