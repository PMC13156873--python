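"""The three early-stopping rules, applied retrospectively to trajectories.

* **Criterion 1** — stop once the number of relevant records found reaches
  an estimate extrapolated from the prior sample: with r_s relevants in a
  random sample of n_s, R_hat = round(r_s / n_s * N).
* **Criterion 2** — stop after a threshold ``c`` of consecutively screened
  irrelevant records with no relevant in between.
* **Criterion 3** — stop once a fixed fraction ``p`` of the corpus has been
  screened.

Because the trajectories carry oracle labels, each rule's cost can be
scored exactly: the recall at the stop point, the relevant records missed,
and the share of the corpus never screened (work saved).  The
``minimal_safe_streak`` statistic is the per-run break-even of criterion 2:
the largest interior gap between two relevant records, so a threshold of
gap+1 would have missed nothing on that run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import round_half_up
from .screener import Trajectory


@dataclass(frozen=True)
class StopOutcome:
    """Where a rule halted one trajectory and at what cost.

    ``stop_index`` counts records screened when the rule fires (prior phase
    included), or N if it never fires.
    """

    stop_index: int
    triggered: bool
    found_relevant: int
    missed: int
    recall: float
    work_saved_pct: float

    @classmethod
    def at(cls, traj: Trajectory, stop_index: int, triggered: bool) -> "StopOutcome":
        found = int(traj.labels[:stop_index].sum())
        return cls(
            stop_index=stop_index,
            triggered=triggered,
            found_relevant=found,
            missed=traj.R - found,
            recall=found / traj.R if traj.R else 1.0,
            work_saved_pct=(1 - stop_index / traj.N) * 100,
        )


def estimate_relevant_total(n_s: int, r_s: int, N: int) -> int:
    """Criterion-1 estimator: extrapolate the prior sample's prevalence.

    R_hat = round(r_s / n_s * N), half-up.  E.g. 5 relevants in a random
    sample of 100 from a corpus of 10,000 estimates 500 relevant records.
    """
    if n_s <= 0:
        raise ValueError("prior sample size must be positive")
    if not 0 <= r_s <= n_s:
        raise ValueError("need 0 <= r_s <= n_s")
    if n_s > N:
        raise ValueError("prior sample cannot exceed the corpus")
    return int(round_half_up(r_s / n_s * N))


def apply_criterion1(traj: Trajectory, R_hat: int) -> StopOutcome:
    """Stop at the first position where cumulative relevants reach R_hat.

    R_hat = 0 fires immediately at position 0 (nothing screened); an
    unreachable R_hat (> R) means the whole corpus is screened and the rule
    never triggers.
    """
    if R_hat < 0:
        raise ValueError("R_hat must be >= 0")
    if R_hat == 0:
        return StopOutcome.at(traj, 0, True)
    cum = np.cumsum(traj.labels)
    hit = np.nonzero(cum >= R_hat)[0]
    if hit.size == 0:
        return StopOutcome.at(traj, traj.N, False)
    return StopOutcome.at(traj, int(hit[0]) + 1, True)


def apply_criterion2(traj: Trajectory, c: int, scope: str = "active-only") -> StopOutcome:
    """Stop when ``c`` consecutive irrelevant records have been screened.

    The streak resets on every relevant record.  With ``scope="active-only"``
    (default) streak counting starts after the prior phase — runs of
    irrelevants inside the random prior say nothing about the ranker; with
    ``scope="full"`` counting starts at position 0.  ``stop_index`` always
    counts all screened records, prior phase included.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if scope not in ("active-only", "full"):
        raise ValueError(f"unknown scope {scope!r}")
    start = traj.prior_len if scope == "active-only" else 0
    streak = 0
    for pos in range(start, traj.N):
        if traj.labels[pos] == 1:
            streak = 0
        else:
            streak += 1
            if streak == c:
                return StopOutcome.at(traj, pos + 1, True)
    return StopOutcome.at(traj, traj.N, False)


def apply_criterion3(traj: Trajectory, p: float) -> StopOutcome:
    """Stop once ceil(p * N) records (prior phase included) are screened."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    stop = int(np.ceil(p * traj.N))
    return StopOutcome.at(traj, stop, stop < traj.N)


def minimal_safe_streak(traj: Trajectory) -> tuple[int, float]:
    """Largest run of consecutive irrelevants between two relevant records.

    Returns ``(g, g_pct)`` with ``g_pct = g / N * 100``.  Runs before the
    first and after the last relevant are excluded: the statistic asks how
    patient criterion 2 must be *while relevants are still coming*.  A
    criterion-2 threshold of ``g + 1`` misses nothing on this trajectory
    (provided streak counting cannot fire before the first relevant — under
    active-only scope this holds whenever the prior phase contains at least
    one relevant), while ``g`` itself misses at least one record whenever
    any interior gap exists.
    """
    labels = traj.labels
    rel = np.nonzero(labels == 1)[0]
    if rel.size == 0:
        raise ValueError("trajectory has no relevant records")
    gaps = np.diff(rel) - 1  # irrelevant run lengths between consecutive relevants
    g = int(gaps.max()) if gaps.size else 0
    return g, g / traj.N * 100


def classify_c1_outcome(R_hat: int, R: int) -> str:
    """Bucket a criterion-1 estimate against the truth.

    ``overestimate`` (R_hat > R: the rule never fires, full screen),
    ``exact`` (the only reliable case), ``miss_one`` (one relevant record
    erroneously excluded), ``miss_many`` (more than one excluded).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if R_hat > R:
        return "overestimate"
    if R_hat == R:
        return "exact"
    if R_hat == R - 1:
        return "miss_one"
    return "miss_many"


C1_CATEGORIES = ("overestimate", "exact", "miss_one", "miss_many")


def relative_estimation_error(R_hat: int, R: int) -> float:
    """(R_hat - R) / R * 100; positive means overestimation."""
    if R < 1:
        raise ValueError("R must be >= 1")
    return (R_hat - R) / R * 100
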