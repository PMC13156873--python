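"""The active-learning screening simulation.

One simulated run mimics a reviewer using an active-learning screening tool
with its default pipeline: TF-IDF features, a multinomial naive Bayes
relevance model, and certainty-based selection.  A random *prior sample* is
labeled first (the reviewer's initial manual screening); then the loop
repeats {train on every label revealed so far; rank the unscreened records
by predicted relevance; reveal the oracle label of the top record} until the
whole corpus has been screened.  Stop criteria are never applied inside the
loop — the full trajectory is recorded and the rules are evaluated
retrospectively.

Featurization is frozen to keep trajectories reproducible across machines:
text is title + " " + abstract, lowercased, tokenized with the regex
``(?u)\\b\\w\\w+\\b`` (word characters, length >= 2), weighted by
tf x (ln((1+N)/(1+df)) + 1) and L2-normalized per record.  The vocabulary
is fit once on the full corpus; labels never touch featurization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.naive_bayes import MultinomialNB

from ._util import round_half_up
from .corpus import Corpus

TOKEN_PATTERN = r"(?u)\b\w\w+\b"


@dataclass
class FeatureMatrix:
    """Sparse TF-IDF term weights, one L2-normalized row per record."""

    X: sp.csr_matrix
    vocabulary: dict[str, int]
    record_ids: list[str]
    empty_mask: np.ndarray  # True where the record had no usable text
    row_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.row_index = {rid: i for i, rid in enumerate(self.record_ids)}


@dataclass(frozen=True)
class PriorSample:
    """The initial random training subset.

    ``n_s`` and ``r_s`` feed the criterion-1 estimator: the prevalence in
    this sample is extrapolated to the full corpus.
    """

    record_ids: tuple[str, ...]
    n_s: int
    r_s: int
    f: float
    n_resamples: int = 0


@dataclass
class Trajectory:
    """The ordered (record_id, label) reveals of one full screening run.

    A permutation of the corpus: prior-phase records first (in sampling
    order), then the active phase.  ``labels[k]`` is the oracle label of the
    (k+1)-th record screened.
    """

    steps: list[tuple[str, int]]
    prior_len: int
    N: int
    R: int
    seed: int | None = None
    dataset: str = "corpus"
    f: float | None = None
    prior: PriorSample | None = None

    def __post_init__(self) -> None:
        if len(self.steps) != self.N:
            raise ValueError("trajectory must cover all N records")
        if sum(lab for _, lab in self.steps) != self.R:
            raise ValueError("trajectory labels must sum to R")

    @property
    def labels(self) -> np.ndarray:
        return np.fromiter((lab for _, lab in self.steps), dtype=np.int8, count=self.N)

    @property
    def record_ids(self) -> list[str]:
        return [rid for rid, _ in self.steps]

    def to_frame(self) -> pd.DataFrame:
        """One row per screening step: step (1-based), record_id, label, phase."""
        return pd.DataFrame(
            {
                "step": np.arange(1, self.N + 1),
                "record_id": self.record_ids,
                "label": self.labels,
                "phase": ["prior"] * self.prior_len
                + ["active"] * (self.N - self.prior_len),
            }
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        *,
        seed: int | None = None,
        dataset: str = "corpus",
        f: float | None = None,
    ) -> "Trajectory":
        steps = [(str(r.record_id), int(r.label)) for r in df.itertuples(index=False)]
        prior_len = int((df["phase"] == "prior").sum())
        return cls(
            steps=steps,
            prior_len=prior_len,
            N=len(steps),
            R=sum(l for _, l in steps),
            seed=seed,
            dataset=dataset,
            f=f,
        )


def featurize(corpus: Corpus) -> FeatureMatrix:
    """TF-IDF featurize the whole corpus once (label-blind)."""
    texts = [rec.text.lower() for rec in corpus]
    empty_mask = np.array([rec.is_empty for rec in corpus], dtype=bool)
    if empty_mask.all():
        raise ValueError("corpus has no usable text in any record")
    vec = TfidfVectorizer(
        lowercase=True,
        token_pattern=TOKEN_PATTERN,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    X = vec.fit_transform(texts).tocsr()
    return FeatureMatrix(
        X=X,
        vocabulary=dict(vec.vocabulary_),
        record_ids=corpus.record_ids,
        empty_mask=empty_mask,
    )


class RelevanceModel:
    """Multinomial naive Bayes over TF-IDF weights; exposes P(relevant)."""

    def __init__(self, clf: MultinomialNB):
        self._clf = clf
        self._rel_col = int(np.where(clf.classes_ == 1)[0][0])

    def predict_relevance(self, X: sp.csr_matrix) -> np.ndarray:
        return self._clf.predict_proba(X)[:, self._rel_col]


def fit_classifier(
    features: FeatureMatrix,
    labeled: dict[str, int] | list[tuple[str, int]],
    *,
    alpha: float = 1.0,
) -> RelevanceModel:
    """Fit the relevance model on the labeled subset.

    Requires at least one record of each class; additive smoothing ``alpha``
    defaults to 1.0.  A list of (record_id, label) pairs may contain
    repeats (each occurrence counts as one training document); a mapping
    cannot.
    """
    pairs = list(labeled.items()) if isinstance(labeled, dict) else list(labeled)
    if len({lab for _, lab in pairs}) < 2:
        raise ValueError("training set must contain both classes")
    idx = features.row_index
    rows = [idx[rid] for rid, _ in pairs]
    y = np.array([lab for _, lab in pairs])
    clf = MultinomialNB(alpha=alpha)
    clf.fit(features.X[rows], y)
    return RelevanceModel(clf)


def rank_unlabeled(
    model: RelevanceModel, features: FeatureMatrix, unlabeled: list[str] | set[str]
) -> list[str]:
    """Unscreened records in descending P(relevant).

    Ties break by ascending corpus row order, so rankings are deterministic.
    Records with no usable text are always placed last (among themselves,
    again in corpus order).
    """
    if not unlabeled:
        raise ValueError("no unlabeled records to rank")
    idx = features.row_index
    rows = np.array(sorted(idx[rid] for rid in unlabeled))
    p = model.predict_relevance(features.X[rows])
    p = np.where(features.empty_mask[rows], -np.inf, p)
    order = np.argsort(-p, kind="stable")  # stable keeps ascending-row tie-break
    return [features.record_ids[r] for r in rows[order]]


def draw_prior(
    corpus: Corpus,
    f: float,
    seed: int,
    *,
    policy: str = "resample",
    max_resamples: int = 1000,
) -> PriorSample:
    """Draw the initial random training subset of size max(2, round(f*N)).

    With ``policy="resample"`` (default), a sample that lacks a relevant or
    lacks an irrelevant record is redrawn with an incremented sub-seed, up to
    ``max_resamples`` times; the number of redraws is recorded because it
    biases r_s upward at tiny f.  ``policy="accept-degenerate"`` keeps the
    first draw regardless (the criterion-1 estimator may then be 0 or N).
    """
    if not 0 < f < 1:
        raise ValueError(f"prior fraction must be in (0,1), got {f}")
    if policy not in ("resample", "accept-degenerate"):
        raise ValueError(f"unknown prior policy {policy!r}")
    n_s = max(2, int(round_half_up(f * corpus.N)))
    ids = np.array(corpus.record_ids)
    labels = np.array(corpus.labels)
    for attempt in range(max_resamples + 1):
        rng = np.random.default_rng([seed, attempt])
        pick = rng.choice(corpus.N, size=n_s, replace=False)
        r_s = int(labels[pick].sum())
        if policy == "accept-degenerate" or 0 < r_s < n_s:
            return PriorSample(
                record_ids=tuple(ids[pick]),
                n_s=n_s,
                r_s=r_s,
                f=f,
                n_resamples=attempt,
            )
    raise ValueError(
        f"could not draw a two-class prior sample in {max_resamples} attempts "
        f"(N={corpus.N}, R={corpus.R}, n_s={n_s})"
    )


def simulate_screening(
    corpus: Corpus,
    f: float,
    seed: int,
    *,
    retrain_every: int = 1,
    alpha: float = 1.0,
    prior_policy: str = "resample",
) -> Trajectory:
    """Run one full simulated screening and record the trajectory.

    Prior phase: the ``draw_prior`` sample, screened in sampling order.
    Active phase: retrain on all revealed labels every ``retrain_every``
    reveals, consuming the current ranking between retrains, until all N
    records are revealed.  If the labeled pool is single-class at a retrain
    point (possible under ``prior_policy="accept-degenerate"``), records are
    consumed in corpus order until both classes have been seen.
    """
    corpus.validate_for_screening()
    if retrain_every < 1:
        raise ValueError("retrain_every must be >= 1")
    features = featurize(corpus)
    prior = draw_prior(corpus, f, seed, policy=prior_policy)

    oracle = {rec.record_id: rec.label for rec in corpus}
    steps: list[tuple[str, int]] = [(rid, oracle[rid]) for rid in prior.record_ids]
    revealed: dict[str, int] = dict(steps)
    unlabeled = [rid for rid in corpus.record_ids if rid not in revealed]

    while unlabeled:
        if len(set(revealed.values())) < 2:
            # degenerate labeled pool: no model can be fit yet
            batch = unlabeled[:retrain_every]
        else:
            model = fit_classifier(features, revealed, alpha=alpha)
            ranking = rank_unlabeled(model, features, unlabeled)
            batch = ranking[:retrain_every]
        for rid in batch:
            steps.append((rid, oracle[rid]))
            revealed[rid] = oracle[rid]
        remaining = set(batch)
        unlabeled = [rid for rid in unlabeled if rid not in remaining]

    return Trajectory(
        steps=steps,
        prior_len=prior.n_s,
        N=corpus.N,
        R=corpus.R,
        seed=seed,
        dataset=corpus.name,
        f=f,
        prior=prior,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Serialize one row per screening step, with run metadata in a header."""
    path = Path(path)
    meta = (
        f"# dataset={traj.dataset} f={traj.f} seed={traj.seed} "
        f"N={traj.N} R={traj.R} prior_len={traj.prior_len}"
    )
    if traj.prior is not None:
        meta += (
            f" n_s={traj.prior.n_s} r_s={traj.prior.r_s}"
            f" n_resamples={traj.prior.n_resamples}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(meta + "\n")
        traj.to_frame().to_csv(fh, index=False)
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        df = pd.read_csv(fh, dtype={"record_id": str})
    traj = Trajectory.from_frame(
        df,
        seed=int(meta["seed"]) if meta.get("seed", "None") != "None" else None,
        dataset=meta.get("dataset", "corpus"),
        f=float(meta["f"]) if meta.get("f", "None") != "None" else None,
    )
    if "n_s" in meta:
        traj.prior = PriorSample(
            record_ids=tuple(df["record_id"][: traj.prior_len]),
            n_s=int(meta["n_s"]),
            r_s=int(meta["r_s"]),
            f=traj.f if traj.f is not None else 0.0,
            n_resamples=int(meta.get("n_resamples", 0)),
        )
    return traj
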