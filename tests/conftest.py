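import numpy as np
import pytest

from screenstop import Corpus, LabeledRecord, Trajectory


def make_trajectory(labels, prior_len=0, dataset="toy", f=None, seed=0):
    """Build a Trajectory directly from a 0/1 label sequence."""
    labels = list(labels)
    return Trajectory(
        steps=[(f"r{i}", int(lab)) for i, lab in enumerate(labels)],
        prior_len=prior_len,
        N=len(labels),
        R=sum(labels),
        seed=seed,
        dataset=dataset,
        f=f,
    )


def make_corpus(labels, text_fn=None, name="toy"):
    """Corpus with given labels; texts default to distinct single tokens."""
    if text_fn is None:
        text_fn = lambda i, lab: f"token{i:03d} filler"
    return Corpus(
        [
            LabeledRecord(f"r{i}", "", text_fn(i, lab), int(lab))
            for i, lab in enumerate(labels)
        ],
        name=name,
    )


@pytest.fixture
def tiny_corpus():
    return make_corpus([1, 0, 0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# --- independent brute-force oracles (pure python, no package internals) ----


def brute_stop_at_count(labels, r_hat):
    """First 1-based position where cumulative relevants reach r_hat."""
    if r_hat == 0:
        return 0
    seen = 0
    for pos, lab in enumerate(labels, start=1):
        seen += lab
        if seen >= r_hat:
            return pos
    return len(labels)


def brute_stop_at_streak(labels, c, start=0):
    """1-based position where a run of c consecutive 0s completes."""
    streak = 0
    for pos in range(start, len(labels)):
        streak = 0 if labels[pos] == 1 else streak + 1
        if streak == c:
            return pos + 1
    return len(labels)


def brute_max_interior_gap(labels):
    """Largest run of 0s strictly between two 1s."""
    rel = [i for i, lab in enumerate(labels) if lab == 1]
    return max((b - a - 1 for a, b in zip(rel, rel[1:])), default=0)


def brute_last_relevant_pct(labels):
    rel = [i for i, lab in enumerate(labels) if lab == 1]
    return (rel[-1] + 1) / len(labels) * 100
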