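"""Featurization, the relevance model, prior sampling, and the loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenstop import (
    Corpus,
    LabeledRecord,
    SyntheticSpec,
    draw_prior,
    featurize,
    fit_classifier,
    generate_corpus,
    rank_unlabeled,
    read_trajectory,
    simulate_screening,
    write_trajectory,
)
from tests.conftest import make_corpus


def _corpus(texts, labels):
    return Corpus(
        [LabeledRecord(f"r{i}", "", t, lab) for i, (t, lab) in enumerate(zip(texts, labels))]
    )


class TestFeaturize:
    def test_single_term_record_has_unit_weight(self):
        c = _corpus(["gene gene gene", "protein"], [1, 0])
        fm = featurize(c)
        row = fm.X[0].toarray().ravel()
        assert row[fm.vocabulary["gene"]] == pytest.approx(1.0)
        assert np.count_nonzero(row) == 1

    def test_identical_records_identical_rows(self):
        c = _corpus(["alpha beta", "alpha beta"], [1, 0])
        fm = featurize(c)
        assert np.allclose(fm.X[0].toarray(), fm.X[1].toarray())

    def test_weights_match_hand_computed_tfidf(self):
        """Brute-force tf * (ln((1+N)/(1+df)) + 1), L2-normalized."""
        c = _corpus(["alpha beta", "alpha alpha"], [1, 0])
        fm = featurize(c)
        n = 2
        idf = {"alpha": math.log((1 + n) / (1 + 2)) + 1, "beta": math.log((1 + n) / (1 + 1)) + 1}
        # doc 0: tf alpha=1, beta=1 ; doc 1: tf alpha=2
        raw0 = np.array([1 * idf["alpha"], 1 * idf["beta"]])
        exp0 = raw0 / np.linalg.norm(raw0)
        row0 = fm.X[0].toarray().ravel()
        assert row0[fm.vocabulary["alpha"]] == pytest.approx(exp0[0])
        assert row0[fm.vocabulary["beta"]] == pytest.approx(exp0[1])
        assert fm.X[1].toarray().ravel()[fm.vocabulary["alpha"]] == pytest.approx(1.0)

    def test_short_tokens_dropped_and_lowercased(self):
        c = _corpus(["A B Gene-X", "other words"], [1, 0])
        fm = featurize(c)
        assert "a" not in fm.vocabulary and "b" not in fm.vocabulary
        assert "gene" in fm.vocabulary

    def test_all_empty_corpus_rejected(self):
        c = Corpus([LabeledRecord("a", "", "", 1), LabeledRecord("b", " ", "", 0)])
        with pytest.raises(ValueError):
            featurize(c)


class TestClassifier:
    def test_disjoint_vocab_posterior_separates(self):
        c = _corpus(["relevant topic terms", "unrelated background noise"], [1, 0])
        fm = featurize(c)
        model = fit_classifier(fm, {"r0": 1, "r1": 0})
        p = model.predict_relevance(fm.X)
        assert p[0] > 0.5 > p[1]

    def test_probabilities_sum_to_one(self):
        c = _corpus(["alpha beta", "beta gamma", "gamma delta"], [1, 0, 0])
        fm = featurize(c)
        model = fit_classifier(fm, {"r0": 1, "r1": 0})
        p = model.predict_relevance(fm.X)
        assert np.all((0 <= p) & (p <= 1))

    def test_single_class_training_rejected(self):
        c = _corpus(["alpha", "beta"], [1, 0])
        fm = featurize(c)
        with pytest.raises(ValueError):
            fit_classifier(fm, {"r0": 1})

    def test_duplicated_training_set_preserves_ranking(self):
        """Training on each record twice rescales class counts but cannot
        reorder the scored test set: doubled counts leave the per-class term
        distributions unchanged.  Exact only up to additive smoothing, so
        the check uses a negligible alpha (refit-and-compare oracle)."""
        corpus = generate_corpus(SyntheticSpec(N=60, R=6, seed=5))
        fm = featurize(corpus)
        ids = corpus.record_ids
        pairs = [(rid, corpus[rid].label) for rid in ids[:20]]
        rest = ids[20:]
        base = rank_unlabeled(fit_classifier(fm, pairs, alpha=1e-10), fm, rest)
        ranked2 = rank_unlabeled(fit_classifier(fm, pairs * 2, alpha=1e-10), fm, rest)
        assert base == ranked2


class TestRanking:
    def test_pure_tie_break_is_corpus_order(self):
        c = _corpus(["same text"] * 4 + ["other thing"], [1, 0, 0, 0, 0])
        fm = featurize(c)
        model = fit_classifier(fm, {"r0": 1, "r4": 0})
        assert rank_unlabeled(model, fm, ["r3", "r1", "r2"]) == ["r1", "r2", "r3"]

    def test_singleton(self):
        c = _corpus(["alpha", "beta"], [1, 0])
        fm = featurize(c)
        model = fit_classifier(fm, {"r0": 1, "r1": 0})
        assert rank_unlabeled(model, fm, ["r1"]) == ["r1"]

    def test_empty_text_records_ranked_last(self):
        c = Corpus(
            [
                LabeledRecord("a", "", "alpha topic", 1),
                LabeledRecord("empty", "", "", 0),
                LabeledRecord("b", "", "beta other", 0),
            ]
        )
        fm = featurize(c)
        model = fit_classifier(fm, {"a": 1, "b": 0})
        assert rank_unlabeled(model, fm, ["empty", "b"])[-1] == "empty"


class TestDrawPrior:
    @pytest.mark.parametrize("f,N,expected", [(0.20, 10, 2), (0.01, 2873, 29), (0.01, 150, 2)])
    def test_sample_size_rule(self, f, N, expected):
        c = make_corpus([1] * (N // 4) + [0] * (N - N // 4))
        assert draw_prior(c, f, seed=0).n_s == expected

    def test_deterministic_given_seed(self):
        c = make_corpus([1] * 10 + [0] * 90)
        assert draw_prior(c, 0.1, seed=7) == draw_prior(c, 0.1, seed=7)

    def test_resample_guarantees_both_classes(self):
        c = make_corpus([1] + [0] * 199)  # 0.5% prevalence
        for seed in range(30):
            s = draw_prior(c, 0.02, seed=seed)
            assert 0 < s.r_s < s.n_s

    def test_accept_degenerate_keeps_first_draw(self):
        c = make_corpus([1] + [0] * 199)
        samples = [draw_prior(c, 0.02, seed=s, policy="accept-degenerate") for s in range(50)]
        assert all(s.n_resamples == 0 for s in samples)
        assert any(s.r_s == 0 for s in samples)  # degenerate draws do occur

    def test_impossible_sample_errors(self):
        # R=0 can never satisfy the two-class requirement
        with pytest.raises(ValueError):
            draw_prior(make_corpus([0] * 10), 0.3, seed=0, max_resamples=5)


class TestSimulateScreening:
    def test_trajectory_is_permutation_with_label_sum_R(self):
        corpus = generate_corpus(SyntheticSpec(N=80, R=8, seed=2))
        traj = simulate_screening(corpus, 0.1, seed=4)
        assert sorted(traj.record_ids) == sorted(corpus.record_ids)
        assert traj.labels.sum() == corpus.R
        assert traj.prior_len == traj.prior.n_s

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(
        n=st.integers(30, 70),
        r=st.integers(2, 6),
        seed=st.integers(0, 10_000),
        f=st.sampled_from([0.05, 0.1, 0.2]),
    )
    def test_permutation_property(self, n, r, seed, f):
        corpus = generate_corpus(SyntheticSpec(N=n, R=r, seed=seed % 97))
        traj = simulate_screening(corpus, f, seed=seed)
        assert sorted(traj.record_ids) == sorted(corpus.record_ids)
        assert traj.labels.sum() == r

    def test_separable_relevants_fill_first_active_positions(self):
        corpus = generate_corpus(
            SyntheticSpec(N=200, R=10, separability=1.0, hard_fraction=0.0, seed=6)
        )
        traj = simulate_screening(corpus, 0.05, seed=6)
        remaining = corpus.R - traj.labels[: traj.prior_len].sum()
        assert traj.labels[traj.prior_len : traj.prior_len + remaining].sum() == remaining

    def test_identical_config_identical_trajectory(self):
        corpus = generate_corpus(SyntheticSpec(N=60, R=5, seed=8))
        a = simulate_screening(corpus, 0.1, seed=9)
        b = simulate_screening(corpus, 0.1, seed=9)
        assert a.steps == b.steps

    def test_small_batching_does_not_change_separable_results(self):
        """Retraining every <=5 reveals must not reorder a fully separable
        corpus: relevants still occupy the first active positions."""
        corpus = generate_corpus(
            SyntheticSpec(N=150, R=8, separability=1.0, hard_fraction=0.0, seed=10)
        )
        for batch in (1, 3, 5):
            traj = simulate_screening(corpus, 0.05, seed=10, retrain_every=batch)
            remaining = corpus.R - traj.labels[: traj.prior_len].sum()
            assert traj.labels[traj.prior_len : traj.prior_len + remaining].sum() == remaining

    def test_trajectory_roundtrip(self, tmp_path):
        corpus = generate_corpus(SyntheticSpec(N=40, R=4, seed=1))
        traj = simulate_screening(corpus, 0.1, seed=2)
        back = read_trajectory(write_trajectory(traj, tmp_path / "t.csv"))
        assert back.steps == traj.steps
        assert back.prior_len == traj.prior_len
        assert (back.prior.n_s, back.prior.r_s) == (traj.prior.n_s, traj.prior.r_s)
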