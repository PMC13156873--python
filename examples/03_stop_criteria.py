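"""Score the three early-stopping rules on one recorded trajectory.

Each rule is applied retrospectively: the trajectory already contains the
oracle labels, so we can say exactly how many relevant records a rule would
have missed and how much screening work it would have saved.
"""

from screenstop import (
    SyntheticSpec,
    apply_criterion1,
    apply_criterion2,
    apply_criterion3,
    estimate_relevant_total,
    generate_corpus,
    simulate_screening,
)

corpus = generate_corpus(
    SyntheticSpec(N=500, R=30, separability=0.8, hard_fraction=0.1, seed=12, name="common")
)
traj = simulate_screening(corpus, f=0.05, seed=3)

r_hat = estimate_relevant_total(traj.prior.n_s, traj.prior.r_s, traj.N)
for label, outcome in [
    (f"criterion 1 (stop at R_hat={r_hat} relevants found)", apply_criterion1(traj, r_hat)),
    ("criterion 2 (stop after 50 consecutive irrelevants)", apply_criterion2(traj, 50)),
    ("criterion 3 (stop after screening 40% of corpus)", apply_criterion3(traj, 0.40)),
]:
    print(f"{label}:")
    print(
        f"  stopped after {outcome.stop_index}/{traj.N} records, "
        f"recall {outcome.recall:.2f}, missed {outcome.missed} relevant, "
        f"work saved {outcome.work_saved_pct:.1f}%"
    )
# recall < 1 means the rule would have excluded truly relevant studies;
# work saved is the share of the corpus never screened.
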