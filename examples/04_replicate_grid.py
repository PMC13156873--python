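"""Run a small replicate grid and render the three summary tables.

The grid crosses datasets x prior fractions x replicates, screens every
combination, and aggregates the per-run statistics: the criterion-1
relative estimation error (table t3), the percentage screened to find all
relevant records (t4), and the minimal safe criterion-2 streak (t5).
This scaled-down grid finishes in about a minute; the full study design
(7 fractions x 1000 replicates per dataset) is just configuration.
"""

from pathlib import Path

from screenstop import RunConfig, run_grid

config = RunConfig(
    datasets=[
        {"synthetic": {"N": 300, "R": 3, "seed": 11, "name": "rare"}},
        {"synthetic": {"N": 300, "R": 18, "seed": 12, "name": "common"}},
    ],
    prior_fractions=[0.05, 0.10],
    replicates=5,
    base_seed=0,
    c2_thresholds=[10, 50],
    c3_percentages=[0.4, 0.8],
)
out = run_grid(config, Path("grid_run"))
print(f"{config.n_trajectories} trajectories -> {out}/")
for t in ("t3", "t4", "t5"):
    print()
    print((out / f"table_{t}.txt").read_text())
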