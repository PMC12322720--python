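"""A small density × exposure simulation study.

Runs the ground-truth evaluation harness over the three coverage regimes at
both exposure conditions with a handful of seeds (the full 20-seed study is
`nwloc study --seed 1 --out study/` or `scripts/acceptance.py`), prints the
summary table, and saves a plot.
"""

from nwloc.evaluate import plot_study, run_simulation_study, summarize_study

results = run_simulation_study(n_seeds=5, seed=42)
summary = summarize_study(results)

cols = ["density", "exposure_ms", "variant", "jaccard_mean", "jaccard_sd",
        "fp_fraction", "recall_mean"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

plot_study(summary, "study.png")
print("\nwrote study.png")

full = summary[(summary["variant"] == "full")
               & (summary["exposure_ms"] == 100.0)]
print(f"min mean JI (full, 100 ms): {full['jaccard_mean'].min():.3f}")
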